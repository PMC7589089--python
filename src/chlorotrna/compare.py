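"""Cross-genome and cross-clade comparison of tRNA inventories.

Identity granularity is (amino acid, cognate codon) — the column semantics of
clade survey tables.  Cross-clade categories (common to all clades, shared by
a clade pair, unique to one clade) are computed at identity level, because
gene copies in different clades have no locus correspondence to match.  For
identities unique to ONE clade the member loci are distinguishable within
that clade's synteny, so the unique GENE count expands each unique identity
by the largest per-genome copy number observed in the clade (two clade-private
Thr-ACG loci count as two unique genes, not one).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from Bio.Seq import Seq
from Bio.SeqIO import write as seqio_write
from Bio.SeqRecord import SeqRecord

from .annotations import GenomeRecord
from .trna import TrnaGene, build_inventory


class CompareError(ValueError):
    pass


@dataclass
class PresenceMatrix:
    """(identity x genome) incidence with a genome->clade mapping."""

    matrix: pd.DataFrame  # bool; index: identity labels, columns: genome ids
    clade_map: dict[str, str]
    include_pseudogenes: bool = True

    @property
    def identities(self) -> list[str]:
        return list(self.matrix.index)

    def incidence(self, identity: str) -> int:
        if identity not in self.matrix.index:
            return 0
        return int(self.matrix.loc[identity].sum())

    def clade_presence(self, identity: str) -> set[str]:
        if identity not in self.matrix.index:
            return set()
        row = self.matrix.loc[identity]
        return {self.clade_map[g] for g in self.matrix.columns if row[g]}


@dataclass
class SharedUniqueSummary:
    common_all_clades: set[str]
    unique_per_clade: dict[str, set[str]]
    shared_pairs: dict[frozenset, set[str]]
    unique_locus_counts: dict[str, int] = field(default_factory=dict)

    @property
    def clades(self) -> set[str]:
        return set(self.unique_per_clade)


def presence_matrix(
    inventories: dict[str, list[TrnaGene]],
    clade_map: dict[str, str],
    include_pseudogenes: bool = True,
) -> PresenceMatrix:
    """Build the identity-by-genome presence matrix."""
    for gid in inventories:
        if gid not in clade_map:
            raise CompareError(f"genome {gid!r} missing from clade map")
    identities: list[str] = []
    seen = set()
    for genes in inventories.values():
        for g in genes:
            if g.identity and g.label not in seen:
                seen.add(g.label)
                identities.append(g.label)
    data = {
        gid: [
            any(
                g.identity is not None
                and g.label == ident
                and (include_pseudogenes or not g.pseudogene)
                for g in genes
            )
            for ident in identities
        ]
        for gid, genes in inventories.items()
    }
    matrix = pd.DataFrame(data, index=identities, dtype=bool)
    return PresenceMatrix(
        matrix=matrix,
        clade_map={g: clade_map[g] for g in inventories},
        include_pseudogenes=include_pseudogenes,
    )


def _max_copies_in_clade(
    inventories: dict[str, list[TrnaGene]],
    clade_map: dict[str, str],
    clade: str,
    identity: str,
) -> int:
    best = 0
    for gid, genes in inventories.items():
        if clade_map[gid] != clade:
            continue
        n = sum(1 for g in genes if g.identity and g.label == identity)
        best = max(best, n)
    return best


def clade_shared_unique(
    matrix: PresenceMatrix,
    inventories: dict[str, list[TrnaGene]] | None = None,
) -> SharedUniqueSummary:
    """Partition identities into common-to-all / pair-shared / clade-unique.

    An identity is clade-present if any member genome carries it.  When the
    per-genome inventories are supplied, ``unique_locus_counts`` additionally
    counts clade-private duplicated loci separately (see module docstring);
    otherwise the locus counts equal the unique identity counts.
    """
    clades = sorted(set(matrix.clade_map.values()))
    if len(clades) < 2:
        raise CompareError("need at least two clades to compare")
    presence: dict[str, set[str]] = {
        ident: matrix.clade_presence(ident) for ident in matrix.identities
    }
    common_all = {i for i, cl in presence.items() if cl == set(clades)}
    unique = {c: {i for i, cl in presence.items() if cl == {c}} for c in clades}
    shared_pairs: dict[frozenset, set[str]] = {}
    for ident, cl in presence.items():
        if len(cl) == 2:
            shared_pairs.setdefault(frozenset(cl), set()).add(ident)
    locus_counts = {}
    for c in clades:
        if inventories is None:
            locus_counts[c] = len(unique[c])
        else:
            locus_counts[c] = sum(
                max(1, _max_copies_in_clade(inventories, matrix.clade_map, c, ident))
                for ident in unique[c]
            )
    return SharedUniqueSummary(
        common_all_clades=common_all,
        unique_per_clade=unique,
        shared_pairs=shared_pairs,
        unique_locus_counts=locus_counts,
    )


def gene_order_similarity(order_a: list[str], order_b: list[str]) -> float:
    """Normalized longest-common-subsequence synteny score in [0, 1]:
    2*LCS(a,b) / (|a| + |b|); 1 for identical orders, 0 for label-disjoint."""
    if not order_a and not order_b:
        return 1.0
    if not order_a or not order_b:
        return 0.0
    n, m = len(order_a), len(order_b)
    prev = [0] * (m + 1)
    for i in range(1, n + 1):
        cur = [0] * (m + 1)
        for j in range(1, m + 1):
            if order_a[i - 1] == order_b[j - 1]:
                cur[j] = prev[j - 1] + 1
            else:
                cur[j] = max(prev[j], cur[j - 1])
        prev = cur
    return 2.0 * prev[m] / (n + m)


def concatenate_markers(
    genomes: list[GenomeRecord],
    markers: list[str],
    fasta_path=None,
) -> list[SeqRecord]:
    """Concatenate spliced marker tRNA gene sequences per genome.

    Genomes missing any marker are skipped with a warning (mirroring marker-
    based phylogenies that drop taxa lacking a marker); when a genome has
    several copies of a marker the first in genome order is used.
    """
    import warnings

    if not markers:
        raise CompareError("empty marker list")
    out: list[SeqRecord] = []
    for rec in genomes:
        inventory = build_inventory(rec)
        parts: list[str] = []
        ok = True
        for marker in markers:
            copies = [g for g in inventory if g.identity and g.label == marker]
            if not copies:
                warnings.warn(
                    f"{rec.id}: missing marker {marker}; genome skipped", stacklevel=2
                )
                ok = False
                break
            if len(copies) > 1:
                warnings.warn(
                    f"{rec.id}: {len(copies)} copies of {marker}; first in genome "
                    "order used",
                    stacklevel=2,
                )
            parts.append(copies[0].spliced_sequence)
        if ok:
            out.append(
                SeqRecord(Seq("".join(parts)), id=rec.id,
                          description=f"concatenated:{'+'.join(markers)}")
            )
    if fasta_path is not None:
        with open(fasta_path, "w") as fh:
            seqio_write(out, fh, "fasta")
    return out


def summary_stats(
    inventories: dict[str, list[TrnaGene]],
    clade_map: dict[str, str] | None = None,
) -> dict:
    """Cohort-level summary: totals, distinct identities/amino acids,
    per-genome strand uniformity, per-identity incidence."""
    n_genomes = len(inventories)
    total = sum(len(v) for v in inventories.values())
    identities = sorted(
        {g.label for v in inventories.values() for g in v if g.identity}
    )
    amino_acids = sorted({i.split("-")[0] for i in identities})
    strand_uniform = {
        gid: len({g.strand for g in genes}) <= 1 for gid, genes in inventories.items()
    }
    incidence = {
        ident: sum(
            1
            for genes in inventories.values()
            if any(g.identity and g.label == ident for g in genes)
        )
        for ident in identities
    }
    return {
        "n_genomes": n_genomes,
        "total_trna_genes": total,
        "distinct_identities": len(identities),
        "identities": identities,
        "distinct_amino_acids": len(amino_acids),
        "amino_acids": amino_acids,
        "strand_uniform": strand_uniform,
        "all_same_strand": all(strand_uniform.values()),
        "identity_incidence": incidence,
        "per_genome_counts": {gid: len(v) for gid, v in inventories.items()},
        "clade_map": dict(clade_map or {}),
    }
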