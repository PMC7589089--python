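"""Synthetic host and virus genomes with fully known ground truth.

The generator emulates the statistical structure of the study system: an
AT-rich virus (~40% GC) whose CDS codons are drawn i.i.d. from a configured
codon-frequency table, carrying one tRNA gene cluster with short (1 to ~30 nt)
intergenic spacers on a single strand, optionally interrupted by a CDS,
with pseudogenes, a tRNA-Tyr intron one nucleotide 3' of the anticodon, and an
orphan tRNA tens of kb downstream; and a GC-rich host (~67% GC coding bias)
with no tRNA cluster.  Every emitted gene is recorded in a
:class:`TruthRecord` so that parsers, inventory building and cluster detection
can be checked against exact ground truth.

tRNA genes are built on a fixed 73 nt scaffold (a canonical cytosolic tRNA
gene body without the 3' CCA, which chlorovirus tRNA genes do not encode):
the anticodon sits at positions 34-36, the internal RNA polymerase III Box A
and Box B promoter elements are embedded at fixed offsets (A 5' of B), and an
optional intron is inserted starting one exonic nucleotide 3' of the
anticodon.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotations import GenomeRecord, GenomicFeature, write_genbank, write_gff3_fasta
from .genetic import SENSE_CODONS_DNA, codon_amino_acid3, dna, revcomp_rna, rna
from .trna import BoxMotifConfig

# 73 nt tRNA gene scaffold (yeast tRNA-Phe body, CCA-less).  Anticodon at
# 34-36 (GAA here, replaced per gene); Box A matches TRGCNNARYNN at offset 7,
# Box B matches GTTCGANNCNN at offset 52 (0-based).
SCAFFOLD = (
    "GCGGATTTAGCTCAGTTGGGAGAGCGCCAGACTGAAGATCTGGAGGTCCTGTGTTCGATCCACAGAATTCGCA"
)
ANTICODON_OFFSET = 33  # 0-based start of the anticodon triplet
BOX_A_OFFSET = 7
BOX_B_OFFSET = 52


class SimulationError(ValueError):
    pass


@dataclass
class ClusterEntry:
    """One tRNA gene of a cluster spec."""

    amino_acid: str
    anticodon: str  # RNA 5'->3'
    pseudogene: bool = False
    intron: tuple[int, int] | None = None  # (offset 3' of anticodon, length)


@dataclass
class OrphanEntry:
    amino_acid: str
    anticodon: str
    distance_nt: int  # intergenic gap beyond the cluster 3' end


@dataclass
class ClusterSpec:
    """Gene order, spacers, interruptions and orphans of a simulated cluster."""

    entries: list[ClusterEntry]
    spacers: list[int]
    interrupting_cds: dict[int, int] = field(default_factory=dict)  # junction -> CDS len
    strand: str = "+"
    offset_fraction: float = 0.45  # cluster start as a fraction of genome length
    orphans: list[OrphanEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.spacers) != len(self.entries) - 1:
            raise SimulationError("need exactly one spacer per gene junction")
        if any(s < 0 for s in self.spacers):
            raise SimulationError("spacers must be non-negative")
        for j, cds_len in self.interrupting_cds.items():
            if not 0 <= j < len(self.spacers):
                raise SimulationError(f"interrupting CDS at bad junction {j}")
            if self.spacers[j] < cds_len + 2:
                raise SimulationError(
                    f"junction {j} spacer {self.spacers[j]} cannot hold a "
                    f"{cds_len} nt CDS"
                )


@dataclass
class GenomeSimConfig:
    seed: int
    genome_length: int = 60_000
    cds_count: int = 25
    cds_length_codons: tuple[int, int] = (100, 350)
    codon_table: pd.Series | None = None  # percent per RNA codon; None = uniform
    gc_intergenic: float = 40.0  # percent target for non-coding sequence
    cluster: ClusterSpec | None = None
    clade: str = "other"
    genome_id: str = "synthetic"


@dataclass
class TruthGene:
    label: str
    amino_acid: str
    codon: str
    anticodon: str
    start: int
    end: int
    strand: str
    pseudogene: bool
    intron_offset: int | None
    intron_length: int | None
    in_cluster: bool
    orphan_distance: int | None


@dataclass
class TruthRecord:
    """Exact ground truth for every emitted tRNA gene."""

    genome_id: str
    clade: str
    genome_length: int
    genes: list[TruthGene]
    spacers: list[int]
    cluster_span: tuple[int, int] | None
    n_cds: int
    interrupting_cds_junctions: list[int]

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=1, sort_keys=True))
        return path

    @staticmethod
    def from_json(path: str | Path) -> "TruthRecord":
        raw = json.loads(Path(path).read_text())
        raw["genes"] = [TruthGene(**g) for g in raw["genes"]]
        raw["cluster_span"] = tuple(raw["cluster_span"]) if raw["cluster_span"] else None
        return TruthRecord(**raw)


# ---------------------------------------------------------------------------
# sequence builders
# ---------------------------------------------------------------------------


def _random_sequence(n: int, gc_percent: float, rng: np.random.Generator) -> str:
    g = gc_percent / 200.0
    a = (100.0 - gc_percent) / 200.0
    return "".join(rng.choice(list("ACGT"), size=n, p=[a, g, g, a]))


def generate_trna_gene_sequence(
    amino_acid: str,
    anticodon: str,
    intron: tuple[int, int] | None = None,
    pseudogene: bool = False,
    boxes: BoxMotifConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[str, list[tuple[int, int]] | None]:
    """Build one tRNA gene (DNA, coding strand) on the fixed scaffold.

    Returns (sequence, local exon intervals or None).  The identity must be
    consistent: reverse-complement(anticodon) must be a sense codon for
    ``amino_acid``.  An intron (offset, length) is inserted ``offset`` exonic
    nt 3' of the anticodon; pseudogenes get a two-base anticodon-loop
    disruption adjacent to the (intact) anticodon triplet.
    """
    rng = rng or np.random.default_rng(0)
    codon = revcomp_rna(rna(anticodon))
    if codon_amino_acid3(codon) != amino_acid:
        raise SimulationError(
            f"anticodon {anticodon} reads {codon} which is not a {amino_acid} codon"
        )
    seq = SCAFFOLD[:ANTICODON_OFFSET] + dna(anticodon) + SCAFFOLD[ANTICODON_OFFSET + 3 :]
    if pseudogene:
        # disrupt the anticodon loop just 5' of the anticodon (positions 31-32,
        # outside both promoter boxes and the anticodon itself)
        loop = seq[30:32]
        repl = "TT" if loop != "TT" else "AA"
        seq = seq[:30] + repl + seq[32:]
    if intron is None:
        return seq, None
    offset, length = intron
    if offset < 0 or length < 1:
        raise SimulationError("intron offset must be >= 0 and length >= 1")
    cut = ANTICODON_OFFSET + 3 + offset  # 0-based: intron starts after this many nt
    intron_seq = _random_sequence(length, 45.0, rng)
    full = seq[:cut] + intron_seq + seq[cut:]
    exons = [(1, cut), (cut + length + 1, len(full))]
    return full, exons


def _make_cds(n_codons: int, codon_probs: pd.Series, rng: np.random.Generator) -> str:
    codons = rng.choice(codon_probs.index.to_numpy(), size=n_codons, p=codon_probs.to_numpy())
    return "ATG" + "".join(dna(c) for c in codons) + "TAA"


def _codon_probs(table: pd.Series | None) -> pd.Series:
    if table is None:
        table = pd.Series(100.0 / 61, index=[rna(c) for c in SENSE_CODONS_DNA])
    probs = table.astype(float)
    if abs(probs.sum() - 100.0) > 1.0 and abs(probs.sum() - 1.0) > 0.1:
        raise SimulationError("codon table must be percentages (sum ~100)")
    return probs / probs.sum()


# ---------------------------------------------------------------------------
# genome assembly
# ---------------------------------------------------------------------------


def _fill_with_cds(
    length: int,
    n_cds: int,
    config: GenomeSimConfig,
    probs: pd.Series,
    rng: np.random.Generator,
    feature_offset: int,
    id_prefix: str,
) -> tuple[str, list[GenomicFeature]]:
    """Fill a region of exactly ``length`` nt with up to n_cds CDSs separated
    by intergenic sequence."""
    parts: list[str] = []
    feats: list[GenomicFeature] = []
    pos = 0  # 0-based within region
    placed = 0
    lo, hi = config.cds_length_codons
    while placed < n_cds:
        gap = int(rng.integers(120, 400))
        n_codons = int(rng.integers(lo, hi + 1))
        cds_len = 3 * n_codons + 6
        if pos + gap + cds_len > length:
            break
        parts.append(_random_sequence(gap, config.gc_intergenic, rng))
        start = feature_offset + pos + gap + 1
        parts.append(_make_cds(n_codons, probs, rng))
        feats.append(
            GenomicFeature(
                feature_id=f"{id_prefix}_cds{placed + 1}",
                kind="CDS",
                start=start,
                end=start + cds_len - 1,
                strand="+",
                qualifiers={"product": "hypothetical protein"},
            )
        )
        pos += gap + cds_len
        placed += 1
    parts.append(_random_sequence(length - pos, config.gc_intergenic, rng))
    return "".join(parts), feats


def _trna_feature(
    entry: ClusterEntry | OrphanEntry,
    start: int,
    strand: str,
    seq_len: int,
    exons: list[tuple[int, int]] | None,
    fid: str,
) -> GenomicFeature:
    end = start + seq_len - 1
    quals = {
        "product": f"tRNA-{entry.amino_acid}",
        "anticodon": dna(entry.anticodon).lower(),
    }
    if getattr(entry, "pseudogene", False):
        quals["pseudo"] = ""
    genomic_exons = None
    if exons:
        if strand == "+":
            genomic_exons = [(start + s - 1, start + e - 1) for s, e in exons]
        else:
            genomic_exons = sorted((end - e + 1, end - s + 1) for s, e in exons)
    return GenomicFeature(
        feature_id=fid,
        kind="tRNA",
        start=start,
        end=end,
        strand=strand,
        qualifiers=quals,
        exons=genomic_exons,
    )


def generate_virus_genome(config: GenomeSimConfig) -> tuple[GenomeRecord, TruthRecord]:
    """Simulate one annotated virus genome plus its exact truth record.

    CDS codons are i.i.d. draws from the configured codon table; the tRNA
    cluster follows the :class:`ClusterSpec` with all tRNA genes on one
    strand; output is deterministic per seed.
    """
    if config.cluster is None:
        raise SimulationError("virus config needs a ClusterSpec")
    rng = np.random.default_rng(config.seed)
    probs = _codon_probs(config.codon_table)
    spec = config.cluster

    # build the cluster block
    block_parts: list[str] = []
    rel_feats: list[tuple] = []  # (entry, rel_start, seq_len, exons, fid)
    rel = 0
    truth_genes: list[TruthGene] = []
    for i, entry in enumerate(spec.entries):
        seq, exons = generate_trna_gene_sequence(
            entry.amino_acid, entry.anticodon, entry.intron, entry.pseudogene, rng=rng
        )
        rel_feats.append((entry, rel, len(seq), exons, f"trna{i + 1}"))
        block_parts.append(seq)
        rel += len(seq)
        if i < len(spec.spacers):
            gap = spec.spacers[i]
            if i in spec.interrupting_cds:
                cds_len = spec.interrupting_cds[i]
                n_codons = (cds_len - 6) // 3
                lead = (gap - cds_len) // 2
                cds_seq = _make_cds(n_codons, probs, rng)
                block_parts.append(_random_sequence(lead, config.gc_intergenic, rng))
                rel_feats.append((None, rel + lead, len(cds_seq), None, f"intercds{i + 1}"))
                block_parts.append(cds_seq)
                block_parts.append(
                    _random_sequence(gap - lead - len(cds_seq), config.gc_intergenic, rng)
                )
            else:
                block_parts.append(_random_sequence(gap, config.gc_intergenic, rng))
            rel += gap
    # orphans beyond the cluster 3' end
    orphan_rel: list[tuple] = []
    for k, orphan in enumerate(spec.orphans):
        seq, exons = generate_trna_gene_sequence(
            orphan.amino_acid, orphan.anticodon, rng=rng
        )
        orphan_rel.append((orphan, rel + orphan.distance_nt, len(seq), exons,
                           f"orphan{k + 1}"))

    cluster_len = rel
    tail_needed = max(
        (orel + olen for _, orel, olen, _, _ in orphan_rel), default=cluster_len
    )
    cluster_start = int(config.genome_length * spec.offset_fraction) + 1
    if cluster_start + tail_needed + 500 > config.genome_length:
        raise SimulationError(
            f"cluster (+ orphans) of {tail_needed} nt starting at {cluster_start} "
            f"does not fit in a {config.genome_length} nt genome"
        )

    # distribute CDSs around the cluster region
    pre_len = cluster_start - 1
    post_start = cluster_start + tail_needed
    post_len = config.genome_length - post_start + 1
    n_pre = int(round(config.cds_count * pre_len / (pre_len + post_len)))
    pre_seq, pre_feats = _fill_with_cds(
        pre_len, n_pre, config, probs, rng, 0, f"{config.genome_id}_5p"
    )
    post_seq, post_feats = _fill_with_cds(
        post_len, config.cds_count - n_pre, config, probs, rng, post_start - 1,
        f"{config.genome_id}_3p",
    )

    # fill inter-orphan gaps inside the cluster..orphan region
    region = list("".join(block_parts).ljust(tail_needed, "N"))
    cursor = cluster_len
    for _, orel, olen, _, _ in orphan_rel:
        gap_seq = _random_sequence(orel - cursor, config.gc_intergenic, rng)
        region[cursor:orel] = list(gap_seq)
        cursor = orel + olen
    for orphan, orel, olen, exons, fid in orphan_rel:
        seq, _ = generate_trna_gene_sequence(orphan.amino_acid, orphan.anticodon,
                                             rng=np.random.default_rng(config.seed + 7))
        region[orel:orel + olen] = list(seq)
    region_seq = "".join(region)

    sequence = pre_seq + region_seq + post_seq
    assert len(sequence) == config.genome_length

    features: list[GenomicFeature] = list(pre_feats) + list(post_feats)
    strand = spec.strand
    for entry, r, slen, exons, fid in rel_feats:
        start = cluster_start + r
        if entry is None:  # interrupting CDS
            features.append(
                GenomicFeature(
                    feature_id=f"{config.genome_id}_{fid}",
                    kind="CDS",
                    start=start,
                    end=start + slen - 1,
                    strand="+",
                    qualifiers={"product": "hypothetical protein"},
                )
            )
            continue
        feat = _trna_feature(entry, start, strand, slen, exons,
                             f"{config.genome_id}_{fid}")
        features.append(feat)
        codon = revcomp_rna(rna(entry.anticodon))
        truth_genes.append(
            TruthGene(
                label=f"{entry.amino_acid}-{codon}",
                amino_acid=entry.amino_acid,
                codon=codon,
                anticodon=rna(entry.anticodon),
                start=feat.start,
                end=feat.end,
                strand=strand,
                pseudogene=entry.pseudogene,
                intron_offset=entry.intron[0] if entry.intron else None,
                intron_length=entry.intron[1] if entry.intron else None,
                in_cluster=True,
                orphan_distance=None,
            )
        )
    for orphan, orel, olen, exons, fid in orphan_rel:
        start = cluster_start + orel
        feat = _trna_feature(orphan, start, strand, olen, exons,
                             f"{config.genome_id}_{fid}")
        features.append(feat)
        codon = revcomp_rna(rna(orphan.anticodon))
        cluster_end = cluster_start + cluster_len - 1
        truth_genes.append(
            TruthGene(
                label=f"{orphan.amino_acid}-{codon}",
                amino_acid=orphan.amino_acid,
                codon=codon,
                anticodon=rna(orphan.anticodon),
                start=feat.start,
                end=feat.end,
                strand=strand,
                pseudogene=False,
                intron_offset=None,
                intron_length=None,
                in_cluster=False,
                orphan_distance=feat.start - cluster_end - 1,
            )
        )

    record = GenomeRecord(
        id=config.genome_id, clade=config.clade, sequence=sequence, features=features
    )
    cluster_genes = [g for g in truth_genes if g.in_cluster]
    truth = TruthRecord(
        genome_id=config.genome_id,
        clade=config.clade,
        genome_length=config.genome_length,
        genes=truth_genes,
        spacers=list(spec.spacers),
        cluster_span=(cluster_genes[0].start, cluster_genes[-1].end),
        n_cds=len([f for f in record.features if f.kind == "CDS"]),
        interrupting_cds_junctions=sorted(spec.interrupting_cds),
    )
    return record, truth


def generate_host_genome(config: GenomeSimConfig) -> tuple[GenomeRecord, TruthRecord]:
    """Simulate the GC-rich host: CDSs drawn from its codon table, no tRNA
    cluster."""
    if config.cds_count < 1:
        raise SimulationError("host genome needs at least one CDS")
    rng = np.random.default_rng(config.seed)
    probs = _codon_probs(config.codon_table)
    seq, feats = _fill_with_cds(
        config.genome_length, config.cds_count, config, probs, rng, 0, config.genome_id
    )
    record = GenomeRecord(
        id=config.genome_id, clade=config.clade, sequence=seq, features=feats
    )
    truth = TruthRecord(
        genome_id=config.genome_id,
        clade=config.clade,
        genome_length=config.genome_length,
        genes=[],
        spacers=[],
        cluster_span=None,
        n_cds=len(feats),
        interrupting_cds_junctions=[],
    )
    return record, truth


def write_outputs(
    record: GenomeRecord, truth: TruthRecord, outdir: str | Path, basename: str | None = None
) -> dict[str, Path]:
    """Emit GenBank, GFF3+FASTA and truth JSON for one simulated genome."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    base = basename or record.id
    paths = {
        "genbank": outdir / f"{base}.gbk",
        "gff3": outdir / f"{base}.gff3",
        "fasta": outdir / f"{base}.fa",
        "truth": outdir / f"{base}.truth.json",
    }
    write_genbank(record, paths["genbank"])
    write_gff3_fasta(record, paths["gff3"], paths["fasta"])
    truth.to_json(paths["truth"])
    return paths


# ---------------------------------------------------------------------------
# canned study-like configurations
# ---------------------------------------------------------------------------

#: the 14-gene NC64A-type cluster with its printed spacers
MA1E_LIKE_ENTRIES = [
    ("Leu", "CAA"), ("Ile", "UAU"), ("Asn", "GUU"), ("Leu", "UAA"),
    ("Arg", "UCU"), ("Asn", "GUU"), ("Gly", "UCC"), ("Asn", "GUU"),
    ("Lys", "CUU"), ("Gln", "CUG"), ("Lys", "CUU"), ("Tyr", "GUA"),
    ("Lys", "UUU"), ("Lys", "CUU"),
]
MA1E_SPACERS = [25, 23, 24, 3, 23, 3, 27, 3, 22, 23, 23, 30, 1]


def ma1e_like_cluster(intron: tuple[int, int] = (1, 13)) -> ClusterSpec:
    """An NC64A-type 14-gene cluster; the tRNA-Tyr gene carries an intron one
    nt 3' of the anticodon (NC64A intron lengths run 13-14 nt)."""
    entries = [
        ClusterEntry(aa, ac, intron=intron if aa == "Tyr" else None)
        for aa, ac in MA1E_LIKE_ENTRIES
    ]
    return ClusterSpec(entries=entries, spacers=list(MA1E_SPACERS))


def sag_like_cluster(orphan_distance: int = 30_000) -> ClusterSpec:
    """A SAG-type cluster (first genome third) with the orphan tRNA-Thr
    roughly 30 kb downstream."""
    entries = [
        ClusterEntry("Ser", "ACU"), ClusterEntry("Arg", "UCU"),
        ClusterEntry("Asn", "GUU"), ClusterEntry("Gly", "UCC"),
        ClusterEntry("Ile", "AAU"), ClusterEntry("Asn", "GUU"),
        ClusterEntry("Met", "CAU"), ClusterEntry("Asn", "GUU"),
        ClusterEntry("Tyr", "GUA", intron=(1, 10)),
        ClusterEntry("Lys", "CUU"), ClusterEntry("Leu", "UAA"),
        ClusterEntry("Leu", "CAA"),
    ]
    spacers = [4, 25, 22, 22, 25, 23, 22, 2, 21, 148, 22]
    return ClusterSpec(
        entries=entries,
        spacers=spacers,
        offset_fraction=0.15,
        orphans=[OrphanEntry("Thr", "AGU", orphan_distance)],
    )
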