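"""Semantic tRNA inventory: identities, codon recognition, introns, promoters.

Anticodons are stored 5'->3' in the RNA alphabet.  The cognate codon of an
anticodon is its reverse complement; wobble at anticodon position 34 (the 5'
base, pairing with the codon third position) can widen the recognition set.
The lysidine pathway (TilS) is modeled as a recognition-set rewrite on
tRNA-Met(CAU): the modified tRNA reads the isoleucine codon AUA instead of AUG.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

from .annotations import GenomeRecord, GenomicFeature, extract_features
from .genetic import (
    AA3_TO_AA1,
    CODON_TO_AA1,
    codon_amino_acid3,
    dna,
    is_rna_triplet,
    revcomp_rna,
    rna,
)

import re

import pandas as pd


class TrnaError(ValueError):
    pass


@dataclass(frozen=True)
class TrnaIdentity:
    """(amino acid, cognate codon) pair, e.g. ('Tyr', 'UAC')."""

    amino_acid: str  # three-letter code
    cognate_codon: str  # RNA triplet

    def __post_init__(self) -> None:
        if dna(self.cognate_codon) not in CODON_TO_AA1:
            raise TrnaError(f"{self.cognate_codon!r} is not a sense codon")
        if codon_amino_acid3(self.cognate_codon) != self.amino_acid:
            raise TrnaError(
                f"{self.cognate_codon} does not encode {self.amino_acid} "
                "in the standard genetic code"
            )

    @property
    def label(self) -> str:
        return f"{self.amino_acid}-{self.cognate_codon}"


@dataclass
class WobbleRules:
    """Third-position pairing rules keyed by anticodon position-34 base.

    The default follows classical wobble for G34 (pairs C and U); A, C and U
    at position 34 are restricted to Watson-Crick partners.  The Watson-Crick
    partner is always included.
    """

    enabled: bool = True
    pairings: dict[str, frozenset[str]] = field(
        default_factory=lambda: {
            "G": frozenset({"C", "U"}),
            "A": frozenset({"U"}),
            "C": frozenset({"G"}),
            "U": frozenset({"A"}),
        }
    )

    def __post_init__(self) -> None:
        wc = {"G": "C", "A": "U", "C": "G", "U": "A"}
        for base, partners in self.pairings.items():
            if wc[base] not in partners:
                raise TrnaError(
                    f"wobble pairings for {base}34 must include the "
                    f"Watson-Crick partner {wc[base]}"
                )


@dataclass
class BoxMotifConfig:
    """Intragenic RNA polymerase III type-2 promoter elements (Box A / Box B).

    Both consensus strings are 11-mers in IUPAC DNA code.  The defaults are
    literature-canonical (the internal promoter boxes of eukaryotic tRNA
    genes); they are configuration, not data derived from any one genome set.
    """

    box_a_consensus: str = "TRGCNNARYNN"
    box_b_consensus: str = "GTTCGANNCNN"
    max_mismatches: int = 2

    def __post_init__(self) -> None:
        for name, cons in (("A", self.box_a_consensus), ("B", self.box_b_consensus)):
            if len(cons) != 11:
                raise TrnaError(f"Box {name} consensus must be an 11-mer")


@dataclass
class TrnaGene:
    """One tRNA gene with coordinates, identity and recognition semantics.

    ``sequence`` is the unspliced coding-strand gene sequence (DNA);
    ``exons_local`` are 1-based (start, end) pairs in coding orientation, or
    ``None`` for single-exon genes.
    """

    identity: TrnaIdentity | None
    anticodon: str | None  # RNA, 5'->3'
    start: int
    end: int
    strand: str
    sequence: str = ""
    exons_local: list[tuple[int, int]] | None = None
    pseudogene: bool = False
    tils_recoded: bool = False
    source_feature_id: str = ""
    genome_id: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def spliced_sequence(self) -> str:
        if not self.exons_local:
            return self.sequence
        return "".join(self.sequence[s - 1 : e] for s, e in self.exons_local)

    @property
    def label(self) -> str:
        return self.identity.label if self.identity else "unknown"

    def recognition_set(self, rules: WobbleRules | None = None) -> frozenset[str]:
        """Codons read by this tRNA; empty for pseudogenes/unknown identity."""
        if self.pseudogene or self.anticodon is None:
            return frozenset()
        if self.tils_recoded:
            return frozenset({"AUA"})
        if rules is None or not rules.enabled:
            return frozenset({anticodon_to_codon(self.anticodon)})
        return wobble_recognition_set(self.anticodon, rules)


# ---------------------------------------------------------------------------
# Core anticodon/codon operations
# ---------------------------------------------------------------------------


def anticodon_to_codon(anticodon: str) -> str:
    """Watson-Crick cognate codon (RNA 5'->3') of an anticodon (RNA 5'->3').

    An anticodon written 5'-CAU-3' is 3'-UAC-5' against the mRNA and reads
    the codon 5'-AUG-3': the operation is reverse complementation, and it is
    an involution on the 64 triplets.
    """
    ac = rna(anticodon)
    if not is_rna_triplet(ac):
        raise TrnaError(f"{anticodon!r} is not an RNA triplet")
    return revcomp_rna(ac)


def wobble_recognition_set(anticodon: str, rules: WobbleRules | None = None) -> frozenset[str]:
    """All codons read by an anticodon under third-position wobble rules.

    Position 34 of the tRNA (the anticodon 5' base) pairs with the codon
    third position; e.g. a G34 tRNA-Tyr(GUA) reads both UAC and UAU.
    """
    rules = rules or WobbleRules()
    ac = rna(anticodon)
    if not is_rna_triplet(ac):
        raise TrnaError(f"{anticodon!r} is not an RNA triplet")
    wc = anticodon_to_codon(ac)
    if not rules.enabled:
        return frozenset({wc})
    third_bases = rules.pairings.get(ac[0], frozenset({wc[2]}))
    return frozenset({wc[:2] + b for b in third_bases} | {wc})


def apply_tils(trna: TrnaGene) -> TrnaGene:
    """Return a copy recoded by tRNA-Ile lysidine synthase.

    TilS converts C34 of tRNA-Met(CAU) to lysidine; the modified anticodon
    pairs with A at the codon third position, so the gene is relabeled
    Ile/AUA and reads exactly {AUA}.  Only Met/AUG genes with anticodon CAU
    are substrates.
    """
    if trna.identity is None or trna.anticodon is None:
        raise TrnaError("cannot apply TilS to an identity-unknown tRNA")
    if trna.identity.amino_acid != "Met" or rna(trna.anticodon) != "CAU":
        raise TrnaError(
            f"TilS modifies tRNA-Met(CAU) only, not {trna.label}({trna.anticodon})"
        )
    return replace(
        trna, identity=TrnaIdentity("Ile", "AUA"), anticodon="CAU", tils_recoded=True
    )


# ---------------------------------------------------------------------------
# Gene geometry
# ---------------------------------------------------------------------------


def _locate_anticodon(gene: TrnaGene) -> int:
    """1-based position of the anticodon first base in the SPLICED sequence."""
    if gene.anticodon is None:
        raise TrnaError("anticodon unknown")
    spliced = rna(gene.spliced_sequence)
    ac = rna(gene.anticodon)
    # canonical anticodon position 34..36; search near there first
    if len(spliced) >= 36 and spliced[33:36] == ac:
        return 34
    idx = spliced.find(ac)
    if idx < 0:
        raise TrnaError(
            f"anticodon {gene.anticodon} not found in exonic sequence of {gene.label}"
        )
    return idx + 1


def intron_geometry(gene: TrnaGene) -> tuple[int, int] | None:
    """(offset, length): exonic nt between the anticodon 3' end and the intron
    start, and the intron length; ``None`` for single-exon genes."""
    if not gene.exons_local or len(gene.exons_local) < 2:
        return None
    if len(gene.exons_local) != 2:
        raise TrnaError("tRNA genes with more than one intron are not supported")
    (s1, e1), (s2, e2) = gene.exons_local
    intron_len = s2 - e1 - 1
    ac_start = _locate_anticodon(gene)  # spliced coordinates
    ac_end = ac_start + 2
    if ac_end > e1:
        raise TrnaError("anticodon does not lie in the 5' exon")
    offset = e1 - ac_end
    return offset, intron_len


def detect_cca_end(gene: TrnaGene) -> bool:
    """True iff the spliced gene sequence ends in CCA on the coding strand."""
    return dna(gene.spliced_sequence).endswith("CCA")


# ---------------------------------------------------------------------------
# Promoter boxes
# ---------------------------------------------------------------------------

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def _mismatches(window: str, consensus: str) -> int:
    return sum(b not in _IUPAC[c] for b, c in zip(window, consensus))


def find_polIII_boxes(
    gene_sequence: str, config: BoxMotifConfig | None = None
) -> list[tuple[str, int, int]]:
    """Scan a gene for intragenic Box A / Box B promoter elements.

    Returns (box, offset, mismatches) tuples, best (fewest mismatches) first
    within each box; 0-based offsets.  A-box hits are reported only 5' of the
    best B-box hit when both boxes are found.
    """
    config = config or BoxMotifConfig()
    seq = dna(gene_sequence)
    hits: dict[str, list[tuple[int, int]]] = {"A": [], "B": []}
    for box, consensus in (("A", config.box_a_consensus), ("B", config.box_b_consensus)):
        for off in range(len(seq) - 10):
            mm = _mismatches(seq[off : off + 11], consensus)
            if mm <= config.max_mismatches:
                hits[box].append((mm, off))
        hits[box].sort()
    out: list[tuple[str, int, int]] = []
    b_hits = hits["B"]
    best_b = b_hits[0][1] if b_hits else None
    for mm, off in hits["A"]:
        if best_b is None or off < best_b:
            out.append(("A", off, mm))
    out.extend(("B", off, mm) for mm, off in b_hits)
    return out


# ---------------------------------------------------------------------------
# Inventory construction
# ---------------------------------------------------------------------------

_PRODUCT_RE = re.compile(
    r"tRNA-([A-Z][a-z]{2})(?:[ (\-]+([ACGUTacgut]{3})\)?)?"
)
_ANTICODON_SEQ_RE = re.compile(r"seq\s*:\s*([acgut]{3})", re.IGNORECASE)


def _parse_anticodon_qualifier(value: str) -> str | None:
    value = value.strip()
    m = _ANTICODON_SEQ_RE.search(value)
    if m:
        return rna(m.group(1))
    if re.fullmatch(r"[ACGUTacgut]{3}", value):
        return rna(value)
    return None


def _resolve_identity(feat: GenomicFeature) -> tuple[TrnaIdentity | None, str | None]:
    """Identity from the anticodon qualifier (preferred) or the product string."""
    anticodon = None
    if "anticodon" in feat.qualifiers:
        anticodon = _parse_anticodon_qualifier(feat.qualifiers["anticodon"])
    aa_hint = None
    m = _PRODUCT_RE.search(feat.qualifiers.get("product", ""))
    if m:
        aa_hint = m.group(1)
        if anticodon is None and m.group(2):
            anticodon = rna(m.group(2))
    if anticodon is not None:
        codon = revcomp_rna(anticodon)
        if dna(codon) in CODON_TO_AA1:
            return TrnaIdentity(codon_amino_acid3(codon), codon), anticodon
        # anticodon implies a stop codon; identity from product if possible
        return None, anticodon
    if aa_hint is not None and aa_hint in AA3_TO_AA1:
        return None, None  # amino acid alone cannot fix the cognate codon
    return None, None


def build_inventory(record: GenomeRecord) -> list[TrnaGene]:
    """One :class:`TrnaGene` per tRNA feature, in genome order.

    Identities are resolved from the anticodon qualifier when present,
    falling back to product-string parsing ("tRNA-Tyr (GTA)").  Pseudogenes
    are flagged, never dropped; features with no resolvable identity are kept
    as identity-unknown with a warning.
    """
    inventory: list[TrnaGene] = []
    for feat in extract_features(record, "tRNA"):
        identity, anticodon = _resolve_identity(feat)
        if identity is None and anticodon is None:
            warnings.warn(
                f"tRNA feature {feat.feature_id} has neither anticodon nor "
                "parsable product; recorded as identity-unknown",
                stacklevel=2,
            )
        seq = record.feature_sequence(feat, spliced=False)
        exons_local = None
        if feat.exons:
            if feat.strand == "+":
                exons_local = [(s - feat.start + 1, e - feat.start + 1) for s, e in feat.exons]
            else:
                exons_local = sorted(
                    (feat.end - e + 1, feat.end - s + 1) for s, e in feat.exons
                )
        inventory.append(
            TrnaGene(
                identity=identity,
                anticodon=anticodon,
                start=feat.start,
                end=feat.end,
                strand=feat.strand,
                sequence=seq,
                exons_local=exons_local,
                pseudogene=feat.pseudo,
                source_feature_id=feat.feature_id,
                genome_id=record.id,
            )
        )
    return inventory


def inventory_table(inventory: list[TrnaGene]) -> pd.DataFrame:
    """Tidy per-gene export (one row per tRNA gene, genome order)."""
    rows = []
    for i, g in enumerate(inventory):
        nxt = inventory[i + 1] if i + 1 < len(inventory) else None
        geom = None
        if g.exons_local and len(g.exons_local) == 2:
            try:
                geom = intron_geometry(g)
            except TrnaError:
                geom = None
        rows.append(
            {
                "genome": g.genome_id,
                "index": i,
                "amino_acid": g.identity.amino_acid if g.identity else "",
                "codon": g.identity.cognate_codon if g.identity else "",
                "anticodon": g.anticodon or "",
                "start": g.start,
                "end": g.end,
                "strand": g.strand,
                "spacer_to_next": (nxt.start - g.end - 1) if nxt else pd.NA,
                "pseudogene": g.pseudogene,
                "intron_offset": geom[0] if geom else pd.NA,
                "intron_length": geom[1] if geom else pd.NA,
                "cca": detect_cca_end(g) if g.sequence else False,
            }
        )
    return pd.DataFrame(rows)
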