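"""Codon-usage tables, the virus/host ratio statistic, and tRNA favorability.

Codon frequencies are percentages over counted sense codons (stop codons
excluded) so a 61-row table sums to 100.  The ratio statistic for codon c is

    R_c = mean_v f_{v,c} / f_{host,c}

(the mean over virus tables first, then the ratio); R_c > 1 means the codon
is used more by the viruses than by the host, so a viral tRNA reading c
assists the virus against the host's codon-usage bias.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .genetic import CODON_TO_AA1, SENSE_CODONS_DNA, STOP_CODONS_DNA, dna, rna
from .trna import TrnaGene, WobbleRules, apply_tils


class CubError(ValueError):
    pass


@dataclass
class CodonUsageTable:
    """Per-codon percent frequencies over the 61 sense codons."""

    frequencies: pd.Series  # index: RNA codons, values: percent
    total_codons: int
    source: str = ""
    internal_stops: int = 0

    def __post_init__(self) -> None:
        idx = [rna(c) for c in SENSE_CODONS_DNA]
        self.frequencies = self.frequencies.reindex(idx).fillna(0.0)
        if (self.frequencies < 0).any():
            raise CubError("negative codon frequency")

    def __getitem__(self, codon: str) -> float:
        return float(self.frequencies[rna(codon)])

    @property
    def sum(self) -> float:
        return float(self.frequencies.sum())


@dataclass
class CubRatioTable:
    """Mean-virus/host frequency ratio per codon.

    ``ratio`` holds NaN where the host frequency is zero; those codons are
    listed in ``undefined`` and never enter favorability comparisons.
    """

    table: pd.DataFrame  # columns: amino_acid, f_virus_mean, f_host, ratio, favored
    n_virus_tables: int = 1

    def ratio(self, codon: str) -> float:
        val = self.table.loc[rna(codon), "ratio"]
        if pd.isna(val):
            raise CubError(f"ratio undefined for {codon} (host frequency is 0)")
        return float(val)

    @property
    def undefined(self) -> list[str]:
        return list(self.table.index[self.table["ratio"].isna()])


@dataclass
class FavorabilityParams:
    threshold: float = 1.0
    counting: str = "distinct_codons"  # or "per_gene"
    use_wobble: bool = False
    apply_tils: bool = False

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise CubError("threshold must be positive")
        if self.counting not in ("distinct_codons", "per_gene"):
            raise CubError(f"unknown counting mode {self.counting!r}")


@dataclass
class FavorabilityReport:
    gene_count: int
    recognized_codons: list[str]
    assisting: list[str]
    neutral: list[str]
    boundary: list[str]
    excluded_genes: int
    counting: str
    assisting_genes: int | None = None

    @property
    def assisting_count(self) -> int:
        return (
            self.assisting_genes
            if self.counting == "per_gene" and self.assisting_genes is not None
            else len(self.assisting)
        )


# ---------------------------------------------------------------------------


def codon_frequencies(cds_sequences: list[str], source: str = "") -> CodonUsageTable:
    """Count frame-0 codons of each CDS into a percent frequency table.

    A terminal stop codon is excluded; internal stops are tallied in a QC
    side channel (``internal_stops``) but never enter the percentages;
    codons containing non-ACGT characters are skipped.
    """
    if not cds_sequences:
        raise CubError("no CDS sequences given")
    counts: Counter[str] = Counter()
    internal_stops = 0
    for seq in cds_sequences:
        s = dna(seq)
        if len(s) < 3:
            raise CubError("CDS shorter than one codon")
        codons = [s[i : i + 3] for i in range(0, len(s) - len(s) % 3, 3)]
        if codons and codons[-1] in STOP_CODONS_DNA:
            codons.pop()
        for c in codons:
            if c in STOP_CODONS_DNA:
                internal_stops += 1
            elif c in CODON_TO_AA1:
                counts[c] += 1
            # else: ambiguous characters, skipped
    total = sum(counts.values())
    if total == 0:
        raise CubError("no sense codons counted")
    freqs = pd.Series(
        {rna(c): 100.0 * counts.get(c, 0) / total for c in SENSE_CODONS_DNA}
    )
    return CodonUsageTable(
        frequencies=freqs, total_codons=total, source=source, internal_stops=internal_stops
    )


def gc_content(sequence_or_record) -> float:
    """Percent G+C among unambiguous bases; ambiguous bases are excluded."""
    seq = getattr(sequence_or_record, "sequence", sequence_or_record)
    s = dna(seq)
    gc = s.count("G") + s.count("C")
    at = s.count("A") + s.count("T")
    if gc + at == 0:
        raise CubError("sequence has no unambiguous bases")
    return 100.0 * gc / (gc + at)


def cub_ratio(
    virus_tables: list[CodonUsageTable] | CodonUsageTable,
    host_table: CodonUsageTable,
) -> CubRatioTable:
    """Mean-virus/host ratio per codon (mean first, then the ratio).

    With a single virus table this degrades to a plain virus/host ratio.
    Codons the host never uses get an undefined (NaN) ratio, flagged rather
    than computed as infinity.
    """
    if isinstance(virus_tables, CodonUsageTable):
        virus_tables = [virus_tables]
    if not virus_tables:
        raise CubError("at least one virus table required")
    codons = [rna(c) for c in SENSE_CODONS_DNA]
    mean_virus = sum(t.frequencies for t in virus_tables) / len(virus_tables)
    host = host_table.frequencies
    ratio = mean_virus / host.where(host > 0)
    favored = pd.Series(
        [
            "undefined" if pd.isna(r) else
            "virus" if r > 1 else "host" if r < 1 else "neutral-boundary"
            for r in ratio
        ],
        index=codons,
    )
    table = pd.DataFrame(
        {
            "amino_acid": [CODON_TO_AA1[dna(c)] for c in codons],
            "f_virus_mean": mean_virus,
            "f_host": host,
            "ratio": ratio,
            "favored": favored,
        },
        index=pd.Index(codons, name="codon"),
    )
    return CubRatioTable(table=table, n_virus_tables=len(virus_tables))


def round_half_up(x: float, digits: int = 2) -> float:
    """Presentation rounding matching printed tables (half away from zero)."""
    from decimal import ROUND_HALF_UP, Decimal

    return float(Decimal(repr(x)).quantize(Decimal(f"1e-{digits}"), ROUND_HALF_UP))


def preferred_codons(table: CodonUsageTable) -> dict[str, set[str]]:
    """Per amino acid, the highest-frequency synonymous codon(s); ties give
    multi-element sets."""
    best: dict[str, set[str]] = {}
    by_aa: dict[str, list[str]] = {}
    for c in SENSE_CODONS_DNA:
        by_aa.setdefault(CODON_TO_AA1[c], []).append(rna(c))
    for aa, codons in by_aa.items():
        vals = {c: table[c] for c in codons}
        top = max(vals.values())
        best[aa] = {c for c, v in vals.items() if v == top}
    return best


def classify_favorability(
    inventory: list[TrnaGene],
    ratios: CubRatioTable,
    params: FavorabilityParams | None = None,
) -> FavorabilityReport:
    """Which recognized codons (or genes) assist the virus against host CUB.

    The recognized-codon set is assembled from the inventory per the
    parameters: strict cognate codons by default, wobble expansion and/or the
    TilS rewrite of tRNA-Met(CAU) when enabled.  A codon assists when its
    ratio exceeds the threshold; equal-to-threshold codons are boundary, not
    assisting.  Pseudogenes and identity-unknown genes are excluded with a
    warning.
    """
    params = params or FavorabilityParams()
    rules = WobbleRules() if params.use_wobble else WobbleRules(enabled=False)
    excluded = 0
    gene_codons: list[frozenset[str]] = []
    usable_genes: list[TrnaGene] = []
    for g in inventory:
        if g.pseudogene or g.identity is None:
            excluded += 1
            continue
        gene = g
        if params.apply_tils and g.identity.amino_acid == "Met" and g.anticodon == "CAU":
            gene = apply_tils(g)
        rec = gene.recognition_set(rules)
        if rec:
            usable_genes.append(gene)
            gene_codons.append(rec)
    if excluded:
        warnings.warn(
            f"{excluded} pseudogene/identity-unknown tRNA(s) excluded from "
            "favorability classification",
            stacklevel=2,
        )
    recognized = sorted(set().union(*gene_codons)) if gene_codons else []
    assisting, neutral, boundary = [], [], []
    defined = [c for c in recognized if c not in ratios.undefined]
    for c in defined:
        r = ratios.ratio(c)
        if r > params.threshold:
            assisting.append(c)
        elif r == params.threshold:
            boundary.append(c)
        else:
            neutral.append(c)
    assisting_genes = None
    if params.counting == "per_gene":
        assisting_set = set(assisting)
        assisting_genes = sum(
            1 for rec in gene_codons if rec & assisting_set
        )
    return FavorabilityReport(
        gene_count=len(usable_genes),
        recognized_codons=recognized,
        assisting=assisting,
        neutral=neutral,
        boundary=boundary,
        excluded_genes=excluded,
        counting=params.counting,
        assisting_genes=assisting_genes,
    )


def classify_codon_set(
    codons: set[str] | list[str],
    ratios: CubRatioTable,
    threshold: float = 1.0,
) -> tuple[list[str], list[str]]:
    """(assisting, not-assisting) partition of an explicit codon set."""
    assisting, rest = [], []
    for c in sorted(rna(x) for x in codons):
        if c in ratios.undefined:
            rest.append(c)
        elif ratios.ratio(c) > threshold:
            assisting.append(c)
        else:
            rest.append(c)
    return assisting, rest


def tils_benefit(ratios: CubRatioTable, threshold: float = 1.0) -> tuple[str, float, str]:
    """The AUA ratio and its assisting/neutral label: the benefit conferred
    by TilS recoding tRNA-Met(CAU) to read the isoleucine codon AUA."""
    r = ratios.ratio("AUA")  # raises if undefined
    label = "assisting" if r > threshold else "boundary" if r == threshold else "neutral"
    return "AUA", r, label
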