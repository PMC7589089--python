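"""Packaged fixtures: transcriptions of the five chlorovirus survey tables.

``load_fixture`` returns validated DataFrames; helpers build in-memory tRNA
inventories and codon-usage tables from them.  The fixtures are data, not
code: each file's SHA-256 is pinned and a mismatch is an error.  Known
misprints and every transcription judgment call are documented in the errata
sidecar (``data/errata.md``), never silently corrected.
"""

from __future__ import annotations

import hashlib
from importlib import resources

import pandas as pd

from .cub import CodonUsageTable
from .genetic import revcomp_rna
from .trna import TrnaGene, TrnaIdentity

FIXTURE_NAMES = (
    "table1_nc64a",
    "table2_sag",
    "table3_pbi",
    "table4_presence",
    "table5_codon_usage",
)

_CHECKSUMS: dict[str, str] = {}  # filled below at import from data/CHECKSUMS


class FixtureError(ValueError):
    pass


def _data_path(filename: str):
    return resources.files("chlorotrna").joinpath("data", filename)


def _load_checksums() -> dict[str, str]:
    text = _data_path("CHECKSUMS").read_text()
    out = {}
    for line in text.strip().split("\n"):
        digest, name = line.split()
        out[name] = digest
    return out


def load_fixture(name: str) -> pd.DataFrame:
    """Load and validate one packaged table fixture by name."""
    if name not in FIXTURE_NAMES:
        raise FixtureError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    if not _CHECKSUMS:
        _CHECKSUMS.update(_load_checksums())
    filename = f"{name}.tsv"
    raw = _data_path(filename).read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _CHECKSUMS[filename]:
        raise FixtureError(f"checksum mismatch for {filename}: fixture corrupted")
    df = pd.read_csv(_data_path(filename), sep="\t")
    _validate(name, df)
    return df


def _validate(name: str, df: pd.DataFrame) -> None:
    if name == "table5_codon_usage":
        if len(df) != 61:
            raise FixtureError("codon-usage fixture must have 61 sense-codon rows")
        if df["codon"].duplicated().any():
            raise FixtureError("duplicate codon rows")
    elif name == "table4_presence":
        if not {"c", "d", "u"} >= set(x for col in ("nc64a", "sag", "pbi")
                                      for x in df[col].dropna()):
            raise FixtureError("presence marks must be c/d/u")
    else:
        by_virus = df.groupby("virus", sort=False)
        for virus, sub in by_virus:
            total = sub["printed_total"].iloc[0]
            if len(sub) != total:
                raise FixtureError(f"{name}/{virus}: {len(sub)} rows != total {total}")
            n_cluster = int((sub["orphan"] == 0).sum())
            n_spacers = sub["spacer_to_next"].notna().sum()
            if n_spacers != n_cluster - 1:
                raise FixtureError(f"{name}/{virus}: spacer count mismatch")


def errata_text() -> str:
    """The errata sidecar documenting printed-table inconsistencies."""
    return _data_path("errata.md").read_text()


# ---------------------------------------------------------------------------
# Derived in-memory objects
# ---------------------------------------------------------------------------

_GENE_LEN = 73  # nominal tRNA gene length used for synthesized fixture coordinates


def fixture_gene_table() -> pd.DataFrame:
    """Tables 1-3 concatenated into one tidy per-gene DataFrame."""
    return pd.concat(
        [load_fixture(n) for n in ("table1_nc64a", "table2_sag", "table3_pbi")],
        ignore_index=True,
    )


def fixture_inventories() -> tuple[dict[str, list[TrnaGene]], dict[str, str]]:
    """Per-virus tRNA inventories synthesized from the cluster-table fixtures.

    Coordinates are reconstructed by walking the printed spacers with a
    nominal 73 nt gene footprint (the tables publish spacers and order, not
    absolute coordinates); identities, order, spacers, orphan distances and
    strand are faithful to the fixture.
    """
    table = fixture_gene_table()
    inventories: dict[str, list[TrnaGene]] = {}
    clade_map: dict[str, str] = {}
    for virus, sub in table.groupby("virus", sort=False):
        clade_map[virus] = sub["clade"].iloc[0]
        genes: list[TrnaGene] = []
        pos = 1001
        prev_spacer: float | None = None
        for _, row in sub.sort_values("position").iterrows():
            if row["orphan"] == 1:
                pos = genes[-1].end + int(row["orphan_distance_nt"]) + 1
            elif prev_spacer is not None:
                pos = genes[-1].end + int(prev_spacer) + 1
            codon = row["codon"]
            genes.append(
                TrnaGene(
                    identity=TrnaIdentity(row["amino_acid"], codon),
                    anticodon=revcomp_rna(codon),
                    start=pos,
                    end=pos + _GENE_LEN - 1,
                    strand="+",
                    pseudogene=bool(row["pseudogene"]),
                    source_feature_id=f"{virus}_t{int(row['position'])}",
                    genome_id=virus,
                )
            )
            prev_spacer = row["spacer_to_next"] if pd.notna(row["spacer_to_next"]) else None
        inventories[virus] = genes
    return inventories, clade_map


def codon_usage_fixture() -> tuple[CodonUsageTable, CodonUsageTable, CodonUsageTable, pd.Series]:
    """(PBCV-1, AN69C, host) percent tables plus the printed ratio column."""
    df = load_fixture("table5_codon_usage").set_index("codon")

    def table(col: str, source: str) -> CodonUsageTable:
        return CodonUsageTable(
            frequencies=df[col].astype(float), total_codons=0, source=source
        )

    return (
        table("pbcv1", "PBCV-1"),
        table("an69c", "AN69C"),
        table("host", "C. variabilis NC64A"),
        df["ratio_printed"].astype(float),
    )


#: codons misprinted in the published ratio column (formula value differs;
#: see errata sidecar).  GAU is the gross outlier; the others are moderate.
RATIO_ERRATA = ("GAU", "CUU", "AUG", "GGG")


def pbcv1_inventory() -> list[TrnaGene]:
    """Convenience: the PBCV-1 inventory from the NC64A cluster fixture."""
    inventories, _ = fixture_inventories()
    return inventories["PBCV-1"]
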