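"""Uniform feature model over annotated genomes (GenBank and GFF3+FASTA).

Coordinates are 1-based inclusive throughout (GenBank convention).  Minus-strand
features keep plus-strand coordinates; :meth:`GenomeRecord.feature_sequence`
reverse-complements on demand.  Feature kinds other than tRNA/CDS are retained
as ``other`` so downstream cluster-interruption logic can see them; the only
exceptions are ``source`` and ``gene`` rows, which merely duplicate the span of
the record or of their child features and are skipped on read.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .genetic import revcomp_dna

KINDS = ("tRNA", "CDS", "other")

#: qualifier keys preserved by both serializers (field order is deterministic)
_QUAL_KEYS = ("product", "anticodon", "pseudo", "note")


class AnnotationError(ValueError):
    """Malformed annotation input."""


@dataclass
class GenomicFeature:
    """One annotated feature with optional exon sub-intervals.

    ``exons`` are plus-strand genomic (start, end) pairs that tile
    ``[start, end]``; ``None`` means single-exon.
    """

    feature_id: str
    kind: str
    start: int
    end: int
    strand: str
    qualifiers: dict[str, str] = field(default_factory=dict)
    exons: list[tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise AnnotationError(f"unknown feature kind {self.kind!r}")
        if not (1 <= self.start <= self.end):
            raise AnnotationError(
                f"feature {self.feature_id}: bad coordinates {self.start}..{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"feature {self.feature_id}: bad strand {self.strand!r}")
        if self.exons is not None:
            exons = sorted(self.exons)
            if exons[0][0] != self.start or exons[-1][1] != self.end:
                raise AnnotationError(
                    f"feature {self.feature_id}: exons do not tile {self.start}..{self.end}"
                )
            for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
                if e1 >= s2:
                    raise AnnotationError(
                        f"feature {self.feature_id}: exons overlap or are unordered"
                    )
            self.exons = exons

    @property
    def pseudo(self) -> bool:
        return "pseudo" in self.qualifiers

    def signature(self) -> tuple:
        """Format-independent identity used by round-trip checks."""
        return (
            self.kind,
            self.start,
            self.end,
            self.strand,
            tuple(self.exons) if self.exons else None,
            self.pseudo,
            self.qualifiers.get("product", ""),
            self.qualifiers.get("anticodon", "").lower(),
        )


@dataclass
class GenomeRecord:
    """A single annotated contig with ordered features."""

    id: str
    clade: str
    sequence: str
    features: list[GenomicFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        self.features.sort(key=lambda f: (f.start, f.end))
        for f in self.features:
            if f.end > self.length:
                raise AnnotationError(
                    f"feature {f.feature_id} ends at {f.end}, beyond genome length {self.length}"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def feature_sequence(self, feat: GenomicFeature, spliced: bool = True) -> str:
        """Coding-strand sequence of a feature, exon-spliced by default."""
        intervals = feat.exons if (spliced and feat.exons) else [(feat.start, feat.end)]
        seq = "".join(self.sequence[s - 1 : e] for s, e in intervals)
        return revcomp_dna(seq) if feat.strand == "-" else seq


def extract_features(record: GenomeRecord, kind: str) -> list[GenomicFeature]:
    """All and only features of ``kind``, genome order preserved."""
    return [f for f in record.features if f.kind == kind]


# ---------------------------------------------------------------------------
# GenBank
# ---------------------------------------------------------------------------

_CLADE_RE = re.compile(r"clade=(\S+)")


def _kind_of(gb_type: str) -> str:
    return gb_type if gb_type in ("tRNA", "CDS") else "other"


def read_genbank(path: str | Path) -> GenomeRecord:
    """Parse a single-record GenBank flat file into a :class:`GenomeRecord`."""
    try:
        records = list(SeqIO.parse(str(path), "genbank"))
    except Exception as exc:  # Biopython raises assorted ValueError subclasses
        raise AnnotationError(f"cannot parse GenBank file {path}: {exc}") from exc
    if not records:
        raise AnnotationError(f"{path}: no GenBank record found")
    if len(records) > 1:
        raise AnnotationError(
            f"{path}: {len(records)} records found; process one record per file"
        )
    rec = records[0]
    clade_m = _CLADE_RE.search(rec.description or "")
    features: list[GenomicFeature] = []
    counter = 0
    for ft in rec.features:
        if ft.type in ("source", "gene"):
            continue
        counter += 1
        start = int(ft.location.start) + 1
        end = int(ft.location.end)
        strand = "-" if ft.location.strand == -1 else "+"
        parts = sorted(ft.location.parts, key=lambda p: int(p.start))
        exons = (
            [(int(p.start) + 1, int(p.end)) for p in parts] if len(parts) > 1 else None
        )
        quals = {}
        for key, val in ft.qualifiers.items():
            quals[key] = str(val[0]) if isinstance(val, list) and val else ""
        fid = quals.pop("label", f"{rec.id}_{ft.type}_{counter}")
        features.append(
            GenomicFeature(
                feature_id=fid,
                kind=_kind_of(ft.type),
                start=start,
                end=end,
                strand=strand,
                qualifiers=quals,
                exons=exons,
            )
        )
    return GenomeRecord(
        id=rec.id,
        clade=clade_m.group(1) if clade_m else "other",
        sequence=str(rec.seq),
        features=features,
    )


def write_genbank(record: GenomeRecord, path: str | Path) -> Path:
    """Serialize to a GenBank flat file; ``read_genbank`` round-trips it."""
    seqrec = SeqRecord(
        Seq(record.sequence),
        id=record.id,
        name=record.id[:16],
        description=f"synthetic genome clade={record.clade}",
    )
    seqrec.annotations["molecule_type"] = "DNA"
    seqrec.annotations["topology"] = "linear"
    seqrec.annotations["data_file_division"] = "ENV"
    seqrec.annotations["date"] = "01-JAN-1980"  # fixed: byte-identical re-runs
    for feat in record.features:
        strand = -1 if feat.strand == "-" else 1
        if feat.exons:
            loc = CompoundLocation(
                [SimpleLocation(s - 1, e, strand) for s, e in feat.exons]
            )
        else:
            loc = SimpleLocation(feat.start - 1, feat.end, strand)
        quals: dict[str, list[str]] = {"label": [feat.feature_id]}
        for key in _QUAL_KEYS:
            if key in feat.qualifiers:
                quals[key] = [feat.qualifiers[key]]
        gb_type = feat.kind if feat.kind != "other" else feat.qualifiers.get(
            "original_type", "misc_feature"
        )
        seqrec.features.append(SeqFeature(loc, type=gb_type, qualifiers=quals))
    path = Path(path)
    with open(path, "w") as fh:
        SeqIO.write([seqrec], fh, "genbank")
    return path


# ---------------------------------------------------------------------------
# GFF3 + FASTA
# ---------------------------------------------------------------------------


def read_gff3_fasta(gff_path: str | Path, fasta_path: str | Path) -> GenomeRecord:
    """Parse a GFF3 + FASTA pair; gene→tRNA→exon hierarchies collapse to one
    feature with exon sub-intervals."""
    fasta_records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(fasta_records) != 1:
        raise AnnotationError(f"{fasta_path}: expected exactly one FASTA record")
    fasta = fasta_records[0]

    clade = "other"
    with open(gff_path) as fh:
        first = fh.readline()
        if not first.startswith("##gff-version"):
            raise AnnotationError(f"{gff_path}: missing ##gff-version pragma")
        for line in fh:
            if line.startswith("##clade"):
                clade = line.split()[1]
            elif not line.startswith("#"):
                break

    try:
        db = gffutils.create_db(
            str(gff_path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
        rows = list(db.all_features(order_by=("start", "end")))
    except gffutils.exceptions.EmptyInputError:
        rows = []
    features: list[GenomicFeature] = []
    counter = 0
    for ft in rows:
        if ft.featuretype in ("gene", "exon"):
            continue
        if ft.seqid != fasta.id:
            raise AnnotationError(
                f"{gff_path}: seqid {ft.seqid!r} does not match FASTA id {fasta.id!r}"
            )
        if ft.end > len(fasta.seq):
            raise AnnotationError(
                f"{gff_path}: feature {ft.id} ends beyond sequence length"
            )
        counter += 1
        exon_children = sorted(
            ((c.start, c.end) for c in db.children(ft, featuretype="exon")),
        )
        quals = {k: v[0] for k, v in ft.attributes.items() if k not in ("ID", "Parent")}
        if quals.pop("pseudogene", "") == "true" or quals.get("pseudo") == "true":
            quals["pseudo"] = ""
        features.append(
            GenomicFeature(
                feature_id=ft.id or f"{fasta.id}_{ft.featuretype}_{counter}",
                kind=_kind_of(ft.featuretype),
                start=ft.start,
                end=ft.end,
                strand="-" if ft.strand == "-" else "+",
                qualifiers=quals,
                exons=exon_children if len(exon_children) > 1 else None,
            )
        )
    return GenomeRecord(id=fasta.id, clade=clade, sequence=str(fasta.seq), features=features)


def write_gff3_fasta(
    record: GenomeRecord, gff_path: str | Path, fasta_path: str | Path
) -> tuple[Path, Path]:
    """Serialize to GFF3 + FASTA with deterministic field order."""
    gff_path, fasta_path = Path(gff_path), Path(fasta_path)
    lines = [
        "##gff-version 3",
        f"##sequence-region {record.id} 1 {record.length}",
        f"##clade {record.clade}",
    ]
    src = "chlorotrna"
    for feat in record.features:
        gff_type = feat.kind if feat.kind != "other" else "region"
        attrs = [f"ID={feat.feature_id}"]
        for key in _QUAL_KEYS:
            if key in feat.qualifiers:
                val = feat.qualifiers[key] if key != "pseudo" else "true"
                attrs.append(f"{key}={val}")
        lines.append(
            "\t".join(
                [
                    record.id,
                    src,
                    gff_type,
                    str(feat.start),
                    str(feat.end),
                    ".",
                    feat.strand,
                    ".",
                    ";".join(attrs),
                ]
            )
        )
        if feat.exons:
            for i, (s, e) in enumerate(feat.exons, 1):
                lines.append(
                    "\t".join(
                        [
                            record.id,
                            src,
                            "exon",
                            str(s),
                            str(e),
                            ".",
                            feat.strand,
                            ".",
                            f"ID={feat.feature_id}.exon{i};Parent={feat.feature_id}",
                        ]
                    )
                )
    gff_path.write_text("\n".join(lines) + "\n")
    with open(fasta_path, "w") as fh:
        SeqIO.write(
            [SeqRecord(Seq(record.sequence), id=record.id, description="")], fh, "fasta"
        )
    return gff_path, fasta_path


def records_equivalent(a: GenomeRecord, b: GenomeRecord) -> bool:
    """Same sequence and the same feature signatures, order included."""
    return (
        a.sequence == b.sequence
        and len(a.features) == len(b.features)
        and all(x.signature() == y.signature() for x, y in zip(a.features, b.features))
    )


def copy_record(record: GenomeRecord) -> GenomeRecord:
    return GenomeRecord(
        id=record.id,
        clade=record.clade,
        sequence=record.sequence,
        features=[replace(f, qualifiers=dict(f.qualifiers),
                          exons=list(f.exons) if f.exons else None)
                  for f in record.features],
    )
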