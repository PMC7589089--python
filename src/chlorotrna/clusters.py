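"""tRNA gene cluster detection, spacers, orphans and genome position.

A cluster is two or more tRNA genes chained left-to-right while the gap to the
next tRNA stays within ``max_gap_nt``, the strand constraint holds, and the
number of intervening non-tRNA features is acceptable: zero in ``strict`` mode
(the survey definition: no intervening genes, 2 or more tRNAs), up to
``max_intervening_features`` in ``relaxed`` mode (clusters interrupted by the
occasional CDS stay whole).  tRNAs not in any cluster are orphans, reported
with their distance to the nearest cluster boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .annotations import GenomeRecord, GenomicFeature
from .trna import TrnaGene, build_inventory


class ClusterError(ValueError):
    pass


@dataclass
class ClusterParams:
    mode: str = "relaxed"
    max_gap_nt: int = 2000
    max_intervening_features: int = 3
    min_genes: int = 2
    require_same_strand: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("strict", "relaxed"):
            raise ClusterError(f"unknown mode {self.mode!r}")
        if self.min_genes < 2:
            raise ClusterError("a cluster needs at least 2 genes")

    @property
    def intervening_budget(self) -> int:
        return 0 if self.mode == "strict" else self.max_intervening_features


@dataclass
class TrnaCluster:
    genes: list[TrnaGene]
    spacers: list[int]
    interrupting_features: list[GenomicFeature] = field(default_factory=list)

    @property
    def span(self) -> tuple[int, int]:
        return self.genes[0].start, self.genes[-1].end

    @property
    def strand(self) -> str:
        strands = {g.strand for g in self.genes}
        return strands.pop() if len(strands) == 1 else "mixed"

    @property
    def size(self) -> int:
        return len(self.genes)

    @property
    def order(self) -> list[str]:
        return [g.label for g in self.genes]


@dataclass
class OrphanAssignment:
    gene: TrnaGene
    nearest_cluster: TrnaCluster | None
    distance_nt: int | None


def intergenic_spacer(prev: TrnaGene, next_: TrnaGene) -> int:
    """Nucleotides between two adjacent genes: start(next) - end(prev) - 1."""
    if next_.start <= prev.end:
        raise ClusterError(
            f"features {prev.label}@{prev.start} and {next_.label}@{next_.start} "
            "overlap: annotation conflict"
        )
    return next_.start - prev.end - 1


def _intervening(all_features: list[GenomicFeature], lo: int, hi: int) -> list[GenomicFeature]:
    """Non-tRNA features lying strictly between coordinates lo and hi."""
    return [
        f
        for f in all_features
        if f.kind != "tRNA" and f.start > lo and f.end < hi
    ]


def detect_clusters(
    inventory: list[TrnaGene],
    all_features: list[GenomicFeature] | None = None,
    params: ClusterParams | None = None,
) -> tuple[list[TrnaCluster], list[OrphanAssignment]]:
    """Greedy left-to-right chaining of a genome-ordered tRNA inventory.

    Every tRNA ends up in exactly one cluster or in the orphan list.
    """
    params = params or ClusterParams()
    all_features = all_features or []
    chains: list[list[TrnaGene]] = []
    chain_interruptions: list[list[GenomicFeature]] = []
    for gene in sorted(inventory, key=lambda g: (g.start, g.end)):
        if chains:
            prev = chains[-1][-1]
            gap = intergenic_spacer(prev, gene)
            between = _intervening(all_features, prev.end, gene.start)
            strand_ok = (not params.require_same_strand) or gene.strand == prev.strand
            if (
                gap <= params.max_gap_nt
                and len(between) <= params.intervening_budget
                and strand_ok
            ):
                chains[-1].append(gene)
                chain_interruptions[-1].extend(between)
                continue
        chains.append([gene])
        chain_interruptions.append([])

    clusters: list[TrnaCluster] = []
    leftovers: list[TrnaGene] = []
    for chain, inter in zip(chains, chain_interruptions):
        if len(chain) >= params.min_genes:
            spacers = [intergenic_spacer(a, b) for a, b in zip(chain, chain[1:])]
            clusters.append(TrnaCluster(genes=chain, spacers=spacers,
                                        interrupting_features=inter))
        else:
            leftovers.extend(chain)

    orphans = []
    for gene in leftovers:
        best, dist = None, None
        for cl in clusters:
            lo, hi = cl.span
            d = lo - gene.end - 1 if gene.end < lo else gene.start - hi - 1
            if dist is None or d < dist:
                best, dist = cl, d
        orphans.append(OrphanAssignment(gene=gene, nearest_cluster=best, distance_nt=dist))
    return clusters, orphans


def genome_third(cluster: TrnaCluster, genome_length: int) -> str:
    """Classify the cluster midpoint into first/middle/last genome third.

    Boundaries are closed on the left: a midpoint exactly at length/3 is
    'first'.
    """
    lo, hi = cluster.span
    if hi > genome_length:
        raise ClusterError("cluster span exceeds genome length")
    mid = (lo + hi) / 2
    if mid <= genome_length / 3:
        return "first"
    if mid <= 2 * genome_length / 3:
        return "middle"
    return "last"


def cotranscription_candidate(cluster: TrnaCluster, max_spacer: int = 500) -> bool:
    """Could this cluster plausibly be transcribed as one Pol III transcript?

    True iff single strand, no interrupting feature, and every spacer at most
    ``max_spacer`` nt.
    """
    return (
        cluster.strand != "mixed"
        and not cluster.interrupting_features
        and all(s <= max_spacer for s in cluster.spacers)
    )


def cluster_table(
    genomes: list[GenomeRecord], params: ClusterParams | None = None
) -> pd.DataFrame:
    """Per-genome cluster report: ordered identity labels with spacers,
    pseudogene flags, and total tRNA counts (pseudogenes included)."""
    rows = []
    for rec in genomes:
        inventory = build_inventory(rec)
        clusters, orphans = detect_clusters(inventory, rec.features, params)
        order_parts: list[str] = []
        for cl in clusters:
            toks = []
            for i, g in enumerate(cl.genes):
                toks.append(g.label + ("(pseudo)" if g.pseudogene else ""))
                if i < len(cl.spacers):
                    toks.append(str(cl.spacers[i]))
            order_parts.append(" ".join(toks))
        rows.append(
            {
                "genome": rec.id,
                "clade": rec.clade,
                "n_trna": len(inventory),
                "n_clusters": len(clusters),
                "n_orphans": len(orphans),
                "largest_cluster": max((c.size for c in clusters), default=0),
                "order": " | ".join(order_parts),
            }
        )
    return pd.DataFrame(rows)
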