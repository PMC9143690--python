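"""Tandem-duplication clustering and exon/intron structure profiling.

A tandem cluster is a maximal run of same-family genes on one scaffold in
which at most ``max_intervening`` genes of any other family sit between
consecutive members (default 1).  One cluster counts as one duplication
event regardless of its size.  Strand is ignored throughout.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

from .formats import GeneModel

__all__ = [
    "TandemCluster",
    "TandemSummary",
    "ExonProfile",
    "detect_tandem_clusters",
    "tandem_summary",
    "exon_profile",
]

DEFAULT_MAX_INTERVENING = 1


@dataclass(frozen=True)
class TandemCluster:
    scaffold: str
    family: str
    members: tuple[str, ...]  # gene ids ordered by start coordinate

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("a tandem cluster needs at least two members")

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class TandemSummary:
    family: str
    n_events: int  # = number of clusters
    n_scaffolds: int  # distinct scaffolds bearing at least one cluster
    genes_in_clusters: int
    total_genes: int
    percent_involved: float  # one-decimal rounding
    size_histogram: dict[int, int]


@dataclass(frozen=True)
class ExonProfile:
    exon_counts: dict[str, int]  # gene id -> number of exons
    histogram: dict[int, int]  # exon count -> number of genes
    percentages: dict[int, float]  # exon count -> % of genes, 2 decimals
    intronless: tuple[str, ...]


def detect_tandem_clusters(
    genes: Sequence[GeneModel], max_intervening: int = DEFAULT_MAX_INTERVENING
) -> list[TandemCluster]:
    """Chain same-family neighbors on each scaffold into maximal clusters.

    Genes are sorted internally by (start, end, id), so input order is
    irrelevant.  Genes without a family label never join a cluster.
    """
    if max_intervening < 0:
        raise ValueError("max_intervening must be non-negative")
    ids = [g.gene_id for g in genes]
    dup = [i for i, c in Counter(ids).items() if c > 1]
    if dup:
        raise ValueError(f"duplicate gene ids: {dup}")

    by_scaffold: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_scaffold.setdefault(g.scaffold, []).append(g)

    clusters: list[TandemCluster] = []
    for scaffold in sorted(by_scaffold):
        ordered = sorted(by_scaffold[scaffold], key=lambda g: (g.start, g.end, g.gene_id))
        families = sorted({g.family for g in ordered if g.family is not None})
        for fam in families:
            indices = [i for i, g in enumerate(ordered) if g.family == fam]
            chain: list[int] = []
            for idx in indices:
                if chain and idx - chain[-1] - 1 > max_intervening:
                    if len(chain) >= 2:
                        clusters.append(
                            TandemCluster(scaffold, fam, tuple(ordered[i].gene_id for i in chain))
                        )
                    chain = []
                chain.append(idx)
            if len(chain) >= 2:
                clusters.append(
                    TandemCluster(scaffold, fam, tuple(ordered[i].gene_id for i in chain))
                )
    return clusters


def tandem_summary(
    clusters: Sequence[TandemCluster], total_family_counts: Mapping[str, int]
) -> dict[str, TandemSummary]:
    """Per-family event counts, scaffold counts and involvement percentage."""
    out: dict[str, TandemSummary] = {}
    for fam, total in total_family_counts.items():
        fam_clusters = [c for c in clusters if c.family == fam]
        in_clusters = sum(c.size for c in fam_clusters)
        if total == 0 and fam_clusters:
            raise ValueError(f"family {fam!r}: clusters present but total count is zero")
        if in_clusters > total:
            raise ValueError(f"family {fam!r}: clustered genes exceed family total")
        percent = 0.0 if total == 0 else round(100.0 * in_clusters / total, 1)
        out[fam] = TandemSummary(
            family=fam,
            n_events=len(fam_clusters),
            n_scaffolds=len({c.scaffold for c in fam_clusters}),
            genes_in_clusters=in_clusters,
            total_genes=total,
            percent_involved=percent,
            size_histogram=dict(sorted(Counter(c.size for c in fam_clusters).items())),
        )
    return out


def exon_profile(genes: Sequence[GeneModel]) -> ExonProfile:
    """Exon-count histogram, per-bin percentages and intronless genes."""
    if not genes:
        return ExonProfile({}, {}, {}, ())
    counts = {g.gene_id: g.n_exons for g in genes}
    hist = dict(sorted(Counter(counts.values()).items()))
    n = len(genes)
    percentages = {k: round(100.0 * v / n, 2) for k, v in hist.items()}
    intronless = tuple(g.gene_id for g in genes if g.intronless)
    return ExonProfile(counts, hist, percentages, intronless)
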