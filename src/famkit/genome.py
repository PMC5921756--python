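"""Genome organization: chromosomal distribution, isoform census,
tandem-cluster detection, and duplication-pair evolution.

Clustering gap convention: the distance between coordinate-sorted
neighbors is end-to-start (``next.start - prev.end``), 1-based closed
coordinates. This reproduces the sub-190-kb separations of the known
tandem clusters in the packaged family table.
"""

from __future__ import annotations

import logging
import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from famkit.errors import FamkitError, UndefinedRatioError
from famkit.model import (
    NEUTRAL,
    POSITIVE,
    PURIFYING_OR_DRIFT,
    DuplicatePair,
    GeneRecord,
)

log = logging.getLogger("famkit.genome")

#: Synonymous substitution rate for eudicots, substitutions/site/year.
DEFAULT_GAMMA = 6.1e-9

#: Maximum inter-gene gap (bp) for two genes to share a tandem cluster.
DEFAULT_TANDEM_WINDOW = 250_000


@dataclass
class ChromosomeDistribution:
    counts: dict[str, int]
    mapped_total: int
    fractions: dict[str, float]  # proportion of mapped genes, in [0, 1]

    def percent(self, chromosome: str) -> float:
        """Fraction as a percentage rounded to one decimal."""
        return round(100.0 * self.fractions.get(chromosome, 0.0), 1)


@dataclass
class TandemCluster:
    chromosome: str
    members: tuple[str, ...]
    span: int  # bp from first start to last end (1-based closed)
    max_gap: int

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise FamkitError("a tandem cluster requires at least two members")


def chromosome_distribution(records: Iterable[GeneRecord]) -> ChromosomeDistribution:
    """Count placed genes per chromosome; unplaced genes are excluded."""
    placed = [r for r in records if r.placed]
    if not placed:
        raise FamkitError("no placed records: chromosome distribution undefined")
    counts = Counter(r.chromosome for r in placed)
    total = len(placed)
    fractions = {c: n / total for c, n in counts.items()}
    return ChromosomeDistribution(counts=dict(counts), mapped_total=total, fractions=fractions)


def isoform_census(records: Iterable[GeneRecord]) -> tuple[dict[int, int], int]:
    """Histogram of isoform counts plus the total transcript count."""
    records = list(records)
    hist = Counter(r.isoform_count for r in records)
    total = sum(r.isoform_count for r in records)
    return dict(hist), total


def detect_tandem_clusters(
    records: Iterable[GeneRecord], window: int = DEFAULT_TANDEM_WINDOW
) -> list[TandemCluster]:
    """Find maximal same-chromosome runs of genes with inter-gene gaps
    below ``window``.

    Genes are sorted by start within each chromosome; consecutive genes
    with ``next.start - prev.end < window`` extend a run, and runs of
    length >= 2 become clusters. The result is independent of input
    order. Overlapping genes (negative gap) are treated as gap 0 with a
    logged warning.
    """
    by_chrom: dict[str, list[GeneRecord]] = defaultdict(list)
    for r in records:
        if r.placed:
            by_chrom[r.chromosome].append(r)
    clusters: list[TandemCluster] = []
    for chrom in sorted(by_chrom):
        genes = sorted(by_chrom[chrom], key=lambda r: (r.start, r.name))
        run: list[GeneRecord] = [genes[0]]
        gaps: list[int] = []
        for prev, nxt in zip(genes, genes[1:]):
            gap = nxt.start - prev.end  # type: ignore[operator]
            if gap < 0:
                log.warning(
                    "%s and %s overlap on %s; treating gap as 0", prev.name, nxt.name, chrom
                )
                gap = 0
            if gap < window:
                run.append(nxt)
                gaps.append(gap)
            else:
                if len(run) >= 2:
                    clusters.append(_make_cluster(chrom, run, gaps))
                run, gaps = [nxt], []
        if len(run) >= 2:
            clusters.append(_make_cluster(chrom, run, gaps))
    return clusters


def _make_cluster(chrom: str, run: Sequence[GeneRecord], gaps: Sequence[int]) -> TandemCluster:
    return TandemCluster(
        chromosome=chrom,
        members=tuple(r.name for r in run),
        span=run[-1].end - run[0].start + 1,  # type: ignore[operator]
        max_gap=max(gaps),
    )


def divergence_time(ks: float, gamma: float = DEFAULT_GAMMA) -> float:
    """Divergence time T = Ks / (2 * gamma) in million years.

    Full precision is kept; round to integer Mya only at presentation.
    """
    if ks < 0:
        raise FamkitError(f"Ks must be >= 0, got {ks}")
    if gamma <= 0:
        raise FamkitError(f"gamma must be > 0, got {gamma}")
    return ks / (2.0 * gamma) / 1e6


def selection_mode(ka: float, ks: float, neutral_tol: float = 0.05) -> str:
    """Classify the selection regime of a duplicate pair from Ka/Ks.

    ratio within ``neutral_tol`` of 1 -> neutral; above -> positive;
    below -> purifying selection on one copy (or neutral drift on the
    other). Ks = 0 makes the ratio undefined and raises.
    """
    if ks <= 0:
        raise UndefinedRatioError("Ka/Ks undefined: Ks = 0")
    ratio = ka / ks
    if abs(ratio - 1.0) <= neutral_tol:
        return NEUTRAL
    if ratio > 1.0 + neutral_tol:
        return POSITIVE
    return PURIFYING_OR_DRIFT


def annotate_pair(
    pair: DuplicatePair, gamma: float = DEFAULT_GAMMA, neutral_tol: float = 0.05
) -> DuplicatePair:
    """Fill in ratio, divergence time and selection mode for a raw pair."""
    ratio = pair.ka / pair.ks if pair.ks > 0 else None
    mode = selection_mode(pair.ka, pair.ks, neutral_tol) if pair.ks > 0 else None
    return DuplicatePair(
        gene_a=pair.gene_a,
        gene_b=pair.gene_b,
        ka=pair.ka,
        ks=pair.ks,
        ratio=ratio,
        time_mya=divergence_time(pair.ks, gamma),
        mode=mode,
    )


@dataclass
class DuplicationSummary:
    mean_ratio: float
    ratio_range: tuple[float, float]
    time_histogram: dict[int, int] = field(default_factory=dict)  # 10-Mya bin lower edges
    n_pairs: int = 0
    n_undefined: int = 0


def duplication_summary(pairs: Iterable[DuplicatePair], bin_mya: float = 10.0) -> DuplicationSummary:
    """Mean and range of defined Ka/Ks ratios plus a divergence-time
    histogram in 10-Mya bins (keyed by bin lower edge)."""
    pairs = list(pairs)
    if not pairs:
        raise FamkitError("duplication_summary requires at least one pair")
    ratios = [p.ratio for p in pairs if p.ratio is not None]
    if not ratios:
        raise FamkitError("all Ka/Ks ratios undefined (Ks = 0 everywhere)")
    hist: Counter[int] = Counter()
    for p in pairs:
        if p.time_mya is not None:
            hist[int(math.floor(p.time_mya / bin_mya) * bin_mya)] += 1
    return DuplicationSummary(
        mean_ratio=sum(ratios) / len(ratios),
        ratio_range=(min(ratios), max(ratios)),
        time_histogram=dict(hist),
        n_pairs=len(pairs),
        n_undefined=len(pairs) - len(ratios),
    )
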