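"""RT-qPCR analytics.

Amplification efficiency from a log-dilution regression slope,
reference-gene stability (geNorm M and the coefficient of variation of
normalized relative quantities), efficiency-corrected multi-reference
normalization with replicate-based error propagation, a 3':5'
RNA-integrity check, and expression-matrix ordination/clustering.

Replicate Cq values are averaged before quantity computation; their
standard error feeds the propagated NRQ uncertainty. A missing Cq
(no amplification within the cycle limit) is treated as not detected
and never imputed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from famkit.errors import FamkitError, SchemaError

log = logging.getLogger("famkit.qpcr")

CYCLE_LIMIT = 40.0

OK = "OK"
BORDERLINE = "BORDERLINE"
INADEQUATE = "INADEQUATE"


@dataclass
class CqTable:
    """Long-format quantification-cycle data (sample, assay, replicate, cq).

    ``cq`` NaN marks no amplification within the cycle limit.
    """

    data: pd.DataFrame

    REQUIRED = ("sample", "assay", "replicate", "cq")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.data.columns)
        if missing:
            raise SchemaError(f"Cq table missing columns {sorted(missing)}")
        bad = self.data["cq"].dropna() <= 0
        if bad.any():
            raise FamkitError("Cq values must be positive where present")

    @classmethod
    def from_csv(cls, path: str | Path) -> "CqTable":
        return cls(pd.read_csv(path))

    @classmethod
    def from_wide(cls, frame: pd.DataFrame) -> "CqTable":
        """Wide layout: one row per (sample, replicate), one column per assay."""
        long = frame.melt(id_vars=["sample", "replicate"], var_name="assay", value_name="cq")
        return cls(long)

    @property
    def samples(self) -> list[str]:
        return list(dict.fromkeys(self.data["sample"]))

    @property
    def assays(self) -> list[str]:
        return list(dict.fromkeys(self.data["assay"]))

    def summary(self) -> pd.DataFrame:
        """Mean, SD and replicate count per (sample, assay); missing
        replicates are excluded from means."""
        g = self.data.dropna(subset=["cq"]).groupby(["sample", "assay"])["cq"]
        out = g.agg(mean="mean", sd="std", n="count").reset_index()
        out["sd"] = out["sd"].fillna(0.0)
        return out


@dataclass
class EfficiencyEstimate:
    assay: str
    efficiency: float  # fraction; 1.0 = 100 %
    slope: float
    flagged: bool = False


def efficiency_from_slope(slope: float, assay: str = "") -> EfficiencyEstimate:
    """Amplification efficiency E = 10**slope - 1 from the
    log-fluorescence regression slope."""
    if not math.isfinite(slope):
        raise FamkitError("slope must be finite")
    e = 10.0 ** slope - 1.0
    flagged = not (0.0 < e <= 1.2)
    if flagged:
        log.warning("%s: efficiency %.3f outside (0, 1.2]", assay or "assay", e)
    return EfficiencyEstimate(assay=assay, efficiency=e, slope=slope, flagged=flagged)


def relative_quantity(cq: float, calibrator_cq: float, efficiency: float) -> float:
    """Efficiency-corrected relative quantity (1+E)**(calibrator_cq - cq)."""
    if math.isnan(cq) or math.isnan(calibrator_cq):
        return math.nan
    return (1.0 + efficiency) ** (calibrator_cq - cq)


# ---------------------------------------------------------------------------
# geNorm stability
# ---------------------------------------------------------------------------

@dataclass
class StabilityResult:
    m_values: dict[str, float]         # full-panel M per assay
    cv_values: dict[str, float]        # CV of NRQs against the final reference set
    ranking: list[str]                 # most stable first
    elimination_order: list[str]       # assays removed, least stable first
    final_pair: tuple[str, str]


def _pairwise_m(quantities: pd.DataFrame) -> dict[str, float]:
    logq = np.log2(quantities)
    m = {}
    for j in quantities.columns:
        sds = [
            float((logq[j] - logq[k]).std(ddof=1))
            for k in quantities.columns
            if k != j
        ]
        m[j] = float(np.mean(sds))
    return m


def genorm_m(quantities: pd.DataFrame) -> StabilityResult:
    """geNorm expression-stability analysis.

    ``quantities`` is a sample x assay frame of positive relative
    quantities. M_j is the mean, over the other assays k, of the
    standard deviation across samples of log2(q_j / q_k). Iterative
    elimination of the least-stable assay yields the ranking; the CV of
    each assay's quantities normalized by the geometric mean of the
    final reference pair completes the result.
    """
    if quantities.shape[1] < 2 or quantities.shape[0] < 2:
        raise FamkitError("geNorm requires >= 2 assays and >= 2 samples")
    bad = quantities.stack()
    offenders = bad[bad <= 0]
    if len(offenders):
        sample, assay = offenders.index[0]
        raise FamkitError(f"non-positive quantity at sample {sample!r}, assay {assay!r}")

    full_m = _pairwise_m(quantities)
    remaining = quantities.copy()
    eliminated: list[str] = []
    while remaining.shape[1] > 2:
        m = _pairwise_m(remaining)
        worst = max(sorted(m), key=lambda a: m[a])
        eliminated.append(worst)
        remaining = remaining.drop(columns=[worst])
    final_pair = tuple(sorted(remaining.columns))
    ranking = list(final_pair) + list(reversed(eliminated))

    ref_factor = np.exp(np.log(remaining).mean(axis=1))  # geometric mean per sample
    cv = {}
    for j in quantities.columns:
        nrq = quantities[j] / ref_factor
        cv[j] = float(nrq.std(ddof=1) / nrq.mean())
    return StabilityResult(
        m_values=full_m,
        cv_values=cv,
        ranking=ranking,
        elimination_order=eliminated,
        final_pair=final_pair,  # type: ignore[arg-type]
    )


# ---------------------------------------------------------------------------
# NRQ with error propagation
# ---------------------------------------------------------------------------

@dataclass
class NRQMatrix:
    nrq: pd.DataFrame       # sample x target
    se: pd.DataFrame        # propagated standard errors, same shape
    calibrator: str
    references: tuple[str, ...]


def nrq(
    cq_table: CqTable,
    efficiencies: dict[str, float],
    references: list[str],
    calibrator: str,
    pool_replicate_variance: bool = True,
) -> NRQMatrix:
    """Normalized relative quantities with propagated uncertainties.

    NRQ(s, t) = RQ_t(s) / geomean_r RQ_r(s), rescaled so the calibrator
    sample equals 1 for every target. Relative standard errors combine
    in quadrature: the target's ln(1+E) * SEM(Cq) term plus the
    reference geometric-mean term (1/R^2 weighting) and the calibrator
    cell's own terms from the rescaling.

    With ``pool_replicate_variance`` (default) the replicate Cq variance
    is pooled per assay across samples before SEM computation. Per-cell
    SDs from 2-3 technical replicates are too unstable (and biased low)
    to give calibrated intervals; pooling assumes homoscedastic
    replicate noise within an assay, the usual situation for technical
    replicates on one plate.
    """
    if not references:
        raise FamkitError("at least one reference assay is required")
    summary = cq_table.summary()
    if pool_replicate_variance:
        pooled = {}
        for assay, group in summary.groupby("assay"):
            df = (group["n"] - 1).sum()
            if df > 0:
                pooled[assay] = math.sqrt(
                    ((group["n"] - 1) * group["sd"] ** 2).sum() / df
                )
        summary = summary.copy()
        summary["sd"] = summary["assay"].map(pooled).fillna(summary["sd"])
    summary = summary.set_index(["sample", "assay"])
    samples = cq_table.samples
    targets = [a for a in cq_table.assays if a not in references]
    if calibrator not in samples:
        raise FamkitError(f"calibrator sample {calibrator!r} not in table")
    for assay in cq_table.assays:
        if assay not in efficiencies:
            raise FamkitError(f"no efficiency for assay {assay!r}")

    def cell(sample: str, assay: str) -> tuple[float, float]:
        """(mean Cq, SEM) or (nan, nan) when absent."""
        try:
            row = summary.loc[(sample, assay)]
        except KeyError:
            return math.nan, math.nan
        sem = row["sd"] / math.sqrt(row["n"]) if row["n"] > 0 else math.nan
        return float(row["mean"]), float(sem)

    def rq_and_rse(sample: str, assay: str) -> tuple[float, float]:
        e = efficiencies[assay]
        mean, sem = cell(sample, assay)
        cal_mean, _ = cell(calibrator, assay)
        q = relative_quantity(mean, cal_mean, e)
        rse = math.log(1.0 + e) * sem  # relative SE of the quantity
        return q, rse

    nrq_frame = pd.DataFrame(index=samples, columns=targets, dtype=float)
    se_frame = pd.DataFrame(index=samples, columns=targets, dtype=float)
    r = len(references)
    for s in samples:
        ref_qs, ref_rses = [], []
        for refa in references:
            q, rse = rq_and_rse(s, refa)
            ref_qs.append(q)
            ref_rses.append(rse)
        if any(math.isnan(q) for q in ref_qs):
            log.warning("sample %s: reference assay missing; NRQs set missing", s)
            continue
        ref_geo = math.exp(sum(math.log(q) for q in ref_qs) / r)
        ref_var = sum(rse ** 2 for rse in ref_rses) / r ** 2
        for t in targets:
            q, rse = rq_and_rse(s, t)
            if math.isnan(q):
                continue
            nrq_frame.loc[s, t] = q / ref_geo
            se_frame.loc[s, t] = math.sqrt(rse ** 2 + ref_var)  # relative, pre-rescale

    # rescale to the calibrator sample and convert relative SE -> absolute SE
    for t in targets:
        cal_val = nrq_frame.loc[calibrator, t]
        if math.isnan(cal_val):
            log.warning("target %s missing in calibrator; left unscaled", t)
            cal_val = 1.0
        cal_rse = se_frame.loc[calibrator, t]
        cal_rse = 0.0 if math.isnan(cal_rse) else cal_rse
        for s in samples:
            val = nrq_frame.loc[s, t]
            if math.isnan(val):
                continue
            scaled = val / cal_val
            rse = se_frame.loc[s, t]
            if s != calibrator:
                rse = math.sqrt(rse ** 2 + cal_rse ** 2)
            nrq_frame.loc[s, t] = scaled
            se_frame.loc[s, t] = scaled * rse
    return NRQMatrix(nrq=nrq_frame, se=se_frame, calibrator=calibrator, references=tuple(references))


# ---------------------------------------------------------------------------
# RNA integrity
# ---------------------------------------------------------------------------

@dataclass
class IntegrityResult:
    ratio: float
    verdict: str


def integrity_ratio(cq_5prime: float, cq_3prime: float) -> IntegrityResult:
    """3':5' comparative-Cq amplification ratio 2**(Cq5' - Cq3').

    Verdict: OK below 3.8, INADEQUATE above 4.4, BORDERLINE between.
    Assumes E = 1 for both fragments (the comparative-Cq convention).
    """
    if math.isnan(cq_5prime) or math.isnan(cq_3prime):
        raise FamkitError("both Cq values are required for an integrity verdict")
    ratio = 2.0 ** (cq_5prime - cq_3prime)
    if ratio < 3.8:
        verdict = OK
    elif ratio > 4.4:
        verdict = INADEQUATE
    else:
        verdict = BORDERLINE
    return IntegrityResult(ratio=ratio, verdict=verdict)


# ---------------------------------------------------------------------------
# Expression matrix: log2 transform, clustering, ordination
# ---------------------------------------------------------------------------

def expression_matrix(nrq_matrix: NRQMatrix) -> pd.DataFrame:
    """log2-transformed NRQ matrix (samples x targets)."""
    values = nrq_matrix.nrq
    if (values.stack() <= 0).any():
        raise FamkitError("NRQ values must be positive for the log2 transform")
    return np.log2(values)


@dataclass
class Dendrogram:
    labels: list[str]
    linkage: np.ndarray

    def newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def fmt(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6f}"
            return (
                f"({fmt(node.left, node.dist)},{fmt(node.right, node.dist)}):{length:.6f}"
            )

        return f"({fmt(tree.left, tree.dist)},{fmt(tree.right, tree.dist)});"


def hier_cluster(matrix: pd.DataFrame, axis: int = 1, metric: str = "pearson", method: str = "average") -> Dendrogram:
    """Hierarchical clustering with 1 - Pearson correlation distance and
    average linkage by default. ``axis=1`` clusters columns (genes),
    ``axis=0`` clusters rows (samples)."""
    data = matrix.T if axis == 1 else matrix
    labels = list(data.index)
    if len(labels) < 2:
        raise FamkitError("clustering requires at least 2 items")
    if metric == "pearson":
        corr = np.corrcoef(data.values)
        corr = np.nan_to_num(corr, nan=0.0)
        dist = 1.0 - corr
        np.fill_diagonal(dist, 0.0)
        dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
        z = hierarchy.linkage(squareform(dist, checks=False), method=method)
    else:
        z = hierarchy.linkage(data.values, method=method, metric=metric)
    return Dendrogram(labels=labels, linkage=z)


@dataclass
class Ordination:
    coordinates: pd.DataFrame        # samples x components
    variance_fractions: np.ndarray   # nonnegative, non-increasing, sums to 1


def svd_ordination(matrix: pd.DataFrame) -> Ordination:
    """Principal-component ordination of samples via singular value
    decomposition of the column-centered matrix."""
    if matrix.shape[0] < 3:
        raise FamkitError("ordination requires at least 3 samples")
    centered = matrix.values - matrix.values.mean(axis=0, keepdims=True)
    if np.allclose(centered, 0.0):
        raise FamkitError("constant matrix: ordination undefined")
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    fractions = s ** 2 / np.sum(s ** 2)
    coords = pd.DataFrame(
        u * s,
        index=matrix.index,
        columns=[f"dim{i+1}" for i in range(len(s))],
    )
    return Ordination(coordinates=coords, variance_fractions=fractions)
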