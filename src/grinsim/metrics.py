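"""Ground-truth-aware evaluation of extracted traces.

Quantifies how faithfully an optical configuration demixes neighbouring
sources: pairwise correlations of adjacent ROIs against an expected
(ground-truth) correlation threshold, a GLM-based purity index per ROI,
the correlation with the most-correlated contributing ground-truth source,
and linear radial-trend regressions with permutation-test significance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .activity import pairwise_correlation_matrix
from .extract import ROIRecord
from .stats import PermutationSpec, normality_gate, perm_test_slope_zero

__all__ = [
    "PurityModel",
    "PairRecord",
    "expected_pair_correlation",
    "adjacent_pair_analysis",
    "purity_glm",
    "first_source_correlation",
    "radial_trend",
    "RadialTrend",
    "ADJACENCY_UM",
]

ADJACENCY_UM = 25.0  # adjacent-pair centroid distance (alternative: 30 µm)
FIRST_SOURCE_SNR_MIN = 10.0


@dataclass
class PurityModel:
    """Least-squares fit Y(t) = sum_j a_j X_j(t) + q and its purity index.

    ``purity = max_j(a_j^2) / sum_j(a_j^2)``; 1 means the extracted trace
    reflects a single ground-truth source.
    """

    coefficients: np.ndarray
    intercept: float
    source_ids: np.ndarray
    purity: float | None

    @property
    def k(self) -> int:
        return self.coefficients.size


@dataclass
class PairRecord:
    """One pair of detected ROIs."""

    id_a: int
    id_b: int
    distance_um: float
    radial_um: float  # distance of the pair midpoint from the FOV centre
    correlation: float


def expected_pair_correlation(
    fov_traces: list[np.ndarray], n_sd: float = 3.0
) -> tuple[float, float, float]:
    """Expected cell-pair correlation threshold from ground-truth traces.

    For each FOV, all-pairs Pearson correlations of the ground-truth source
    traces are computed; the threshold is the across-FOV average of the
    per-FOV means plus ``n_sd`` times the SD of the pooled pair
    correlations. Returns (threshold, mean, sd).
    """
    if not fov_traces:
        raise ValueError("need at least one FOV")
    fov_means = []
    pooled = []
    for tr in fov_traces:
        c = pairwise_correlation_matrix(np.asarray(tr))
        iu = np.triu_indices(c.shape[0], k=1)
        vals = c[iu]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise ValueError("FOV with no valid ground-truth pairs")
        fov_means.append(vals.mean())
        pooled.append(vals)
    pooled = np.concatenate(pooled)
    if pooled.size < 2:
        raise ValueError("SD undefined with a single pair")
    mean = float(np.mean(fov_means))
    sd = float(pooled.std(ddof=1))
    return mean + n_sd * sd, mean, sd


def build_pairs(
    rois: list[ROIRecord],
    positions_um: np.ndarray,
    traces: np.ndarray | None = None,
) -> list[PairRecord]:
    """All unordered ROI pairs with calibrated distances and correlations.

    ``positions_um``: (n, 2) calibrated sample-space positions relative to
    the FOV centre. Correlations are Pearson on dF/F0 unless ``traces``
    overrides the trace matrix.
    """
    if traces is None:
        traces = np.stack([r.dff for r in rois])
    c = pairwise_correlation_matrix(traces)
    out = []
    n = len(rois)
    for i in range(n):
        for j in range(i + 1, n):
            d = float(np.linalg.norm(positions_um[i] - positions_um[j]))
            mid = (positions_um[i] + positions_um[j]) / 2.0
            out.append(
                PairRecord(
                    rois[i].roi_id,
                    rois[j].roi_id,
                    d,
                    float(np.linalg.norm(mid)),
                    float(c[i, j]),
                )
            )
    return out


def adjacent_pair_analysis(
    pairs: list[PairRecord],
    snrs_by_id: dict[int, float],
    threshold: float,
    snr_grid=(0, 5, 10, 11, 12.5, 15, 16.5, 17.5, 20, 22.5, 25, 27.5, 30),
    adjacency_um: float = ADJACENCY_UM,
) -> dict:
    """Fraction of adjacent ROI pairs more correlated than expected, per
    peak-SNR cutoff.

    At each cutoff only ROIs with finite peak SNR above the cutoff survive.
    Returns per-cutoff fractions (NaN when no adjacent pair survives) plus
    the raw above-threshold and total counts.
    """
    fr, n_above, n_total = [], [], []
    for cutoff in snr_grid:
        kept_pairs = [
            p
            for p in pairs
            if p.distance_um <= adjacency_um
            and np.isfinite(snrs_by_id.get(p.id_a, np.nan))
            and np.isfinite(snrs_by_id.get(p.id_b, np.nan))
            and snrs_by_id[p.id_a] > cutoff
            and snrs_by_id[p.id_b] > cutoff
        ]
        total = len(kept_pairs)
        above = sum(1 for p in kept_pairs if p.correlation > threshold)
        n_total.append(total)
        n_above.append(above)
        fr.append(above / total if total else np.nan)
    return dict(
        snr_grid=np.asarray(snr_grid, dtype=float),
        fraction=np.asarray(fr),
        n_above=np.asarray(n_above),
        n_total=np.asarray(n_total),
    )


def purity_glm(y: np.ndarray, source_traces: np.ndarray, source_ids=None) -> PurityModel:
    """Fit the contributing-source GLM (identity link, with intercept) and
    compute the purity index from the linear coefficients.

    Collinear source sets fall back to the minimum-norm least-squares
    solution with a warning. An all-zero coefficient vector leaves the
    purity undefined (None) with a warning.
    """
    y = np.asarray(y, dtype=float)
    x = np.atleast_2d(np.asarray(source_traces, dtype=float))
    if x.shape[1] != y.size:
        x = x.T
    k = x.shape[0]
    if k < 1:
        raise ValueError("need at least one contributing source")
    design = np.column_stack([np.ones(y.size), x.T])
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        warnings.warn("collinear sources: minimum-norm solution", stacklevel=2)
    a = coef[1:]
    ss = float(a @ a)
    if ss == 0.0:
        warnings.warn("all-zero GLM coefficients: purity undefined", stacklevel=2)
        purity = None
    else:
        purity = float(np.max(a**2) / ss)
    ids = np.arange(k) if source_ids is None else np.asarray(source_ids)
    return PurityModel(a, float(coef[0]), ids, purity)


def first_source_correlation(
    dff: np.ndarray, source_traces: np.ndarray
) -> tuple[float, int]:
    """Maximum Pearson correlation of the extracted trace over its
    contributing ground-truth sources; returns (correlation, argmax index)."""
    x = np.atleast_2d(np.asarray(source_traces, dtype=float))
    if x.shape[0] == 0:
        raise ValueError("no contributing sources")
    cors = np.array(
        [sps.pearsonr(dff, x[j]).statistic if np.ptp(x[j]) > 0 else np.nan
         for j in range(x.shape[0])]
    )
    if np.all(np.isnan(cors)):
        raise ValueError("all sources constant")
    j = int(np.nanargmax(cors))
    return float(cors[j]), j


@dataclass
class RadialTrend:
    slope: float
    intercept: float
    stderr: float
    p_slope: float
    test: str  # 'wald' or 'permutation'
    n: int
    r_max: float


def radial_trend(
    xs,
    ys,
    spec: PermutationSpec | None = None,
    restrict_r_max: float | None = None,
    alpha: float = 0.05,
) -> RadialTrend:
    """OLS trend of a metric against radial distance.

    Significance of the slope uses a Wald t-test when the fit residuals
    pass the normality gate and a pairings permutation test otherwise.
    ``restrict_r_max`` truncates the data to a common radial range before
    fitting (used when comparing two probe conditions).
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    keep = np.isfinite(xs) & np.isfinite(ys)
    xs, ys = xs[keep], ys[keep]
    if restrict_r_max is not None:
        keep = xs <= restrict_r_max
        xs, ys = xs[keep], ys[keep]
    if xs.size < 3:
        raise ValueError("need n >= 3")
    if np.ptp(xs) == 0:
        raise ValueError("degenerate x-range")
    if np.ptp(ys) == 0:
        return RadialTrend(
            0.0, float(ys[0]), 0.0, 1.0, "wald", int(xs.size), float(xs.max())
        )
    fit = sps.linregress(xs, ys)
    resid = ys - (fit.intercept + fit.slope * xs)
    if np.ptp(resid) == 0 or normality_gate(resid, alpha):
        p, test = float(fit.pvalue), "wald"
    else:
        p, test = perm_test_slope_zero(xs, ys, spec), "permutation"
    return RadialTrend(
        float(fit.slope),
        float(fit.intercept),
        float(fit.stderr),
        p,
        test,
        int(xs.size),
        float(xs.max()),
    )
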