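"""Permutation tests and normality gating.

Permutation p-values use the add-one (Phipson–Smyth) correction so they are
never zero, and subsets of the permutation group are sampled uniformly with
replacement. The permutation count follows the convention of the reference
analysis: 10^4 permutations for n < 500, 10^5 for n >= 500.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "PermutationSpec",
    "perm_test_slope_zero",
    "perm_test_slope_difference",
    "perm_test_mean_difference",
    "rank_test",
    "normality_gate",
]


@dataclass
class PermutationSpec:
    """Permutation-test configuration.

    ``kind`` is 'pairings' (shuffle the x–y pairing) or 'independent'
    (shuffle condition labels). ``n_perm=None`` selects 10^4 or 10^5 by
    sample size.
    """

    kind: str = "pairings"
    n_perm: int | None = None
    seed: int = 0

    def resolve_n_perm(self, n: int) -> int:
        if self.n_perm is not None:
            if self.n_perm < 1:
                raise ValueError("n_perm must be >= 1")
            return self.n_perm
        return 10_000 if n < 500 else 100_000


def _slope(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    return float(xc @ (y - y.mean()) / (xc @ xc))


def _slopes_permuted(x: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Slopes of y-permutations (rows of ``ys``) against fixed x."""
    xc = x - x.mean()
    sxx = xc @ xc
    return (ys - ys.mean(axis=1, keepdims=True)) @ xc / sxx


def perm_test_slope_zero(x, y, spec: PermutationSpec | None = None) -> float:
    """Two-sided permutation p-value for an OLS slope differing from zero.

    The null is built by refitting the regression on random re-pairings of
    x and y.
    """
    spec = spec or PermutationSpec()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need matched samples with n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("x is constant")
    n_perm = spec.resolve_n_perm(x.size)
    rng = np.random.default_rng(spec.seed)
    obs = abs(_slope(x, y))
    perm_idx = rng.permuted(
        np.broadcast_to(np.arange(x.size), (n_perm, x.size)).copy(), axis=1
    )
    null = np.abs(_slopes_permuted(x, y[perm_idx]))
    return float((1 + np.sum(null >= obs)) / (n_perm + 1))


def perm_test_slope_difference(
    x1, y1, x2, y2, spec: PermutationSpec | None = None
) -> float:
    """Two-sided permutation p-value for slope_1 != slope_2.

    The null reassigns the pooled (x, y) observations at random to the two
    conditions, preserving the sample sizes.
    """
    spec = spec or PermutationSpec(kind="independent")
    x1, y1 = np.asarray(x1, float), np.asarray(y1, float)
    x2, y2 = np.asarray(x2, float), np.asarray(y2, float)
    if x1.size < 3 or x2.size < 3:
        raise ValueError("both samples need n >= 3")
    n1 = x1.size
    xs = np.concatenate([x1, x2])
    ys = np.concatenate([y1, y2])
    n = xs.size
    n_perm = spec.resolve_n_perm(n)
    rng = np.random.default_rng(spec.seed)
    obs = abs(_slope(x1, y1) - _slope(x2, y2))
    count = 0
    batch = max(1, min(n_perm, int(2e6 // max(n, 1))))
    done = 0
    while done < n_perm:
        b = min(batch, n_perm - done)
        idx = rng.permuted(np.broadcast_to(np.arange(n), (b, n)).copy(), axis=1)
        xa, ya = xs[idx[:, :n1]], ys[idx[:, :n1]]
        xb, yb = xs[idx[:, n1:]], ys[idx[:, n1:]]
        sa = _rowwise_slopes(xa, ya)
        sb = _rowwise_slopes(xb, yb)
        count += int(np.sum(np.abs(sa - sb) >= obs))
        done += b
    return float((1 + count) / (n_perm + 1))


def _rowwise_slopes(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    sxx = np.sum(xc * xc, axis=1)
    sxx[sxx == 0] = np.nan
    return np.sum(xc * yc, axis=1) / sxx


def perm_test_mean_difference(a, b, spec: PermutationSpec | None = None) -> float:
    """Two-sided permutation p-value for mean(a) != mean(b) (labels shuffled)."""
    spec = spec or PermutationSpec(kind="independent")
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("samples must be non-empty")
    pooled = np.concatenate([a, b])
    n, na = pooled.size, a.size
    n_perm = spec.resolve_n_perm(n)
    rng = np.random.default_rng(spec.seed)
    obs = abs(a.mean() - b.mean())
    count = 0
    batch = max(1, min(n_perm, int(2e6 // max(n, 1))))
    done = 0
    total = pooled.sum()
    while done < n_perm:
        bsize = min(batch, n_perm - done)
        idx = rng.permuted(np.broadcast_to(np.arange(n), (bsize, n)).copy(), axis=1)
        suma = pooled[idx[:, :na]].sum(axis=1)
        diff = suma / na - (total - suma) / (n - na)
        count += int(np.sum(np.abs(diff) >= obs))
        done += bsize
    return float((1 + count) / (n_perm + 1))


def rank_test(a, b) -> float:
    """Two-sided Mann–Whitney U p-value."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("samples must be non-empty")
    return float(sps.mannwhitneyu(a, b, alternative="two-sided").pvalue)


def normality_gate(x, alpha: float = 0.05) -> bool:
    """True when the sample looks Gaussian: Shapiro–Wilk for n < 50,
    D'Agostino–Pearson for n >= 50."""
    x = np.asarray(x, float)
    if x.size < 3:
        raise ValueError("need n >= 3 for a normality test")
    if x.size < 50:
        p = sps.shapiro(x).pvalue
    else:
        p = sps.normaltest(x).pvalue
    return bool(p >= alpha)
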