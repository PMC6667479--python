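"""Harmonic-regression detection of circadian oscillations.

The core model is the three-parameter cosinor

    y(t) = m + a·cos(ωt) + b·sin(ωt),        ω = 2π / T

fitted by ordinary least squares at a fixed period T. Amplitude is
A = sqrt(a² + b²) and the acrophase (time of the model peak) follows the
cosine convention y(t) = m + A·cos(2π(t − φ_h)/T), i.e. φ = atan2(b, a)
and φ_h = (φ / 2π)·T mod T. Significance comes from the F-test of
(a, b) = (0, 0) against the intercept-only model with (2, n − 3) degrees
of freedom.

Oscillation calling scans a period grid (default 21–27 h for array-style
calls; 14–27 h by 0.1 h is the conventional reporting grid for qPCR
series), takes the best-p fit, runs a nonparametric rank-periodicity
companion test at the best period, and combines the two p-values by
Fisher's method (−2Σln p ~ χ²₄). Genes with combined p below alpha are
flagged as oscillating. No multiple-testing correction is applied across
genes by default; pass ``adjust="bh"`` to opt in.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .io import TimeCourseMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "HarmonicFit",
    "RhythmCall",
    "fit_harmonic",
    "scan_periods",
    "rank_periodicity_test",
    "detect_oscillating",
    "acrophase_shift",
    "combine_fisher",
]

_TINY_P = 1e-300  # floor for log of p-values in Fisher's combination
_ZERO_SS = 1e-24  # relative threshold below which a sum of squares is "zero"


@dataclass
class HarmonicFit:
    """Least-squares cosinor fit of one series at a fixed period."""

    mesor: float
    cos_coef: float
    sin_coef: float
    amplitude: float
    acrophase_rad: float
    acrophase_h: float
    period_h: float
    f_statistic: float
    p_value: float

    def predict(self, times_h: np.ndarray) -> np.ndarray:
        omega = 2 * np.pi / self.period_h
        t = np.asarray(times_h, dtype=float)
        return self.mesor + self.cos_coef * np.cos(omega * t) + self.sin_coef * np.sin(omega * t)


@dataclass
class RhythmCall:
    """Per-gene oscillation call over a period band."""

    gene_id: str
    best_period_h: float
    harmonic_p: float
    rank_p: float
    combined_p: float
    is_oscillating: bool
    fit: HarmonicFit | None = None


def _design(times_h: np.ndarray, period_h: float) -> np.ndarray:
    omega = 2 * np.pi / period_h
    return np.column_stack(
        [np.ones_like(times_h), np.cos(omega * times_h), np.sin(omega * times_h)]
    )


def _check_series(series, times_h):
    y = np.asarray(series, dtype=float)
    t = np.asarray(times_h, dtype=float)
    if y.shape != t.shape or y.ndim != 1:
        raise ValueError("series and times_h must be 1-D and of equal length")
    if len(y) < 4:
        raise ValueError(f"need >=4 points for a 3-parameter cosinor fit, got {len(y)}")
    if not np.all(np.isfinite(y)):
        raise ValueError("series contains non-finite values")
    if np.ptp(t) == 0:
        raise ValueError("all sampling times are equal")
    return y, t


def fit_harmonic(series: Sequence[float], times_h: Sequence[float], period_h: float) -> HarmonicFit:
    """OLS cosinor fit of one series at the given period.

    Raises a conditioning error when the sampling times alias the period
    (singular design), and an insufficient-data error below 4 points.
    """
    if period_h <= 0:
        raise ValueError("period_h must be positive")
    y, t = _check_series(series, times_h)
    X = _design(t, period_h)
    # rank check catches times aliasing the period (e.g. all t multiples of T)
    if np.linalg.matrix_rank(X) < 3:
        raise np.linalg.LinAlgError(
            f"design singular at period {period_h} h: sampling times alias the period"
        )
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sse = float(resid @ resid)
    sst = float(np.sum((y - y.mean()) ** 2))
    n = len(y)
    scale = max(sst, float(y @ y), 1.0)
    if sst <= _ZERO_SS * scale:  # constant series: null model exact
        m = float(y.mean())
        return HarmonicFit(m, 0.0, 0.0, 0.0, 0.0, 0.0, period_h, 0.0, 1.0)
    if sse <= _ZERO_SS * scale:  # perfect fit
        f_stat, p = np.inf, 0.0
    else:
        f_stat = ((sst - sse) / 2) / (sse / (n - 3))
        f_stat = max(f_stat, 0.0)
        p = float(stats.f.sf(f_stat, 2, n - 3))
    m, a, b = (float(v) for v in beta)
    amp = math.hypot(a, b)
    phi = math.atan2(b, a)  # in (-pi, pi]
    phi_h = (phi / (2 * np.pi)) * period_h % period_h
    if period_h - phi_h < 1e-9 * period_h:  # roundoff can land exactly on T
        phi_h = 0.0
    return HarmonicFit(m, a, b, amp, phi, phi_h, period_h, float(f_stat), p)


def scan_periods(
    series: Sequence[float],
    times_h: Sequence[float],
    period_range_h: tuple = (14.0, 27.0),
    step_h: float = 0.1,
) -> HarmonicFit:
    """Best cosinor fit over a period grid; ties broken by lower period."""
    lo, hi = period_range_h
    if not (0 < lo <= hi) or step_h <= 0:
        raise ValueError("invalid period range or step")
    grid = _period_grid(lo, hi, step_h)
    if len(grid) == 0:
        raise ValueError("empty period grid")
    best: HarmonicFit | None = None
    for T in grid:
        fit = fit_harmonic(series, times_h, T)
        if best is None or fit.p_value < best.p_value:
            best = fit
    assert best is not None
    return best


def _period_grid(lo: float, hi: float, step: float) -> np.ndarray:
    n = int(round((hi - lo) / step))
    grid = lo + step * np.arange(n + 1)
    return grid[grid <= hi + 1e-9]


def rank_periodicity_test(
    series: Sequence[float],
    times_h: Sequence[float],
    period_h: float,
    phase_grid: int = 24,
) -> float:
    """Nonparametric periodicity p-value at a fixed period.

    Kendall's tau between the observed series and a cosine reference is
    evaluated at ``phase_grid`` equally spaced acrophases over one cycle;
    the minimal one-sided (greater) exact-tau p is Bonferroni-corrected
    for the number of phases. Anti-phase signals are caught by the phase
    grid itself. A constant series returns p = 1 by convention.
    """
    y = np.asarray(series, dtype=float)
    t = np.asarray(times_h, dtype=float)
    if len(y) < 6:
        raise ValueError("rank periodicity test needs >=6 points")
    if phase_grid < 1:
        raise ValueError("phase_grid must be >=1")
    if np.ptp(y) == 0:
        return 1.0
    best = 1.0
    for k in range(phase_grid):
        phase = k * period_h / phase_grid
        ref = np.cos(2 * np.pi * (t - phase) / period_h)
        res = stats.kendalltau(ref, y, alternative="greater")
        if np.isfinite(res.pvalue):
            best = min(best, float(res.pvalue))
    return float(min(1.0, best * phase_grid))


def combine_fisher(p_values: Sequence[float]) -> float:
    """Fisher's combination: −2Σln p ~ χ² with 2k degrees of freedom."""
    ps = np.clip(np.asarray(p_values, dtype=float), _TINY_P, 1.0)
    stat = -2.0 * np.sum(np.log(ps))
    return float(stats.chi2.sf(stat, 2 * len(ps)))


def detect_oscillating(
    matrix: TimeCourseMatrix,
    period_range_h: tuple = (21.0, 27.0),
    alpha: float = 0.05,
    step_h: float = 0.1,
    phase_grid: int = 24,
    adjust: str | None = None,
) -> list:
    """Call oscillating genes over a period band.

    For every gene the harmonic F-test p at the best period of the grid and
    the rank-periodicity p at that period are combined by Fisher's method;
    genes with combined p < alpha are flagged. Results are sorted by
    combined p. Per-gene fit failures are logged and the gene skipped.
    """
    lo, hi = period_range_h
    grid = _period_grid(lo, hi, step_h)
    if len(grid) == 0:
        raise ValueError("empty period grid")
    t = matrix.times_h
    n = len(t)
    if n < 4:
        raise ValueError("need >=4 time points")
    Y = matrix.values
    centered = Y - Y.mean(axis=1, keepdims=True)
    sst = np.sum(centered**2, axis=1)
    scale = np.maximum(np.maximum(sst, np.sum(Y**2, axis=1)), 1.0)
    best_p = np.ones(matrix.n_genes)
    best_T = np.full(matrix.n_genes, grid[0])
    # vectorized scan: solve all genes at once per period
    for T in grid:
        X = _design(t, T)
        if np.linalg.matrix_rank(X) < 3:
            logger.warning("period %.2f h aliases the sampling grid; skipped", T)
            continue
        beta, _, _, _ = np.linalg.lstsq(X, Y.T, rcond=None)
        resid = Y.T - X @ beta
        sse = np.sum(resid**2, axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            f = ((sst - sse) / 2) / (sse / (n - 3))
        p = np.where(
            sst <= _ZERO_SS * scale,
            1.0,
            np.where(sse <= _ZERO_SS * scale, 0.0, stats.f.sf(np.maximum(f, 0.0), 2, n - 3)),
        )
        better = p < best_p  # strict: earlier (lower) period wins ties
        best_p[better] = p[better]
        best_T[better] = T
    calls: list = []
    for i, gene in enumerate(matrix.gene_ids):
        try:
            fit = fit_harmonic(Y[i], t, float(best_T[i]))
            rank_p = rank_periodicity_test(Y[i], t, float(best_T[i]), phase_grid)
        except (ValueError, np.linalg.LinAlgError) as exc:
            logger.warning("gene %s skipped: %s", gene, exc)
            continue
        combined = combine_fisher([fit.p_value, rank_p])
        calls.append(
            RhythmCall(gene, float(best_T[i]), fit.p_value, rank_p, combined, False, fit)
        )
    if adjust == "bh":
        from statsmodels.stats.multitest import multipletests

        adj = multipletests([c.combined_p for c in calls], method="fdr_bh")[1]
        for c, q in zip(calls, adj):
            c.combined_p = float(q)
    elif adjust is not None:
        raise ValueError(f"unknown adjustment {adjust!r}")
    for c in calls:
        c.is_oscillating = c.combined_p < alpha
    calls.sort(key=lambda c: (c.combined_p, c.gene_id))
    return calls


def acrophase_shift(fit_a: HarmonicFit, fit_b: HarmonicFit) -> float:
    """Signed minimal circular acrophase difference b − a, in (−T/2, T/2].

    Negative values mean condition b peaks earlier than condition a. The
    two fits must agree on period within 10% (relative to their mean).
    """
    Ta, Tb = fit_a.period_h, fit_b.period_h
    T = 0.5 * (Ta + Tb)
    if abs(Ta - Tb) > 0.1 * T:
        raise ValueError(f"periods differ by more than 10%: {Ta} vs {Tb} h")
    d = (fit_b.acrophase_h - fit_a.acrophase_h + T / 2) % T - T / 2
    if d <= -T / 2:  # map [-T/2, T/2) onto (-T/2, T/2]
        d += T
    return float(d)
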