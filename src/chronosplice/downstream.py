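"""Correlation analyses and qPCR quantification feeding the rhythm fits.

Correlations (Pearson or Spearman) are computed between row sets of a
time-course matrix across its time columns; zero-variance series yield
missing (NaN) entries, never silent zeros.

qPCR quantification follows the 2^−ΔΔCT convention: CT replicates are
averaged, ΔCT = CT_target − CT_reference per sample, ΔΔCT subtracts the
calibrator ΔCT (a named sample, or the per-gene mean ΔCT in time-course
mode), and relative expression is 2^−ΔΔCT with amplification efficiency
fixed at 2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import TimeCourseMatrix
from .rhythms import HarmonicFit, acrophase_shift, scan_periods

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationMatrix",
    "correlate_sets",
    "oscillating_count_correlation",
    "quantify_ddct",
    "fit_qpcr_rhythms",
    "TIMECOURSE_MEAN",
]

TIMECOURSE_MEAN = "timecourse_mean"


@dataclass
class CorrelationMatrix:
    """Pairwise correlations between two gene sets across time points."""

    row_ids: list
    col_ids: list
    method: str
    values: np.ndarray  # NaN marks undefined (zero-variance) entries

    def __post_init__(self) -> None:
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < -1 - 1e-9 or finite.max() > 1 + 1e-9):
            raise ValueError("correlation values outside [-1, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids, columns=self.col_ids)


def correlate_sets(
    matrix: TimeCourseMatrix,
    rows_a: Sequence[str],
    rows_b: Sequence[str],
    method: str = "pearson",
) -> CorrelationMatrix:
    """Correlate two row sets of a time-course matrix across time columns.

    Spearman uses average ranks for ties. Zero-variance series produce NaN
    entries (flagged, not imputed). Requires >=3 time points.
    """
    if method not in {"pearson", "spearman"}:
        raise ValueError(f"method must be pearson or spearman, got {method!r}")
    if len(matrix.times_h) < 3:
        raise ValueError("need >=3 time points for correlation")
    missing = [g for g in [*rows_a, *rows_b] if g not in matrix.gene_ids]
    if missing:
        raise KeyError(f"gene(s) not in matrix: {', '.join(sorted(set(missing)))}")
    A = np.vstack([matrix.row(g) for g in rows_a])
    B = np.vstack([matrix.row(g) for g in rows_b])
    if method == "spearman":
        A = np.apply_along_axis(stats.rankdata, 1, A)
        B = np.apply_along_axis(stats.rankdata, 1, B)
    A_c = A - A.mean(axis=1, keepdims=True)
    B_c = B - B.mean(axis=1, keepdims=True)
    sd_a = np.sqrt(np.sum(A_c**2, axis=1))
    sd_b = np.sqrt(np.sum(B_c**2, axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = (A_c @ B_c.T) / np.outer(sd_a, sd_b)
    vals[sd_a == 0, :] = np.nan
    vals[:, sd_b == 0] = np.nan
    n_undef = int(np.sum(~np.isfinite(vals)))
    if n_undef:
        logger.warning("%d undefined correlation entrie(s) (zero variance)", n_undef)
    vals = np.clip(vals, -1.0, 1.0)  # NaN entries pass through unchanged
    return CorrelationMatrix(list(rows_a), list(rows_b), method, vals)


def oscillating_count_correlation(
    counts_a: Sequence[float], counts_b: Sequence[float]
) -> float:
    """Spearman rho between paired per-dataset oscillator counts."""
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.size} vs {b.size}")
    if a.size < 3:
        raise ValueError("need counts from >=3 datasets")
    return float(stats.spearmanr(a, b).statistic)


def quantify_ddct(
    ct_table: pd.DataFrame,
    reference_gene: str,
    calibrator: str = TIMECOURSE_MEAN,
) -> pd.DataFrame:
    """Relative quantification by the 2^−ΔΔCT method.

    ``ct_table`` is tidy with columns sample_id, gene_id, ct (replicate
    rows are averaged first; extra columns such as time_h/condition are
    carried through). ``calibrator`` is either a sample_id or
    ``TIMECOURSE_MEAN``, which calibrates each gene to its mean ΔCT over
    samples (the time-course convention).

    Returns a DataFrame with columns sample_id, gene_id, ct, delta_ct,
    ddct, relative_expression (2^−ΔΔCT).
    """
    required = {"sample_id", "gene_id", "ct"}
    if missing := required - set(ct_table.columns):
        raise ValueError(f"ct_table missing column(s): {', '.join(sorted(missing))}")
    carry = [c for c in ct_table.columns if c not in {*required, "replicate"}]
    agg = {"ct": "mean", **{c: "first" for c in carry}}
    mean_ct = ct_table.groupby(["sample_id", "gene_id"], as_index=False, sort=False).agg(agg)

    ref = mean_ct[mean_ct["gene_id"] == reference_gene].set_index("sample_id")["ct"]
    out = mean_ct[mean_ct["gene_id"] != reference_gene].copy()
    missing_ref = sorted(set(out["sample_id"]) - set(ref.index))
    if missing_ref:
        raise ValueError(
            f"reference gene {reference_gene!r} not measured in sample(s): "
            + ", ".join(missing_ref)
        )
    out["delta_ct"] = out["ct"] - out["sample_id"].map(ref)
    if calibrator == TIMECOURSE_MEAN:
        cal = out.groupby("gene_id")["delta_ct"].transform("mean")
    else:
        cal_rows = out[out["sample_id"] == calibrator].set_index("gene_id")["delta_ct"]
        if cal_rows.empty:
            raise ValueError(f"calibrator sample {calibrator!r} not found")
        cal = out["gene_id"].map(cal_rows)
    out["ddct"] = out["delta_ct"] - cal
    out["relative_expression"] = np.exp2(-out["ddct"])
    return out.reset_index(drop=True)


def fit_qpcr_rhythms(
    quants: pd.DataFrame,
    period_range_h: tuple = (14.0, 27.0),
    step_h: float = 0.1,
    alpha: float = 0.05,
    condition_col: str = "condition",
    reference_condition: str | None = None,
) -> dict:
    """Cosinor fits of qPCR time courses per gene and condition.

    ``quants`` is the output of :func:`quantify_ddct` and must carry a
    ``time_h`` column. The fitted series is −ΔΔCT (log2 relative
    expression, mean-normalized by construction in time-course mode);
    :func:`chronosplice.rhythms.scan_periods` picks the best period on the
    grid. Fits with p >= alpha are flagged non-rhythmic. When exactly two
    conditions are present (or ``reference_condition`` names the baseline),
    the acrophase shift of the other condition relative to the baseline is
    reported; negative shifts mean the perturbed condition peaks earlier.

    A phase difference is only defined at a shared period, so the shift is
    measured at the baseline condition's best period: the perturbed
    condition is refitted at that period and the two acrophases compared.
    The per-condition scanned fits are what is reported in ``fits``.

    Returns ``{gene_id: {"fits": {condition: HarmonicFit},
    "rhythmic": {condition: bool}, "shift_h": float | None}}``.
    """
    if "time_h" not in quants.columns:
        raise ValueError("quants must carry a time_h column")
    has_cond = condition_col in quants.columns
    out: dict = {}
    for gene, gene_grp in quants.groupby("gene_id", sort=False):
        fits: dict = {}
        rhythmic: dict = {}
        series: dict = {}
        conditions = gene_grp[condition_col].unique() if has_cond else ["all"]
        for cond in conditions:
            sub = gene_grp[gene_grp[condition_col] == cond] if has_cond else gene_grp
            sub = sub.sort_values("time_h")
            if len(sub) < 4:
                raise ValueError(f"gene {gene}, condition {cond}: <4 time points")
            y, t = -sub["ddct"].to_numpy(), sub["time_h"].to_numpy()
            series[cond] = (y, t)
            fit = scan_periods(y, t, period_range_h, step_h)
            fits[cond] = fit
            rhythmic[cond] = fit.p_value < alpha
        shift = None
        if len(fits) == 2:
            base = reference_condition or sorted(fits)[0]
            other = next(c for c in fits if c != base)
            # refit the perturbed condition at the baseline's best period:
            # a phase difference is only defined at a shared period
            from .rhythms import fit_harmonic

            other_at_base = fit_harmonic(*series[other], fits[base].period_h)
            shift = acrophase_shift(fits[base], other_at_base)
        out[gene] = {"fits": fits, "rhythmic": rhythmic, "shift_h": shift}
    return out
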