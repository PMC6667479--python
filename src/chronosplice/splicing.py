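"""PSI estimation, binned differential-splicing tests and event ranking.

PSI (percent spliced-in) is estimated per sample as I / (I + E), where I
and E are the medians of the linear-scale (2^x) probe intensities of the
inclusion and exclusion paths. Time points are grouped into chronological
bins of two (the study's replication strategy: with one array per time
point, the two members of a bin act as replicates of a bin condition) and
consecutive bins are contrasted.

The differential statistic is a probe-level two-way ANOVA: the linear
model  log2 intensity = mu + sample + path + path x bin  is fitted over
all probes of both paths and the four samples of a comparison, and the
path x bin interaction (1 df) is F-tested. A change in isoform balance
between bins loads exactly this interaction. Probe main effects are
deliberately not modelled; with heterogeneous probe affinities the test
is conservative (the balanced design keeps probe effects orthogonal to
the interaction, so they inflate only the residual).

Filtering follows two conventions kept deliberately distinct: the
per-comparison filter keeps events with p < p_max AND |dPSI| > dpsi_min
(both strict), while the recurrent intersection keeps events significant
in ALL comparisons with |dPSI| >= dpsi_min in AT LEAST ONE comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import EventAnnotation, GenomicInterval

logger = logging.getLogger(__name__)

__all__ = [
    "EventQuantification",
    "ComparisonPlan",
    "SplicingEventResult",
    "estimate_psi",
    "plan_comparisons",
    "test_event",
    "filter_events",
    "intersect_recurrent",
    "rank_by_dpsi_variance",
    "classify_event",
    "quantifications_from_table",
]

_ZERO_SS = 1e-20


@dataclass
class EventQuantification:
    """Probe-level signals for one event across samples."""

    event_id: str
    times_h: np.ndarray
    incl_probes: np.ndarray  # probes x samples, log2 intensity
    excl_probes: np.ndarray

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.incl_probes = np.atleast_2d(np.asarray(self.incl_probes, dtype=float))
        self.excl_probes = np.atleast_2d(np.asarray(self.excl_probes, dtype=float))
        ns = self.times_h.size
        if self.incl_probes.shape[1] != ns or self.excl_probes.shape[1] != ns:
            raise ValueError("probe matrices must share the sample columns")
        if self.incl_probes.shape[0] < 1 or self.excl_probes.shape[0] < 1:
            raise ValueError("need >=1 probe per path")

    @property
    def psi_per_sample(self) -> np.ndarray:
        return np.array(
            [
                estimate_psi(self.incl_probes[:, j], self.excl_probes[:, j])
                for j in range(self.times_h.size)
            ]
        )

    def _cols(self, times: Sequence[float]) -> list:
        cols = []
        for t in times:
            hits = np.nonzero(np.isclose(self.times_h, t))[0]
            if hits.size == 0:
                raise ValueError(f"event {self.event_id}: no sample at t={t} h")
            cols.append(int(hits[0]))
        return cols


@dataclass
class ComparisonPlan:
    """Chronological two-time-point bins and consecutive-bin contrasts."""

    bins: list
    excluded_times: list = field(default_factory=list)

    def __post_init__(self) -> None:
        for b in self.bins:
            if len(b) != 2:
                raise ValueError("each bin must contain exactly 2 time points")
        flat = [t for b in self.bins for t in b]
        if sorted(flat) != flat or len(set(flat)) != len(flat):
            raise ValueError("bins must be chronologically ordered and disjoint")

    @property
    def comparisons(self) -> list:
        return [(self.bins[i], self.bins[i + 1]) for i in range(len(self.bins) - 1)]


@dataclass
class SplicingEventResult:
    """Per-event differential-splicing summary across comparisons."""

    event_id: str
    gene_id: str = ""
    event_type: str = "complex"
    interval: GenomicInterval | None = None
    strand: str = "."
    delta_psi: list = field(default_factory=list)
    p_values: list = field(default_factory=list)
    dpsi_variance: float = 0.0
    passes_filter: list = field(default_factory=list)
    recurrent: bool = False

    def __post_init__(self) -> None:
        for d in self.delta_psi:
            if not -1.0 - 1e-9 <= d <= 1.0 + 1e-9:
                raise ValueError(f"delta PSI {d} outside [-1, 1]")
        if self.dpsi_variance < 0:
            raise ValueError("dpsi_variance must be >= 0")


def estimate_psi(incl_probes: Sequence[float], excl_probes: Sequence[float]) -> float:
    """PSI = I / (I + E) from log2 probe intensities of one sample.

    I and E are medians of the linear-scale (2^x) intensities per path;
    -inf log2 values map to linear 0. Raises when both medians are zero.
    """
    incl = np.asarray(incl_probes, dtype=float)
    excl = np.asarray(excl_probes, dtype=float)
    if incl.size < 1 or excl.size < 1:
        raise ValueError("need >=1 probe per path")
    i = float(np.median(np.exp2(incl)))
    e = float(np.median(np.exp2(excl)))
    if i + e == 0:
        raise ValueError("undefined PSI: inclusion + exclusion signal is zero")
    return i / (i + e)


def plan_comparisons(times_h: Sequence[float], excluded: Sequence[float] = ()) -> ComparisonPlan:
    """Pair the retained time points into chronological bins of two.

    After dropping ``excluded``, an even number (>= 4) of time points must
    remain; consecutive pairs form bins, consecutive bins form the
    comparisons.
    """
    excluded = list(excluded)
    kept = sorted(t for t in times_h if not any(np.isclose(t, e) for e in excluded))
    if len(kept) < 4 or len(kept) % 2:
        middle = kept[len(kept) // 2] if kept else None
        raise ValueError(
            f"{len(kept)} time points remain after exclusion; an even number >= 4 "
            f"is required — exclude one more (e.g. t={middle})"
        )
    bins = [(kept[i], kept[i + 1]) for i in range(0, len(kept), 2)]
    return ComparisonPlan(bins, excluded_times=excluded)


def test_event(
    quant: EventQuantification, bin_a: Sequence[float], bin_b: Sequence[float]
) -> tuple:
    """Differential splicing between two bins: (delta_psi, p_value).

    delta_psi is mean PSI(bin_b) − mean PSI(bin_a). The p-value comes
    from the F-test (1 df) of the path x bin interaction in the linear
    model  log2 intensity = mu + sample + path + path x bin  over all
    probes of both paths and the four samples.
    """
    ca, cb = quant._cols(bin_a), quant._cols(bin_b)
    psi = quant.psi_per_sample
    delta = float(np.mean(psi[cb]) - np.mean(psi[ca]))

    cols = ca + cb
    n_samp = len(cols)
    y_blocks, path_flag, sample_idx, bin_flag = [], [], [], []
    for path_id, mat in ((0, quant.incl_probes), (1, quant.excl_probes)):
        sub = mat[:, cols]  # probes x 4 samples
        for j in range(n_samp):
            y_blocks.append(sub[:, j])
            npair = sub.shape[0]
            path_flag.extend([path_id] * npair)
            sample_idx.extend([j] * npair)
            bin_flag.extend([1 if j >= len(ca) else 0] * npair)
    y = np.concatenate(y_blocks)
    if not np.all(np.isfinite(y)):
        raise ValueError(
            f"event {quant.event_id}: non-finite log2 intensity in tested samples"
        )
    path_flag = np.asarray(path_flag, dtype=float)
    sample_idx = np.asarray(sample_idx)
    bin_flag = np.asarray(bin_flag, dtype=float)

    X_cols = [np.ones_like(y)]
    for j in range(1, n_samp):  # sample dummies (reference = first sample)
        X_cols.append((sample_idx == j).astype(float))
    X_cols.append(path_flag)
    X_red = np.column_stack(X_cols)
    X_full = np.column_stack(X_cols + [path_flag * bin_flag])

    df_resid = y.size - X_full.shape[1]
    if df_resid <= 0:
        raise ValueError(
            f"event {quant.event_id}: zero residual df — p-value undefined "
            "(need more probes per path)"
        )
    sse_full = _sse(X_full, y)
    sse_red = _sse(X_red, y)
    ss_int = max(sse_red - sse_full, 0.0)
    scale = max(float(y @ y), 1.0)
    if ss_int <= _ZERO_SS * scale:
        p = 1.0
    elif sse_full <= _ZERO_SS * scale:
        p = 0.0
    else:
        f = ss_int / (sse_full / df_resid)
        p = float(stats.f.sf(f, 1, df_resid))
    return delta, p


test_event.__test__ = False  # not a pytest item despite the field-standard name


def _sse(X: np.ndarray, y: np.ndarray) -> float:
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def filter_events(results: Sequence, p_max: float = 0.01, dpsi_min: float = 0.1) -> list:
    """Keep results with p < p_max AND |dPSI| > dpsi_min (both strict)."""
    return [
        r
        for r in results
        if r["p_value"] < p_max and abs(r["delta_psi"]) > dpsi_min
    ]


def intersect_recurrent(
    per_comparison_results: Sequence,
    p_max: float = 0.01,
    dpsi_min: float = 0.1,
    annotations: dict | None = None,
) -> list:
    """Events significant in every comparison at identical coordinates.

    ``per_comparison_results`` is one list per comparison of dicts with
    keys event_id, interval, gene_id, delta_psi, p_value. An event is
    recurrent when p < p_max in ALL comparisons and |dPSI| >= dpsi_min in
    AT LEAST ONE. Returns :class:`SplicingEventResult` records with the
    sample variance (n−1 denominator) of the per-comparison dPSI.
    """
    keyed = []
    for results in per_comparison_results:
        keyed.append({(r["event_id"], r.get("interval")): r for r in results})
    common = set(keyed[0])
    for k in keyed[1:]:
        common &= set(k)
    all_ids = [{eid for eid, _ in k} for k in keyed]
    shared_ids = set.intersection(*all_ids) if all_ids else set()
    # an event id present in every comparison but with differing coordinates
    # means the annotations disagree between comparisons
    drifted = shared_ids - {eid for eid, _ in common}
    if drifted:
        raise ValueError(
            "annotation mismatch between comparisons for event(s): "
            + ", ".join(sorted(drifted))
        )
    out = []
    for key in sorted(common, key=lambda k: k[0]):
        records = [k[key] for k in keyed]
        ps = [r["p_value"] for r in records]
        dpsis = [r["delta_psi"] for r in records]
        if not all(p < p_max for p in ps):
            continue
        if not any(abs(d) >= dpsi_min for d in dpsis):
            continue
        ann = (annotations or {}).get(key[0])
        out.append(
            SplicingEventResult(
                event_id=key[0],
                gene_id=records[0].get("gene_id", ""),
                event_type=classify_event(ann) if ann else records[0].get("event_type", "complex"),
                interval=key[1] if key[1] is not None else (ann.span() if ann else None),
                strand=ann.strand if ann else records[0].get("strand", "."),
                delta_psi=list(dpsis),
                p_values=list(ps),
                dpsi_variance=float(np.var(dpsis, ddof=1)),
                passes_filter=[p < p_max and abs(d) > dpsi_min for p, d in zip(ps, dpsis)],
                recurrent=True,
            )
        )
    return out


def rank_by_dpsi_variance(results: Sequence[SplicingEventResult]) -> list:
    """Descending by sample variance of per-comparison dPSI; ties by id."""
    for r in results:
        if len(r.delta_psi) < 2:
            raise ValueError(f"event {r.event_id}: need >=2 dPSI values to rank")
        r.dpsi_variance = float(np.var(r.delta_psi, ddof=1))
    return sorted(results, key=lambda r: (-r.dpsi_variance, r.event_id))


# ---------------------------------------------------------------------------
# Event-type classification
# ---------------------------------------------------------------------------


def classify_event(annotation: EventAnnotation) -> str:
    """Classify an event from its path structure.

    Rules, applied in order on genomic-order interval sets (full paths =
    variable intervals plus shared flanks):

    - cassette_exon: paths differ by exactly one internal interval with
      shared flanking intervals on both genomic sides;
    - intron_retention: one path's single interval spans the other path's
      two intervals plus the gap between them;
    - alt_5ss / alt_3ss: the paths differ in one interval each sharing one
      boundary; which class depends on the varying end and the strand
      (the donor is the transcript-5' splice site);
    - alt_first_exon / alt_last_exon: the divergence includes the
      transcript's first/last interval with no shared flank on that side;
    - complex: anything else.
    """
    incl = set(annotation.path_inclusion) | set(annotation.flank_intervals)
    excl = set(annotation.path_exclusion) | set(annotation.flank_intervals)
    if incl == excl:
        raise ValueError(f"event {annotation.event_id}: identical paths")
    only_incl = sorted(incl - excl)
    only_excl = sorted(excl - incl)
    shared = sorted(incl & excl)
    diff = sorted(only_incl + only_excl)
    lo, hi = diff[0].start, diff[-1].end
    left_flank = any(s.end <= lo for s in shared)
    right_flank = any(s.start >= hi for s in shared)

    # cassette exon: one extra internal interval in one path, flanks both sides
    if (len(only_incl), len(only_excl)) in {(1, 0), (0, 1)} and left_flank and right_flank:
        return "cassette_exon"

    # intron retention: single interval spanning the other path's two + gap
    for single, pair in ((only_incl, only_excl), (only_excl, only_incl)):
        if len(single) == 1 and len(pair) == 2:
            s, (p1, p2) = single[0], sorted(pair)
            if s.start == p1.start and s.end == p2.end and p1.end < p2.start:
                return "intron_retention"

    # alternative donor/acceptor: one differing interval per path, one shared
    # end; restricted to internal variation (flanks on both sides)
    if len(only_incl) == 1 and len(only_excl) == 1 and left_flank and right_flank:
        a, b = only_incl[0], only_excl[0]
        if a.start == b.start and a.end != b.end:
            varying_right = True
        elif a.end == b.end and a.start != b.start:
            varying_right = False
        else:
            varying_right = None
        if varying_right is not None:
            # exon end varying on the transcript-5' splice site = alt donor
            if annotation.strand == "+":
                return "alt_5ss" if varying_right else "alt_3ss"
            return "alt_3ss" if varying_right else "alt_5ss"

    # terminal-exon switches: divergence reaches an unflanked transcript end
    if not left_flank or not right_flank:
        genomic_left_open = not left_flank
        if annotation.strand == "+":
            return "alt_first_exon" if genomic_left_open else "alt_last_exon"
        return "alt_last_exon" if genomic_left_open else "alt_first_exon"

    return "complex"


# ---------------------------------------------------------------------------
# Probe table → quantifications
# ---------------------------------------------------------------------------


def quantifications_from_table(df: pd.DataFrame, times_h: np.ndarray) -> list:
    """Build EventQuantification objects from a probe-level table.

    ``df`` has columns event_id, path, probe_id plus one column per sample
    (the layout produced by the simulator and read by io.read_event_quantifications).
    """
    sample_cols = [c for c in df.columns if c not in ("event_id", "path", "probe_id")]
    if len(sample_cols) != len(times_h):
        raise ValueError("sample columns do not match times")
    out = []
    for event_id, grp in df.groupby("event_id", sort=False):
        incl = grp[grp["path"] == "incl"][sample_cols].to_numpy(dtype=float)
        excl = grp[grp["path"] == "excl"][sample_cols].to_numpy(dtype=float)
        out.append(EventQuantification(event_id, times_h, incl, excl))
    return out
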