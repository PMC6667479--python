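"""Ground-truth-annotated synthetic inputs for every pipeline stage.

The generators emulate the statistical structure of a circadian
time-course microarray study: 9 samples taken every 3 h between 6 h and
30 h after synchronization (one array per time point), a fraction of
genes oscillating with periods in the circadian band (cosinor signal plus
Gaussian noise on the log2 scale), splicing events whose inclusion ratio
(PSI) varies over time measured through several noisy probes per path,
labelled interaction networks with tunable cross-set edge enrichment, and
qPCR CT tables derived from cosinor expression profiles.

All randomness flows through one ``numpy.random.default_rng(seed)``; the
same seed yields byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import LabelledNetwork, TimeCourseMatrix

__all__ = [
    "DEFAULT_TIMES_H",
    "RhythmTruth",
    "EventTruth",
    "constant_psi",
    "sinusoidal_psi",
    "step_psi",
    "simulate_rhythmic_matrix",
    "simulate_event_signals",
    "simulate_labelled_network",
    "simulate_qpcr_timecourse",
]

# study sampling design: every 3 h between 6 h and 30 h after synchronization
DEFAULT_TIMES_H = np.arange(6.0, 30.0 + 1e-9, 3.0)


@dataclass
class RhythmTruth:
    """Ground truth for one simulated gene's temporal profile."""

    gene_id: str
    is_oscillating: bool
    period_h: float
    amplitude: float
    acrophase_h: float
    mesor: float

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.is_oscillating and not (0 <= self.acrophase_h < self.period_h):
            raise ValueError("acrophase_h must lie in [0, period_h)")


@dataclass
class EventTruth:
    """Ground truth for one simulated splicing event."""

    event_id: str
    psi_trajectory: np.ndarray
    event_type: str = "cassette_exon"
    is_temporal: bool = False

    def __post_init__(self) -> None:
        self.psi_trajectory = np.asarray(self.psi_trajectory, dtype=float)
        if np.any(self.psi_trajectory < 0) or np.any(self.psi_trajectory > 1):
            raise ValueError(f"event {self.event_id}: PSI outside [0, 1]")


# -- PSI trajectory constructors --------------------------------------------


def constant_psi(psi: float, times_h: Sequence[float]) -> np.ndarray:
    return np.full(len(times_h), float(psi))


def sinusoidal_psi(
    mesor: float, amplitude: float, period_h: float, acrophase_h: float, times_h: Sequence[float]
) -> np.ndarray:
    t = np.asarray(times_h, dtype=float)
    return mesor + amplitude * np.cos(2 * np.pi * (t - acrophase_h) / period_h)


def step_psi(before: float, after: float, t_switch: float, times_h: Sequence[float]) -> np.ndarray:
    t = np.asarray(times_h, dtype=float)
    return np.where(t < t_switch, float(before), float(after))


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------


def simulate_rhythmic_matrix(
    n_genes: int = 1000,
    frac_osc: float = 0.3,
    period_range_h: tuple = (21.0, 27.0),
    amp_range: tuple = (1.0, 1.0),
    noise_sd: float = 0.5,
    times_h: Sequence[float] | None = None,
    seed: int | None = None,
    mesor_mean: float = 8.0,
    mesor_sd: float = 1.0,
) -> tuple:
    """Simulate a log2 expression time course with known oscillators.

    Oscillating genes follow ``mesor + A·cos(2π(t − φ)/T) + N(0, noise_sd²)``
    with T uniform in ``period_range_h``, A uniform in ``amp_range`` and
    acrophase uniform in [0, T); the rest are mesor + noise. Exactly
    ``ceil(frac_osc · n_genes)`` genes oscillate: assignment is the first
    block after a seeded shuffle, so the count is deterministic.

    Returns ``(TimeCourseMatrix, list[RhythmTruth])``.
    """
    if not 0 <= frac_osc <= 1:
        raise ValueError("frac_osc must be in [0, 1]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    times = DEFAULT_TIMES_H if times_h is None else np.asarray(times_h, dtype=float)
    if times.size == 0:
        raise ValueError("times_h is empty")
    if times.size < 4:
        raise ValueError("need >=4 time points")
    rng = np.random.default_rng(seed)
    n_osc = math.ceil(frac_osc * n_genes)
    order = rng.permutation(n_genes)
    osc_mask = np.zeros(n_genes, dtype=bool)
    osc_mask[order[:n_osc]] = True

    gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    mesors = rng.normal(mesor_mean, mesor_sd, size=n_genes)
    periods = rng.uniform(*period_range_h, size=n_genes)
    amps = np.where(osc_mask, rng.uniform(*amp_range, size=n_genes), 0.0)
    phases = rng.uniform(0, 1, size=n_genes) * periods

    values = mesors[:, None] + rng.normal(0.0, noise_sd, size=(n_genes, times.size))
    osc_idx = np.where(osc_mask)[0]
    values[osc_idx] += amps[osc_idx, None] * np.cos(
        2 * np.pi * (times[None, :] - phases[osc_idx, None]) / periods[osc_idx, None]
    )

    truths = [
        RhythmTruth(
            gene_ids[i],
            bool(osc_mask[i]),
            float(periods[i]),
            float(amps[i]),
            float(phases[i]) if osc_mask[i] else 0.0,
            float(mesors[i]),
        )
        for i in range(n_genes)
    ]
    return TimeCourseMatrix(gene_ids, times, values), truths


# ---------------------------------------------------------------------------
# Probe-level splicing-event signals
# ---------------------------------------------------------------------------


def simulate_event_signals(
    events: Sequence[EventTruth],
    n_probes_per_path: int = 3,
    sample_times_h: Sequence[float] | None = None,
    probe_affinity_sd: float = 0.2,
    noise_sd: float = 0.1,
    total_abundance: float = 1000.0,
    seed: int | None = None,
) -> tuple:
    """Simulate log2 probe intensities for inclusion/exclusion paths.

    On the linear scale the inclusion path carries ``total_abundance·PSI(t)``
    and the exclusion path ``total_abundance·(1 − PSI(t))``. Each probe
    multiplies its path abundance by a fixed per-probe affinity
    (log-normal with σ = ``probe_affinity_sd`` on the log2 scale), then
    Gaussian noise with ``noise_sd`` is added in the log2 domain. A PSI of
    exactly 0 or 1 leaves the silent path at linear 0 (log2 = −inf).

    Returns ``(DataFrame, list[EventTruth])`` in the probe-table layout
    read by :func:`chronosplice.io.read_event_quantifications`.
    """
    if n_probes_per_path < 1:
        raise ValueError("n_probes_per_path must be >= 1")
    times = DEFAULT_TIMES_H if sample_times_h is None else np.asarray(sample_times_h, dtype=float)
    rng = np.random.default_rng(seed)
    rows = []
    sample_cols = [_time_col(t) for t in times]
    for ev in events:
        psi = np.asarray(ev.psi_trajectory, dtype=float)
        if psi.shape != times.shape:
            raise ValueError(
                f"event {ev.event_id}: trajectory length {psi.size} != {times.size} times"
            )
        if np.any(psi < 0) or np.any(psi > 1):
            raise ValueError(f"event {ev.event_id}: PSI outside [0, 1]")
        for path, frac in (("incl", psi), ("excl", 1.0 - psi)):
            affinities = 2.0 ** rng.normal(0.0, probe_affinity_sd, size=n_probes_per_path)
            noise = rng.normal(0.0, noise_sd, size=(n_probes_per_path, times.size))
            linear = total_abundance * frac[None, :] * affinities[:, None]
            with np.errstate(divide="ignore"):
                log2_int = np.log2(linear) + noise
            log2_int = np.where(linear == 0.0, -np.inf, log2_int)
            for p in range(n_probes_per_path):
                rows.append(
                    [ev.event_id, path, f"{ev.event_id}_{path}_p{p}", *log2_int[p]]
                )
    df = pd.DataFrame(rows, columns=["event_id", "path", "probe_id", *sample_cols])
    return df, list(events)


def _time_col(t: float) -> str:
    return f"T{int(t):02d}" if float(t).is_integer() else f"T{t}"


# ---------------------------------------------------------------------------
# Labelled networks
# ---------------------------------------------------------------------------


def simulate_labelled_network(
    n_sf: int = 251,
    n_ncrg: int = 130,
    n_background: int = 500,
    p_within: float = 0.025,
    p_cross: float = 0.0057,
    enrichment: float = 1.0,
    seed: int | None = None,
    background_label: str = "ASG",
) -> LabelledNetwork:
    """Random labelled network with tunable SF–NCRG edge enrichment.

    Within-label pairs are wired with probability ``p_within``; SF×NCRG
    pairs with ``p_cross · enrichment``; every pair involving a background
    node (labelled ``background_label``) with the unenriched ``p_cross``.
    The background group provides the resampling universe for the
    random-set null. Deterministic under seed.
    """
    for p in (p_within, p_cross):
        if not 0 <= p <= 1:
            raise ValueError("probabilities must be in [0, 1]")
    if not 0 <= p_cross * enrichment <= 1:
        raise ValueError("p_cross * enrichment must be in [0, 1]")
    rng = np.random.default_rng(seed)
    groups = {
        "SF": [f"SF{i:04d}" for i in range(n_sf)],
        "NCRG": [f"NCRG{i:04d}" for i in range(n_ncrg)],
        background_label: [f"BG{i:04d}" for i in range(n_background)],
    }
    edges: list = []

    def bernoulli_pairs(nodes_a, nodes_b, p, within=False):
        if p == 0:
            return
        if within:
            idx = np.triu_indices(len(nodes_a), k=1)
            mask = rng.random(len(idx[0])) < p
            for i, j in zip(idx[0][mask], idx[1][mask]):
                edges.append((nodes_a[i], nodes_a[j]))
        else:
            mask = rng.random((len(nodes_a), len(nodes_b))) < p
            for i, j in zip(*np.nonzero(mask)):
                edges.append((nodes_a[i], nodes_b[j]))

    bernoulli_pairs(groups["SF"], None, p_within, within=True)
    bernoulli_pairs(groups["NCRG"], None, p_within, within=True)
    bernoulli_pairs(groups[background_label], None, p_within, within=True)
    bernoulli_pairs(groups["SF"], groups["NCRG"], p_cross * enrichment)
    bernoulli_pairs(groups["SF"], groups[background_label], p_cross)
    bernoulli_pairs(groups["NCRG"], groups[background_label], p_cross)

    labels = {n: {lab} for lab, nodes in groups.items() for n in nodes}
    all_nodes = [n for nodes in groups.values() for n in nodes]
    return LabelledNetwork.from_edges(edges, labels, extra_nodes=all_nodes)


# ---------------------------------------------------------------------------
# qPCR CT tables
# ---------------------------------------------------------------------------


def simulate_qpcr_timecourse(
    genes: Sequence[Mapping],
    times_h: Sequence[float] | None = None,
    ref_gene_ct: float = 18.0,
    efficiency: float = 2.0,
    ct_noise_sd: float = 0.0,
    n_replicates: int = 3,
    seed: int | None = None,
    ref_gene: str = "REF",
    condition: str = "control",
) -> pd.DataFrame:
    """Simulate a qPCR CT table from cosinor expression profiles.

    Each entry of ``genes`` is a mapping with keys ``gene_id``, ``mesor``,
    ``amplitude``, ``period_h``, ``acrophase_h``: relative expression is
    ``2**(mesor + A·cos(2π(t − φ)/T))`` and the target CT follows
    ``CT(t) = ref_gene_ct − log_efficiency(relative expression(t))`` plus
    Gaussian noise of ``ct_noise_sd`` cycles per replicate. The reference
    gene is emitted at a constant ``ref_gene_ct`` (plus replicate noise).

    Returns a tidy DataFrame: sample_id, condition, time_h, gene_id,
    replicate, ct.
    """
    if efficiency <= 1:
        raise ValueError("amplification efficiency must exceed 1")
    times = DEFAULT_TIMES_H if times_h is None else np.asarray(times_h, dtype=float)
    rng = np.random.default_rng(seed)
    rows = []
    for ti, t in enumerate(times):
        sample = f"{condition}_T{int(t):02d}" if float(t).is_integer() else f"{condition}_T{t}"
        for r in range(n_replicates):
            rows.append(
                [sample, condition, float(t), ref_gene, r,
                 ref_gene_ct + rng.normal(0.0, ct_noise_sd)]
            )
        for g in genes:
            log2_expr = g["mesor"] + g["amplitude"] * math.cos(
                2 * math.pi * (t - g["acrophase_h"]) / g["period_h"]
            )
            rel = 2.0**log2_expr
            if rel <= 0:
                raise ValueError(f"non-positive expression for {g['gene_id']} at t={t}")
            ct = ref_gene_ct - math.log(rel, efficiency)
            for r in range(n_replicates):
                rows.append(
                    [sample, condition, float(t), g["gene_id"], r,
                     ct + rng.normal(0.0, ct_noise_sd)]
                )
    return pd.DataFrame(
        rows, columns=["sample_id", "condition", "time_h", "gene_id", "replicate", "ct"]
    )
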