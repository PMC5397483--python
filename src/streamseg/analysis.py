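"""Percept readout, build-up functions, difference scores and sweeps.

The percept readout follows the model convention: in each time bin a trial
counts as *integrated* when the bin-averaged activity of the AB unit exceeds
the bin-averaged summed activity of the A and B units, and *segregated*
otherwise (ties count as integrated).  Build-up functions are time-binned
trial-averaged proportions segregated over a frozen-noise ensemble, with
binomial standard errors.

Bins are one triplet (400 ms) wide and aligned to triplet boundaries.  When
the timeline carries a pause, the model keeps running through the silence
and the pause interval becomes its own bin, so curves remain continuous
across the gap; difference scores are always evaluated at the final test
triplet's bin, mirroring subjects reporting the percept of the last triplet.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .a1 import A1Params, compute_input_trace
from .competition import EnsembleResult, NetworkParams, NetworkTrajectory, NoiseBank, run_ensemble
from .paradigm import TRIPLET_MS, StimulusTimeline, apply_distractor, make_triplet_sequence

__all__ = [
    "PerceptSeries",
    "BuildUpFunction",
    "SweepResult",
    "bin_edges_for_timeline",
    "classify_bins",
    "build_up",
    "snapshot",
    "difference_score",
    "first_switch_times",
    "ab_first_fraction",
    "distractor_sweep",
]


@dataclass
class PerceptSeries:
    """Binary percept per (trial, bin); True = segregated."""

    bin_centers: np.ndarray
    bin_edges: np.ndarray            # (n_bins, 2)
    segregated: np.ndarray           # bool, (n_trials, n_bins)
    bin_kinds: tuple[str, ...]       # "triplet" or "pause" per bin


@dataclass
class BuildUpFunction:
    """Time-binned trial-averaged proportion segregated."""

    bin_centers: np.ndarray
    proportion_segregated: np.ndarray
    n_trials: int
    sem: np.ndarray
    bin_kinds: tuple[str, ...] = ()
    meta: dict = field(default_factory=dict)

    @property
    def proportion_integrated(self) -> np.ndarray:
        return 1.0 - self.proportion_segregated

    def triplet_bin_index(self, triplet: int) -> int:
        """Bin index of 1-based triplet ``triplet`` (skipping pause bins)."""
        count = 0
        for i, kind in enumerate(self.bin_kinds or ("triplet",) * len(self.bin_centers)):
            if kind == "triplet":
                count += 1
                if count == triplet:
                    return i
        raise IndexError(f"triplet {triplet} outside the build-up function")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "bin_center_ms": self.bin_centers,
                "proportion_segregated": self.proportion_segregated,
                "sem": self.sem,
                "bin_kind": list(self.bin_kinds)
                if self.bin_kinds
                else ["triplet"] * len(self.bin_centers),
            }
        )


@dataclass
class SweepResult:
    """Change in proportion segregated per (distractor spec, DF)."""

    freq_specs: tuple[str, ...]
    df_list: tuple[float, ...]
    delta: np.ndarray       # (n_specs, n_df)
    sem: np.ndarray         # (n_specs, n_df) paired-difference s.e.
    hypothesis: str         # "gated" or "ungated"

    def to_frame(self):
        import pandas as pd

        rows = []
        for i, spec in enumerate(self.freq_specs):
            for j, df in enumerate(self.df_list):
                rows.append(
                    {
                        "freq_spec": spec,
                        "df_st": df,
                        "delta_proportion_segregated": self.delta[i, j],
                        "sem": self.sem[i, j],
                        "hypothesis": self.hypothesis,
                    }
                )
        return pd.DataFrame(rows)


def bin_edges_for_timeline(timeline: StimulusTimeline) -> tuple[np.ndarray, tuple[str, ...]]:
    """Triplet-aligned bin edges; a pause becomes its own bin.

    Returns (edges, kinds) with edges shaped (n_bins, 2) in ms.
    """
    edges = []
    kinds = []
    p = timeline.perturbation
    for i in range(1, timeline.n_triplets + 1):
        s = timeline.triplet_start_ms(i)
        edges.append((s, s + TRIPLET_MS))
        kinds.append("triplet")
        if p.kind == "pause" and i == p.after_triplet:
            edges.append((s + TRIPLET_MS, s + TRIPLET_MS + p.pause_ms))
            kinds.append("pause")
    return np.asarray(edges, dtype=float), tuple(kinds)


def _uniform_edges(duration_ms: float, bin_ms: float) -> tuple[np.ndarray, tuple[str, ...]]:
    n_bins = duration_ms / bin_ms
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError(
            f"bin_ms={bin_ms} does not divide the trajectory duration {duration_ms} ms"
        )
    n_bins = int(round(n_bins))
    lo = np.arange(n_bins) * bin_ms
    return np.stack([lo, lo + bin_ms], axis=1), ("triplet",) * n_bins


def _r_and_t(traj) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(traj, EnsembleResult):
        return traj.r, traj.t
    if isinstance(traj, NetworkTrajectory):
        return traj.r[None, :, :], traj.t
    raise TypeError(f"expected NetworkTrajectory or EnsembleResult, got {type(traj)}")


def classify_bins(
    traj,
    bin_ms: float = 400.0,
    edges: Optional[np.ndarray] = None,
    bin_kinds: Optional[tuple[str, ...]] = None,
    mode: str = "bin_mean",
) -> PerceptSeries:
    """Classify each (trial, bin) as integrated or segregated.

    ``mode="bin_mean"`` (default) compares bin-averaged r_AB against
    bin-averaged r_A + r_B; ``mode="sample"`` classifies each sample then
    takes the bin's majority.  Ties are integrated in both modes.
    """
    r, t = _r_and_t(traj)
    if r.shape[1] == 0:
        raise ValueError("cannot classify an empty trajectory")
    if edges is None:
        edges, bin_kinds = _uniform_edges(float(t[-1]), bin_ms)
    if bin_kinds is None:
        bin_kinds = ("triplet",) * len(edges)
    seg = np.empty((r.shape[0], len(edges)), dtype=bool)
    for j, (lo, hi) in enumerate(edges):
        mask = (t >= lo) & (t < hi)
        if not mask.any():
            raise ValueError(f"bin [{lo}, {hi}) ms contains no samples")
        rb = r[:, mask, :]
        if mode == "bin_mean":
            ab = rb[:, :, 1].mean(axis=1)
            periph = rb[:, :, 0].mean(axis=1) + rb[:, :, 2].mean(axis=1)
            seg[:, j] = periph > ab
        elif mode == "sample":
            seg_samples = (rb[:, :, 0] + rb[:, :, 2]) > rb[:, :, 1]
            seg[:, j] = seg_samples.mean(axis=1) > 0.5
        else:
            raise ValueError(f"mode must be 'bin_mean' or 'sample', got {mode!r}")
    centers = edges.mean(axis=1)
    return PerceptSeries(
        bin_centers=centers, bin_edges=np.asarray(edges), segregated=seg,
        bin_kinds=tuple(bin_kinds),
    )


def build_up(
    ensemble,
    bin_ms: float = 400.0,
    edges: Optional[np.ndarray] = None,
    bin_kinds: Optional[tuple[str, ...]] = None,
    mode: str = "bin_mean",
    meta: Optional[dict] = None,
) -> BuildUpFunction:
    """Trial-averaged proportion segregated per bin, with binomial s.e.m."""
    series = classify_bins(ensemble, bin_ms=bin_ms, edges=edges,
                           bin_kinds=bin_kinds, mode=mode)
    n = series.segregated.shape[0]
    p = series.segregated.mean(axis=0)
    sem = np.sqrt(p * (1.0 - p) / n)
    return BuildUpFunction(
        bin_centers=series.bin_centers,
        proportion_segregated=p,
        n_trials=n,
        sem=sem,
        bin_kinds=series.bin_kinds,
        meta=meta or {},
    )


def snapshot(buf: BuildUpFunction, triplet_indices: Sequence[int]) -> np.ndarray:
    """Build-up values at the bins of the given 1-based triplet indices."""
    return np.array(
        [buf.proportion_segregated[buf.triplet_bin_index(i)] for i in triplet_indices]
    )


def difference_score(
    test: BuildUpFunction, control: BuildUpFunction, at_bin: int = -1
) -> float:
    """p_test - p_control at the evaluation bin (default: final triplet bin).

    Positive values mean the perturbation promoted segregation; negative
    values mean a reset toward integration.
    """

    def _resolve(buf: BuildUpFunction) -> int:
        if at_bin != -1:
            return at_bin
        kinds = buf.bin_kinds or ("triplet",) * len(buf.bin_centers)
        idx = [i for i, k in enumerate(kinds) if k == "triplet"]
        return idx[-1]

    it, ic = _resolve(test), _resolve(control)
    return float(test.proportion_segregated[it] - control.proportion_segregated[ic])


def first_switch_times(
    ensemble, edges: Optional[np.ndarray] = None, bin_ms: float = 400.0
) -> np.ndarray:
    """Per-trial time (ms) of the first segregated bin; NaN if none occurs.

    The time reported is the center of the first bin classified segregated.
    """
    series = classify_bins(ensemble, bin_ms=bin_ms, edges=edges)
    seg = series.segregated
    out = np.full(seg.shape[0], np.nan)
    for i in range(seg.shape[0]):
        hits = np.nonzero(seg[i])[0]
        if hits.size:
            out[i] = series.bin_centers[hits[0]]
    return out


def ab_first_fraction(ensemble, threshold: float = 0.5) -> float:
    """Fraction of trials in which AB is the first unit to become active.

    Activation is judged on the slow NMDA variable e_k (the sustained
    activity that outlasts individual tone pulses): the active unit is the
    one with the largest e at the first sample where any unit's e crosses
    ``threshold``.  Requires an ensemble simulated with ``store_aux=True``.
    """
    if not isinstance(ensemble, EnsembleResult) or ensemble.e is None:
        raise ValueError("ab_first_fraction needs an EnsembleResult with e stored")
    e = ensemble.e
    wins = 0
    counted = 0
    for i in range(e.shape[0]):
        idx = np.nonzero((e[i] > threshold).any(axis=1))[0]
        if not idx.size:
            continue
        counted += 1
        if int(e[i, idx[0]].argmax()) == 1:
            wins += 1
    return wins / counted if counted else float("nan")


def distractor_sweep(
    freq_specs: Sequence[str],
    df_list: Sequence[float],
    hypothesis: str = "gated",
    n_trials: int = 500,
    master_seed: int = 0,
    a1_params: Optional[A1Params] = None,
    net_params: Optional[NetworkParams] = None,
    n_triplets: int = 6,
    after_triplet: int = 3,
) -> SweepResult:
    """Delta proportion segregated vs distractor frequency, per DF.

    For each DF a 6-triplet control ensemble is simulated; each distractor
    condition reuses the identical frozen noise, so the delta at the final
    triplet is attributable solely to the distractor.  ``hypothesis`` selects
    whether non-triplet tones are gated away from the AB unit ("gated") or
    propagate to all units ("ungated").
    """
    if hypothesis not in ("gated", "ungated"):
        raise ValueError(f"hypothesis must be 'gated' or 'ungated', got {hypothesis!r}")
    from dataclasses import replace as _replace

    a1p = a1_params or A1Params()
    a1p = _replace(a1p, gate_non_triplet_from_ab=(hypothesis == "gated"))
    netp = (net_params or NetworkParams()).validate()
    bank = NoiseBank(n_trials=n_trials, master_seed=master_seed)
    delta = np.empty((len(freq_specs), len(df_list)))
    sem = np.empty_like(delta)
    for j, df in enumerate(df_list):
        control_tl = make_triplet_sequence(n_triplets, df)
        control = run_ensemble(
            compute_input_trace(control_tl, a1p, netp.dt), netp, bank
        )
        ctrl_edges, ctrl_kinds = bin_edges_for_timeline(control_tl)
        ctrl_series = classify_bins(control, edges=ctrl_edges, bin_kinds=ctrl_kinds)
        ctrl_final = ctrl_series.segregated[:, -1]
        for i, spec in enumerate(freq_specs):
            tl = apply_distractor(control_tl, spec, after_triplet)
            ens = run_ensemble(compute_input_trace(tl, a1p, netp.dt), netp, bank)
            edges, kinds = bin_edges_for_timeline(tl)
            series = classify_bins(ens, edges=edges, bin_kinds=kinds)
            final = series.segregated[:, -1]
            d = final.astype(float) - ctrl_final.astype(float)
            delta[i, j] = d.mean()
            sem[i, j] = d.std(ddof=1) / np.sqrt(n_trials)
    return SweepResult(
        freq_specs=tuple(freq_specs),
        df_list=tuple(float(d) for d in df_list),
        delta=delta,
        sem=sem,
        hypothesis=hypothesis,
    )
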