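"""Calibration harness for the under-specified constants.

The published operating point fixes the competition-stage time constants and
coupling gains, but the sigmoid threshold/slope, the noise constants, the
input gain and the input-stage shape constants (tuning width, onset gain,
onset DF fraction, masking factor) are free.  This harness searches those
constants until the model reproduces its qualitative signatures: flat static
build-up, adapting build-up rising from an integrated start to the static
level, DF-ordered asymptotes, pause resets, gated-perturbation promotion of
segregation, no effect of a far distractor, and seconds-scale first
switches.  The passing set becomes the packaged defaults.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np

from .a1 import A1Params
from .battery import run_property_battery
from .competition import NetworkParams

__all__ = ["Criterion", "DEFAULT_CRITERIA", "evaluate_criteria", "calibrate",
           "CalibrationResult"]


@dataclass(frozen=True)
class Criterion:
    """A named pass/fail predicate over a battery result dict."""

    name: str
    check: Callable[[dict], bool]

    def __call__(self, battery: dict) -> bool:
        return bool(self.check(battery))


def _sem(b: dict) -> float:
    return float(np.sqrt(0.25 / b["n_trials"]))


def _static_flat(b: dict) -> bool:
    return all(
        abs(b[f"static_final_df{df:g}"] - b[f"static_first_df{df:g}"]) < 3 * _sem(b)
        for df in (4, 7, 10)
    )


def _adapting_starts_integrated(b: dict) -> bool:
    return all(b[f"adapting_first_df{df:g}"] < 0.2 for df in (4, 7, 10))


def _adapting_reaches_static(b: dict) -> bool:
    return all(
        abs(b[f"adapting_final_df{df:g}"] - b[f"static_final_df{df:g}"])
        < 2 * (b[f"sem_final_df{df:g}"] + _sem(b))
        for df in (4, 7, 10)
    )


def _df_ordering(b: dict) -> bool:
    return (
        b["adapting_final_df4"]
        < b["adapting_final_df7"]
        < b["adapting_final_df10"]
    )


def _pause_resets(b: dict) -> bool:
    return all(
        b[f"delta_pause{p}_df{df:g}"] < 0 for p in (300, 600) for df in (4, 7, 10)
    )


def _gated_promotion(b: dict) -> bool:
    return all(
        b[f"delta_dis_b2_gated_df{df:g}"] > 0 and b[f"delta_deviant2_gated_df{df:g}"] > 0
        for df in (4, 7)
    )


def _far_distractor_null(b: dict) -> bool:
    return all(
        abs(b[f"delta_dis_b15_gated_df{df:g}"]) < 2 * _sem(b) for df in (4, 7, 10)
    )


def _ungated_mid_reset(b: dict) -> bool:
    return b["delta_dis_mid_ungated_df10"] < 0


def _pause_toward_half(b: dict) -> bool:
    # directional test: while the stimulus is off the proportion moves toward
    # 0.5 from whichever side it started on (decreases when build-up had
    # passed 0.5, increases when it was still below); no direction is
    # required when the pre-pause proportion is already at 0.5 within noise
    ok = True
    for df in (4, 7, 10):
        pre = b[f"pseg_pre_pause_df{df:g}"]
        during = b[f"pseg_during_pause_df{df:g}"]
        if abs(pre - 0.5) <= 2 * _sem(b):
            continue
        ok &= (during - pre) * (0.5 - pre) > 0
    return ok


def _switch_timescale(b: dict) -> bool:
    return 1.0 <= b["first_switch_median_s"] <= 10.0


def _ab_first(b: dict) -> bool:
    return b["ab_first_fraction"] > 0.5


DEFAULT_CRITERIA: tuple[Criterion, ...] = (
    Criterion("static_buildup_flat", _static_flat),
    Criterion("adapting_starts_integrated", _adapting_starts_integrated),
    Criterion("adapting_reaches_static_level", _adapting_reaches_static),
    Criterion("df_ordering_4_7_10", _df_ordering),
    Criterion("pause_deltas_negative", _pause_resets),
    Criterion("gated_perturbation_promotes_segregation", _gated_promotion),
    Criterion("far_distractor_no_effect", _far_distractor_null),
    Criterion("ungated_midpoint_resets_df10", _ungated_mid_reset),
    Criterion("pause_moves_toward_half", _pause_toward_half),
    Criterion("first_switch_seconds_scale", _switch_timescale),
    Criterion("ab_unit_active_first", _ab_first),
)

# which search keys belong to which parameter object
_A1_KEYS = {
    "tuning_width_st", "amp_onset_gain", "df_onset_frac", "masking_factor",
    "input_gain", "tau_a1", "tau_rec",
}
_NET_KEYS = {"f_threshold", "f_slope", "noise_sigma", "noise_tau"}


@dataclass
class CalibrationResult:
    """Outcome of a calibration search."""

    passed: bool
    a1_params: A1Params
    net_params: NetworkParams
    report: list = field(default_factory=list)  # one dict per evaluated candidate

    @property
    def best(self) -> dict:
        return max(self.report, key=lambda r: r["n_passed"]) if self.report else {}


def _apply_candidate(a1p: A1Params, netp: NetworkParams, candidate: dict):
    a1_kw = {k: v for k, v in candidate.items() if k in _A1_KEYS}
    net_kw = {k: v for k, v in candidate.items() if k in _NET_KEYS}
    unknown = set(candidate) - _A1_KEYS - _NET_KEYS
    if unknown:
        raise ValueError(f"unknown calibration keys: {sorted(unknown)}")
    return replace(a1p, **a1_kw), replace(netp, **net_kw)


def evaluate_criteria(
    a1_params: A1Params,
    net_params: NetworkParams,
    criteria: Sequence[Criterion] = DEFAULT_CRITERIA,
    n_trials: int = 200,
    master_seed: int = 0,
) -> dict:
    """Run the battery and score each criterion; returns a report dict."""
    battery = run_property_battery(
        a1_params, net_params, n_trials=n_trials, master_seed=master_seed
    )
    results = {c.name: c(battery) for c in criteria}
    return {
        "criteria": results,
        "n_passed": sum(results.values()),
        "n_criteria": len(results),
        "battery": battery,
    }


def calibrate(
    search_space: Optional[dict[str, Sequence]] = None,
    criteria: Sequence[Criterion] = DEFAULT_CRITERIA,
    a1_params: Optional[A1Params] = None,
    net_params: Optional[NetworkParams] = None,
    n_trials: int = 200,
    master_seed: int = 0,
    max_evals: int = 50,
    rng_seed: int = 0,
) -> CalibrationResult:
    """Search the under-specified constants until all criteria pass.

    ``search_space`` maps parameter names (any field of A1Params or the free
    fields of NetworkParams) to candidate value sequences; the grid is
    sampled in random order up to ``max_evals`` candidates.  With an empty
    criteria list the defaults are returned unchanged.  If no candidate
    passes everything, the result has ``passed=False`` and the report ranks
    the closest candidates.
    """
    a1p = (a1_params or A1Params()).validate()
    netp = (net_params or NetworkParams()).validate()
    if not criteria:
        return CalibrationResult(True, a1p, netp, [])
    space = search_space or {}
    keys = sorted(space)
    combos = list(itertools.product(*(space[k] for k in keys))) if keys else [()]
    rng = np.random.default_rng(rng_seed)
    order = rng.permutation(len(combos))[:max_evals]
    report = []
    for idx in order:
        candidate = dict(zip(keys, combos[idx]))
        cand_a1, cand_net = _apply_candidate(a1p, netp, candidate)
        res = evaluate_criteria(
            cand_a1, cand_net, criteria, n_trials=n_trials, master_seed=master_seed
        )
        res["candidate"] = candidate
        report.append(res)
        if res["n_passed"] == res["n_criteria"]:
            return CalibrationResult(True, cand_a1, cand_net, report)
    best = max(report, key=lambda r: r["n_passed"])
    best_a1, best_net = _apply_candidate(a1p, netp, best["candidate"])
    return CalibrationResult(False, best_a1, best_net, report)
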