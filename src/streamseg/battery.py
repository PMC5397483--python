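"""Standard simulation battery for the model's qualitative signatures.

One function runs the full set of frozen-noise ensemble comparisons the
model is meant to reproduce — build-up with static vs adapting inputs at
DF 4/7/10, pause resets (300/600 ms after 7 context triplets), gated
distractor/deviant promotion of segregation, the no-effect far distractor,
the ungated midpoint distractor, and single-trial switch timing — and
returns a flat dictionary of named quantities.  The calibration harness,
the test suite and the acceptance script all consume this battery so that
every reported number comes from the same code path.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Optional

import numpy as np

from .a1 import A1Params, compute_input_trace
from .analysis import (
    ab_first_fraction,
    bin_edges_for_timeline,
    build_up,
    classify_bins,
    difference_score,
    first_switch_times,
)
from .competition import NetworkParams, NoiseBank, run_ensemble
from .paradigm import (
    apply_deviant,
    apply_distractor,
    apply_pause,
    make_triplet_sequence,
)

__all__ = ["run_property_battery", "buildup_for_timeline"]

DF_LIST = (4.0, 7.0, 10.0)


def buildup_for_timeline(
    timeline,
    a1_params: A1Params,
    net_params: NetworkParams,
    bank: NoiseBank,
):
    """(BuildUpFunction, PerceptSeries) for one timeline under frozen noise."""
    trace = compute_input_trace(timeline, a1_params, net_params.dt)
    ens = run_ensemble(trace, net_params, bank)
    edges, kinds = bin_edges_for_timeline(timeline)
    buf = build_up(ens, edges=edges, bin_kinds=kinds)
    series = classify_bins(ens, edges=edges, bin_kinds=kinds)
    return buf, series


def run_property_battery(
    a1_params: Optional[A1Params] = None,
    net_params: Optional[NetworkParams] = None,
    n_trials: int = 500,
    master_seed: int = 0,
    df_list=DF_LIST,
    long_df: float = 7.0,
    long_triplets: int = 30,
) -> dict:
    """Run the standard ensemble comparisons; return a flat name -> value dict.

    Per DF d (suffix ``_df{d:g}``):

    * ``static_first`` / ``static_final``: first/last-bin proportion
      segregated with static (pre-adapted) inputs, 10 triplets;
    * ``adapting_first`` / ``adapting_final``: same with adapting inputs;
    * ``delta_pause300`` / ``delta_pause600``: final-triplet difference vs
      the 10-triplet control (negative = reset toward integration);
    * ``pseg_pre_pause`` / ``pseg_during_pause``: proportion segregated in
      the last context-triplet bin and in the pause bin (600 ms pause);
    * ``delta_dis_b2_gated`` / ``delta_deviant2_gated`` /
      ``delta_dis_b15_gated``: final-triplet difference vs the 6-triplet
      control for a gated distractor at B+2, a gated deviant at +2 st, and a
      gated distractor at B+15 (positive = promotion of segregation);
    * ``sem_final``: binomial s.e.m. scale sqrt(0.25 / n_trials).

    Globals: ``delta_dis_mid_ungated_df10`` (ungated distractor at the
    semitone midpoint, DF 10), ``first_switch_median_s`` and
    ``ab_first_fraction`` (adapting input at ``long_df``, ``long_triplets``
    triplets), and the segregated-trial retention comparison
    ``seg_retention_test`` / ``seg_retention_control`` (gated distractor at
    B+2, DF 10: of the trials already segregated in the perturbation bin,
    the fraction still segregated in the final bin).
    """
    a1p = (a1_params or A1Params()).validate()
    netp = (net_params or NetworkParams()).validate()
    bank = NoiseBank(n_trials=n_trials, master_seed=master_seed)
    gated = replace(a1p, gate_non_triplet_from_ab=True)
    ungated = replace(a1p, gate_non_triplet_from_ab=False)
    static = replace(a1p, adapting=False)

    out: dict[str, float] = {"n_trials": float(n_trials)}
    sem_scale = float(np.sqrt(0.25 / n_trials))

    for df in df_list:
        tag = f"_df{df:g}"
        tl10 = make_triplet_sequence(10, df)
        buf_static, _ = buildup_for_timeline(tl10, static, netp, bank)
        buf_adapt, _ = buildup_for_timeline(tl10, a1p, netp, bank)
        out["static_first" + tag] = float(buf_static.proportion_segregated[0])
        out["static_final" + tag] = float(buf_static.proportion_segregated[-1])
        out["adapting_first" + tag] = float(buf_adapt.proportion_segregated[0])
        out["adapting_final" + tag] = float(buf_adapt.proportion_segregated[-1])
        out["sem_final" + tag] = sem_scale

        for pause_ms in (300, 600):
            tl_pause = apply_pause(tl10, pause_ms, after_triplet=7)
            buf_pause, _ = buildup_for_timeline(tl_pause, a1p, netp, bank)
            out[f"delta_pause{pause_ms}" + tag] = difference_score(buf_pause, buf_adapt)
            if pause_ms == 600:
                i_pre = buf_pause.triplet_bin_index(7)
                kinds = buf_pause.bin_kinds
                i_pause = kinds.index("pause")
                out["pseg_pre_pause" + tag] = float(
                    buf_pause.proportion_segregated[i_pre]
                )
                out["pseg_during_pause" + tag] = float(
                    buf_pause.proportion_segregated[i_pause]
                )

        tl6 = make_triplet_sequence(6, df)
        buf_ctrl6, series_ctrl6 = buildup_for_timeline(tl6, gated, netp, bank)
        buf_b2, series_b2 = buildup_for_timeline(
            apply_distractor(tl6, "B+2", 3), gated, netp, bank
        )
        buf_dev, _ = buildup_for_timeline(
            apply_deviant(tl6, 2.0, 3), gated, netp, bank
        )
        buf_b15, _ = buildup_for_timeline(
            apply_distractor(tl6, "B+15", 3), gated, netp, bank
        )
        out["delta_dis_b2_gated" + tag] = difference_score(buf_b2, buf_ctrl6)
        out["delta_deviant2_gated" + tag] = difference_score(buf_dev, buf_ctrl6)
        out["delta_dis_b15_gated" + tag] = difference_score(buf_b15, buf_ctrl6)

        if df == 10.0:
            buf_mid, _ = buildup_for_timeline(
                apply_distractor(tl6, "(A+B)/2", 3), ungated, netp, bank
            )
            out["delta_dis_mid_ungated_df10"] = difference_score(buf_mid, buf_ctrl6)
            # retention: among trials segregated in the perturbation bin
            # (triplet 3), the fraction still segregated at the final bin
            seg_at_pert = series_ctrl6.segregated[:, 2]
            if seg_at_pert.any():
                out["seg_retention_control"] = float(
                    series_ctrl6.segregated[seg_at_pert, -1].mean()
                )
                out["seg_retention_test"] = float(
                    series_b2.segregated[seg_at_pert, -1].mean()
                )

    tl_long = make_triplet_sequence(long_triplets, long_df)
    trace_long = compute_input_trace(tl_long, a1p, netp.dt)
    ens_long = run_ensemble(trace_long, netp, bank, store_aux=True)
    switches = first_switch_times(ens_long)
    out["first_switch_median_s"] = float(np.nanmedian(switches) / 1000.0)
    out["first_switch_nan_frac"] = float(np.mean(np.isnan(switches)))
    out["ab_first_fraction"] = float(ab_first_fraction(ens_long))
    return out
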