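"""Run configuration, validation, seeds and experiment artifacts.

A :class:`RunConfig` bundles the input-stage and competition-stage
parameters with an experiment descriptor, an ensemble size and a master
seed.  A single master seed determines every noise path and initial
condition through a counter-based spawning scheme (trial i, stream s), so
all outputs are reproducible independent of execution order.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .a1 import A1Params
from .analysis import difference_score
from .battery import buildup_for_timeline
from .competition import NetworkParams, NoiseBank
from .paradigm import (
    TONE_MS,
    apply_deviant,
    apply_distractor,
    apply_pause,
    make_triplet_sequence,
    pause_experiment_design,
    perturbation_experiment_design,
)

__all__ = ["RunConfig", "load_config", "run_experiment", "EXPERIMENTS"]

log = logging.getLogger("streamseg")

EXPERIMENTS = ("buildup", "pause", "perturbation", "sweep")


@dataclass
class RunConfig:
    """Everything needed to reproduce one experiment run."""

    a1: A1Params = field(default_factory=A1Params)
    network: NetworkParams = field(default_factory=NetworkParams)
    experiment: str = "buildup"
    n_trials: int = 500
    master_seed: int = 0
    df_list: tuple[float, ...] = (4.0, 7.0, 10.0)
    base_freq_hz: float = 500.0
    sweep_specs: tuple[str, ...] = ("A-2", "A", "(A+B)/2", "B", "B+2", "B+4", "B+8")
    gate_non_triplet: bool = True

    def validate(self) -> "RunConfig":
        self.a1.validate()
        self.network.validate()
        if self.experiment not in EXPERIMENTS:
            raise ValueError(
                f"experiment must be one of {EXPERIMENTS}, got {self.experiment!r}"
            )
        if self.n_trials < 1:
            raise ValueError(f"n_trials must be >= 1, got {self.n_trials}")
        if TONE_MS % self.network.dt:
            raise ValueError(
                f"dt ({self.network.dt} ms) must divide the {TONE_MS} ms tone duration"
            )
        return self

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["df_list"] = list(self.df_list)
        d["sweep_specs"] = list(self.sweep_specs)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _build_section(cls, section: dict, name: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - known
    if unknown:
        raise ValueError(f"unknown key(s) in '{name}' section: {sorted(unknown)}")
    return cls(**section)


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Load a YAML/JSON config; unknown keys are rejected, missing keys take
    the packaged defaults, and the resolved config is echoed to the log."""
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    if overrides:
        raw = {**raw, **overrides}
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown top-level config key(s): {sorted(unknown)}")
    kwargs = dict(raw)
    if "a1" in kwargs:
        kwargs["a1"] = _build_section(A1Params, kwargs["a1"] or {}, "a1")
    if "network" in kwargs:
        kwargs["network"] = _build_section(
            NetworkParams, kwargs["network"] or {}, "network"
        )
    for key in ("df_list", "sweep_specs"):
        if key in kwargs and kwargs[key] is not None:
            kwargs[key] = tuple(kwargs[key])
    cfg = RunConfig(**kwargs).validate()
    log.info("resolved config: %s", json.dumps(cfg.to_dict(), sort_keys=True))
    return cfg


# ---------------------------------------------------------------------------
# Experiment runners
# ---------------------------------------------------------------------------


def _provenance(cfg: RunConfig, outdir: Path, extra: dict | None = None) -> None:
    rec = {
        "version": __version__,
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "master_seed": cfg.master_seed,
    }
    if extra:
        rec.update(extra)
    (outdir / "provenance.json").write_text(json.dumps(rec, indent=2, sort_keys=True))


def _buildup_frame(bufs: dict):
    import pandas as pd

    frames = []
    for (label, df), buf in bufs.items():
        frame = buf.to_frame()
        frame.insert(0, "condition", label)
        frame.insert(1, "df_st", df)
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def _plot_buildup(bufs: dict, path: Path, title: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for (label, df), buf in sorted(bufs.items(), key=lambda kv: (kv[0][1], kv[0][0])):
        style = "--" if "static" in label or "control" in label else "-"
        ax.errorbar(
            buf.bin_centers / 1000.0,
            buf.proportion_segregated,
            yerr=buf.sem,
            ls=style,
            label=f"{label} DF={df:g}",
            lw=1.2,
        )
    ax.set_xlabel("time (s)")
    ax.set_ylabel("proportion segregated")
    ax.set_ylim(-0.02, 1.02)
    ax.set_title(title)
    ax.legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_experiment(config: RunConfig, outdir) -> dict:
    """Run the named experiment; write CSVs, a figure and provenance.

    Deterministic given ``config.master_seed``: two runs with the same
    config produce byte-identical CSVs.  Returns a small summary dict.
    """
    cfg = config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    a1p, netp = cfg.a1, cfg.network
    bank = NoiseBank(n_trials=cfg.n_trials, master_seed=cfg.master_seed)
    summary: dict = {"experiment": cfg.experiment}

    if cfg.experiment == "buildup":
        bufs = {}
        for df in cfg.df_list:
            tl = make_triplet_sequence(10, df, cfg.base_freq_hz)
            for label, params in (
                ("adapting", a1p),
                ("static", replace(a1p, adapting=False)),
            ):
                bufs[(label, df)], _ = buildup_for_timeline(tl, params, netp, bank)
        _buildup_frame(bufs).to_csv(outdir / "buildup.csv", index=False)
        _plot_buildup(bufs, outdir / "buildup.png", "build-up of segregation")
        summary["final"] = {
            f"DF{df:g}": float(bufs[("adapting", df)].proportion_segregated[-1])
            for df in cfg.df_list
        }
    elif cfg.experiment == "pause":
        bufs = {}
        deltas = []
        for df in cfg.df_list:
            tl10 = make_triplet_sequence(10, df, cfg.base_freq_hz)
            bufs[("control10", df)], _ = buildup_for_timeline(tl10, a1p, netp, bank)
            for pause in (300, 600):
                tl = apply_pause(tl10, pause, after_triplet=7)
                buf, _ = buildup_for_timeline(tl, a1p, netp, bank)
                bufs[(f"pause{pause}", df)] = buf
                deltas.append(
                    {
                        "df_st": df,
                        "condition": f"pause{pause}",
                        "delta": difference_score(buf, bufs[("control10", df)]),
                    }
                )
        import pandas as pd

        _buildup_frame(bufs).to_csv(outdir / "pause_buildup.csv", index=False)
        pd.DataFrame(deltas).to_csv(outdir / "pause_deltas.csv", index=False)
        _plot_buildup(bufs, outdir / "pause.png", "pause-induced reset")
        pause_experiment_design().to_csv(
            outdir / "pause_design.csv", master_seed=cfg.master_seed
        )
        summary["deltas"] = deltas
    elif cfg.experiment == "perturbation":
        a1_run = replace(a1p, gate_non_triplet_from_ab=cfg.gate_non_triplet)
        bufs = {}
        deltas = []
        for df in cfg.df_list:
            tl6 = make_triplet_sequence(6, df, cfg.base_freq_hz)
            bufs[("control6", df)], _ = buildup_for_timeline(tl6, a1_run, netp, bank)
            conds = {
                "disB+2": apply_distractor(tl6, "B+2", 3),
                "deviant+2": apply_deviant(tl6, 2.0, 3),
            }
            for label, tl in conds.items():
                buf, _ = buildup_for_timeline(tl, a1_run, netp, bank)
                bufs[(label, df)] = buf
                deltas.append(
                    {
                        "df_st": df,
                        "condition": label,
                        "delta": difference_score(buf, bufs[("control6", df)]),
                    }
                )
        import pandas as pd

        _buildup_frame(bufs).to_csv(outdir / "perturbation_buildup.csv", index=False)
        pd.DataFrame(deltas).to_csv(outdir / "perturbation_deltas.csv", index=False)
        _plot_buildup(bufs, outdir / "perturbation.png", "distractor / deviant effects")
        perturbation_experiment_design(["distractor:B+2", "deviant:+2"]).to_csv(
            outdir / "perturbation_design.csv", master_seed=cfg.master_seed
        )
        summary["deltas"] = deltas
    elif cfg.experiment == "sweep":
        from .analysis import distractor_sweep

        hypothesis = "gated" if cfg.gate_non_triplet else "ungated"
        sweep = distractor_sweep(
            cfg.sweep_specs,
            cfg.df_list,
            hypothesis=hypothesis,
            n_trials=cfg.n_trials,
            master_seed=cfg.master_seed,
            a1_params=a1p,
            net_params=netp,
        )
        frame = sweep.to_frame()
        frame.to_csv(outdir / "sweep.csv", index=False)
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
        x = np.arange(len(sweep.freq_specs))
        width = 0.8 / len(sweep.df_list)
        for j, df in enumerate(sweep.df_list):
            ax.bar(x + j * width, sweep.delta[:, j], width, label=f"DF={df:g}")
        ax.axhline(0, color="k", lw=0.8)
        ax.set_xticks(x + 0.4 - width / 2)
        ax.set_xticklabels(sweep.freq_specs, rotation=45, fontsize=7)
        ax.set_ylabel("delta proportion segregated")
        ax.set_title(f"distractor frequency sweep ({hypothesis})")
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(outdir / "sweep.png", dpi=120)
        plt.close(fig)
        summary["sweep"] = frame.to_dict("records")

    _provenance(cfg, outdir)
    return summary
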