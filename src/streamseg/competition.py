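"""Three-unit stochastic competition network.

Downstream of A1, three firing-rate units — A and B encoding the two
segregated streams and AB encoding the integrated percept — compete through
global inhibition.  Each unit k in {A, AB, B} carries four state variables:

* ``r_k``: mean firing rate, the sigmoid-bounded output,
      tau_r dr_k/dt = -r_k + F(beta_e e_k - beta_i (r_A + r_AB + r_B)
                               - g a_k + I_k + chi_k)
* ``e_k``: recurrent NMDA-like excitation, relaxing toward r_k with tau_e
  (70 ms — slow enough to bridge the silent gaps between tones),
* ``a_k``: linear spike-frequency adaptation, relaxing toward r_k with
  tau_a (1.4 s — the slow negative feedback that paces build-up),
* ``chi_k``: an independent Ornstein-Uhlenbeck noise process.

Global inhibition is instantaneous and pools all three rates including the
unit's own.  With beta_e = 0.65 > beta_i = 0.3 there is net local
excitation, so a dominant unit can sustain itself across silent gaps; noise
plus rising adaptation of the dominant unit produce the stochastic switches
between the integrated and segregated attractors.

Integration is Euler-Maruyama with stepsize dt = 0.5 tau_r = 5 ms.  The OU
noise uses its exact one-step discretization (mean-reverting update with
per-step variance matched), which is an intentional refinement over a naive
Euler noise update and exact for any dt.  Ensembles reuse a frozen bank of
noise paths and initial conditions so that two conditions differing only
from some time T produce bit-identical trajectories before T.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Optional

import numpy as np

from .a1 import A1InputTrace

__all__ = [
    "UNITS",
    "NetworkParams",
    "NetworkState",
    "NetworkTrajectory",
    "NoiseBank",
    "EnsembleResult",
    "firing_rate_function",
    "step",
    "simulate_trial",
    "run_ensemble",
    "quiescent_fixed_point",
]

UNITS = ("A", "AB", "B")
_VAR_NAMES = ("r", "e", "a", "chi")


@dataclass
class NetworkParams:
    """Competition-stage parameters (times in ms, gains dimensionless).

    tau_r/tau_e/tau_a, beta_e/beta_i and g are the published operating
    point; F_threshold, F_slope and the noise constants are fixed by the
    calibration harness (docs/methods.md).
    """

    tau_r: float = 10.0
    tau_e: float = 70.0
    tau_a: float = 1400.0
    beta_e: float = 0.65
    beta_i: float = 0.3
    g: float = 0.045
    f_threshold: float = 0.26
    f_slope: float = 0.04
    noise_sigma: float = 0.065
    noise_tau: float = 100.0
    dt: float = 5.0  # 0.5 * tau_r

    def validate(self) -> "NetworkParams":
        for name in ("tau_r", "tau_e", "tau_a", "noise_tau", "dt", "f_slope"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.beta_e <= self.beta_i:
            raise ValueError(
                f"beta_e ({self.beta_e}) must exceed beta_i ({self.beta_i}): "
                "the network requires net local excitation"
            )
        if self.dt > self.tau_r:
            raise ValueError(f"dt ({self.dt}) must not exceed tau_r ({self.tau_r})")
        if self.noise_sigma < 0:
            raise ValueError(f"noise_sigma must be >= 0, got {self.noise_sigma}")
        return self


def firing_rate_function(x, params: NetworkParams):
    """Logistic firing-rate function F(x) = 1 / (1 + exp(-(x - thr)/slope))."""
    z = (np.asarray(x, dtype=float) - params.f_threshold) / params.f_slope
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500.0, 500.0)))


@dataclass(frozen=True)
class NetworkState:
    """Instantaneous state of the three units; arrays of shape (..., 3)."""

    r: np.ndarray
    e: np.ndarray
    a: np.ndarray
    chi: np.ndarray

    @classmethod
    def zeros(cls, shape=(3,)) -> "NetworkState":
        return cls(*(np.zeros(shape) for _ in range(4)))


def _step_arrays(r, e, a, chi, I_now, params, noise_normal=None):
    """One Euler-Maruyama update; all derivatives evaluated at the old state."""
    drive = (
        params.beta_e * e
        - params.beta_i * r.sum(axis=-1, keepdims=True)
        - params.g * a
        + I_now
        + chi
    )
    F = firing_rate_function(drive, params)
    dt = params.dt
    r_new = r + (dt / params.tau_r) * (F - r)
    e_new = e + (dt / params.tau_e) * (r - e)
    a_new = a + (dt / params.tau_a) * (r - a)
    if noise_normal is None or params.noise_sigma == 0.0:
        chi_new = chi * np.exp(-dt / params.noise_tau)
    else:
        alpha = np.exp(-dt / params.noise_tau)
        chi_new = chi * alpha + params.noise_sigma * np.sqrt(1.0 - alpha**2) * noise_normal
    return r_new, e_new, a_new, chi_new


def step(
    state: NetworkState,
    inputs: np.ndarray,
    params: NetworkParams,
    noise_increment: Optional[np.ndarray] = None,
) -> NetworkState:
    """Advance the full 12-variable state by one Euler-Maruyama step.

    ``inputs`` are the per-unit drives I_k at the current time;
    ``noise_increment`` is a standard-normal draw per unit (the OU update is
    the exact discretization, so the increment enters with the matched
    per-step standard deviation).
    """
    r, e, a, chi = _step_arrays(
        state.r, state.e, state.a, state.chi, np.asarray(inputs, dtype=float),
        params, noise_increment,
    )
    new = NetworkState(r, e, a, chi)
    _check_finite({"r": r, "e": e, "a": a, "chi": chi}, step_index=None)
    return new


def _check_finite(named_arrays: dict, step_index) -> None:
    for name, arr in named_arrays.items():
        if not np.all(np.isfinite(arr)):
            where = "" if step_index is None else f" at step {step_index}"
            raise FloatingPointError(
                f"non-finite value in variable {name!r}{where}"
            )


def quiescent_fixed_point(params: NetworkParams, tol: float = 1e-12) -> float:
    """Symmetric zero-input fixed point: r* = F((beta_e - 3 beta_i - g) r*).

    At the fixed point e_k = a_k = r_k for all units; solved by damped
    fixed-point iteration.
    """
    c = params.beta_e - 3.0 * params.beta_i - params.g
    r = 0.0
    for _ in range(10000):
        r_next = float(firing_rate_function(c * r, params))
        if abs(r_next - r) < tol:
            return r_next
        r = 0.5 * r + 0.5 * r_next
    raise RuntimeError("quiescent fixed point iteration did not converge")


# ---------------------------------------------------------------------------
# Frozen noise and initial conditions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NoiseBank:
    """Deterministic per-trial noise and initial-condition streams.

    Trial ``i`` of a bank with a given ``master_seed`` always sees the same
    OU driving path and the same initial condition, regardless of ensemble
    size, simulation length or execution order: stream (i, 0) yields the
    stationary initial chi and the per-step standard normals, stream (i, 1)
    the initial conditions.  Longer simulations extend a path without
    changing its prefix, which is what makes frozen-noise condition
    comparisons bit-exact before the conditions diverge.
    """

    n_trials: int
    master_seed: int
    init_max: float = 0.1  # r, e, a drawn uniformly from [0, init_max]

    def _rng(self, trial: int, stream: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(self.master_seed, spawn_key=(trial, stream))
        )

    def noise_draws(self, n_steps: int) -> tuple[np.ndarray, np.ndarray]:
        """(chi0_standard, normals): shapes (n_trials, 3), (n_trials, n_steps, 3).

        ``chi0_standard`` is standard normal; the engine scales it by the
        stationary s.d. ``noise_sigma``.
        """
        chi0 = np.empty((self.n_trials, 3))
        normals = np.empty((self.n_trials, n_steps, 3))
        for i in range(self.n_trials):
            rng = self._rng(i, 0)
            chi0[i] = rng.standard_normal(3)
            normals[i] = rng.standard_normal((n_steps, 3))
        return chi0, normals

    def initial_states(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(r0, e0, a0), each (n_trials, 3), uniform on [0, init_max]."""
        r0 = np.empty((self.n_trials, 3))
        e0 = np.empty((self.n_trials, 3))
        a0 = np.empty((self.n_trials, 3))
        for i in range(self.n_trials):
            rng = self._rng(i, 1)
            r0[i], e0[i], a0[i] = rng.uniform(0.0, self.init_max, (3, 3))
        return r0, e0, a0


# ---------------------------------------------------------------------------
# Trajectories and ensembles
# ---------------------------------------------------------------------------


@dataclass
class NetworkTrajectory:
    """State time series of one trial; arrays shaped (n_samples, 3)."""

    t: np.ndarray
    r: np.ndarray
    e: Optional[np.ndarray]
    a: Optional[np.ndarray]
    chi: Optional[np.ndarray]
    seed: Optional[int]
    params: NetworkParams
    input: Optional[A1InputTrace] = None

    def to_frame(self):
        import pandas as pd

        cols = {"t_ms": self.t}
        for name, arr in (("r", self.r), ("e", self.e), ("a", self.a)):
            if arr is not None:
                for j, unit in enumerate(UNITS):
                    cols[f"{name}_{unit}"] = arr[:, j]
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class EnsembleResult:
    """Trial-stacked rate trajectories; ``r`` has shape (n_trials, n_samples, 3)."""

    t: np.ndarray
    r: np.ndarray
    master_seed: int
    params: NetworkParams
    input: Optional[A1InputTrace] = None
    e: Optional[np.ndarray] = None
    a: Optional[np.ndarray] = None

    @property
    def n_trials(self) -> int:
        return self.r.shape[0]

    def trajectory(self, i: int) -> NetworkTrajectory:
        return NetworkTrajectory(
            t=self.t,
            r=self.r[i],
            e=None if self.e is None else self.e[i],
            a=None if self.a is None else self.a[i],
            chi=None,
            seed=self.master_seed,
            params=self.params,
            input=self.input,
        )

    def __len__(self) -> int:
        return self.n_trials

    def __iter__(self) -> Iterator[NetworkTrajectory]:
        return (self.trajectory(i) for i in range(self.n_trials))


def _integrate(
    I: np.ndarray,
    params: NetworkParams,
    r0: np.ndarray,
    e0: np.ndarray,
    a0: np.ndarray,
    chi0: np.ndarray,
    normals: Optional[np.ndarray],
    store_aux: bool = False,
    check_every: int = 16,
):
    """Vectorized Euler-Maruyama over trials; I is (n_samples, 3)."""
    n_steps = I.shape[0] - 1
    n_trials = r0.shape[0]
    r, e, a, chi = (x.copy() for x in (r0, e0, a0, chi0))
    R = np.empty((n_trials, n_steps + 1, 3))
    R[:, 0] = r
    E = A = None
    if store_aux:
        E = np.empty_like(R)
        A = np.empty_like(R)
        E[:, 0], A[:, 0] = e, a
    for i in range(n_steps):
        xi = None if normals is None else normals[:, i]
        r, e, a, chi = _step_arrays(r, e, a, chi, I[i], params, xi)
        R[:, i + 1] = r
        if store_aux:
            E[:, i + 1], A[:, i + 1] = e, a
        if (i + 1) % check_every == 0 or i == n_steps - 1:
            _check_finite({"r": r, "e": e, "a": a, "chi": chi}, step_index=i + 1)
    return R, E, A, chi


def _check_grid(input: A1InputTrace, params: NetworkParams) -> None:
    if abs(input.dt - params.dt) > 1e-12:
        raise ValueError(
            f"input grid step ({input.dt} ms) must equal params.dt ({params.dt} ms)"
        )


def simulate_trial(
    input: A1InputTrace,
    params: NetworkParams,
    trial_seed: int,
    init: Optional[NetworkState] = None,
) -> NetworkTrajectory:
    """Integrate one trial; deterministic given (input, params, seed, init)."""
    params.validate()
    _check_grid(input, params)
    bank = NoiseBank(n_trials=1, master_seed=trial_seed)
    chi0_std, normals = bank.noise_draws(input.n_steps)
    if init is None:
        r0, e0, a0 = bank.initial_states()
    else:
        r0 = np.atleast_2d(init.r)
        e0 = np.atleast_2d(init.e)
        a0 = np.atleast_2d(init.a)
    chi0 = (
        np.atleast_2d(init.chi)
        if init is not None and init.chi is not None and np.any(init.chi)
        else params.noise_sigma * chi0_std
    )
    R, E, A, _ = _integrate(
        input.I, params, r0, e0, a0, chi0,
        normals if params.noise_sigma > 0 else None, store_aux=True,
    )
    t = input.t.copy()
    return NetworkTrajectory(
        t=t, r=R[0], e=E[0], a=A[0], chi=None, seed=trial_seed,
        params=params, input=input,
    )


def run_ensemble(
    input: A1InputTrace,
    params: NetworkParams,
    noise: NoiseBank,
    store_aux: bool = False,
) -> EnsembleResult:
    """Integrate a frozen-noise ensemble; trial i uses noise path i and init i."""
    params.validate()
    _check_grid(input, params)
    chi0_std, normals = noise.noise_draws(input.n_steps)
    r0, e0, a0 = noise.initial_states()
    R, E, A, _ = _integrate(
        input.I, params, r0, e0, a0, params.noise_sigma * chi0_std,
        normals if params.noise_sigma > 0 else None, store_aux=store_aux,
    )
    return EnsembleResult(
        t=input.t.copy(), r=R, master_seed=noise.master_seed, params=params,
        input=input, e=E, a=A,
    )
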