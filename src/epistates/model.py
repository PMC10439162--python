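"""Wendling neural mass model of hippocampal epileptic dynamics.

The model couples four neural populations — pyramidal cells, excitatory
interneurons, slow (dendritic) inhibitory interneurons and fast (somatic)
inhibitory interneurons — through average postsynaptic potential (PSP)
kernels and a static sigmoidal wave-to-pulse conversion.  Three synaptic
gains control the regime:

* ``A`` — excitatory gain (mV)
* ``B`` — slow-inhibitory gain (mV)
* ``G`` — fast-inhibitory gain (mV)

Four canonical (A, B, G) configurations reproduce the four epileptic brain
state types seen in hippocampal recordings: interictal background,
preonset sporadic spiking, low-voltage fast onset activity (15–40 Hz) and
rhythmic ictal discharges (4–10 Hz).  The model output, interpreted as an
EEG/LFP-like signal, is the summed PSP on the pyramidal population,
``y1 - y2 - y3``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import IntEnum

import numpy as np

__all__ = [
    "BrainStateLabel",
    "WendlingParams",
    "StateConfig",
    "Segment",
    "STATE_CONFIGS",
    "sigmoid",
    "derivatives",
    "simulate",
    "simulate_type_set",
    "NumericalDivergenceError",
]


class BrainStateLabel(IntEnum):
    """The four epileptic brain-state types, with fixed integer codes."""

    INTERICTAL = 1
    PREONSET = 2
    ONSET = 3
    ICTAL = 4


class NumericalDivergenceError(RuntimeError):
    """Raised when the state becomes non-finite during integration."""

    def __init__(self, step: int):
        self.step = step
        super().__init__(f"model state became non-finite at integration step {step}")


@dataclass(frozen=True)
class WendlingParams:
    """Parameters of the Wendling model.

    Synaptic gains A/B/G are in mV; rate constants a/b/g in 1/s; the
    connectivity constants C1..C7 are fixed fractions of the base
    connectivity C.  The sigmoid converts membrane potential (mV) into a
    population firing rate (1/s); the input noise drive p(t) is drawn per
    integration step from N(noise_mean, noise_std) (1/s).
    """

    A: float = 3.25
    B: float = 22.0
    G: float = 10.0
    a: float = 100.0
    b: float = 30.0
    g: float = 350.0
    C: float = 135.0
    v0: float = 6.0
    e0: float = 2.5
    r: float = 0.56
    noise_mean: float = 90.0
    noise_std: float = 30.0

    def __post_init__(self):
        for name in ("a", "b", "g", "C", "e0", "r"):
            if getattr(self, name) <= 0:
                raise ValueError(f"parameter {name} must be positive")
        if self.noise_std < 0:
            raise ValueError("noise_std must be non-negative")

    # connectivity constants derived from C
    @property
    def C1(self) -> float:
        return self.C

    @property
    def C2(self) -> float:
        return 0.8 * self.C

    @property
    def C3(self) -> float:
        return 0.25 * self.C

    @property
    def C4(self) -> float:
        return 0.25 * self.C

    @property
    def C5(self) -> float:
        return 0.3 * self.C

    @property
    def C6(self) -> float:
        return 0.1 * self.C

    @property
    def C7(self) -> float:
        return 0.8 * self.C


@dataclass(frozen=True)
class StateConfig:
    """A brain-state type and the gain configuration that generates it."""

    label: BrainStateLabel
    params: WendlingParams


#: Canonical (A, B, G) gain configurations for the four brain-state types.
STATE_CONFIGS: dict[BrainStateLabel, StateConfig] = {
    BrainStateLabel.INTERICTAL: StateConfig(
        BrainStateLabel.INTERICTAL, WendlingParams(A=3.5, B=13.2, G=10.76)
    ),
    BrainStateLabel.PREONSET: StateConfig(
        BrainStateLabel.PREONSET, WendlingParams(A=4.6, B=20.4, G=11.48)
    ),
    BrainStateLabel.ONSET: StateConfig(
        BrainStateLabel.ONSET, WendlingParams(A=7.7, B=4.3, G=15.1)
    ),
    BrainStateLabel.ICTAL: StateConfig(
        BrainStateLabel.ICTAL, WendlingParams(A=8.7, B=11.4, G=2.1)
    ),
}


@dataclass
class Segment:
    """A fixed-duration single-channel time series."""

    samples: np.ndarray
    fs: float
    true_label: BrainStateLabel | None = None

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs


def sigmoid(v, params: WendlingParams = WendlingParams()):
    """Wave-to-pulse sigmoid S(v) = 2*e0 / (1 + exp(r*(v0 - v))).

    Maps an average membrane potential ``v`` (mV) to a population firing
    rate (1/s), bounded in (0, 2*e0) and strictly increasing.
    """
    return 2.0 * params.e0 / (1.0 + np.exp(params.r * (params.v0 - v)))


def derivatives(state, p_t, params: WendlingParams):
    """Time derivative of the ten-dimensional Wendling state.

    ``state`` holds five second-order PSP channels y0..y4 and their
    derivatives y5..y9 (the last axis may be an ensemble axis):

    * y0 — pyramidal output PSP, driving all interneuron populations
    * y1 — excitatory feedback PSP on pyramidal cells (receives p(t))
    * y2 — slow (dendritic) inhibitory PSP on pyramidal cells
    * y3 — fast (somatic) inhibitory PSP on pyramidal cells
    * y4 — slow-inhibitory PSP on the fast interneurons

    Each channel obeys dy = y', dy' = K*k*input - 2*k*y' - k^2*y with
    (K, k) = (A, a), (B, b) or (G, g).  The model output is y1 - y2 - y3.
    """
    y = np.asarray(state, dtype=float)
    if not np.all(np.isfinite(y)):
        raise NumericalDivergenceError(step=-1)
    A, B, G = params.A, params.B, params.G
    a, b, g = params.a, params.b, params.g

    S = lambda v: sigmoid(v, params)
    out = np.empty_like(y)
    out[0:5] = y[5:10]
    out[5] = A * a * S(y[1] - y[2] - y[3]) - 2 * a * y[5] - a * a * y[0]
    out[6] = A * a * (p_t + params.C2 * S(params.C1 * y[0])) - 2 * a * y[6] - a * a * y[1]
    out[7] = B * b * params.C4 * S(params.C3 * y[0]) - 2 * b * y[7] - b * b * y[2]
    out[8] = (
        G * g * params.C7 * S(params.C5 * y[0] - params.C6 * y[4])
        - 2 * g * y[8]
        - g * g * y[3]
    )
    out[9] = B * b * S(params.C3 * y[0]) - 2 * b * y[9] - b * b * y[4]
    return out


def _integrate_ensemble(
    params: WendlingParams,
    noise: np.ndarray,
    dt: float,
) -> np.ndarray:
    """Fixed-step Euler integration of an ensemble of trajectories.

    ``noise`` has shape (n_steps, n_ensemble): one p(t) draw per step per
    trajectory.  Returns the output y1 - y2 - y3 at every step, shape
    (n_steps, n_ensemble).  Initial state is all zeros.
    """
    n_steps, n_ens = noise.shape
    y = np.zeros((10, n_ens))
    out = np.empty((n_steps, n_ens))

    A, B, G = params.A, params.B, params.G
    a, b, g = params.a, params.b, params.g
    C1, C2, C3, C4 = params.C1, params.C2, params.C3, params.C4
    C5, C6, C7 = params.C5, params.C6, params.C7
    two_e0, r, v0 = 2.0 * params.e0, params.r, params.v0

    for i in range(n_steps):
        y0, y1, y2, y3, y4 = y[0], y[1], y[2], y[3], y[4]
        v_out = y1 - y2 - y3
        s_pyr = two_e0 / (1.0 + np.exp(r * (v0 - v_out)))
        s_exc = two_e0 / (1.0 + np.exp(r * (v0 - C1 * y0)))
        s_slow = two_e0 / (1.0 + np.exp(r * (v0 - C3 * y0)))
        s_fast = two_e0 / (1.0 + np.exp(r * (v0 - (C5 * y0 - C6 * y4))))

        y[0] = y0 + dt * y[5]
        y[1] = y1 + dt * y[6]
        y[2] = y2 + dt * y[7]
        y[3] = y3 + dt * y[8]
        y[4] = y4 + dt * y[9]
        y[5] += dt * (A * a * s_pyr - 2 * a * y[5] - a * a * y0)
        y[6] += dt * (A * a * (noise[i] + C2 * s_exc) - 2 * a * y[6] - a * a * y1)
        y[7] += dt * (B * b * C4 * s_slow - 2 * b * y[7] - b * b * y2)
        y[8] += dt * (G * g * C7 * s_fast - 2 * g * y[8] - g * g * y3)
        y[9] += dt * (B * b * s_slow - 2 * b * y[9] - b * b * y4)

        out[i] = y[1] - y[2] - y[3]
        if i % 512 == 0 and not np.all(np.isfinite(y[5])):
            raise NumericalDivergenceError(step=i)
    if not np.all(np.isfinite(out[-1])):
        raise NumericalDivergenceError(step=n_steps - 1)
    return out


def _simulate_ensemble(
    config: StateConfig,
    duration: float,
    fs: float,
    seeds: list[int],
    fs_int: float | None = None,
    burn_in: float = 2.0,
) -> list[Segment]:
    """Simulate one segment per seed, vectorized over the ensemble.

    Each ensemble member draws its noise stream from its own seeded
    Generator, so the result is identical to simulating each seed alone.
    """
    if duration <= 0 or fs <= 0:
        raise ValueError("duration and fs must be positive")
    if fs_int is None:
        fs_int = fs
    step_ratio = fs_int / fs
    if abs(step_ratio - round(step_ratio)) > 1e-9:
        raise ValueError(f"fs_int={fs_int} must be an integer multiple of fs={fs}")
    step_ratio = int(round(step_ratio))
    dt = 1.0 / fs_int
    n_keep = int(round(duration * fs))
    n_steps = int(round((burn_in + duration) * fs_int))

    p = config.params
    noise = np.empty((n_steps, len(seeds)))
    for j, s in enumerate(seeds):
        rng = np.random.default_rng(s)
        if p.noise_std > 0:
            noise[:, j] = rng.normal(p.noise_mean, p.noise_std, size=n_steps)
        else:
            noise[:, j] = p.noise_mean
    out = _integrate_ensemble(p, noise, dt)
    # discard burn-in, then decimate by stride (output is band-limited by
    # the synaptic kernels well below the internal Nyquist)
    n_burn = n_steps - n_keep * step_ratio
    kept = out[n_burn::step_ratio]
    assert kept.shape[0] == n_keep
    return [
        Segment(kept[:, j].copy(), fs=fs, true_label=config.label)
        for j in range(len(seeds))
    ]


def simulate(
    config: StateConfig,
    duration: float = 5.0,
    fs: float = 512.0,
    seed: int | None = None,
    fs_int: float | None = None,
    burn_in: float = 2.0,
) -> Segment:
    """Simulate one labeled segment of the given brain-state type.

    Integrates the model with fixed-step Euler at ``fs_int`` (default:
    the output rate ``fs``, one noise draw per output sample, as in the
    discrete reference implementations of this model), discards a
    ``burn_in`` transient from the all-zero initial state, and — when
    ``fs_int`` exceeds ``fs`` — decimates the output y1 - y2 - y3 to
    ``fs``.  Reproducible given ``seed``.
    """
    return _simulate_ensemble(config, duration, fs, [seed], fs_int, burn_in)[0]


def simulate_type_set(
    n_per_type: int = 100,
    duration: float = 5.0,
    fs: float = 512.0,
    seed: int | None = None,
    fs_int: float | None = None,
    burn_in: float = 2.0,
) -> list[Segment]:
    """Simulate ``n_per_type`` labeled segments per canonical state type.

    Returns 4*n_per_type segments ordered interictal, preonset, onset,
    ictal.  Per-segment seeds are derived deterministically from the
    master seed (master + running segment index), so any single segment
    can be regenerated independently.
    """
    if n_per_type < 1:
        raise ValueError("n_per_type must be >= 1")
    base = 0 if seed is None else int(seed)
    segments: list[Segment] = []
    idx = 0
    for label in BrainStateLabel:
        config = STATE_CONFIGS[label]
        seeds = [base + idx + j for j in range(n_per_type)]
        idx += n_per_type
        segments.extend(
            _simulate_ensemble(config, duration, fs, seeds, fs_int, burn_in)
        )
    return segments


def config_with_gains(
    label: BrainStateLabel, A: float, B: float, G: float, **overrides
) -> StateConfig:
    """Build a StateConfig with custom synaptic gains (other params default)."""
    return StateConfig(label, replace(WendlingParams(), A=A, B=B, G=G, **overrides))
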