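"""Neural mass model of alpha-generating cortical populations under tCS.

Each cortical patch is modeled as three interacting subpopulations:
pyramidal cells (P), fast somatic-targeting interneurons (I, GABA_A,fast)
and slow dendrite-targeting interneurons (I', GABA_A,slow).  Mean firing
rates are obtained from mean membrane potentials through a Wilson-Cowan
sigmoid, and rates are converted back into post-synaptic potentials by
second-order linear kernels (one per synapse type).  A network of
``n_cortical`` such populations is driven by one extra "subcortical"
population acting as a common pacemaker: it receives a slow periodic
trapezoid input and projects unidirectionally (glutamatergic) onto every
cortical population, which synchronizes their alpha activity into
spindle-like bursts.

Transcranial current stimulation enters the model as an additive offset
on the mean membrane potential of pyramidal cells only (the field effect
on interneurons is neglected), constant for tDCS or sinusoidal for tACS,
with a per-region amplitude proportional to the mean normal component of
the stimulation-induced electric field over that region.

The per-region output (the local field potential proxy) is the net
summed post-synaptic potential at pyramidal cells: EPSPs minus fast and
slow IPSPs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "SubpopulationParams",
    "Connectivity",
    "PopulationParams",
    "TrapezoidDrive",
    "NoiseSpec",
    "NetworkConfig",
    "StimulusSpec",
    "SimulationResult",
    "InstabilityError",
    "alpha_population_params",
    "sigmoid_rate",
    "psp_impulse_response",
    "trapezoid_drive",
    "tcs_offset",
    "simulate_network",
    "simulate_trials",
]


class InstabilityError(RuntimeError):
    """Raised when the fixed-step integration diverges."""


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SubpopulationParams:
    """Parameters of one neuronal subpopulation.

    Parameters
    ----------
    gain : float
        Synaptic gain of the PSP kernel fed by this subpopulation (mV).
    w1, w2 : float
        Rise/decay rate constants of the bi-exponential PSP kernel
        (s^-1), with ``w2 > w1 > 0``.
    e0 : float
        Half-maximum firing rate of the sigmoid (s^-1); rates saturate
        at ``2 * e0``.
    v0 : float
        Sigmoid threshold: membrane potential of half-maximum firing
        (mV).
    r : float
        Sigmoid steepness (mV^-1).
    """

    gain: float
    w1: float
    w2: float
    e0: float
    v0: float
    r: float

    def __post_init__(self) -> None:
        if not (self.w2 > self.w1 > 0):
            raise ValueError(f"require w2 > w1 > 0, got w1={self.w1}, w2={self.w2}")
        if self.e0 <= 0 or self.r <= 0:
            raise ValueError("e0 and r must be positive")


@dataclass(frozen=True)
class Connectivity:
    """Average numbers of synaptic contacts between subpopulations.

    ``C_XY`` couples the output of subpopulation X into the membrane
    potential of subpopulation Y (e.g. ``C_PI`` is pyramidal excitation
    of fast interneurons).
    """

    C_PP: float = 55.0
    C_PI: float = 80.0
    C_PIs: float = 90.0
    C_IP: float = 20.0
    C_II: float = 15.0
    C_IsP: float = 25.0
    C_IsI: float = 20.0
    C_IsIs: float = 40.0

    def __post_init__(self) -> None:
        for name in ("C_PP", "C_PI", "C_PIs", "C_IP", "C_II", "C_IsP", "C_IsI", "C_IsIs"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


KernelNorm = Literal["scaled_dc", "biexp", "unit_dc"]

#: Reference synaptic rate (s^-1) for the ``"scaled_dc"`` kernel convention.
W_REF = 400.0


@dataclass(frozen=True)
class PopulationParams:
    """Full parameter set of a single neuronal population.

    ``tcs_gain`` gives the per-subpopulation susceptibility to the
    stimulation-induced membrane offset, ordered (P, I, I'); the default
    (1, 0, 0) applies the field to pyramidal cells only.

    ``kernel_norm`` selects the PSP kernel scaling convention.  The
    default ``"scaled_dc"`` uses unit-integral bi-exponential kernels
    with the synaptic gain read per a common reference rate
    ``w_ref`` = 400 s^-1, i.e. h(t) has DC gain ``gain / w_ref``
    (seconds):

        h(t) = gain * w1 w2 / (w_ref (w2 - w1)) * (e^{-w1 t} - e^{-w2 t})

    Under this convention the default synaptic gains and connectivity
    constants produce millivolt-scale potentials with both the fast and
    slow inhibitory feedback loops active, which is what places the
    population's oscillation in the alpha band.  ``"unit_dc"``
    normalizes the kernel integral to ``gain`` exactly and ``"biexp"``
    drops the prefactor altogether; both are kept for sensitivity
    studies.
    """

    P: SubpopulationParams
    I: SubpopulationParams  # noqa: E741 - field name follows the model
    Iprime: SubpopulationParams
    C: Connectivity = field(default_factory=Connectivity)
    tcs_gain: tuple[float, float, float] = (1.0, 0.0, 0.0)
    kernel_norm: KernelNorm = "scaled_dc"
    w_ref: float = W_REF


def alpha_population_params() -> PopulationParams:
    """Parameter set tuned for ~10 Hz alpha-like activity.

    Synaptic gains A=5.5, B=8, G=10 mV; PSP rate constants
    (a1,a2)=(40,80), (b1,b2)=(20,60), (g1,g2)=(150,200) s^-1;
    sigmoid e0=10 s^-1, r=0.7 mV^-1, thresholds v0_P=1 mV and
    v0_I=v0_I'=4 mV; connectivity constants as in :class:`Connectivity`.
    """
    return PopulationParams(
        P=SubpopulationParams(gain=5.5, w1=40.0, w2=80.0, e0=10.0, v0=1.0, r=0.7),
        I=SubpopulationParams(gain=10.0, w1=150.0, w2=200.0, e0=10.0, v0=4.0, r=0.7),
        Iprime=SubpopulationParams(gain=8.0, w1=20.0, w2=60.0, e0=10.0, v0=4.0, r=0.7),
    )


@dataclass(frozen=True)
class TrapezoidDrive:
    """Periodic trapezoid input rate to the subcortical pacemaker.

    One period consists of a linear ramp up (``ramp_up`` s), a plateau
    at ``amplitude`` (``plateau`` s), a linear ramp down (``ramp_down``
    s) and zero for the remainder of ``period``.
    """

    period: float = 2.5
    ramp_up: float = 0.6
    plateau: float = 0.5
    ramp_down: float = 0.6
    amplitude: float = 250.0

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise ValueError("period must be positive")
        if min(self.ramp_up, self.plateau, self.ramp_down) < 0:
            raise ValueError("trapezoid segments must be non-negative")
        if self.ramp_up + self.plateau + self.ramp_down > self.period:
            raise ValueError("trapezoid segments exceed the period")


@dataclass(frozen=True)
class NoiseSpec:
    """Gaussian input firing rate (s^-1) delivered to every population.

    The rate is drawn independently per population and integration step
    and held over the step.  ``sd`` is defined as the per-step standard
    deviation at the reference step ``dt_ref``; at other step sizes the
    per-step draw is scaled by sqrt(dt_ref / dt) so that the
    continuous-time noise intensity is independent of ``dt``.
    """

    mean: float = 212.0
    sd: float = 30.0
    dt_ref: float = 1.0 / 512.0

    def __post_init__(self) -> None:
        if self.sd < 0 or self.dt_ref <= 0:
            raise ValueError("noise sd must be non-negative and dt_ref positive")

    def step_sd(self, dt: float) -> float:
        return self.sd * math.sqrt(self.dt_ref / dt)


@dataclass(frozen=True)
class NetworkConfig:
    """Configuration of the coupled population network.

    Parameters
    ----------
    n_cortical : int
        Number of cortical populations (the subcortical pacemaker is
        added on top of these).
    subcortical_gain : float
        Synaptic weight from the subcortical pyramidal firing rate into
        the excitatory input of each cortical population
        (dimensionless, same convention as the ``C`` constants).
    drive : TrapezoidDrive
        Slow periodic input to the subcortical population.
    noise : NoiseSpec
        Stochastic input rate statistics.
    dt : float
        Integration step (s).
    duration : float
        Length of the retained output (s), after transient discard.
    transient : float
        Initial stretch discarded from the output (s).
    """

    n_cortical: int = 66
    subcortical_gain: float = 16.0
    drive: TrapezoidDrive = field(default_factory=TrapezoidDrive)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    dt: float = 1.0 / 512.0
    duration: float = 30.0
    transient: float = 2.0

    def __post_init__(self) -> None:
        if self.n_cortical < 1:
            raise ValueError("need at least one cortical population")
        if self.dt <= 0 or self.duration <= 0 or self.transient < 0:
            raise ValueError("dt and duration must be positive, transient >= 0")


@dataclass(frozen=True)
class StimulusSpec:
    """Membrane-potential perturbation applied to pyramidal cells.

    ``offsets`` holds the per-region amplitude Delta_k (mV), one entry
    per cortical population; mode ``"dc"`` applies it as a constant,
    ``"sinusoid"`` as Delta_k * sin(2 pi f t) and ``"none"`` disables
    stimulation regardless of the offsets.
    """

    mode: Literal["none", "dc", "sinusoid"] = "none"
    frequency: float = 10.0
    offsets: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.mode == "sinusoid" and self.frequency <= 0:
            raise ValueError("sinusoid mode requires a positive frequency")
        if self.mode != "none" and self.offsets is None:
            raise ValueError(f"mode {self.mode!r} requires offsets")


@dataclass
class SimulationResult:
    """Output of a network simulation.

    ``S`` is the (n_cortical, n_samples) matrix of per-region LFP-like
    time courses (mV); ``subcortical_trace`` the pacemaker's own output;
    ``fs`` the sampling rate (Hz).
    """

    S: np.ndarray
    subcortical_trace: np.ndarray
    fs: float
    seed: int

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.S.shape[1]) / self.fs


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------


def sigmoid_rate(v, sub: SubpopulationParams):
    """Wilson-Cowan wave-to-pulse sigmoid.

    S(v) = 2 e0 / (1 + exp(r (v0 - v))), monotone increasing and
    bounded in (0, 2 e0).  ``v`` may be a scalar or array (mV); the
    result is a firing rate (s^-1).
    """
    return 2.0 * sub.e0 / (1.0 + np.exp(sub.r * (sub.v0 - np.asarray(v, dtype=float))))


def _kernel_input_coeff(gain: float, w1: float, w2: float, norm: KernelNorm,
                        w_ref: float = W_REF) -> float:
    # coefficient k in   y'' = k u - (w1+w2) y' - w1 w2 y
    if norm == "scaled_dc":
        return gain * w1 * w2 / w_ref
    if norm == "biexp":
        return gain * (w2 - w1)
    if norm == "unit_dc":
        return gain * w1 * w2
    raise ValueError(f"unknown kernel normalization {norm!r}")


def psp_impulse_response(t, gain: float, w1: float, w2: float,
                         norm: KernelNorm = "scaled_dc", w_ref: float = W_REF):
    """Bi-exponential post-synaptic potential kernel h(t).

    All conventions share the shape e^{-w1 t} - e^{-w2 t} (zero at
    t = 0, peak at t* = ln(w2/w1)/(w2 - w1)) and differ only in the
    prefactor: ``"scaled_dc"`` (default) uses
    gain * w1 w2 / (w_ref (w2 - w1)), ``"unit_dc"`` uses
    gain * w1 w2 / (w2 - w1) (kernel integral = gain, recovering
    gain * a^2 t e^{-a t} in the equal-rate limit), and ``"biexp"``
    uses the bare ``gain``.  Negative times return 0.
    """
    if not w2 > w1 > 0:
        raise ValueError(f"require w2 > w1 > 0, got w1={w1}, w2={w2}")
    t = np.asarray(t, dtype=float)
    h = np.where(t >= 0, np.exp(-w1 * np.clip(t, 0, None)) - np.exp(-w2 * np.clip(t, 0, None)), 0.0)
    return _kernel_input_coeff(gain, w1, w2, norm, w_ref) / (w2 - w1) * h


def trapezoid_drive(t, drive: TrapezoidDrive):
    """Evaluate the periodic trapezoid waveform at time(s) ``t`` (s)."""
    t = np.asarray(t, dtype=float)
    tau = np.mod(t, drive.period)
    up, flat, down = drive.ramp_up, drive.plateau, drive.ramp_down
    out = np.zeros_like(tau)
    if up > 0:
        rising = tau < up
        out = np.where(rising, tau / up, out)
    on_plateau = (tau >= up) & (tau < up + flat)
    out = np.where(on_plateau, 1.0, out)
    if down > 0:
        falling = (tau >= up + flat) & (tau < up + flat + down)
        out = np.where(falling, 1.0 - (tau - up - flat) / down, out)
    return drive.amplitude * out


def tcs_offset(t, stim: StimulusSpec, region: int):
    """Membrane offset (mV) applied to region ``region`` at time(s) ``t``.

    The returned value is the perturbation of the pyramidal membrane
    potential before the sigmoid; interneurons receive it scaled by
    their ``tcs_gain`` entries (0 by default).
    """
    t = np.asarray(t, dtype=float)
    if stim.mode == "none":
        return np.zeros_like(t)
    offsets = np.asarray(stim.offsets, dtype=float)
    if region < 0 or region >= offsets.size:
        raise IndexError(f"region {region} outside 0..{offsets.size - 1}")
    if stim.mode == "dc":
        return np.full_like(t, offsets[region])
    return offsets[region] * np.sin(2.0 * math.pi * stim.frequency * t)


# ---------------------------------------------------------------------------
# network integration
# ---------------------------------------------------------------------------

_CHUNK = 2048  # steps per noise block; stream order is per trial, so the
               # chunk size does not affect results


def _filter_propagator(w1: float, w2: float, dt: float) -> tuple[float, ...]:
    """Exact one-step propagator of y'' = -(w1+w2) y' - w1 w2 y.

    The state (y, y') evolves as x(t+dt) = E (x(t) - x_ss) + x_ss for a
    zero-order-hold input with steady state x_ss = (DC * u, 0).  With
    eigenvalues -w1, -w2 the matrix exponential E is closed-form.
    """
    e1, e2 = math.exp(-w1 * dt), math.exp(-w2 * dt)
    d = w2 - w1
    return ((w2 * e1 - w1 * e2) / d, (e1 - e2) / d,
            -w1 * w2 * (e1 - e2) / d, (w2 * e2 - w1 * e1) / d)


def _filter_step(E, y, z, y_ss):
    """Advance a bank of second-order filters one step (ZOH input).

    ``y_ss`` is the per-filter steady-state output DC * u for the input
    held over the step.
    """
    e11, e12, e21, e22 = E
    dy = y - y_ss
    return e11 * dy + e12 * z + y_ss, e21 * dy + e22 * z


def _stim_wave(stim: StimulusSpec, t: np.ndarray) -> np.ndarray:
    """Unit stimulation waveform (multiplies the per-region offsets)."""
    if stim.mode == "none":
        return np.zeros_like(t)
    if stim.mode == "dc":
        return np.ones_like(t)
    return np.sin(2.0 * math.pi * stim.frequency * t)


def _subcortical_reference_rate(pop: PopulationParams, net: NetworkConfig) -> float:
    """Tonic pyramidal rate of the driven, noise-free pacemaker.

    The subcortical population is integrated deterministically (noise at
    its mean, trapezoid drive on) and the post-transient pyramidal rate
    is averaged over full drive periods.  The cortico-petal projection
    conveys fluctuations about this tonic rate, so the cortical
    operating point is independent of the coupling gain.
    """
    P, I, Ip, C = pop.P, pop.I, pop.Iprime, pop.C
    dt = net.dt
    exp_e = _filter_propagator(P.w1, P.w2, dt)
    exp_i = _filter_propagator(I.w1, I.w2, dt)
    exp_s = _filter_propagator(Ip.w1, Ip.w2, dt)
    k_e = _kernel_input_coeff(P.gain, P.w1, P.w2, pop.kernel_norm, pop.w_ref)
    k_i = _kernel_input_coeff(I.gain, I.w1, I.w2, pop.kernel_norm, pop.w_ref)
    k_s = _kernel_input_coeff(Ip.gain, Ip.w1, Ip.w2, pop.kernel_norm, pop.w_ref)
    dc_e, dc_i, dc_s = k_e / (P.w1 * P.w2), k_i / (I.w1 * I.w2), k_s / (Ip.w1 * Ip.w2)
    n_trans = int(round(2.0 / dt))
    n_avg = int(round(4 * net.drive.period / dt))
    t_grid = np.arange(n_trans + n_avg) * dt
    drive = trapezoid_drive(t_grid, net.drive)
    y_e = z_e = y_n = z_n = y_i = z_i = y_s = z_s = 0.0
    acc = 0.0
    for t_idx in range(n_trans + n_avg):
        v_p = C.C_PP * y_e + y_n - C.C_IP * y_i - C.C_IsP * y_s
        v_i = C.C_PI * y_e - C.C_II * y_i - C.C_IsI * y_s
        v_is = C.C_PIs * y_e - C.C_IsIs * y_s
        r_p = 2.0 * P.e0 / (1.0 + math.exp(min(max(P.r * (P.v0 - v_p), -60), 60)))
        r_i = 2.0 * I.e0 / (1.0 + math.exp(min(max(I.r * (I.v0 - v_i), -60), 60)))
        r_is = 2.0 * Ip.e0 / (1.0 + math.exp(min(max(Ip.r * (Ip.v0 - v_is), -60), 60)))
        u_n = net.noise.mean + drive[t_idx]
        y_e, z_e = _filter_step(exp_e, y_e, z_e, dc_e * r_p)
        y_n, z_n = _filter_step(exp_e, y_n, z_n, dc_e * u_n)
        y_i, z_i = _filter_step(exp_i, y_i, z_i, dc_i * r_i)
        y_s, z_s = _filter_step(exp_s, y_s, z_s, dc_s * r_is)
        if t_idx >= n_trans:
            acc += r_p
    return acc / n_avg


def _simulate_batch(pop: PopulationParams, net: NetworkConfig, stim: StimulusSpec,
                    seeds: Sequence[int]) -> tuple[np.ndarray, np.ndarray]:
    """Integrate a batch of independent trials in lock-step.

    Returns (S, sub) with shapes (B, n_cortical, T) and (B, T).  Trial b
    is bit-identical to a single run with ``seeds[b]``: each trial owns
    its own PCG64 stream, consumed in step order.
    """
    n_c = net.n_cortical
    n = n_c + 1  # subcortical population appended last
    dt = net.dt
    n_trans = int(round(net.transient / dt))
    n_keep = int(round(net.duration / dt))
    n_steps = n_trans + n_keep
    B = len(seeds)

    P, I, Ip, C = pop.P, pop.I, pop.Iprime, pop.C
    k_e = _kernel_input_coeff(P.gain, P.w1, P.w2, pop.kernel_norm, pop.w_ref)
    k_i = _kernel_input_coeff(I.gain, I.w1, I.w2, pop.kernel_norm, pop.w_ref)
    k_s = _kernel_input_coeff(Ip.gain, Ip.w1, Ip.w2, pop.kernel_norm, pop.w_ref)
    # exact exponential propagator of each linear second-order filter
    # over one step (zero-order hold on the input)
    exp_e = _filter_propagator(P.w1, P.w2, dt)
    exp_i = _filter_propagator(I.w1, I.w2, dt)
    exp_s = _filter_propagator(Ip.w1, Ip.w2, dt)
    dc_e, dc_i, dc_s = k_e / (P.w1 * P.w2), k_i / (I.w1 * I.w2), k_s / (Ip.w1 * Ip.w2)
    gP, gI, gIs = pop.tcs_gain

    offsets = np.zeros(n)
    if stim.mode != "none":
        off = np.asarray(stim.offsets, dtype=float)
        if off.shape != (n_c,):
            raise ValueError(f"stimulus offsets must have length {n_c}, got {off.shape}")
        offsets[:n_c] = off

    # filter states: (value, derivative) per synapse-type filter, per trial & population
    y_e = np.zeros((B, n)); z_e = np.zeros((B, n))   # recurrent pyramidal EPSP
    y_n = np.zeros((B, n)); z_n = np.zeros((B, n))   # external/noise EPSP
    y_i = np.zeros((B, n)); z_i = np.zeros((B, n))   # fast IPSP
    y_s = np.zeros((B, n)); z_s = np.zeros((B, n))   # slow IPSP

    rngs = [np.random.default_rng(int(s)) for s in seeds]
    t_grid = np.arange(n_steps) * dt
    wave = _stim_wave(stim, t_grid)
    drive = trapezoid_drive(t_grid, net.drive)
    noise_mean, noise_sd = net.noise.mean, net.noise.step_sd(dt)
    # phasic cortico-petal coupling: fluctuations about the tonic rate
    r_sub_ref = (_subcortical_reference_rate(pop, net)
                 if net.subcortical_gain != 0.0 else 0.0)

    S = np.empty((B, n_c, n_keep))
    sub = np.empty((B, n_keep))

    step = 0
    while step < n_steps:
        m = min(_CHUNK, n_steps - step)
        if noise_sd > 0:
            noise = np.stack([rng.normal(noise_mean, noise_sd, (m, n)) for rng in rngs], axis=1)
        else:
            noise = np.full((m, B, n), noise_mean)
        for j in range(m):
            t_idx = step + j
            v_p = C.C_PP * y_e + y_n - C.C_IP * y_i - C.C_IsP * y_s
            v_i = C.C_PI * y_e - C.C_II * y_i - C.C_IsI * y_s
            v_is = C.C_PIs * y_e - C.C_IsIs * y_s

            d = offsets * wave[t_idx]  # (n,), 0 at the subcortical slot
            # exponent clipped: saturated rates are exact at double precision
            r_p = 2.0 * P.e0 / (1.0 + np.exp(np.clip(P.r * (P.v0 - (v_p + gP * d)), -60, 60)))
            r_i = 2.0 * I.e0 / (1.0 + np.exp(np.clip(I.r * (I.v0 - (v_i + gI * d)), -60, 60)))
            r_is = 2.0 * Ip.e0 / (1.0 + np.exp(np.clip(Ip.r * (Ip.v0 - (v_is + gIs * d)), -60, 60)))

            u_n = noise[j].copy()
            u_n[:, n_c] += drive[t_idx]                       # pacemaker drive
            u_n[:, :n_c] += net.subcortical_gain * (r_p[:, n_c:n_c + 1] - r_sub_ref)

            y_e, z_e = _filter_step(exp_e, y_e, z_e, dc_e * r_p)
            y_n, z_n = _filter_step(exp_e, y_n, z_n, dc_e * u_n)
            y_i, z_i = _filter_step(exp_i, y_i, z_i, dc_i * r_i)
            y_s, z_s = _filter_step(exp_s, y_s, z_s, dc_s * r_is)

            if t_idx >= n_trans:
                k = t_idx - n_trans
                S[:, :, k] = v_p[:, :n_c]
                sub[:, k] = v_p[:, n_c]
        vmax = max(float(np.max(np.abs(v))) for v in (v_p, v_i, v_is))
        if not np.isfinite(vmax) or vmax > 1e3:
            raise InstabilityError(
                f"membrane potential reached {vmax:.3g} mV (> 1000 mV) at "
                f"t={t_idx * dt:.3f} s; integration step dt={dt:g} s is too "
                f"large or parameters are unstable")
        step += m
    return S, sub


def simulate_network(pop: PopulationParams, net: NetworkConfig, stim: StimulusSpec,
                     seed: int) -> SimulationResult:
    """Simulate the coupled 66+1 population network.

    Fixed-step stochastic integration: the Gaussian input rates are
    held constant over each step (dt = 1/512 s by default) while the
    linear PSP filters are advanced with their exact exponential
    propagator, so the integration error comes only from the
    zero-order hold on the sigmoid outputs and inputs.

    Cortical populations receive recurrent excitation (C_PP), fast and
    slow inhibition (C_IP, C_I'P), independent Gaussian input rates, the
    subcortical pyramidal rate through the excitatory kernel and the tCS
    membrane offset on pyramidal cells.  The subcortical population
    receives the trapezoid drive instead of the tCS offset.  With
    ``n_cortical=1`` and ``subcortical_gain=0`` this reduces to a single
    isolated population.

    The first ``net.transient`` seconds are discarded.  Identical seeds
    give bit-identical results.
    """
    S, sub = _simulate_batch(pop, net, stim, [seed])
    return SimulationResult(S=S[0], subcortical_trace=sub[0], fs=1.0 / net.dt, seed=int(seed))


def simulate_trials(pop: PopulationParams, net: NetworkConfig, stim: StimulusSpec,
                    seeds: Sequence[int]) -> list[SimulationResult]:
    """Simulate independent trials (vectorized across trials).

    Equivalent to ``[simulate_network(..., s) for s in seeds]`` but
    integrates all trials in lock-step for speed.
    """
    S, sub = _simulate_batch(pop, net, stim, list(seeds))
    fs = 1.0 / net.dt
    return [SimulationResult(S=S[b], subcortical_trace=sub[b], fs=fs, seed=int(s))
            for b, s in enumerate(seeds)]


def export_result(result: SimulationResult, path, metadata_path=None) -> None:
    """Write a simulation as a delimited matrix (samples x regions).

    A sidecar metadata file records the sampling rate and seed.
    """
    np.savetxt(path, result.S.T, delimiter="\t")
    if metadata_path is not None:
        with open(metadata_path, "w") as fh:
            fh.write(f"fs\t{result.fs}\nseed\t{result.seed}\n"
                     f"n_regions\t{result.S.shape[0]}\nn_samples\t{result.S.shape[1]}\n")
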