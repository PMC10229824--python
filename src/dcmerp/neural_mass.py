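"""Two-source neural-mass forward model for tone-offset evoked potentials.

Each source (MCN, vlPAG) is a three-population network (output,
excitatory interneuron, inhibitory interneuron).  Every population owns
two receptor channels (excitatory / inhibitory), each realizing the
alpha-form synaptic convolution kernel

    p(t) = A * (H / tau) * t * exp(-t / tau)

as a critically damped second-order system driven by the delayed,
gain-weighted sigmoid firing rates of presynaptic populations plus
exogenous Gaussian-bump input.  The observed LFP of a source is a scalar
gain times the composite membrane potential of its output population.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import expm

__all__ = [
    "SynapticKernel",
    "SigmoidSpec",
    "Population",
    "IntrinsicConnection",
    "SourceArchitecture",
    "ExtrinsicConnection",
    "ModelVariant",
    "InputSpec",
    "SimulationGrid",
    "EvokedResponse",
    "SimulationError",
    "sigmoid_rate",
    "kernel_value",
    "channel_response",
    "channel_impulse_response",
    "exogenous_input",
    "default_source",
    "build_model_space",
    "CompiledVariant",
    "simulate_erp",
]

#: conduction delay between populations of the same source, ms
INTRINSIC_DELAY_MS = 2.0
#: conduction delay between the two sources (either direction), ms
EXTRINSIC_DELAY_MS = 16.0

#: fixed normalization of extrinsic drive so that unit prior rates yield a
#: stable coupled system (the printed rates 1, 1/2, 1/8 are relative)
EXTRINSIC_SCALE = 0.15

_ROLES = ("output", "excitatory_interneuron", "inhibitory_interneuron")


class SimulationError(RuntimeError):
    """Raised when the forward simulation produces non-finite state."""


class ConfigurationError(ValueError):
    """Raised for invalid model/architecture configuration."""


# ---------------------------------------------------------------------------
# primitive components


@dataclass(frozen=True)
class SynapticKernel:
    """Alpha-kernel parameters of one receptor channel."""

    H: float  # maximum post-synaptic potential, mV
    tau: float  # time constant, ms
    polarity: str = "excitatory"

    def __post_init__(self):
        if self.H <= 0 or self.tau <= 0:
            raise ConfigurationError("SynapticKernel requires H > 0 and tau > 0")
        if self.polarity not in ("excitatory", "inhibitory"):
            raise ConfigurationError(f"unknown polarity {self.polarity!r}")


#: default receptor kernels (AMPA-like 8 ms, GABAa-like 16 ms)
DEFAULT_EXC_KERNEL = SynapticKernel(H=4.0, tau=8.0, polarity="excitatory")
DEFAULT_INH_KERNEL = SynapticKernel(H=16.0, tau=16.0, polarity="inhibitory")


@dataclass(frozen=True)
class SigmoidSpec:
    """Curvature of the membrane-potential-to-rate sigmoid."""

    r: float = 0.56

    def __post_init__(self):
        if self.r <= 0:
            raise ConfigurationError("sigmoid curvature r must be > 0")


def sigmoid_rate(V, spec: SigmoidSpec = SigmoidSpec()):
    """Normalized firing rate S(V) = 1/(1+exp(-rV)) - 1/2, in (-1/2, 1/2)."""
    return 1.0 / (1.0 + np.exp(-spec.r * np.asarray(V, dtype=float))) - 0.5


def kernel_value(t, k: SynapticKernel, A: float = 1.0):
    """Closed-form alpha kernel p(t) = A*(H/tau)*t*exp(-t/tau) for t >= 0."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("kernel_value requires t >= 0")
    return A * (k.H / k.tau) * t * np.exp(-t / k.tau)


# ---------------------------------------------------------------------------
# architecture


@dataclass(frozen=True)
class Population:
    label: str
    role: str  # output | excitatory_interneuron | inhibitory_interneuron

    def __post_init__(self):
        if self.role not in _ROLES:
            raise ConfigurationError(f"unknown population role {self.role!r}")


@dataclass(frozen=True)
class IntrinsicConnection:
    from_pop: str
    to_pop: str
    polarity: str  # excitatory | inhibitory
    gain: float
    delay: float = INTRINSIC_DELAY_MS


@dataclass(frozen=True)
class SourceArchitecture:
    """One source: populations plus intrinsic wiring."""

    name: str
    populations: tuple[Population, ...]
    intrinsic_connections: tuple[IntrinsicConnection, ...]
    ii_self: bool = False
    exc_kernel: SynapticKernel = DEFAULT_EXC_KERNEL
    inh_kernel: SynapticKernel = DEFAULT_INH_KERNEL

    def __post_init__(self):
        labels = [p.label for p in self.populations]
        if len(set(labels)) != len(labels):
            raise ConfigurationError("duplicate population labels")
        n_out = sum(p.role == "output" for p in self.populations)
        if n_out != 1:
            raise ConfigurationError("exactly one output population required")
        roles = {p.label: p.role for p in self.populations}
        for c in self.intrinsic_connections:
            if c.from_pop not in roles or c.to_pop not in roles:
                raise ConfigurationError(
                    f"connection references unknown population: {c.from_pop}->{c.to_pop}"
                )
            if c.polarity == "inhibitory" and roles[c.from_pop] != "inhibitory_interneuron":
                raise ConfigurationError(
                    "inhibitory connections must originate from the inhibitory population"
                )

    @property
    def output_population(self) -> str:
        return next(p.label for p in self.populations if p.role == "output")


def default_source(name: str, ii_self: bool = False) -> SourceArchitecture:
    """Canonical three-population source used for both regions.

    The excitatory interneuron relays input to the output population,
    which reciprocally drives both interneuron classes; the inhibitory
    interneuron feeds back onto the output population.  ``ii_self`` adds
    the optional inhibitory self-connection.
    """
    pops = (
        Population("output", "output"),
        Population("exc_int", "excitatory_interneuron"),
        Population("inh_int", "inhibitory_interneuron"),
    )
    conns = [
        IntrinsicConnection("exc_int", "output", "excitatory", 0.25),
        IntrinsicConnection("output", "exc_int", "excitatory", 0.10),
        IntrinsicConnection("output", "inh_int", "excitatory", 0.40),
        IntrinsicConnection("inh_int", "output", "inhibitory", 0.10),
    ]
    if ii_self:
        conns.append(IntrinsicConnection("inh_int", "inh_int", "inhibitory", 0.05))
    return SourceArchitecture(name=name, populations=pops,
                              intrinsic_connections=tuple(conns), ii_self=ii_self)


@dataclass(frozen=True)
class ExtrinsicConnection:
    """Delayed excitatory projection between sources.

    One free log-scaling parameter (named ``param``) governs the whole
    connection; each target population receives base rate ``prior_rate``
    times the fixed extrinsic normalization.
    """

    from_source: str
    to_source: str
    target_populations: tuple[str, ...]
    prior_rate: float
    param: str
    delay: float = EXTRINSIC_DELAY_MS

    def __post_init__(self):
        if self.prior_rate < 0:
            raise ConfigurationError("prior_rate must be >= 0")
        if self.delay <= 0:
            raise ConfigurationError("extrinsic delay must be > 0")


@dataclass(frozen=True)
class InputSpec:
    """Exogenous drive: Gaussian bumps delivered to both sources."""

    onsets: tuple[float, ...] = (10.0, 40.0)
    dispersions: tuple[float, ...] = (8.0, 8.0)
    amplitudes: tuple[float, ...] = (0.3, 0.3)

    def __post_init__(self):
        if len(self.onsets) != len(self.dispersions) or len(self.onsets) != len(self.amplitudes):
            raise ConfigurationError("onsets, dispersions, amplitudes must align")
        if any(d <= 0 for d in self.dispersions):
            raise ConfigurationError("dispersions must be > 0")


def exogenous_input(t, spec: InputSpec):
    """Sum of Gaussian bumps at the component onsets."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    for a, mu, sd in zip(spec.amplitudes, spec.onsets, spec.dispersions):
        out += a * np.exp(-0.5 * ((t - mu) / sd) ** 2)
    return out


@dataclass(frozen=True)
class SimulationGrid:
    window: tuple[float, float] = (1.0, 200.0)
    dt: float = 0.1  # integration step, ms
    output_rate: float = 1000.0  # Hz

    def __post_init__(self):
        if self.dt > 1.0:
            raise ConfigurationError("integration step must be <= 1 ms")
        lo, hi = self.window
        if not 0 < lo < hi:
            raise ConfigurationError("window must satisfy 0 < start < end")

    @property
    def output_times(self) -> np.ndarray:
        """Output sample times in ms (1 kHz grid inside the window)."""
        step = 1000.0 / self.output_rate
        return np.arange(self.window[0], self.window[1] + 0.5 * step, step)


@dataclass(frozen=True)
class ModelVariant:
    """One connectivity hypothesis: shared sources + an extrinsic set."""

    id: str
    sources: tuple[SourceArchitecture, SourceArchitecture]
    extrinsic: tuple[ExtrinsicConnection, ...]
    input: InputSpec = InputSpec()

    def __post_init__(self):
        names = {s.name for s in self.sources}
        for c in self.extrinsic:
            if c.from_source not in names or c.to_source not in names:
                raise ConfigurationError(f"extrinsic connection references unknown source: {c}")


def build_model_space(ii_self: bool = False,
                      m4_bidirectional_all: bool = True) -> list[ModelVariant]:
    """The five competing connectivity hypotheses.

    M1: vlPAG->MCN "IO"-type projection plus MCN->vlPAG onto the
    glutamatergic output population (rates 1).  M2: MCN->vlPAG onto the
    glutamatergic and GABAergic populations (rates 1/2).  M3: MCN->vlPAG
    onto all populations (rates 1/8).  M4: "all" targeting; with
    ``m4_bidirectional_all`` the vlPAG->MCN direction is also "all".
    M5: null model with no extrinsic connections.
    """
    mcn = default_source("MCN", ii_self=ii_self)
    pag = default_source("vlPAG", ii_self=ii_self)
    sources = (mcn, pag)
    io_proj = ExtrinsicConnection("vlPAG", "MCN", ("exc_int",), 1.0, "A_vlPAG_to_MCN")
    all_pops = ("output", "exc_int", "inh_int")

    def fwd(targets, rate):
        return ExtrinsicConnection("MCN", "vlPAG", targets, rate, "A_MCN_to_vlPAG")

    m1 = ModelVariant("M1", sources, (io_proj, fwd(("output",), 1.0)))
    m2 = ModelVariant("M2", sources, (io_proj, fwd(("output", "inh_int"), 0.5)))
    m3 = ModelVariant("M3", sources, (io_proj, fwd(all_pops, 0.125)))
    if m4_bidirectional_all:
        back_all = ExtrinsicConnection("vlPAG", "MCN", all_pops, 0.125, "A_vlPAG_to_MCN")
        m4 = ModelVariant("M4", sources, (back_all, fwd(all_pops, 0.125)))
    else:
        m4 = ModelVariant("M4", sources, (io_proj, fwd(all_pops, 0.125)))
    m5 = ModelVariant("M5", sources, ())
    return [m1, m2, m3, m4, m5]


# ---------------------------------------------------------------------------
# observation container


@dataclass
class EvokedResponse:
    """Per-region trial-averaged waveform on a fixed post-offset grid."""

    region: str
    time_ms: np.ndarray
    amplitude: np.ndarray
    n_trials: int = 1
    channel_id: int | None = None

    def __post_init__(self):
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        if self.time_ms.shape != self.amplitude.shape:
            raise ValueError("time and amplitude grids differ in shape")

    def peak_to_trough(self) -> float:
        return float(self.amplitude.max() - self.amplitude.min())


# ---------------------------------------------------------------------------
# discretization of one receptor channel (exact for piecewise-linear input)


def _channel_discretization(H: float, tau: float, dt: float):
    """First-order-hold matrices for Vdd = (H/tau) u - (2/tau) Vd - V/tau^2."""
    A = np.array([[0.0, 1.0], [-1.0 / tau**2, -2.0 / tau]])
    B = np.array([[0.0], [H / tau]])
    M = np.zeros((4, 4))
    M[:2, :2] = A
    M[:2, 2:3] = B
    M[2, 3] = 1.0
    Phi = expm(M * dt)
    Ad = Phi[:2, :2]
    G1 = Phi[:2, 2]  # integral of e^{A(dt-s)} B ds
    G2 = Phi[:2, 3]  # integral of e^{A(dt-s)} B s ds
    B0 = G1 - G2 / dt  # weight on u_k
    B1 = G2 / dt  # weight on u_{k+1}
    return Ad, B0, B1


def channel_impulse_response(n_samples: int, H: float, tau: float, dt: float) -> np.ndarray:
    """Channel output after a unit-area impulse at t = 0.

    The impulse instantaneously sets dV/dt = H/tau; the state is then
    propagated homogeneously, so the result is exact up to rounding and
    must match :func:`kernel_value` on the same grid.
    """
    Ad, _, _ = _channel_discretization(H, tau, dt)
    x = np.array([0.0, H / tau])
    V = np.empty(n_samples)
    for k in range(n_samples):
        V[k] = x[0]
        x = Ad @ x
    return V


def channel_response(u: np.ndarray, H: float, tau: float, dt: float) -> np.ndarray:
    """Integrate one receptor channel driven by sampled input ``u``.

    Exact for piecewise-linear ``u``; the impulse response (unit-area
    pulse at t=0) reproduces :func:`kernel_value` up to sampling of the
    input waveform.
    """
    u = np.asarray(u, dtype=float)
    Ad, B0, B1 = _channel_discretization(H, tau, dt)
    x = np.zeros(2)
    V = np.empty_like(u)
    V[0] = 0.0
    for k in range(len(u) - 1):
        x = Ad @ x + B0 * u[k] + B1 * u[k + 1]
        V[k + 1] = x[0]
    return V


# ---------------------------------------------------------------------------
# compiled variant: flat arrays for the integrator, cached per variant


from . import _integrate  # noqa: E402  (numba kernel)


class CompiledVariant:
    """Flattened representation of a :class:`ModelVariant` for simulation.

    Caches connection arrays, channel discretizations and unit input
    waveforms so that repeated simulations (as in inversion) only rescale
    gains and call the compiled integrator.
    """

    def __init__(self, variant: ModelVariant, grid: SimulationGrid = SimulationGrid(),
                 sigmoid: SigmoidSpec = SigmoidSpec()):
        self.variant = variant
        self.grid = grid
        self.sigmoid = sigmoid
        self.dt = grid.dt
        self.n_steps = int(round(grid.window[1] / grid.dt))
        self.source_names = [s.name for s in variant.sources]

        # population indexing: source-major
        self.pop_index: dict[tuple[str, str], int] = {}
        pops = []
        for s in variant.sources:
            for p in s.populations:
                self.pop_index[(s.name, p.label)] = len(pops)
                pops.append((s, p))
        self.n_pop = len(pops)

        # per-population channel discretizations (exc=0, inh=1)
        Ad = np.empty((self.n_pop, 2, 2, 2))
        B0 = np.empty((self.n_pop, 2, 2))
        B1 = np.empty((self.n_pop, 2, 2))
        for i, (s, _p) in enumerate(pops):
            for ch, k in enumerate((s.exc_kernel, s.inh_kernel)):
                # inhibitory channels hyperpolarize: their kernel enters with
                # negative sign in the composite membrane potential
                H = k.H if ch == 0 else -k.H
                Ad[i, ch], B0[i, ch], B1[i, ch] = _channel_discretization(H, k.tau, grid.dt)
        self._Ad, self._B0, self._B1 = Ad, B0, B1

        # connections -> flat arrays
        c_from, c_to, c_ch, c_gain, c_delay, c_scale = [], [], [], [], [], []
        for s in variant.sources:
            for c in s.intrinsic_connections:
                c_from.append(self.pop_index[(s.name, c.from_pop)])
                c_to.append(self.pop_index[(s.name, c.to_pop)])
                c_ch.append(0 if c.polarity == "excitatory" else 1)
                c_gain.append(c.gain)
                c_delay.append(c.delay / grid.dt)
                kind = "exc" if c.polarity == "excitatory" else "inh"
                c_scale.append(f"g_{kind}_{s.name}")
        for c in variant.extrinsic:
            src = next(s for s in variant.sources if s.name == c.from_source)
            for tgt in c.target_populations:
                c_from.append(self.pop_index[(c.from_source, src.output_population)])
                c_to.append(self.pop_index[(c.to_source, tgt)])
                c_ch.append(0)  # extrinsic projections are glutamatergic
                c_gain.append(c.prior_rate * EXTRINSIC_SCALE)
                c_delay.append(c.delay / grid.dt)
                c_scale.append(c.param)
        self._c_from = np.asarray(c_from, dtype=np.int64)
        self._c_to = np.asarray(c_to, dtype=np.int64)
        self._c_ch = np.asarray(c_ch, dtype=np.int64)
        self._c_base_gain = np.asarray(c_gain, dtype=float)
        self._c_delay = np.asarray(c_delay, dtype=float)
        self._c_scale = list(c_scale)

        # exogenous input: unit bumps per component, delivered to the
        # excitatory channel of the excitatory-interneuron populations
        t = np.arange(self.n_steps + 1) * grid.dt
        self._unit_bumps = np.stack(
            [np.exp(-0.5 * ((t - mu) / sd) ** 2)
             for mu, sd in zip(variant.input.onsets, variant.input.dispersions)]
        )  # (n_components, n_steps+1)
        self._input_pops = np.asarray(
            [i for i, (_s, p) in enumerate(pops) if p.role == "excitatory_interneuron"],
            dtype=np.int64)
        self._base_amps = np.asarray(variant.input.amplitudes, dtype=float)

        self._output_pops = np.asarray(
            [self.pop_index[(s.name, s.output_population)] for s in variant.sources],
            dtype=np.int64)
        self._out_idx = np.round(grid.output_times / grid.dt).astype(np.int64)

        self.param_names = self._free_parameter_names()

    def _free_parameter_names(self) -> list[str]:
        names = []
        for c in self.variant.extrinsic:
            if c.param not in names:
                names.append(c.param)
        names += [f"input_amp_{i + 1}" for i in range(len(self.variant.input.onsets))]
        names += [f"obs_{s}" for s in self.source_names]
        for s in self.source_names:
            names += [f"g_exc_{s}", f"g_inh_{s}"]
        return names

    def theta_dict(self, theta=None) -> dict[str, float]:
        """Full latent parameter dict (zeros = prior means) updated with theta."""
        d = {n: 0.0 for n in self.param_names}
        if theta is not None:
            for k, v in theta.items():
                if k not in d:
                    raise KeyError(f"unknown parameter {k!r} for variant {self.variant.id}")
                d[k] = float(v)
        return d

    def simulate(self, theta=None, linearize: bool = False) -> np.ndarray:
        """Simulate, returning waveforms (n_sources, n_output_samples)."""
        th = self.theta_dict(theta)
        gains = self._c_base_gain * np.exp([th.get(s, 0.0) for s in self._c_scale])
        amps = self._base_amps * np.exp(
            [th[f"input_amp_{i + 1}"] for i in range(len(self._base_amps))])
        drive = amps @ self._unit_bumps  # (n_steps+1,)
        ex_in = np.zeros((self.n_steps + 1, self.n_pop))
        for p in self._input_pops:
            ex_in[:, p] = drive
        Vhist = _integrate.integrate(
            self.n_steps, self.n_pop, self._Ad, self._B0, self._B1,
            self._c_from, self._c_to, self._c_ch, gains, self._c_delay,
            ex_in, self.sigmoid.r, 1 if linearize else 0)
        if not np.all(np.isfinite(Vhist)):
            bad = max(zip(np.abs(np.exp(list(th.values()))), th.keys()))
            raise SimulationError(
                f"non-finite state in variant {self.variant.id}; "
                f"largest parameter excursion: {bad[1]}={th[bad[1]]:.3f}")
        obs = np.exp([th[f"obs_{s}"] for s in self.source_names])
        return obs[:, None] * Vhist[self._out_idx][:, self._output_pops].T


_COMPILED_CACHE: dict[tuple, CompiledVariant] = {}


def compile_variant(variant: ModelVariant, grid: SimulationGrid = SimulationGrid()) -> CompiledVariant:
    key = (id(variant), grid.window, grid.dt, grid.output_rate)
    cv = _COMPILED_CACHE.get(key)
    if cv is None:
        cv = _COMPILED_CACHE[key] = CompiledVariant(variant, grid)
    return cv


def simulate_erp(variant: ModelVariant, theta=None,
                 grid: SimulationGrid = SimulationGrid(),
                 linearize: bool = False) -> tuple[EvokedResponse, EvokedResponse]:
    """Simulate the evoked response pair for one parameter assignment.

    ``theta`` maps latent parameter names to log-scaling values (0 = prior
    mean); missing entries default to 0.  Returns one
    :class:`EvokedResponse` per source, sampled at the output rate on the
    analysis window.
    """
    cv = compile_variant(variant, grid)
    Y = cv.simulate(theta)
    t = grid.output_times
    return tuple(EvokedResponse(region=name, time_ms=t.copy(), amplitude=Y[i])
                 for i, name in enumerate(cv.source_names))
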