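"""Synthetic single-molecule ligand-binding fluorescence traces.

A tetrameric channel carries four cyclic-nucleotide binding sites. Each site
alternates between unbound sojourns (exponential, concentration dependent) and
bound sojourns (two-component exponential mixture: short- and long-lived bound
conformations). A bound site contributes a fluorescence step whose amplitude is
drawn once per event from a slightly right-skewed near-Gaussian distribution;
within-event frame noise grows linearly with event intensity. The channel trace
is the sum of the four site traces, with baseline noise added only to frames
where all four sites are unbound, so that noise from each bound ligand adds
without quadrupling the baseline noise.

Two generator modes are provided: dwell-mixture sampling (the default, used for
idealization benchmarks) and exact continuous-time Markov-chain simulation from
a kinetic model (used for parameter-recovery tests of the model-fitting stage).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "FRAME_INTERVAL_S",
    "SITE_OCCUPANCY",
    "MOLECULES_PER_CONCENTRATION",
    "DEFAULT_DETECTION_P",
    "SimulationConfig",
    "SiteKinetics",
    "AmplitudeModel",
    "SiteTrace",
    "FluorescenceTrace",
    "TruthRecord",
    "molecule_rng",
    "sample_dwell_mixture",
    "simulate_site_occupancy",
    "render_single_site_trace",
    "compose_tetramer_trace",
    "simulate_molecule",
    "simulate_channel_markov",
    "generate_bleach_counts",
]

#: Camera frame interval: 20 Hz acquisition, 50 ms per frame.
FRAME_INTERVAL_S = 0.05

#: Per-site bound probability at each tested ligand concentration (nM), from
#: binomial fits assuming four identical and independent sites.
SITE_OCCUPANCY = {10: 0.08, 30: 0.10, 60: 0.12, 100: 0.21, 200: 0.26}

#: Number of molecules recorded at each concentration (nM) in the reference
#: data set; used as the default dataset composition.
MOLECULES_PER_CONCENTRATION = {10: 112, 30: 325, 60: 63, 100: 65, 200: 132}

#: Default per-subunit GFP detection probability for bleach-step counting.
DEFAULT_DETECTION_P = 0.82

#: Default bound-dwell mixture: weights and time constants (s). The weighted
#: mean is 0.912 s; the long component is an order of magnitude shorter than
#: the ~23 s mean fluorophore bleach time, so bleaching is ignored.
DEFAULT_BOUND_WEIGHTS = (0.7, 0.3)
DEFAULT_BOUND_TAUS = (0.30, 2.34)


def molecule_rng(seed: int, index: int) -> np.random.Generator:
    """Deterministic per-molecule RNG stream.

    Child streams are keyed on the molecule index so that changing the number
    of molecules never reshuffles the streams of earlier molecules.
    """
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index,)))


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters for one simulated recording batch."""

    frames_per_trace: int
    concentration_nM: float
    frame_interval_s: float = FRAME_INTERVAL_S
    n_sites: int = 4
    n_molecules: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.frames_per_trace < 1:
            raise ValueError("frames_per_trace must be >= 1")

    @property
    def duration_s(self) -> float:
        return self.frames_per_trace * self.frame_interval_s


@dataclass(frozen=True)
class SiteKinetics:
    """Single-site dwell-time law: exponential-mixture bound dwells and a
    single-exponential unbound dwell.

    ``unbound_mean_s`` is the per-site mean; when calibrated from channel-level
    records it is four times the channel-level unbound mean (four sites share
    the unbound time).
    """

    bound_weights: tuple[float, ...] = DEFAULT_BOUND_WEIGHTS
    bound_taus: tuple[float, ...] = DEFAULT_BOUND_TAUS
    unbound_mean_s: float = 2.596

    def __post_init__(self) -> None:
        w = np.asarray(self.bound_weights, dtype=float)
        t = np.asarray(self.bound_taus, dtype=float)
        if w.shape != t.shape:
            raise ValueError("bound_weights and bound_taus must have equal length")
        if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise ValueError("bound_weights must be nonnegative and sum to 1")
        if np.any(t <= 0):
            raise ValueError("bound_taus must be positive")
        if not self.unbound_mean_s > 0:
            raise ValueError("unbound_mean_s must be positive (use np.inf for no binding)")

    @property
    def mean_bound_s(self) -> float:
        return float(np.dot(self.bound_weights, self.bound_taus))

    @property
    def occupancy(self) -> float:
        """Long-run per-site bound probability (renewal-theory fraction)."""
        if np.isinf(self.unbound_mean_s):
            return 0.0
        mb = self.mean_bound_s
        return mb / (mb + self.unbound_mean_s)

    @classmethod
    def for_concentration(cls, concentration_nM: float) -> "SiteKinetics":
        """Default calibration: unbound mean chosen so the per-site occupancy
        equals the binomial-fit value at that concentration."""
        try:
            p = SITE_OCCUPANCY[int(concentration_nM)]
        except KeyError:
            raise ValueError(
                f"no default calibration for {concentration_nM} nM; "
                f"known concentrations: {sorted(SITE_OCCUPANCY)}"
            ) from None
        mb = float(np.dot(DEFAULT_BOUND_WEIGHTS, DEFAULT_BOUND_TAUS))
        return cls(unbound_mean_s=mb * (1.0 - p) / p)


@dataclass(frozen=True)
class AmplitudeModel:
    """Event-amplitude and noise model.

    Each binding event receives one amplitude draw from a skew-normal with the
    given mean / between-event SD / shape (positive shape = slight skew toward
    higher intensities). Within-event frame noise has SD = intercept + slope*I
    (the observed linear intensity/noise correlation); frames with no bound
    ligand receive baseline noise only at the channel level.
    """

    mean_amplitude: float = 1000.0
    between_event_sd: float = 150.0
    skew_shape: float = 3.0
    noise_intercept: float = 50.0
    noise_slope: float = 0.1
    baseline_sd: float = 50.0

    def __post_init__(self) -> None:
        if self.baseline_sd <= 0:
            raise ValueError("baseline_sd must be positive")
        if self.between_event_sd < 0:
            raise ValueError("between_event_sd must be nonnegative")

    def _skewnorm_loc_scale(self) -> tuple[float, float]:
        a = self.skew_shape
        delta = a / np.sqrt(1.0 + a * a)
        scale_factor = np.sqrt(max(1.0 - 2.0 * delta * delta / np.pi, 1e-12))
        omega = self.between_event_sd / scale_factor
        xi = self.mean_amplitude - omega * delta * np.sqrt(2.0 / np.pi)
        return xi, omega

    def sample_amplitudes(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.between_event_sd == 0:
            return np.full(n, self.mean_amplitude)
        xi, omega = self._skewnorm_loc_scale()
        return stats.skewnorm.rvs(
            self.skew_shape, loc=xi, scale=omega, size=n, random_state=rng
        )

    def event_noise_sd(self, intensity: float) -> float:
        sd = self.noise_intercept + self.noise_slope * intensity
        if sd < 0:
            raise ValueError(
                f"event noise SD {sd:.3g} < 0 for intensity {intensity:.3g}"
            )
        return sd


@dataclass
class SiteTrace:
    """Rendered fluorescence of a single site with its ground truth."""

    intensity: np.ndarray
    occupancy: np.ndarray  # bool, per frame
    events: list[tuple[int, int, float]]  # (start_frame, end_frame) half-open, amplitude


@dataclass
class FluorescenceTrace:
    """Uniformly sampled intensity series (arbitrary units)."""

    intensity: np.ndarray
    frame_interval_s: float = FRAME_INTERVAL_S
    concentration_nM: float | None = None
    molecule_id: str | None = None

    @property
    def n_frames(self) -> int:
        return int(self.intensity.size)

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_s


@dataclass
class TruthRecord:
    """Ground truth for one simulated molecule.

    ``events`` holds (site, start_frame, end_frame, amplitude) with half-open
    frame intervals; channel counts are the per-frame sum of site occupancies.
    """

    site_occupancy: np.ndarray  # (n_sites, n_frames) bool
    events: list[tuple[int, int, int, float]] = field(default_factory=list)

    @property
    def channel_counts(self) -> np.ndarray:
        return self.site_occupancy.sum(axis=0).astype(np.int64)


def sample_dwell_mixture(
    weights,
    taus,
    n: int,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Draw ``n`` i.i.d. dwell times from an exponential mixture (seconds)."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    w = np.asarray(weights, dtype=float)
    t = np.asarray(taus, dtype=float)
    if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
        raise ValueError("mixture weights must be nonnegative and sum to 1")
    if np.any(t <= 0):
        raise ValueError("mixture time constants must be positive")
    if n == 0:
        return np.empty(0)
    comp = rng.choice(len(w), size=n, p=w / w.sum())
    return rng.exponential(t[comp])


def _stationary_first_dwell(
    kinetics: SiteKinetics, rng: np.random.Generator
) -> tuple[bool, float]:
    """Start the alternating renewal process in its stationary regime.

    Returns (bound?, residual time of the in-progress dwell). Because every
    mixture component is exponential, the residual life within a component is
    again exponential; the in-progress component is chosen length-biased.
    """
    p = kinetics.occupancy
    if rng.random() < p:
        w = np.asarray(kinetics.bound_weights) * np.asarray(kinetics.bound_taus)
        comp = rng.choice(len(w), p=w / w.sum())
        return True, rng.exponential(kinetics.bound_taus[comp])
    return False, rng.exponential(kinetics.unbound_mean_s)


def simulate_site_occupancy(
    kinetics: SiteKinetics,
    n_frames: int,
    frame_interval_s: float = FRAME_INTERVAL_S,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Simulate one site's per-frame occupancy (bool array).

    Sojourns alternate between exponential unbound dwells and mixture bound
    dwells; the process is started stationary so the long-run bound fraction is
    unbiased even for short traces. A frame is bound iff the site is bound at
    the frame midpoint.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    duration = n_frames * frame_interval_s
    occ = np.zeros(n_frames, dtype=bool)
    if np.isinf(kinetics.unbound_mean_s):
        return occ

    bound, dwell = _stationary_first_dwell(kinetics, rng)
    t = 0.0
    midpoints = (np.arange(n_frames) + 0.5) * frame_interval_s
    while t < duration:
        t_next = t + dwell
        if bound:
            i0, i1 = np.searchsorted(midpoints, [t, t_next])
            occ[i0:i1] = True
        t = t_next
        bound = not bound
        if bound:
            dwell = float(sample_dwell_mixture(
                kinetics.bound_weights, kinetics.bound_taus, 1, rng)[0])
        else:
            dwell = rng.exponential(kinetics.unbound_mean_s)
    return occ


def _occupancy_runs(occ: np.ndarray) -> list[tuple[int, int]]:
    """Half-open (start, end) frame intervals of maximal bound runs."""
    if occ.size == 0:
        return []
    padded = np.diff(np.concatenate(([0], occ.view(np.int8), [0])))
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def render_single_site_trace(
    occupancy: np.ndarray,
    amplitude_model: AmplitudeModel,
    rng: np.random.Generator | int | None = None,
) -> SiteTrace:
    """Render a single site's occupancy into fluorescence.

    One amplitude draw per event, held for the event's duration, plus per-frame
    Gaussian noise with SD = intercept + slope * amplitude. Unbound frames stay
    exactly zero; baseline noise is added later at the channel level.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    occ = np.asarray(occupancy).astype(bool)
    trace = np.zeros(occ.size)
    runs = _occupancy_runs(occ)
    amps = amplitude_model.sample_amplitudes(len(runs), rng)
    events: list[tuple[int, int, float]] = []
    for (i0, i1), amp in zip(runs, amps):
        sd = amplitude_model.event_noise_sd(float(amp))
        trace[i0:i1] = amp + rng.normal(0.0, sd, size=i1 - i0)
        events.append((int(i0), int(i1), float(amp)))
    return SiteTrace(intensity=trace, occupancy=occ, events=events)


def compose_tetramer_trace(
    site_traces: list[SiteTrace],
    amplitude_model: AmplitudeModel,
    rng: np.random.Generator | int | None = None,
    frame_interval_s: float = FRAME_INTERVAL_S,
    concentration_nM: float | None = None,
) -> tuple[FluorescenceTrace, TruthRecord]:
    """Sum site traces into a channel trace.

    Gaussian baseline noise is added only to frames where every site is
    unbound: bound frames already carry the (larger) per-ligand event noise, so
    this sums the noise from each bound ligand without quadrupling the baseline
    noise.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    lengths = {st.intensity.size for st in site_traces}
    if len(lengths) != 1:
        raise ValueError(f"site traces have mismatched lengths: {sorted(lengths)}")
    total = np.sum([st.intensity for st in site_traces], axis=0)
    occupancy = np.stack([st.occupancy for st in site_traces])
    baseline = ~occupancy.any(axis=0)
    total[baseline] += rng.normal(0.0, amplitude_model.baseline_sd, size=baseline.sum())
    events = [
        (site, i0, i1, amp)
        for site, st in enumerate(site_traces)
        for (i0, i1, amp) in st.events
    ]
    trace = FluorescenceTrace(
        intensity=total,
        frame_interval_s=frame_interval_s,
        concentration_nM=concentration_nM,
    )
    return trace, TruthRecord(site_occupancy=occupancy, events=events)


def simulate_molecule(
    config: SimulationConfig,
    kinetics: SiteKinetics | None = None,
    amplitude_model: AmplitudeModel | None = None,
    rng: np.random.Generator | int | None = None,
) -> tuple[FluorescenceTrace, TruthRecord]:
    """Simulate one molecule: occupancy, rendering and tetramer composition."""
    rng = np.random.default_rng(rng if rng is not None else config.seed) \
        if not isinstance(rng, np.random.Generator) else rng
    kinetics = kinetics or SiteKinetics.for_concentration(config.concentration_nM)
    amplitude_model = amplitude_model or AmplitudeModel()
    sites = []
    for _ in range(config.n_sites):
        occ = simulate_site_occupancy(
            kinetics, config.frames_per_trace, config.frame_interval_s, rng)
        sites.append(render_single_site_trace(occ, amplitude_model, rng))
    return compose_tetramer_trace(
        sites, amplitude_model, rng,
        frame_interval_s=config.frame_interval_s,
        concentration_nM=config.concentration_nM,
    )


def simulate_channel_markov(
    model,
    params: dict,
    concentration_M: float,
    n_frames: int,
    frame_interval_s: float = FRAME_INTERVAL_S,
    rng: np.random.Generator | int | None = None,
):
    """Exact stochastic (jump-chain) simulation of a kinetic model.

    Returns (classes, states): the observed bound-ligand count at each frame
    midpoint and the hidden state index at each frame midpoint. The initial
    state is drawn from the model's equilibrium distribution.
    """
    from .models import build_generator_matrix, equilibrium_distribution

    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    Q = build_generator_matrix(model, params, concentration_M)
    exit_rates = -np.diag(Q)
    if np.all(exit_rates <= 0):
        raise ValueError("model has only absorbing states at this concentration")
    pi = equilibrium_distribution(Q)
    duration = n_frames * frame_interval_s
    midpoints = (np.arange(n_frames) + 0.5) * frame_interval_s

    state = int(rng.choice(len(pi), p=pi))
    t = 0.0
    jump_times = [0.0]
    jump_states = [state]
    while t < duration:
        rate = exit_rates[state]
        if rate <= 0:  # absorbing: stay forever
            break
        t += rng.exponential(1.0 / rate)
        probs = Q[state].copy()
        probs[state] = 0.0
        probs = np.maximum(probs, 0.0) / rate
        state = int(rng.choice(len(pi), p=probs / probs.sum()))
        jump_times.append(t)
        jump_states.append(state)

    idx = np.searchsorted(np.asarray(jump_times), midpoints, side="right") - 1
    states = np.asarray(jump_states)[idx]
    classes = np.asarray(model.class_map)[states]
    return classes, states


def generate_bleach_counts(
    n_spots: int,
    p_detect: float = DEFAULT_DETECTION_P,
    n_subunits: int = 4,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Simulated per-spot GFP bleach-step counts: Binomial(n_subunits, p)."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if not 0.0 <= p_detect <= 1.0:
        raise ValueError("p_detect must lie in [0, 1]")
    return rng.binomial(n_subunits, p_detect, size=n_spots)
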