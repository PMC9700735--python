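"""Synthetic-data generation for every input the pipeline consumes.

The generators emulate the statistical structure of constant-force
optical-tweezers measurements on nucleosome arrays:

- force-clamp distance-time traces in which each nucleosome draws an
  exponential waiting time whose rate is calibrated so that the
  probability of unwrapping within the observation window equals the
  two-state model P(F); a minor tetrasome subpopulation unwraps with a
  strongly accelerated rate; each unwrap adds a ~26 nm step; transient
  loop-extrusion excursions (translocase activity) shorten the tether
  and recover; Gaussian distance noise is added per sample;
- post-clamp stretch curves with one rupture (a ~26 nm contour-length
  shift above 15 pN) per remaining wrapped nucleosome;
- kymographs as Poisson photon counts over Gaussian point-spread
  functions on a 75-nm pixel grid;
- piecewise-constant-velocity sliding trajectories.

Every generator returns a ground-truth record so that detection,
kinetics and counting can be validated by recovery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from nucleoforce.fractions import ArrheniusFit, arrhenius_probability
from nucleoforce.kymo import Kymograph
from nucleoforce.mechanics import WlcParams, wlc_extension
from nucleoforce.stepfit import ForceClampTrace, StretchCurve

CONDITIONS = ("NO_PROTEIN", "PICH_ATP", "PICH_AMPPNP")

#: Generator-side two-state parameters (F_half pN, delta_x nm) per condition.
#: AMP-PNP (non-hydrolysable ATP analog) leaves the bare-nucleosome
#: energetics unchanged.
CONDITION_PARAMS = {
    "NO_PROTEIN": (10.6, 5.7),
    "PICH_ATP": (5.5, 4.4),
    "PICH_AMPPNP": (10.6, 5.7),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the force-clamp generator.

    Defaults encode the assay: a 10-minute (600 s) observation window
    sampled at 50 Hz, ~26 nm unwrapping steps, a ~26% tetrasome
    subpopulation unwrapping >100-fold faster, and (for the
    ATP-hydrolysing condition) transient loop-extrusion excursions that
    shorten the tether at the translocation speed (~10 nm/s) and
    recover.
    """

    n_nucleosomes: int = 15
    condition: str = "NO_PROTEIN"
    f_half: float | None = None  # pN; None -> condition default
    delta_x: float | None = None  # nm; None -> condition default
    tetrasome_fraction: float = 0.26
    tetrasome_speedup: float = 137.0
    observation_window: float = 600.0  # s
    sample_rate: float = 50.0  # Hz
    step_mean: float = 26.0  # nm
    step_sd: float = 3.5  # nm
    noise_sd: float = 2.0  # nm
    loop_rate: float = 0.005  # episodes per second (ATP condition only)
    loop_depth: float = 100.0  # nm, maximum transient shortening
    loop_speed: float = 10.0  # nm/s
    seed: int = 0

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        if not (0.0 <= self.tetrasome_fraction <= 1.0):
            raise ValueError("tetrasome_fraction must lie in [0, 1]")
        if self.tetrasome_speedup < 1.0:
            raise ValueError("tetrasome_speedup must be >= 1")
        if self.observation_window <= 0 or self.sample_rate <= 0:
            raise ValueError("observation_window and sample_rate must be positive")

    def two_state_fit(self) -> ArrheniusFit:
        fh, dx = CONDITION_PARAMS[self.condition]
        return ArrheniusFit(
            f_half=self.f_half if self.f_half is not None else fh,
            delta_x=self.delta_x if self.delta_x is not None else dx,
        )


@dataclass
class GroundTruth:
    """What the generator actually did, for recovery testing."""

    unwrap_times: np.ndarray | None = None  # s, inf where censored
    censored: np.ndarray | None = None  # bool per nucleosome
    is_tetrasome: np.ndarray | None = None
    step_sizes: np.ndarray | None = None  # nm per nucleosome (uncensored only used)
    loop_intervals: list = field(default_factory=list)  # (start, peak_depth) tuples
    emitters: list = field(default_factory=list)  # (position_nm, oligomer)
    segment_plan: list = field(default_factory=list)  # (duration_s, velocity)

    @property
    def n_censored(self) -> int:
        return int(np.sum(self.censored)) if self.censored is not None else 0


def unwrap_rate(p_window: float, window: float) -> float:
    """Exponential rate reproducing a given within-window unwrap probability.

    k = -ln(1 - P) / T.  P outside (0, 1) is clamped (with a warning) so
    the rate stays in [0, inf).
    """
    if not (0.0 < p_window < 1.0):
        warnings.warn("P(F) outside (0,1); clamping rate", stacklevel=2)
        p_window = float(np.clip(p_window, 1e-12, 1.0 - 1e-12))
    return -np.log1p(-p_window) / window


def simulate_force_clamp(
    config: SimulationConfig,
    force: float,
    unwrap_times: np.ndarray | None = None,
) -> tuple[ForceClampTrace, GroundTruth]:
    """Simulate one constant-force distance-time trace.

    Parameters
    ----------
    config : SimulationConfig
    force : float
        Clamp force in pN.
    unwrap_times : array, optional
        Override the stochastic waiting times (seconds; use ``np.inf``
        for a nucleosome that never unwraps).  Length must equal
        ``config.n_nucleosomes``.

    Returns
    -------
    (ForceClampTrace, GroundTruth)
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_nucleosomes
    T = config.observation_window

    is_tet = rng.random(n) < config.tetrasome_fraction
    if unwrap_times is None:
        p = arrhenius_probability(force, config.two_state_fit())
        k = unwrap_rate(p, T)
        rates = np.where(is_tet, k * config.tetrasome_speedup, k)
        with np.errstate(divide="ignore"):
            times = np.where(rates > 0, rng.exponential(1.0, n) / np.maximum(rates, 1e-300), np.inf)
    else:
        times = np.asarray(unwrap_times, dtype=float)
        if times.size != n:
            raise ValueError("unwrap_times length must equal n_nucleosomes")
    censored = times > T
    steps = config.step_mean + config.step_sd * rng.standard_normal(n)

    n_samples = int(round(T * config.sample_rate))
    t = np.arange(n_samples) / config.sample_rate
    signal = np.zeros(n_samples)
    order = np.argsort(times)
    for i in order:
        if censored[i]:
            break
        signal[t >= times[i]] += steps[i]

    loop_intervals = []
    if config.condition == "PICH_ATP" and config.loop_rate > 0:
        n_loops = rng.poisson(config.loop_rate * T)
        starts = np.sort(rng.uniform(0, T, n_loops))
        for s in starts:
            depth = rng.uniform(0.3, 1.0) * config.loop_depth
            dur = 2.0 * depth / config.loop_speed
            mask = (t >= s) & (t < s + dur)
            tau = t[mask] - s
            excursion = np.where(
                tau < depth / config.loop_speed,
                -config.loop_speed * tau,
                -depth + config.loop_speed * (tau - depth / config.loop_speed),
            )
            signal[mask] += excursion
            loop_intervals.append((float(s), float(depth)))

    if config.noise_sd > 0:
        signal = signal + config.noise_sd * rng.standard_normal(n_samples)

    trace = ForceClampTrace(
        time=t, distance=signal, force_setpoint=float(force), condition=config.condition
    )
    truth = GroundTruth(
        unwrap_times=times,
        censored=censored,
        is_tetrasome=is_tet,
        step_sizes=steps,
        loop_intervals=loop_intervals,
    )
    return trace, truth


def simulate_stretch_curve(
    n_remaining: int,
    params: WlcParams = WlcParams(),
    seed: int = 0,
    base_contour: float = 5000.0,
    shift_mean: float = 26.0,
    shift_sd: float = 1.0,
    noise_sd: float = 1.0,
    n_points: int = 500,
) -> tuple[StretchCurve, GroundTruth]:
    """Simulate a post-clamp stretch curve with ``n_remaining`` ruptures.

    Each remaining inner-turn nucleosome ruptures at a force drawn from
    (15, 32) pN, adding a ~26 nm contour-length shift.  The force ramp
    spans 2-40 pN so the curve satisfies the >= 35 pN requirement of
    rupture counting.
    """
    if n_remaining < 0:
        raise ValueError("n_remaining must be >= 0")
    rng = np.random.default_rng(seed)
    force = np.linspace(2.0, 40.0, n_points)
    rupture_forces = np.sort(rng.uniform(15.0, 32.0, n_remaining))
    shifts = shift_mean + shift_sd * rng.standard_normal(n_remaining)
    contour = np.full(n_points, base_contour)
    for rf, sh in zip(rupture_forces, shifts):
        contour[force >= rf] += sh
    distance = wlc_extension(force, contour, params)
    if noise_sd > 0:
        distance = distance + noise_sd * rng.standard_normal(n_points)
    curve = StretchCurve(distance=distance, force=force)
    truth = GroundTruth()
    truth.loop_intervals = []
    truth.segment_plan = [(float(rf), float(sh)) for rf, sh in zip(rupture_forces, shifts)]
    return curve, truth


def simulate_kymograph(
    emitters,
    psf_sigma: float = 150.0,
    photons_per_monomer_per_line: float = 50.0,
    background: float = 2.0,
    n_lines: int = 100,
    seed: int = 0,
    pixel_nm: float = 75.0,
    n_pixels: int = 144,
    line_time: float = 0.1,
) -> tuple[Kymograph, GroundTruth]:
    """Simulate a confocal-line-scan kymograph of static fluorescent spots.

    Parameters
    ----------
    emitters : sequence of (position_nm, oligomer_count)
        Static emitters along the scan axis; each contributes
        ``oligomer_count`` times the monomer photon flux, spread over a
        Gaussian point-spread function of width ``psf_sigma`` (nm).
    background : float
        Expected background photons per pixel per line.

    Photon counts are Poisson-sampled per pixel per line.
    """
    scan_length = n_pixels * pixel_nm
    for pos, cnt in emitters:
        if not (0.0 <= pos <= scan_length):
            raise ValueError(f"emitter position {pos} nm outside scan range")
        if cnt < 1:
            raise ValueError("oligomer count must be >= 1")
    rng = np.random.default_rng(seed)
    centers = (np.arange(n_pixels) + 0.5) * pixel_nm
    expected = np.full(n_pixels, float(background))
    for pos, cnt in emitters:
        psf = np.exp(-0.5 * ((centers - pos) / psf_sigma) ** 2)
        psf *= pixel_nm / (psf_sigma * np.sqrt(2 * np.pi))  # integrates to ~1
        expected += cnt * photons_per_monomer_per_line * psf
    photons = rng.poisson(expected, size=(n_lines, n_pixels)).astype(np.uint16)
    kymo = Kymograph(photons=photons, pixel_size=pixel_nm, line_time=line_time)
    truth = GroundTruth(emitters=[(float(p), int(c)) for p, c in emitters])
    return kymo, truth


def simulate_sliding_trajectory(
    plan,
    noise_sd: float = 5.0,
    dt: float = 0.5,
    seed: int = 0,
    start_position: float = 0.0,
):
    """Simulate a piecewise-constant-velocity position track.

    ``plan`` is a sequence of (duration_s, velocity_nm_per_s) phases;
    Gaussian localization noise of ``noise_sd`` nm is added per sample.
    Returns (time, position, GroundTruth).
    """
    plan = [(float(d), float(v)) for d, v in plan]
    if any(d <= 0 for d, _ in plan):
        raise ValueError("phase durations must be positive")
    rng = np.random.default_rng(seed)
    total = sum(d for d, _ in plan)
    t = np.arange(0.0, total + dt / 2, dt)
    pos = np.empty_like(t)
    level = start_position
    t0 = 0.0
    pos[:] = start_position
    for dur, vel in plan:
        mask = (t >= t0) & (t <= t0 + dur + 1e-12)
        pos[mask] = level + vel * (t[mask] - t0)
        level += vel * dur
        t0 += dur
        pos[t > t0] = level
    if noise_sd > 0:
        pos = pos + noise_sd * rng.standard_normal(t.size)
    truth = GroundTruth(segment_plan=plan)
    return t, pos, truth


def config_for(condition: str, **overrides) -> SimulationConfig:
    """Convenience constructor with per-condition defaults applied."""
    return replace(SimulationConfig(condition=condition), **overrides)
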