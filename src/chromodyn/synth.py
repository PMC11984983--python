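"""Synthetic ground-truth generators.

This module replaces the microscope: it produces single-molecule
trajectories, rendered image stacks, astral-microtubule length traces and
FRAP recovery traces whose statistical structure matches what the analysis
modules assume, so that every downstream stage can be validated against a
known truth.

Distributional conventions: binding dwell times, photobleach survival and
dynamic-instability phase durations are all exponential; localization error
is Gaussian per coordinate; a freely diffusing molecule is censored (the
track ends) when its simulated axial position leaves the detection slab.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import AcquisitionParams, Track, TrackSet
from .frap import FrapTrace
from .mtdyn import MTTrace, Phase

__all__ = [
    "KineticTruth",
    "MTDynamicsTruth",
    "FrapTruth",
    "ImageStack",
    "simulate_tracks",
    "simulate_movie",
    "simulate_mt_trace",
    "simulate_frap_trace",
    "draw_dwell_times",
]

# ground-truth state labels carried on simulated tracks
STATE_BOUND_SPECIFIC = "bound_s"
STATE_BOUND_NONSPECIFIC = "bound_ns"
STATE_FREE = "free"


@dataclass(frozen=True)
class KineticTruth:
    """Ground truth for the two-state (bound/free) molecule population.

    ``frac_bound`` is the fraction of molecules starting bound (the mixture
    weight of the slow state); of those, ``frac_ns_of_bound`` are
    non-specifically bound and unbind at the fast rate ``k_ns``; the rest
    unbind at the slow, specific rate ``k_s``. Diffusion coefficients are in
    um^2/s; ``bleach_lifetime_s`` is the mean exponential photobleach time.
    With ``interconvert`` off, molecules keep their initial state for the
    whole track (the assumption behind jump-length model fixtures); with it
    on, bound molecules unbind into the free state after their exponential
    dwell (the dwell-time fixtures). No rebinding is modelled.
    """

    frac_bound: float = 0.5
    frac_ns_of_bound: float = 0.6
    k_ns: float = 2.0
    k_s: float = 0.2
    D_bound: float = 0.005
    D_free: float = 2.0
    bleach_lifetime_s: float = 20.0
    interconvert: bool = False

    def __post_init__(self) -> None:
        for name in ("frac_bound", "frac_ns_of_bound"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not self.k_ns >= self.k_s > 0:
            raise ValueError("need k_ns >= k_s > 0 (non-specific dwell is the shorter one)")
        if not self.D_free >= self.D_bound >= 0:
            raise ValueError("need D_free >= D_bound >= 0")
        if self.bleach_lifetime_s <= 0:
            raise ValueError("bleach_lifetime_s must be positive")


@dataclass(frozen=True)
class MTDynamicsTruth:
    """Two-state dynamic-instability truth for astral microtubules.

    Speeds in um/min; ``f_cat`` is the catastrophe rate per minute of
    growth, ``f_res`` the rescue rate per minute of shrinkage; ``l0`` the
    starting length (um); ``dt_s`` the sampling interval.
    """

    v_poly: float = 1.5
    v_depoly: float = 2.5
    f_cat: float = 0.5
    f_res: float = 0.5
    l0: float = 1.0
    dt_s: float = 15.0

    def __post_init__(self) -> None:
        if self.v_poly < 0 or self.v_depoly < 0:
            raise ValueError("speeds must be non-negative")
        if self.f_cat < 0 or self.f_res < 0:
            raise ValueError("rates must be non-negative")
        if self.l0 < 0:
            raise ValueError("l0 must be non-negative")


@dataclass(frozen=True)
class FrapTruth:
    """Fixture parameters for an exponential-recovery FRAP trace.

    The bleached half recovers as
    ``b(t) = (1 - bleach_depth) + (plateau - (1 - bleach_depth)) * (1 - exp(-t / recovery_tau))``
    and the unbleached half loses the same fluorescence mirror-wise so that
    the post-bleach total is conserved (turnover exchanges subunits, it does
    not create them). Under this convention a 50%-of-lost-signal recovery
    is only reachable when ``plateau > (2 - bleach_depth) / 2``; the
    defaults describe a full-depth half-spindle bleach recovering to 55% of
    pre-bleach with a half-time of a few hundred seconds.
    """

    recovery_tau_s: float = 150.0
    plateau: float = 0.55
    bleach_depth: float = 1.0
    noise_sd: float = 0.02
    dt_s: float = 30.0

    def __post_init__(self) -> None:
        if self.recovery_tau_s <= 0:
            raise ValueError("recovery_tau_s must be positive")
        if not 0.0 <= self.bleach_depth <= 1.0:
            raise ValueError("bleach_depth must be in [0, 1]")
        if not 0.0 < self.plateau <= 1.0:
            raise ValueError("plateau must be in (0, 1]")


@dataclass
class ImageStack:
    """A single-channel movie plus its pixel size."""

    data: np.ndarray  # (n_frames, height, width)
    pixel_size_nm: float = 110.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("ImageStack data must be (frames, height, width)")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def to_tiff(self, path) -> None:
        import tifffile

        tifffile.imwrite(path, self.data.astype(np.float32))

    @classmethod
    def from_tiff(cls, path, pixel_size_nm: float = 110.0) -> "ImageStack":
        import tifffile

        return cls(tifffile.imread(path), pixel_size_nm=pixel_size_nm)


def draw_dwell_times(truth: KineticTruth, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` bound dwell times from the specific/non-specific mixture.

    The pooled distribution is
    ``F_ns * Exp(k_ns) + (1 - F_ns) * Exp(k_s)``.
    """
    is_ns = rng.random(n) < truth.frac_ns_of_bound
    rates = np.where(is_ns, truth.k_ns, truth.k_s)
    return rng.exponential(1.0 / rates)


def simulate_tracks(
    truth: KineticTruth,
    acq: AcquisitionParams,
    n_molecules: int,
    seed: int,
    fov_px: tuple[float, float] = (64.0, 64.0),
    min_observations: int = 2,
) -> TrackSet:
    """Simulate two-state single-molecule trajectories.

    Each molecule is assigned an initial state (bound-specific,
    bound-non-specific or free) from ``truth``; positions evolve by 2D
    Brownian steps with the state's diffusion coefficient, observed with
    independent Gaussian localization error per coordinate. Tracks end at an
    exponential photobleach time; free molecules additionally end when their
    simulated 1D axial Brownian position leaves the detection slab of depth
    ``acq.axial_range_nm`` (bound molecules are held at the focal plane).
    The returned tracks carry per-frame ground-truth state labels.
    """
    if n_molecules <= 0:
        raise ValueError("n_molecules must be positive")
    if seed is None:
        raise ValueError("a seed is required; simulations must be reproducible")
    rng = np.random.default_rng(seed)

    dt = acq.frame_interval_s
    px_um = acq.pixel_size_um
    sigma_px = acq.localization_error_um / px_um
    half_slab_um = acq.axial_range_nm / 2000.0  # nm -> um, half-depth
    n_frames = acq.n_frames

    tracks: list[Track] = []
    for mol in range(n_molecules):
        bound = rng.random() < truth.frac_bound
        if bound:
            nonspecific = rng.random() < truth.frac_ns_of_bound
            state0 = STATE_BOUND_NONSPECIFIC if nonspecific else STATE_BOUND_SPECIFIC
            k_off = truth.k_ns if nonspecific else truth.k_s
        else:
            state0 = STATE_FREE
            k_off = None

        t_bleach = rng.exponential(truth.bleach_lifetime_s)
        n_obs = min(n_frames, int(np.floor(t_bleach / dt)) + 1)
        if n_obs < min_observations:
            # molecule bleached before yielding a usable track; draw anyway
            # for stream stability, then skip
            continue

        # per-frame state labels
        states = np.full(n_obs, state0, dtype=object)
        if bound and truth.interconvert:
            t_unbind = rng.exponential(1.0 / k_off)
            free_from = int(np.ceil(t_unbind / dt))
            if free_from < n_obs:
                states[free_from:] = STATE_FREE

        D_per_step = np.where(
            states[:-1] == STATE_FREE, truth.D_free, truth.D_bound
        ).astype(float)

        # lateral motion (true positions, px)
        step_sd_px = np.sqrt(2.0 * D_per_step * dt) / px_um
        x0 = rng.uniform(0, fov_px[0])
        y0 = rng.uniform(0, fov_px[1])
        dx = rng.normal(0.0, 1.0, n_obs - 1) * step_sd_px
        dy = rng.normal(0.0, 1.0, n_obs - 1) * step_sd_px
        x = np.concatenate([[x0], x0 + np.cumsum(dx)])
        y = np.concatenate([[y0], y0 + np.cumsum(dy)])

        # axial censoring of free motion
        if half_slab_um > 0:
            z = np.empty(n_obs)
            z[0] = rng.uniform(-half_slab_um, half_slab_um) if state0 == STATE_FREE else 0.0
            dz_sd = np.where(states[:-1] == STATE_FREE, np.sqrt(2.0 * truth.D_free * dt), 0.0)
            z[1:] = z[0] + np.cumsum(rng.normal(0.0, 1.0, n_obs - 1) * dz_sd)
            outside = np.abs(z) > half_slab_um
            if outside.any():
                n_obs = int(np.argmax(outside))  # first frame outside
                if n_obs < min_observations:
                    continue
                x, y, states = x[:n_obs], y[:n_obs], states[:n_obs]

        # localization error
        x_obs = x + rng.normal(0.0, sigma_px, n_obs)
        y_obs = y + rng.normal(0.0, sigma_px, n_obs)

        tracks.append(
            Track(
                track_id=mol,
                frames=np.arange(n_obs),
                x_px=x_obs,
                y_px=y_obs,
                true_state=states,
            )
        )
    return TrackSet(tracks=tracks, acq=acq, provenance=f"simulate_tracks(seed={seed})")


def simulate_movie(
    tracks: TrackSet,
    psf_sigma_px: float = 1.3,
    photon_scale: float = 200.0,
    background: float = 10.0,
    shape: tuple[int, int] | None = None,
    n_frames: int | None = None,
    seed: int = 0,
    poisson_noise: bool = True,
) -> ImageStack:
    """Render a TrackSet into a noisy image stack.

    Each localization becomes a 2D Gaussian of width ``psf_sigma_px`` with
    peak amplitude ``photon_scale`` on a constant ``background``; Poisson
    shot noise is applied to the expected photon image.
    """
    if psf_sigma_px <= 0:
        raise ValueError("psf_sigma_px must be positive")
    rng = np.random.default_rng(seed)

    if shape is None:
        if len(tracks) == 0:
            shape = (32, 32)
        else:
            xmax = max(float(np.max(t.x_px)) for t in tracks)
            ymax = max(float(np.max(t.y_px)) for t in tracks)
            shape = (int(np.ceil(ymax)) + 8, int(np.ceil(xmax)) + 8)
    if n_frames is None:
        n_frames = max((int(t.frames[-1]) + 1 for t in tracks), default=1)

    h, w = shape
    expected = np.full((n_frames, h, w), float(background))
    yy, xx = np.mgrid[0:h, 0:w]
    half = int(np.ceil(4 * psf_sigma_px))
    for t in tracks:
        for f, x, y in zip(t.frames, t.x_px, t.y_px):
            if f >= n_frames:
                continue
            r0, r1 = max(0, int(y) - half), min(h, int(y) + half + 1)
            c0, c1 = max(0, int(x) - half), min(w, int(x) + half + 1)
            if r0 >= r1 or c0 >= c1:
                continue
            g = np.exp(
                -((xx[r0:r1, c0:c1] - x) ** 2 + (yy[r0:r1, c0:c1] - y) ** 2)
                / (2.0 * psf_sigma_px**2)
            )
            expected[f, r0:r1, c0:c1] += photon_scale * g
    data = rng.poisson(expected).astype(float) if poisson_noise else expected
    return ImageStack(data=data, pixel_size_nm=tracks.acq.pixel_size_nm)


def simulate_mt_trace(
    truth: MTDynamicsTruth,
    duration_s: float,
    seed: int,
    cell_id: str = "sim",
    mt_id: str = "mt0",
    bud_directed: bool = True,
) -> tuple[MTTrace, list[Phase]]:
    """Simulate a dynamic-instability length trace sampled every ``dt_s``.

    Growth and shrinkage phases alternate with exponential durations
    (rates ``f_cat`` and ``f_res`` per minute of the respective phase);
    length changes linearly at ``v_poly`` / ``v_depoly``. When the length
    hits zero mid-shrinkage a rescue is forced (re-nucleation at zero).
    Returns the sampled trace together with the ground-truth phase list.
    """
    if duration_s < 10 * truth.dt_s:
        raise ValueError("duration must cover at least 10 sampling intervals")
    rng = np.random.default_rng(seed)

    # continuous-time phase sequence
    phases: list[Phase] = []
    t, length = 0.0, truth.l0
    growing = True
    while t < duration_s:
        if growing:
            rate = truth.f_cat / 60.0  # per second of growth
            dur = rng.exponential(1.0 / rate) if rate > 0 else duration_s - t + 1.0
            dur = min(dur, duration_s - t)
            end_len = length + truth.v_poly / 60.0 * dur
            phases.append(Phase("growth", t, t + dur, length, end_len))
        else:
            rate = truth.f_res / 60.0
            dur = rng.exponential(1.0 / rate) if rate > 0 else duration_s - t + 1.0
            v = truth.v_depoly / 60.0
            if v > 0 and length - v * dur < 0:
                dur = length / v  # hits zero: forced rescue
            dur = min(dur, duration_s - t)
            end_len = max(length - v * dur, 0.0)
            phases.append(Phase("shrink", t, t + dur, length, end_len))
        t += dur
        length = phases[-1].end_length
        growing = not growing

    # sample on the regular grid by linear interpolation of breakpoints
    bp_t = [phases[0].start_time] + [p.end_time for p in phases]
    bp_l = [phases[0].start_length] + [p.end_length for p in phases]
    times = np.arange(0.0, duration_s + 0.5 * truth.dt_s, truth.dt_s)
    times = times[times <= duration_s]
    lengths = np.interp(times, bp_t, bp_l)
    trace = MTTrace(
        times=times, lengths=lengths, cell_id=cell_id, mt_id=mt_id, bud_directed=bud_directed
    )
    return trace, phases


def simulate_frap_trace(
    truth: FrapTruth,
    n_pre: int = 3,
    n_post: int = 26,
    seed: int = 0,
    signal_scale: float = 1000.0,
    background_level: float = 100.0,
) -> FrapTrace:
    """Simulate background-added bleached/unbleached/background ROI traces.

    Pre-bleach points sit at 1.0 (in normalized units); the post-bleach
    bleached-ROI signal recovers exponentially toward ``plateau`` while the
    unbleached ROI loses fluorescence mirror-wise so the post-bleach total
    ``2 - bleach_depth`` is conserved. Gaussian noise of sd ``noise_sd`` is
    added in normalized units; the background channel is constant.
    """
    if n_pre < 1:
        raise ValueError("need at least one pre-bleach point")
    rng = np.random.default_rng(seed)
    dt = truth.dt_s

    t_pre = -dt * np.arange(n_pre, 0, -1)
    t_post = dt * np.arange(n_post)
    times = np.concatenate([t_pre, t_post])

    floor = 1.0 - truth.bleach_depth
    b_post = floor + (truth.plateau - floor) * (1.0 - np.exp(-t_post / truth.recovery_tau_s))
    u_post = (2.0 - truth.bleach_depth) - b_post
    bleached = np.concatenate([np.ones(n_pre), b_post])
    unbleached = np.concatenate([np.ones(n_pre), u_post])

    bleached = bleached + rng.normal(0.0, truth.noise_sd, len(times)) if truth.noise_sd > 0 else bleached
    unbleached = (
        unbleached + rng.normal(0.0, truth.noise_sd, len(times)) if truth.noise_sd > 0 else unbleached
    )

    return FrapTrace(
        times=times,
        bleached=background_level + signal_scale * bleached,
        unbleached=background_level + signal_scale * unbleached,
        background=np.full(len(times), background_level),
    )
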