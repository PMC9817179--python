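"""Seeded synthetic fixtures with known ground truth.

Every generator is a pure function of its spec (including the seed): the
same spec yields bit-identical output.  Generated objects emulate only the
statistical structure the analyses assume — nuclei as elliptical regions of
uniform background with Gaussian-profile puncta plus additive Gaussian
noise, and dwell times as a two-component exponential mixture whose observed
rates include an exponential photobleaching contribution (the assumption
under which the H2B correction is exact).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .puncta import NucleusMask, NucleusStack
from .spt import MaskSeries, SMTrajectory

__all__ = [
    "SyntheticImageSpec",
    "SyntheticDwellSpec",
    "SyntheticGroundTruth",
    "make_nucleus_stack",
    "make_live_fixed_pair",
    "make_dwell_times",
    "make_trajectory_set",
]


@dataclass(frozen=True)
class SyntheticImageSpec:
    """Parameters of a synthetic nucleus z-stack with planted puncta.

    Defaults give a 5x192x192 stack whose elliptical nucleus holds 12 clearly
    resolvable puncta (sigma 2 px, amplitude 50x the noise floor) on a
    uniform nucleoplasm background — the regime of a strongly phase-
    separating protein imaged confocally.
    """

    shape: tuple[int, int, int] = (5, 192, 192)
    nucleus_axes: tuple[float, float] = (80.0, 70.0)  # semi-axes (y, x), px
    n_puncta: int = 12
    sigma: float = 2.0
    amplitude: float = 50.0
    background: float = 10.0
    noise_sd: float = 1.0
    min_separation: float | None = None  # default 6 * sigma
    seed: int = 0

    @property
    def separation(self) -> float:
        sep = 6.0 * self.sigma if self.min_separation is None else self.min_separation
        if sep < 6.0 * self.sigma:
            raise ValueError("min_separation must be >= 6*sigma for resolvable puncta")
        return sep


@dataclass(frozen=True)
class SyntheticDwellSpec:
    """Two-component exponential dwell-time mixture with photobleaching.

    A is the nonspecific (fast, tau_ns) fraction; observed per-component
    rates are 1/tau + 1/tau_bleach; dwells are rounded up to whole frames.
    """

    A: float = 0.5
    tau_ns: float = 2.0
    tau_s: float = 10.0
    tau_bleach: float = 100.0
    n: int = 5000
    frame_interval: float = 0.5
    window: float | None = None  # observation cap in seconds (movie length)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.A <= 1:
            raise ValueError("A must be in [0, 1]")
        if not (0 < self.tau_ns < self.tau_s):
            raise ValueError("need 0 < tau_ns < tau_s")
        if self.tau_bleach <= 0 or self.frame_interval <= 0:
            raise ValueError("tau_bleach and frame_interval must be > 0")


@dataclass
class SyntheticGroundTruth:
    """Planted truth attached to every generated fixture."""

    spec: object
    seed: int
    centers: np.ndarray | None = None  # (n, 2) punctum centers (y, x)
    sigmas: np.ndarray | None = None
    amplitudes: np.ndarray | None = None
    extra: dict = field(default_factory=dict)


def _place_puncta(rng, spec: SyntheticImageSpec) -> np.ndarray:
    """Rejection-sample punctum centers inside the nucleus at min separation."""
    _, h, w = spec.shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    ay, ax = spec.nucleus_axes
    margin = 3.0 * spec.sigma
    centers: list[tuple[float, float]] = []
    for _ in range(20000):
        if len(centers) == spec.n_puncta:
            break
        y = rng.uniform(cy - ay, cy + ay)
        x = rng.uniform(cx - ax, cx + ax)
        # stay inside a shrunken ellipse so the full punctum fits in the mask
        if ((y - cy) / (ay - margin)) ** 2 + ((x - cx) / (ax - margin)) ** 2 > 1:
            continue
        if any(math.hypot(y - py, x - px) < spec.separation for py, px in centers):
            continue
        centers.append((y, x))
    if len(centers) < spec.n_puncta:
        raise ValueError(
            f"could not place {spec.n_puncta} puncta at separation "
            f"{spec.separation:.1f}px; reduce n_puncta or separation"
        )
    return np.asarray(centers)


def _render(spec: SyntheticImageSpec, centers: np.ndarray, amplitudes: np.ndarray,
            rng) -> tuple[NucleusStack, NucleusMask]:
    nz, h, w = spec.shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    ay, ax = spec.nucleus_axes
    yy, xx = np.mgrid[0:h, 0:w]
    mask = ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1

    zc = (nz - 1) / 2.0
    sz = 2.0 * spec.sigma  # axial PSF wider than lateral, confocal-like
    stack = np.where(mask, spec.background, 0.0)[None].repeat(nz, axis=0).astype(float)
    for (py, px), amp in zip(centers, amplitudes):
        # render on a local window only; 4 sigma covers the profile
        r = int(np.ceil(4 * spec.sigma))
        y0, y1 = max(0, int(py) - r), min(h, int(py) + r + 1)
        x0, x1 = max(0, int(px) - r), min(w, int(px) + r + 1)
        ys, xs = np.mgrid[y0:y1, x0:x1]
        lateral = np.exp(-((ys - py) ** 2 + (xs - px) ** 2) / (2 * spec.sigma**2))
        for z in range(nz):
            axial = math.exp(-((z - zc) ** 2) / (2 * sz**2))
            stack[z, y0:y1, x0:x1] += amp * axial * lateral
    if spec.noise_sd > 0:
        stack += rng.normal(0.0, spec.noise_sd, size=stack.shape)
    np.clip(stack, 0.0, None, out=stack)
    return NucleusStack(stack), NucleusMask(mask)


def make_nucleus_stack(
    spec: SyntheticImageSpec,
) -> tuple[NucleusStack, NucleusMask, SyntheticGroundTruth]:
    """Synthetic nucleus stack, its mask, and the planted ground truth."""
    rng = np.random.default_rng(spec.seed)
    centers = _place_puncta(rng, spec) if spec.n_puncta else np.empty((0, 2))
    amplitudes = np.full(len(centers), float(spec.amplitude))
    stack, mask = _render(spec, centers, amplitudes, rng)
    truth = SyntheticGroundTruth(
        spec=spec,
        seed=spec.seed,
        centers=centers,
        sigmas=np.full(len(centers), spec.sigma),
        amplitudes=amplitudes,
    )
    return stack, mask, truth


def make_live_fixed_pair(
    base: SyntheticImageSpec,
    puncta_count_factor: float = 1.0,
    amplitude_factor: float = 1.0,
):
    """Paired live/fixed stacks with a controlled planted artifact.

    The fixed image reuses the live nucleus but scales the planted punctum
    count and amplitude; extra puncta (count factor > 1) are placed fresh.
    Returns (live, fixed) as (stack, mask, truth) tuples; the expected sign
    of each parameter change is recorded in the fixed truth's ``extra``.
    """
    if puncta_count_factor <= 0 or amplitude_factor <= 0:
        raise ValueError("scale factors must be > 0")
    live = make_nucleus_stack(base)
    n_fixed = int(round(base.n_puncta * puncta_count_factor))
    fixed_spec = replace(
        base,
        n_puncta=n_fixed,
        amplitude=base.amplitude * amplitude_factor,
        seed=base.seed + 1,
    )
    fixed = make_nucleus_stack(fixed_spec)

    def sign(x: float) -> int:
        return 0 if x == 0 else (1 if x > 0 else -1)

    expected_signs = {
        "n_puncta": sign(n_fixed - base.n_puncta),
        # more/brighter puncta raise both roughness and punctate percentage
        "surface_roughness": sign(amplitude_factor * puncta_count_factor - 1.0)
        if (amplitude_factor - 1.0) * (puncta_count_factor - 1.0) >= 0
        else None,
        "punctate_percentage": sign(amplitude_factor * puncta_count_factor - 1.0)
        if (amplitude_factor - 1.0) * (puncta_count_factor - 1.0) >= 0
        else None,
    }
    fixed[2].extra["expected_signs"] = expected_signs
    fixed[2].extra["factors"] = {
        "puncta_count_factor": puncta_count_factor,
        "amplitude_factor": amplitude_factor,
    }
    return live, fixed


def make_dwell_times(spec: SyntheticDwellSpec) -> tuple[np.ndarray, SyntheticGroundTruth]:
    """Dwell times from the bleach-truncated two-exponential mixture.

    Component rates are 1/tau + 1/tau_bleach (bleaching composes at the rate
    level); each continuous dwell is rounded up to a whole number of camera
    frames, and optionally capped at the observation window.
    """
    rng = np.random.default_rng(spec.seed)
    fast = rng.random(spec.n) < spec.A
    rate_fast = 1.0 / spec.tau_ns + 1.0 / spec.tau_bleach
    rate_slow = 1.0 / spec.tau_s + 1.0 / spec.tau_bleach
    raw = np.where(
        fast,
        rng.exponential(1.0 / rate_fast, size=spec.n),
        rng.exponential(1.0 / rate_slow, size=spec.n),
    )
    if spec.window is not None:
        raw = np.minimum(raw, spec.window)
    dwells = np.ceil(raw / spec.frame_interval) * spec.frame_interval
    dwells = np.maximum(dwells, spec.frame_interval)  # shortest observable: 1 frame
    truth = SyntheticGroundTruth(
        spec=spec,
        seed=spec.seed,
        extra={
            "observed_tau_ns": 1.0 / rate_fast,
            "observed_tau_s": 1.0 / rate_slow,
        },
    )
    return np.sort(dwells), truth


def make_trajectory_set(
    masks: MaskSeries,
    n_in: int,
    n_out: int,
    n_ambiguous: int,
    seed: int = 0,
    n_frames: int = 20,
    frame_interval: float = 0.5,
) -> tuple[list[SMTrajectory], list[str]]:
    """Trajectories with known in/out/ambiguous labels against ``masks``.

    In-puncta tracks place 80% of localizations on punctum pixels (F = 0.8),
    out tracks none (F = 0), ambiguous tracks 25% (F = 0.25).  Track lengths
    vary uniformly between 4 frames and ``n_frames`` so that downstream
    dwell-time sets are non-degenerate.  Returns the trajectories and their
    true labels, in matching order.
    """
    rng = np.random.default_rng(seed)
    trajs: list[SMTrajectory] = []
    labels: list[str] = []

    def pixels_for(t: float, inside: bool) -> np.ndarray:
        m = masks.nearest(t)
        pts = np.argwhere(m if inside else ~m)
        if pts.size == 0:
            raise ValueError(
                f"mask has no {'punctum' if inside else 'background'} pixels; "
                "cannot generate the requested trajectories"
            )
        return pts

    def build(tid: str, frac_in: float) -> SMTrajectory:
        nf = int(rng.integers(min(4, n_frames), n_frames + 1))
        k = int(round(frac_in * nf))
        flags = np.zeros(nf, bool)
        flags[rng.choice(nf, size=k, replace=False)] = True
        pos = np.empty((nf, 2))
        for i in range(nf):
            pts = pixels_for(i * frame_interval, bool(flags[i]))
            pos[i] = pts[rng.integers(len(pts))]
        return SMTrajectory(tid, np.arange(nf), pos, frame_interval)

    for i in range(n_in):
        trajs.append(build(f"in_{i}", 0.8))
        labels.append("in")
    for i in range(n_out):
        trajs.append(build(f"out_{i}", 0.0))
        labels.append("out")
    for i in range(n_ambiguous):
        trajs.append(build(f"amb_{i}", 0.25))
        labels.append("ambiguous")
    return trajs, labels
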