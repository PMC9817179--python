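"""Quantification of LLPS appearance in nucleus images.

Three parameters characterize how punctate a nucleus looks on a z-projection:

* number of puncta — prominence-based local-maxima count inside the nucleus
  mask (``find_puncta``), matching ImageJ-style "find maxima" semantics with
  a noise tolerance;
* surface roughness — standard deviation of the normalized pixel intensities
  across the nucleus mask;
* punctate percentage — fraction of total nuclear fluorescence (sum
  z-projection) falling inside per-punctum disks whose diameter is the
  punctum's maximum FWHM over 36 radial slices.

Live and fixed images of the same cell are compared as percent changes of
these parameters, 100 * (fixed - live) / live.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "NucleusStack",
    "NucleusMask",
    "Punctum",
    "PunctaQuantResult",
    "PairedChange",
    "project",
    "normalize_to_mask",
    "find_puncta",
    "surface_roughness",
    "refine_center_and_fwhm",
    "punctate_percentage",
    "quantify",
    "compare_live_fixed",
    "estimate_nucleus_mask",
]

PARAMETERS = ("n_puncta", "surface_roughness", "punctate_percentage")


@dataclass
class NucleusStack:
    """3-D fluorescence stack indexed (z, y, x), with optional pixel size in um."""

    voxels: np.ndarray
    pixel_size: float | None = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim == 2:
            self.voxels = self.voxels[None]
        if self.voxels.ndim != 3 or self.voxels.shape[0] < 1:
            raise ValueError("stack must be (z, y, x) with >= 1 plane")
        if not np.all(np.isfinite(self.voxels)) or np.any(self.voxels < 0):
            raise ValueError("stack intensities must be finite and non-negative")


@dataclass
class NucleusMask:
    """2-D boolean nucleus region, same (y, x) shape as the projections."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels).astype(bool)
        if self.pixels.ndim != 2 or not self.pixels.any():
            raise ValueError("mask must be a non-empty 2-D boolean array")
        _, n = ndimage.label(self.pixels, structure=np.ones((3, 3)))
        if n > 1:
            warnings.warn(f"nucleus mask has {n} connected regions; expected 1")


@dataclass
class Punctum:
    preliminary_center: tuple[int, int]
    refined_center: tuple[float, float]
    fwhm: float
    resolved: bool = True


@dataclass
class PunctaQuantResult:
    """The three LLPS parameters for one cell image."""

    n_puncta: int
    surface_roughness: float
    punctate_percentage: float
    puncta: list[Punctum] = field(default_factory=list)
    noise_tolerance: float | None = None  # as specified by the caller
    tolerance_units: str = "normalized"

    def as_dict(self) -> dict[str, float]:
        return {
            "n_puncta": float(self.n_puncta),
            "surface_roughness": self.surface_roughness,
            "punctate_percentage": self.punctate_percentage,
        }


@dataclass
class PairedChange:
    """Live-to-fixed change of each LLPS parameter for one cell.

    percent_change is 100 * (fixed - live) / live and is flagged invalid
    (NaN, valid=False) for parameters whose live value is zero.
    """

    percent_change: dict[str, float]
    absolute_change: dict[str, float]
    valid: dict[str, bool]


def _as_stack(stack) -> np.ndarray:
    if isinstance(stack, NucleusStack):
        return stack.voxels
    return NucleusStack(np.asarray(stack)).voxels


def _as_mask(mask) -> np.ndarray:
    if isinstance(mask, NucleusMask):
        return mask.pixels
    arr = np.asarray(mask)
    if arr.ndim != 2 or not arr.astype(bool).any():
        raise ValueError("mask must be a non-empty 2-D boolean array")
    return arr.astype(bool)


def project(stack, method: str = "max") -> np.ndarray:
    """Z-projection of the stack: element-wise ``max`` or ``sum`` across planes."""
    voxels = _as_stack(stack)
    if method == "max":
        return voxels.max(axis=0)
    if method == "sum":
        return voxels.sum(axis=0)
    raise ValueError(f"unknown projection method {method!r}; use 'max' or 'sum'")


def normalize_to_mask(image: np.ndarray, mask) -> np.ndarray:
    """Scale so the intensities inside the nucleus sum to 1; zero outside."""
    m = _as_mask(mask)
    img = np.asarray(image, dtype=float)
    if img.shape != m.shape:
        raise ValueError(f"image shape {img.shape} != mask shape {m.shape}")
    total = img[m].sum()
    if total <= 0:
        raise ValueError("masked image has zero total intensity; cannot normalize")
    out = np.where(m, img / total, 0.0)
    return out


def find_puncta(
    image: np.ndarray,
    mask,
    noise_tolerance: float,
    *,
    exclude_edge: bool = False,
) -> list[tuple[int, int]]:
    """Prominence-based local maxima of ``image`` restricted to ``mask``.

    A candidate is a (plateau-aware) local maximum over the 8-connected masked
    neighborhood; it is reported when its prominence — its height above the
    highest saddle connecting it to any higher masked maximum (or above its
    component minimum if there is no higher maximum) — strictly exceeds
    ``noise_tolerance``.  Among maxima whose separation is below tolerance
    only the highest survives, ties going to the earliest pixel in row-major
    order.  Each plateau contributes one representative point (its rounded
    centroid).  Returned points are ordered by decreasing peak height.
    """
    if noise_tolerance < 0:
        raise ValueError("noise_tolerance must be >= 0")
    m = _as_mask(mask)
    img = np.asarray(image, dtype=float)
    if img.shape != m.shape:
        raise ValueError("image and mask shapes differ")

    h, w = img.shape
    idx = np.flatnonzero(m.ravel())
    vals = img.ravel()[idx]
    # descending value, row-major tie-break
    order = idx[np.lexsort((idx, -vals))]
    rank = np.full(h * w, -1, dtype=np.int64)
    rank[order] = np.arange(order.size)

    parent = {}
    peak_val = {}
    peak_idx = {}
    alive = {}

    def find(a: int) -> int:
        root = a
        while parent[root] != root:
            root = parent[root]
        while parent[a] != root:
            parent[a], a = root, parent[a]
        return root

    accepted: list[int] = []
    flat = img.ravel()
    for pos, p in enumerate(order):
        py, px = divmod(p, w)
        v = flat[p]
        roots = []
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if dy == 0 and dx == 0:
                    continue
                ny, nx = py + dy, px + dx
                if 0 <= ny < h and 0 <= nx < w:
                    q = ny * w + nx
                    if rank[q] != -1 and rank[q] < pos:
                        r = find(q)
                        if r not in roots:
                            roots.append(r)
        if not roots:
            parent[p] = p
            peak_val[p] = v
            peak_idx[p] = p
            alive[p] = True
            continue
        # winner: highest peak; ties -> earliest-processed peak
        winner = min(roots, key=lambda r: rank[peak_idx[r]])
        for r in roots:
            if r is winner or r == winner:
                continue
            if alive[r]:
                if peak_val[r] - v > noise_tolerance:
                    accepted.append(peak_idx[r])
                alive[r] = False
            parent[r] = winner
        parent[p] = winner

    # components never absorbed: prominence relative to their own minimum
    seen = set()
    for p in reversed(order):  # reversed: minima encountered first per component
        r = find(p)
        if r in seen:
            continue
        seen.add(r)
        if alive[r] and peak_val[r] - flat[p] > noise_tolerance:
            accepted.append(peak_idx[r])

    accepted.sort(key=lambda q: rank[q])
    centers = []
    for p in accepted:
        py, px = divmod(p, w)
        cy, cx = _plateau_centroid(img, m, py, px)
        if exclude_edge and _touches_mask_edge(m, cy, cx, img, py, px):
            continue
        centers.append((cy, cx))
    return centers


def _plateau_centroid(img: np.ndarray, mask: np.ndarray, py: int, px: int) -> tuple[int, int]:
    """Rounded centroid of the equal-valued 8-connected plateau containing (py, px)."""
    level = img[py, px]
    plateau = (img == level) & mask
    lab, _ = ndimage.label(plateau, structure=np.ones((3, 3)))
    region = lab == lab[py, px]
    ys, xs = np.nonzero(region)
    return int(round(ys.mean())), int(round(xs.mean()))


def _touches_mask_edge(mask, cy, cx, img, py, px) -> bool:
    level = img[py, px]
    plateau = (img == level) & mask
    lab, _ = ndimage.label(plateau, structure=np.ones((3, 3)))
    region = lab == lab[py, px]
    interior = ndimage.binary_erosion(mask, structure=np.ones((3, 3)), border_value=0)
    return bool(np.any(region & ~interior))


def surface_roughness(image: np.ndarray, mask) -> float:
    """Population standard deviation of the masked pixel intensities."""
    m = _as_mask(mask)
    if m.sum() < 2:
        raise ValueError("surface roughness needs >= 2 masked pixels")
    return float(np.std(np.asarray(image, dtype=float)[m]))


def refine_center_and_fwhm(
    image: np.ndarray,
    preliminary_center: tuple[int, int],
    n_slices: int = 36,
    max_half_length: float = 30.0,
    step: float = 0.25,
) -> Punctum:
    """Punctum diameter as the maximum FWHM over radial slices.

    ``n_slices`` diameters through the preliminary center (default 36, i.e.
    5-degree increments over 180 degrees) are sampled by bilinear
    interpolation at ``step``-pixel resolution.  Each profile's FWHM is
    measured at half maximum above its own minimum (local baseline); the
    largest FWHM is the slice through the true punctum center, and the
    midpoint of its half-maximum crossings refines the center.  A punctum
    whose profile never falls below half maximum on some side of every slice
    is flagged unresolved.
    """
    img = np.asarray(image, dtype=float)
    cy, cx = preliminary_center
    if not (0 <= cy < img.shape[0] and 0 <= cx < img.shape[1]):
        raise ValueError(f"preliminary center {preliminary_center} outside image")
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")

    u = np.arange(-max_half_length, max_half_length + step / 2, step)
    ic = int(np.argmin(np.abs(u)))
    best_fwhm = -np.inf
    best_center = (float(cy), float(cx))
    resolved_any = False
    for k in range(n_slices):
        theta = math.pi * k / n_slices
        dy, dx = math.cos(theta), math.sin(theta)
        ys = cy + u * dy
        xs = cx + u * dx
        prof = ndimage.map_coordinates(img, [ys, xs], order=1, mode="nearest")
        # hill-climb from the center to the local peak of this slice
        ip = ic
        while ip + 1 < prof.size and prof[ip + 1] > prof[ip]:
            ip += 1
        while ip - 1 >= 0 and prof[ip - 1] > prof[ip]:
            ip -= 1
        baseline = prof.min()
        amp = prof[ip] - baseline
        if amp <= 1e-9 * max(abs(prof[ip]), 1e-300):
            continue  # flat slice: no measurable width
        half = baseline + amp / 2.0
        left = _crossing(prof, u, ip, half, direction=-1)
        right = _crossing(prof, u, ip, half, direction=+1)
        if left is None or right is None:
            continue
        resolved_any = True
        fwhm = right - left
        if fwhm > best_fwhm:
            best_fwhm = fwhm
            mid = (left + right) / 2.0
            best_center = (cy + mid * dy, cx + mid * dx)
    if not resolved_any:
        warnings.warn(
            f"punctum at {preliminary_center} unresolved within half-length "
            f"{max_half_length}px; excluded from disk-based metrics"
        )
        return Punctum((cy, cx), (float(cy), float(cx)), float("nan"), resolved=False)
    return Punctum((cy, cx), best_center, float(best_fwhm), resolved=True)


def _crossing(prof, u, ip, half, direction):
    """Sub-sample position where the profile first falls below ``half``."""
    i = ip
    while 0 <= i + direction < prof.size:
        j = i + direction
        if prof[j] < half:
            # linear interpolation between samples i and j
            frac = (prof[i] - half) / (prof[i] - prof[j])
            return u[i] + frac * (u[j] - u[i])
        i = j
    return None


def punctate_percentage(stack, mask, puncta: list[Punctum]) -> float:
    """Percent of nuclear sum-projection intensity inside the punctum disks.

    Each resolved punctum contributes a disk of diameter FWHM centered at its
    refined center; overlapping disks are counted once and disks are clipped
    to the nucleus mask.
    """
    m = _as_mask(mask)
    sumproj = project(stack, "sum")
    total = sumproj[m].sum()
    if total <= 0:
        raise ValueError("zero total nuclear intensity")
    disk = np.zeros_like(m)
    yy, xx = np.mgrid[0 : m.shape[0], 0 : m.shape[1]]
    for p in puncta:
        if not p.resolved or not np.isfinite(p.fwhm):
            continue
        r = p.fwhm / 2.0
        cy, cx = p.refined_center
        disk |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
    disk &= m
    return float(100.0 * sumproj[disk].sum() / total)


def quantify(
    stack,
    mask,
    noise_tolerance: float,
    *,
    n_slices: int = 36,
    max_half_length: float = 30.0,
    step: float = 0.25,
    exclude_edge: bool = False,
    tolerance_units: str = "normalized",
) -> PunctaQuantResult:
    """Full single-image pipeline: all three LLPS parameters for one nucleus.

    Peak finding, FWHM refinement and surface roughness operate on the
    normalized maximum z-projection; punctate percentage integrates the sum
    z-projection inside the FWHM disks.  ``noise_tolerance`` is interpreted
    on the normalized image by default; pass ``tolerance_units="raw"`` to
    give it on the scale of the input stack instead.
    """
    voxels = _as_stack(stack)
    m = _as_mask(mask)
    tol_as_given = noise_tolerance
    if tolerance_units == "raw":
        noise_tolerance = noise_tolerance / project(voxels, "max")[m].sum()
    elif tolerance_units != "normalized":
        raise ValueError("tolerance_units must be 'normalized' or 'raw'")
    maxproj = normalize_to_mask(project(voxels, "max"), m)
    centers = find_puncta(maxproj, m, noise_tolerance, exclude_edge=exclude_edge)
    puncta = [
        refine_center_and_fwhm(
            maxproj, c, n_slices=n_slices, max_half_length=max_half_length, step=step
        )
        for c in centers
    ]
    return PunctaQuantResult(
        n_puncta=len(centers),
        surface_roughness=surface_roughness(maxproj, m),
        punctate_percentage=punctate_percentage(voxels, m, puncta),
        puncta=puncta,
        noise_tolerance=tol_as_given,
        tolerance_units=tolerance_units,
    )


def compare_live_fixed(live: PunctaQuantResult, fixed: PunctaQuantResult) -> PairedChange:
    """Percent and absolute change of each LLPS parameter across fixation."""
    if (
        live.noise_tolerance is not None
        and fixed.noise_tolerance is not None
        and (live.noise_tolerance, live.tolerance_units)
        != (fixed.noise_tolerance, fixed.tolerance_units)
    ):
        raise ValueError("live and fixed images must use the same noise tolerance")
    pct, absolute, valid = {}, {}, {}
    lv, fv = live.as_dict(), fixed.as_dict()
    for p in PARAMETERS:
        absolute[p] = fv[p] - lv[p]
        if lv[p] == 0:
            pct[p] = float("nan")
            valid[p] = False
        else:
            pct[p] = 100.0 * (fv[p] - lv[p]) / lv[p]
            valid[p] = True
    return PairedChange(percent_change=pct, absolute_change=absolute, valid=valid)


def estimate_nucleus_mask(image: np.ndarray) -> np.ndarray:
    """Convenience Otsu-threshold nucleus mask (largest component, filled).

    Offered for exploratory use only; quantitative comparisons should use a
    hand-drawn or otherwise curated nucleus boundary.
    """
    from skimage.filters import threshold_otsu

    img = np.asarray(image, dtype=float)
    bw = img > threshold_otsu(img)
    lab, n = ndimage.label(bw)
    if n == 0:
        raise ValueError("no foreground found")
    largest = np.argmax(ndimage.sum_labels(bw, lab, index=np.arange(1, n + 1))) + 1
    return ndimage.binary_fill_holes(lab == largest)
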