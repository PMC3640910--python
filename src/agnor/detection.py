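"""Per-nucleus AgNOR detection and conglomerate-corrected counting.

Nucleus masks are *inputs*: in the semi-automatic workflow the tumour nuclei
are marked by the observer, and the software only measures inside them. A
particle is a connected component of sub-threshold (dark) pixels within the
mask, filtered by a minimum area. Silver-stained dots that lie so close
together that they fuse into a single component are flagged as a
*conglomerate* and given a corrected multiplicity from the ratio of their
area to a robust per-case reference particle area.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage import measure
from skimage.filters import threshold_otsu

__all__ = [
    "AgNORParticle",
    "NucleusRecord",
    "DetectionParams",
    "detect_agnors",
    "detect_case",
    "correct_count",
    "estimate_reference_area",
]


@dataclass
class AgNORParticle:
    """One detected silver-stained particle.

    ``corrected_count`` is 1 for a plain particle and >= 2 for a
    conglomerate; ``d_norm`` is the normalised radial position — centroid
    distance from the nucleus centroid divided by the centroid-to-boundary
    distance along the same ray, so 0 is central and values approach 1 at
    the nuclear border regardless of nucleus shape.
    """

    area_um2: float
    centroid_um: tuple[float, float]  # (y, x)
    d_norm: float
    is_conglomerate: bool = False
    corrected_count: int = 1
    n_pixels: int = 0

    def __post_init__(self):
        if self.area_um2 <= 0:
            raise ValueError("particle area must be > 0")
        if self.is_conglomerate and self.corrected_count < 2:
            raise ValueError("a conglomerate must carry corrected_count >= 2")
        if not self.is_conglomerate and self.corrected_count != 1:
            raise ValueError("a non-conglomerate particle has corrected_count == 1")


@dataclass
class NucleusRecord:
    """One marked nucleus with its geometry and detected particles."""

    nucleus_id: int
    area_um2: float
    centroid_um: tuple[float, float]
    particles: list[AgNORParticle] = field(default_factory=list)
    boundary_um: np.ndarray | None = None  # (N, 2) polygon, (y, x) in um

    @property
    def corrected_count(self) -> int:
        return int(sum(p.corrected_count for p in self.particles))

    @property
    def raw_count(self) -> int:
        return len(self.particles)


@dataclass(frozen=True)
class DetectionParams:
    """Measurement settings.

    ``threshold`` is either ``"otsu"`` (per-nucleus Otsu on within-mask
    intensities) or a fixed grey level; with Otsu, the split is accepted only
    when the dark/bright class means differ by at least ``min_contrast`` grey
    levels, which keeps particle-free nuclei from being carved out of noise.
    ``kappa`` (> 1) is the conglomerate area factor: a particle larger than
    kappa times the reference single-AgNOR area is treated as a fused group.
    """

    threshold: str | float = "otsu"
    min_area_px: int = 2
    kappa: float = 1.5
    calibration: float = 0.25  # um / pixel
    min_contrast: float = 25.0

    def __post_init__(self):
        if self.min_area_px < 1:
            raise ValueError("min_area_px must be >= 1 pixel")
        if self.kappa <= 1.0:
            raise ValueError("kappa must be > 1")
        if self.calibration <= 0:
            raise ValueError("calibration must be > 0")
        if isinstance(self.threshold, str) and self.threshold != "otsu":
            raise ValueError("threshold must be 'otsu' or a fixed grey level")


def correct_count(particle_area: float, reference_area: float, kappa: float = 1.5) -> int:
    """Corrected AgNOR multiplicity of one particle.

    Particles up to ``kappa * reference_area`` count as one AgNOR; anything
    larger is a conglomerate counted as ``round(area / reference_area)``
    (half up), floored at 2. Small particles never count as zero.
    """
    if particle_area <= 0 or reference_area <= 0:
        raise ValueError("areas must be > 0")
    if particle_area <= kappa * reference_area:
        return 1
    return max(2, int(math.floor(particle_area / reference_area + 0.5)))


def estimate_reference_area(areas, kappa: float = 1.5) -> float:
    """Robust single-AgNOR reference area for a case.

    One trimming pass: the median of all particle areas defines a crude
    centre; particles above ``kappa`` times that median are treated as
    conglomerates and excluded; the reference is the median of the rest.
    """
    areas = np.asarray(list(areas), dtype=float)
    if areas.size == 0:
        raise ValueError("need at least one particle to estimate a reference area")
    if np.any(areas <= 0):
        raise ValueError("areas must be > 0")
    med = float(np.median(areas))
    kept = areas[areas <= kappa * med]
    return float(np.median(kept))


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------


def _inside(mask: np.ndarray, y: float, x: float) -> bool:
    iy, ix = int(round(y)), int(round(x))
    if iy < 0 or ix < 0 or iy >= mask.shape[0] or ix >= mask.shape[1]:
        return False
    return bool(mask[iy, ix])


def ray_d_norm(mask: np.ndarray, center: tuple[float, float], point: tuple[float, float]) -> float:
    """Normalised radial position of ``point`` inside ``mask``.

    Marches from the mask centroid through the point to the boundary and
    returns (centre-to-point distance) / (centre-to-boundary distance along
    the same ray), clipped to [0, 1). A point at the centroid maps to 0.
    """
    cy, cx = center
    py, px = point
    dy, dx = py - cy, px - cx
    dist = math.hypot(dy, dx)
    if dist < 1e-9:
        return 0.0
    uy, ux = dy / dist, dx / dist
    # march outward until we leave the mask
    t_in = dist if _inside(mask, py, px) else 0.0
    t = max(t_in, 0.5)
    t_max = float(mask.shape[0] + mask.shape[1])
    while _inside(mask, cy + t * uy, cx + t * ux):
        t_in = t
        t += 0.5
        if t > t_max:
            return 0.0  # degenerate mask: treat as central
    t_out = t
    for _ in range(30):
        tm = 0.5 * (t_in + t_out)
        if _inside(mask, cy + tm * uy, cx + tm * ux):
            t_in = tm
        else:
            t_out = tm
    boundary = 0.5 * (t_in + t_out)
    if boundary < 1e-9:
        return 0.0
    return float(min(dist / boundary, 0.999))


def _threshold_level(values: np.ndarray, params: DetectionParams) -> float | None:
    """Grey level below which pixels are particle candidates, or None if flat."""
    if not isinstance(params.threshold, str):
        return float(params.threshold)
    vals = values.astype(float)
    if np.ptp(vals) < 1e-12:
        return None
    thr = float(threshold_otsu(vals))
    lo, hi = vals[vals < thr], vals[vals >= thr]
    if lo.size == 0 or hi.size == 0:
        return None
    if hi.mean() - lo.mean() < params.min_contrast:
        return None  # no meaningful dark class: particle-free nucleus
    return thr


def _measure_particles(image, mask, params: DetectionParams) -> list[AgNORParticle]:
    cal = params.calibration
    level = _threshold_level(image[mask], params)
    if level is None:
        return []
    below = (image < level) & mask
    lab = measure.label(below, connectivity=2)
    out = []
    for rp in measure.regionprops(lab):
        if rp.area < params.min_area_px:
            continue
        cy, cx = rp.centroid
        out.append(
            AgNORParticle(
                area_um2=float(rp.area) * cal * cal,
                centroid_um=(cy * cal, cx * cal),
                d_norm=0.0,  # filled in by the caller (needs the mask)
                n_pixels=int(rp.area),
            )
        )
    return out


def _finalize_record(nucleus_id, image, mask, params, particles) -> NucleusRecord:
    cal = params.calibration
    ys, xs = np.nonzero(mask)
    center = (float(ys.mean()), float(xs.mean()))
    for p in particles:
        py, px = p.centroid_um[0] / cal, p.centroid_um[1] / cal
        p.d_norm = ray_d_norm(mask, center, (py, px))
    particles.sort(key=lambda p: (-p.area_um2, p.centroid_um[0], p.centroid_um[1]))
    contours = measure.find_contours(mask.astype(float), 0.5)
    boundary = max(contours, key=len) * cal if contours else None
    return NucleusRecord(
        nucleus_id=nucleus_id,
        area_um2=float(ys.size) * cal * cal,
        centroid_um=(center[0] * cal, center[1] * cal),
        particles=particles,
        boundary_um=boundary,
    )


def _assign_conglomerates(particles: list[AgNORParticle], reference_area: float, kappa: float):
    for p in particles:
        c = correct_count(p.area_um2, reference_area, kappa)
        p.corrected_count = c
        p.is_conglomerate = c >= 2


def detect_agnors(
    image: np.ndarray,
    nucleus_mask: np.ndarray,
    params: DetectionParams | None = None,
    reference_area_um2: float | None = None,
) -> NucleusRecord:
    """Detect AgNOR particles inside one nucleus mask.

    ``nucleus_mask`` is a boolean array over the same grid as ``image``.
    When ``reference_area_um2`` is not given, the single-AgNOR reference is
    estimated from this nucleus's own particles; pass the case-level value
    (see :func:`detect_case`) for the intended per-case correction.
    """
    params = params or DetectionParams()
    image = np.asarray(image)
    nucleus_mask = np.asarray(nucleus_mask).astype(bool)
    if image.shape != nucleus_mask.shape:
        raise ValueError(f"image shape {image.shape} != mask shape {nucleus_mask.shape}")
    if not nucleus_mask.any():
        raise ValueError("empty nucleus mask")
    particles = _measure_particles(image, nucleus_mask, params)
    record = _finalize_record(1, image, nucleus_mask, params, particles)
    if particles:
        ref = reference_area_um2
        if ref is None:
            ref = estimate_reference_area([p.area_um2 for p in particles], params.kappa)
        _assign_conglomerates(record.particles, ref, params.kappa)
    return record


def detect_case(
    image: np.ndarray,
    label_mask: np.ndarray,
    params: DetectionParams | None = None,
) -> list[NucleusRecord]:
    """Detect AgNORs in every labelled nucleus of one field.

    ``label_mask`` holds 0 for background and k for nucleus k. The reference
    single-AgNOR area is estimated once from all particles of the case, then
    used to flag conglomerates and assign corrected counts in every nucleus.
    """
    params = params or DetectionParams()
    image = np.asarray(image)
    label_mask = np.asarray(label_mask)
    if image.shape != label_mask.shape:
        raise ValueError(f"image shape {image.shape} != mask shape {label_mask.shape}")
    ids = np.unique(label_mask)
    ids = ids[ids > 0]
    if ids.size == 0:
        raise ValueError("label mask contains no nuclei")
    from scipy import ndimage

    slices = ndimage.find_objects(label_mask)
    cal = params.calibration
    records = []
    for k in ids:
        sl = slices[int(k) - 1]
        sub_img = image[sl]
        sub_mask = label_mask[sl] == k
        particles = _measure_particles(sub_img, sub_mask, params)
        rec = _finalize_record(int(k), sub_img, sub_mask, params, particles)
        oy, ox = sl[0].start * cal, sl[1].start * cal
        rec.centroid_um = (rec.centroid_um[0] + oy, rec.centroid_um[1] + ox)
        for p in rec.particles:
            p.centroid_um = (p.centroid_um[0] + oy, p.centroid_um[1] + ox)
        if rec.boundary_um is not None:
            rec.boundary_um = rec.boundary_um + np.array([oy, ox])
        records.append(rec)
    all_areas = [p.area_um2 for r in records for p in r.particles]
    if all_areas:
        ref = estimate_reference_area(all_areas, params.kappa)
        for r in records:
            _assign_conglomerates(r.particles, ref, params.kappa)
    return records
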