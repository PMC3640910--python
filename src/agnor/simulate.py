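"""Seeded synthetic inputs for the AgNOR pipeline.

Two generators live here:

* :func:`generate_image_set` renders grayscale microscopy-like fields of
  elliptical tumour nuclei containing dark AgNOR dots (optionally fused into
  conglomerates), together with a label mask and an analytic ground truth.
* :func:`generate_cohort` draws a survival cohort whose hazard follows an
  exponential proportional-hazards model on a chosen covariate subset, with
  administrative and/or random right-censoring and a cause-of-death mix.

Everything is a pure function of (specification, seed): the RNG stream is
split hierarchically (field -> nucleus) with ``numpy.random.SeedSequence`` so
outputs are stable under changes of field count.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ImageScenario",
    "GroundTruth",
    "CohortEffectSpec",
    "COVARIATE_MENU",
    "AGNOR_FEATURE_NAMES",
    "CLINICAL_NAMES",
    "generate_image_set",
    "generate_cohort",
    "default_feature_distributions",
    "scenario_preset",
    "draw_survival",
    "write_image_set",
]

# ---------------------------------------------------------------------------
# distribution mini-spec
# ---------------------------------------------------------------------------
# A distribution is a tuple ("kind", *params). Supported kinds:
#   ("categorical", {value: prob})      discrete values with given probabilities
#   ("uniform", lo, hi)                 continuous uniform
#   ("normal", mu, sd[, lo, hi])        Gaussian, optionally clipped
#   ("beta", a, b)                      Beta on [0, 1]
#   ("poisson", lam)                    Poisson (truncated by the caller)


def draw_distribution(dist: tuple, rng: np.random.Generator, size=None):
    kind = dist[0]
    if kind == "categorical":
        table = dist[1]
        values = np.asarray(list(table.keys()))
        probs = np.asarray(list(table.values()), dtype=float)
        if np.any(probs < 0) or not np.isclose(probs.sum(), 1.0, atol=1e-6):
            raise ValueError("categorical probabilities must be >= 0 and sum to 1")
        idx = rng.choice(len(values), size=size, p=probs / probs.sum())
        return values[idx]
    if kind == "uniform":
        return rng.uniform(dist[1], dist[2], size=size)
    if kind == "normal":
        x = rng.normal(dist[1], dist[2], size=size)
        if len(dist) >= 5:
            x = np.clip(x, dist[3], dist[4])
        return x
    if kind == "beta":
        return rng.beta(dist[1], dist[2], size=size)
    if kind == "poisson":
        return rng.poisson(dist[1], size=size)
    raise ValueError(f"unknown distribution kind {kind!r}")


# ---------------------------------------------------------------------------
# image scenario
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ImageScenario:
    """Parameters of one synthetic histology field.

    Intensities are 8-bit grey levels; AgNORs are dark dots on lighter
    nuclei, so ``particle_intensity < nucleus_intensity`` is enforced.
    ``calibration`` is the pixel size in micrometres per pixel.
    """

    n_nuclei: int = 25
    nucleus_radius_range: tuple[float, float] = (3.5, 5.0)  # um
    agnor_count_distribution: tuple = ("poisson", 3.0)  # over counts 0..12
    agnor_radius_range: tuple[float, float] = (0.4, 0.7)  # um
    radial_position_distribution: tuple = ("beta", 2.0, 2.5)  # d_norm in [0,1)
    conglomerate_probability: float = 0.1
    background_intensity: int = 205
    nucleus_intensity: int = 150
    particle_intensity: int = 40
    noise_sd: float = 0.0
    calibration: float = 0.25  # um / pixel
    field_shape: tuple[int, int] | None = None  # (rows, cols) px; None = auto grid
    max_count: int = 12

    def __post_init__(self):
        if self.n_nuclei < 1:
            raise ValueError("n_nuclei must be >= 1")
        for name in ("nucleus_radius_range", "agnor_radius_range"):
            lo, hi = getattr(self, name)
            if lo < 0 or hi < lo:
                raise ValueError(f"{name} must be a nonnegative (lo, hi) pair")
        if not 0.0 <= self.conglomerate_probability <= 1.0:
            raise ValueError("conglomerate_probability must lie in [0, 1]")
        if not self.particle_intensity < self.nucleus_intensity:
            raise ValueError("particle_intensity must be below nucleus_intensity "
                             "(AgNORs are dark dots on lighter nuclei)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.calibration <= 0:
            raise ValueError("calibration must be > 0")

    def replace(self, **kw) -> "ImageScenario":
        return dataclasses.replace(self, **kw)


def scenario_preset(name: str, **overrides) -> ImageScenario:
    """Named scenario presets.

    ``low_variability`` emulates fields whose nuclei carry a narrow range of
    AgNOR counts, sizes and radial positions; ``high_variability`` emulates
    fields with a wide spread in number, size and location of the dots.
    """
    if name == "low_variability":
        base = ImageScenario(
            n_nuclei=25,
            nucleus_radius_range=(3.8, 4.6),
            agnor_count_distribution=("categorical", {2: 0.3, 3: 0.4, 4: 0.3}),
            agnor_radius_range=(0.45, 0.60),
            radial_position_distribution=("beta", 4.0, 6.0),
            conglomerate_probability=0.05,
            noise_sd=4.0,
        )
    elif name == "high_variability":
        base = ImageScenario(
            n_nuclei=25,
            nucleus_radius_range=(3.5, 5.5),
            agnor_count_distribution=("poisson", 4.5),
            agnor_radius_range=(0.25, 0.85),
            radial_position_distribution=("uniform", 0.0, 0.97),
            conglomerate_probability=0.25,
            noise_sd=4.0,
        )
    else:
        raise ValueError(f"unknown scenario preset {name!r}")
    return base.replace(**overrides) if overrides else base


@dataclass
class GroundTruth:
    """Analytic truth for a generated image set.

    ``particles`` has one row per individual AgNOR (conglomerate members are
    separate rows sharing ``conglomerate_group``); ``nuclei`` has one row per
    nucleus with its true (member-level) count.
    """

    particles: pd.DataFrame
    nuclei: pd.DataFrame

    def counts_per_nucleus(self, case_id: int = 0) -> pd.Series:
        nuc = self.nuclei[self.nuclei["case_id"] == case_id]
        return nuc.set_index("nucleus_id")["true_count"]


class PlacementError(RuntimeError):
    """Raised when nuclei or particles cannot be placed in the field."""


# -- geometry helpers -------------------------------------------------------


def _ellipse_ray(a: float, b: float, theta: float, phi: float) -> float:
    """Distance from the ellipse centre to its boundary along world angle phi."""
    u = np.cos(phi - theta)
    v = np.sin(phi - theta)
    return 1.0 / np.sqrt((u / a) ** 2 + (v / b) ** 2)


def _inside_ellipse(dy, dx, a, b, theta) -> bool:
    u = np.cos(theta) * dx + np.sin(theta) * dy
    v = -np.sin(theta) * dx + np.cos(theta) * dy
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _disk_fits(dy, dx, r, a, b, theta) -> bool:
    # conservative: centre must fall inside the ellipse shrunk by r + 1 px
    aa, bb = a - r - 1.0, b - r - 1.0
    if aa <= 0 or bb <= 0:
        return False
    return _inside_ellipse(dy, dx, aa, bb, theta)


def _draw_count(scenario: ImageScenario, rng: np.random.Generator) -> int:
    n = int(draw_distribution(scenario.agnor_count_distribution, rng))
    return int(np.clip(n, 0, scenario.max_count))


def _plan_nucleus(scenario: ImageScenario, rng: np.random.Generator):
    """Plan one nucleus: shape plus particle positions/radii in local px coords.

    Returns (a, b, theta, groups) where groups is a list of lists of
    (dy, dx, r_px, d_norm) member tuples. Raises PlacementError when the
    particles cannot be placed disjointly after bounded restarts.
    """
    cal = scenario.calibration
    r_um = rng.uniform(*scenario.nucleus_radius_range)
    ratio = rng.uniform(0.6, 1.0)
    theta = rng.uniform(0.0, np.pi)
    a = r_um / cal
    b = a * ratio

    n_total = _draw_count(scenario, rng)

    # split the true count into conglomerate groups of size 1-3
    sizes: list[int] = []
    remaining = n_total
    while remaining > 0:
        if remaining >= 2 and rng.random() < scenario.conglomerate_probability:
            m = int(rng.integers(2, min(3, remaining) + 1))
        else:
            m = 1
        sizes.append(m)
        remaining -= m

    radii = rng.uniform(*scenario.agnor_radius_range, size=n_total) / cal
    radii = np.maximum(radii, 0.8)  # at least ~2 px of area
    # crowding guard: cap total particle area at 18% of the nucleus area
    if n_total:
        cap = 0.18 * np.pi * a * b
        tot = np.pi * float(np.sum(radii**2))
        if tot > cap:
            radii = radii * np.sqrt(cap / tot)

    for _restart in range(40):
        placed: list[tuple[float, float, float]] = []  # (dy, dx, r) all groups
        groups: list[list[tuple[float, float, float, float]]] = []
        k = 0
        ok = True
        for m in sizes:
            rs = radii[k : k + m]
            k += m
            group = _place_group(rs, a, b, theta, placed, scenario, rng)
            if group is None:
                ok = False
                break
            groups.append(group)
            placed.extend((gy, gx, gr) for gy, gx, gr, _ in group)
        if ok:
            return a, b, theta, n_total, groups
    raise PlacementError(
        f"could not place {n_total} AgNOR particles inside a nucleus of "
        f"semi-axes ({a:.1f}, {b:.1f}) px after bounded restarts"
    )


def _place_group(rs, a, b, theta, placed, scenario, rng):
    """Place one conglomerate group (1-3 touching members), disjoint from others."""
    for _try in range(200):
        d_target = float(draw_distribution(scenario.radial_position_distribution, rng))
        d_target = min(max(d_target, 0.0), 0.98)
        phi = rng.uniform(0.0, 2 * np.pi)
        ray = _ellipse_ray(a, b, theta, phi)
        t = d_target * ray
        r0 = rs[0]
        dy0, dx0 = t * np.sin(phi), t * np.cos(phi)
        if not _disk_fits(dy0, dx0, r0, a, b, theta):
            continue
        members = [(dy0, dx0, float(r0))]
        good = True
        for rm in rs[1:]:
            for _mt in range(60):
                psi = rng.uniform(0.0, 2 * np.pi)
                s = rng.uniform(0.55, 0.90) * (members[-1][2] + rm)
                my = members[-1][0] + s * np.sin(psi)
                mx = members[-1][1] + s * np.cos(psi)
                if _disk_fits(my, mx, rm, a, b, theta):
                    members.append((my, mx, float(rm)))
                    break
            else:
                good = False
                break
        if not good:
            continue
        # disjointness from other groups (gap of 1.6 px between boundaries)
        clear = all(
            np.hypot(my - py, mx - px) >= mr + pr + 1.6
            for (my, mx, mr) in members
            for (py, px, pr) in placed
        )
        if not clear:
            continue
        out = []
        for my, mx, mr in members:
            dist = float(np.hypot(my, mx))
            if dist < 1e-9:
                dn = 0.0
            else:
                ang = float(np.arctan2(my, mx))
                dn = dist / _ellipse_ray(a, b, theta, ang)
            out.append((my, mx, mr, min(dn, 0.999)))
        return out
    return None


def _render_field(scenario: ImageScenario, rng_children, noise_rng, field_id: int):
    """Render one field: returns (image uint8, labels uint16, particle rows, nucleus rows)."""
    cal = scenario.calibration
    max_r_px = scenario.nucleus_radius_range[1] / cal
    cell = int(np.ceil(2 * max_r_px + 8))

    n = scenario.n_nuclei
    if scenario.field_shape is None:
        g = int(np.ceil(np.sqrt(n)))
        shape = (g * cell + 4, g * cell + 4)
        centers_grid = [
            (4 + cell // 2 + (i // g) * cell, 4 + cell // 2 + (i % g) * cell)
            for i in range(n)
        ]
    else:
        shape = tuple(scenario.field_shape)
        centers_grid = None

    img = np.full(shape, float(scenario.background_intensity))
    labels = np.zeros(shape, dtype=np.uint16)

    particle_rows = []
    nucleus_rows = []
    group_counter = 0
    occupied: list[tuple[float, float, float]] = []  # (cy, cx, a) for random placement

    for i in range(n):
        rng = np.random.default_rng(rng_children[i])
        a, b, theta, true_count, groups = _plan_nucleus(scenario, rng)

        if centers_grid is not None:
            base_y, base_x = centers_grid[i]
            jit = max(cell / 2 - a - 2.0, 0.0)
            cy = base_y + rng.uniform(-jit, jit)
            cx = base_x + rng.uniform(-jit, jit)
        else:
            cy = cx = None
            for _try in range(300):
                ty = rng.uniform(a + 2, shape[0] - a - 2)
                tx = rng.uniform(a + 2, shape[1] - a - 2)
                if all(np.hypot(ty - oy, tx - ox) >= a + oa + 3 for oy, ox, oa in occupied):
                    cy, cx = ty, tx
                    break
            if cy is None:
                raise PlacementError(
                    f"could not place nucleus {i + 1} in a field of shape {shape}: "
                    "field too small for the requested nuclei"
                )
            occupied.append((cy, cx, a))

        # rasterise the ellipse
        y0, y1 = int(np.floor(cy - a - 1)), int(np.ceil(cy + a + 2))
        x0, x1 = int(np.floor(cx - a - 1)), int(np.ceil(cx + a + 2))
        yy, xx = np.mgrid[y0:y1, x0:x1]
        dy, dx = yy - cy, xx - cx
        u = np.cos(theta) * dx + np.sin(theta) * dy
        v = -np.sin(theta) * dx + np.cos(theta) * dy
        inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        img[y0:y1, x0:x1][inside] = scenario.nucleus_intensity
        labels[y0:y1, x0:x1][inside] = i + 1

        # particles: anti-aliased dark disks, coverage combined with max
        cov = np.zeros_like(img[y0:y1, x0:x1])
        for gi, group in enumerate(groups):
            group_counter += 1
            for pj, (py, px, pr, dn) in enumerate(group):
                wy, wx = cy + py, cx + px
                dist = np.hypot(yy - wy, xx - wx)
                cov = np.maximum(cov, np.clip(pr - dist + 0.5, 0.0, 1.0))
                particle_rows.append(
                    dict(
                        case_id=field_id,
                        nucleus_id=i + 1,
                        particle_id=len(particle_rows) + 1,
                        area_um2=np.pi * (pr * cal) ** 2,
                        x_um=wx * cal,
                        y_um=wy * cal,
                        d_norm=dn,
                        conglomerate_group=group_counter,
                        group_size=len(group),
                        true_count=true_count,
                    )
                )
        cov[~inside] = 0.0
        patch = img[y0:y1, x0:x1]
        img[y0:y1, x0:x1] = patch + (scenario.particle_intensity - patch) * cov

        nucleus_rows.append(
            dict(
                case_id=field_id,
                nucleus_id=i + 1,
                true_count=true_count,
                centroid_y_um=cy * cal,
                centroid_x_um=cx * cal,
                semi_major_um=a * cal,
                semi_minor_um=b * cal,
                angle_rad=theta,
            )
        )

    if scenario.noise_sd > 0:
        img = img + noise_rng.normal(0.0, scenario.noise_sd, size=img.shape)
    return np.clip(np.round(img), 0, 255).astype(np.uint8), labels, particle_rows, nucleus_rows


_PARTICLE_COLUMNS = [
    "case_id", "nucleus_id", "particle_id", "area_um2", "x_um", "y_um",
    "d_norm", "conglomerate_group", "group_size", "true_count",
]
_NUCLEUS_COLUMNS = [
    "case_id", "nucleus_id", "true_count", "centroid_y_um", "centroid_x_um",
    "semi_major_um", "semi_minor_um", "angle_rad",
]


def generate_image_set(
    scenario: ImageScenario, seed: int, n_fields: int = 1
) -> tuple[list[np.ndarray], list[np.ndarray], GroundTruth]:
    """Render ``n_fields`` grayscale fields with label masks and ground truth.

    Identical ``(scenario, seed)`` give identical arrays. Every ground-truth
    particle lies strictly inside its nucleus; a field too small for the
    requested nuclei raises :class:`PlacementError` rather than silently
    truncating.
    """
    root = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0xA6_0B])
    field_seeds = root.spawn(n_fields)
    images, masks = [], []
    all_particles, all_nuclei = [], []
    for f in range(n_fields):
        children = field_seeds[f].spawn(scenario.n_nuclei + 1)
        noise_rng = np.random.default_rng(children[-1])
        img, lab, prows, nrows = _render_field(scenario, children[:-1], noise_rng, f)
        images.append(img)
        masks.append(lab)
        all_particles.extend(prows)
        all_nuclei.extend(nrows)
    particles = pd.DataFrame(all_particles, columns=_PARTICLE_COLUMNS)
    nuclei = pd.DataFrame(all_nuclei, columns=_NUCLEUS_COLUMNS)
    return images, masks, GroundTruth(particles=particles, nuclei=nuclei)


def write_image_set(outdir, images, masks, gt: GroundTruth, prefix: str = "field"):
    """Write fields as 8-bit grayscale TIFF, masks as 16-bit label TIFF, truth as CSV."""
    import tifffile
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, (img, lab) in enumerate(zip(images, masks)):
        ip = outdir / f"{prefix}_{i:03d}.tif"
        mp = outdir / f"{prefix}_{i:03d}_labels.tif"
        tifffile.imwrite(ip, img)
        tifffile.imwrite(mp, lab)
        paths.append((ip, mp))
    gt.particles.to_csv(outdir / "ground_truth_particles.csv", index=False)
    gt.nuclei.to_csv(outdir / "ground_truth_nuclei.csv", index=False)
    return paths


# ---------------------------------------------------------------------------
# survival cohorts
# ---------------------------------------------------------------------------

AGNOR_FEATURE_NAMES = [
    "nornbc_m", "nor_k1", "nor_k2", "nor_k3", "nor_k4", "nor_k5", "nor_k6",
    "nor_k7", "nor_k8", "snar_r_v", "center_v", "cent_r_v", "bord_r_v",
    "locat_v", "mnrat2_m",
]
CLINICAL_NAMES = ["pT", "pN", "G", "pkt_grad", "polym"]
COVARIATE_MENU = CLINICAL_NAMES + AGNOR_FEATURE_NAMES


@dataclass(frozen=True)
class CohortEffectSpec:
    """True hazard structure for a simulated cohort.

    ``coefficients`` maps covariate names to log hazard ratios; the event
    rate for case i is ``baseline_hazard * exp(sum_j beta_j x_ij)`` (events
    per month). Censoring combines an administrative horizon and/or an
    independent exponential censoring rate; ``cause_mix`` is the probability
    that an event is a breast-cancer death (the remainder die of other causes).
    """

    coefficients: dict[str, float] = field(default_factory=dict)
    baseline_hazard: float = 0.005
    admin_censor_months: float | None = 240.0
    censor_rate: float | None = None
    cause_mix: float = 0.8

    def __post_init__(self):
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")
        if not 0.0 <= self.cause_mix <= 1.0:
            raise ValueError("cause_mix must lie in [0, 1]")
        if self.censor_rate is not None and self.censor_rate < 0:
            raise ValueError("censor_rate must be >= 0")


def default_feature_distributions() -> dict[str, tuple]:
    """Marginal sampling distributions for the full covariate menu.

    Clinical covariates are ordinal categoricals with frequencies typical of
    an unselected breast-carcinoma series; AgNOR features are clipped
    Gaussians on the scales the detection pipeline produces (counts per
    nucleus, percentages of nuclei, per-mille area ratios, d_norm spreads).
    """
    return {
        "pT": ("categorical", {1: 0.35, 2: 0.45, 3: 0.12, 4: 0.08}),
        "pN": ("categorical", {0: 0.55, 1: 0.30, 2: 0.10, 3: 0.05}),
        "G": ("categorical", {1: 0.15, 2: 0.55, 3: 0.30}),
        "pkt_grad": ("categorical", {3: 0.06, 4: 0.12, 5: 0.2, 6: 0.24, 7: 0.2, 8: 0.12, 9: 0.06}),
        "polym": ("categorical", {1: 0.20, 2: 0.50, 3: 0.30}),
        "nornbc_m": ("normal", 2.5, 0.8, 0.2, 12.0),
        "nor_k1": ("normal", 30.0, 10.0, 0.0, 100.0),
        "nor_k2": ("normal", 25.0, 8.0, 0.0, 100.0),
        "nor_k3": ("normal", 15.0, 6.0, 0.0, 100.0),
        "nor_k4": ("normal", 8.0, 4.0, 0.0, 100.0),
        "nor_k5": ("normal", 5.0, 3.0, 0.0, 100.0),
        "nor_k6": ("normal", 3.0, 2.0, 0.0, 100.0),
        "nor_k7": ("normal", 2.0, 1.5, 0.0, 100.0),
        "nor_k8": ("normal", 1.5, 1.2, 0.0, 100.0),
        "snar_r_v": ("normal", 120.0, 40.0, 0.0, 400.0),
        "center_v": ("normal", 0.12, 0.04, 0.0, 0.6),
        "cent_r_v": ("normal", 0.25, 0.08, 0.0, 0.7),
        "bord_r_v": ("normal", 0.20, 0.07, 0.0, 0.7),
        "locat_v": ("normal", 0.06, 0.02, 0.0, 0.25),
        "mnrat2_m": ("normal", 550.0, 120.0, 50.0, 1000.0),
    }


def baseline_for_event_fraction(
    coefficients: dict[str, float],
    target_fraction: float,
    horizon_months: float,
    feature_distributions: dict[str, tuple] | None = None,
    n_probe: int = 20000,
    seed: int = 12345,
) -> float:
    """Baseline hazard giving an expected event fraction under administrative
    censoring at ``horizon_months``.

    Solves E_x[1 - exp(-lam0 * exp(beta'x) * horizon)] = target by bisection
    on a large probe draw of the covariate distributions. Used to pin study
    conditions (e.g. a 30%-event cohort) independently of the effect sizes.
    """
    from scipy.optimize import brentq

    if not 0.0 < target_fraction < 1.0:
        raise ValueError("target_fraction must lie in (0, 1)")
    dists = feature_distributions or default_feature_distributions()
    rng = np.random.default_rng(seed)
    lin = np.zeros(n_probe)
    for name, beta in coefficients.items():
        lin += beta * np.asarray(draw_distribution(dists[name], rng, size=n_probe), dtype=float)
    rel = np.exp(lin - lin.mean())
    scale = np.exp(lin.mean())

    def frac(lam0):
        return float(np.mean(1.0 - np.exp(-lam0 * scale * rel * horizon_months))) - target_fraction

    return float(brentq(frac, 1e-12, 1e3, maxiter=200))


def draw_survival(
    X: pd.DataFrame, effects: CohortEffectSpec, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw (time_months, event, cause) for covariate rows ``X``.

    Event times are exponential with rate ``baseline * exp(X @ beta)``; the
    observed time is the minimum of the event time and the censoring time.
    """
    unknown = set(effects.coefficients) - set(X.columns)
    if unknown:
        raise ValueError(f"effect coefficients refer to unknown covariates: {sorted(unknown)}")
    n = len(X)
    lin = np.zeros(n)
    for name, beta in effects.coefficients.items():
        lin += beta * X[name].to_numpy(dtype=float)
    rate = effects.baseline_hazard * np.exp(lin)
    t_event = rng.exponential(1.0 / rate)
    t_cens = np.full(n, np.inf)
    if effects.censor_rate is not None and effects.censor_rate > 0:
        t_cens = rng.exponential(1.0 / effects.censor_rate, size=n)
    if effects.admin_censor_months is not None:
        t_cens = np.minimum(t_cens, effects.admin_censor_months)
    event = (t_event <= t_cens).astype(int)
    time = np.where(event == 1, t_event, t_cens)
    is_bc = rng.random(n) < effects.cause_mix
    cause = np.where(event == 1, np.where(is_bc, "breast_cancer", "other"), "none")
    return pd.DataFrame({"time_months": time, "event": event, "cause": cause}, index=X.index)


def generate_cohort(
    n: int,
    effects: CohortEffectSpec,
    feature_distributions: dict[str, tuple] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a survival cohort with the full covariate menu.

    Returns one row per case: ``case_id``, every covariate, ``time_months``,
    ``event`` (0/1) and ``cause`` ({breast_cancer, other, none}).
    """
    if n < 2:
        raise ValueError("need n >= 2 cases")
    dists = feature_distributions or default_feature_distributions()
    unknown = set(effects.coefficients) - set(dists)
    if unknown:
        raise ValueError(f"effect coefficients refer to unknown covariates: {sorted(unknown)}")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0xC0_47]))
    X = pd.DataFrame({name: draw_distribution(d, rng, size=n) for name, d in dists.items()})
    surv = draw_survival(X, effects, rng)
    out = pd.concat([X, surv], axis=1)
    out.insert(0, "case_id", np.arange(1, n + 1))
    return out
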