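"""End-to-end orchestration: images -> detection -> features -> survival.

Two input modes:

* ``synthetic`` — per case, render a field of nuclei, detect AgNORs inside
  the known label masks, compute the case feature vector, draw clinical
  covariates, and simulate survival whose hazard depends (through the
  configured effect spec) on the *ground-truth* feature values; the
  analysis then runs on the *detected* features, exactly as it would on
  real material.
* ``images`` — load user-supplied image/mask pairs plus a clinical CSV and
  run the same detection/feature/survival chain.

Every run writes a manifest (config hash, seed, versions) and is
byte-reproducible for identical configs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .detection import DetectionParams, detect_case
from .features import (
    ZoneDefinition,
    features_from_records,
    records_from_ground_truth,
)
from .simulate import (
    CLINICAL_NAMES,
    CohortEffectSpec,
    ImageScenario,
    default_feature_distributions,
    draw_distribution,
    draw_survival,
    generate_image_set,
    scenario_preset,
)
from .survival import (
    ENDPOINTS,
    CoxBackwardStepwise,
)

logger = logging.getLogger("agnor")

__all__ = ["RunConfig", "RunReport", "run_pipeline", "load_config"]

DEFAULT_COVARIATES = ["pT", "pN", "G", "pkt_grad", "polym", "mnrat2_m", "locat_v"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one input mode applies. In synthetic mode each case gets its own
    field rendered from ``scenario``; the per-case mean AgNOR count is drawn
    uniformly from ``count_lambda_range`` (truncated-Poisson counts), which
    is what makes the AgNOR features vary across cases.
    """

    mode: str = "synthetic"  # "synthetic" | "images"
    # synthetic mode
    scenario: ImageScenario | str = "high_variability"
    n_cases: int = 80
    nuclei_per_case: int = 12
    count_lambda_range: tuple[float, float] = (1.5, 7.0)
    effects: CohortEffectSpec = field(default_factory=CohortEffectSpec)
    # images mode
    cases: list[dict] = field(default_factory=list)  # {case_id, image, mask}
    clinical_csv: str | None = None
    # shared analysis settings
    detection: DetectionParams = field(default_factory=DetectionParams)
    zones: ZoneDefinition = field(default_factory=ZoneDefinition)
    covariates: list[str] = field(default_factory=lambda: list(DEFAULT_COVARIATES))
    endpoints: list[str] = field(default_factory=lambda: list(ENDPOINTS))
    p_remove: float = 0.10
    seed: int | None = 0
    outdir: str | None = None

    def __post_init__(self):
        if self.mode not in ("synthetic", "images"):
            raise ValueError("mode must be 'synthetic' or 'images'")
        if self.mode == "synthetic" and self.seed is None:
            raise ValueError("synthetic mode requires a seed")
        for ep in self.endpoints:
            if ep not in ENDPOINTS:
                raise ValueError(f"unknown endpoint {ep!r}")

    def resolved_scenario(self) -> ImageScenario:
        sc = self.scenario
        if isinstance(sc, str):
            sc = scenario_preset(sc)
        return sc.replace(n_nuclei=self.nuclei_per_case)

    def config_hash(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return {k: enc(v) for k, v in dataclasses.asdict(o).items()}
            if isinstance(o, (list, tuple)):
                return [enc(v) for v in o]
            if isinstance(o, dict):
                return {str(k): enc(v) for k, v in o.items()}
            if isinstance(o, (np.integer, np.floating)):
                return o.item()
            return o

        blob = json.dumps(enc(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()


@dataclass
class RunReport:
    """In-memory results of one pipeline run plus the files written."""

    features: pd.DataFrame
    cohort: pd.DataFrame
    truth_features: pd.DataFrame | None
    stepwise: dict
    case_processing: dict
    km: dict
    manifest: dict
    paths: dict = field(default_factory=dict)


def _synthetic_cohort(config: RunConfig):
    sc = config.resolved_scenario()
    root = np.random.SeedSequence([int(config.seed) & 0x7FFFFFFF, 0x91_6E])
    case_seeds = root.spawn(config.n_cases + 1)
    clin_rng = np.random.default_rng(case_seeds[-1])

    dists = default_feature_distributions()
    det_rows, truth_rows = {}, {}
    for i in range(config.n_cases):
        ss = case_seeds[i]
        rng = np.random.default_rng(ss)
        lam = rng.uniform(*config.count_lambda_range)
        sc_i = sc.replace(agnor_count_distribution=("poisson", float(lam)))
        img_seed = int(rng.integers(0, 2**31 - 1))
        images, masks, gt = generate_image_set(sc_i, seed=img_seed, n_fields=1)
        records = detect_case(images[0], masks[0], config.detection)
        det_rows[i + 1] = features_from_records(records, config.zones).to_series()
        truth_records = records_from_ground_truth(gt.particles, gt.nuclei, case_id=0)
        truth_rows[i + 1] = features_from_records(truth_records, config.zones).to_series()

    features = pd.DataFrame.from_dict(det_rows, orient="index")
    truth = pd.DataFrame.from_dict(truth_rows, orient="index")
    features.index.name = truth.index.name = "case_id"

    clinical = pd.DataFrame(
        {name: draw_distribution(dists[name], clin_rng, size=config.n_cases)
         for name in CLINICAL_NAMES},
        index=features.index,
    )
    # the true hazard acts on the truth-side features + clinical covariates
    design = pd.concat([truth, clinical], axis=1)
    surv = draw_survival(design, config.effects, clin_rng)
    cohort = pd.concat([features, clinical, surv], axis=1).reset_index()
    return features.reset_index(), truth.reset_index(), cohort


def _images_cohort(config: RunConfig):
    import tifffile

    if not config.cases or config.clinical_csv is None:
        raise ValueError("images mode needs case image/mask paths and a clinical CSV")
    rows = {}
    for entry in config.cases:
        cid = entry["case_id"]
        image = tifffile.imread(entry["image"])
        mask = tifffile.imread(entry["mask"])
        try:
            records = detect_case(image, mask, config.detection)
        except Exception as exc:
            raise RuntimeError(f"detection failed for case {cid!r}: {exc}") from exc
        rows[cid] = features_from_records(records, config.zones).to_series()
    features = pd.DataFrame.from_dict(rows, orient="index")
    features.index.name = "case_id"
    clinical = pd.read_csv(config.clinical_csv)
    cohort = features.reset_index().merge(clinical, on="case_id", how="inner")
    return features.reset_index(), None, cohort


def run_pipeline(config: RunConfig) -> RunReport:
    """Run the full chain and (optionally) write the report bundle.

    Stages: simulate/load images -> detect -> case features -> join clinical
    -> per-endpoint case-processing summary, backward stepwise Cox, KM curve.
    Any stage error aborts with the stage and case identified in the log.
    """
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
        fh = logging.FileHandler(outdir / "run.log")
        fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        logger.addHandler(fh)
    try:
        logger.info("stage: input (%s mode)", config.mode)
        if config.mode == "synthetic":
            features, truth, cohort = _synthetic_cohort(config)
        else:
            features, truth, cohort = _images_cohort(config)

        stepwise, case_proc, km = {}, {}, {}
        for ep in config.endpoints:
            logger.info("stage: survival (%s)", ep)
            model = CoxBackwardStepwise(cohort, config.covariates, endpoint=ep)
            case_proc[ep] = model.case_processing()
            res = model.fit(p_remove=config.p_remove)
            stepwise[ep] = res
            km[ep] = model.km()

        manifest = {
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "mode": config.mode,
            "n_cases": len(cohort),
            "versions": _versions(),
        }
        report = RunReport(
            features=features, cohort=cohort, truth_features=truth,
            stepwise=stepwise, case_processing=case_proc, km=km, manifest=manifest,
        )
        if outdir:
            _write_report(outdir, config, report)
        return report
    finally:
        if outdir:
            logger.removeHandler(fh)
            fh.close()


def _versions() -> dict:
    import lifelines
    import skimage
    import statsmodels

    return {
        "agnor": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "statsmodels": statsmodels.__version__,
        "lifelines": lifelines.__version__,
        "scikit-image": skimage.__version__,
    }


def _write_report(outdir: Path, config: RunConfig, report: RunReport):
    report.features.to_csv(outdir / "features.csv", index=False)
    report.cohort.to_csv(outdir / "cohort.csv", index=False)
    if report.truth_features is not None:
        report.truth_features.to_csv(outdir / "ground_truth_features.csv", index=False)
    for ep, res in report.stepwise.items():
        res.trace.to_frame().to_csv(outdir / f"stepwise_{ep}.csv", index=False)
    for ep, cp in report.case_processing.items():
        cp.to_frame().to_csv(outdir / f"case_processing_{ep}.csv", index=False)
    for ep, km in report.km.items():
        km.to_csv(outdir / f"km_{ep}.csv", index=False)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(report.manifest, fh, indent=2, sort_keys=True)
    report.paths = {p.name: str(p) for p in sorted(outdir.iterdir())}


# ---------------------------------------------------------------------------
# YAML config loading
# ---------------------------------------------------------------------------


def load_config(path) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML file.

    Nested sections ``scenario`` (ImageScenario fields or a preset name),
    ``effects`` (CohortEffectSpec fields), ``detection`` and ``zones`` map
    onto the corresponding dataclasses.
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kw = dict(raw)
    sc = kw.pop("scenario", "high_variability")
    if isinstance(sc, dict):
        preset = sc.pop("preset", None)
        for key in ("nucleus_radius_range", "agnor_radius_range", "field_shape"):
            if key in sc and sc[key] is not None:
                sc[key] = tuple(sc[key])
        for key in ("agnor_count_distribution", "radial_position_distribution"):
            if key in sc:
                sc[key] = _dist_from_yaml(sc[key])
        sc = scenario_preset(preset, **sc) if preset else ImageScenario(**sc)
    kw["scenario"] = sc
    if "effects" in kw and isinstance(kw["effects"], dict):
        kw["effects"] = CohortEffectSpec(**kw["effects"])
    if "detection" in kw and isinstance(kw["detection"], dict):
        kw["detection"] = DetectionParams(**kw["detection"])
    if "zones" in kw and isinstance(kw["zones"], dict):
        kw["zones"] = ZoneDefinition(**kw["zones"])
    if "count_lambda_range" in kw:
        kw["count_lambda_range"] = tuple(kw["count_lambda_range"])
    return RunConfig(**kw)


def _dist_from_yaml(spec):
    if isinstance(spec, (list, tuple)):
        kind, *rest = spec
        if kind == "categorical":
            return ("categorical", {type_key(k): float(v) for k, v in rest[0].items()})
        return tuple([kind] + [float(x) for x in rest])
    raise ValueError(f"cannot parse distribution spec {spec!r}")


def type_key(k):
    try:
        return int(k)
    except (TypeError, ValueError):
        return k
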