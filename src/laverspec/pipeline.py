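"""End-to-end run: generate -> calibrate -> crop -> segment -> model -> grade.

One top-level seed fans out to per-stage seeds through a spawned
``numpy.random.SeedSequence``, so a rerun with the same configuration
reproduces every stage bit for bit and the manifest's checksums match.
The performance section mirrors the conventional three-column layout:
trained model (TM, metrics on the 80% training split), cross-validation
(CV, pooled 10-split venetian blinds over the full dataset), and
predicted model (PR, metrics on the held-out 20%).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import chemometrics as chem
from .cube_io import ROISpec, calibrate, crop_roi
from .grading import DEFAULT_CRITERIA, GradingCriteria, assign_grades, assign_zone
from .segmentation import IsodataParams, extract_sample_spectrum
from .synthetic import GeneratorConfig, generate_dataset

logger = logging.getLogger("laverspec")

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "report_render"]

MODEL_CHOICES = ("plsda", "vip-plsda", "ann", "pls-ann")


@dataclass
class RunConfig:
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    roi_height: int = 50
    roi_width: int = 300
    isodata: IsodataParams = field(default_factory=IsodataParams)
    model: str = "plsda"
    n_splits: int = 10
    test_size: float = 0.2
    max_components: int = 15
    criteria: GradingCriteria = field(default_factory=lambda: DEFAULT_CRITERIA)
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        if self.model not in MODEL_CHOICES:
            raise ValueError(f"model must be one of {MODEL_CHOICES}")
        if not 0 < self.test_size < 1:
            raise ValueError("test_size must be in (0, 1)")


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    model: str
    n_components: int | None
    stage_checksums: dict
    performance: dict  # keys TM / CV / PR -> metric dict
    grade_table: list  # per-sample dict rows
    counts: dict

    def to_json(self, **kwargs) -> str:
        return json.dumps(asdict(self), indent=2, default=str, **kwargs)


def _sha(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def _report_dict(rep: chem.PerformanceReport) -> dict:
    return {
        "accuracy": rep.accuracy,
        "error_rate": rep.error_rate,
        "fraction_correct": rep.fraction_correct,
        "sensitivity": [float(v) for v in rep.sensitivity],
        "specificity": [float(v) for v in rep.specificity],
        "r2_pooled": rep.r2_pooled,
        "rmse_pooled": rep.rmse_pooled,
        "confusion": rep.confusion.tolist(),
        "classes": [int(c) for c in rep.classes],
    }


def extract_spectra(items, config: RunConfig) -> tuple[np.ndarray, np.ndarray, list]:
    """Calibrate, crop the centred ROI, mask pores, average: spectra matrix.

    Returns (X: n x bands, pore fractions, masks).
    """
    X, fracs, masks = [], [], []
    for item in items:
        refl = calibrate(item.raw, item.white)
        roi = ROISpec(
            center=(refl.lines // 2, refl.samples // 2),
            height=config.roi_height,
            width=config.roi_width,
        )
        cropped = crop_roi(refl, roi)
        spectrum, mask = extract_sample_spectrum(cropped, config.isodata)
        X.append(spectrum)
        fracs.append(mask.pore_fraction)
        masks.append(mask)
    return np.array(X), np.array(fracs), masks


def _model_fn(config: RunConfig, n_components: int, ann_seed: int):
    if config.model == "plsda":
        return chem.plsda_model_fn(n_components)
    if config.model == "vip-plsda":
        return chem.vip_plsda_model_fn(n_components)
    if config.model == "ann":
        return chem.ann_model_fn(seed=ann_seed)
    return chem.pls_ann_model_fn(n_components, seed=ann_seed)


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute all stages; returns the manifest (and writes files if outdir)."""
    root = np.random.SeedSequence(config.seed)
    gen_seed, split_seed, ann_seed = (
        int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(3)
    )

    gen_config = GeneratorConfig(**{**asdict_config(config.generator), "seed": gen_seed})
    logger.info("generating %d synthetic sheets", gen_config.n_samples)
    items, truth = generate_dataset(gen_config)

    logger.info("extracting pore-free mean spectra (ROI %dx%d)", config.roi_height, config.roi_width)
    X, pore_fracs, _ = extract_spectra(items, config)
    y = np.array(truth.zones)
    logger.info("mean recovered pore fraction: %.4f", float(pore_fracs.mean()))

    plan = chem.CVPlan(n_splits=config.n_splits, test_size=config.test_size, seed=split_seed)

    n_components: int | None = None
    if config.model in ("plsda", "vip-plsda", "pls-ann"):
        n_components = chem.select_components(X, y, config.max_components, plan)
        logger.info("selected %d PLS components by CV", n_components)
    model_fn = _model_fn(config, n_components or 1, ann_seed)

    # CV over the full dataset
    cv_report = chem.venetian_cv(X, y, model_fn, plan)

    # 80/20 stratified split: TM on training data, PR on held-out data
    X_tr, X_te, y_tr, y_te = chem.holdout_split(X, y, plan)
    predictor = model_fn(X_tr, y_tr)
    tm_labels, tm_cont = predictor(X_tr)
    pr_labels, pr_cont = predictor(X_te)
    classes = np.unique(y)
    tm_report = chem.score_report(y_tr, tm_labels, np.asarray(tm_cont), classes=classes)
    pr_report = chem.score_report(y_te, pr_labels, np.asarray(pr_cont), classes=classes)

    grade_rows = []
    for rec in truth.records:
        g = assign_grades(rec, config.criteria)
        z = assign_zone(g, rec.sample_id)
        grade_rows.append(
            {
                "sample_id": rec.sample_id,
                "moisture": rec.moisture,
                "protein": rec.protein,
                "cutting_stress": rec.cutting_stress,
                "grade_moisture": g.moisture,
                "grade_protein": g.protein,
                "grade_cutting": g.cutting_stress,
                "zone": z.zone,
            }
        )

    config_blob = json.dumps(
        {"run": {k: v for k, v in asdict_config(config).items() if k != "outdir"}},
        sort_keys=True, default=str,
    )
    manifest = RunManifest(
        config_hash=hashlib.sha256(config_blob.encode()).hexdigest()[:16],
        seed=config.seed,
        model=config.model,
        n_components=n_components,
        stage_checksums={
            "spectra": _sha(X),
            "zones": _sha(y),
            "pore_fractions": _sha(pore_fracs),
        },
        performance={
            "TM": _report_dict(tm_report),
            "CV": _report_dict(cv_report),
            "PR": _report_dict(pr_report),
        },
        grade_table=grade_rows,
        counts={
            "n_samples": len(items),
            "n_bands": X.shape[1],
            "mean_pore_fraction": float(pore_fracs.mean()),
            "zone_counts": {int(c): int(np.sum(y == c)) for c in classes},
            "fold_sizes": [len(f) for f in plan.folds(len(y))],
        },
    )

    if config.outdir:
        import os

        os.makedirs(config.outdir, exist_ok=True)
        wl = items[0].raw.wavelengths
        spectra = pd.DataFrame(X, columns=[f"{w:.2f}" for w in wl])
        spectra.insert(0, "sample_id", [r.sample_id for r in truth.records])
        spectra.to_csv(os.path.join(config.outdir, "spectra.csv"), index=False)
        pd.DataFrame(grade_rows).to_csv(os.path.join(config.outdir, "grades.csv"), index=False)
        with open(os.path.join(config.outdir, "manifest.json"), "w") as fh:
            fh.write(manifest.to_json())
    return manifest


def asdict_config(cfg) -> dict:
    """Dataclass -> dict, leaving nested non-serialisable members intact."""
    out = {}
    for k, v in vars(cfg).items():
        out[k] = v
    return out


def report_render(manifest: RunManifest | dict) -> str:
    """Tabulate TM/CV/PR accuracy, R^2 and RMSE as a text table."""
    perf = manifest.performance if isinstance(manifest, RunManifest) else manifest.get("performance", {})
    model = manifest.model if isinstance(manifest, RunManifest) else manifest.get("model", "?")

    def cell(section, key, pct=False):
        d = perf.get(section)
        if not d or d.get(key) is None:
            return "n/a"
        v = d[key]
        return f"{100 * v:.1f}%" if pct else f"{v:.3f}"

    lines = [
        f"model: {model}",
        f"{'':<12}{'TM':>10}{'CV':>10}{'PR':>10}",
        f"{'Accuracy':<12}" + "".join(f"{cell(s, 'accuracy', pct=True):>10}" for s in ("TM", "CV", "PR")),
        f"{'R2':<12}" + "".join(f"{cell(s, 'r2_pooled', pct=True):>10}" for s in ("TM", "CV", "PR")),
        f"{'RMSE':<12}" + "".join(f"{cell(s, 'rmse_pooled'):>10}" for s in ("TM", "CV", "PR")),
    ]
    missing = [s for s in ("TM", "CV", "PR") if s not in perf]
    if missing:
        lines.append(f"warning: missing sections: {', '.join(missing)}")
    return "\n".join(lines)
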