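"""End-to-end orchestration: inputs -> feature table -> comparisons -> classifier.

A run is driven by a :class:`RunConfig` (loadable from flat YAML).  Inputs are
either generated synthetic cohorts or files on disk (a directory of VOI NIfTIs
named ``<subject>_<region>.nii`` plus a labels CSV and, optionally, one
landmark CSV per subject for the femur-geometry columns).  The run writes

* ``features.csv`` — the labeled feature table (15 trabecular columns per
  region, optionally + 3 geometry columns),
* ``comparisons.csv`` — normality-routed univariate group comparisons,
* ``model.json`` — CV summary (per-repeat AUCs, mean, 95% CI), chosen
  hyperparameters and the full-data coefficient table,
* ``roc_points.csv`` — the repeat-averaged ROC curve,
* ``run.log`` — package/library versions, the seed and a config hash.

Reruns with the same config and seed are bit-identical.  Stage failures abort
with the stage name and the offending input identifier.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify, groupstats, synth
from .geometry import FemurLandmarks, compute_pfg
from .texture import TEXTURE_FEATURE_NAMES
from .density import DENSITY_FEATURE_NAMES
from .voi import read_voi_nifti

__all__ = ["RunConfig", "StageError", "run_pipeline", "trabecular_feature_names", "select_features"]

TRABECULAR_WIDTH = 15


class StageError(RuntimeError):
    def __init__(self, stage: str, identifier: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed on {identifier!r}: {cause}")
        self.stage = stage
        self.identifier = identifier


def trabecular_feature_names() -> list[str]:
    """The 15 per-region variables: BV/TV, 9 textures, 5 GV histogram stats."""
    return ["bvtv"] + TEXTURE_FEATURE_NAMES + [n for n in DENSITY_FEATURE_NAMES if n != "bvtv"]


@dataclass
class RunConfig:
    """Flat, YAML-serializable description of one pipeline run."""

    outdir: str
    seed: int = 0
    # input: synthetic cohort ...
    synthetic: str | None = "default"  # "default" | "null" | None for file input
    n_fracture: int = 98
    n_control: int = 107
    # ... or files
    voi_dir: str | None = None
    labels_csv: str | None = None
    landmarks_dir: str | None = None
    # feature set
    regions: list[str] = field(default_factory=lambda: ["FHR1", "FHR2"])
    include_pfg: bool = True
    # model + CV
    model: str = "blr"  # "blr" | "en" | "en_grid"
    en_alpha: float = 0.5
    en_lambda: float = 0.05
    grid_repeats: int = 3
    k: int = 10
    repeats: int = 50

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def config_hash(self) -> str:
        payload = {k: v for k, v in asdict(self).items() if k != "outdir"}
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def _load_file_features(cfg: RunConfig) -> tuple[pd.DataFrame, pd.Series]:
    labels = pd.read_csv(cfg.labels_csv).set_index("subject")["label"]
    rows: dict[str, dict] = {}
    for path in sorted(Path(cfg.voi_dir).glob("*.nii*")):
        stem = path.name.split(".")[0]
        try:
            subject, region = stem.rsplit("_", 1)
        except ValueError as exc:
            raise StageError("extraction", path.name, exc)
        if region not in cfg.regions:
            continue
        try:
            voi = read_voi_nifti(path)
            feats = synth.subject_features(voi)
        except Exception as exc:  # noqa: BLE001 - rewrap with provenance
            raise StageError("features", path.name, exc)
        rows.setdefault(subject, {}).update({f"{n}_{region}": v for n, v in feats.items()})
    if cfg.include_pfg and cfg.landmarks_dir:
        for subject in rows:
            lm_path = Path(cfg.landmarks_dir) / f"{subject}.csv"
            try:
                pfg = compute_pfg(FemurLandmarks.from_csv(lm_path))
            except Exception as exc:  # noqa: BLE001
                raise StageError("geometry", str(lm_path), exc)
            rows[subject].update(pfg.as_series().to_dict())
    features = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    labels = labels.loc[features.index]
    return features, labels


def select_features(features: pd.DataFrame, regions: list[str], include_pfg: bool) -> pd.DataFrame:
    """Column subset for a feature-set selector, in canonical order."""
    cols = [f"{name}_{region}" for region in regions for name in trabecular_feature_names()]
    missing = [c for c in cols if c not in features.columns]
    if missing:
        raise ValueError(f"feature table lacks columns {missing[:3]}...")
    if include_pfg:
        cols += [c for c in ("nsa", "fnala", "fnalb") if c in features.columns]
    return features[cols]


def run_pipeline(config: RunConfig) -> dict:
    """Execute extraction -> features -> statistics -> classification."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # --- features
    if config.synthetic is not None:
        if config.synthetic == "default":
            recipe = synth.default_cohort_recipe(config.n_fracture, config.n_control, seed=config.seed)
        elif config.synthetic == "null":
            recipe = synth.null_cohort_recipe(config.n_fracture, seed=config.seed,
                                             include_pfg=config.include_pfg)
        else:
            raise StageError("input", str(config.synthetic), ValueError("unknown synthetic cohort"))
        recipe.include_pfg = config.include_pfg
        try:
            features, labels = synth.gen_cohort(recipe)
        except Exception as exc:  # noqa: BLE001
            raise StageError("synthesis", config.synthetic, exc)
    else:
        features, labels = _load_file_features(config)
    X = select_features(features, config.regions, config.include_pfg)
    table = X.copy()
    table.insert(0, "label", labels)
    table.to_csv(outdir / "features.csv", index_label="subject")

    # --- group statistics
    try:
        comparisons = groupstats.compare_groups(table, group_col="label")
        corr, flags = groupstats.correlation_screen(X)
    except Exception as exc:  # noqa: BLE001
        raise StageError("statistics", "feature table", exc)
    comparisons.to_csv(outdir / "comparisons.csv", index=False)

    # --- classification
    y = labels.to_numpy()
    try:
        if config.model == "blr":
            cv = classify.repeated_kfold(
                X.to_numpy(), y, classify.make_blr_fitter(), k=config.k,
                repeats=config.repeats, seed=config.seed,
            )
            basis, scores = classify.pca_reduce(X)
            final = classify.BayesLogit(y, scores).fit()
            coef = dict(zip(["intercept"] + [f"PC{i+1}" for i in range(scores.shape[1])],
                            map(float, final.params)))
            chosen: dict = {"n_components": int(basis.n_retained)}
        elif config.model == "en":
            cv = classify.repeated_kfold(
                X.to_numpy(), y, classify.make_en_fitter(config.en_alpha, config.en_lambda),
                k=config.k, repeats=config.repeats, seed=config.seed,
            )
            final = classify.ElasticNetLogit(y, X, config.en_alpha, config.en_lambda).fit()
            coef = dict(zip(final.param_names, map(float, final.params)))
            chosen = {"alpha": config.en_alpha, "lambda": config.en_lambda}
        elif config.model == "en_grid":
            alpha, lam, cv = classify.grid_search_en(
                X.to_numpy(), y, k=config.k, repeats=config.grid_repeats, seed=config.seed
            )
            final = classify.ElasticNetLogit(y, X, alpha, lam).fit()
            coef = dict(zip(final.param_names, map(float, final.params)))
            chosen = {"alpha": alpha, "lambda": lam}
        else:
            raise ValueError(f"unknown model {config.model!r}")
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("classification", config.model, exc)

    report = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_subjects": int(len(y)),
        "n_features": int(X.shape[1]),
        "model": config.model,
        "chosen_params": chosen,
        "mean_auc": cv.mean_auc,
        "ci": [cv.ci_low, cv.ci_high],
        "repeat_aucs": [float(a) for a in cv.repeat_aucs],
        "coefficients": coef,
        "multicollinear_pairs": int(len(flags)),
    }
    (outdir / "model.json").write_text(json.dumps(report, indent=2))

    grid = np.linspace(0, 1, 101)
    tprs = []
    for r in range(cv.scores.shape[0]):
        _, curve = classify.roc_auc(cv.scores[r], cv.labels)
        tprs.append(np.interp(grid, curve["fpr"], curve["tpr"]))
    pd.DataFrame({"fpr": grid, "tpr": np.mean(tprs, axis=0)}).to_csv(
        outdir / "roc_points.csv", index=False
    )

    import scipy
    import sklearn

    from . import __version__

    log = [
        f"trabpipe {__version__}",
        f"numpy {np.__version__}, scipy {scipy.__version__}, "
        f"pandas {pd.__version__}, scikit-learn {sklearn.__version__}",
        f"seed {config.seed}",
        f"config_hash {config.config_hash()}",
        f"mean_auc {cv.mean_auc:.6f}",
    ]
    (outdir / "run.log").write_text("\n".join(log) + "\n")
    return report
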