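"""Synthetic cohorts with the statistical structure the analysis assumes.

Clinical PACS data cannot be redistributed, so every pipeline stage is
exercised on generated inputs with controllable group structure:

* Trabecular-like VOIs are thresholded Gaussian random fields: seeded white
  noise smoothed with an anisotropic Gaussian kernel (correlation lengths in
  mm per axis) and mapped through a two-plateau sigmoid whose cut quantile
  equals 1 - target BV/TV.  The plateau gray levels are solved from the target
  gray-value mean and SD of the resulting two-point mixture, so density (cut
  quantile, plateau levels) and texture (correlation length) are controlled
  independently.  No biomechanical realism is claimed — the surrogate only
  reproduces the feature-level contrasts (BV/TV, GV mean/SD, spatial
  correlation) that the extractors measure.

* Femur-geometry tables draw (NSA, FNALa, FNALb) per subject from a correlated
  normal model.  Default group means come from the study summaries printed for
  the fracture (n=98) and control (n=107) femurs; the SDs are back-derived
  from the printed 95% confidence intervals as half-width / 1.96 * sqrt(n).
  Landmark CSVs consistent with any drawn triple can be emitted so the
  geometry module reproduces the drawn values exactly (a constructive
  inverse).

All randomness flows from one integer master seed; per-subject substreams are
spawned deterministically so cohorts are reproducible and order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from .density import density_features
from .geometry import FemurLandmarks
from .texture import texture_features
from .voi import VOI_SHAPE, VOI_SPACING, VOIGrid

__all__ = [
    "VOIRecipe",
    "GroupRecipe",
    "CohortRecipe",
    "ci_to_sd",
    "gen_voi",
    "gen_pfg_table",
    "landmarks_for_pfg",
    "gen_cohort",
    "subject_features",
    "PFG_PRINTED",
    "default_cohort_recipe",
    "null_cohort_recipe",
    "pfg_cohort_recipe",
]


def ci_to_sd(half_width: float, n: int) -> float:
    """Back-derive a sample SD from a normal-theory 95% CI half-width."""
    return half_width * np.sqrt(n) / 1.96


def _mean_hw(mean: float, lo: float, hi: float) -> tuple[float, float]:
    return mean, (hi - lo) / 2


# Printed femur-cohort summaries: mean and 95% CI per group (fracture n=98,
# control n=107).  FNALa is not printed; its defaults are a package choice
# satisfying FNALa > FNALb (see docs/methods.md).
PFG_PRINTED = {
    "fracture": {
        "n": 98,
        "nsa": _mean_hw(121.71, 120.58, 122.84),
        "fnalb": _mean_hw(78.36, 77.14, 79.58),
        "fnala": (90.0, None),
    },
    "control": {
        "n": 107,
        "nsa": _mean_hw(124.60, 123.49, 125.70),
        "fnalb": _mean_hw(76.03, 74.75, 77.30),
        "fnala": (88.0, None),
    },
}
_FNALA_SD_DEFAULT = 7.0


def _pfg_group_params(group: str) -> dict:
    src = PFG_PRINTED[group]
    n = src["n"]
    out = {"n": n}
    for var in ("nsa", "fnala", "fnalb"):
        mean, hw = src[var]
        sd = ci_to_sd(hw, n) if hw is not None else _FNALA_SD_DEFAULT
        out[var] = (mean, sd)
    return out


# ---------------------------------------------------------------------------
# VOI generation


@dataclass
class VOIRecipe:
    """Targets for one synthetic trabecular VOI."""

    shape: tuple[int, int, int] = VOI_SHAPE
    spacing: tuple[float, float, float] = VOI_SPACING
    target_bvtv: float = 0.5
    corr_length: tuple[float, float, float] = (1.6, 1.6, 1.6)  # mm per axis
    gv_mean: float = 140.0
    gv_sd: float = 40.0
    sharpness: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.target_bvtv < 1.0:
            raise ValueError("target_bvtv must lie in (0, 1)")
        cl = self.corr_length
        if np.isscalar(cl):
            cl = (float(cl),) * 3
        self.corr_length = tuple(float(c) for c in cl)
        if any(c <= 0 for c in self.corr_length):
            raise ValueError("correlation lengths must be positive")


def gen_voi(recipe: VOIRecipe) -> VOIGrid:
    """Generate one VOI from a thresholded-Gaussian-random-field recipe."""
    sigma_vox = np.array(recipe.corr_length) / np.array(recipe.spacing)
    if np.any(2 * sigma_vox >= np.array(recipe.shape)):
        raise ValueError(
            f"smoothing kernel (sigma {tuple(sigma_vox)} voxels) is wider than "
            f"the volume {recipe.shape}"
        )
    rng = np.random.default_rng(recipe.seed)
    noise = rng.standard_normal(recipe.shape)
    fld = gaussian_filter(noise, sigma=sigma_vox, mode="wrap")
    fld = (fld - fld.mean()) / fld.std()
    cut = np.quantile(fld, 1.0 - recipe.target_bvtv)
    g = expit(recipe.sharpness * (fld - cut))
    p = recipe.target_bvtv
    high = recipe.gv_mean + recipe.gv_sd * np.sqrt((1 - p) / p)
    low = recipe.gv_mean - recipe.gv_sd * np.sqrt(p / (1 - p))
    values = np.clip(low + (high - low) * g, 0, 255)
    values = np.floor(values + 0.5).astype(np.uint8)
    return VOIGrid(values, recipe.spacing, meta={"recipe_seed": recipe.seed})


# ---------------------------------------------------------------------------
# Femur geometry tables and landmark round trip


def gen_pfg_table(
    n_per_group: dict[str, int] | None = None,
    means: dict[str, dict[str, tuple[float, float]]] | None = None,
    corr: float = 0.0,
    seed: int = 0,
    variables: tuple[str, ...] = ("nsa", "fnala", "fnalb"),
) -> pd.DataFrame:
    """Two-group per-subject geometry table from a correlated normal model.

    ``means`` maps group -> variable -> (mean, sd); defaults are the printed
    study summaries (with CI-derived SDs).  ``corr`` is the common pairwise
    correlation between the geometry variables.
    """
    if means is None:
        means = {g: {v: _pfg_group_params(g)[v] for v in variables} for g in ("fracture", "control")}
    if n_per_group is None:
        n_per_group = {g: _pfg_group_params(g)["n"] for g in means}
    k = len(variables)
    C = np.full((k, k), corr)
    np.fill_diagonal(C, 1.0)
    if np.linalg.eigvalsh(C).min() <= 0:
        raise ValueError(f"correlation {corr} gives a non-positive-definite matrix")
    L = np.linalg.cholesky(C)
    rng = np.random.default_rng(seed)
    rows = []
    for group in means:
        n = n_per_group[group]
        mu = np.array([means[group][v][0] for v in variables])
        sd = np.array([means[group][v][1] for v in variables])
        draws = mu + (rng.standard_normal((n, k)) @ L.T) * sd
        for i in range(n):
            rows.append({"group": group, **dict(zip(variables, draws[i]))})
    df = pd.DataFrame(rows)
    df.insert(0, "subject", [f"s{i:04d}" for i in range(len(df))])
    return df


def landmarks_for_pfg(nsa: float, fnala: float, fnalb: float) -> FemurLandmarks:
    """Construct a landmark set whose measured geometry equals the given triple.

    The neck axis runs along +x from the origin; the shaft direction is placed
    at the requested angle in the xy-plane, pointing distal-to-proximal.
    """
    theta = np.radians(nsa)
    neck_start = np.zeros(3)
    neck_dir = np.array([1.0, 0.0, 0.0])
    shaft_dir = np.array([np.cos(theta), np.sin(theta), 0.0])
    return FemurLandmarks(
        neck_start=neck_start,
        head_anterior=neck_start + fnala * neck_dir,
        head_center=neck_start + fnalb * neck_dir,
        shaft_p1=neck_start - 100.0 * shaft_dir,
        shaft_p2=neck_start.copy(),
    )


# ---------------------------------------------------------------------------
# Cohorts


@dataclass
class GroupRecipe:
    """Per-group targets; between-subject SDs give subject-level variation."""

    n: int
    regions: dict[str, VOIRecipe] = field(default_factory=dict)
    bvtv_between_sd: float = 0.08
    gv_mean_between_sd: float = 27.0
    # lognormal sigma of per-subject correlation-length jitter; without it the
    # texture knob would separate groups almost deterministically
    corr_length_jitter_sd: float = 0.2
    pfg: dict[str, tuple[float, float]] | None = None  # var -> (mean, sd)


@dataclass
class CohortRecipe:
    """Paired fracture/control cohort: VOI-derived features + geometry columns."""

    groups: dict[str, GroupRecipe]
    inter_region_corr: float = 0.7
    pfg_corr: float = 0.0
    include_pfg: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name, g in self.groups.items():
            if g.n < 5:
                raise ValueError(f"group {name!r}: need n >= 5 per group")
            if g.bvtv_between_sd <= 0 or g.gv_mean_between_sd <= 0:
                raise ValueError("between-subject SDs must be positive")


def _fhr_recipes(gv_mean: float, bvtv: float, corr_length: float) -> VOIRecipe:
    return VOIRecipe(target_bvtv=bvtv, gv_mean=gv_mean, corr_length=(corr_length,) * 3)


def default_cohort_recipe(n_fracture: int = 98, n_control: int = 107, seed: int = 0) -> CohortRecipe:
    """Femoral-head cohort with group contrasts mirroring the printed study
    summaries: lower GV mean and BV/TV and a longer spatial correlation
    (lower contrast) on the fracture side."""
    return CohortRecipe(
        groups={
            "fracture": GroupRecipe(
                n=n_fracture,
                regions={
                    "FHR1": _fhr_recipes(136.41, 0.49, 2.0),
                    "FHR2": _fhr_recipes(150.63, 0.51, 2.0),
                },
                gv_mean_between_sd=27.5,
                bvtv_between_sd=0.08,
                pfg={v: _pfg_group_params("fracture")[v] for v in ("nsa", "fnala", "fnalb")},
            ),
            "control": GroupRecipe(
                n=n_control,
                regions={
                    "FHR1": _fhr_recipes(147.99, 0.50, 1.6),
                    "FHR2": _fhr_recipes(163.47, 0.55, 1.6),
                },
                gv_mean_between_sd=27.85,
                bvtv_between_sd=0.08,
                pfg={v: _pfg_group_params("control")[v] for v in ("nsa", "fnala", "fnalb")},
            ),
        },
        seed=seed,
    )


def null_cohort_recipe(n_per_group: int = 93, seed: int = 0, include_pfg: bool = False) -> CohortRecipe:
    """Zero group effect everywhere: both groups share one set of targets."""
    shared = {
        "regions": {"FHR1": _fhr_recipes(140.0, 0.5, 1.6), "FHR2": _fhr_recipes(150.0, 0.52, 1.6)},
        "gv_mean_between_sd": 27.0,
        "bvtv_between_sd": 0.08,
        "pfg": {"nsa": (123.0, 5.8), "fnala": (89.0, 7.0), "fnalb": (77.0, 6.4)},
    }
    return CohortRecipe(
        groups={
            "fracture": GroupRecipe(n=n_per_group, **shared),
            "control": GroupRecipe(n=n_per_group, **shared),
        },
        include_pfg=include_pfg,
        seed=seed,
    )


def pfg_cohort_recipe(corr: float = 0.0, seed: int = 0,
                      variables: tuple[str, ...] = ("nsa", "fnalb")) -> dict:
    """Arguments for :func:`gen_pfg_table` at the printed group summaries."""
    return {
        "n_per_group": {g: _pfg_group_params(g)["n"] for g in ("fracture", "control")},
        "means": {
            g: {v: _pfg_group_params(g)[v] for v in variables} for g in ("fracture", "control")
        },
        "corr": corr,
        "seed": seed,
        "variables": variables,
    }


def subject_features(voi: VOIGrid) -> pd.Series:
    """The 15 trabecular features of one VOI: BV/TV, 9 textures, 5 GV stats."""
    dens = density_features(voi).as_series()
    tex = texture_features(voi).as_series()
    ordered = pd.concat([dens[["bvtv"]], tex, dens.drop("bvtv")])
    return ordered


def gen_cohort(recipe: CohortRecipe, return_vois: bool = False):
    """Generate a labeled feature table (and optionally the VOIs themselves).

    Per subject and region a VOI is generated with subject-level jitter on the
    density targets (a shared latent factor induces the configured inter-region
    correlation), features are extracted with the real extractors, and the
    geometry columns are appended if requested.  Label 1 = fracture group.
    """
    master = np.random.SeedSequence(recipe.seed)
    group_streams = master.spawn(len(recipe.groups))
    rows = []
    labels = []
    vois: dict[tuple[str, str], VOIGrid] = {}
    sid = 0
    for gi, (group, grp) in enumerate(sorted(recipe.groups.items())):
        group_ss = group_streams[gi]
        subject_seeds = group_ss.generate_state(grp.n * 4).reshape(grp.n, 4) % (2**31 - 1)
        for i in range(grp.n):
            rng = np.random.default_rng(subject_seeds[i, 0])
            shared = rng.standard_normal()
            row = {}
            rho = recipe.inter_region_corr
            for ri, (region, base) in enumerate(sorted(grp.regions.items())):
                local = rng.standard_normal()
                z = np.sqrt(rho) * shared + np.sqrt(1 - rho) * local
                gv_mean = float(np.clip(base.gv_mean + grp.gv_mean_between_sd * z, 40, 230))
                bvtv_t = float(np.clip(base.target_bvtv + grp.bvtv_between_sd * rng.standard_normal(), 0.05, 0.95))
                cl_scale = float(np.exp(rng.normal(0.0, grp.corr_length_jitter_sd)))
                cl = tuple(np.clip(np.array(base.corr_length) * cl_scale, 0.3, 4.0))
                r = replace(base, gv_mean=gv_mean, target_bvtv=bvtv_t, corr_length=cl,
                            seed=int(subject_seeds[i, 1] + ri))
                voi = gen_voi(r)
                feats = subject_features(voi)
                row.update({f"{name}_{region}": v for name, v in feats.items()})
                if return_vois:
                    vois[(f"s{sid:04d}", region)] = voi
            if recipe.include_pfg and grp.pfg:
                variables = list(grp.pfg)
                k = len(variables)
                C = np.full((k, k), recipe.pfg_corr)
                np.fill_diagonal(C, 1.0)
                L = np.linalg.cholesky(C)
                prng = np.random.default_rng(subject_seeds[i, 2])
                mu = np.array([grp.pfg[v][0] for v in variables])
                sd = np.array([grp.pfg[v][1] for v in variables])
                vals = mu + (L @ prng.standard_normal(k)) * sd
                row.update(dict(zip(variables, vals)))
            rows.append(row)
            labels.append(1 if group == "fracture" else 0)
            sid += 1
    features = pd.DataFrame(rows, index=[f"s{i:04d}" for i in range(len(rows))])
    labels = pd.Series(labels, index=features.index, name="label")
    if return_vois:
        return features, labels, vois
    return features, labels
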