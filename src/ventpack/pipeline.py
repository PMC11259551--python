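"""Config-driven end-to-end orchestration.

``run_pipeline`` chains phantom generation (or ingest), thoracic and
ventilation segmentation, defect sphere-packing, texture extraction,
PCA/Boruta selection, classifier training on the four feature sets
(demographics, spirometry, texture, combined) and the statistical
comparisons, and returns a reproducible report.  All randomness derives
from the single configured seed, so rerunning an identical configuration
reproduces the report byte for byte.
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
from .core import Mask3D
from .modeling import (
    ModelSpec,
    build_model,
    cross_validate,
    default_grid,
    evaluate,
    label_decline,
    predict_scores,
    split_cohort,
)
from .phantom import EffectConfig, PhantomCase, make_cohort
from .segmentation import kmeans_ventilation, max_entropy_roi, region_grow_thoracic
from .selection import BorutaParams, boruta_select, pca, standardize
from .spherepack import cluster_metrics, pack_spheres
from .stats import compare_groups, correlate, delong_test
from .texture import CATALOG_VERSION, TextureConfig, catalog_feature_names, extract_catalog

__all__ = ["RunConfig", "RunReport", "PipelineError", "run_pipeline", "process_case"]

logger = logging.getLogger(__name__)

DEMOGRAPHIC_VARS = ["age", "sex_code", "bmi", "spo2", "pack_years", "years_since_quit"]
SPIROMETRY_VARS = ["fvc", "tlc", "fev1_baseline", "ic", "svc", "rv_tlc"]

#: fallback texture shortlist if Boruta confirms nothing (the features most
#: consistently informative for decline prediction)
TEXTURE_SHORTLIST = [
    "custom_CDD1",
    "shape_MajorAxisLength",
    "original_glcm_Idn",
    "original_glcm_Idmn",
    "wavelet-LL_glszm_LowGrayLevelZoneEmphasis",
    "wavelet-LL_glrlm_ShortRunLowGrayLevelEmphasis",
    "wavelet-LL_gldm_SmallDependenceLowGrayLevelEmphasis",
]


class PipelineError(RuntimeError):
    """Stage-tagged pipeline failure."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to regenerate a run: sizes, seeds, parameters."""

    n_stable: int = 57
    n_rapid: int = 31
    grid_shape: tuple[int, int, int] = (64, 64, 14)
    spacing_mm: tuple[float, float, float] = (5.0, 5.0, 5.0)
    seed: int = 42
    effects: str = "default"  # "default" or "null"
    kmeans_k: int = 5
    region_grow_tolerance: float = 30.0
    test_fraction: float = 0.2
    stratified: bool = True
    cv_folds: int = 5
    texture: TextureConfig = field(default_factory=TextureConfig)
    boruta: BorutaParams = field(default_factory=BorutaParams)
    families: dict = field(
        default_factory=lambda: {
            "demographics": ["logistic"],
            "spirometry": ["knn_cosine"],
            "texture": ["rusboost"],
            "combined": ["svm_rbf_medium"],
        }
    )

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, sort_keys=True, indent=2, default=list)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        if "texture" in d:
            d["texture"] = TextureConfig(**d["texture"])
        if "boruta" in d:
            d["boruta"] = BorutaParams(**d["boruta"])
        for key in ("grid_shape", "spacing_mm"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """Full pipeline output: per-model metrics, DeLong contrasts,
    selected features, group comparisons, correlations, provenance."""

    model_blocks: dict
    delong_comparisons: list
    selected_features: list
    group_comparisons: list
    correlations: list
    pca_explained_variance: list
    subject_table: pd.DataFrame
    provenance: dict

    def to_json(self) -> str:
        d = {
            "model_blocks": self.model_blocks,
            "delong_comparisons": self.delong_comparisons,
            "selected_features": self.selected_features,
            "group_comparisons": self.group_comparisons,
            "correlations": self.correlations,
            "pca_explained_variance": self.pca_explained_variance,
            "provenance": self.provenance,
        }
        return json.dumps(d, sort_keys=True, indent=2, default=float)

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(self.to_json())
        self.subject_table.to_csv(out / "subjects.csv", index=False)


def process_case(
    case: PhantomCase, config: RunConfig
) -> dict[str, float]:
    """Segment, pack and featurize one subject; returns the feature row."""
    thoracic = region_grow_thoracic(
        case.proton, case.lung_seed_points, config.region_grow_tolerance
    )
    seg = kmeans_ventilation(case.he3, thoracic, k=config.kmeans_k, seed=config.seed)
    roi = max_entropy_roi(case.he3, thoracic)
    defect = Mask3D(seg.ventilation_labels == 1, case.he3.spacing_mm)
    packing = pack_spheres(defect)
    metrics = cluster_metrics(packing, thoracic.count, case.he3.spacing_mm)
    fv = extract_catalog(case.he3, roi, metrics, seg.vdp_percent, config.texture)
    return dict(fv.values)


def _feature_frame(cohort: pd.DataFrame, rows: list[dict]) -> pd.DataFrame:
    feats = pd.DataFrame(rows, index=cohort.index)
    df = pd.concat([cohort, feats], axis=1)
    df["sex_code"] = (df["sex"] == "F").astype(float)
    return df


def _fit_best(
    feature_set: str,
    families: list[str],
    X_train: np.ndarray,
    y_train: np.ndarray,
    config: RunConfig,
) -> tuple[ModelSpec, float]:
    best: tuple[float, ModelSpec] | None = None
    for family in families:
        for hp in default_grid(family):
            spec = ModelSpec(family=family, hyperparameters=hp, seed=config.seed)
            cv = cross_validate(spec, X_train, y_train, folds=config.cv_folds, seed=config.seed)
            score = cv["mean_cv_auc"]
            if best is None or score > best[0]:
                best = (score, spec)
    assert best is not None
    return best[1], best[0]


def run_pipeline(config: RunConfig | None = None, output_dir=None) -> RunReport:
    """Execute the full pipeline and return (optionally save) the report."""
    config = config or RunConfig()

    # --- phantom stage -----------------------------------------------------
    try:
        effects = EffectConfig.null(config.seed) if config.effects == "null" else EffectConfig.default(config.seed)
        cohort, cases = make_cohort(
            max(config.n_stable, 0),
            max(config.n_rapid, 0),
            effects=effects,
            seed=config.seed,
            grid_shape=config.grid_shape,
            spacing_mm=config.spacing_mm,
            allow_empty_group=True,
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("phantom", str(exc)) from exc
    logger.info("[phantom] generated %d subjects", len(cohort))

    # --- segmentation / packing / texture ----------------------------------
    rows = []
    for case in cases:
        try:
            rows.append(process_case(case, config))
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("segmentation", f"subject {case.subject_id}: {exc}") from exc
    df = _feature_frame(cohort, rows)
    logger.info("[features] extracted %d features per subject", len(catalog_feature_names()))

    # relabel from the two-visit FEV1 pairs (must reproduce the cohort labels)
    df["label_from_fev1"] = [
        label_decline(r.fev1_baseline, r.fev1_followup, r.interval_months)
        for r in df.itertuples()
    ]
    label_mismatches = int((df["label_from_fev1"] != df["label"]).sum())

    if df["label"].nunique() < 2:
        raise PipelineError("modeling", "single-class cohort")

    # --- split & selection ---------------------------------------------------
    train, test = split_cohort(
        df, config.test_fraction, seed=config.seed, stratify=config.stratified
    )
    texture_cols = catalog_feature_names()
    Xt_train = train[texture_cols].fillna(0.0)
    y_train = train["label"].to_numpy()
    y_test = test["label"].to_numpy()

    try:
        Z, _, _ = standardize(Xt_train)
        pca_res = pca(Z)
        boruta_res = boruta_select(Xt_train, y_train, config.boruta, seed=config.seed)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("selection", str(exc)) from exc
    selected = boruta_res.confirmed
    if not selected:
        logger.warning("[selection] Boruta confirmed nothing; using fallback shortlist")
        selected = list(TEXTURE_SHORTLIST)

    feature_sets = {
        "demographics": DEMOGRAPHIC_VARS,
        "spirometry": SPIROMETRY_VARS,
        "texture": selected,
        "combined": DEMOGRAPHIC_VARS + SPIROMETRY_VARS + selected,
    }

    # --- modeling ------------------------------------------------------------
    model_blocks: dict = {}
    test_scores: dict[str, np.ndarray] = {}
    for set_name, cols in feature_sets.items():
        fams = config.families.get(set_name, ["logistic"])
        Xtr = train[cols].fillna(0.0).to_numpy(float)
        Xte = test[cols].fillna(0.0).to_numpy(float)
        try:
            spec, cv_auc = _fit_best(set_name, fams, Xtr, y_train, config)
            model = build_model(spec, Xtr.shape[1])
            model.fit(Xtr, (y_train == "rapid").astype(int))
            s_test = predict_scores(model, Xte)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("modeling", f"{set_name}: {exc}") from exc
        m = evaluate(s_test, y_test == "rapid")
        test_scores[set_name] = s_test
        model_blocks[set_name] = {
            "family": spec.family,
            "hyperparameters": spec.hyperparameters,
            "features": cols,
            "mean_cv_auc": cv_auc,
            "test_metrics": dataclasses.asdict(m),
        }

    # --- statistics ----------------------------------------------------------
    delong_rows = []
    names = list(feature_sets)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            cmp_ = delong_test(test_scores[names[i]], test_scores[names[j]], y_test == "rapid")
            delong_rows.append(
                {
                    "model_a": names[i],
                    "model_b": names[j],
                    "auc_a": cmp_.auc_a,
                    "auc_b": cmp_.auc_b,
                    "z": cmp_.z,
                    "p": cmp_.p,
                }
            )

    compare_vars = [
        "age", "bmi", "spo2", "pack_years", "fev1_baseline", "fvc", "tlc", "rv_tlc",
        "custom_VDP_percent", "custom_VDCP_percent", "custom_CDD1",
        "shape_MajorAxisLength", "original_glcm_Idn", "original_glcm_Idmn",
        "wavelet-LL_glszm_LowGrayLevelZoneEmphasis",
        "wavelet-LL_glrlm_ShortRunLowGrayLevelEmphasis",
        "wavelet-LL_gldm_SmallDependenceLowGrayLevelEmphasis",
    ]
    try:
        group_rows = compare_groups(df, compare_vars)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("stats", str(exc)) from exc

    df["delta_fev1"] = df["fev1_followup"] - df["fev1_baseline"]
    corr_rows = []
    for var in ["fvc", "tlc", "custom_CDD1", "shape_MajorAxisLength",
                "wavelet-LL_gldm_SmallDependenceLowGrayLevelEmphasis"]:
        coef, p = correlate(df[var].fillna(0.0), df["delta_fev1"], method="spearman")
        corr_rows.append({"variable": var, "against": "delta_fev1", "rho": coef, "p": p})

    report = RunReport(
        model_blocks=model_blocks,
        delong_comparisons=delong_rows,
        selected_features=selected,
        group_comparisons=[
            {
                "variable": r.variable,
                "group_stats": {g: list(v) for g, v in r.group_stats.items()},
                "test": r.test,
                "p_raw": r.p_raw,
                "p_adjusted": r.p_adjusted,
            }
            for r in group_rows
        ],
        correlations=corr_rows,
        pca_explained_variance=[float(v) for v in pca_res.explained_variance_ratio[:10]],
        subject_table=df.drop(columns=[c for c in texture_cols if c not in compare_vars + TEXTURE_SHORTLIST]),
        provenance={
            "seed": config.seed,
            "config_hash": config.config_hash,
            "catalog_version": CATALOG_VERSION,
            "package_version": __version__,
            "n_subjects": int(len(df)),
            "label_mismatches": label_mismatches,
            "boruta_iterations": boruta_res.n_iterations,
            "n_confirmed": len(boruta_res.confirmed),
        },
    )
    if output_dir is not None:
        report.save(output_dir)
    return report
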