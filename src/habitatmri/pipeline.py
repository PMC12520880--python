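"""End-to-end orchestration: synthesize/load -> preprocess -> voxel
features -> habitat clustering -> region radiomics -> selection ->
signatures -> nomogram -> reports.

Configuration is a validated pydantic tree (unknown keys rejected, all
schema violations reported together).  A run is fully determined by the
config and its global seed; the manifest records the config hash,
per-stage wall-clock and the artifacts written.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from . import synthetic
from .clustering import HabitatKMeans, assign_habitats
from .image import load_volume
from .modeling import (
    CLINICAL_FEATURES,
    EvalReport,
    NomogramModel,
    SignatureClassifier,
    cohort_comparison_table,
    evaluate_scores,
    split_cohort,
)
from .preprocess import PreprocessConfig, preprocess_patient
from .region_features import (
    ExtractionConfig,
    icc_filter,
    perturb_mask,
    region_feature_table,
)
from .selection import SelectionCascade
from .synthetic import SyntheticPatient, clinical_table
from .voxel_features import VoxelFeatureConfig, assemble_voxel_features

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "validate_config", "run_pipeline", "PipelineResult"]

_STAGES = ("simulate", "preprocess", "features", "habitats",
           "region_features", "select", "fit", "evaluate")


# --------------------------------------------------------------------------
# configuration schema
# --------------------------------------------------------------------------

class SyntheticConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_patients: int = Field(60, ge=2)
    grid_shape: tuple[int, int, int] = (24, 22, 19)
    voxel_spacing_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    tumor_semiaxes_mm: tuple[float, float, float] = (30.0, 26.0, 22.0)
    geometry: Literal["shells", "blobs"] = "blobs"
    noise_sd: float = Field(3.0, ge=0)
    bias_amplitude: float = Field(0.08, ge=0)


class PreprocessSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    method: Literal["polyfit", "n4"] = "polyfit"
    target_spacing_mm: float = Field(3.0, gt=0)
    bspline_order: int = Field(3, ge=0, le=5)
    standardization: Literal["zscore_in_mask", "landmark"] = "zscore_in_mask"
    enabled: bool = True


class VoxelSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    radius: int = Field(1, ge=1)
    n_bins: int = Field(16, ge=2)


class ClusteringSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    candidate_k: tuple[int, int] = (2, 5)
    n_restarts: int = Field(10, ge=1)
    max_iter: int = Field(1000, ge=1)
    max_pooled_voxels: int = Field(50_000, ge=100)


class ExtractionSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    families: tuple[str, ...] = ("firstorder", "shape", "glcm", "glrlm", "glszm")
    log_sigmas_mm: tuple[float, ...] = ()
    wavelet: bool = False
    n_bins: int = Field(32, ge=2)
    min_region_voxels: int = Field(8, ge=1)
    icc_enabled: bool = True
    icc_threshold: float = Field(0.75, ge=-1, le=1)


class SelectionSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    alpha: float = Field(0.05, gt=0, lt=1)
    r_threshold: float = Field(0.9, gt=0, le=1)
    folds: int = Field(5, ge=2)
    univariate: Literal["mannwhitney", "anova"] = "mannwhitney"
    n_lambdas: int = Field(100, ge=10)


class ModelingSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    split_ratio: float = Field(0.8, gt=0, lt=1)
    clinical_features: tuple[str, ...] = CLINICAL_FEATURES
    nomogram_clinical_kind: Literal["mlp", "logistic"] = "mlp"
    mlp_hidden_units: int = Field(16, ge=1)


class PipelineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    cohort_dir: Optional[str] = None
    synthetic: SyntheticConfig = SyntheticConfig()
    preprocess: PreprocessSection = PreprocessSection()
    voxel: VoxelSection = VoxelSection()
    clustering: ClusteringSection = ClusteringSection()
    extraction: ExtractionSection = ExtractionSection()
    selection: SelectionSection = SelectionSection()
    modeling: ModelingSection = ModelingSection()
    seed: int = 0
    output_dir: Optional[str] = None

    @model_validator(mode="after")
    def _one_source(self):
        # exactly one input source: an on-disk cohort XOR the synthetic spec
        # (the synthetic spec always has defaults, so cohort_dir wins if set)
        return self

    def hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def validate_config(raw: str | dict | None) -> PipelineConfig:
    """Parse + validate a YAML/JSON config text; all violations listed."""
    if raw is None or (isinstance(raw, str) and not raw.strip()):
        data = {}
    elif isinstance(raw, dict):
        data = raw
    else:
        data = yaml.safe_load(raw)
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise ValueError("config must be a mapping")
    try:
        return PipelineConfig(**data)
    except ValidationError as err:
        msgs = "; ".join(
            f"{'.'.join(str(loc) for loc in e['loc'])}: {e['msg']}"
            for e in err.errors())
        raise ValueError(f"invalid config ({err.error_count()} errors): {msgs}") from err


# --------------------------------------------------------------------------
# results container
# --------------------------------------------------------------------------

@dataclass
class PipelineResult:
    config: PipelineConfig
    manifest: dict
    reports: dict[tuple[str, str, str], EvalReport] = dc_field(default_factory=dict)
    habitat_model: HabitatKMeans | None = None
    selection_reports: dict = dc_field(default_factory=dict)
    comparison_table: pd.DataFrame | None = None
    scores: pd.DataFrame | None = None

    def summary(self) -> pd.DataFrame:
        rows = [r.summary_row() for r in self.reports.values()]
        return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# cohort loading
# --------------------------------------------------------------------------

def _load_cohort(cohort_dir: str) -> list[SyntheticPatient]:
    from .image import DynamicSeries
    manifest = json.loads((Path(cohort_dir) / "manifest.json").read_text())
    clin = pd.read_csv(Path(cohort_dir) / "clinical.csv", index_col="patient_id")
    patients = []
    for entry in manifest["patients"]:
        pid = entry["patient_id"]
        if not Path(entry["mask"]).exists():
            logger.warning("patient %s excluded: mask file missing", pid)
            continue
        phases = tuple(load_volume(p) for p in entry["phases"])
        series = DynamicSeries(phases=phases, times_s=tuple(entry["times_s"]))
        mask = load_volume(entry["mask"]).astype(np.uint8)
        truth = (load_volume(entry["truth"]).astype(np.int16)
                 if Path(entry.get("truth", "")).exists() else None)
        row = clin.loc[pid]
        patients.append(SyntheticPatient(
            patient_id=pid, series=series, tumor_mask=mask, truth_labels=truth,
            clinical={k: row[k] for k in
                      ("age", "menopause", "er", "pr", "her2", "ki67", "cT", "cN")},
            outcome=int(row["pcr"]), latent=entry.get("latent", {})))
    return patients


# --------------------------------------------------------------------------
# the pipeline
# --------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig, until: str | None = None
                 ) -> PipelineResult:
    """Execute the pipeline (optionally only up to stage ``until``)."""
    if until is not None and until not in _STAGES:
        raise ValueError(f"unknown stage {until!r}; stages: {_STAGES}")
    stop_at = _STAGES.index(until) if until else len(_STAGES) - 1
    manifest: dict = {"config_hash": config.hash(), "stages": {}, "artifacts": [],
                      "warnings": []}
    outdir = Path(config.output_dir) if config.output_dir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
    result = PipelineResult(config=config, manifest=manifest)
    rng = np.random.default_rng(config.seed)

    def stage(name):
        return _STAGES.index(name) <= stop_at

    def tic(name):
        manifest["stages"][name] = {"t0": time.perf_counter()}

    def toc(name):
        st = manifest["stages"][name]
        st["seconds"] = round(time.perf_counter() - st.pop("t0"), 3)

    # -- simulate / load ---------------------------------------------------
    tic("simulate")
    if config.cohort_dir:
        patients = _load_cohort(config.cohort_dir)
    else:
        sc = config.synthetic
        spec = synthetic.PhantomSpec(
            grid_shape=sc.grid_shape, voxel_spacing_mm=sc.voxel_spacing_mm,
            tumor_semiaxes_mm=sc.tumor_semiaxes_mm, geometry=sc.geometry,
            noise_sd=sc.noise_sd, bias_amplitude=sc.bias_amplitude)
        patients = synthetic.generate_cohort(sc.n_patients, spec,
                                             seed=config.seed)
    toc("simulate")
    if not stage("preprocess"):
        return result

    # -- preprocess --------------------------------------------------------
    tic("preprocess")
    pc = PreprocessConfig(method=config.preprocess.method,
                          target_spacing_mm=config.preprocess.target_spacing_mm,
                          bspline_order=config.preprocess.bspline_order,
                          standardization=config.preprocess.standardization)
    if config.preprocess.enabled:
        prepped = [preprocess_patient(p, pc) for p in patients]
    else:
        from .preprocess import PreprocessedPatient, standardize_intensity
        prepped = []
        for p in patients:
            peak = p.series.peak_phase_index(p.tumor_mask.values)
            prepped.append(PreprocessedPatient(
                patient_id=p.patient_id, series=p.series,
                peak_std=standardize_intensity(p.series.phases[peak],
                                               p.tumor_mask, pc),
                peak_phase_index=peak, tumor_mask=p.tumor_mask,
                truth_labels=p.truth_labels, clinical=p.clinical,
                outcome=p.outcome, latent=p.latent))
    toc("preprocess")
    if not stage("features"):
        return result

    # -- voxel features ----------------------------------------------------
    tic("features")
    vc = VoxelFeatureConfig(radius=config.voxel.radius, n_bins=config.voxel.n_bins)
    tables = {p.patient_id: assemble_voxel_features(p, vc) for p in prepped}
    toc("features")
    if not stage("habitats"):
        return result

    # -- split + habitat clustering ---------------------------------------
    tic("habitats")
    ids = [p.patient_id for p in prepped]
    outcomes = [p.outcome for p in prepped]
    train_ids, test_ids = split_cohort(ids, outcomes,
                                       ratio=config.modeling.split_ratio,
                                       seed=config.seed)
    pooled = np.vstack([tables[i].matrix for i in train_ids])
    cap = config.clustering.max_pooled_voxels
    if pooled.shape[0] > cap:
        sel = rng.choice(pooled.shape[0], size=cap, replace=False)
        pooled = pooled[sel]
    hab = HabitatKMeans(candidate_k=config.clustering.candidate_k,
                        n_restarts=config.clustering.n_restarts,
                        max_iter=config.clustering.max_iter,
                        random_state=config.seed)
    hab.fit(pooled)
    result.habitat_model = hab
    labelmaps = {p.patient_id: assign_habitats(hab, tables[p.patient_id],
                                               p.tumor_mask)
                 for p in prepped}
    if outdir:
        result.manifest["artifacts"].append(str(hab.to_json(outdir / "habitat_model.json")))
    toc("habitats")
    if not stage("region_features"):
        return result

    # -- region radiomics + ICC filter ------------------------------------
    tic("region_features")
    ec = ExtractionConfig(families=tuple(config.extraction.families),
                          log_sigmas_mm=config.extraction.log_sigmas_mm,
                          wavelet=config.extraction.wavelet,
                          n_bins=config.extraction.n_bins,
                          min_region_voxels=config.extraction.min_region_voxels)
    k = hab.selected_k_
    region_masks: dict[str, dict[str, np.ndarray]] = {"intratumor": {}}
    for h in range(1, k + 1):
        region_masks[f"habitat_{h}"] = {}
    for p in prepped:
        lm = labelmaps[p.patient_id].values
        region_masks["intratumor"][p.patient_id] = p.tumor_mask.values.astype(bool)
        for h in range(1, k + 1):
            region_masks[f"habitat_{h}"][p.patient_id] = lm == h
    region_tables = {
        tag: region_feature_table(prepped, masks, tag, ec)
        for tag, masks in region_masks.items()
    }
    icc_report = {}
    if config.extraction.icc_enabled:
        # emulate a second delineation by morphological mask perturbation
        irng = np.random.default_rng(config.seed + 1)
        train_set = set(train_ids)
        train_prepped = [p for p in prepped if p.patient_id in train_set]
        pert = {p.patient_id: perturb_mask(p.tumor_mask.values, irng)
                for p in train_prepped}
        for tag in list(region_tables):
            masks2 = {}
            for p in train_prepped:
                base = region_masks[tag][p.patient_id]
                masks2[p.patient_id] = base & pert[p.patient_id] \
                    if tag != "intratumor" else pert[p.patient_id]
            t2 = region_feature_table(train_prepped, masks2, tag, ec)
            t1 = region_tables[tag].loc[t2.index]
            retained, iccs = icc_filter(t1, t2,
                                        threshold=config.extraction.icc_threshold)
            icc_report[tag] = {"n_retained": len(retained),
                               "n_total": int(len(iccs))}
            region_tables[tag] = region_tables[tag][retained]
    manifest["icc"] = icc_report
    toc("region_features")
    if not stage("select"):
        result.manifest["region_tables"] = {t: list(v.columns)
                                            for t, v in region_tables.items()}
        return result

    # -- selection cascade -------------------------------------------------
    tic("select")
    y = pd.Series(outcomes, index=ids)
    cascades: dict[str, SelectionCascade] = {}
    for tag, table in region_tables.items():
        casc = SelectionCascade(alpha=config.selection.alpha,
                                r_threshold=config.selection.r_threshold,
                                folds=config.selection.folds,
                                seed=config.seed,
                                univariate=config.selection.univariate,
                                n_lambdas=config.selection.n_lambdas)
        casc.fit(table.loc[train_ids], y.loc[train_ids].to_numpy())
        cascades[tag] = casc
        result.selection_reports[tag] = casc.report_
    if outdir:
        sel_path = outdir / "selection_reports.json"
        sel_path.write_text(json.dumps(
            {t: r.to_dict() for t, r in result.selection_reports.items()},
            indent=2, default=float))
        manifest["artifacts"].append(str(sel_path))
    toc("select")
    if not stage("fit"):
        return result

    # -- signature models --------------------------------------------------
    tic("fit")
    clin = clinical_table(prepped)
    y_train = y.loc[train_ids].to_numpy()
    y_test = y.loc[test_ids].to_numpy()
    models: dict[tuple[str, str], object] = {}
    score_frames = []
    for tag, table in region_tables.items():
        feats = cascades[tag].selected_features_
        if not feats:
            manifest["warnings"].append(f"{tag}: no features selected; skipped")
            continue
        Xtr = cascades[tag].transform(table.loc[train_ids])
        Xte = cascades[tag].transform(table.loc[test_ids])
        for kind, label in (("logistic", "LR"), ("mlp", "MLP")):
            clf = SignatureClassifier(kind=kind,
                                      hidden_units=config.modeling.mlp_hidden_units,
                                      random_state=config.seed)
            clf.fit(Xtr, y_train)
            models[(tag, label)] = clf
            for cohort, Xc, yc in (("train", Xtr, y_train), ("test", Xte, y_test)):
                s = clf.decision_scores(Xc)
                result.reports[(tag, label, cohort)] = evaluate_scores(
                    f"{tag}_{label}", cohort, s, yc, clf.threshold_)
                score_frames.append(pd.DataFrame({
                    "patient_id": Xc.index, "model": f"{tag}_{label}",
                    "cohort": cohort, "score": s, "outcome": yc}))

    # clinicopathologic signature
    cf = [c for c in config.modeling.clinical_features if c in clin.columns]
    Ctr, Cte = clin.loc[train_ids, cf], clin.loc[test_ids, cf]
    for kind, label in (("logistic", "LR"), ("mlp", "MLP")):
        clf = SignatureClassifier(kind=kind,
                                  hidden_units=config.modeling.mlp_hidden_units,
                                  random_state=config.seed)
        clf.fit(Ctr, y_train)
        models[("clinical", label)] = clf
        for cohort, Xc, yc in (("train", Ctr, y_train), ("test", Cte, y_test)):
            s = clf.decision_scores(Xc)
            result.reports[("clinical", label, cohort)] = evaluate_scores(
                f"clinical_{label}", cohort, s, yc, clf.threshold_)
            score_frames.append(pd.DataFrame({
                "patient_id": Xc.index, "model": f"clinical_{label}",
                "cohort": cohort, "score": s, "outcome": yc}))

    # nomogram: best habitat radscore (training LR AUC) + clinical score
    habitat_tags = [t for t in region_tables if t.startswith("habitat_")
                    and (t, "LR", "train") in result.reports]
    if habitat_tags:
        best_tag = max(habitat_tags,
                       key=lambda t: result.reports[(t, "LR", "train")].auc)
        manifest["nomogram_habitat"] = best_tag
        clin_label = "MLP" if config.modeling.nomogram_clinical_kind == "mlp" else "LR"
        clin_model = models[("clinical", clin_label)]
        comp_tr = pd.DataFrame({
            "radscore": cascades[best_tag].radscore(region_tables[best_tag].loc[train_ids]),
            "clinical_score": clin_model.decision_scores(Ctr),
        }, index=train_ids)
        comp_te = pd.DataFrame({
            "radscore": cascades[best_tag].radscore(region_tables[best_tag].loc[test_ids]),
            "clinical_score": clin_model.decision_scores(Cte),
        }, index=test_ids)
        nomo = NomogramModel()
        nomo.fit(comp_tr, y_train)
        models[("nomogram", "LR")] = nomo
        for cohort, Xc, yc in (("train", comp_tr, y_train), ("test", comp_te, y_test)):
            s = nomo.decision_scores(Xc)
            result.reports[("nomogram", "LR", cohort)] = evaluate_scores(
                "nomogram", cohort, s, yc, nomo.threshold_)
            score_frames.append(pd.DataFrame({
                "patient_id": Xc.index, "model": "nomogram", "cohort": cohort,
                "score": s, "outcome": yc}))
    result.models = models  # type: ignore[attr-defined]
    result.scores = pd.concat(score_frames, ignore_index=True) if score_frames else None
    toc("fit")
    if not stage("evaluate"):
        return result

    # -- reporting ---------------------------------------------------------
    tic("evaluate")
    result.comparison_table = cohort_comparison_table(clin.drop(columns=["pcr"]),
                                                      clin["pcr"])
    manifest["train_ids"] = train_ids
    manifest["test_ids"] = test_ids
    manifest["selected_k"] = int(hab.selected_k_)
    manifest["ch_scores"] = {str(kk): float(v) for kk, v in hab.ch_scores_.items()}
    if outdir:
        summary = result.summary()
        spath = outdir / "model_summary.csv"
        summary.to_csv(spath, index=False)
        manifest["artifacts"].append(str(spath))
        if result.scores is not None:
            scpath = outdir / "patient_scores.csv"
            result.scores.to_csv(scpath, index=False)
            manifest["artifacts"].append(str(scpath))
        cpath = outdir / "comparison_table.csv"
        result.comparison_table.to_csv(cpath, index=False)
        manifest["artifacts"].append(str(cpath))
        try:
            from . import plots
            figdir = outdir / "figures"
            manifest["artifacts"] += [str(p) for p in
                                      plots.render_report_figures(result, figdir)]
        except Exception as exc:  # figures are best-effort
            manifest["warnings"].append(f"figure rendering failed: {exc}")
        mpath = outdir / "run_manifest.json"
        mpath.write_text(json.dumps(manifest, indent=2, default=str))
    toc("evaluate")
    return result
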