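"""End-to-end pipeline: cohort → Z-scores → atrophy calls → topography
maps → outcome models, with seeding, logging and a run report.

Inputs are either a synthetic cohort generated in-process or user data
(CSV volume/clinical tables plus NIfTI lesion masks) in the dialects
written by the synthetic generator.  All gap-filling analysis choices
(multiplicity, PI sweep, FWHM, quantile family) surface as config fields.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import atrophy, outcomes, synth, topography

logger = logging.getLogger("diaschisis")

COUNT_MODEL_TERMS = [
    "bilateral",
    "side_left",
    "baseline_cortical_volume_10ml",
    "age_years",
    "followup_months",
    "sex_male",
    "stroke_volume_ml",
    "stroke_volume_ml:bilateral",
]
COUNT_CENTER_TERMS = ["baseline_cortical_volume_10ml", "age_years", "followup_months"]
ORDINAL_TERMS = ["mrs_baseline_high", "bilateral", "age_years", "sex_male", "n_atrophic"]


@dataclass
class RunConfig:
    """Single config governing every stage."""

    volumes_csv: str | None = None
    masks_dir: str | None = None
    clinical_csv: str | None = None
    out_dir: str = "out"
    alpha: float = 0.05
    multiplicity: str = "datasets"      # "datasets" or "fixed:<m>"
    pi_sweep: bool = False
    fwhm_mm: float = 5.0
    include_fixed_uncertainty: bool = True
    quantile_family: str = "t"      # "t" (df = n_subjects-1) or "normal"
    seed: int = 0
    cohort: dict = field(default_factory=dict)   # CohortConfig overrides

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must lie in (0,1), got {self.alpha}")
        if self.fwhm_mm < 0:
            raise ValueError("fwhm_mm must be >= 0")
        if self.quantile_family not in ("t", "normal"):
            raise ValueError("quantile_family must be 't' or 'normal'")
        if self.multiplicity != "datasets":
            if not self.multiplicity.startswith("fixed:"):
                raise ValueError(
                    "multiplicity must be 'datasets' or 'fixed:<m>', got "
                    f"{self.multiplicity!r}"
                )
            int(self.multiplicity.split(":", 1)[1])


@dataclass
class RunReport:
    n_datasets: int
    n_subjects: int
    m_bonferroni: int
    level_adjusted: float
    n_datasets_with_atrophy: int
    median_atrophic_areas: float
    lobe_group_sizes: dict
    count_model_rr: dict
    ordinal_stratified_or: dict
    sweep_counts: dict = field(default_factory=dict)
    degenerate_reference_areas: int = 0
    seed: int = 0
    decisions: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True, default=float)


# ---------------------------------------------------------------------------
# covariate assembly
# ---------------------------------------------------------------------------

def assemble_dataset_covariates(
    calls: atrophy.AtrophyCallSet,
    volumes: pd.DataFrame,
    masks: list,
    clinical: pd.DataFrame,
) -> pd.DataFrame:
    """One row per dataset with the count-model covariates (Table-style
    units: stroke volume in ml, baseline cortical volume in 10 ml,
    follow-up in months, age in years)."""
    n_atrophic = calls.n_atrophic
    info = volumes.groupby("dataset_id").agg(
        subject_id=("subject_id", "first"),
        followup_months=("time_months", "max"),
    )
    base_target = (
        volumes[(volumes["role"] == "target") & (volumes["time_months"] == 0)]
        .groupby("dataset_id")["volume_ml"]
        .sum()
    )
    has_ref = volumes[volumes["role"] == "reference"]["dataset_id"].unique()
    mask_by_id = {m.dataset_id: m for m in masks}
    rows = []
    for dataset_id, sub in info.iterrows():
        mask = mask_by_id.get(dataset_id)
        if mask is None:
            raise ValueError(f"no lesion mask for dataset {dataset_id}")
        rows.append(
            {
                "dataset_id": dataset_id,
                "subject_id": sub["subject_id"],
                "n_atrophic": int(n_atrophic.get(dataset_id, 0)),
                "stroke_volume_ml": mask.volume_ml,
                "bilateral": int(dataset_id not in has_ref),
                "side_left": int(mask.side == "left"),
                "baseline_cortical_volume_10ml": float(base_target[dataset_id]) / 10.0,
                "followup_months": float(sub["followup_months"]),
            }
        )
    cov = pd.DataFrame(rows)
    clin = clinical.set_index("subject_id")
    cov["age_years"] = cov["subject_id"].map(clin["age_years"]).astype(float)
    cov["sex_male"] = cov["subject_id"].map(clin["sex_male"]).astype(int)
    return cov


def patient_outcome_table(
    covariates: pd.DataFrame, clinical: pd.DataFrame
) -> pd.DataFrame:
    """One row per patient for the ordinal models; a bilateral patient's
    atrophic-area count is the sum over both datasets."""
    per_patient = covariates.groupby("subject_id").agg(
        n_atrophic=("n_atrophic", "sum"),
        bilateral=("bilateral", "max"),
    )
    out = clinical.drop(columns=["bilateral", "n_atrophic"], errors="ignore").merge(
        per_patient, left_on="subject_id", right_index=True
    )
    out["bilateral"] = out["bilateral"].astype(int)
    out["sex_male"] = out["sex_male"].astype(int)
    return outcomes.dichotomize_scores(out)


# ---------------------------------------------------------------------------
# cohort summary
# ---------------------------------------------------------------------------

def summarize_cohort(
    volumes: pd.DataFrame,
    clinical: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
) -> dict:
    """Descriptive summary (medians/IQRs, means/SDs) of a cohort."""
    if len(volumes) == 0 or len(clinical) == 0:
        raise ValueError("cannot summarize an empty cohort")
    for col in ("dataset_id", "subject_id", "time_months"):
        if col not in volumes.columns:
            raise ValueError(f"volume table missing column {col!r}")
    follow = volumes[volumes["time_months"] > 0]
    last = follow.groupby("dataset_id")["time_months"].max()
    n_follow = (
        follow.groupby(["subject_id", "time_months"]).size().reset_index()
        .groupby("subject_id").size()
    )
    out = {
        "n_subjects": int(volumes["subject_id"].nunique()),
        "n_datasets": int(volumes["dataset_id"].nunique()),
        "age_mean": float(clinical["age_years"].mean()),
        "age_sd": float(clinical["age_years"].std(ddof=1)),
        "n_female": int((~clinical["sex_male"].astype(bool)).sum()),
        "followup_months_median": float(last.median()),
        "followup_months_iqr": float(last.quantile(0.75) - last.quantile(0.25)),
        "followup_count_distribution": {
            int(k): int(v) for k, v in n_follow.value_counts().sort_index().items()
        },
        "mrs_baseline_median": float(clinical["mrs_baseline"].median()),
        "mrs_3month_median": float(clinical["mrs_3month"].median()),
        "nihss_baseline_median": float(clinical["nihss_baseline"].median()),
        "nihss_3month_median": float(clinical["nihss_3month"].median()),
    }
    if covariates is not None:
        out["lesion_volume_mean_ml"] = float(covariates["stroke_volume_ml"].mean())
        out["lesion_volume_sd_ml"] = float(covariates["stroke_volume_ml"].std(ddof=1))
    return out


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def _load_inputs(config: RunConfig):
    if config.volumes_csv is None:
        cohort_kwargs = dict(config.cohort)
        cohort_kwargs.setdefault("seed", config.seed)
        cohort = synth.CohortConfig(**cohort_kwargs)
        data = synth.generate_cohort(cohort)
        return data.volumes, data.masks, data.clinical
    volumes = pd.read_csv(config.volumes_csv)
    clinical = pd.read_csv(config.clinical_csv)
    masks = []
    for path in sorted(Path(config.masks_dir).glob("*.nii*")):
        masks.append(topography.read_mask(path))
    side_by_mean = {}
    for m in masks:
        # side from the mean x (mm) of lesioned voxels: x < 0 is left
        idx = np.argwhere(m.grid > 0)
        mm = idx @ m.affine[:3, :3].T + m.affine[:3, 3]
        m.side = "left" if mm[:, 0].mean() < 0 else "right"
        side_by_mean[m.dataset_id] = m.side
    return volumes, masks, clinical


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute every stage and write all outputs under ``config.out_dir``."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "load-inputs"
    try:
        volumes, masks, clinical = _load_inputs(config)

        stage = "zscore-standardize"
        zscores = atrophy.zscore_standardize(volumes)

        stage = "reference-fits"
        fits = atrophy.fit_all_reference_areas(
            zscores, quantile_family=config.quantile_family
        )
        degenerate = sum(f.degenerate for f in fits.values())

        stage = "atrophy-calls"
        n_datasets = int(zscores["dataset_id"].nunique())
        if config.multiplicity == "datasets":
            m = n_datasets
        else:
            m = int(config.multiplicity.split(":", 1)[1])
        level_adjusted, _ = atrophy.bonferroni_level(config.alpha, m)
        calls = atrophy.call_atrophic_areas(
            zscores, fits, level_adjusted,
            level_nominal=1 - config.alpha, m=m,
            include_fixed_uncertainty=config.include_fixed_uncertainty,
        )
        sweep_counts = {}
        if config.pi_sweep:
            sweep = atrophy.sweep_pi_levels(
                zscores, fits, m,
                include_fixed_uncertainty=config.include_fixed_uncertainty,
            )
            sweep_counts = {
                f"{level:.2f}": int(cs.calls["is_atrophic"].sum())
                for level, cs in sweep.items()
            }
            pd.DataFrame(
                sorted(sweep_counts.items()), columns=["pi_level", "n_atrophic_total"]
            ).to_csv(out / "pi_sweep.csv", index=False)

        stage = "lesion-topography"
        groups = topography.assign_lobe_groups(calls)
        maps = topography.build_topography_maps(masks, groups, config.fwhm_mm)
        mapdir = out / "maps"
        mapdir.mkdir(exist_ok=True)
        topography.write_map(maps["overall"], mapdir / "overall_probability.nii.gz")
        for lobe in topography.COMBINE_ORDER:
            topography.write_map(
                maps["probability"][lobe], mapdir / f"{lobe}_probability.nii.gz"
            )
            topography.write_map(maps["ratio"][lobe], mapdir / f"{lobe}_ratio.nii.gz")
        topography.write_map(maps["combined"], mapdir / "combined_lobes.nii.gz")
        legend = {
            "codes": maps["combined"].meta["codes"],
            "tie_break_order": maps["combined"].meta["tie_break_order"],
            "n_tie_voxels": int(maps["combined"].meta["tie_mask"].sum()),
        }
        (mapdir / "combined_legend.json").write_text(json.dumps(legend, indent=2))

        stage = "count-model"
        covariates = assemble_dataset_covariates(calls, volumes, masks, clinical)
        cov_centered = outcomes.center_covariates(covariates, COUNT_CENTER_TERMS)
        count_fit = outcomes.fit_count_model(cov_centered, COUNT_MODEL_TERMS)
        count_fit.stratified_rr = outcomes.stratified_effect(
            cov_centered, "stroke_volume_ml", "bilateral",
            covariates=[t for t in COUNT_MODEL_TERMS
                        if "stroke_volume_ml" not in t and t != "bilateral"],
        )
        count_fit.table().to_csv(out / "count_model.csv", index=False)

        stage = "ordinal-model"
        patients = patient_outcome_table(covariates, clinical)
        patients = outcomes.center_covariates(patients, ["age_years"])
        ordinal_fit = outcomes.fit_ordinal_model(
            patients, "mrs_3month", ORDINAL_TERMS,
            stratified=("n_atrophic", "mrs_baseline_high"),
        )
        ordinal_fit.levelwise_or = outcomes.proportionality_check(
            patients, "mrs_3month", ORDINAL_TERMS
        )
        ordinal_fit.table().to_csv(out / "ordinal_model.csv", index=False)
        ordinal_fit.levelwise_or.to_csv(out / "proportionality.csv", index=False)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    calls.calls.to_csv(out / "calls.csv", index=False)
    fits_json = {
        area: {
            "beta": f.beta, "se_beta": f.se_beta, "sigma_b": f.sigma_b,
            "sigma_e": f.sigma_e, "n_obs": f.n_obs, "n_subjects": f.n_subjects,
            "degenerate": f.degenerate, "quantile_family": f.quantile_family,
            "df_resid": f.df_resid,
        }
        for area, f in fits.items()
    }
    (out / "reference_fits.json").write_text(
        json.dumps(fits_json, indent=2, sort_keys=True)
    )

    n_atrophic = calls.n_atrophic
    report = RunReport(
        n_datasets=n_datasets,
        n_subjects=int(volumes["subject_id"].nunique()),
        m_bonferroni=m,
        level_adjusted=level_adjusted,
        n_datasets_with_atrophy=calls.datasets_with_atrophy,
        median_atrophic_areas=float(n_atrophic.median()),
        lobe_group_sizes={k: len(v) for k, v in groups.items()},
        count_model_rr={
            "volume_bilateral_interaction": count_fit.rr["stroke_volume_ml:bilateral"],
            "volume_unilateral_stratum": count_fit.stratified_rr[0]["rr"],
            "volume_bilateral_stratum": count_fit.stratified_rr[1]["rr"],
        },
        ordinal_stratified_or={
            str(k): v["or"] for k, v in ordinal_fit.stratified_or.items()
        },
        sweep_counts=sweep_counts,
        degenerate_reference_areas=degenerate,
        seed=config.seed,
        decisions={
            "standardization_sd": "sample (n-1) over baseline datasets",
            "quantile_family": config.quantile_family,
            "multiplicity": config.multiplicity,
            "smoothing_boundary": "reflect",
            "tie_break_order": list(topography.COMBINE_ORDER),
        },
    )
    (out / "report.json").write_text(report.to_json())
    logger.info(
        "pipeline done: %d datasets, %d with atrophy",
        report.n_datasets, report.n_datasets_with_atrophy,
    )
    return report
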