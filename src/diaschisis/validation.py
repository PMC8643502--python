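"""Calibration and recovery experiments.

These functions run the package end-to-end on seeded synthetic inputs
and measure the properties the method is supposed to have: family-wise
null calibration of the atrophy calls, unbiased recovery of the
reference-model parameters, confidence-interval coverage of the count
and ordinal outcome models, exact agreement of the lesion-topography
maps with brute-force per-voxel recomputation, and monotonicity of the
prediction-interval sweep.  Both the test suite and the reproduction
script are thin wrappers around them.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from . import topography as topo
from .atrophy import (
    bonferroni_level,
    call_atrophic_areas,
    fit_all_reference_areas,
    fit_reference_model,
    sweep_pi_levels,
    zscore_standardize,
)
from .outcomes import dichotomize_scores, fit_count_model, fit_ordinal_model
from .synth import (
    CohortConfig,
    generate_clinical_scores,
    generate_cohort,
    sample_atrophic_counts,
    sample_lesion_volumes,
)


def null_calibration(n_cohorts: int = 200, seed: int = 0, alpha: float = 0.05) -> dict:
    """Per-dataset rate of >=1 flagged target area in atrophy-free cohorts.

    Each cohort is a full study-sized replicate (22 unilateral + 7
    bilateral) with no injected atrophy, analysed at the Bonferroni-
    adjusted level (m = number of datasets).  Under calibrated bands the
    rate is bounded by alpha; the Monte-Carlo SE is computed over cohort
    means (datasets within a cohort share fitted bands).
    """
    rng = np.random.default_rng(seed)
    rates = []
    for _ in range(n_cohorts):
        cfg = CohortConfig(
            seed=int(rng.integers(2**31)), atrophic_area_fraction=0.0
        )
        data = generate_cohort(cfg)
        zsc = zscore_standardize(data.volumes)
        fits = fit_all_reference_areas(zsc)
        m = int(zsc["dataset_id"].nunique())
        level, _ = bonferroni_level(alpha, m)
        calls = call_atrophic_areas(zsc, fits, level, level_nominal=1 - alpha, m=m)
        rates.append(float((calls.n_atrophic > 0).mean()))
    rates = np.asarray(rates)
    return {
        "rate": float(rates.mean()),
        "mc_se": float(rates.std(ddof=1) / math.sqrt(len(rates))),
        "alpha": alpha,
        "n_cohorts": n_cohorts,
    }


def slope_recovery(
    n_reps: int = 100,
    n_subjects: int = 200,
    seed: int = 0,
    beta: float = -0.05,
    sigma_b: float = 0.02,
    sigma_e: float = 0.1,
) -> dict:
    """Unbiasedness of the reference-model fit at moderate size.

    Simulates z_change = (beta + b_i) t + eps with 1-3 follow-ups per
    subject and refits; reports the mean estimate and Monte-Carlo SE of
    the mean per parameter.
    """
    rng = np.random.default_rng(seed)
    est = np.empty((n_reps, 3))
    for r in range(n_reps):
        rows = []
        for i in range(n_subjects):
            b = rng.normal(0.0, sigma_b)
            for t in rng.uniform(1.0, 12.0, rng.integers(1, 4)):
                rows.append((f"s{i}", t, (beta + b) * t + rng.normal(0.0, sigma_e)))
        df = pd.DataFrame(rows, columns=["subject_id", "time_months", "z_change"])
        fit = fit_reference_model(df, "sim")
        est[r] = (fit.beta, fit.sigma_b, fit.sigma_e)
    out = {}
    for k, (name, truth) in enumerate(
        [("beta", beta), ("sigma_b", sigma_b), ("sigma_e", sigma_e)]
    ):
        mean = float(est[:, k].mean())
        mc_se = float(est[:, k].std(ddof=1) / math.sqrt(n_reps))
        out[name] = {
            "truth": truth, "mean": mean, "mc_se": mc_se,
            "abs_error": abs(mean - truth),
        }
    return out


def count_rr_coverage(
    n_reps: int = 500,
    n_datasets: int = 100,
    rate_ratio: float = 1.08,
    seed: int = 0,
) -> dict:
    """Coverage of the quasi-Poisson 95% Wald CI for the volume effect.

    Each replicate draws bilateral-arm lesion volumes and atrophic-area
    counts from the generator at the configured rate ratio per ml, then
    refits the count model.
    """
    cfg = CohortConfig(volume_count_link=float(np.log(rate_ratio)))
    rng = np.random.default_rng(seed)
    covered = 0
    estimates = []
    for _ in range(n_reps):
        vols = sample_lesion_volumes(cfg, n_datasets, rng)
        counts = sample_atrophic_counts(
            cfg, vols, np.ones(n_datasets, dtype=bool), rng
        )
        df = pd.DataFrame({"n_atrophic": counts, "stroke_volume_ml": vols})
        fit = fit_count_model(df, ["stroke_volume_ml"])
        lo, hi = fit.rr_ci["stroke_volume_ml"]
        covered += lo <= rate_ratio <= hi
        estimates.append(fit.rr["stroke_volume_ml"])
    coverage = covered / n_reps
    return {
        "coverage": float(coverage),
        "mc_se": float(math.sqrt(coverage * (1 - coverage) / n_reps)),
        "mean_rr": float(np.mean(estimates)),
        "true_rr": rate_ratio,
        "n_reps": n_reps,
    }


def ordinal_or_coverage(
    n_reps: int = 200,
    n_patients: int = 150,
    odds_ratio: float = 1.34,
    seed: int = 0,
) -> dict:
    """Coverage of the stratified proportional-odds 95% Wald CI for the
    atrophy-count effect in the high-baseline (mRS >= 3) stratum."""
    cfg = CohortConfig(ordinal_link_beta=float(np.log(odds_ratio)))
    rng = np.random.default_rng(seed)
    covered = fitted = 0
    estimates = []
    for _ in range(n_reps):
        counts = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(n_patients)],
                "n_atrophic": rng.poisson(1.5, n_patients),
                "bilateral": rng.random(n_patients) < 0.25,
            }
        )
        scores = generate_clinical_scores(counts, cfg, rng)
        df = dichotomize_scores(scores)
        df["n_atrophic"] = counts["n_atrophic"].to_numpy()
        try:
            fit = fit_ordinal_model(
                df, "mrs_3month", ["mrs_baseline_high", "n_atrophic"],
                stratified=("n_atrophic", "mrs_baseline_high"),
            )
        except (RuntimeError, ValueError):
            continue
        fitted += 1
        lo, hi = fit.stratified_or[1]["ci"]
        covered += lo <= odds_ratio <= hi
        estimates.append(fit.stratified_or[1]["or"])
    coverage = covered / fitted if fitted else float("nan")
    return {
        "coverage": float(coverage),
        "mc_se": float(math.sqrt(coverage * (1 - coverage) / fitted))
        if fitted else float("nan"),
        "mean_or": float(np.median(estimates)) if estimates else float("nan"),
        "true_or": odds_ratio,
        "n_fitted": fitted,
        "n_reps": n_reps,
    }


def toy_map_oracle(seed: int = 0, shape=(5, 5, 5), n_masks: int = 6) -> dict:
    """Compare every topography stage against brute-force per-voxel
    recomputation on a toy grid; returns maximum absolute deviations."""
    from scipy import ndimage

    rng = np.random.default_rng(seed)
    affine = np.eye(4)
    masks = [
        topo.LesionMask((rng.random(shape) < 0.4).astype(np.uint8), affine, f"d{i}")
        for i in range(n_masks)
    ]
    ids = [m.dataset_id for m in masks]
    groups = {
        "frontal": set(ids[:2]), "occipital": set(ids[2:3]),
        "parietal": set(ids[3:5]), "temporal": set(ids[5:]),
    }
    fwhm = 5.0
    result = topo.build_topography_maps(masks, groups, fwhm_mm=fwhm)
    by_id = {m.dataset_id: m for m in masks}

    overall_bf = np.zeros(shape)
    for idx in np.ndindex(*shape):
        overall_bf[idx] = sum(m.grid[idx] for m in masks) / len(masks)
    prob_err = float(np.abs(result["overall"].grid - overall_bf).max())

    sigma = fwhm * topo.FWHM_TO_SIGMA
    ratio_err = 0.0
    ratio_bf = {}
    for lobe, members in groups.items():
        prob = np.zeros(shape)
        for idx in np.ndindex(*shape):
            prob[idx] = sum(by_id[d].grid[idx] for d in members) / len(members)
        prob_err = max(
            prob_err, float(np.abs(result["probability"][lobe].grid - prob).max())
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            raw = np.where(overall_bf > 0, prob / overall_bf, 0.0)
        ratio_bf[lobe] = ndimage.gaussian_filter(raw, sigma, mode="reflect")
        ratio_err = max(
            ratio_err, float(np.abs(result["ratio"][lobe].grid - ratio_bf[lobe]).max())
        )

    mismatches = 0
    for idx in np.ndindex(*shape):
        if overall_bf[idx] == 0:
            expected = topo.BACKGROUND_CODE
        else:
            values = [ratio_bf[lobe][idx] for lobe in topo.COMBINE_ORDER]
            if max(values) <= 0:
                expected = topo.BACKGROUND_CODE
            else:
                expected = topo.LOBE_CODES[topo.COMBINE_ORDER[int(np.argmax(values))]]
        mismatches += int(result["combined"].grid[idx] != expected)

    # impulse response: mass preservation at FWHM 5 mm
    impulse = np.zeros((41, 41, 41))
    impulse[20, 20, 20] = 1.0
    smoothed = topo.smooth_map(
        topo.VoxelMap(impulse, np.eye(4)), fwhm
    )
    return {
        "probability_max_abs_err": prob_err,
        "ratio_max_abs_err": ratio_err,
        "argmax_mismatches": mismatches,
        "smoothing_mass_error": float(abs(smoothed.grid.sum() - 1.0)),
        "sigma_mm": float(fwhm * topo.FWHM_TO_SIGMA),
    }


def sweep_monotonicity(seed: int = 0) -> dict:
    """Count violations of per-dataset monotonicity of atrophic-area
    counts from the 50% to the 95% nominal PI level on one cohort."""
    data = generate_cohort(CohortConfig(seed=seed))
    zsc = zscore_standardize(data.volumes)
    fits = fit_all_reference_areas(zsc)
    m = int(zsc["dataset_id"].nunique())
    sweep = sweep_pi_levels(zsc, fits, m)
    levels = sorted(sweep)  # ascending nominal level
    violations = 0
    counts = {lvl: sweep[lvl].n_atrophic for lvl in levels}
    for lo, hi in zip(levels, levels[1:]):
        violations += int((counts[lo] < counts[hi]).sum())
    return {
        "violations": violations,
        "levels": levels,
        "total_calls_at_50": int(counts[levels[0]].sum()),
        "total_calls_at_95": int(counts[levels[-1]].sum()),
    }
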