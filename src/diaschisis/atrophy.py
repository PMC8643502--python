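"""Prediction-interval based calling of atrophic cortical areas.

The method standardizes longitudinal per-area cortical volumes to
baseline Z-scores, fits — per area, on reference-hemisphere data only —
an intercept-free linear mixed model of Z-change over time with a
per-subject random slope,

    z_change_ij = (beta + b_i) * t_ij + eps_ij,
    b_i ~ N(0, sigma_b^2),  eps_ij ~ N(0, sigma_e^2),

and flags a target area as atrophic when its observed Z-change at the
last follow-up falls strictly beneath the lower limit of a Bonferroni-
corrected prediction interval of the homologous reference area.
Unilateral datasets use conditional predictions (fixed + estimated
subject effect); bilateral datasets, for which no reference hemisphere
exists, use marginal predictions (fixed effects only).

The model has no intercept because Z-change at baseline is zero by
definition; the random effect is therefore a slope, not an intercept.
Fitting is by maximum likelihood with the variance ratio
gamma = sigma_b^2 / sigma_e^2 profiled out (the fixed slope and the
residual scale have closed-form ML solutions given gamma).

Prediction limits default to Student-t quantiles with n_subjects - 1
degrees of freedom: subjects are the independent units, and with one or
two follow-ups each the variance scale carries roughly between-subject
information only.  Plug-in bands with standard-normal quantiles are
markedly anti-conservative with reference sets of ~20 cases (the null
flag rate runs several-fold above nominal); the quantile family is
recorded in the fit metadata and "normal" remains available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

VOLUME_COLUMNS = [
    "subject_id",
    "dataset_id",
    "role",
    "lobe",
    "area_label",
    "time_months",
    "volume_ml",
]

DEFAULT_SWEEP_LEVELS = (0.95, 0.90, 0.80, 0.70, 0.60, 0.50)


# ---------------------------------------------------------------------------
# Z-score standardization
# ---------------------------------------------------------------------------

def zscore_standardize(table: pd.DataFrame) -> pd.DataFrame:
    """Convert volumes to Z-scores relative to the baseline distribution.

    Per area, the baseline volumes across datasets (a unilateral dataset
    contributes both its target- and reference-hemisphere baselines)
    define the mean and sample SD used for standardization; ``z_change``
    is the Z-score at a timepoint minus the same dataset's and
    hemisphere's baseline Z-score (0 at baseline by construction).
    Sharing one per-area scale between target and reference data keeps
    the target change and the reference band on the same footing.

    Raises
    ------
    ValueError
        If a (dataset, area) lacks a unique baseline record, fewer than
        two datasets contribute a baseline, or the baseline variance of
        an area is zero.
    """
    missing = [c for c in VOLUME_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"volume table missing columns: {missing}")
    out = table.copy()
    is_base = out["time_months"] == 0

    n_base = (
        out[is_base].groupby(["dataset_id", "role", "area_label"]).size()
    )
    if (n_base != 1).any():
        bad = n_base[n_base != 1].index[0]
        raise ValueError(f"dataset/area without unique baseline record: {bad}")
    per_da = out.groupby(["dataset_id", "role", "area_label"]).size().index
    base_index = set(n_base.index)
    for key in per_da:
        if key not in base_index:
            raise ValueError(f"dataset/area without unique baseline record: {key}")

    base = out[is_base].groupby("area_label")["volume_ml"]
    mu = base.mean()
    sd = base.std(ddof=1)
    counts = base.size()
    if (counts < 2).any():
        area = counts[counts < 2].index[0]
        raise ValueError(f"fewer than 2 baseline datasets for area {area}")
    if (sd <= 0).any() or sd.isna().any():
        area = sd[(sd <= 0) | sd.isna()].index[0]
        raise ValueError(f"zero baseline variance for area {area}")

    keys = out["area_label"]
    out["z"] = (out["volume_ml"].to_numpy() - mu.loc[keys].to_numpy()) / sd.loc[
        keys
    ].to_numpy()

    zbase = out.loc[is_base].set_index(["dataset_id", "role", "area_label"])["z"]
    da_keys = pd.MultiIndex.from_frame(out[["dataset_id", "role", "area_label"]])
    out["z_change"] = out["z"].to_numpy() - zbase.loc[da_keys].to_numpy()
    out.loc[is_base, "z_change"] = 0.0
    return out


# ---------------------------------------------------------------------------
# Reference mixed model
# ---------------------------------------------------------------------------

@dataclass
class ReferenceFit:
    """Intercept-free random-slope fit of one reference area."""

    area_label: str
    beta: float                      # fixed slope, z-units/month
    se_beta: float
    sigma_b: float                   # SD of per-subject random slope
    sigma_e: float                   # residual SD, z-units
    subject_effects: dict = field(default_factory=dict)   # subject -> BLUP b_i
    subject_cond_var: dict = field(default_factory=dict)  # subject -> Var(b_i | data)
    n_obs: int = 0
    n_subjects: int = 0
    degenerate: bool = False
    quantile_family: str = "normal"
    df_resid: float = math.inf       # t degrees of freedom when family is "t"

    def slope_p_value(self) -> float:
        """Two-sided Wald p-value for beta = 0, on the fit's quantile
        family (t with n_subjects - 1 df by default)."""
        if self.degenerate or self.se_beta == 0 or not np.isfinite(self.se_beta):
            return float("nan")
        z = abs(self.beta / self.se_beta)
        if self.quantile_family == "t" and math.isfinite(self.df_resid):
            return float(2.0 * stats.t.sf(z, self.df_resid))
        return float(2.0 * stats.norm.sf(z))


def _profile_loglik(gamma, y, X, t, groups, return_fit=False):
    """ML profile over (beta, sigma_e^2) at fixed gamma = sigma_b^2/sigma_e^2.

    Per-subject covariance is sigma_e^2 * W_i with W_i = I + gamma t_i t_i';
    the rank-one Woodbury identity gives W_i^{-1} and log|W_i| cheaply.
    """
    n, p = X.shape
    XtWX = np.zeros((p, p))
    XtWy = np.zeros(p)
    logdet = 0.0
    per_subject = []
    for idx in groups:
        ti = t[idx]
        Xi = X[idx]
        yi = y[idx]
        tt = float(ti @ ti)
        c = gamma / (1.0 + gamma * tt)
        Wi_inv_X = Xi - np.outer(ti, c * (ti @ Xi))
        Wi_inv_y = yi - ti * (c * (ti @ yi))
        XtWX += Xi.T @ Wi_inv_X
        XtWy += Xi.T @ Wi_inv_y
        logdet += math.log1p(gamma * tt)
        per_subject.append((idx, ti, c))
    beta = np.linalg.solve(XtWX, XtWy)
    # residual quadratic form r' W^{-1} r
    quad = 0.0
    for idx, ti, c in per_subject:
        ri = y[idx] - X[idx] @ beta
        quad += float(ri @ ri) - c * float(ti @ ri) ** 2
    quad = max(quad, 1e-300)
    sigma_e2 = quad / n
    ll = -0.5 * (n * (math.log(2 * math.pi * sigma_e2) + 1.0) + logdet)
    if not return_fit:
        return ll
    cov_beta = sigma_e2 * np.linalg.inv(XtWX)
    return ll, beta, sigma_e2, cov_beta


def _fit_random_slope(y, X, t, subjects):
    """Maximize the profiled likelihood over gamma >= 0."""
    labels, inverse = np.unique(subjects, return_inverse=True)
    groups = [np.flatnonzero(inverse == k) for k in range(len(labels))]

    def nll(log_gamma):
        return -_profile_loglik(math.exp(log_gamma), y, X, t, groups)

    ll0 = _profile_loglik(0.0, y, X, t, groups)
    # coarse bracket on log-gamma, then local refinement
    grid = np.linspace(-8.0, 6.0, 15)
    vals = [-nll(g) for g in grid]
    best = int(np.argmax(vals))
    if vals[best] <= ll0 + 1e-10:
        gamma = 0.0
    else:
        lo = grid[max(best - 1, 0)]
        hi = grid[min(best + 1, len(grid) - 1)]
        res = optimize.minimize_scalar(nll, bounds=(lo, hi), method="bounded")
        gamma = math.exp(res.x) if -res.fun > ll0 else 0.0
    ll, beta, sigma_e2, cov_beta = _profile_loglik(
        gamma, y, X, t, groups, return_fit=True
    )
    sigma_b2 = gamma * sigma_e2

    blups, cond_vars = {}, {}
    for k, idx in enumerate(groups):
        ti = t[idx]
        ri = y[idx] - X[idx] @ beta
        tt = float(ti @ ti)
        c = gamma / (1.0 + gamma * tt)
        # b_i = sigma_b^2 t' V^{-1} r = gamma * t' W^{-1} r
        blups[labels[k]] = gamma * (float(ti @ ri) - c * tt * float(ti @ ri))
        # Var(b_i | y) = sigma_b^2 - sigma_b^4 t'V^{-1}t
        tWt = tt - c * tt * tt
        cond_vars[labels[k]] = sigma_b2 - gamma * sigma_b2 * tWt
    return beta, cov_beta, math.sqrt(sigma_b2), math.sqrt(sigma_e2), blups, cond_vars


def fit_reference_model(
    zchanges: pd.DataFrame,
    area_label: str | None = None,
    quantile_family: str = "t",
) -> ReferenceFit:
    """Fit the intercept-free random-slope model to one area's follow-ups.

    ``zchanges`` holds follow-up records only (``time_months > 0``) with
    columns ``subject_id``, ``time_months``, ``z_change``.  A single
    observation is handled by exact interpolation (beta = z/t, both
    variance components zero) and flagged degenerate.
    """
    data = zchanges[zchanges["time_months"] > 0]
    if area_label is None:
        area_label = (
            str(data["area_label"].iloc[0]) if "area_label" in data and len(data) else "?"
        )
    if len(data) == 0:
        raise ValueError(f"no follow-up observations for area {area_label}")
    t = data["time_months"].to_numpy(dtype=float)
    y = data["z_change"].to_numpy(dtype=float)
    subjects = data["subject_id"].to_numpy()
    n = len(y)

    if n == 1:
        beta = float(y[0] / t[0])
        return ReferenceFit(
            area_label, beta, 0.0, 0.0, 0.0,
            {subjects[0]: 0.0}, {subjects[0]: 0.0}, 1, 1, degenerate=True,
            quantile_family=quantile_family, df_resid=1.0,
        )

    # noise-free trajectories: exact no-intercept fit, zero variances
    beta_ols = float(t @ y / (t @ t))
    resid = y - beta_ols * t
    if float(resid @ resid) < 1e-24 * max(1.0, float(y @ y)):
        uniq = np.unique(subjects)
        return ReferenceFit(
            area_label, beta_ols, 0.0, 0.0, 0.0,
            {s: 0.0 for s in uniq}, {s: 0.0 for s in uniq},
            n, len(uniq), degenerate=False,
            quantile_family=quantile_family, df_resid=float(max(len(uniq) - 1, 1)),
        )

    X = t[:, None]
    beta, cov_beta, sigma_b, sigma_e, blups, cond_vars = _fit_random_slope(
        y, X, t, subjects
    )
    return ReferenceFit(
        area_label,
        float(beta[0]),
        float(math.sqrt(cov_beta[0, 0])),
        sigma_b,
        sigma_e,
        blups,
        cond_vars,
        n,
        len(blups),
        quantile_family=quantile_family,
        df_resid=float(max(len(blups) - 1, 1)),
    )


# ---------------------------------------------------------------------------
# Bonferroni arithmetic and prediction bands
# ---------------------------------------------------------------------------

def bonferroni_level(alpha: float, m: int) -> tuple[float, float]:
    """Return (adjusted two-sided coverage, per-test threshold) for m tests.

    ``bonferroni_level(0.05, 36)`` gives the 99.86% prediction-interval
    coverage used when 36 datasets are tested simultaneously.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    if m < 1:
        raise ValueError(f"number of tests m must be >= 1, got {m}")
    threshold = alpha / m
    return 1.0 - threshold, threshold


def _band_quantile(fit: "ReferenceFit", level_adjusted: float) -> float:
    """Two-sided quantile at the fit's family: t(df_resid) or normal."""
    p = 0.5 + level_adjusted / 2.0
    if fit.quantile_family == "t" and math.isfinite(fit.df_resid):
        return float(stats.t.ppf(p, fit.df_resid))
    return float(stats.norm.ppf(p))


@dataclass
class PredictionBand:
    area_label: str
    time_months: float
    center: float
    lower: float
    upper: float
    level_nominal: float
    level_adjusted: float
    mode: str


def prediction_band(
    fit: ReferenceFit,
    t: float,
    level_adjusted: float,
    mode: str = "marginal",
    subject_id=None,
    level_nominal: float | None = None,
    include_fixed_uncertainty: bool = True,
) -> PredictionBand:
    """Prediction interval for a new Z-change observation at time ``t``.

    marginal:    center beta*t,       var = t^2 se^2 + t^2 sigma_b^2 + sigma_e^2
    conditional: center (beta+b_i)*t, var = t^2 se^2 + t^2 Var(b_i|data) + sigma_e^2

    ``include_fixed_uncertainty`` controls the t^2 se_beta^2 term (the
    slope-estimation uncertainty); limits use the fit's quantile family
    (Student-t with n_subjects - 1 df for fitted models by default).
    """
    if t <= 0:
        raise ValueError("prediction time must be positive")
    if mode not in ("marginal", "conditional"):
        raise ValueError(f"unknown prediction mode {mode!r}")
    var = fit.sigma_e**2
    if include_fixed_uncertainty:
        var += (t * fit.se_beta) ** 2
    if mode == "conditional":
        if subject_id is None:
            raise ValueError("conditional prediction requires a subject_id")
        if subject_id not in fit.subject_effects:
            raise ValueError(
                f"subject {subject_id!r} has no estimated effect in area "
                f"{fit.area_label}"
            )
        center = (fit.beta + fit.subject_effects[subject_id]) * t
        var += fit.subject_cond_var[subject_id] * t**2
    else:
        center = fit.beta * t
        var += (fit.sigma_b * t) ** 2
    q = _band_quantile(fit, level_adjusted)
    half = q * math.sqrt(var)
    return PredictionBand(
        fit.area_label,
        float(t),
        float(center),
        float(center - half),
        float(center + half),
        level_nominal if level_nominal is not None else level_adjusted,
        level_adjusted,
        mode,
    )


# ---------------------------------------------------------------------------
# Atrophy calling
# ---------------------------------------------------------------------------

@dataclass
class AtrophyCallSet:
    """Per-dataset, per-target-area atrophy decisions at one PI level."""

    calls: pd.DataFrame            # dataset_id, area_label, lobe, time_months,
                                   # z_change, lower_limit, is_atrophic, mode
    level_nominal: float
    level_adjusted: float
    m: int

    @property
    def n_atrophic(self) -> pd.Series:
        """Number of atrophic target areas per dataset."""
        return self.calls.groupby("dataset_id")["is_atrophic"].sum().astype(int)

    @property
    def datasets_with_atrophy(self) -> int:
        return int((self.n_atrophic > 0).sum())


def _dataset_info(zscores: pd.DataFrame) -> pd.DataFrame:
    """Per-dataset subject, bilaterality (no reference rows) and last follow-up."""
    follow = zscores[zscores["time_months"] > 0]
    last = follow.groupby("dataset_id")["time_months"].max()
    has_ref = (
        zscores[zscores["role"] == "reference"].groupby("dataset_id").size()
    )
    subj = zscores.groupby("dataset_id")["subject_id"].first()
    info = pd.DataFrame({"subject_id": subj, "last_followup": last})
    info["bilateral"] = ~info.index.isin(has_ref.index)
    return info


def call_atrophic_areas(
    zscores: pd.DataFrame,
    fits: dict[str, ReferenceFit],
    level_adjusted: float,
    level_nominal: float | None = None,
    m: int = 1,
    include_fixed_uncertainty: bool = True,
) -> AtrophyCallSet:
    """Flag target areas whose Z-change at last follow-up falls strictly
    beneath the lower prediction limit of the homologous reference fit.

    Unilateral datasets (those contributing reference areas) are judged
    against conditional bands using the subject's own random-slope
    estimate; bilateral datasets against marginal bands.
    """
    info = _dataset_info(zscores)
    targets = zscores[(zscores["role"] == "target") & (zscores["time_months"] > 0)]
    qcache: dict = {}
    rows = []
    for dataset_id, grp in targets.groupby("dataset_id", sort=True):
        t_last = float(info.loc[dataset_id, "last_followup"])
        subject = info.loc[dataset_id, "subject_id"]
        bilateral = bool(info.loc[dataset_id, "bilateral"])
        mode = "marginal" if bilateral else "conditional"
        at_last = grp[grp["time_months"] == t_last]
        for rec in at_last.itertuples(index=False):
            fit = fits.get(rec.area_label)
            if fit is None:
                raise ValueError(
                    f"no homologous reference fit for area {rec.area_label}"
                )
            key = (fit.quantile_family, fit.df_resid)
            q = qcache.get(key)
            if q is None:
                q = qcache[key] = _band_quantile(fit, level_adjusted)
            var = fit.sigma_e**2
            if include_fixed_uncertainty:
                var += (t_last * fit.se_beta) ** 2
            if mode == "conditional":
                if subject not in fit.subject_effects:
                    raise ValueError(
                        f"subject {subject!r} has no estimated effect in area "
                        f"{fit.area_label}"
                    )
                center = (fit.beta + fit.subject_effects[subject]) * t_last
                var += fit.subject_cond_var[subject] * t_last**2
            else:
                center = fit.beta * t_last
                var += (fit.sigma_b * t_last) ** 2
            lower = center - q * math.sqrt(var)
            rows.append(
                (
                    dataset_id,
                    rec.area_label,
                    rec.lobe,
                    t_last,
                    float(rec.z_change),
                    lower,
                    bool(rec.z_change < lower),
                    mode,
                )
            )
    calls = pd.DataFrame(
        rows,
        columns=[
            "dataset_id",
            "area_label",
            "lobe",
            "time_months",
            "z_change",
            "lower_limit",
            "is_atrophic",
            "mode",
        ],
    )
    return AtrophyCallSet(
        calls,
        level_nominal if level_nominal is not None else level_adjusted,
        level_adjusted,
        m,
    )


def fit_all_reference_areas(
    zscores: pd.DataFrame,
    quantile_family: str = "t",
) -> dict[str, ReferenceFit]:
    """Fit the reference model for every area with reference-role records."""
    ref = zscores[(zscores["role"] == "reference") & (zscores["time_months"] > 0)]
    fits = {}
    for area, grp in ref.groupby("area_label", sort=True):
        fits[area] = fit_reference_model(
            grp, area_label=area, quantile_family=quantile_family
        )
    return fits


def sweep_pi_levels(
    zscores: pd.DataFrame,
    fits: dict[str, ReferenceFit],
    m: int,
    alpha_levels=DEFAULT_SWEEP_LEVELS,
    include_fixed_uncertainty: bool = True,
) -> dict[float, AtrophyCallSet]:
    """Repeat atrophy calling at several nominal PI levels (each Bonferroni
    adjusted for ``m`` datasets) to assess the consistency of the calls."""
    out = {}
    for level in alpha_levels:
        if not 0 < level < 1:
            raise ValueError(f"PI level must lie in (0,1), got {level}")
        adjusted, _ = bonferroni_level(1.0 - level, m)
        out[level] = call_atrophic_areas(
            zscores,
            fits,
            adjusted,
            level_nominal=level,
            m=m,
            include_fixed_uncertainty=include_fixed_uncertainty,
        )
    return out


# ---------------------------------------------------------------------------
# Reference-area change tests
# ---------------------------------------------------------------------------

def reference_area_change_tests(
    zscores: pd.DataFrame,
    alpha: float = 0.05,
    m: int | None = None,
) -> pd.DataFrame:
    """Per reference area: Wald tests of the common slope and of a
    baseline-volume × time interaction on Z-change.

    The variance decomposition needs at least one subject with two
    follow-ups; otherwise p-values are reported missing and the area is
    flagged degenerate.  The significance threshold is Bonferroni
    ``alpha / m`` with ``m`` defaulting to the number of reference cases.
    """
    ref = zscores[zscores["role"] == "reference"]
    if ref["dataset_id"].nunique() < 2:
        raise ValueError("need at least 2 reference datasets")
    if m is None:
        m = int(ref["dataset_id"].nunique())
    threshold = alpha / m

    base = (
        ref[ref["time_months"] == 0]
        .set_index(["dataset_id", "area_label"])["volume_ml"]
    )
    rows = []
    follow = ref[ref["time_months"] > 0]
    for area, grp in follow.groupby("area_label", sort=True):
        counts = grp.groupby("subject_id").size()
        degenerate = not (counts >= 2).any()
        if degenerate or len(grp) < 3:
            rows.append((area, np.nan, np.nan, False, False, True))
            continue
        t = grp["time_months"].to_numpy(dtype=float)
        y = grp["z_change"].to_numpy(dtype=float)
        subjects = grp["subject_id"].to_numpy()
        keys = pd.MultiIndex.from_arrays(
            [grp["dataset_id"], grp["area_label"]]
        )
        bvol = base.loc[keys].to_numpy(dtype=float)
        bvol_c = bvol - bvol.mean()

        fit = fit_reference_model(grp, area_label=area)
        p_slope = fit.slope_p_value()

        X2 = np.column_stack([t, t * bvol_c])
        try:
            beta2, cov2, *_ = _fit_random_slope(y, X2, t, subjects)
            se_int = math.sqrt(cov2[1, 1])
            df_int = max(fit.n_subjects - 2, 1)
            p_inter = float(2 * stats.t.sf(abs(beta2[1] / se_int), df_int))
        except np.linalg.LinAlgError:
            p_inter = np.nan
        rows.append(
            (
                area,
                p_slope,
                p_inter,
                bool(p_slope < threshold) if np.isfinite(p_slope) else False,
                bool(p_inter < threshold) if np.isfinite(p_inter) else False,
                False,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "area_label",
            "p_slope",
            "p_interaction",
            "slope_significant",
            "interaction_significant",
            "degenerate",
        ],
    )
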