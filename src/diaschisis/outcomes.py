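"""Count and ordinal outcome models.

Two model families quantify the clinical correlates of the atrophy calls:

* a Poisson generalized linear model (log link) for the number of
  atrophic target areas per dataset, corrected for potential
  overdispersion by Pearson-based quasi-likelihood scaling
  (phi = X^2/df; standard errors scaled by sqrt(phi), point estimates
  untouched), reported as rate ratios (RR); and
* proportional-odds (cumulative-logit) ordinal regression — shift
  analysis — of the 3-month mRS/NIHSS, reported as odds ratios (OR),
  with a level-wise binary-logistic table to inspect the proportionality
  assumption (no automatic pass/fail: no unequivocal criterion exists).

Stratum-specific effects (e.g. the volume effect within unilateral and
bilateral arms) come from a nested reparameterization of the interaction
model: each stratum's slope is a direct coefficient, so shared covariate
adjustment is kept and the joint likelihood is identical to the
interaction coding.
"""

from __future__ import annotations

import math
import warnings

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.miscmodels.ordinal_model import OrderedModel

Z95 = float(stats.norm.ppf(0.975))


# ---------------------------------------------------------------------------
# covariate preparation
# ---------------------------------------------------------------------------

def center_covariates(data: pd.DataFrame, terms: list[str]) -> pd.DataFrame:
    """Replace each continuous term by term - cohort mean (idempotent up to
    numerical noise); the means are stored in ``data.attrs['centered_means']``
    for interpretation at the mean."""
    out = data.copy()
    means = dict(out.attrs.get("centered_means", {}))
    for term in terms:
        if not pd.api.types.is_numeric_dtype(out[term]):
            raise ValueError(f"cannot center non-numeric term {term!r}")
        mu = float(out[term].mean())
        out[term] = out[term] - mu
        means[term] = means.get(term, 0.0) + mu
    out.attrs["centered_means"] = means
    return out


def dichotomize_scores(clinical: pd.DataFrame) -> pd.DataFrame:
    """Add dichotomized baseline severity terms.

    mRS: 0-2 (functionally independent) vs >=3 (impaired self-support);
    NIHSS: <6 (none/mild) vs >=6 (moderate-severe).
    """
    out = clinical.copy()
    mrs = out["mrs_baseline"]
    if ((mrs < 0) | (mrs > 6)).any():
        bad = mrs[(mrs < 0) | (mrs > 6)].iloc[0]
        raise ValueError(f"mRS score out of range 0-6: {bad}")
    nihss = out["nihss_baseline"]
    if ((nihss < 0) | (nihss > 42)).any():
        bad = nihss[(nihss < 0) | (nihss > 42)].iloc[0]
        raise ValueError(f"NIHSS score out of range 0-42: {bad}")
    out["mrs_baseline_high"] = (mrs >= 3).astype(int)
    out["nihss_baseline_high"] = (nihss >= 6).astype(int)
    return out


def _design_matrix(data: pd.DataFrame, terms: list[str], intercept: bool = True):
    """Design matrix from a term list; 'a:b' denotes a product term."""
    cols = {}
    for term in terms:
        if ":" in term:
            parts = term.split(":")
            x = np.ones(len(data))
            for p in parts:
                x = x * pd.to_numeric(data[p]).to_numpy(dtype=float)
            cols[term] = x
        else:
            cols[term] = pd.to_numeric(data[term]).to_numpy(dtype=float)
    X = pd.DataFrame(cols, index=data.index)
    if intercept:
        X.insert(0, "Intercept", 1.0)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # identify aliased columns by pivoted QR
        _, r = np.linalg.qr(X.to_numpy())
        diag = np.abs(np.diag(r))
        aliased = [X.columns[i] for i in range(len(diag)) if diag[i] < 1e-8]
        raise ValueError(f"design matrix is rank deficient; aliased terms: {aliased}")
    return X


def nested_stratum_terms(
    data: pd.DataFrame, effect: str, stratifier: str
) -> tuple[pd.DataFrame, list[str]]:
    """Nested coding: effect×(stratum=0) and effect×(stratum=1) columns."""
    s = pd.to_numeric(data[stratifier]).to_numpy(dtype=float)
    if not np.isin(s, (0, 1)).all():
        raise ValueError(f"stratifier {stratifier!r} must be binary 0/1")
    if s.min() == s.max():
        raise ValueError(f"stratifier {stratifier!r} has an empty stratum")
    out = data.copy()
    low = f"{effect}@{stratifier}=0"
    high = f"{effect}@{stratifier}=1"
    x = pd.to_numeric(data[effect]).to_numpy(dtype=float)
    out[low] = x * (1.0 - s)
    out[high] = x * s
    return out, [low, high]


# ---------------------------------------------------------------------------
# count model
# ---------------------------------------------------------------------------

@dataclass
class CountModelFit:
    coefficients: dict
    se: dict
    phi: float
    rr: dict
    rr_ci: dict
    p: dict
    terms: list
    stratified_rr: dict = field(default_factory=dict)
    llf: float = float("nan")

    def table(self) -> pd.DataFrame:
        rows = [
            (t, self.rr[t], *self.rr_ci[t], self.p[t]) for t in self.terms
        ]
        return pd.DataFrame(
            rows, columns=["term", "RR", "ci_low", "ci_high", "p"]
        )


def fit_count_model(
    data: pd.DataFrame,
    terms: list[str],
    outcome: str = "n_atrophic",
    dispersion: str = "pearson",
) -> CountModelFit:
    """Log-link Poisson GLM of a count outcome, with optional Pearson
    quasi-likelihood dispersion correction of the inference."""
    if dispersion not in ("none", "pearson"):
        raise ValueError(f"dispersion must be none/pearson, got {dispersion!r}")
    y = pd.to_numeric(data[outcome]).to_numpy(dtype=float)
    if y.sum() <= 0:
        raise ValueError("count model needs at least one event in total")
    X = _design_matrix(data, terms)
    model = sm.GLM(y, X, family=sm.families.Poisson())
    res = model.fit(maxiter=200)
    if not res.converged:
        raise RuntimeError("Poisson IRLS did not converge")
    params = res.params
    if dispersion == "pearson" and res.df_resid > 0:
        phi = float(res.pearson_chi2 / res.df_resid)
    else:
        phi = 1.0
    # quasi-likelihood: scale SEs by sqrt(phi), point estimates untouched
    bse = res.bse * math.sqrt(phi)
    with np.errstate(divide="ignore", invalid="ignore"):
        zvals = params / bse
    pvals = pd.Series(2 * stats.norm.sf(np.abs(zvals)), index=params.index)
    return CountModelFit(
        coefficients=params.to_dict(),
        se=bse.to_dict(),
        phi=phi,
        rr=np.exp(params).to_dict(),
        rr_ci={
            t: (
                float(np.exp(params[t] - Z95 * bse[t])),
                float(np.exp(params[t] + Z95 * bse[t])),
            )
            for t in params.index
        },
        p=pvals.to_dict(),
        terms=list(params.index),
        llf=float(res.llf),
    )


def stratified_effect(
    data: pd.DataFrame,
    effect: str,
    stratifier: str,
    covariates: list[str] | None = None,
    outcome: str = "n_atrophic",
    dispersion: str = "pearson",
) -> dict:
    """Per-stratum rate ratio of ``effect`` via nested coding inside the
    joint model (stratifier main effect and shared covariates kept)."""
    expanded, nested = nested_stratum_terms(data, effect, stratifier)
    terms = [stratifier] + nested + list(covariates or [])
    fit = fit_count_model(expanded, terms, outcome=outcome, dispersion=dispersion)
    out = {}
    for stratum, term in zip((0, 1), nested):
        out[stratum] = {
            "rr": fit.rr[term],
            "ci": fit.rr_ci[term],
            "p": fit.p[term],
        }
    return out


# ---------------------------------------------------------------------------
# ordinal model (shift analysis)
# ---------------------------------------------------------------------------

@dataclass
class OrdinalFit:
    cutpoints: list
    coefficients: dict
    se: dict
    odds_ratio: dict
    or_ci: dict
    p: dict
    terms: list
    outcome_levels: list
    stratified_or: dict = field(default_factory=dict)
    levelwise_or: pd.DataFrame | None = None
    llf: float = float("nan")

    def table(self) -> pd.DataFrame:
        rows = [
            (t, self.odds_ratio[t], *self.or_ci[t], self.p[t])
            for t in self.terms
        ]
        return pd.DataFrame(
            rows, columns=["term", "OR", "ci_low", "ci_high", "p"]
        )


def fit_ordinal_model(
    data: pd.DataFrame,
    outcome: str,
    terms: list[str],
    stratified: tuple[str, str] | None = None,
) -> OrdinalFit:
    """Proportional-odds logistic (cumulative logit) fit of an ordinal
    outcome; P(Y <= k) = logistic(c_k - x'beta), so OR = exp(beta) is the
    odds of a one-category-worse outcome per unit predictor.

    ``stratified=(effect, stratifier)`` additionally reports the effect's
    OR per stratum from the nested reparameterization.
    """
    work = data
    nested: list[str] = []
    if stratified is not None:
        work, nested = nested_stratum_terms(data, *stratified)
        terms = [t for t in terms if t not in (
            stratified[0], f"{stratified[0]}:{stratified[1]}"
        )] + nested
    y = pd.to_numeric(work[outcome]).to_numpy()
    levels = np.unique(y)
    if len(levels) < 2:
        raise ValueError(f"outcome {outcome!r} has a single observed level")
    # collapse onto observed, contiguous ranks
    y_ranked = np.searchsorted(levels, y)
    X = _design_matrix(work, terms, intercept=False)
    model = OrderedModel(y_ranked, X, distr="logit")
    res = model.fit(method="bfgs", disp=False, maxiter=500)
    if not res.mle_retvals.get("converged", True):
        res = model.fit(method="nm", disp=False, maxiter=5000)
    params = res.params[: len(terms)]
    if np.abs(params.to_numpy()).max() > 15:
        raise RuntimeError(
            "ordinal fit diverged (possible complete separation); "
            f"largest |coefficient| at {params.abs().idxmax()!r}"
        )
    bse = res.bse[: len(terms)]
    cutpoints = list(
        np.cumsum(
            np.concatenate(
                [[res.params.iloc[len(terms)]],
                 np.exp(res.params.iloc[len(terms) + 1:])]
            )
        )
    )
    or_ci = {
        t: (
            float(np.exp(params[t] - Z95 * bse[t])),
            float(np.exp(params[t] + Z95 * bse[t])),
        )
        for t in params.index
    }
    pvals = {
        t: float(2 * stats.norm.sf(abs(params[t] / bse[t]))) for t in params.index
    }
    fit = OrdinalFit(
        cutpoints=cutpoints,
        coefficients=params.to_dict(),
        se=bse.to_dict(),
        odds_ratio=np.exp(params).to_dict(),
        or_ci=or_ci,
        p=pvals,
        terms=list(params.index),
        outcome_levels=[int(v) for v in levels],
        llf=float(res.llf),
    )
    if stratified is not None:
        for stratum, term in zip((0, 1), nested):
            fit.stratified_or[stratum] = {
                "or": fit.odds_ratio[term],
                "ci": fit.or_ci[term],
                "p": fit.p[term],
            }
    return fit


def proportionality_check(
    data: pd.DataFrame,
    outcome: str,
    terms: list[str],
) -> pd.DataFrame:
    """Level-wise binary-logistic ORs for each cumulative split Y >= k.

    One row per (outcome level, term).  Under proportional odds all
    levels share each term's OR; the table is the diagnostic — no
    automatic pass/fail is applied.  Splits with an empty side are
    skipped with a note row.
    """
    y = pd.to_numeric(data[outcome]).to_numpy()
    levels = np.unique(y)
    X = _design_matrix(data, terms)
    rows = []
    for k in levels[1:]:
        yk = (y >= k).astype(float)
        if yk.min() == yk.max():
            rows.append({"level": int(k), "term": None, "OR": np.nan,
                         "p": np.nan, "note": "empty split side"})
            continue
        try:
            # extreme splits may separate perfectly; flagged below, so the
            # fit-time warnings are expected noise
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.GLM(yk, X, family=sm.families.Binomial()).fit(maxiter=200)
        except Exception as exc:
            rows.append({"level": int(k), "term": None, "OR": np.nan,
                         "p": np.nan, "note": f"fit failed: {exc}"})
            continue
        for term in res.params.index:
            if term == "Intercept":
                continue
            coef = float(res.params[term])
            if not np.isfinite(coef) or abs(coef) > 15:
                rows.append({"level": int(k), "term": term, "OR": np.nan,
                             "p": np.nan, "note": "unstable (separation?)"})
                continue
            rows.append(
                {
                    "level": int(k),
                    "term": term,
                    "OR": float(np.exp(coef)),
                    "p": float(res.pvalues[term]),
                    "note": "",
                }
            )
    return pd.DataFrame(rows, columns=["level", "term", "OR", "p", "note"])
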