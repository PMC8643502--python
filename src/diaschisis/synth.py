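"""Synthetic cohort generator with known ground truth.

Emulates the three inputs of the cerebellar-stroke atrophy analysis:

* long-format longitudinal cortical volume tables (60 Destrieux areas per
  hemisphere; unilateral patients contribute one dataset with target and
  reference hemispheres, bilateral patients two target-only datasets),
* binarized ellipsoidal cerebellar lesion masks on a common grid, and
* ordinal clinical scores (mRS, NIHSS) at baseline and 3 months.

Volumes follow the statistical structure the downstream analysis assumes:
per-area baselines are Normal(mean, SD) across datasets, and follow-up
change on the Z scale is (slope + b_subject)*t + noise with a per-subject
random slope shared across areas and hemispheres (the intra-subject
reference rationale).  Atrophy is injected in randomly chosen target
areas at the last follow-up only.  The number of injected areas per
dataset is Poisson; in the bilateral arm its log-mean increases with
lesion volume (``volume_count_link``), which is the rate-ratio recovery
scenario for the count model.  The 3-month mRS is drawn from a latent-
logistic proportional-odds model whose atrophy-count coefficient is
``ordinal_link_beta`` in the high-baseline (mRS >= 3) stratum only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import lobe_of
from .topography import LesionMask, write_mask

MRS_BASELINE_PROBS = (0.12, 0.20, 0.25, 0.25, 0.13, 0.05)  # median 2
MRS3_CUTPOINTS = (-0.5, 1.5, 3.0, 4.5, 6.0)
MRS3_BASELINE_COEF = 2.0  # latent effect of an impaired (mRS>=3) baseline


@dataclass
class LesionSpec:
    """Geometry request for one synthetic ellipsoidal lesion."""

    side: str                       # "left" or "right"
    center_mm: tuple[float, float, float]
    volume_ml: float
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    grid_shape: tuple[int, int, int] = (40, 40, 40)

    def validate(self) -> None:
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be left/right, got {self.side!r}")
        if self.volume_ml <= 0:
            raise ValueError("volume_ml must be positive")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel_size_mm must be positive")
        voxel_vol = float(np.prod(self.voxel_size_mm))
        if self.volume_ml * 1000.0 > np.prod(self.grid_shape) * voxel_vol:
            raise ValueError(
                f"volume_ml={self.volume_ml} does not fit inside grid "
                f"{self.grid_shape}"
            )


@dataclass
class CohortConfig:
    """Simulation knobs; defaults emulate the study conditions
    (29 patients, 36 datasets, lesion volume 5.4 +/- 8.7 ml, median 1.5
    atrophic areas per dataset, follow-up count distribution 17/11/1)."""

    n_unilateral: int = 22
    n_bilateral: int = 7
    n_areas_per_lobe: dict = field(
        default_factory=lambda: {
            "frontal": 22, "temporal": 12, "occipital": 14, "parietal": 12
        }
    )
    followup_times_months: list | None = None   # per-subject lists; None → sampled
    baseline_mean_ml: float = 8.0               # per-area scalar or map area→ml
    baseline_sd_ml: float = 1.2
    reference_slope: float = -0.005             # z/month, normal ageing drift
    subject_slope_sd: float = 0.01              # z/month
    residual_sd: float = 0.25                   # z
    atrophy_effect: float = -2.0                # z, injected at last follow-up
    atrophic_area_fraction: float = 0.025       # base Poisson rate / 60 areas
    volume_count_link: float = 0.0              # log RR per ml (bilateral arm)
    ordinal_link_beta: float = 0.0              # log OR per atrophic area (mRS>=3 arm)
    lesion_volume_mean_ml: float = 5.4
    lesion_volume_sd_ml: float = 8.7
    grid_shape: tuple = (40, 40, 40)
    voxel_size_mm: tuple = (1.0, 1.0, 1.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n_unilateral < 0:
            raise ValueError("n_unilateral must be >= 0")
        if self.n_bilateral < 0:
            raise ValueError("n_bilateral must be >= 0")
        for lobe, n in self.n_areas_per_lobe.items():
            if n < 0:
                raise ValueError(f"n_areas_per_lobe[{lobe}] must be >= 0")
        if np.isscalar(self.baseline_sd_ml):
            if self.baseline_sd_ml <= 0:
                raise ValueError("baseline_sd_ml must be > 0")
        elif any(v <= 0 for v in dict(self.baseline_sd_ml).values()):
            raise ValueError("baseline_sd_ml must be > 0 for every area")
        if not 0 <= self.atrophic_area_fraction <= 1:
            raise ValueError("atrophic_area_fraction must lie in [0, 1]")
        if self.subject_slope_sd < 0:
            raise ValueError("subject_slope_sd must be >= 0")
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be >= 0")
        if self.followup_times_months is not None:
            for times in self.followup_times_months:
                arr = np.asarray(times, dtype=float)
                if len(arr) < 1 or len(arr) > 3:
                    raise ValueError(
                        "followup_times_months entries must have 1-3 times"
                    )
                if (arr <= 0).any() or (np.diff(arr) <= 0).any():
                    raise ValueError(
                        "followup_times_months must be strictly positive and "
                        "increasing"
                    )


@dataclass
class GroundTruth:
    """What the generator injected — the recovery oracle."""

    atrophic_area_labels: dict      # dataset_id → sorted list of labels
    true_reference_slope: float
    true_subject_slope_sd: float
    true_residual_sd: float
    true_volume_rr: float           # exp(volume_count_link), per ml
    true_ordinal_or: float          # exp(ordinal_link_beta), per atrophic area
    lesion_volume_ml: dict = field(default_factory=dict)   # dataset_id → ml

    def to_json(self) -> str:
        d = asdict(self)
        d["atrophic_area_labels"] = {
            k: sorted(v) for k, v in self.atrophic_area_labels.items()
        }
        return json.dumps(d, indent=2, sort_keys=True)


@dataclass
class CohortData:
    volumes: pd.DataFrame
    masks: list
    clinical: pd.DataFrame
    ground_truth: GroundTruth

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.volumes.to_csv(outdir / "volumes.csv", index=False)
        self.clinical.to_csv(outdir / "clinical.csv", index=False)
        maskdir = outdir / "masks"
        maskdir.mkdir(exist_ok=True)
        for mask in self.masks:
            write_mask(mask, maskdir / f"{mask.dataset_id}.nii.gz")
        (outdir / "ground_truth.json").write_text(self.ground_truth.to_json())


# ---------------------------------------------------------------------------
# lesion masks
# ---------------------------------------------------------------------------

def generate_lesion_mask(spec: LesionSpec, seed: int | np.random.Generator = 0,
                         dataset_id: str = "lesion") -> LesionMask:
    """Binary ellipsoidal lesion of (almost) exactly the requested volume.

    Semi-axes get a small seeded anisotropy jitter; the mask is the set of
    N voxels with smallest scaled distance to the center, where N is the
    requested volume in voxel units — so the realized volume is within
    half a voxel volume of the request.
    """
    spec.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    shape = tuple(spec.grid_shape)
    voxsize = np.asarray(spec.voxel_size_mm, dtype=float)
    voxel_vol_ml = float(np.prod(voxsize)) / 1000.0
    n_target = int(round(spec.volume_ml / voxel_vol_ml))
    if n_target < 1:
        n_target = 1
    if n_target > np.prod(shape):
        raise ValueError("requested lesion volume exceeds grid capacity")

    affine = np.diag(np.append(voxsize, 1.0))
    affine[:3, 3] = -voxsize * (np.asarray(shape) / 2.0)

    # anisotropy factors, product-normalized so volume is radius-controlled
    f = rng.uniform(0.7, 1.3, size=3)
    f /= np.cbrt(np.prod(f))
    coords = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    mm = [coords[a] * voxsize[a] + affine[a, 3] for a in range(3)]
    d2 = sum(((mm[a] - spec.center_mm[a]) / f[a]) ** 2 for a in range(3))
    flat = d2.ravel()
    sel = np.argpartition(flat, n_target - 1)[:n_target]
    grid = np.zeros(np.prod(shape), dtype=np.uint8)
    grid[sel] = 1
    return LesionMask(
        grid.reshape(shape), affine, dataset_id=dataset_id, side=spec.side
    )


# ---------------------------------------------------------------------------
# volume trajectories
# ---------------------------------------------------------------------------

def _area_param(value, areas):
    if np.isscalar(value):
        return {a: float(value) for a in areas}
    return {a: float(dict(value)[a]) for a in areas}


def _plan_areas(config: CohortConfig) -> pd.DataFrame:
    """Area labels and lobes to simulate, honoring n_areas_per_lobe."""
    mapping = lobe_of()
    rows = []
    for lobe, n in config.n_areas_per_lobe.items():
        labels = sorted(a for a, l in mapping.items() if l == lobe)
        if n > len(labels):
            raise ValueError(
                f"n_areas_per_lobe[{lobe}]={n} exceeds the {len(labels)} "
                f"atlas areas of that lobe"
            )
        rows += [(a, lobe) for a in labels[:n]]
    return pd.DataFrame(rows, columns=["area_label", "lobe"])


def generate_volume_trajectories(
    config: CohortConfig,
    dataset_plan: pd.DataFrame,
    atrophic_labels: dict,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Long-format volume table for the planned datasets.

    ``dataset_plan`` rows: subject_id, dataset_id, has_reference,
    followup_times (tuple).  ``atrophic_labels`` maps dataset_id to the
    target-area labels that receive ``atrophy_effect`` (z-units, scaled
    to ml by the area's baseline SD) at the last follow-up.
    """
    config.validate()
    areas = _plan_areas(config)
    mu = _area_param(config.baseline_mean_ml, areas["area_label"])
    sd = _area_param(config.baseline_sd_ml, areas["area_label"])

    subj_slope = {
        s: config.reference_slope + config.subject_slope_sd * rng.standard_normal()
        for s in dataset_plan["subject_id"].unique()
    }

    n_areas = len(areas)
    area_mu = areas["area_label"].map(mu).to_numpy()
    area_sd = areas["area_label"].map(sd).to_numpy()

    records = []
    for row in dataset_plan.itertuples(index=False):
        roles = ["target"] + (["reference"] if row.has_reference else [])
        times = tuple(row.followup_times)
        t_last = times[-1]
        slope = subj_slope[row.subject_id]
        injected = set(atrophic_labels.get(row.dataset_id, ()))
        for role in roles:
            v0 = area_mu + area_sd * rng.standard_normal(n_areas)
            v0 = np.maximum(v0, 0.05 * area_mu)
            for i, (label, lobe) in enumerate(
                zip(areas["area_label"], areas["lobe"])
            ):
                records.append(
                    (row.subject_id, row.dataset_id, role, lobe, label, 0.0, v0[i])
                )
            for t in times:
                eps = config.residual_sd * rng.standard_normal(n_areas)
                dz = slope * t + eps
                if role == "target" and t == t_last and injected:
                    inj = areas["area_label"].isin(injected).to_numpy()
                    dz = dz + config.atrophy_effect * inj
                vt = np.maximum(v0 + area_sd * dz, 0.0)
                for i, (label, lobe) in enumerate(
                    zip(areas["area_label"], areas["lobe"])
                ):
                    records.append(
                        (row.subject_id, row.dataset_id, role, lobe, label,
                         float(t), vt[i])
                    )
    return pd.DataFrame(
        records,
        columns=["subject_id", "dataset_id", "role", "lobe", "area_label",
                 "time_months", "volume_ml"],
    )


# ---------------------------------------------------------------------------
# clinical scores
# ---------------------------------------------------------------------------

def generate_clinical_scores(
    atrophy_counts: pd.DataFrame,
    config: CohortConfig,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Ordinal clinical scores per patient.

    ``atrophy_counts`` needs columns subject_id, n_atrophic, bilateral.
    The 3-month mRS comes from a latent-logistic proportional-odds draw,

        latent = 2.0*[mRS0 >= 3] + beta*n_atrophic*[mRS0 >= 3] + noise,

    categorized at fixed cutpoints chosen so the median baseline mRS is 2
    and the median 3-month mRS is about 1.  The latent predictor uses the
    dichotomized baseline — the same covariate the shift analysis adjusts
    for — so the fitted stratified OR is a calibrated estimate of
    exp(ordinal_link_beta).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(atrophy_counts)
    age = np.clip(rng.normal(58.0, 18.0, size=n), 18.0, 95.0)
    sex_male = rng.random(n) < (20.0 / 29.0)
    mrs0 = rng.choice(6, size=n, p=MRS_BASELINE_PROBS)
    nihss0 = np.minimum(rng.poisson(1.0 + mrs0), 42)

    high = (mrs0 >= 3).astype(float)
    counts = atrophy_counts["n_atrophic"].to_numpy(dtype=float)
    eta = MRS3_BASELINE_COEF * high + config.ordinal_link_beta * counts * high
    latent = eta + rng.logistic(0.0, 1.0, size=n)
    mrs3 = np.digitize(latent, MRS3_CUTPOINTS)
    nihss3 = np.minimum(rng.poisson(0.4 + 0.3 * mrs3), 42)

    return pd.DataFrame(
        {
            "subject_id": atrophy_counts["subject_id"].to_numpy(),
            "age_years": np.round(age, 1),
            "sex_male": sex_male.astype(bool),
            "bilateral": atrophy_counts["bilateral"].to_numpy(dtype=bool),
            "mrs_baseline": mrs0.astype(int),
            "nihss_baseline": nihss0.astype(int),
            "mrs_3month": mrs3.astype(int),
            "nihss_3month": nihss3.astype(int),
        }
    )


# ---------------------------------------------------------------------------
# full cohort
# ---------------------------------------------------------------------------

def _sample_followups(config: CohortConfig, rng, n_subjects):
    if config.followup_times_months is not None:
        times = [tuple(map(float, t)) for t in config.followup_times_months]
        if len(times) < n_subjects:
            raise ValueError(
                f"followup_times_months has {len(times)} entries for "
                f"{n_subjects} subjects"
            )
        return times[:n_subjects]
    out = []
    for _ in range(n_subjects):
        k = rng.choice([1, 2, 3], p=[17 / 29, 11 / 29, 1 / 29])
        t = np.sort(rng.uniform(0.75, 12.0, size=k))
        out.append(tuple(np.round(t, 2)))
    return out


def _lesion_center(side: str, rng) -> tuple[float, float, float]:
    x = rng.uniform(5.0, 14.0)
    y = float(rng.uniform(-8.0, 8.0))
    z = float(rng.uniform(-8.0, 8.0))
    return (-x if side == "left" else x, y, z)



def sample_lesion_volumes(config: CohortConfig, n: int,
                          rng: np.random.Generator) -> np.ndarray:
    """Lesion volumes (ml): lognormal matched to the configured cohort
    mean/SD, clipped to what the default grid accommodates."""
    if config.lesion_volume_sd_ml > 0:
        cv2 = (config.lesion_volume_sd_ml / config.lesion_volume_mean_ml) ** 2
        s2 = np.log1p(cv2)
        mu_log = np.log(config.lesion_volume_mean_ml) - s2 / 2.0
        volumes = np.exp(mu_log + np.sqrt(s2) * rng.standard_normal(n))
    else:
        volumes = np.full(n, config.lesion_volume_mean_ml)
    return np.clip(volumes, 0.1, 25.0)


def sample_atrophic_counts(
    config: CohortConfig,
    lesion_volume_ml: np.ndarray,
    bilateral: np.ndarray,
    rng: np.random.Generator,
    n_areas: int = 60,
) -> np.ndarray:
    """Number of atrophic areas per dataset: Poisson with base rate
    atrophic_area_fraction * n_areas, log-linearly volume-linked in the
    bilateral arm (rate ratio exp(volume_count_link) per ml)."""
    base_rate = config.atrophic_area_fraction * n_areas
    lam = np.where(
        np.asarray(bilateral, dtype=bool),
        base_rate * np.exp(config.volume_count_link * np.asarray(lesion_volume_ml)),
        base_rate,
    )
    counts = np.where(lam > 0, rng.poisson(lam), 0)
    return np.minimum(counts, n_areas)


def generate_cohort(config: CohortConfig) -> CohortData:
    """Generate the full synthetic study: volumes, masks, clinical scores
    and the ground truth of what was injected.

    Unilateral subjects yield one dataset with target and reference
    hemispheres; bilateral subjects yield two target-only datasets.  The
    target hemisphere is contralateral to the lesion side (template
    x < 0 is left).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    areas = _plan_areas(config)
    n_areas = len(areas)

    n_subjects = config.n_unilateral + config.n_bilateral
    followups = _sample_followups(config, rng, n_subjects)

    plan_rows, lesion_plan = [], []
    for i in range(n_subjects):
        subject = f"sub-{i + 1:03d}"
        bilateral = i >= config.n_unilateral
        if bilateral:
            sides = ["left", "right"]
        else:
            sides = ["left" if i % 2 == 0 else "right"]
        for side in sides:
            dataset = f"{subject}_{side[0].upper()}"
            plan_rows.append(
                (subject, dataset, not bilateral, followups[i], bilateral, side)
            )
            lesion_plan.append((dataset, side, bilateral))
    plan = pd.DataFrame(
        plan_rows,
        columns=["subject_id", "dataset_id", "has_reference",
                 "followup_times", "bilateral", "side"],
    )

    volumes = sample_lesion_volumes(config, len(lesion_plan), rng)

    masks, lesion_volume_ml = [], {}
    for (dataset, side, _), vol in zip(lesion_plan, volumes):
        spec = LesionSpec(
            side=side,
            center_mm=_lesion_center(side, rng),
            volume_ml=float(vol),
            voxel_size_mm=tuple(config.voxel_size_mm),
            grid_shape=tuple(config.grid_shape),
        )
        masks.append(generate_lesion_mask(spec, rng, dataset_id=dataset))
        lesion_volume_ml[dataset] = float(vol)

    labels = areas["area_label"].to_numpy()
    counts_per_ds = sample_atrophic_counts(
        config,
        np.array([lesion_volume_ml[d] for d in plan["dataset_id"]]),
        plan["bilateral"].to_numpy(),
        rng,
        n_areas=n_areas,
    )
    atrophic = {}
    for row, k in zip(plan.itertuples(index=False), counts_per_ds):
        chosen = rng.choice(labels, size=int(k), replace=False) if k else []
        atrophic[row.dataset_id] = sorted(map(str, chosen))

    volumes_table = generate_volume_trajectories(
        config, plan, atrophic, rng
    )

    counts = (
        plan.assign(n_atrophic=[len(atrophic[d]) for d in plan["dataset_id"]])
        .groupby("subject_id", sort=True)
        .agg(n_atrophic=("n_atrophic", "sum"), bilateral=("bilateral", "any"))
        .reset_index()
    )
    clinical = generate_clinical_scores(counts, config, rng)

    truth = GroundTruth(
        atrophic_area_labels=atrophic,
        true_reference_slope=config.reference_slope,
        true_subject_slope_sd=config.subject_slope_sd,
        true_residual_sd=config.residual_sd,
        true_volume_rr=float(np.exp(config.volume_count_link)),
        true_ordinal_or=float(np.exp(config.ordinal_link_beta)),
        lesion_volume_ml=lesion_volume_ml,
    )
    return CohortData(volumes_table, masks, clinical, truth)
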