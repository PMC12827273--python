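"""Synthetic cohorts with known causal ground truth.

Generates tabular cohorts that mimic a three-group (AD / MCI / NC) FDG-PET
study: per-subject demographics, region-wise mean SUVs and bounded integer
cognitive (MMSE) and functional (FAQ) scores.  The generative mechanism is a
linear structural causal model

    suv_r   = base_r + a_r * age_std + g_r * gender + eta_r
    score   = intercept_group + sum_r beta_r * suv_r
              + gamma_age * age + gamma_gender * gender + eps

so that age and gender genuinely confound the SUV -> score relationship and
the true per-region effects (``beta_r``) are known exactly, enabling
parameter-recovery benchmarks for the estimation pipeline.

Also provides small synthetic dynamic-PET volumes with a matching integer
label atlas for exercising the SUV-extraction code path.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError
from .regions import region_names

GROUPS = ("AD", "MCI", "NC")
OUTCOMES = ("mmse", "faq")


@dataclass(frozen=True)
class GroupParams:
    """Per-diagnostic-group demographic and score parameters."""

    age_range: tuple[float, float]
    male_fraction: float
    mmse_mean: float
    mmse_sd: float
    faq_mean: float
    faq_sd: float
    mmse_range: tuple[int, int] = (0, 30)
    faq_range: tuple[int, int] = (0, 30)

    def validate(self, name: str) -> None:
        if self.age_range[0] >= self.age_range[1]:
            raise ConfigurationError(f"group_params[{name}].age_range must be increasing")
        if not 0.0 <= self.male_fraction <= 1.0:
            raise ConfigurationError(f"group_params[{name}].male_fraction must be in [0,1]")
        for fld in ("mmse_sd", "faq_sd"):
            if getattr(self, fld) < 0:
                raise ConfigurationError(f"group_params[{name}].{fld} must be >= 0")
        for fld in ("mmse_range", "faq_range"):
            lo, hi = getattr(self, fld)
            if not (0 <= lo <= hi <= 30):
                raise ConfigurationError(
                    f"group_params[{name}].{fld} must satisfy 0 <= lo <= hi <= 30"
                )


#: Default group parameters: 96/96/96 cohort with the published score
#: distributions (AD 22.4+/-3.2 MMSE, 15.0+/-6.7 FAQ; MCI 26.8+/-3.6, 5.4+/-6.9;
#: NC 28.9+/-1.4, 0.3+/-1.3) and per-group observed score ranges.
DEFAULT_GROUP_PARAMS: dict[str, GroupParams] = {
    "AD": GroupParams((55.0, 90.0), 54 / 95, 22.4, 3.2, 15.0, 6.7, (9, 25), (5, 30)),
    "MCI": GroupParams((52.0, 90.0), 57 / 96, 26.8, 3.6, 5.4, 6.9, (10, 28), (0, 26)),
    "NC": GroupParams((59.0, 95.0), 38 / 95, 28.9, 1.4, 0.3, 1.3, (25, 30), (0, 5)),
}


@dataclass
class ConfounderCoeffs:
    """Loadings of age / gender on each region's SUV and on each outcome.

    ``age_on_suv`` is per standardized-age unit; ``age_on_outcome`` is per
    year.  Gender is coded 0/1.
    """

    age_on_suv: np.ndarray
    gender_on_suv: np.ndarray
    age_on_outcome: dict[str, float]
    gender_on_outcome: dict[str, float]

    @classmethod
    def default(cls, n_regions: int, seed: int = 0) -> "ConfounderCoeffs":
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC0F]))
        return cls(
            age_on_suv=rng.uniform(-0.08, -0.02, n_regions),
            gender_on_suv=rng.uniform(-0.03, 0.03, n_regions),
            age_on_outcome={"mmse": -0.04, "faq": 0.06},
            gender_on_outcome={"mmse": 0.2, "faq": -0.3},
        )

    @classmethod
    def none(cls, n_regions: int) -> "ConfounderCoeffs":
        z = np.zeros(n_regions)
        return cls(z, z.copy(), {"mmse": 0.0, "faq": 0.0}, {"mmse": 0.0, "faq": 0.0})


@dataclass
class CohortConfig:
    """Configuration of the synthetic cohort generator."""

    n_per_group: int = 96
    n_regions: int = 120
    group_params: dict[str, GroupParams] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_PARAMS)
    )
    #: region name -> (beta_mmse, beta_faq), score points per SUV unit
    effect_map: dict[str, tuple[float, float]] = field(default_factory=dict)
    confounder_coeffs: ConfounderCoeffs | None = None
    #: outcome residual SD; None = calibrate per group so that the total score
    #: SD matches the configured group SD
    noise_sd: float | None = None
    suv_base_mean: float = 1.2
    suv_base_sd: float = 0.12
    suv_noise_sd: float = 0.08
    #: optional shared latent factor inducing inter-region SUV correlation
    shared_factor_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        self.region_list = region_names(self.n_regions)
        if self.confounder_coeffs is None:
            self.confounder_coeffs = ConfounderCoeffs.default(self.n_regions, self.seed)

    def validate(self) -> None:
        if self.n_per_group < 2:
            raise ConfigurationError("n_per_group must be >= 2")
        if self.n_regions < 1:
            raise ConfigurationError("n_regions must be >= 1")
        if self.noise_sd is not None and self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        for fld in ("suv_base_sd", "suv_noise_sd", "shared_factor_sd"):
            if getattr(self, fld) < 0:
                raise ConfigurationError(f"{fld} must be >= 0")
        for name in GROUPS:
            if name not in self.group_params:
                raise ConfigurationError(f"group_params missing group {name}")
            self.group_params[name].validate(name)
        unknown = set(self.effect_map) - set(self.region_list)
        if unknown:
            raise ConfigurationError(f"effect_map keys not in region set: {sorted(unknown)}")
        cc = self.confounder_coeffs
        if len(cc.age_on_suv) != self.n_regions or len(cc.gender_on_suv) != self.n_regions:
            raise ConfigurationError("confounder_coeffs length must equal n_regions")

    # -- serialization ----------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        d = {
            "n_per_group": self.n_per_group,
            "n_regions": self.n_regions,
            "noise_sd": self.noise_sd,
            "suv_base_mean": self.suv_base_mean,
            "suv_base_sd": self.suv_base_sd,
            "suv_noise_sd": self.suv_noise_sd,
            "shared_factor_sd": self.shared_factor_sd,
            "seed": self.seed,
            "effect_map": {k: list(v) for k, v in self.effect_map.items()},
            "group_params": {
                g: dataclasses.asdict(p) for g, p in self.group_params.items()
            },
            "confounder_coeffs": {
                "age_on_suv": self.confounder_coeffs.age_on_suv.tolist(),
                "gender_on_suv": self.confounder_coeffs.gender_on_suv.tolist(),
                "age_on_outcome": self.confounder_coeffs.age_on_outcome,
                "gender_on_outcome": self.confounder_coeffs.gender_on_outcome,
            },
        }
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        d = yaml.safe_load(Path(path).read_text())
        gp = {
            g: GroupParams(
                age_range=tuple(p["age_range"]),
                male_fraction=p["male_fraction"],
                mmse_mean=p["mmse_mean"], mmse_sd=p["mmse_sd"],
                faq_mean=p["faq_mean"], faq_sd=p["faq_sd"],
                mmse_range=tuple(p["mmse_range"]), faq_range=tuple(p["faq_range"]),
            )
            for g, p in d.pop("group_params").items()
        }
        cc_raw = d.pop("confounder_coeffs")
        cc = ConfounderCoeffs(
            np.asarray(cc_raw["age_on_suv"], float),
            np.asarray(cc_raw["gender_on_suv"], float),
            dict(cc_raw["age_on_outcome"]),
            dict(cc_raw["gender_on_outcome"]),
        )
        em = {k: tuple(v) for k, v in d.pop("effect_map").items()}
        return cls(group_params=gp, confounder_coeffs=cc, effect_map=em, **d)


@dataclass
class GroundTruth:
    """The realized generative parameters behind a cohort."""

    region_list: list[str]
    beta: dict[str, np.ndarray]            # outcome -> (n_regions,) true effects
    confounder_coeffs: ConfounderCoeffs
    intercepts: dict[str, dict[str, float]]  # outcome -> group -> intercept
    noise_sd: dict[str, dict[str, float]]    # outcome -> group -> residual SD
    suv_baselines: np.ndarray
    age_standardization: tuple[float, float]  # cohort (mean, sd) used for age_std
    raw_scores: pd.DataFrame               # pre-rounding, pre-clipping scores


def _age_mixture_moments(config: CohortConfig) -> tuple[float, float]:
    """Theoretical mean/SD of age under the equal-weight mixture of group uniforms."""
    means, variances = [], []
    for g in GROUPS:
        lo, hi = config.group_params[g].age_range
        means.append((lo + hi) / 2.0)
        variances.append((hi - lo) ** 2 / 12.0)
    mu = float(np.mean(means))
    var = float(np.mean([v + (m - mu) ** 2 for v, m in zip(variances, means)]))
    return mu, np.sqrt(var)


def _effect_arrays(config: CohortConfig) -> dict[str, np.ndarray]:
    beta = {o: np.zeros(config.n_regions) for o in OUTCOMES}
    idx = {r: i for i, r in enumerate(config.region_list)}
    for region, (b_mmse, b_faq) in config.effect_map.items():
        beta["mmse"][idx[region]] = b_mmse
        beta["faq"][idx[region]] = b_faq
    return beta


def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a cohort table and the ground truth that produced it.

    Returns a DataFrame with columns ``subject_id, age, gender, group,
    <region columns>, mmse, faq`` (a row per subject) and a
    :class:`GroundTruth` record.  The same ``config`` (including its seed)
    always yields the identical table.
    """
    config.validate()
    ss = np.random.SeedSequence([int(config.seed), 0x5EED])
    rng_struct, rng_subj = (np.random.default_rng(s) for s in ss.spawn(2))

    n_r = config.n_regions
    cc = config.confounder_coeffs
    baselines = rng_struct.normal(config.suv_base_mean, config.suv_base_sd, n_r)
    shared_loadings = (
        rng_struct.uniform(0.5, 1.0, n_r) if config.shared_factor_sd > 0 else np.zeros(n_r)
    )
    beta = _effect_arrays(config)
    age_mu, age_sd = _age_mixture_moments(config)

    n = config.n_per_group
    rows_age, rows_gender, rows_group = [], [], []
    for g in GROUPS:
        p = config.group_params[g]
        ages = rng_subj.uniform(*p.age_range, n)
        n_male = int(round(p.male_fraction * n))
        genders = np.array([1] * n_male + [0] * (n - n_male))
        rng_subj.shuffle(genders)
        rows_age.append(ages)
        rows_gender.append(genders)
        rows_group.extend([g] * n)
    age = np.concatenate(rows_age)
    gender = np.concatenate(rows_gender).astype(int)
    group = np.array(rows_group)
    n_total = len(age)
    age_std = (age - age_mu) / age_sd

    factor = rng_subj.normal(0.0, config.shared_factor_sd, n_total)
    eta = rng_subj.normal(0.0, config.suv_noise_sd, (n_total, n_r))
    suv = (
        baselines[None, :]
        + np.outer(age_std, cc.age_on_suv)
        + np.outer(gender, cc.gender_on_suv)
        + np.outer(factor, shared_loadings)
        + eta
    )
    suv = np.maximum(suv, 1e-6)  # SUV is physically positive

    intercepts: dict[str, dict[str, float]] = {o: {} for o in OUTCOMES}
    noise_sds: dict[str, dict[str, float]] = {o: {} for o in OUTCOMES}
    raw = {}
    final = {}
    for outcome in OUTCOMES:
        b = beta[outcome]
        ga = cc.age_on_outcome[outcome]
        gg = cc.gender_on_outcome[outcome]
        structural = suv @ b + ga * age + gg * gender
        raw_scores = np.empty(n_total)
        for g in GROUPS:
            p = config.group_params[g]
            mask = group == g
            lo_age, hi_age = p.age_range
            mu_g, var_age_g = (lo_age + hi_age) / 2.0, (hi_age - lo_age) ** 2 / 12.0
            pm = p.male_fraction
            e_suv = (
                baselines
                + cc.age_on_suv * (mu_g - age_mu) / age_sd
                + cc.gender_on_suv * pm
            )
            target_mean = getattr(p, f"{outcome}_mean")
            target_sd = getattr(p, f"{outcome}_sd")
            intercept = target_mean - float(b @ e_suv) - ga * mu_g - gg * pm
            if config.noise_sd is not None:
                sd_g = config.noise_sd
            else:
                k_age = ga + float(b @ cc.age_on_suv) / age_sd
                k_gender = gg + float(b @ cc.gender_on_suv)
                var_struct = (
                    k_age**2 * var_age_g
                    + k_gender**2 * pm * (1 - pm)
                    + float(b @ b) * config.suv_noise_sd**2
                    + float(b @ shared_loadings) ** 2 * config.shared_factor_sd**2
                )
                if var_struct > target_sd**2 + 1e-12:
                    raise ConfigurationError(
                        f"noise_sd: structural variance {var_struct:.3f} exceeds "
                        f"configured {outcome} variance {target_sd**2:.3f} for group {g}"
                    )
                sd_g = float(np.sqrt(max(target_sd**2 - var_struct, 0.0)))
            eps = rng_subj.normal(0.0, sd_g, mask.sum()) if sd_g > 0 else 0.0
            raw_scores[mask] = intercept + structural[mask] + eps
            intercepts[outcome][g] = intercept
            noise_sds[outcome][g] = sd_g
        raw[outcome] = raw_scores
        clipped = np.empty(n_total, dtype=int)
        for g in GROUPS:
            lo, hi = getattr(config.group_params[g], f"{outcome}_range")
            mask = group == g
            clipped[mask] = np.clip(np.rint(raw_scores[mask]), lo, hi).astype(int)
        final[outcome] = clipped

    table = pd.concat(
        [
            pd.DataFrame(
                {
                    "subject_id": [f"S{i:04d}" for i in range(n_total)],
                    "age": age,
                    "gender": gender,
                    "group": group,
                }
            ),
            pd.DataFrame(suv, columns=config.region_list),
            pd.DataFrame({"mmse": final["mmse"], "faq": final["faq"]}),
        ],
        axis=1,
    )

    truth = GroundTruth(
        region_list=list(config.region_list),
        beta=beta,
        confounder_coeffs=cc,
        intercepts=intercepts,
        noise_sd=noise_sds,
        suv_baselines=baselines,
        age_standardization=(age_mu, age_sd),
        raw_scores=pd.DataFrame({o: raw[o] for o in OUTCOMES}),
    )
    return table, truth


def demo_effect_map(
    n_regions: int = 120,
    n_signal: int = 10,
    low: float = -8.0,
    high: float = 4.0,
    seed: int = 0,
) -> dict[str, tuple[float, float]]:
    """Pick ``n_signal`` regions with nonzero effects spanning [low, high].

    Magnitudes mirror the reported causal-score range (roughly -8 to +4
    score points per SUV unit).  The same effect is used for both outcomes
    with opposite sign for FAQ (higher metabolism that helps cognition tends
    to lower functional-impairment scores).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xEFFEC7]))
    names = region_names(n_regions)
    chosen = rng.choice(n_regions, size=n_signal, replace=False)
    betas = np.linspace(low, high, n_signal)
    betas = np.where(np.abs(betas) < 0.5, np.where(betas >= 0, 0.5, -0.5), betas)
    rng.shuffle(betas)
    return {names[i]: (float(b), float(-b)) for i, b in zip(chosen, betas)}


# ---------------------------------------------------------------------------
# Synthetic dynamic-PET fixtures
# ---------------------------------------------------------------------------

@dataclass
class SyntheticPETFixture:
    """A small 4-D activity volume plus integer label atlas with known means."""

    volume: np.ndarray          # (x, y, z, frame), kBq/mL
    atlas: np.ndarray           # (x, y, z) integer labels, 0 = background
    injected_dose: float        # MBq
    body_weight: float          # kg
    true_region_means: dict[int, np.ndarray]  # label -> per-frame mean activity

    def save(self, outdir: str | Path, stem: str = "fixture") -> dict[str, Path]:
        import nibabel as nib

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "volume": outdir / f"{stem}_pet.nii.gz",
            "atlas": outdir / f"{stem}_atlas.nii.gz",
            "meta": outdir / f"{stem}_meta.txt",
        }
        affine = np.eye(4)
        nib.save(nib.Nifti1Image(self.volume.astype(np.float64), affine), paths["volume"])
        nib.save(nib.Nifti1Image(self.atlas.astype(np.int16), affine), paths["atlas"])
        lines = [
            f"injected_dose_mbq={self.injected_dose!r}",
            f"body_weight_kg={self.body_weight!r}",
        ]
        for label in sorted(self.true_region_means):
            vals = ",".join(repr(float(v)) for v in self.true_region_means[label])
            lines.append(f"true_mean_{label}={vals}")
        paths["meta"].write_text("\n".join(lines) + "\n")
        return paths

    @classmethod
    def load(cls, outdir: str | Path, stem: str = "fixture") -> "SyntheticPETFixture":
        import nibabel as nib

        outdir = Path(outdir)
        volume = np.asarray(nib.load(outdir / f"{stem}_pet.nii.gz").get_fdata())
        atlas = np.asarray(
            nib.load(outdir / f"{stem}_atlas.nii.gz").get_fdata()
        ).astype(int)
        meta = {}
        for line in (outdir / f"{stem}_meta.txt").read_text().splitlines():
            if line.strip():
                k, v = line.split("=", 1)
                meta[k] = v
        true_means = {
            int(k.removeprefix("true_mean_")): np.array(
                [float(x) for x in v.split(",")]
            )
            for k, v in meta.items()
            if k.startswith("true_mean_")
        }
        return cls(
            volume=volume,
            atlas=atlas,
            injected_dose=float(meta["injected_dose_mbq"]),
            body_weight=float(meta["body_weight_kg"]),
            true_region_means=true_means,
        )


def generate_pet_fixture(
    shape: tuple[int, int, int],
    n_regions: int,
    n_frames: int = 6,
    seed: int = 0,
    noise_sd: float = 0.0,
    injected_dose: float = 370.0,
    body_weight: float = 74.0,
) -> SyntheticPETFixture:
    """Build a labeled 4-D activity volume with recorded per-region means.

    The atlas partitions an interior sub-box into ``n_regions`` contiguous
    blocks of near-equal size (label 0 stays background).  With
    ``noise_sd=0`` every voxel of a region equals the stored per-frame mean.
    """
    if n_frames < 1:
        raise ConfigurationError("n_frames must be >= 1")
    if noise_sd < 0:
        raise ConfigurationError("noise_sd must be >= 0")
    shape = tuple(int(s) for s in shape)
    inner = tuple(max(s - 2, 1) if s >= 3 else s for s in shape)
    n_vox = int(np.prod(inner))
    if n_vox < n_regions:
        raise ConfigurationError(
            f"shape {shape} hosts only {n_vox} interior voxels for {n_regions} regions"
        )
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xF1C5]))

    labels_flat = np.zeros(n_vox, dtype=np.int16)
    bounds = np.linspace(0, n_vox, n_regions + 1).astype(int)
    for r in range(n_regions):
        labels_flat[bounds[r]:bounds[r + 1]] = r + 1
    atlas = np.zeros(shape, dtype=np.int16)
    off = tuple(1 if s >= 3 else 0 for s in shape)
    sl = tuple(slice(o, o + i) for o, i in zip(off, inner))
    atlas[sl] = labels_flat.reshape(inner)

    # quantize means to 1/1024 so zero-noise region means are float-exact:
    # every voxel equals m, the sum k*m is exactly representable, and the
    # correctly-rounded division (k*m)/k returns m bit-for-bit
    true_means = {
        r: np.round(rng.uniform(2.0, 8.0, n_frames) * 1024.0) / 1024.0
        for r in range(1, n_regions + 1)
    }
    volume = np.zeros(shape + (n_frames,), dtype=np.float64)
    for r, means in true_means.items():
        mask = atlas == r
        for t in range(n_frames):
            vals = np.full(mask.sum(), means[t])
            if noise_sd > 0:
                vals = vals + rng.normal(0.0, noise_sd, mask.sum())
            volume[..., t][mask] = vals
    return SyntheticPETFixture(
        volume=volume,
        atlas=atlas,
        injected_dose=float(injected_dose),
        body_weight=float(body_weight),
        true_region_means=true_means,
    )


def save_cohort(table: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort table as comma-separated text (header row, one row/subject)."""
    table.to_csv(path, index=False)


def load_cohort(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
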