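import numpy as np
import pandas as pd
import pytest

from petcog.synth import (
    CohortConfig,
    ConfounderCoeffs,
    GroupParams,
    demo_effect_map,
    generate_cohort,
)
from petcog.regressor import RegressorConfig


@pytest.fixture(scope="session")
def signal_cohort():
    """96/96/96 cohort, 120 regions, 10 planted effects, moderate noise."""
    cfg = CohortConfig(
        n_per_group=96,
        n_regions=120,
        effect_map=demo_effect_map(120, 10, seed=7),
        noise_sd=2.0,
        seed=7,
    )
    table, truth = generate_cohort(cfg)
    return cfg, table, truth


@pytest.fixture(scope="session")
def small_cohort():
    """Quick 20-region cohort for plumbing tests."""
    cfg = CohortConfig(
        n_per_group=30,
        n_regions=20,
        effect_map={"Precentral_L": (2.5, -2.5), "Frontal_Mid_2_R": (-4.0, 4.0)},
        noise_sd=1.0,
        seed=11,
    )
    table, truth = generate_cohort(cfg)
    return cfg, table, truth


@pytest.fixture
def tiny_reg_config():
    """Factory for small, fast regressor configurations."""

    def make(n_features, **kw):
        defaults = dict(
            n_features=n_features,
            embed_dim=16,
            n_heads=2,
            n_encoder_layers=1,
            head_hidden=8,
            dropout=0.0,
            lr=5e-3,
            epochs=50,
            batch_size=8,
            seed=0,
        )
        defaults.update(kw)
        return RegressorConfig(**defaults)

    return make


@pytest.fixture
def linear_frame():
    """Small exactly-linear data frame for estimator identities."""
    rng = np.random.default_rng(5)
    n = 60
    age = rng.uniform(55, 90, n)
    gender = rng.integers(0, 2, n)
    suv = 1.0 + 0.05 * (age - 70) / 10 + rng.normal(0, 0.1, n)
    outcome = 2.0 * suv + 0.5 * age + 0.0 * gender
    return pd.DataFrame(
        {"age": age, "gender": gender, "R1": suv, "mmse": outcome}
    )


def wide_group_params():
    """Mid-range means with non-truncating score bounds (no clipping bias)."""
    return {
        g: GroupParams((55.0, 90.0), 0.5, 15.0, 3.0, 15.0, 3.0, (0, 30), (0, 30))
        for g in ("AD", "MCI", "NC")
    }


def make_confounded_cohort(
    n_per_group=700, seed=0, noise_sd=1.0, n_regions=6, effect_map=None
):
    """Strongly age-confounded cohort; causal effects all zero unless given."""
    cc = ConfounderCoeffs(
        age_on_suv=np.full(n_regions, -0.08),
        gender_on_suv=np.full(n_regions, 0.02),
        age_on_outcome={"mmse": -0.08, "faq": 0.1},
        gender_on_outcome={"mmse": 0.3, "faq": -0.3},
    )
    cfg = CohortConfig(
        n_per_group=n_per_group,
        n_regions=n_regions,
        group_params=wide_group_params(),
        confounder_coeffs=cc,
        effect_map=effect_map or {},
        noise_sd=noise_sd,
        seed=seed,
    )
    return cfg, *generate_cohort(cfg)
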