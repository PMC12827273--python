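"""Backdoor-adjusted linear causal effect estimation, ranking and selection.

The direct effect of a region's SUV on an outcome is the OLS coefficient of
the SUV column in ``outcome ~ 1 + suv + confounders`` fitted on the scoped
rows (whole cohort or one diagnostic group).  Because age and gender close
every backdoor path in the assumed graph, this coefficient identifies the
direct causal effect; standard errors and two-sided p-values come from the
usual OLS sampling formulas.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, RankDeficiencyError, SampleSizeError

SCOPES = ("whole", "AD", "MCI", "NC")


@dataclass(frozen=True)
class CausalEffect:
    region: str
    outcome: str
    scope: str
    effect: float
    std_error: float
    p_value: float
    n: int


def _scope_rows(data: pd.DataFrame, scope: str) -> pd.DataFrame:
    if scope == "whole":
        return data
    if "group" not in data.columns:
        raise KeyError("data has no 'group' column for scoped estimation")
    return data[data["group"] == scope]


def ols_fit(X: np.ndarray, y: np.ndarray):
    """OLS fit returning (coefficients, standard errors, two-sided p-values).

    X must already include the intercept column.
    """
    n, p = X.shape
    if n <= p + 1:
        raise SampleSizeError(f"need n > p + 1 (n={n}, p={p})")
    xtx = X.T @ X
    rank = np.linalg.matrix_rank(xtx)
    if rank < p:
        raise RankDeficiencyError("collinear design matrix")
    xtx_inv = np.linalg.inv(xtx)
    beta = xtx_inv @ (X.T @ y)
    resid = y - X @ beta
    dof = n - p
    sigma2 = float(resid @ resid) / dof
    se = np.sqrt(np.maximum(np.diag(xtx_inv) * sigma2, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    pvals = 2.0 * stats.t.sf(np.abs(tvals), dof)
    return beta, se, pvals


def estimate_direct_effect(
    data: pd.DataFrame,
    region: str,
    outcome: str,
    confounders=("age", "gender"),
    scope: str = "whole",
    standardize: bool = False,
) -> CausalEffect:
    """Backdoor-adjusted OLS estimate of the region's direct effect.

    SUVs enter unstandardized by default so effects read as score points
    per SUV unit; ``standardize=True`` re-expresses effect and SE per SD of
    the scoped SUV column (p-value and n are scale-invariant).
    """
    rows = _scope_rows(data, scope)
    n = len(rows)
    if n <= 4:
        raise SampleSizeError(f"scope {scope} leaves n={n} <= 4")
    cols = [region, *confounders]
    X = np.column_stack([np.ones(n)] + [rows[c].to_numpy(float) for c in cols])
    y = rows[outcome].to_numpy(float)
    beta, se, pvals = ols_fit(X, y)
    factor = float(rows[region].std(ddof=0)) if standardize else 1.0
    return CausalEffect(
        region=region, outcome=outcome, scope=scope,
        effect=float(beta[1]) * factor, std_error=float(se[1]) * factor,
        p_value=float(pvals[1]), n=n,
    )


@dataclass
class EffectTable:
    """All per-region effects for one (outcome, scope), ranked by |effect|."""

    outcome: str
    scope: str
    effects: list[CausalEffect]
    failures: dict = field(default_factory=dict)  # region -> error message

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            [
                {
                    "region": e.region, "outcome": e.outcome, "scope": e.scope,
                    "effect": e.effect, "se": e.std_error, "p": e.p_value, "n": e.n,
                }
                for e in self.effects
            ]
        )
        df = df.sort_values(
            by=["effect", "region"],
            key=lambda s: -s.abs() if s.name == "effect" else s,
        ).reset_index(drop=True)
        df["rank"] = np.arange(1, len(df) + 1)
        return df

    def save_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def lookup(self, region: str) -> CausalEffect:
        for e in self.effects:
            if e.region == region:
                return e
        raise KeyError(region)


def estimate_all_effects(
    data: pd.DataFrame,
    outcome: str,
    scope: str = "whole",
    regions=None,
    confounders=("age", "gender"),
    standardize: bool = False,
) -> EffectTable:
    """Apply :func:`estimate_direct_effect` to every region column."""
    if regions is None:
        reserved = {"subject_id", "age", "gender", "group", "mmse", "faq"}
        regions = [c for c in data.columns if c not in reserved]
    effects, failures = [], {}
    for region in regions:
        try:
            effects.append(
                estimate_direct_effect(
                    data, region, outcome, confounders, scope, standardize
                )
            )
        except Exception as exc:  # per-region failures are collected, not fatal
            failures[region] = str(exc)
    return EffectTable(outcome=outcome, scope=scope, effects=effects, failures=failures)


def rank_and_select(table: EffectTable, k: int) -> list[str]:
    """Top-k regions by |effect| descending, ties broken by name ascending."""
    if k <= 0:
        raise DomainError("k must be > 0")
    if k > len(table.effects):
        raise DomainError(f"k={k} exceeds region count {len(table.effects)}")
    ordered = sorted(table.effects, key=lambda e: (-abs(e.effect), e.region))
    return [e.region for e in ordered[:k]]


@dataclass
class RegionSelection:
    outcome: str
    regions: list[str]                 # ordered by descending max |effect|
    provenance: dict[str, list[str]]   # region -> contributing scopes

    def to_json(self, path: "str | Path | None" = None) -> str:
        text = json.dumps(
            {
                "outcome": self.outcome,
                "regions": self.regions,
                "provenance": self.provenance,
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(text)
        return text


def union_selection(
    whole: EffectTable,
    per_group: dict[str, EffectTable],
    k_whole: int = 30,
    k_group: int = 20,
) -> RegionSelection:
    """Union of the whole-cohort top-k and each group's top-k, with provenance."""
    contributions: dict[str, dict[str, float]] = {}

    def add(scope: str, table: EffectTable, k: int):
        for region in rank_and_select(table, min(k, len(table.effects))):
            eff = table.lookup(region).effect
            contributions.setdefault(region, {})[scope] = eff

    add("whole", whole, k_whole)
    for g, table in per_group.items():
        add(g, table, k_group)

    ordered = sorted(
        contributions,
        key=lambda r: (-max(abs(v) for v in contributions[r].values()), r),
    )
    provenance = {r: sorted(contributions[r]) for r in ordered}
    return RegionSelection(outcome=whole.outcome, regions=ordered, provenance=provenance)


def cross_group_overlap(per_group: dict[str, list[str]]) -> dict[str, list[str]]:
    """Partition the union of per-group region lists by exact group membership.

    Keys are '+'-joined sorted group-name combinations (e.g. ``"AD+MCI"``);
    values are sorted region lists belonging to exactly that combination.
    """
    if len(per_group) < 2:
        raise DomainError("need at least two groups for overlap analysis")
    sets = {g: set(v) for g, v in per_group.items()}
    union = set().union(*sets.values())
    partition: dict[str, list[str]] = {}
    for region in sorted(union):
        members = sorted(g for g, s in sets.items() if region in s)
        partition.setdefault("+".join(members), []).append(region)
    return partition
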