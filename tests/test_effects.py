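import numpy as np
import pandas as pd
import pytest

from petcog.effects import (
    CausalEffect,
    EffectTable,
    cross_group_overlap,
    estimate_all_effects,
    estimate_direct_effect,
    rank_and_select,
    union_selection,
)
from petcog.errors import DomainError, RankDeficiencyError, SampleSizeError

from conftest import make_confounded_cohort


def frisch_waugh(data, region, outcome, confounders=("age", "gender")):
    """Partialling-out oracle: residualize both sides on confounders."""
    n = len(data)
    Z = np.column_stack([np.ones(n)] + [data[c].to_numpy(float) for c in confounders])

    def resid(col):
        v = data[col].to_numpy(float)
        beta, *_ = np.linalg.lstsq(Z, v, rcond=None)
        return v - Z @ beta

    ry, rx = resid(outcome), resid(region)
    return float(rx @ ry / (rx @ rx))


class TestEstimateDirectEffect:
    def test_noiseless_recovery(self, linear_frame):
        eff = estimate_direct_effect(linear_frame, "R1", "mmse")
        assert eff.effect == pytest.approx(2.0, abs=1e-9)

    def test_confounded_null_region(self):
        _, table, _ = make_confounded_cohort(n_per_group=700, seed=21)
        region = table.columns[4]
        unadjusted = np.polyfit(table[region], table["mmse"], 1)[0]
        adj = estimate_direct_effect(table, region, "mmse")
        assert abs(unadjusted) > 1.0
        assert abs(adj.effect) < 3 * adj.std_error

    def test_frisch_waugh_equivalence(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            n = 100
            df = pd.DataFrame(
                {
                    "age": rng.uniform(50, 90, n),
                    "gender": rng.integers(0, 2, n),
                    "R": rng.normal(1.2, 0.2, n),
                }
            )
            df["mmse"] = rng.normal(size=n)
            eff = estimate_direct_effect(df, "R", "mmse")
            assert eff.effect == pytest.approx(
                frisch_waugh(df, "R", "mmse"), abs=1e-10
            )

    def test_sample_size_error(self):
        df = pd.DataFrame(
            {"age": [1, 2, 3], "gender": [0, 1, 0], "R": [1, 2, 3], "mmse": [1, 2, 3]}
        )
        with pytest.raises(SampleSizeError):
            estimate_direct_effect(df, "R", "mmse")

    def test_collinear_design_error(self):
        rng = np.random.default_rng(0)
        n = 50
        age = rng.uniform(50, 90, n)
        df = pd.DataFrame(
            {"age": age, "gender": rng.integers(0, 2, n), "R": age, "mmse": age}
        )
        with pytest.raises(RankDeficiencyError):
            estimate_direct_effect(df, "R", "mmse")

    def test_standardize_rescales_by_sd(self, signal_cohort):
        _, table, _ = signal_cohort
        raw = estimate_direct_effect(table, "Angular_L", "mmse")
        std = estimate_direct_effect(table, "Angular_L", "mmse", standardize=True)
        sd = table["Angular_L"].std(ddof=0)
        assert std.effect == pytest.approx(raw.effect * sd, rel=1e-12)
        assert std.std_error == pytest.approx(raw.std_error * sd, rel=1e-12)
        assert std.p_value == raw.p_value

    def test_scope_filter(self, signal_cohort):
        _, table, _ = signal_cohort
        eff = estimate_direct_effect(table, "Angular_L", "mmse", scope="AD")
        assert eff.n == 96


class TestEstimateAllEffects:
    def test_region_count(self, signal_cohort):
        _, table, _ = signal_cohort
        et = estimate_all_effects(table, "mmse")
        assert len(et.effects) == 120
        assert not et.failures

    def test_true_signals_occupy_top_ranks(self):
        from petcog.synth import demo_effect_map

        em = demo_effect_map(20, 5, seed=2)
        _, table, truth = make_confounded_cohort(
            n_per_group=700, seed=2, noise_sd=0.3, n_regions=20, effect_map=em
        )
        et = estimate_all_effects(table, "mmse")
        top5 = set(rank_and_select(et, 5))
        expected = set(
            sorted(em, key=lambda r: -abs(em[r][0]))[:5]
        )
        assert top5 == expected

    def test_scope_additivity(self, signal_cohort):
        _, table, _ = signal_cohort
        n_whole = estimate_all_effects(table, "mmse").effects[0].n
        n_groups = sum(
            estimate_all_effects(table, "mmse", scope=g).effects[0].n
            for g in ("AD", "MCI", "NC")
        )
        assert n_whole == n_groups == 288

    def test_csv_export(self, tmp_path, small_cohort):
        _, table, _ = small_cohort
        et = estimate_all_effects(table, "faq")
        path = tmp_path / "effects.csv"
        et.save_csv(path)
        df = pd.read_csv(path)
        assert list(df.columns) == [
            "region", "outcome", "scope", "effect", "se", "p", "n", "rank"
        ]
        assert (df["rank"] == np.arange(1, len(df) + 1)).all()
        assert df["effect"].abs().is_monotonic_decreasing


def _table_from(effects: dict, outcome="mmse", scope="whole"):
    return EffectTable(
        outcome=outcome,
        scope=scope,
        effects=[
            CausalEffect(r, outcome, scope, e, 0.1, 0.01, 288)
            for r, e in effects.items()
        ],
    )


class TestRankAndSelect:
    def test_reported_score_ordering(self):
        # reported whole-cohort scores: ITG_L 3.68, Angular_L 3.25, Caudate_L 1.73
        t = _table_from({"ITG_L": 3.68, "Angular_L": 3.25, "Caudate_L": 1.73})
        assert rank_and_select(t, 2) == ["ITG_L", "Angular_L"]

    def test_magnitude_ordering(self):
        t = _table_from({"A": -8.26, "B": 4.0})
        assert rank_and_select(t, 1) == ["A"]

    def test_tie_breaks_alphabetical(self):
        t = _table_from({"C": 1.0, "A": 1.0, "B": 1.0})
        assert rank_and_select(t, 2) == ["A", "B"]

    def test_k_errors(self):
        t = _table_from({"A": 1.0})
        with pytest.raises(DomainError):
            rank_and_select(t, 0)
        with pytest.raises(DomainError):
            rank_and_select(t, 5)


class TestUnionSelection:
    def test_identical_lists(self):
        whole = _table_from({"A": 3.0, "B": 2.0, "C": 1.0})
        groups = {g: _table_from({"A": 3.0, "B": 2.0, "C": 1.0}, scope=g)
                  for g in ("AD", "MCI", "NC")}
        sel = union_selection(whole, groups, k_whole=2, k_group=2)
        assert sel.regions == ["A", "B"]
        assert sel.provenance["A"] == ["AD", "MCI", "NC", "whole"]

    def test_disjoint_lists(self):
        whole = _table_from({"W1": 5.0, "W2": 4.0, "W3": 3.0})
        groups = {
            "AD": _table_from({"A1": 5.0, "A2": 4.0, "A3": 3.0}, scope="AD"),
            "MCI": _table_from({"M1": 5.0, "M2": 4.0, "M3": 3.0}, scope="MCI"),
            "NC": _table_from({"N1": 5.0, "N2": 4.0, "N3": 3.0}, scope="NC"),
        }
        sel = union_selection(whole, groups, k_whole=3, k_group=3)
        assert len(sel.regions) == 12
        assert all(len(v) == 1 for v in sel.provenance.values())

    def test_group_specific_signal_provenance(self):
        whole = _table_from({"A": 5.0, "B": 0.1, "C": 0.05})
        groups = {
            "AD": _table_from({"A": 5.0, "B": 4.0, "C": 0.1}, scope="AD"),
            "MCI": _table_from({"A": 5.0, "B": 0.1, "C": 0.2}, scope="MCI"),
            "NC": _table_from({"A": 5.0, "B": 0.01, "C": 0.1}, scope="NC"),
        }
        sel = union_selection(whole, groups, k_whole=1, k_group=2)
        assert "B" in sel.regions
        assert sel.provenance["B"] == ["AD"]

    def test_ordering_by_max_abs_effect(self):
        whole = _table_from({"A": 1.0, "B": -6.0, "C": 2.0})
        groups = {"AD": _table_from({"A": 1.0, "B": -6.0, "C": 2.0}, scope="AD")}
        sel = union_selection(whole, groups, k_whole=3, k_group=1)
        assert sel.regions[0] == "B"


class TestCrossGroupOverlap:
    def test_identical_lists(self):
        part = cross_group_overlap({g: ["A", "B"] for g in ("AD", "MCI", "NC")})
        assert part == {"AD+MCI+NC": ["A", "B"]}

    def test_pairwise_example(self):
        part = cross_group_overlap(
            {"AD": ["A", "B"], "MCI": ["B", "C"], "NC": ["C", "A"]}
        )
        assert part == {"AD+MCI": ["B"], "MCI+NC": ["C"], "AD+NC": ["A"]}

    def test_matches_set_arithmetic(self):
        rng = np.random.default_rng(12)
        universe = [f"R{i}" for i in range(30)]
        lists = {
            g: list(rng.choice(universe, size=10, replace=False))
            for g in ("AD", "MCI", "NC")
        }
        part = cross_group_overlap(lists)
        # brute-force check: each region lands in exactly its membership class
        for region in set().union(*(set(v) for v in lists.values())):
            members = "+".join(sorted(g for g in lists if region in lists[g]))
            assert region in part[members]
        assert sum(len(v) for v in part.values()) == len(
            set().union(*(set(v) for v in lists.values()))
        )

    def test_needs_two_groups(self):
        with pytest.raises(DomainError):
            cross_group_overlap({"AD": ["A"]})
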