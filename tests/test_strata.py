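"""Operon-position comparisons, expression strata, and profile correlations."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hbramp import (
    GeneratorSpec,
    Orfeome,
    OperonTable,
    build_codon_matrix,
    expression_strata,
    generate_expression,
    generate_orfeome,
    generate_operons,
    hbond_profile,
    metric_correlation_network,
    operon_comparison,
    qc_filter,
    region_correlation,
    strata_profiles,
)
from hbramp.profiles import PositionalProfile


def _profile(means, positions=None):
    means = np.asarray(means, dtype=float)
    pos = np.arange(means.size) + 2 if positions is None else positions
    return PositionalProfile(pos, means, means, means, np.zeros_like(means), 10)


class TestOperonTable:
    def test_singletons_dropped_and_positions_validated(self):
        df = pd.DataFrame(
            {
                "cds_id": ["a", "b", "c"],
                "operon_id": ["op1", "op1", "op2"],
                "position": [1, 2, 1],
            }
        )
        table = OperonTable(df)
        assert set(table.table["operon_id"]) == {"op1"}  # op2 has a single CDS
        bad = pd.DataFrame(
            {"cds_id": ["a", "b"], "operon_id": ["op1", "op1"], "position": [1, 3]}
        )
        with pytest.raises(ValueError, match="consecutive"):
            OperonTable(bad)


class TestOperonComparison:
    def test_identical_groups_are_not_significant(self):
        spec = GeneratorSpec(n_cds=60, cds_length_codons=101, ramp=None, flat_mu=7.4, seed=4)
        orf, _ = generate_orfeome(spec)
        kept, _ = qc_filter(orf, 100)
        matrix = build_codon_matrix(kept, 100)
        # positions 1 and 2 hold the *same* CDSs (duplicated rows)
        dup = Orfeome(
            ids=[f"{c}_p{p}" for p in (1, 2) for c in kept.ids],
            seqs=[s for _ in (1, 2) for s in kept.seqs],
        )
        dmatrix = build_codon_matrix(dup, 100)
        table = OperonTable(
            pd.DataFrame(
                {
                    "cds_id": dup.ids,
                    "operon_id": [c for _ in (1, 2) for c in kept.ids],
                    "position": [p for p in (1, 2) for _ in kept.ids],
                }
            )
        )
        reports = operon_comparison(dmatrix, table)
        assert np.all(reports["pairwise"]["p_adj"] > 0.5)
        assert np.all(reports["groupwise"]["p"] > 0.5)

    def test_implanted_first_position_effect_is_detected(self):
        spec = GeneratorSpec(n_cds=400, cds_length_codons=101, ramp=(7.9, 0.3, 7.0), seed=6)
        orf, _ = generate_orfeome(spec)
        table, orf = generate_operons(
            orf, spec, sizes=[2] * 200, first_position_delta=0.5, seed=60
        )
        kept, _ = qc_filter(orf, 100)
        matrix = build_codon_matrix(kept, 100)
        reports = operon_comparison(matrix, table)
        pair = reports["pairwise"]
        head = pair[(pair["region"] == "P2-P21") & (pair["group_a"] == 1) & (pair["group_b"] == 2)]
        assert len(head) == 1
        assert float(head["p_adj"].iloc[0]) < 0.001

    def test_unknown_cds_id_errors(self, toy_orfeome):
        matrix = build_codon_matrix(toy_orfeome, 4)
        table = OperonTable(
            pd.DataFrame(
                {"cds_id": ["g1", "ghost"], "operon_id": ["op1", "op1"], "position": [1, 2]}
            )
        )
        with pytest.raises(ValueError, match="ghost"):
            operon_comparison(matrix, table)


class TestRankTestOracles:
    """scipy's rank tests against independent small-sample computations."""

    SAMPLES = [
        ([1.0, 2.0, 3.0], [4.0, 5.0, 6.0]),
        ([1.0, 3.0, 5.0], [2.0, 4.0, 6.0]),
        ([1.0, 2.0], [3.0, 4.0, 5.0]),
        ([10.0, 12.0, 14.0, 16.0], [11.0, 13.0, 15.0]),
        ([0.1, 0.2, 0.3, 0.9], [0.4, 0.5]),
    ]

    @pytest.mark.parametrize("a,b", SAMPLES)
    def test_mann_whitney_p_matches_exhaustive_permutation(self, a, b):
        obs = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        pooled = np.array(a + b)
        n_a = len(a)
        u_stats = []
        for idx in itertools.combinations(range(len(pooled)), n_a):
            ga = pooled[list(idx)]
            gb = np.delete(pooled, list(idx))
            u = sum((x > y) + 0.5 * (x == y) for x in ga for y in gb)
            u_stats.append(u)
        u_stats = np.array(u_stats)
        u_obs = sum((x > y) + 0.5 * (x == y) for x in a for y in b)
        mu = u_stats.mean()
        p_exact = np.mean(np.abs(u_stats - mu) >= np.abs(u_obs - mu) - 1e-12)
        assert obs.pvalue == pytest.approx(p_exact, abs=1e-9)

    @pytest.mark.parametrize("a,b", SAMPLES)
    def test_kruskal_statistic_matches_hand_computation(self, a, b):
        obs = stats.kruskal(a, b)
        pooled = np.concatenate([a, b])
        ranks = stats.rankdata(pooled)
        n = len(pooled)
        r_a, r_b = ranks[: len(a)], ranks[len(a) :]
        h = 12 / (n * (n + 1)) * (
            len(a) * (r_a.mean() - (n + 1) / 2) ** 2 + len(b) * (r_b.mean() - (n + 1) / 2) ** 2
        )
        assert obs.statistic == pytest.approx(h, abs=1e-9)
        assert obs.pvalue == pytest.approx(stats.chi2.sf(h, 1), abs=1e-9)


class TestExpressionStrata:
    def test_identical_rankings_intersect_to_top_set(self):
        expr = pd.DataFrame(
            {"e1": [4.0, 3.0, 2.0, 1.0], "e2": [40.0, 30.0, 20.0, 10.0]},
            index=["a", "b", "c", "d"],
        )
        high, low = expression_strata(expr, 50, 50)
        assert high == ["a", "b"]
        assert low == ["c", "d"]

    def test_reversed_rankings_empty_the_intersection(self):
        expr = pd.DataFrame(
            {"e1": [4.0, 3.0, 2.0, 1.0], "e2": [1.0, 2.0, 3.0, 4.0]},
            index=["a", "b", "c", "d"],
        )
        high, low = expression_strata(expr, 25, 25)
        assert high == [] and low == []

    def test_single_experiment_is_a_quantile_cut(self):
        expr = pd.DataFrame({"e1": [5.0, 4.0, 3.0, 2.0, 1.0]}, index=list("abcde"))
        high, low = expression_strata(expr, 40, 20)
        assert high == ["a", "b"] and low == ["e"]

    def test_set_size_non_increasing_in_experiments(self, rng):
        n = 200
        base = rng.normal(size=n)
        cols = {f"e{j}": base + rng.normal(scale=0.5, size=n) for j in range(6)}
        expr = pd.DataFrame(cols, index=[f"g{i}" for i in range(n)])
        sizes = [
            len(expression_strata(expr[[f"e{j}" for j in range(k)]], 20, 20)[0])
            for k in range(1, 7)
        ]
        assert all(s1 >= s2 for s1, s2 in zip(sizes, sizes[1:]))

    def test_percentage_validation(self):
        expr = pd.DataFrame({"e1": [1.0, 2.0]}, index=["a", "b"])
        with pytest.raises(ValueError):
            expression_strata(expr, 0, 10)


class TestStrataProfiles:
    def test_identical_groups_get_identical_smoothed_curves(self, ramped_matrix):
        ids = ramped_matrix.cds_ids[:100]
        out = strata_profiles(ramped_matrix, {"g1": ids, "g2": list(ids)}, n_boot=20, seed=0)
        (p1, s1), (p2, s2) = out["g1"], out["g2"]
        assert p1.mean == pytest.approx(p2.mean)
        assert s1 == pytest.approx(s2)

    def test_smoother_on_constant_data_is_constant(self):
        orf = Orfeome([f"g{i}" for i in range(5)], ["ATG" + "AAA" * 30] * 5)
        matrix = build_codon_matrix(orf, 30)
        out = strata_profiles(matrix, {"all": orf.ids}, n_boot=10, seed=0)
        _, smooth = out["all"]
        assert smooth == pytest.approx(np.full(30, 6.0))

    def test_lower_capacity_group_stays_below_beyond_the_ramp(self):
        lo, _ = generate_orfeome(GeneratorSpec(n_cds=700, cds_length_codons=101, ramp=(7.8, 0.3, 7.0), seed=8))
        hi, _ = generate_orfeome(GeneratorSpec(n_cds=700, cds_length_codons=101, ramp=(7.9, 0.3, 7.0), seed=9))
        merged = Orfeome(
            ids=[f"lo_{c}" for c in lo.ids] + [f"hi_{c}" for c in hi.ids],
            seqs=lo.seqs + hi.seqs,
        )
        matrix = build_codon_matrix(merged, 100)
        out = strata_profiles(
            matrix,
            {"lo": [f"lo_{c}" for c in lo.ids], "hi": [f"hi_{c}" for c in hi.ids]},
            n_boot=20,
            seed=0,
        )
        (_, s_lo), (_, s_hi) = out["lo"], out["hi"]
        beyond = np.asarray(matrix.positions) > 20
        assert np.mean(s_lo[beyond] < s_hi[beyond]) > 0.9

    def test_small_group_rejected(self, ramped_matrix):
        with pytest.raises(ValueError, match="fewer than 2"):
            strata_profiles(ramped_matrix, {"tiny": ramped_matrix.cds_ids[:1]}, n_boot=10)


class TestCorrelations:
    def test_self_correlation_is_one(self):
        p = _profile(np.sin(np.linspace(0, 3, 50)) + 7)
        edges, graph = metric_correlation_network({"a": p, "b": p})
        assert edges["rho"].iloc[0] == pytest.approx(1.0)
        assert graph.has_edge("a", "b")

    def test_negated_profile_gives_minus_one(self):
        base = np.sin(np.linspace(0, 3, 50)) + 7
        edges, _ = metric_correlation_network({"a": _profile(base), "b": _profile(-base)})
        assert edges["rho"].iloc[0] == pytest.approx(-1.0)

    def test_independent_profiles_are_weakly_correlated(self):
        hits = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            edges, _ = metric_correlation_network(
                {"a": _profile(r.normal(size=100)), "b": _profile(r.normal(size=100))}
            )
            hits += abs(edges["rho"].iloc[0]) < 0.3
        assert hits >= 9

    def test_region_correlation_identity_and_monotone_transform(self):
        base = np.linspace(7.0, 7.9, 119)
        pos = np.arange(119) + 2
        a = _profile(base, pos)
        b = _profile(np.exp(base), pos)  # monotone transform: rank-identical
        df = region_correlation(a, a, regions=[(2, 120), (2, 60), (2, 30)])
        assert df["pearson_r"].to_numpy() == pytest.approx(np.ones(3))
        df2 = region_correlation(a, b, regions=[(2, 120)])
        assert df2["spearman_rho"].iloc[0] == pytest.approx(1.0)

    def test_too_small_region_errors(self):
        a = _profile(np.linspace(7, 8, 50))
        with pytest.raises(ValueError, match="fewer than 3"):
            region_correlation(a, a, regions=[(2, 3)])

    def test_by_adjustment_is_monotone_and_conservative(self):
        profs = {
            f"m{k}": _profile(np.random.default_rng(k).normal(size=30)) for k in range(5)
        }
        edges, _ = metric_correlation_network(profs)
        assert np.all(edges["p_adj"] >= edges["p_raw"] - 1e-15)
        order_raw = edges.sort_values("p_raw")["p_adj"].to_numpy()
        assert np.all(np.diff(order_raw) >= -1e-15)
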