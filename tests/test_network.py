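import numpy as np
import pandas as pd
import pytest
from scipy import stats

import darkmir as dm
from darkmir.network import PerturbationProfile


def two_pass_pearson(x, y):
    """Independent textbook covariance/variance oracle."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    vx = sum((a - mx) ** 2 for a in x)
    vy = sum((b - my) ** 2 for b in y)
    return cov / (vx**0.5 * vy**0.5)


class TestPearson:
    def test_perfect_linear(self):
        assert dm.pearson([1, 2, 3], [2, 4, 6]) == pytest.approx(1.0)

    def test_zero_variance_is_invalid(self):
        assert np.isnan(dm.pearson([1, 2, 3], [5, 5, 5]))

    def test_length_checks(self):
        with pytest.raises(ValueError):
            dm.pearson([1, 2], [1, 2])
        with pytest.raises(ValueError):
            dm.pearson([1, 2, 3], [1, 2])

    def test_matches_two_pass_oracle(self, rng):
        for _ in range(20):
            x = rng.normal(size=20)
            y = rng.normal(size=20)
            assert dm.pearson(x, y) == pytest.approx(
                two_pass_pearson(x, y), abs=1e-12
            )


class TestReferenceNetwork:
    def _instance(self, rng, n_edges=30, n_samples=10):
        n_reg, n_tgt = 8, 15
        reg = pd.DataFrame(rng.normal(size=(n_reg, n_samples)),
                           index=[f"m{i}" for i in range(n_reg)],
                           columns=[f"s{i}" for i in range(n_samples)])
        tgt = pd.DataFrame(rng.normal(size=(n_tgt, n_samples)),
                           index=[f"g{i}" for i in range(n_tgt)],
                           columns=[f"s{i}" for i in range(n_samples)])
        pairs = sorted({(f"m{rng.integers(n_reg)}", f"g{rng.integers(n_tgt)}")
                        for _ in range(n_edges)})
        inter = dm.InteractionSet(
            pd.DataFrame(pairs, columns=["regulator", "target"]), "mRNA")
        em_r = dm.ExpressionMatrix(reg, "miRNA")
        em_t = dm.ExpressionMatrix(tgt, "mRNA")
        return em_r, em_t, inter

    def test_pcc_equals_direct_pearson(self, rng):
        em_r, em_t, inter = self._instance(rng, n_edges=2, n_samples=5)
        ref = dm.build_reference_network(em_r, em_t, inter)
        for _, row in ref.edges.iterrows():
            direct = dm.pearson(em_r.values.loc[row["regulator"]],
                                em_t.values.loc[row["target"]])
            assert row["pcc"] == pytest.approx(direct, abs=1e-12)

    def test_constant_target_marked_invalid(self, rng):
        em_r, em_t, inter = self._instance(rng, n_edges=5)
        tgt0 = inter.edges["target"].iloc[0]
        em_t.values.loc[tgt0] = 3.14
        ref = dm.build_reference_network(em_r, em_t, inter)
        sub = ref.edges[ref.edges["target"] == tgt0]
        assert not sub["valid"].any()
        assert ref.n_valid == len(ref.edges) - len(sub)

    def test_matches_full_corrcoef_oracle(self, rng):
        em_r, em_t, inter = self._instance(rng, n_edges=30)
        ref = dm.build_reference_network(em_r, em_t, inter)
        big = np.corrcoef(np.vstack([em_r.values, em_t.values]))
        ri = {f: i for i, f in enumerate(em_r.feature_ids)}
        ti = {f: i + len(ri) for i, f in enumerate(em_t.feature_ids)}
        for _, row in ref.edges.iterrows():
            assert row["pcc"] == pytest.approx(
                big[ri[row["regulator"]], ti[row["target"]]], abs=1e-10)

    def test_sample_mismatch_errors(self, rng):
        em_r, em_t, inter = self._instance(rng)
        em_t.values.columns = [f"x{i}" for i in range(em_t.n_samples)]
        with pytest.raises(ValueError, match="sample ids"):
            dm.build_reference_network(em_r, em_t, inter)


class TestEdgeZStatistic:
    def test_zero_numerator(self):
        assert dm.edge_z_statistic(0.7, 0.0, 10) == 0.0

    def test_unit_denominator(self):
        assert dm.edge_z_statistic(0.0, 0.1, 11) == pytest.approx(1.0)

    def test_matches_independent_transcription(self, rng):
        oracle = lambda d, p, n: d * (n - 1) / (1 - p * p)  # noqa: E731
        for _ in range(50):
            p = rng.uniform(-0.99, 0.99)
            d = rng.uniform(-0.5, 0.5)
            n = int(rng.integers(3, 200))
            assert dm.edge_z_statistic(p, d, n) == pytest.approx(
                oracle(d, p, n), abs=1e-12)
        assert dm.edge_z_statistic(0.6, -0.05, 87) == pytest.approx(
            oracle(-0.05, 0.6, 87), abs=1e-12)

    def test_sign_follows_delta(self, rng):
        for _ in range(20):
            p = rng.uniform(-0.9, 0.9)
            d = rng.uniform(-1, 1)
            assert np.sign(dm.edge_z_statistic(p, d, 30)) == np.sign(d)

    def test_perfect_correlation_is_clamped_not_infinite(self):
        z = dm.edge_z_statistic(1.0, 0.1, 10)
        assert np.isfinite(z)

    def test_sqrt_variant(self):
        z = dm.edge_z_statistic(0.0, 0.1, 11, variant="sqrt")
        assert z == pytest.approx(0.1 * np.sqrt(10))


class TestPerturbSample:
    def _setup(self, rng, n=8, n_edges=10):
        tester = TestReferenceNetwork()
        em_r, em_t, inter = tester._instance(rng, n_edges=n_edges,
                                             n_samples=n)
        ref = dm.build_reference_network(em_r, em_t, inter)
        return em_r, em_t, inter, ref

    def test_unchanged_correlation_not_significant(self, make_expr):
        # appending a point on the exact trend keeps pcc == 1 -> delta 0
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        reg = make_expr(x[None, :], "miRNA", prefix="m")
        tgt = make_expr(2 * x[None, :], "mRNA", prefix="g")
        inter = dm.InteractionSet(
            pd.DataFrame([("m0", "g0")], columns=["regulator", "target"]),
            "mRNA")
        ref = dm.build_reference_network(reg, tgt, inter)
        prof = dm.perturb_sample(
            ref, reg, tgt,
            pd.Series({"m0": 6.0}), pd.Series({"g0": 12.0}), "new")
        rec = prof.records.iloc[0]
        assert rec["delta_pcc"] == pytest.approx(0.0, abs=1e-12)
        assert not rec["significant"]

    def test_add_mode_matches_from_scratch_recomputation(self, rng):
        em_r, em_t, inter, ref = self._setup(rng, n=5)
        s_reg = pd.Series(rng.normal(size=len(em_r.feature_ids)) * 3,
                          index=em_r.feature_ids)
        s_tgt = pd.Series(rng.normal(size=len(em_t.feature_ids)) * 3,
                          index=em_t.feature_ids)
        prof = dm.perturb_sample(ref, em_r, em_t, s_reg, s_tgt, "q1")
        for _, rec in prof.records.iterrows():
            x = np.append(em_r.values.loc[rec["regulator"]],
                          s_reg[rec["regulator"]])
            y = np.append(em_t.values.loc[rec["target"]],
                          s_tgt[rec["target"]])
            assert rec["pcc_perturbed"] == pytest.approx(
                dm.pearson(x, y), abs=1e-10)
            assert rec["delta_pcc"] == pytest.approx(
                dm.pearson(x, y) - rec["pcc_ref"], abs=1e-10)

    def test_leave_one_out_matches_direct_recomputation(self, rng):
        em_r, em_t, inter, ref = self._setup(rng, n=8)
        sid = em_r.sample_ids[3]
        prof = dm.perturb_sample(
            ref, em_r, em_t, em_r.sample(sid), em_t.sample(sid), sid,
            mode="leave_one_out")
        keep = [s for s in em_r.sample_ids if s != sid]
        for _, rec in prof.records.iterrows():
            full = dm.pearson(em_r.values.loc[rec["regulator"]],
                              em_t.values.loc[rec["target"]])
            loo = dm.pearson(em_r.values.loc[rec["regulator"], keep],
                             em_t.values.loc[rec["target"], keep])
            assert rec["delta_pcc"] == pytest.approx(full - loo, abs=1e-10)
        assert prof.n_ref == em_r.n_samples - 1

    def test_add_mode_rejects_reference_member(self, rng):
        em_r, em_t, inter, ref = self._setup(rng)
        sid = em_r.sample_ids[0]
        with pytest.raises(ValueError, match="already a reference"):
            dm.perturb_sample(ref, em_r, em_t, em_r.sample(sid),
                              em_t.sample(sid), sid, mode="add")

    def test_record_count_equals_valid_edges(self, rng):
        em_r, em_t, inter, ref = self._setup(rng, n_edges=12)
        s_reg = pd.Series(0.0, index=em_r.feature_ids)
        s_tgt = pd.Series(0.0, index=em_t.feature_ids)
        prof = dm.perturb_sample(ref, em_r, em_t, s_reg, s_tgt, "q")
        assert len(prof.records) == ref.n_valid


def planted_profiles(n_profiles, flags_per_edge):
    """Profiles with hand-planted significance flags (edges x profiles)."""
    edges = [(f"m{i}", f"g{i}") for i in range(len(flags_per_edge))]
    profiles = []
    for j in range(n_profiles):
        rec = pd.DataFrame(
            {
                "regulator": [e[0] for e in edges],
                "target": [e[1] for e in edges],
                "pcc_ref": 0.0,
                "pcc_perturbed": 0.0,
                "delta_pcc": 0.0,
                "z": 0.0,
                "p_value": 1.0,
                "significant": [bool(flags[j]) for flags in flags_per_edge],
            }
        )
        profiles.append(PerturbationProfile(f"s{j}", rec, 0.05, "add", 10))
    return profiles


class TestEdgeScores:
    def test_worked_example_630_of_755(self):
        flags = [[1] * 630 + [0] * 125]
        table = dm.compute_edge_scores(planted_profiles(755, flags)).table
        assert table["sig_count"].iloc[0] == 630
        assert round(float(table["score"].iloc[0]), 3) == 0.834

    def test_never_significant_scores_zero(self):
        flags = [[0] * 10, [1] * 10]
        table = dm.compute_edge_scores(planted_profiles(10, flags)).table
        assert table.set_index("regulator").loc["m0", "score"] == 0.0

    def test_matches_brute_force_counting(self, rng):
        flags = rng.integers(0, 2, size=(7, 10))
        table = dm.compute_edge_scores(planted_profiles(10, flags)).table
        lookup = table.set_index(["regulator", "target"])
        for i in range(7):
            assert lookup.loc[(f"m{i}", f"g{i}"), "sig_count"] == flags[i].sum()
            assert lookup.loc[(f"m{i}", f"g{i}"), "score"] == pytest.approx(
                flags[i].sum() / 10)

    def test_sorted_descending_with_lexicographic_ties(self, rng):
        flags = rng.integers(0, 2, size=(9, 6))
        table = dm.compute_edge_scores(planted_profiles(6, flags)).table
        key = list(zip(-table["score"], table["regulator"], table["target"]))
        assert key == sorted(key)

    def test_zero_profiles_errors(self):
        with pytest.raises(ValueError):
            dm.compute_edge_scores([])

    def test_score_times_n_is_exact_count(self, rng):
        flags = rng.integers(0, 2, size=(5, 12))
        t = dm.compute_edge_scores(planted_profiles(12, flags)).table
        assert (t["score"] * t["n_samples"] == t["sig_count"]).all()

    def test_monotone_in_alpha(self, tiny_sim):
        model = dm.SampleNetworkModel.from_simulation(tiny_sim, "mRNA")
        ref = dm.build_reference_network(
            model.expr_reg_normal, model.expr_tgt_normal, model.interactions)
        counts = {}
        for alpha in (0.1, 0.05, 0.01):
            profiles = dm.perturb_cohort(
                ref, model.expr_reg_normal, model.expr_tgt_normal,
                model.expr_reg_cancer, model.expr_tgt_cancer, alpha=alpha)
            counts[alpha] = dm.compute_edge_scores(profiles).table.set_index(
                ["regulator", "target"])["sig_count"].sort_index()
        assert (counts[0.05] <= counts[0.1]).all()
        assert (counts[0.01] <= counts[0.05]).all()


class TestBasicNetwork:
    def _table(self, scores):
        n = 20
        tab = pd.DataFrame(
            {
                "regulator": [f"m{i}" for i in range(len(scores))],
                "target": [f"g{i}" for i in range(len(scores))],
                "sig_count": [int(round(s * n)) for s in scores],
                "n_samples": n,
                "score": scores,
            }
        ).sort_values("score", ascending=False)
        return dm.EdgeScoreTable(tab.reset_index(drop=True), 0.05, "mRNA")

    def test_threshold_definition(self):
        net = dm.build_basic_network(self._table([0.9, 0.41, 0.39]), 0.4)
        assert len(net) == 2

    def test_empty_network_warns(self):
        with pytest.warns(UserWarning, match="empty"):
            net = dm.build_basic_network(self._table([0.5, 0.3]), 1.0)
        assert len(net) == 0

    def test_matches_brute_force_filter(self, rng):
        scores = rng.random(100).round(3)
        tab = self._table(list(scores))
        net = dm.build_basic_network(tab, 0.4)
        brute = {(r, t) for r, t, s in tab.table[
            ["regulator", "target", "score"]].itertuples(index=False)
            if s >= 0.4}
        assert set(net.edge_tuples) == brute

    def test_size_monotone_in_threshold(self, rng):
        tab = self._table(list(rng.random(50)))
        sizes = [len(dm.build_basic_network(tab, th))
                 for th in (0.2, 0.4, 0.6, 0.8)]
        assert sizes == sorted(sizes, reverse=True)

    def test_invalid_threshold_errors(self):
        with pytest.raises(ValueError):
            dm.build_basic_network(self._table([0.5]), 1.5)

    def test_node_counts_and_networkx_export(self):
        net = dm.build_basic_network(self._table([0.9, 0.8, 0.1]), 0.4)
        assert net.node_counts == {"miRNA": 2, "mRNA": 2}
        g = net.to_networkx()
        assert g.number_of_edges() == 2
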