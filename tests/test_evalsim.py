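"""Gold-standard DE evaluation, ROC/PR construction, detection depth,
NB parameter estimation, simulation, testing, and power curves."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from brbkit.evalsim import (
    DispersionTrend,
    GoldStandard,
    bh_adjust,
    depth_for_detection,
    empirical_power,
    estimate_nb_params,
    filter_de,
    make_de_table,
    nb_two_group_test,
    power_curve,
    read_de_table,
    roc_pr_from_ranked,
    simulate_de_counts,
    write_de_table,
)


class TestFilterDE:
    def test_predicate_examples(self):
        tab = make_de_table(
            ["kept", "small_fc", "big_fdr"],
            [2.0, 0.5, 2.0],
            [1e-6, 1e-6, 0.5],
            padj=[0.01, 0.01, 0.2],
        )
        assert filter_de(tab) == {"kept"}

    def test_boundary_inclusive(self):
        tab = make_de_table(["g"], [1.0], [0.01], padj=[0.05])
        assert filter_de(tab, fc_cut=2, fdr_cut=0.05) == {"g"}

    def test_empty_table(self):
        assert filter_de(make_de_table([], [], [])) == set()

    def test_matches_row_oracle_and_permutation_invariant(self):
        rng = np.random.default_rng(8)
        n = 300
        tab = make_de_table(
            [f"g{i}" for i in range(n)],
            rng.normal(0, 2, n),
            rng.random(n),
        )
        expected = {
            row.gene_id
            for row in tab.itertuples()
            if abs(row.log2fc) >= 1.0 and row.padj <= 0.05
        }
        assert filter_de(tab) == expected
        shuffled = tab.sample(frac=1, random_state=1).reset_index(drop=True)
        assert filter_de(shuffled) == expected


class TestEmpiricalPower:
    gold = GoldStandard.from_sets({"a", "b"}, {"a", "b", "c", "d"})

    def test_perfect(self):
        assert empirical_power({"a", "b"}, self.gold)["tpr"] == 1.0

    def test_disjoint(self):
        out = empirical_power({"c"}, self.gold)
        assert out["tpr"] == 0.0 and out["n_de"] == 1

    def test_set_algebra_oracle(self):
        rng = np.random.default_rng(9)
        universe = {f"g{i}" for i in range(100)}
        pos = set(rng.choice(sorted(universe), 30, replace=False))
        called = set(rng.choice(sorted(universe), 40, replace=False))
        out = empirical_power(called, GoldStandard.from_sets(pos, universe))
        assert out["n_true_positive"] == len(called & pos)
        assert out["tpr"] == len(called & pos) / 30

    def test_empty_positives_flagged(self):
        gold = GoldStandard.from_sets(set(), {"a"})
        out = empirical_power({"a"}, gold)
        assert out["tpr"] == 0.0 and out["positives_empty"]


def brute_force_curves(pvals: dict, positives: set, universe: set):
    """Enumerate every cutoff naively with set operations."""
    p = {g: pvals.get(g, 1.0) for g in universe}
    negatives = universe - positives
    pts = []
    for cut in sorted(set(p.values())):
        called = {g for g, v in p.items() if v <= cut}
        tp = len(called & positives)
        fp = len(called & negatives)
        pts.append(
            (fp / len(negatives), tp / len(positives), tp / len(called))
        )
    fpr = [0.0] + [x for x, _, _ in pts]
    tpr = [0.0] + [y for _, y, _ in pts]
    roc_auc = np.trapezoid(tpr, fpr)
    rec = [0.0] + [y for _, y, _ in pts]
    prec = [pts[0][2]] + [z for _, _, z in pts]
    pr_auc = np.trapezoid(prec, rec)
    return pts, roc_auc, pr_auc


class TestRocPr:
    def test_perfect_ranking(self):
        tab = make_de_table(["a", "b", "c", "d"], [0] * 4, [0.01, 0.02, 0.5, 0.9])
        gold = GoldStandard.from_sets({"a", "b"}, {"a", "b", "c", "d"})
        cs = roc_pr_from_ranked(tab, gold)
        assert cs.roc_auc == 1.0 and cs.pr_auc == pytest.approx(1.0)

    def test_inverted_ranking(self):
        tab = make_de_table(["a", "b", "c", "d"], [0] * 4, [0.9, 0.8, 0.1, 0.2])
        gold = GoldStandard.from_sets({"a", "b"}, {"a", "b", "c", "d"})
        assert roc_pr_from_ranked(tab, gold).roc_auc == 0.0

    def test_missing_genes_penalized_with_p1(self):
        tab = make_de_table(["a"], [0], [0.01])
        gold = GoldStandard.from_sets({"a", "b"}, {"a", "b", "c"})
        cs = roc_pr_from_ranked(tab, gold)
        # b (positive) only called at cutoff 1 together with negative c
        assert cs.roc[1].tolist() == [0.0, 0.5]
        assert cs.roc[-1].tolist() == [1.0, 1.0]

    def test_empty_sides_rejected(self):
        tab = make_de_table(["a"], [0], [0.5])
        with pytest.raises(ValueError):
            roc_pr_from_ranked(tab, GoldStandard.from_sets({"a"}, {"a"}))

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(data=st.data(), n=st.integers(3, 20))
    def test_matches_brute_force_with_ties(self, data, n):
        genes = [f"g{i}" for i in range(n)]
        # coarse grid of p-values forces plenty of ties
        pvals = data.draw(
            st.lists(
                st.sampled_from([0.0, 0.05, 0.2, 0.5, 1.0]),
                min_size=n, max_size=n,
            )
        )
        n_pos = data.draw(st.integers(1, n - 1))
        positives = set(genes[:n_pos])
        universe = set(genes)
        tab = make_de_table(genes, [0.0] * n, pvals)
        cs = roc_pr_from_ranked(tab, GoldStandard.from_sets(positives, universe))
        pts, roc_auc, pr_auc = brute_force_curves(
            dict(zip(genes, pvals)), positives, universe
        )
        assert np.allclose(cs.roc[1:], [[x, y] for x, y, _ in pts])
        assert cs.roc_auc == pytest.approx(roc_auc)
        assert cs.pr_auc == pytest.approx(pr_auc)

    def test_matches_sklearn_on_tie_free_instance(self):
        from sklearn.metrics import average_precision_score, roc_auc_score

        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(200)]
        p = rng.random(200)
        pos = set(rng.choice(genes, 50, replace=False))
        tab = make_de_table(genes, np.zeros(200), p)
        cs = roc_pr_from_ranked(tab, GoldStandard.from_sets(pos, set(genes)))
        y = np.array([g in pos for g in genes])
        assert cs.roc_auc == pytest.approx(roc_auc_score(y, -p), abs=1e-12)
        # trapezoidal PR-AUC and step-wise average precision agree closely
        # on dense tie-free rankings
        assert cs.pr_auc == pytest.approx(average_precision_score(y, -p), abs=0.02)


class TestDepthForDetection:
    def test_cpm_saturated(self):
        assert depth_for_detection(1e6) == 1

    def test_closed_form_value(self):
        d = depth_for_detection(1000, 0.95)
        assert d == math.ceil(math.log(0.05) / math.log(1 - 1e-3))

    def test_monotone(self):
        cpms = [1, 10, 100, 1000, 1e4]
        depths = [depth_for_detection(c, 0.95) for c in cpms]
        assert depths == sorted(depths, reverse=True)
        probs = [0.5, 0.9, 0.95, 0.99]
        dd = [depth_for_detection(100, p) for p in probs]
        assert dd == sorted(dd)

    @pytest.mark.parametrize("bad", [0, -1, 1e6 + 1])
    def test_bad_cpm(self, bad):
        with pytest.raises(ValueError):
            depth_for_detection(bad)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.5])
    def test_bad_prob(self, bad):
        with pytest.raises(ValueError):
            depth_for_detection(100, bad)

    def test_monte_carlo_brackets_closed_form(self):
        """Binomial simulation: detection frequency crosses the target
        probability exactly at the analytic depth."""
        rng = np.random.default_rng(17)
        for cpm, prob in [(1000, 0.95), (50, 0.9), (5000, 0.99), (200, 0.8)]:
            d = depth_for_detection(cpm, prob)
            rate = cpm / 1e6
            trials = 100_000
            freq_d = (rng.binomial(d, rate, trials) > 0).mean()
            freq_dm1 = (rng.binomial(d - 1, rate, trials) > 0).mean() if d > 1 else 0.0
            se = 3.5 / math.sqrt(trials)
            assert freq_d >= prob - se
            assert freq_dm1 <= prob + se


class TestEstimateNbParams:
    def test_poisson_dispersion_near_zero(self):
        rng = np.random.default_rng(21)
        mu = rng.lognormal(3, 1, 500)
        counts = rng.poisson(mu[:, None], size=(500, 50))
        params, _ = estimate_nb_params(counts)
        assert np.median(params["dispersion"]) < 0.05

    def test_recovers_known_dispersion(self):
        rng = np.random.default_rng(22)
        true_disp = 0.2
        mu = rng.lognormal(3, 1, 1000)
        r = 1 / true_disp
        counts = rng.negative_binomial(r, r / (r + mu[:, None]), size=(1000, 50))
        params, trend = estimate_nb_params(counts)
        well_expressed = mu > 5
        med = np.median(params["dispersion"][well_expressed])
        assert abs(med - true_disp) / true_disp < 0.25
        assert abs(trend(float(np.median(mu))) - true_disp) / true_disp < 0.25

    def test_constant_gene(self):
        counts = np.full((1, 10), 7)
        params, _ = estimate_nb_params(counts)
        assert params["dispersion"].iloc[0] == 0.0
        assert params["mean"].iloc[0] == pytest.approx(7.0)

    def test_grouped_estimation_ignores_signal(self):
        rng = np.random.default_rng(23)
        mu = rng.lognormal(3, 0.5, 400)
        a = rng.poisson(mu[:, None], size=(400, 10))
        b = rng.poisson(4 * mu[:, None], size=(400, 10))
        counts = np.hstack([a, b])
        params, _ = estimate_nb_params(counts, groups=[0] * 10 + [1] * 10)
        # between-group fold change must not masquerade as dispersion
        assert np.median(params["dispersion"]) < 0.25


class TestSimulateDeCounts:
    def test_de_gene_count_exact(self):
        _, _, truth = simulate_de_counts(n_genes=1000, frac_de=0.1, n_reps=3, seed=1)
        assert truth.table["is_de"].sum() == 100
        assert (truth.table.loc[~truth.table["is_de"], "log2fc"] == 0).all()

    def test_frac_de_zero(self):
        counts, groups, truth = simulate_de_counts(
            n_genes=200, frac_de=0.0, n_reps=3, seed=2
        )
        assert truth.table["is_de"].sum() == 0
        assert (truth.table["log2fc"] == 0).all()
        assert counts.shape == (200, 6)

    def test_seeded_reproducibility(self):
        c1, _, t1 = simulate_de_counts(n_genes=300, n_reps=4, seed=7)
        c2, _, t2 = simulate_de_counts(n_genes=300, n_reps=4, seed=7)
        assert (c1 == c2).all()
        pd.testing.assert_frame_equal(t1.table, t2.table)

    def test_group_mean_ratio_tracks_lfc(self):
        counts, groups, truth = simulate_de_counts(
            n_genes=2000, frac_de=0.1, n_reps=50, seed=3
        )
        tab = truth.table
        de = tab["is_de"].to_numpy() & (tab["mean"].to_numpy() > 20)
        m1 = counts[:, groups == 0].mean(axis=1)
        m2 = counts[:, groups == 1].mean(axis=1)
        obs_lfc = np.log2((m1[de] + 0.5) / (m2[de] + 0.5))
        # sample-mean oracle: observed log ratio ~ true lfc
        resid = obs_lfc - tab.loc[de, "log2fc"]
        assert np.abs(np.median(resid)) < 0.1
        assert np.corrcoef(obs_lfc, tab.loc[de, "log2fc"])[0, 1] > 0.9

    def test_roundtrip_dispersion_recovery(self):
        trend_in = DispersionTrend(intercept=np.log(0.15), slope=0.0)
        counts, groups, truth = simulate_de_counts(
            n_genes=1000, frac_de=0.0, n_reps=50, trend=trend_in, seed=4
        )
        params, trend_out = estimate_nb_params(counts, groups=groups)
        mid = float(np.median(truth.table["mean"]))
        assert abs(trend_out(mid) - 0.15) / 0.15 < 0.25


class TestNbTwoGroupTest:
    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(11)
        mu = rng.lognormal(2.0, 1.5, 2000)
        disp = 0.1 + 1 / mu
        r = 1 / disp
        counts = rng.negative_binomial(
            r[:, None], (r / (r + mu))[:, None], size=(2000, 20)
        )
        tab = nb_two_group_test(counts, [0] * 10 + [1] * 10)
        rate = (tab["pvalue"] <= 0.05).mean()
        assert 0.03 <= rate <= 0.07

    def test_strong_effect_detected(self):
        """An 8-fold change at n=10 per group is found in >= 95% of seeds."""
        hits = 0
        r = 1 / 0.1
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            # 99 stable background genes anchor the size factors; gene 0 is DE
            mu = rng.lognormal(3.5, 0.5, 100)
            counts = rng.negative_binomial(
                r, r / (r + mu[:, None]), (100, 20)
            ).astype(np.int64)
            mu0 = 50.0
            counts[0, :10] = rng.negative_binomial(r, r / (r + 8 * mu0), 10)
            counts[0, 10:] = rng.negative_binomial(r, r / (r + mu0), 10)
            tab = nb_two_group_test(counts, [0] * 10 + [1] * 10)
            hits += int(tab.loc[0, "padj"] < 0.05)
        assert hits >= 19

    def test_all_zero_gene(self):
        counts = np.zeros((3, 10), dtype=int)
        counts[1] = 5  # keep size factors finite
        tab = nb_two_group_test(counts, [0] * 5 + [1] * 5)
        assert tab.loc[0, "pvalue"] == 1.0 and tab.loc[0, "log2fc"] == 0.0

    def test_sign_convention(self):
        rng = np.random.default_rng(12)
        # stable background keeps size factors near 1
        counts = rng.poisson(50, size=(40, 10))
        counts[0, :5] = rng.poisson(200, 5)
        counts[0, 5:] = rng.poisson(10, 5)
        tab = nb_two_group_test(counts, [0] * 5 + [1] * 5)
        assert tab.loc[0, "log2fc"] > 2  # group 0 higher -> positive lfc


class TestBhAdjust:
    def test_monotone_and_idempotent(self):
        rng = np.random.default_rng(13)
        p = rng.random(100)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert np.allclose(bh_adjust(q), q) or (bh_adjust(q) >= q - 1e-12).all()
        assert (q >= p - 1e-12).all()


class TestPowerCurve:
    def test_more_replicates_more_power(self):
        pc = power_curve(
            replicate_levels=(5, 20), n_sims=5, n_genes=1000, seed=2
        )
        tpr = dict(zip(pc["n_replicates"], pc["mean_tpr"]))
        assert tpr[20] >= tpr[5]

    def test_huge_effect_high_power(self):
        pc = power_curve(
            replicate_levels=(50,), n_sims=3, n_genes=500,
            lfc_shape=8.0, lfc_scale=0.5, seed=3,
        )
        assert pc["mean_tpr"].iloc[0] > 0.9

    def test_alpha_monotonicity(self):
        tprs = []
        for alpha in (0.05, 1e-4, 1e-8):
            pc = power_curve(
                replicate_levels=(10,), n_sims=2, n_genes=500,
                alpha=alpha, seed=4,
            )
            tprs.append(pc["mean_tpr"].iloc[0])
        assert tprs[0] >= tprs[1] >= tprs[2]


class TestDeTableIO:
    def test_roundtrip(self, tmp_path):
        tab = make_de_table(["a", "b"], [1.5, -2.0], [0.01, 0.5])
        p = tmp_path / "de.tsv"
        write_de_table(tab, p)
        back = read_de_table(p)
        pd.testing.assert_frame_equal(tab, back)

    def test_padj_computed_when_missing(self, tmp_path):
        p = tmp_path / "de.tsv"
        p.write_text("gene_id\tlog2fc\tpvalue\na\t1.0\t0.02\nb\t0.0\t0.5\n")
        back = read_de_table(p)
        assert np.allclose(back["padj"], bh_adjust([0.02, 0.5]))

    def test_missing_columns_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("gene\tlfc\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_de_table(p)
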