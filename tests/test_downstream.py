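"""Downstream analyses: BH adjustment, proxy selection, colocalization,
replication, the genotype x expression interaction and profiles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from germdrug import (PanelConfig, PhenotypeTable, bh_adjust, boxplot_outliers,
                      coloc_call, interaction_test, lm_scan,
                      replicate_candidates, select_proxy, simulate_genotypes,
                      stratified_profile)

from conftest import manual_panel

import pandas as pd


def bh_bruteforce(p):
    """Step-up BH oracle: independent textbook implementation."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


class TestBHAdjust:
    def test_three_equal_spaced(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_sorted_input_nondecreasing(self):
        adj = bh_adjust(np.sort(np.random.default_rng(0).random(20)))
        assert np.all(np.diff(adj) >= -1e-12)

    @settings(max_examples=200, derandomize=True)
    @given(st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=1,
                    max_size=6))
    def test_matches_bruteforce_oracle(self, p):
        assert np.allclose(bh_adjust(p), bh_bruteforce(p), atol=1e-12)


@pytest.fixture(scope="module")
def ld_panel():
    rng = np.random.default_rng(10)
    x = rng.integers(0, 3, 2000).astype(float)

    def correlated(target_r):
        best = None
        noise = rng.standard_normal(2000)
        for w in np.linspace(0.05, 3.0, 600):
            y = x + w * noise
            r2 = np.corrcoef(x, y)[0, 1] ** 2
            if best is None or abs(r2 - target_r) < best[0]:
                best = (abs(r2 - target_r), y)
        return best[1]

    d = np.column_stack([x, correlated(0.85), correlated(0.95),
                         correlated(0.3)])
    return manual_panel(d, pos=[1000, 2000, 3000, 4000])


class TestSelectProxy:

    def test_lead_itself_wins(self, ld_panel):
        assert select_proxy("v0", ["v0", "v1"], ld_panel) == ("v0", 1.0)

    def test_highest_r2_candidate_selected(self, ld_panel):
        proxy, r2 = select_proxy("v0", ["v1", "v2"], ld_panel, r2_min=0.8)
        assert proxy == "v2"
        assert r2 > 0.9

    def test_below_threshold_returns_none(self, ld_panel):
        assert select_proxy("v0", ["v3"], ld_panel, r2_min=0.8) is None

    def test_window_restriction(self, ld_panel):
        assert select_proxy("v0", ["v2"], ld_panel, window_bp=500,
                            r2_min=0.8) is None


class TestColocCall:
    def test_identical_profiles(self):
        prof = np.array([1.0, 5.0, 2.0, 8.0])
        r, called = coloc_call(prof, prof)
        assert r == pytest.approx(1.0) and called

    def test_anticorrelated_profiles(self):
        prof = np.array([1.0, 5.0, 2.0, 8.0])
        r, called = coloc_call(prof, -prof)
        assert r == pytest.approx(-1.0) and not called

    def test_constant_profile_flagged(self):
        with pytest.warns(UserWarning, match="constant"):
            r, called = coloc_call([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert np.isnan(r) and not called

    def test_symmetric(self):
        rng = np.random.default_rng(11)
        a, b = rng.random(10), rng.random(10)
        assert coloc_call(a, b) == coloc_call(b, a)

    def test_shared_vs_disjoint_causal_signals(self):
        # two traits driven by the same LD block colocalize; disjoint do not
        panel = simulate_genotypes(PanelConfig(
            n_samples=800, n_variants=40, ld_block_size=10, within_block_r=0.8,
            n_chromosomes=1, seed=12))
        rng = np.random.default_rng(13)
        hits_shared, hits_disjoint = 0, 0
        for rep in range(10):
            z1 = panel.dosages[:, 3]
            z3 = panel.dosages[:, 33]
            y1 = z1 + rng.standard_normal(800)
            y2 = z1 + rng.standard_normal(800)
            y3 = z3 + rng.standard_normal(800)
            lp = [-np.log10(lm_scan(y, None, panel.dosages)["p_value"]
                            .to_numpy()) for y in (y1, y2, y3)]
            hits_shared += coloc_call(lp[0], lp[1])[1]
            hits_disjoint += not coloc_call(lp[0], lp[2])[1]
        assert hits_shared >= 9
        assert hits_disjoint >= 9


@pytest.fixture(scope="module")
def replication_setup():
    panel = simulate_genotypes(PanelConfig(
        n_samples=800, n_variants=60, ld_block_size=1, within_block_r=0.0,
        seed=14))
    rng = np.random.default_rng(15)
    drugs = {}
    pairs = []
    for j in range(10):  # true pairs
        z = panel.dosages[:, j]
        z = (z - z.mean()) / z.std()
        drugs[f"true{j}"] = 0.35 * z + rng.standard_normal(800)
        pairs.append((panel.variants["id"].iloc[j], f"true{j}", 0.35))
    for j in range(10, 18):  # null pairs
        drugs[f"null{j}"] = rng.standard_normal(800)
        pairs.append((panel.variants["id"].iloc[j], f"null{j}"))
    pheno = PhenotypeTable(values=pd.DataFrame(
        drugs, index=panel.samples.index).T)
    return panel, pheno, pairs


class TestReplicateCandidates:

    def test_true_pairs_replicate_nulls_mostly_not(self, replication_setup):
        panel, pheno, pairs = replication_setup
        res = replicate_candidates(pairs, panel, pheno)
        true_rep = sum(r.status == "replicated" for r in res
                       if r.drug.startswith("true"))
        false_rep = sum(r.status == "replicated" for r in res
                        if r.drug.startswith("null"))
        assert true_rep >= 8
        assert false_rep <= 2

    def test_partition_exhaustive(self, replication_setup):
        panel, pheno, pairs = replication_setup
        pairs = pairs + [("var000001", "absent_drug"), ("nope", "true0")]
        res = replicate_candidates(pairs, panel, pheno)
        assert len(res) == len(pairs)
        assert all(r.status in {"replicated", "not_replicated", "skipped"}
                   for r in res)
        skipped = [r for r in res if r.status == "skipped"]
        assert len(skipped) == 2
        assert all(r.skip_reason for r in skipped)

    def test_empty_testable_set(self, replication_setup):
        panel, pheno, _ = replication_setup
        res = replicate_candidates([("nope1", "x"), ("nope2", "y")],
                                   panel, pheno)
        assert all(r.status == "skipped" for r in res)

    def test_direction_mismatch_blocks_replication(self, replication_setup):
        panel, pheno, _ = replication_setup
        vid = panel.variants["id"].iloc[0]
        res = replicate_candidates([(vid, "true0", -0.35)], panel, pheno)
        assert res[0].status == "not_replicated"


class TestInteraction:
    def test_null_calibration(self):
        rng = np.random.default_rng(16)
        n = 200
        ps = []
        for _ in range(400):
            expr = rng.standard_normal(n)
            geno = rng.integers(0, 3, n).astype(float)
            y = rng.standard_normal(n)
            ps.append(interaction_test(y, expr, geno).p_value)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_constructed_interaction_detected(self):
        rng = np.random.default_rng(17)
        n = 890
        expr = rng.standard_normal(n)
        geno = rng.integers(0, 3, n).astype(float)
        grp = (geno < 2).astype(float)
        y = expr * grp + 0.5 * rng.standard_normal(n)
        res = interaction_test(y, expr, geno)
        assert res.p_value < 1e-6
        assert res.beta_interaction == pytest.approx(1.0, abs=0.1)

    def test_allele_relabel_flips_sign(self):
        # swapping which allele counts as functional is a reparameterization:
        # the interaction beta negates, the LR P value is unchanged
        rng = np.random.default_rng(18)
        n = 400
        expr = rng.standard_normal(n)
        geno = rng.integers(0, 3, n).astype(float)
        y = expr * (geno < 2) + 0.5 * rng.standard_normal(n)
        a = interaction_test(y, expr, geno, coding="additive")
        b = interaction_test(y, expr, 2 - geno, coding="additive")
        assert np.sign(a.beta_interaction) == -np.sign(b.beta_interaction)
        assert a.p_value == pytest.approx(b.p_value, rel=1e-6)
        # group coding: complementing the binary group does the same
        grp = (geno < 2).astype(float)
        c = interaction_test(y, expr, 2.0 * grp)       # group = 1 - grp
        d = interaction_test(y, expr, 2.0 * (1 - grp))  # group = grp
        assert np.sign(c.beta_interaction) == -np.sign(d.beta_interaction)
        assert c.p_value == pytest.approx(d.p_value, rel=1e-6)

    def test_empty_group_errors(self):
        with pytest.raises(ValueError, match="empty genotype group"):
            interaction_test(np.zeros(10), np.arange(10.0), np.full(10, 2.0))


class TestStratifiedProfile:
    def test_constant_response(self):
        prof = stratified_profile(np.ones(40), np.arange(40.0),
                                  ["a"] * 20 + ["b"] * 20, n_bins=4)
        present = prof[prof["n"] > 0]
        assert (present["mean"] == 1.0).all()
        assert (present["sem"] == 0.0).all()

    def test_group_offsets_flat_profiles(self):
        rng = np.random.default_rng(19)
        expr = rng.standard_normal(400)
        grp = np.array(["g0", "g1"] * 200)
        y = (grp == "g1").astype(float)
        prof = stratified_profile(y, expr, grp, n_bins=4)
        assert np.allclose(prof.loc[prof["group"] == "g0", "mean"], 0.0)
        assert np.allclose(prof.loc[prof["group"] == "g1", "mean"], 1.0)

    def test_planted_interaction_diverges_across_bins(self):
        rng = np.random.default_rng(20)
        n = 2000
        expr = rng.standard_normal(n)
        grp = rng.integers(0, 2, n)
        y = expr * grp + 0.3 * rng.standard_normal(n)
        prof = stratified_profile(y, expr, grp, n_bins=5)
        diff = (prof[prof["group"] == "1"]["mean"].to_numpy()
                - prof[prof["group"] == "0"]["mean"].to_numpy())
        rho = stats.spearmanr(diff, np.arange(5)).statistic
        assert rho > 0.9


class TestBoxplotOutliers:
    def test_single_extreme_value(self):
        mask = boxplot_outliers([1.0, 2.0, 3.0, 4.0, 100.0])
        assert mask.tolist() == [False, False, False, False, True]

    def test_constant_vector(self):
        assert not boxplot_outliers(np.full(10, 3.0)).any()

    def test_data_within_fences(self):
        assert not boxplot_outliers(np.linspace(-1, 1, 50)).any()
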