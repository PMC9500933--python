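"""Marker selection, clumping, PRS computation and variance explained."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from hybridprs import (
    GenotypeDistribution,
    clump,
    compute_prs,
    compute_pve,
    compute_set_pve,
    filter_maf,
    select_markers,
)
from hybridprs.prs_scoring import RiskMarkerSet

from conftest import make_geno, make_sumstats


class TestSelectMarkers:
    def test_threshold_filters_by_p(self):
        ss = make_sumstats([0.1, 0.2, 0.3], [1e-9, 0.03, 0.5])
        assert len(select_markers(ss, 5e-8)) == 1
        assert len(select_markers(ss, 0.04)) == 2

    def test_pt_one_keeps_everything(self):
        ss = make_sumstats([0.1, 0.2, 0.3], [1e-9, 0.03, 0.5])
        mk = select_markers(ss, 1.0)
        assert mk.vids == ss.table["vid"].tolist()
        assert np.array_equal(mk.betas, ss.table["beta"].to_numpy())

    def test_empty_selection_is_valid(self):
        ss = make_sumstats([0.1], [0.5])
        assert len(select_markers(ss, 1e-8)) == 0

    @pytest.mark.parametrize("pt", [0, -0.1, 1.5])
    def test_invalid_threshold_rejected(self, pt):
        with pytest.raises(ValueError):
            select_markers(make_sumstats([0.1], [0.5]), pt)


class TestClump:
    def test_unlinked_markers_all_retained(self):
        rng = np.random.default_rng(0)
        geno = make_geno(rng.integers(0, 3, (200, 4)).astype(float))
        ss = make_sumstats([0.1] * 4, [1e-4, 1e-3, 1e-2, 0.1])
        out = clump(ss, geno, r2_max=0.5)
        assert len(out) == 4

    def test_perfect_ld_keeps_most_significant(self):
        col = np.array([0, 0, 1, 1, 2, 2], dtype=float)
        other = np.array([0, 1, 0, 1, 2, 0], dtype=float)
        geno = make_geno(np.column_stack([col, col, other]))
        # v0 and v1 are 10 kb apart (1000 vs 2000 bp) and identical
        ss = make_sumstats([0.1, 0.2, 0.3], [1e-3, 1e-6, 0.05])
        out = clump(ss, geno, r2_max=0.1, window_kb=250)
        assert "v1" in out.table["vid"].tolist()  # smaller p wins
        assert "v0" not in out.table["vid"].tolist()

    def test_tie_broken_toward_genome_order(self):
        col = np.array([0, 0, 1, 1, 2, 2], dtype=float)
        geno = make_geno(np.column_stack([col, col]))
        ss = make_sumstats([0.1, 0.2], [1e-4, 1e-4])
        out = clump(ss, geno, r2_max=0.1)
        assert out.table["vid"].tolist() == ["v0"]

    def test_outside_window_not_clumped(self):
        col = np.array([0, 0, 1, 1, 2, 2], dtype=float)
        variants = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "pos": [1000, 500_000_000],
             "vid": ["v0", "v1"], "a1": ["G", "G"], "a2": ["A", "A"]}
        )
        geno = make_geno(np.column_stack([col, col]), variants=variants)
        assert len(clump(make_sumstats([0.1, 0.2], [1e-4, 1e-3]), geno)) == 2

    def test_monomorphic_treated_as_unlinked(self):
        col = np.array([0, 0, 1, 1, 2, 2], dtype=float)
        mono = np.ones(6)
        geno = make_geno(np.column_stack([col, mono]))
        out = clump(make_sumstats([0.1, 0.2], [1e-4, 1e-3]), geno, r2_max=0.1)
        assert len(out) == 2

    def test_order_invariance(self):
        rng = np.random.default_rng(7)
        base = rng.integers(0, 3, (100, 1)).astype(float)
        noise = rng.integers(0, 3, (100, 5)).astype(float)
        d = np.column_stack([base.ravel(), *(0.0 + noise.T), base.ravel()])
        geno = make_geno(d)
        p = [1e-5, 0.2, 0.3, 0.01, 0.4, 0.02, 1e-3]
        ss = make_sumstats([0.1] * 7, p)
        kept = set(clump(ss, geno, r2_max=0.2).table["vid"])
        perm = ss.table.sample(frac=1, random_state=1).reset_index(drop=True)
        from hybridprs.types import SummaryStats

        kept_perm = set(clump(SummaryStats(perm), geno, r2_max=0.2).table["vid"])
        assert kept == kept_perm


class TestComputePrs:
    def test_single_marker_hard_call(self):
        geno = make_geno([[2.0]])
        mk = select_markers(make_sumstats([0.5], [0.01]), 1.0)
        assert compute_prs(mk, geno).scores.iloc[0] == pytest.approx(1.0)

    def test_two_term_sum_with_signs(self):
        geno = make_geno([[1.0, 2.0]])
        mk = select_markers(make_sumstats([0.5, -1.0], [0.01, 0.01]), 1.0)
        assert compute_prs(mk, geno).scores.iloc[0] == pytest.approx(-1.5)

    def test_probabilistic_genotype_uses_expectation(self):
        mk = select_markers(make_sumstats([1.0], [0.01]), 1.0)
        dist = GenotypeDistribution(
            samples=["s0"], vids=["v0"], probs=np.array([[[0.25, 0.5, 0.25]]])
        )
        assert compute_prs(mk, dist).scores.iloc[0] == pytest.approx(1.0)

    def test_missing_policy_drop_skips_marker(self):
        geno = make_geno([[np.nan, 2.0], [1.0, 0.0]])
        mk = select_markers(make_sumstats([1.0, 1.0], [0.01, 0.01]), 1.0)
        res = compute_prs(mk, geno, missing_policy="drop")
        assert res.scores["s0"] == pytest.approx(2.0)
        assert res.n_markers["s0"] == 1 and res.n_markers["s1"] == 2

    def test_missing_policy_mean_imputes_panel_mean(self):
        geno = make_geno([[np.nan], [1.0], [2.0]])
        mk = select_markers(make_sumstats([1.0], [0.01]), 1.0)
        res = compute_prs(mk, geno, missing_policy="mean")
        assert res.scores["s0"] == pytest.approx(1.5)  # mean of 1 and 2

    def test_all_markers_missing_scores_nan_not_zero(self):
        geno = make_geno([[np.nan, np.nan], [1.0, 2.0]])
        mk = select_markers(make_sumstats([1.0, 1.0], [0.01, 0.01]), 1.0)
        res = compute_prs(mk, geno, missing_policy="drop")
        assert np.isnan(res.scores["s0"]) and res.n_markers["s0"] == 0
        # mean policy can still impute from the rest of the panel
        res = compute_prs(mk, geno, missing_policy="mean")
        assert res.scores["s0"] == pytest.approx(3.0)
        # ... but not when the marker is missing panel-wide
        geno2 = make_geno([[np.nan], [np.nan]])
        mk2 = select_markers(make_sumstats([1.0], [0.01]), 1.0)
        res2 = compute_prs(mk2, geno2, missing_policy="mean")
        assert res2.scores.isna().all()

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_linearity_in_the_genotype_distribution(self, seed):
        """PRS of a mixture distribution is the mixture of PRSs."""
        rng = np.random.default_rng(seed)
        n, m = 4, 3
        betas = rng.normal(size=m)
        mk = select_markers(make_sumstats(betas.tolist(), [0.01] * m), 1.0)

        def rand_dist():
            w = rng.dirichlet(np.ones(3), size=(n, m))
            return GenotypeDistribution(
                samples=[f"s{i}" for i in range(n)], vids=[f"v{i}" for i in range(m)],
                probs=w,
            )

        d1, d2 = rand_dist(), rand_dist()
        lam = rng.random()
        mix = GenotypeDistribution(
            samples=d1.samples, vids=d1.vids,
            probs=lam * d1.probs + (1 - lam) * d2.probs,
        )
        s1 = compute_prs(mk, d1).scores
        s2 = compute_prs(mk, d2).scores
        sm = compute_prs(mk, mix).scores
        assert np.allclose(sm, lam * s1 + (1 - lam) * s2)

    def test_pt_one_equals_scoring_all_markers(self, small_study):
        ss, geno = small_study["sumstats"], small_study["geno"]
        all_mk = select_markers(ss, 1.0)
        scores = compute_prs(all_mk, geno).scores
        manual = np.nan_to_num(geno.take_variants(
            pd.Index(geno.variants["vid"]).get_indexer(all_mk.vids)
        ).dosage) @ all_mk.betas
        # panel has no missing calls, so manual dot product matches
        assert np.allclose(scores.to_numpy(), manual)


class TestMafFilter:
    def test_low_maf_variants_dropped(self):
        # v0: af 0.25 (maf 0.25, dropped); v1: af 0.5 (kept)
        d = np.array([[0, 0], [0, 1], [0, 1], [2, 2]], dtype=float)
        out = filter_maf(make_geno(d), min_maf=0.3)
        assert out.variants["vid"].tolist() == ["v1"]


class TestPve:
    def test_zero_beta_zero_pve(self):
        assert compute_pve(0.0, 0.1, 100, 0.3) == 0.0

    def test_unit_case_is_half(self):
        for f in (0.1, 0.3, 0.5):
            assert compute_pve(1.0, 1.0, 1, f) == pytest.approx(0.5)

    def test_vanishing_se_limit_is_one(self):
        assert compute_pve(1.0, 1e-12, 1000, 0.3) == pytest.approx(1.0)

    def test_monotone_in_beta_and_se(self):
        lo = compute_pve(0.5, 0.2, 100, 0.3)
        hi = compute_pve(1.0, 0.2, 100, 0.3)
        assert hi > lo
        assert compute_pve(0.5, 0.4, 100, 0.3) < lo

    def test_bounded_in_unit_interval(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            v = compute_pve(rng.normal(), rng.uniform(0.01, 2),
                            rng.integers(2, 5000), rng.uniform(0.01, 0.99))
            assert 0 <= v <= 1

    def test_missing_inputs_instruct_caller(self):
        with pytest.raises(ValueError, match="n"):
            compute_pve(0.5, 0.1, np.nan, 0.3)
        with pytest.raises(ValueError, match="af"):
            compute_pve(0.5, 0.1, 100, np.nan)

    def test_set_pve_approximates_h2_on_independent_causals(self):
        """Sum of per-marker PVE over the true causal set tracks realized
        heritability when causal loci are independent."""
        from hybridprs import SimConfig, ols_scan, simulate_genotypes, simulate_phenotypes

        cfg = SimConfig(n_samples=1500, n_variants=60, n_causal=12, h2=0.5,
                        inbreeding=0.9, seed=23)
        geno = simulate_genotypes(cfg)
        pheno, truth = simulate_phenotypes(geno, cfg)
        ss = ols_scan(geno, pheno)
        causal_vids = set(truth[truth != 0].index)
        sub = ss.table[ss.table["vid"].isin(causal_vids)]
        mk = RiskMarkerSet(markers=sub, pt=1.0)
        g = np.nan_to_num(geno.dosage) @ truth.to_numpy()
        realized_h2 = g.var() / pheno.var()
        assert compute_set_pve(mk) == pytest.approx(realized_h2, abs=0.12)
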