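"""Expression filtering, normalization, cis-pair enumeration, the OLS
association model, BH adjustment and the consolidation/summary steps."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tipselect.eqtl import (
    bh_adjust,
    compare_variance_explained,
    consolidate_replicates,
    effect_size_frequency_profile,
    enumerate_cis_pairs,
    filter_expressed_genes,
    fit_linear_association,
    normalize_counts,
    run_eqtl_scan,
    shared_associations,
    size_factors,
)


class TestExpressionFilter:
    def test_strict_ten_percent(self):
        counts = pd.DataFrame(
            np.zeros((3, 100)), index=["g10", "g11", "g0"],
            columns=[f"s{i}" for i in range(100)],
        )
        counts.iloc[0, :10] = 5  # exactly 10% -> dropped
        counts.iloc[1, :11] = 5  # 11% -> kept
        out = filter_expressed_genes(counts)
        assert list(out.index) == ["g11"]

    def test_negative_counts_rejected(self):
        counts = pd.DataFrame([[-1, 2]], index=["g"], columns=["a", "b"])
        with pytest.raises(ValueError):
            filter_expressed_genes(counts)


class TestNormalization:
    def test_identical_samples_unit_factors(self):
        counts = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30]})
        sf = size_factors(counts)
        np.testing.assert_allclose(sf, [1.0, 1.0])
        norm = normalize_counts(counts)
        np.testing.assert_allclose(norm["a"], norm["b"])

    def test_doubled_library_equalized(self):
        a = np.array([10.0, 25.0, 40.0, 100.0, 7.0])
        counts = pd.DataFrame({"a": a, "b": 2 * a})
        sf = size_factors(counts)
        assert sf["b"] / sf["a"] == pytest.approx(2.0)
        norm = normalize_counts(counts)
        np.testing.assert_allclose(norm["a"], norm["b"], rtol=1e-12)

    def test_monotone_within_sample(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.integers(0, 500, size=(50, 3)).astype(float))
        norm = normalize_counts(counts)
        for c in counts:
            order = counts[c].argsort().to_numpy()
            assert (np.diff(norm[c].to_numpy()[order]) >= 0).all()

    def test_fallback_to_library_size(self):
        counts = pd.DataFrame({"a": [0, 5], "b": [5, 0]}, dtype=float)
        with pytest.warns(UserWarning, match="library-size"):
            sf = size_factors(counts)
        np.testing.assert_allclose(sf, [1.0, 1.0])


class TestCisPairs:
    GENES = pd.DataFrame({
        "id": ["g1"], "chrom": ["chr1"], "start": [10_000], "end": [12_000],
        "strand": ["+"],
    })

    def _pairs(self, positions):
        markers = pd.DataFrame({
            "id": [f"m{i}" for i in range(len(positions))],
            "chrom": "chr1", "pos": positions,
        })
        return enumerate_cis_pairs(self.GENES, markers, window=5000)

    def test_outer_boundaries(self):
        # exactly 5000 bp before start: excluded; 4999 bp past the last
        # gene base: included with distance +4999
        pairs = self._pairs([5_000, 5_001, 12_000 + 4_998, 12_000 + 4_999])
        got = dict(zip(pairs["marker"], pairs["distance"]))
        assert "m0" not in got
        assert got["m1"] == -4_999
        assert got["m2"] == 4_999
        assert "m3" not in got

    def test_inside_gene_distance_zero(self):
        pairs = self._pairs([10_000, 11_999])
        assert pairs["distance"].tolist() == [0, 0]

    def test_strand_flips_sign(self):
        genes = self.GENES.assign(strand="-")
        markers = pd.DataFrame({"id": ["m"], "chrom": "chr1", "pos": [9_000]})
        pair = enumerate_cis_pairs(genes, markers, window=5000)
        # left of a minus-strand gene is downstream -> positive distance
        assert pair["distance"].iloc[0] == 1_000

    def test_other_chromosome_ignored(self):
        markers = pd.DataFrame({"id": ["m"], "chrom": "chr2", "pos": [11_000]})
        assert enumerate_cis_pairs(self.GENES, markers).empty


class TestLinearAssociation:
    def test_exact_recovery_noiseless(self):
        rng = np.random.default_rng(1)
        g = rng.integers(0, 2, 80).astype(float)
        y = 2.0 * g + 1e-12 * rng.normal(size=80)
        res = fit_linear_association(y, g)
        assert res["beta"] == pytest.approx(2.0, abs=1e-6)
        assert res["p"] < 1e-30
        assert res["r2"] > 0.999

    def test_matches_normal_equations_oracle(self):
        """Residualized slope equals a brute-force full-design OLS solve on
        random small designs."""
        rng = np.random.default_rng(2)
        for _ in range(20):
            n = int(rng.integers(12, 40))
            n_cov = int(rng.integers(0, 3))
            g = rng.integers(0, 2, n).astype(float)
            while np.ptp(g) == 0:
                g = rng.integers(0, 2, n).astype(float)
            covars = rng.normal(size=(n, n_cov)) if n_cov else None
            y = rng.normal(size=n)
            res = fit_linear_association(y, g, covars)
            x = np.column_stack(
                [np.ones(n)] + ([covars] if n_cov else []) + [g])
            coef, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
            resid = y - x @ coef
            dof = n - x.shape[1]
            sigma2 = resid @ resid / dof
            cov_beta = sigma2 * np.linalg.inv(x.T @ x)
            se = np.sqrt(cov_beta[-1, -1])
            t = coef[-1] / se
            p = 2 * stats.t.sf(abs(t), dof)
            assert res["beta"] == pytest.approx(coef[-1], rel=1e-8, abs=1e-10)
            assert res["se"] == pytest.approx(se, rel=1e-8)
            assert res["p"] == pytest.approx(p, rel=1e-6, abs=1e-12)

    def test_null_p_uniform(self):
        rng = np.random.default_rng(3)
        n = 30
        pvals = [
            fit_linear_association(rng.normal(size=n),
                                   rng.integers(0, 2, n).astype(float))["p"]
            for _ in range(1000)
        ]
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_subpopulation_confounding_removed(self):
        """A marker correlated with subpopulation shows a spurious effect
        without the covariate and none with it."""
        rng = np.random.default_rng(4)
        n = 200
        subpop = (np.arange(n) < n // 2).astype(float)
        g = np.where(rng.random(n) < 0.8, subpop, 1 - subpop)
        y = 1.5 * subpop + rng.normal(size=n)
        biased = fit_linear_association(y, g)
        adjusted = fit_linear_association(y, g, covariates=subpop[:, None])
        assert biased["p"] < 1e-4  # spurious association without covariate
        assert adjusted["p"] > 0.01  # gone once subpopulation is included
        assert abs(adjusted["beta"]) < abs(biased["beta"])

    def test_constant_marker_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fit_linear_association(np.ones(10), np.ones(10))


class TestBH:
    def test_hand_example(self):
        q = bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_identity(self):
        assert bh_adjust(np.array([0.3]))[0] == pytest.approx(0.3)

    def test_monotone_in_sorted_order(self):
        rng = np.random.default_rng(5)
        p = rng.random(100)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_matches_stepup_oracle_small_m(self):
        """Direct enumeration of the step-up definition for m <= 10, and
        agreement with the statsmodels implementation."""
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(6)
        for _ in range(50):
            m = int(rng.integers(1, 11))
            p = np.round(rng.random(m), 3)
            q = bh_adjust(p)
            # oracle: q_i = min over j with p_j >= p_i of m * p_j / rank_j
            order = np.argsort(p, kind="mergesort")
            sp = p[order]
            oracle_sorted = [
                min(m * sp[j] / (j + 1) for j in range(i, m))
                for i in range(m)
            ]
            oracle = np.empty(m)
            oracle[order] = np.minimum(oracle_sorted, 1.0)
            np.testing.assert_allclose(q, oracle, rtol=1e-12)
            np.testing.assert_allclose(
                q, multipletests(p, method="fdr_bh")[1], rtol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.5, 1.2]))


def _toy_results(rows):
    cols = ["gene", "marker", "distance", "beta", "se", "t", "p", "r2", "q",
            "condition", "replicate", "population", "marker_type"]
    return pd.DataFrame(rows, columns=cols)


class TestConsolidation:
    def _row(self, gene="g", marker="m", q=0.01, beta=1.0, rep=1, dist=100,
             cond="wet", p=None):
        return [gene, marker, dist, beta, 0.1, beta / 0.1,
                p if p is not None else q / 2, 0.2, q, cond, rep, "pop1", "TIP"]

    def test_hit_rule_any_replicate(self):
        res = _toy_results([
            self._row(q=0.04, rep=1), self._row(q=0.2, rep=2),
            self._row(q=0.3, rep=3),
        ])
        hits = consolidate_replicates(res)
        assert len(hits) == 1
        assert hits["min_q"].iloc[0] == pytest.approx(0.04)

    def test_no_hit_when_all_above(self):
        res = _toy_results([self._row(q=0.06, rep=r) for r in (1, 2, 3)])
        assert consolidate_replicates(res).empty

    def test_leading_marker_min_q_then_distance(self):
        res = _toy_results([
            self._row(marker="m1", q=0.01, dist=500),
            self._row(marker="m2", q=0.02, dist=10),
            self._row(marker="m3", q=0.01, dist=100),
        ])
        hits = consolidate_replicates(res)
        lead = hits.loc[hits["leading"], "marker"].iloc[0]
        assert lead == "m3"  # ties on q broken by smaller |distance|

    def test_sign_conflict_flagged(self):
        res = _toy_results([
            self._row(q=0.01, beta=1.0, rep=1),
            self._row(q=0.02, beta=-1.0, rep=2),
        ])
        hits = consolidate_replicates(res)
        assert bool(hits["sign_conflict"].iloc[0])


class TestVarianceComparison:
    def _hits(self, rows):
        return pd.DataFrame(
            rows, columns=["gene", "marker", "condition", "population",
                           "marker_type", "min_q", "p_best", "beta", "r2",
                           "sign", "distance", "sign_conflict", "leading"])

    def test_categories(self):
        tip = self._hits([
            ["g1", "t1", "wet", "pop1", "TIP", 0.01, 0.001, 1, 0.5, 1, 0,
             False, True],
            ["g2", "t2", "wet", "pop1", "TIP", 0.01, 0.001, 1, 0.3, 1, 0,
             False, True],
        ])
        snp = self._hits([
            ["g2", "s1", "wet", "pop1", "SNP", 0.01, 0.001, 1, 0.4, 1, 0,
             False, True],
        ])
        out = compare_variance_explained(tip, snp)
        cats = dict(zip(out["gene"], out["category"]))
        assert cats == {"g1": "TIP_only", "g2": "SNP_ge_TIP"}


class TestSharing:
    def test_identical_scans_fully_shared(self):
        res = _toy_results([
            ["g", "m", 0, 1.0, 0.1, 10, 0.001, 0.5, 0.01, "wet", 1, "pop1",
             "TIP"],
        ])
        hits = consolidate_replicates(res)
        out = shared_associations(hits, res)
        assert out.attrs["shared_fraction"] == 1.0

    def test_opposite_sign_not_shared(self):
        res_a = _toy_results([
            ["g", "m", 0, 1.0, 0.1, 10, 0.001, 0.5, 0.01, "wet", 1, "pop1",
             "TIP"],
        ])
        res_b = res_a.assign(beta=-1.0)
        hits = consolidate_replicates(res_a)
        out = shared_associations(hits, res_b)
        assert out.attrs["shared_fraction"] == 0.0


class TestEffectFrequencyProfile:
    def _hits(self, markers, betas):
        return pd.DataFrame({
            "marker": markers, "beta": betas,
        })

    def test_single_bin(self):
        hits = self._hits(["m1", "m2"], [1.0, 1.0])
        freqs = pd.Series({"m1": 0.5, "m2": 0.51})
        prof = effect_size_frequency_profile(hits, freqs)
        row = prof[(prof["sign"] == "positive") & (prof["n"] > 0)]
        assert len(row) == 1
        assert row["mean_beta"].iloc[0] == pytest.approx(1.0)
        assert row["bin_low"].iloc[0] == pytest.approx(0.5)

    def test_bins_partition_unit_interval(self):
        hits = self._hits(["m"], [0.5])
        prof = effect_size_frequency_profile(hits, pd.Series({"m": 0.2}))
        pos = prof[prof["sign"] == "positive"]
        assert pos["bin_low"].iloc[0] == 0.0
        assert pos["bin_high"].iloc[-1] == 1.0
        np.testing.assert_allclose(pos["bin_low"].iloc[1:],
                                   pos["bin_high"].iloc[:-1])

    def test_rare_variant_u_shape(self):
        rng = np.random.default_rng(7)
        freqs = rng.uniform(0.02, 0.98, 300)
        maf = np.minimum(freqs, 1 - freqs)
        betas = 0.2 / maf  # planted rare-variant architecture
        hits = self._hits([f"m{i}" for i in range(300)], betas)
        prof = effect_size_frequency_profile(
            hits, pd.Series(freqs, index=hits["marker"]))
        pos = prof[(prof["sign"] == "positive") & (prof["n"] > 0)]
        edge = pos[(pos["bin_low"] < 0.1) | (pos["bin_high"] > 0.9)]
        mid = pos[(pos["bin_low"] >= 0.4) & (pos["bin_high"] <= 0.6)]
        assert edge["mean_beta"].mean() > 2 * mid["mean_beta"].mean()


class TestScan:
    def _cohort(self, seed, beta=0.0):
        from tipselect.simulate import SimulationConfig, generate_cohort

        cfg = SimulationConfig(
            n_pop1=40, n_pop2=4, n_pop3=2, n_tips=60, n_snps=30, n_genes=30,
            n_eqtl_tips=10 if beta else 0, n_selected_tips=1,
            beta_range=(beta, beta) if beta else (0.5, 1.5),
            missing_frac=0.0, n_sweep_loci=1, sweep_region_snps=60, seed=seed,
        )
        return generate_cohort(cfg), cfg

    def test_deterministic_and_order_invariant(self):
        cohort, _ = self._cohort(21, beta=1.0)
        from tipselect.tip_matrix import filter_maf_missing

        markers = filter_maf_missing(cohort.genotypes, preset="eqtl")
        args = (cohort.counts, markers, cohort.metadata, cohort.genes)
        a = run_eqtl_scan(*args, population="pop1")
        b = run_eqtl_scan(*args, population="pop1")
        pd.testing.assert_frame_equal(a, b)
        # permute gene and marker order: same set of (pair, p) results
        genes_shuf = cohort.genes.sample(frac=1, random_state=0)
        order = np.random.default_rng(0).permutation(markers.n_loci)
        markers_shuf = type(markers)(
            markers.loci.iloc[order].reset_index(drop=True),
            markers.samples, markers.calls[order])
        c = run_eqtl_scan(cohort.counts, markers_shuf, cohort.metadata,
                          genes_shuf, population="pop1")
        key = ["gene", "marker", "condition", "replicate"]
        merged = a.merge(c, on=key, suffixes=("_a", "_c"))
        assert len(merged) == len(a)
        np.testing.assert_allclose(merged["p_a"], merged["p_c"], rtol=1e-10)
        np.testing.assert_allclose(merged["q_a"], merged["q_c"], rtol=1e-10)

    def test_mismatched_samples_rejected(self):
        cohort, _ = self._cohort(22)
        from tipselect.tip_matrix import filter_maf_missing

        markers = filter_maf_missing(cohort.genotypes, preset="eqtl")
        broken = cohort.metadata.copy()
        broken.loc[broken.index[0], "sample"] = "not_a_library"
        with pytest.raises(ValueError, match="absent from counts"):
            run_eqtl_scan(cohort.counts, markers, broken, cohort.genes,
                          population="pop1")
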