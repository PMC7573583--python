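"""Expression normalization, leave-one-donor-out consistency, PLSR and
gene-level spatial correlation tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from connsig import (
    ExpressionPanel,
    gene_set_tests,
    generate_atlas,
    genome_wide_correlation,
    loo_consistency,
    normalize_expression,
    plsr_association,
    plsr_per_region,
    regional_response,
)
from connsig.connectome import matrixize, n_pairs, vectorize
from connsig.exceptions import (
    ConfigurationError,
    DegenerateDataError,
    SampleSizeError,
    SchemaError,
)
from connsig.expression import scaled_robust_sigmoid


def make_samples(profiles_by_donor, n_regions, gene_names=None):
    """Sample table with one sample per region per donor."""
    rows, counter = [], 0
    n_genes = next(iter(profiles_by_donor.values())).shape[1]
    genes = gene_names or [f"g{k}" for k in range(n_genes)]
    for donor, profile in profiles_by_donor.items():
        for region in range(n_regions):
            rows.append(
                {
                    "donor_id": donor,
                    "sample_id": f"s{counter}",
                    "region_id": region,
                    **dict(zip(genes, profile[region])),
                }
            )
            counter += 1
    return pd.DataFrame(rows)


class TestScaledRobustSigmoid:
    def test_matches_formula_oracle(self):
        rng = np.random.default_rng(0)
        x = rng.normal(3.0, 2.0, size=31)
        iqr = np.percentile(x, 75) - np.percentile(x, 25)
        s = 1 / (1 + np.exp(-(x - np.median(x)) / (iqr / 1.35)))
        expected = (s - s.min()) / (s.max() - s.min())
        assert np.allclose(scaled_robust_sigmoid(x), expected, atol=1e-14)

    def test_symmetric_vector_median_maps_to_half(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])  # symmetric around 3
        out = scaled_robust_sigmoid(x)
        assert out[2] == pytest.approx(0.5)

    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=20)
        assert np.allclose(
            scaled_robust_sigmoid(x), scaled_robust_sigmoid(10.0 + 4.0 * x), atol=1e-12
        )

    def test_zero_iqr_named(self):
        with pytest.raises(DegenerateDataError, match="flatgene"):
            scaled_robust_sigmoid(np.ones(5), name="flatgene")


class TestNormalizeExpression:
    def test_single_donor_equals_stage2(self):
        n_regions, n_genes = 6, 5
        atlas = generate_atlas(n_regions, 2, 0)
        rng = np.random.default_rng(2)
        profile = rng.normal(size=(n_regions, n_genes))
        samples = make_samples({"d0": profile}, n_regions)
        panel = normalize_expression(samples, atlas)
        # oracle: stage 1 across genes per sample, stage 2 across samples per gene
        stage1 = np.stack([scaled_robust_sigmoid(row) for row in profile])
        stage2 = np.column_stack(
            [scaled_robust_sigmoid(stage1[:, g]) for g in range(n_genes)]
        )
        assert np.allclose(panel.X, stage2, atol=1e-12)

    def test_identical_donors_collapse(self):
        n_regions = 5
        atlas = generate_atlas(n_regions, 1, 0)
        rng = np.random.default_rng(3)
        profile = rng.normal(size=(n_regions, 4))
        single = normalize_expression(make_samples({"d0": profile}, n_regions), atlas)
        double = normalize_expression(
            make_samples({"d0": profile, "d1": profile}, n_regions), atlas
        )
        assert np.allclose(single.X, double.X, atol=1e-12)

    def test_per_sample_affine_rescaling_invariance(self):
        n_regions = 6
        atlas = generate_atlas(n_regions, 2, 0)
        rng = np.random.default_rng(4)
        profile = rng.normal(size=(n_regions, 8))
        base = normalize_expression(make_samples({"d0": profile}, n_regions), atlas)
        scales = rng.uniform(0.5, 3.0, size=n_regions)[:, None]
        shifts = rng.normal(size=n_regions)[:, None]
        rescaled = normalize_expression(
            make_samples({"d0": profile * scales + shifts}, n_regions), atlas
        )
        assert np.allclose(base.X, rescaled.X, atol=1e-10)

    def test_uncovered_regions_flagged_missing(self):
        atlas = generate_atlas(6, 2, 0)
        rng = np.random.default_rng(5)
        samples = make_samples({"d0": rng.normal(size=(4, 5))}, 4)  # regions 0..3 only
        panel = normalize_expression(samples, atlas)
        assert panel.regions_covered == {0, 1, 2, 3}
        assert np.all(np.isnan(panel.X[4:]))

    def test_unknown_region_rejected(self):
        atlas = generate_atlas(3, 1, 0)
        samples = make_samples({"d0": np.random.default_rng(6).normal(size=(4, 5))}, 4)
        with pytest.raises(SchemaError):
            normalize_expression(samples, atlas)


class TestLooConsistency:
    @staticmethod
    def _donor_samples(n_donors, shared, noise_sd, rng, n_regions):
        donors = {
            f"d{k}": shared + rng.normal(0, noise_sd, size=shared.shape)
            for k in range(n_donors)
        }
        return make_samples(donors, n_regions)

    def test_identical_donors_give_one(self):
        n_regions = 8
        atlas = generate_atlas(n_regions, 2, 0)
        rng = np.random.default_rng(7)
        shared = rng.normal(size=(n_regions, 10))
        samples = make_samples({f"d{k}": shared for k in range(4)}, n_regions)
        assert loo_consistency(samples, atlas) == pytest.approx(1.0)

    def test_shared_structure_with_small_noise(self):
        n_regions = 16
        atlas = generate_atlas(n_regions, 4, 0)
        rng = np.random.default_rng(8)
        shared = rng.normal(size=(n_regions, 30))
        samples = self._donor_samples(6, shared, 0.05 * shared.std(), rng, n_regions)
        assert loo_consistency(samples, atlas) > 0.9

    def test_independent_donors_lower_than_structured(self):
        # leave-one-out panels share donors, so even independent donors do
        # not reach zero; they must sit clearly below the structured case
        n_regions = 16
        atlas = generate_atlas(n_regions, 4, 0)
        rng = np.random.default_rng(9)
        shared = rng.normal(size=(n_regions, 30))
        structured = loo_consistency(
            self._donor_samples(6, shared, 0.05 * shared.std(), rng, n_regions), atlas
        )
        independent = loo_consistency(
            self._donor_samples(6, 0.0 * shared, 1.0, rng, n_regions), atlas
        )
        assert independent < structured - 0.1

    def test_requires_three_donors(self):
        atlas = generate_atlas(4, 1, 0)
        rng = np.random.default_rng(10)
        samples = make_samples(
            {"d0": rng.normal(size=(4, 5)), "d1": rng.normal(size=(4, 5))}, 4
        )
        with pytest.raises(SampleSizeError):
            loo_consistency(samples, atlas)


class TestRegionalResponse:
    def test_constant_map(self):
        beta = np.full(n_pairs(5), 2.5)
        assert np.allclose(regional_response(beta), 2.5)

    def test_three_region_toy_row_means(self):
        mat = np.array([[1.0, 2.0, 3.0], [2.0, 4.0, 5.0], [3.0, 5.0, 6.0]])
        response = regional_response(vectorize(mat))
        assert np.allclose(response, [2.0, 11 / 3, 14 / 3])


def make_panel(X, genes=None):
    genes = genes or [f"g{k}" for k in range(X.shape[1])]
    return ExpressionPanel(X=np.asarray(X, dtype=float), genes=genes)


def orthogonal_predictors(rng, n, g):
    """Centered predictors with orthogonal columns: with these, k PLS
    components span exactly a k-gene response (Krylov property)."""
    X = rng.normal(size=(n, g))
    X -= X.mean(axis=0)
    q, _ = np.linalg.qr(X)
    return q - q.mean(axis=0)


class TestPLSR:
    def test_exact_linear_span_two_components(self):
        rng = np.random.default_rng(11)
        X = orthogonal_predictors(rng, 20, 6)
        y = X[:, 0] + X[:, 3]
        nulls = rng.normal(size=(10, 20))
        res = plsr_association(make_panel(X), y, k=2, null_y=nulls)
        assert res.r2_response >= 0.999

    def test_single_gene_one_component(self):
        rng = np.random.default_rng(12)
        X = orthogonal_predictors(rng, 15, 4)
        res = plsr_association(
            make_panel(X), 3.0 * X[:, 2], k=1, null_y=rng.normal(size=(5, 15))
        )
        assert res.r2_response >= 0.999

    def test_full_rank_fits_noiseless_linear_response(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(12, 5))
        y = X @ rng.normal(size=5)
        res = plsr_association(
            make_panel(X), y, k=5, null_y=rng.normal(size=(5, 12))
        )
        assert res.r2_response >= 1 - 1e-6

    def test_r2_non_decreasing_in_k(self):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(30, 8))
        y = X @ rng.normal(size=8) + rng.normal(size=30)
        nulls = rng.normal(size=(5, 30))
        r2 = [
            plsr_association(make_panel(X), y, k=k, null_y=nulls).r2_response
            for k in range(1, 7)
        ]
        assert all(b >= a - 1e-10 for a, b in zip(r2, r2[1:]))

    def test_k_too_large_and_too_few_nulls(self):
        rng = np.random.default_rng(15)
        X = rng.normal(size=(10, 3))
        y = rng.normal(size=10)
        with pytest.raises(ValueError):
            plsr_association(make_panel(X), y, k=4, null_y=rng.normal(size=(5, 10)))
        with pytest.raises(ConfigurationError):
            plsr_association(make_panel(X), y, k=2, null_y=rng.normal(size=(2, 10)))

    def test_missing_regions_dropped_pairwise(self):
        rng = np.random.default_rng(16)
        X = rng.normal(size=(12, 4))
        y = X @ rng.normal(size=4)
        X[5] = np.nan
        res = plsr_association(make_panel(X), y, k=4, null_y=rng.normal(size=(5, 12)))
        assert res.r2_response >= 0.999

    def test_per_region_variant_counts_and_fdr(self):
        rng = np.random.default_rng(17)
        r = 8
        panel = make_panel(rng.normal(size=(r, 5)))
        beta = rng.normal(size=n_pairs(r))
        nulls = rng.normal(size=(30, n_pairs(r)))
        out = plsr_per_region(panel, beta, k=2, null_signatures=nulls)
        assert len(out) == r
        assert (out["q"] >= out["p_perm"] - 1e-12).all()


class TestGenomeWideCorrelation:
    def test_exact_extremes_and_percentiles(self):
        rng = np.random.default_rng(18)
        y = rng.normal(size=20)
        yc = (y - y.mean()) / np.linalg.norm(y - y.mean())
        e = rng.normal(size=20)
        e -= e.mean()
        e -= (e @ yc) * yc
        e /= np.linalg.norm(e)
        cols = {
            "r_plus1": yc,
            "r_half": 0.5 * yc + np.sqrt(0.75) * e,
            "r_zero": e,
            "r_minus_half": -0.5 * yc + np.sqrt(0.75) * e,
            "r_minus1": -yc,
        }
        panel = make_panel(np.column_stack(list(cols.values())), list(cols))
        out = genome_wide_correlation(panel, y, null_y=rng.normal(size=(9, 20)))
        by_gene = {c.gene: c for c in out}
        for name, want_r, want_pct in [
            ("r_plus1", 1.0, 100.0),
            ("r_half", 0.5, 75.0),
            ("r_zero", 0.0, 50.0),
            ("r_minus_half", -0.5, 25.0),
            ("r_minus1", -1.0, 0.0),
        ]:
            assert by_gene[name].r == pytest.approx(want_r, abs=1e-10)
            assert by_gene[name].percentile == pytest.approx(want_pct)

    def test_zero_variance_gene_skipped(self):
        rng = np.random.default_rng(19)
        X = rng.normal(size=(10, 3))
        X[:, 1] = 5.0
        with pytest.warns(UserWarning, match="g1"):
            out = genome_wide_correlation(
                make_panel(X), rng.normal(size=10), null_y=rng.normal(size=(5, 10))
            )
        assert [c.gene for c in out] == ["g0", "g2"]

    @given(seed=st.integers(0, 200))
    @settings(max_examples=20, deadline=None)
    def test_percentiles_permutation_invariant(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(12, 6))
        y = rng.normal(size=12)
        nulls = rng.normal(size=(5, 12))
        base = genome_wide_correlation(make_panel(X), y, nulls)
        perm = rng.permutation(6)
        shuffled = genome_wide_correlation(
            make_panel(X[:, perm], [f"g{k}" for k in perm]), y, nulls
        )
        assert {c.gene: c.percentile for c in base} == {
            c.gene: c.percentile for c in shuffled
        }


class TestGeneSetTests:
    @staticmethod
    def _correlations(rng, y, n_signal, n_decoys, sigma):
        from connsig.expression import GeneCorrelation

        ys = (y - y.mean()) / y.std()
        cols = [ys + rng.normal(0, sigma, size=y.size) for _ in range(n_signal)]
        cols += [rng.normal(size=y.size) for _ in range(n_decoys)]
        names = [f"sig{k}" for k in range(n_signal)] + [
            f"dec{k}" for k in range(n_decoys)
        ]
        panel = make_panel(np.column_stack(cols), names)
        return genome_wide_correlation(panel, y, null_y=rng.normal(size=(5, y.size)))

    def test_top_genes_significant(self):
        rng = np.random.default_rng(20)
        corr = self._correlations(rng, rng.normal(size=64), 10, 200, sigma=0.3)
        top = sorted(corr, key=lambda c: -c.r)[:10]
        p_median, p_top = gene_set_tests(
            [c.gene for c in top], corr, n_random=1000, seed=1
        )
        assert p_median <= 0.05
        assert p_top <= 0.05

    def test_signal_set_recovered_by_percentile_test(self):
        rng = np.random.default_rng(21)
        corr = self._correlations(rng, rng.normal(size=64), 10, 200, sigma=0.5)
        _, p_top = gene_set_tests(
            [f"sig{k}" for k in range(10)], corr, n_random=1000, seed=2
        )
        assert p_top <= 0.05

    def test_degenerate_full_set(self):
        rng = np.random.default_rng(22)
        corr = self._correlations(rng, rng.normal(size=30), 0, 50, sigma=1.0)
        p_median, _ = gene_set_tests(
            [c.gene for c in corr], corr, n_random=200, seed=3
        )
        assert p_median >= 0.5

    def test_random_set_p_roughly_uniform(self):
        rng = np.random.default_rng(23)
        corr = self._correlations(rng, rng.normal(size=30), 0, 120, sigma=1.0)
        genes = [c.gene for c in corr]
        pvals = [
            gene_set_tests(
                list(rng.choice(genes, size=12, replace=False)),
                corr,
                n_random=200,
                seed=int(rng.integers(1 << 30)),
            )[0]
            for _ in range(100)
        ]
        from scipy import stats as sps

        assert sps.kstest(pvals, "uniform").pvalue > 0.01

    def test_errors(self):
        rng = np.random.default_rng(24)
        corr = self._correlations(rng, rng.normal(size=20), 0, 10, sigma=1.0)
        with pytest.raises(ConfigurationError):
            gene_set_tests(["nonexistent"], corr, n_random=200, seed=0)
        with pytest.raises(ConfigurationError):
            gene_set_tests([c.gene for c in corr], corr, n_random=10, seed=0)
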