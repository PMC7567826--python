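import math

import numpy as np
import pytest

from cpelhap import (
    CpelML,
    CpelModel,
    NpdML,
    NpiML,
    ObservedRead,
    SaConfig,
    aic_small_sample,
    akaike_weight,
    jsd,
)
from cpelhap.testing import null_region_layout


def full_reads(matrix):
    return [ObservedRead(allele=1, obs=row) for row in np.asarray(matrix, dtype=np.int8)]


class TestCpelFit:
    def test_recovers_parameters_from_many_full_reads(self):
        layout = null_region_layout(8, 1)
        truth = CpelModel(layout, (1.0,), 0.0)
        reads = truth.sample_reads(1000, rng=42)
        fit = CpelML(reads, layout).fit(SaConfig.fast(rng_seed=0))
        assert fit.params["alpha"][0] == pytest.approx(1.0, abs=0.2)
        assert fit.params["beta"] == pytest.approx(0.0, abs=0.15)
        assert fit.n_params == 2
        assert fit.nobs == 1000

    def test_loglik_at_estimate_not_below_truth(self):
        # the SA+polish optimum should never fall below the generating
        # parameters' likelihood (up to numerical slack)
        layout = null_region_layout(6, 2)
        rng = np.random.default_rng(5)
        ok = 0
        for rep in range(10):
            truth = CpelModel(layout, tuple(rng.uniform(-2, 2, 2)), float(rng.uniform(-1, 1)))
            reads = truth.sample_reads(15, rng=rng)
            fit = CpelML(reads, layout).fit(SaConfig.fast(rng_seed=rep))
            llf_truth = sum(truth.read_log_likelihood(r) for r in reads)
            if fit.llf >= llf_truth - 1e-6:
                ok += 1
        assert ok >= 9

    def test_separated_data_is_degenerate(self):
        # all-ones reads: the likelihood is monotone in alpha; on a single
        # site the estimate runs to the box bound (and is flagged), and in
        # general the fitted PDM collapses onto the fully methylated state
        layout1 = null_region_layout(1, 1)
        fit1 = CpelML(full_reads([[1]] * 10), layout1).fit(SaConfig.fast(rng_seed=1))
        assert fit1.params["alpha"][0] == pytest.approx(10.0, abs=1e-6)
        assert "param_at_bound" in fit1.flags

        layout4 = null_region_layout(4, 1)
        fit4 = CpelML(full_reads([[1, 1, 1, 1]] * 10), layout4).fit(
            SaConfig.fast(rng_seed=1)
        )
        assert fit4.pdm.prob_of([1, 1, 1, 1]) == pytest.approx(1.0, abs=1e-5)

    def test_deterministic_given_seed(self):
        layout = null_region_layout(5, 1)
        truth = CpelModel(layout, (0.5,), 0.3)
        reads = truth.sample_reads(10, rng=3)
        f1 = CpelML(reads, layout).fit(SaConfig.fast(rng_seed=11))
        f2 = CpelML(reads, layout).fit(SaConfig.fast(rng_seed=11))
        assert f1.params == f2.params

    def test_no_informative_reads_rejected(self):
        layout = null_region_layout(3, 1)
        empty = [ObservedRead(allele=1, obs=[-1, -1, -1])]
        with pytest.raises(ValueError, match="insufficient data"):
            CpelML(empty, layout).fit(SaConfig.fast())


class TestNpi:
    def test_two_opposite_reads_give_uniform_pdm(self):
        layout = null_region_layout(2, 1)
        fit = NpiML(full_reads([[1, 1], [0, 0]]), layout).fit()
        assert fit.params["p_site"] == [0.5, 0.5]
        np.testing.assert_allclose(fit.pdm.probs, 0.25)
        assert fit.n_params == 2

    def test_all_methylated_reads_put_mass_on_ones(self):
        layout = null_region_layout(3, 1)
        fit = NpiML(full_reads([[1, 1, 1]] * 4), layout).fit()
        assert fit.pdm.prob_of([1, 1, 1]) == pytest.approx(1.0)

    def test_zero_coverage_site_gets_half_and_flag(self):
        layout = null_region_layout(3, 1)
        reads = [ObservedRead(allele=1, obs=[1, -1, 0]),
                 ObservedRead(allele=1, obs=[1, -1, 1])]
        fit = NpiML(reads, layout).fit()
        assert fit.params["p_site"][1] == 0.5
        assert "zero_coverage_site_1" in fit.flags

    def test_ignores_correlation_structure(self):
        # under strong coupling the product model misses the joint badly
        layout = null_region_layout(4, 1)
        truth = CpelModel(layout, (0.0,), 3.0)
        rng = np.random.default_rng(17)
        wins = 0
        for rep in range(20):
            reads = truth.sample_reads(20, rng=rng)
            npi = NpiML(reads, layout).fit()
            cpel = CpelML(reads, layout).fit(SaConfig.fast(rng_seed=rep))
            if jsd(cpel.pdm, truth.pdm()) < jsd(npi.pdm, truth.pdm()):
                wins += 1
        assert wins > 10  # CPEL wins the median comparison


class TestNpd:
    def test_pattern_frequencies(self):
        layout = null_region_layout(2, 1)
        fit = NpdML(full_reads([[1, 1], [1, 1], [0, 0], [0, 0]]), layout).fit()
        assert fit.pdm.prob_of([1, 1]) == pytest.approx(0.5)
        assert fit.pdm.prob_of([0, 0]) == pytest.approx(0.5)
        assert fit.pdm.prob_of([1, 0]) == 0.0

    def test_free_parameter_count(self):
        layout = null_region_layout(4, 1)
        fit = NpdML(full_reads([[0, 1, 0, 1]]), layout).fit()
        assert fit.n_params == 15

    def test_partial_reads_are_discarded(self):
        layout = null_region_layout(2, 1)
        reads = full_reads([[1, 1]]) + [ObservedRead(allele=1, obs=[1, -1])]
        fit = NpdML(reads, layout).fit()
        assert fit.nobs == 1

    def test_requires_full_observations(self):
        layout = null_region_layout(2, 1)
        partial = [ObservedRead(allele=1, obs=[1, -1])]
        with pytest.raises(ValueError, match="full observations"):
            NpdML(partial, layout).fit()

    def test_epiallele_window_variant(self):
        layout = null_region_layout(6, 1)
        rng = np.random.default_rng(2)
        reads = full_reads(rng.integers(0, 2, size=(30, 6)))
        fit = NpdML(reads, layout).fit(window=4)
        assert fit.n_params == (2**4 - 1) + (2**2 - 1)
        assert fit.pdm.probs.sum() == pytest.approx(1.0)
        # product structure: block marginals match the blockwise empirical fits
        full = NpdML(reads, layout).fit()
        np.testing.assert_allclose(
            fit.pdm.marginalize([0, 1, 2, 3]).probs,
            full.pdm.marginalize([0, 1, 2, 3]).probs,
            atol=1e-12,
        )


class TestModelSelection:
    def test_small_sample_aic_by_direct_substitution(self):
        fit = _stub(llf=-10.0, eta=2, nobs=13)
        assert aic_small_sample(fit) == pytest.approx(20 + 4 + 12 / 10)

    def test_zero_parameters_reduces_to_deviance(self):
        assert aic_small_sample(_stub(llf=-7.5, eta=0, nobs=5)) == pytest.approx(15.0)

    def test_undefined_when_observations_too_few(self):
        assert math.isnan(aic_small_sample(_stub(llf=-1.0, eta=4, nobs=5)))

    def test_akaike_weight_anchors(self):
        assert akaike_weight(10.0, 10.0) == pytest.approx(0.5)
        assert akaike_weight(8.0, 10.0) == pytest.approx(math.e / (math.e + 1))
        assert akaike_weight(0.0, 100.0) == pytest.approx(1.0, abs=1e-9)
        assert math.isnan(akaike_weight(float("nan"), 1.0))

    def test_summary_mentions_fit_quantities(self):
        layout = null_region_layout(2, 1)
        fit = CpelML(full_reads([[1, 0], [0, 1]]), layout).fit(SaConfig.fast(rng_seed=0))
        text = fit.summary()
        assert "CPEL" in text and "Log-likelihood" in text and "beta" in text


def _stub(llf, eta, nobs):
    from cpelhap.models import AlleleFitResults
    from cpelhap import DiscretePdm

    return AlleleFitResults(
        model_kind="NPI",
        pdm=DiscretePdm.uniform(1),
        params={},
        n_params=eta,
        nobs=nobs,
        llf=llf,
    )
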