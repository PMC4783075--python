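"""Tests of the Metropolis-Hastings sampler."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy.stats import beta, kstest

from phlabayes import PriorSpec, RunConfig, propose, run_chain, run_chains
from phlabayes.sampler import reflect_unit


class TestProposal:
    @given(
        x=arrays(np.float64, 3, elements=st.floats(0, 1)),
        step=st.floats(0.001, 5.0),
        seed=st.integers(0, 10_000),
    )
    @settings(max_examples=100, derandomize=True)
    def test_proposals_stay_inside_the_hypercube(self, x, step, seed):
        rng = np.random.default_rng(seed)
        y = propose(x, step, rng)
        assert np.all((y >= 0.0) & (y <= 1.0))

    def test_zero_step_limit_returns_current(self):
        rng = np.random.default_rng(0)
        x = np.full(4, 0.5)
        assert np.array_equal(propose(x, 0.0, rng), x)

    def test_reflection_is_an_even_fold(self):
        # points just outside either wall map back symmetrically
        assert reflect_unit(np.array([-0.2, 1.2, 2.5, -1.3])) == pytest.approx(
            np.array([0.2, 0.8, 0.5, 0.7])
        )

    def test_empirical_mean_is_centred(self):
        """Reflected-Gaussian proposals from the centre stay centred: the
        reflection is symmetric about 0.5 there."""
        rng = np.random.default_rng(1)
        draws = np.array([propose(np.array([0.5]), 0.05, rng)[0] for _ in range(10_000)])
        assert draws.mean() == pytest.approx(0.5, abs=3 * 0.05 / 100)


class TestRunChain:
    def test_bit_identical_under_fixed_seed(self, toy_two_allele_cohort, uniform_prior_two):
        cfg = RunConfig(chain_length=2_000, seed=9)
        a = run_chain(toy_two_allele_cohort, "pep_1", uniform_prior_two, cfg)
        b = run_chain(toy_two_allele_cohort, "pep_1", uniform_prior_two, cfg)
        assert np.array_equal(a.samples, b.samples)
        assert a.acceptance_rate == b.acceptance_rate

    def test_burn_in_discarded_and_shapes(self, toy_two_allele_cohort, uniform_prior_two):
        cfg = RunConfig(chain_length=5_000, burn_in_fraction=0.2, seed=3)
        chain = run_chain(toy_two_allele_cohort, "pep_1", uniform_prior_two, cfg)
        assert chain.samples.shape == (4_000, 2)
        assert np.all((chain.samples >= 0) & (chain.samples <= 1))

    def test_acceptance_rate_strictly_interior(self, toy_two_allele_cohort, uniform_prior_two):
        cfg = RunConfig(chain_length=5_000, seed=4)
        chain = run_chain(toy_two_allele_cohort, "pep_1", uniform_prior_two, cfg)
        assert 0.0 < chain.acceptance_rate < 1.0

    def test_too_short_chain_rejected(self, toy_two_allele_cohort, uniform_prior_two):
        with pytest.raises(ValueError, match="at least"):
            run_chain(
                toy_two_allele_cohort, "pep_1", uniform_prior_two, RunConfig(chain_length=999)
            )

    def test_prior_mismatch_rejected(self, toy_two_allele_cohort):
        with pytest.raises(ValueError, match="prior alleles"):
            run_chain(
                toy_two_allele_cohort, "pep_1", PriorSpec.uniform(["X", "Y"]), RunConfig()
            )

    def test_empty_cohort_recovers_uniform_prior(self, empty_cohort, uniform_prior_two):
        """With no data the posterior is the prior; thinned samples pass a
        KS test against Uniform(0,1) at the 1% level."""
        cfg = RunConfig(chain_length=100_000, seed=5)
        chain = run_chain(empty_cohort, "pep_1", uniform_prior_two, cfg)
        for j in range(2):
            thinned = chain.samples[::100, j]
            assert kstest(thinned, "uniform").pvalue > 0.01

    def test_uncarried_allele_marginal_equals_its_prior(self):
        """An allele nobody carries gets no likelihood signal: its marginal
        reproduces the prior (here a Beta), checked by KS on a thinned chain."""
        import pandas as pd

        from phlabayes import CohortTable

        cohort = CohortTable(
            [f"s{i}" for i in range(10)],
            ["A", "B"],
            np.column_stack([np.ones(10, int), np.zeros(10, int)]),
            pd.DataFrame({"pep_1": [True] * 4 + [False] * 6}, dtype="boolean"),
        )
        prior = PriorSpec(("A", "B"), np.array([1.0, 2.0]), np.array([1.0, 2.0]), ("u", "b"))
        chain = run_chain(cohort, "pep_1", prior, RunConfig(chain_length=100_000, seed=6))
        thinned = chain.samples[::100, 1]
        assert kstest(thinned, beta(2, 2).cdf).pvalue > 0.01

    def test_batch_runs_match_requested_peptides(self, toy_two_allele_cohort, uniform_prior_two):
        import pandas as pd

        c = toy_two_allele_cohort
        resp = c.responses.copy()
        resp["pep_2"] = pd.array([False] * c.n_subjects, dtype="boolean")
        from phlabayes import CohortTable

        cohort = CohortTable(c.subject_ids, c.allele_names, c.copy_matrix, resp)
        chains = run_chains(cohort, ["pep_1", "pep_2"], uniform_prior_two, RunConfig(
            chain_length=5_000, seed=7
        ))
        assert set(chains) == {"pep_1", "pep_2"}
        # all-negative peptide pulls immunogenicities down relative to pep_1
        assert chains["pep_2"].samples.mean() < chains["pep_1"].samples.mean()

    def test_summaries_insensitive_to_doubling_burn_in(
        self, single_allele_cohort
    ):
        prior = PriorSpec.uniform(["A"])
        base = run_chain(
            single_allele_cohort, "pep_1", prior, RunConfig(chain_length=60_000, seed=8)
        )
        doubled = run_chain(
            single_allele_cohort,
            "pep_1",
            prior,
            RunConfig(chain_length=60_000, burn_in_fraction=0.2, seed=8),
        )
        assert base.samples[:, 0].mean() == pytest.approx(
            doubled.samples[:, 0].mean(), abs=0.02
        )


class TestChainLengthEquivalence:
    def test_long_and_short_chains_agree_on_marginal_summaries(
        self, toy_two_allele_cohort, uniform_prior_two
    ):
        """A 100k chain reproduces the marginal distributions of a 10x
        longer chain: means within 0.02, two-sample KS statistic < 0.02,
        and modes within one coarse histogram bin.  (The raw 100-bin
        argmax mode carries a few bins of estimator jitter on a broad
        6-subject marginal, so modes are compared on 20 bins.)"""
        from scipy.stats import ks_2samp

        from phlabayes import marginal_mode

        short = run_chain(
            toy_two_allele_cohort, "pep_1", uniform_prior_two,
            RunConfig(chain_length=100_000, seed=21),
        )
        long = run_chain(
            toy_two_allele_cohort, "pep_1", uniform_prior_two,
            RunConfig(chain_length=1_000_000, seed=22),
        )
        for j in range(2):
            assert short.samples[:, j].mean() == pytest.approx(
                long.samples[:, j].mean(), abs=0.02
            )
            assert ks_2samp(short.samples[:, j], long.samples[:, j]).statistic < 0.02
            assert marginal_mode(short.samples[:, j], bins=20) == pytest.approx(
                marginal_mode(long.samples[:, j], bins=20), abs=0.05
            )
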