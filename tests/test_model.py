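import numpy as np
import pytest

from consegment import model
from consegment.alignment import CodeSequence
from consegment.model import (
    ChangepointModel,
    ClassParams,
    SampleChain,
    Segmentation,
    compute_profiles,
    convergence_diagnostics,
    information_criteria,
    joint_log_prob,
    marginal_log_likelihood,
    mcmc_run,
    read_wiggle,
    segment_log_marginal,
    write_wiggle,
)

from oracle_utils import batch_mean_se, dm_log, enumerate_posterior


class TestSegmentLogMarginal:
    def test_two_identical_codes_uniform_prior(self):
        # Gamma(3)/Gamma(5) * Gamma(3)/Gamma(1) = 1/6
        assert segment_log_marginal((2, 0, 0), (1, 1, 1)) == pytest.approx(
            np.log(1 / 6))

    def test_empty_segment_is_certain(self):
        assert segment_log_marginal((0, 0, 0), (3.2, 0.5, 9.0)) == 0.0

    def test_one_of_each_code_uniform_prior(self):
        # Monte-Carlo oracle: E[theta0 theta1 theta2] under Dirichlet(1,1,1)
        rng = np.random.default_rng(42)
        theta = rng.dirichlet((1.0, 1.0, 1.0), size=200_000)
        mc = theta.prod(axis=1).mean()
        exact = segment_log_marginal((1, 1, 1), (1, 1, 1))
        assert exact == pytest.approx(np.log(1 / 60))
        assert np.exp(exact) == pytest.approx(mc, rel=0.02)

    def test_order_invariance_counts_only(self):
        a = segment_log_marginal((5, 2, 1), (0.5, 2.0, 7.0))
        b = dm_log((5, 2, 1), (0.5, 2.0, 7.0))
        assert a == pytest.approx(b)

    def test_concentrated_limit_is_categorical(self):
        # alpha -> inf with fixed proportions: i.i.d. categorical likelihood
        props = np.array([0.6, 0.3, 0.1])
        counts = np.array([60, 30, 10])
        lm = segment_log_marginal(counts, props * 1e6)
        iid = float(np.sum(counts * np.log(props)))
        assert abs(lm - iid) < 1e-3 * counts.sum()

    def test_rejects_nonpositive_alpha(self):
        with pytest.raises(ValueError):
            segment_log_marginal((1, 0, 0), (0.0, 1.0, 1.0))


class TestJointLogProb:
    def test_single_segment_composition(self):
        seq = CodeSequence(np.array([0, 0], dtype=np.int8))
        seg = Segmentation([], [1], 2)
        params = ClassParams([[1.0, 1.0, 1.0]], [1.0], 0.5)
        expected = np.log(1 / 6) + np.log(0.5)  # one absent boundary
        assert joint_log_prob(seq, seg, params) == pytest.approx(expected)

    def test_counts_sufficiency(self):
        params = ClassParams([[2.0, 1.0, 1.0], [1.0, 1.0, 3.0]],
                             [0.4, 0.6], 0.1)
        seg = Segmentation([3], [1, 2], 6)
        a = joint_log_prob(np.array([0, 1, 0, 2, 2, 1]), seg, params)
        b = joint_log_prob(np.array([0, 0, 1, 1, 2, 2]), seg, params)
        assert a == pytest.approx(b)

    def test_label_permutation_symmetry(self):
        codes = np.array([0, 0, 1, 2, 2, 2, 0, 1])
        seg = Segmentation([4], [1, 2], 8)
        seg_p = Segmentation([4], [2, 1], 8)
        alphas = np.array([[5.0, 1.0, 1.0], [1.0, 1.0, 5.0]])
        params = ClassParams(alphas, [0.3, 0.7], 0.2)
        params_p = ClassParams(alphas[::-1], [0.7, 0.3], 0.2)
        assert joint_log_prob(codes, seg, params) == pytest.approx(
            joint_log_prob(codes, seg_p, params_p))

    def test_nonpositive(self):
        codes = np.array([0, 1, 2, 0])
        seg = Segmentation([2], [1, 1], 4)
        params = ClassParams([[1.0, 1.0, 1.0]], [1.0], 0.3)
        assert joint_log_prob(codes, seg, params) <= 0.0

    def test_label_out_of_range(self):
        codes = np.array([0, 1])
        seg = Segmentation([], [3], 2)
        params = ClassParams([[1.0, 1.0, 1.0], [1.0, 1.0, 1.0]],
                             [0.5, 0.5], 0.3)
        with pytest.raises(ValueError, match="label"):
            joint_log_prob(codes, seg, params)


FIXED = ClassParams(
    [[10.0, 1.0, 1.0], [1.0, 1.0, 10.0]], [0.5, 0.5], 0.1)


class TestMcmcRun:
    def test_k1_degenerate(self):
        chain = mcmc_run(np.array([0, 1, 2, 0, 1] * 10, dtype=np.int8),
                         k=1, n_iter=50, seed=7)
        prof = compute_profiles(chain, burn_in=10)
        np.testing.assert_array_equal(prof.values, 1.0)

    def test_seeded_determinism(self):
        codes = np.array([0, 0, 0, 2, 2, 2, 1, 1] * 5, dtype=np.int8)
        a = mcmc_run(codes, k=2, n_iter=100, seed=11)
        b = mcmc_run(codes, k=2, n_iter=100, seed=11)
        np.testing.assert_array_equal(a.log_likelihood, b.log_likelihood)
        np.testing.assert_array_equal(a._cp_flat, b._cp_flat)
        np.testing.assert_array_equal(a.alpha_trace, b.alpha_trace)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            mcmc_run(np.array([0, 1]), k=0, n_iter=10, seed=0)
        with pytest.raises(ValueError):
            mcmc_run(np.array([], dtype=np.int8), k=1, n_iter=10, seed=0)

    def test_matches_enumeration_oracle(self):
        """Marginal changepoint and class probabilities agree with full
        enumeration over all 2^11 boundary configurations (N=12, k=2,
        fixed class parameters), within 3 Monte-Carlo SE."""
        codes = np.array([0] * 6 + [2] * 6, dtype=np.int8)
        boundary, pos_class, _ = enumerate_posterior(
            codes, FIXED.pi, FIXED.alpha, FIXED.rho)
        n_iter, burn = 50_000, 2000
        chain = mcmc_run(codes, k=2, n_iter=n_iter, seed=5,
                         fixed_params=FIXED)
        # changepoint indicator draws at the central boundary (index 6)
        ind = np.zeros(n_iter - burn)
        pos3 = np.zeros((n_iter - burn, 2))
        for t, it in enumerate(range(burn, n_iter)):
            seg = chain.segmentation(it)
            ind[t] = 6 in set(seg.changepoints.tolist())
            lab = seg.position_labels()
            pos3[t, lab[3] - 1] = 1.0
        se = max(batch_mean_se(ind), 1e-3)
        assert abs(ind.mean() - boundary[5]) < 3 * se
        se3 = max(batch_mean_se(pos3[:, 0]), 1e-3)
        assert abs(pos3[:, 0].mean() - pos_class[3, 0]) < 3 * se3
        prof = compute_profiles(chain, burn)
        # profile rows track the enumerated position-class marginals
        assert np.max(np.abs(prof.values - pos_class)) < 0.02


class TestComputeProfiles:
    def _chain_two_samples(self):
        # sample 0: positions 0-5 class 1; sample 1: cp at 3, classes 1|2
        return SampleChain(
            k=2, n_positions=6, n_symbols=3, seed=0,
            codes=np.zeros(6, np.int8),
            log_likelihood=np.zeros(2),
            data_log_likelihood=np.zeros(2),
            n_changepoints=np.array([0, 1]),
            rho_trace=np.full(2, 0.1),
            pi_trace=np.full((2, 2), 0.5),
            alpha_trace=np.ones((2, 2, 3)),
            _cp_flat=np.array([3]),
            _cp_off=np.array([0, 0, 1]),
            _lab_flat=np.array([0, 0, 1], dtype=np.int32),
            _lab_off=np.array([0, 1, 3]),
        )

    def test_disagreeing_samples_average(self):
        prof = compute_profiles(self._chain_two_samples(), burn_in=0)
        np.testing.assert_allclose(prof.values[0], [1.0, 0.0])
        np.testing.assert_allclose(prof.values[4], [0.5, 0.5])

    def test_identical_sample_is_certain(self):
        prof = compute_profiles(self._chain_two_samples(), burn_in=1)
        np.testing.assert_allclose(prof.values[4], [0.0, 1.0])

    def test_burn_in_window(self):
        chain = mcmc_run(np.array([0, 1, 2] * 8, dtype=np.int8), k=2,
                         n_iter=1000, seed=3)
        res = model.ChangepointResults(None, chain, burn_in=500)
        assert res.n_retained == 500
        with pytest.raises(ValueError):
            compute_profiles(chain, burn_in=1000)

    def test_rows_sum_to_one(self, fitted_well_separated):
        for _, res in fitted_well_separated.values():
            rows = res.profiles.values.sum(axis=1)
            assert np.max(np.abs(rows - 1.0)) < 1e-9


class TestInformationCriteria:
    def test_parameter_count(self):
        codes = np.array([0, 1, 2] * 20, dtype=np.int8)
        chains = [mcmc_run(codes, k, n_iter=40, seed=1) for k in (1, 4)]
        ic = information_criteria(chains, burn_in=20, dic_draws=0)
        assert ic.loc[4, "n_params"] == 16
        assert ic.loc[1, "n_params"] == 4  # 3*1 + 0 + 1

    def test_single_class_data_prefers_k1(self):
        """AIC(k=1) <= AIC(k=2) in at least 90% of seeded replicates when
        the data really has one class."""
        wins = 0
        for rep in range(20):
            rng = np.random.default_rng(1000 + rep)
            codes = rng.choice(3, size=1500, p=[0.7, 0.2, 0.1]).astype(
                np.int8)
            chains = [mcmc_run(codes, k, n_iter=150, seed=rep)
                      for k in (1, 2)]
            ic = information_criteria(chains, burn_in=75, dic_draws=0,
                                      max_segment=400)
            wins += ic.loc[1, "AIC"] <= ic.loc[2, "AIC"]
        assert wins >= 18

    def test_marginal_likelihood_matches_enumeration(self):
        codes = np.array([0, 0, 1, 2, 1, 0, 0, 0], dtype=np.int8)
        params = ClassParams([[5.0, 1.0, 1.0], [1.0, 1.0, 5.0]],
                             [0.6, 0.4], 0.2)
        _, _, log_z_seg = enumerate_posterior(
            codes, params.pi, params.alpha, params.rho)
        assert marginal_log_likelihood(codes, params) == pytest.approx(
            log_z_seg, abs=1e-9)

    def test_empty_window_errors(self):
        chain = mcmc_run(np.array([0, 1, 2] * 5, dtype=np.int8), k=1,
                         n_iter=10, seed=0)
        with pytest.raises(ValueError):
            information_criteria([chain], burn_in=10)


class TestConvergenceDiagnostics:
    def _chain_with_loglik(self, ll):
        n = len(ll)
        return SampleChain(
            k=1, n_positions=4, n_symbols=3, seed=0,
            codes=np.zeros(4, np.int8),
            log_likelihood=np.asarray(ll, float),
            data_log_likelihood=np.asarray(ll, float),
            n_changepoints=np.zeros(n, int),
            rho_trace=np.full(n, 0.1),
            pi_trace=np.ones((n, 1)),
            alpha_trace=np.ones((n, 1, 3)),
            _cp_flat=np.array([], dtype=np.int64),
            _cp_off=np.zeros(n + 1, dtype=np.int64),
            _lab_flat=np.zeros(n, dtype=np.int32),
            _lab_off=np.arange(n + 1, dtype=np.int64),
        )

    def test_stationary_chain_not_flagged(self):
        rng = np.random.default_rng(0)
        rep = convergence_diagnostics(
            self._chain_with_loglik(rng.normal(-100, 1, 400)))
        assert not rep.drift_flag

    def test_drifting_chain_flagged(self):
        rng = np.random.default_rng(0)
        ll = rng.normal(-100, 1, 400) + np.linspace(0, 30, 400)
        rep = convergence_diagnostics(self._chain_with_loglik(ll))
        assert rep.drift_flag

    def test_traces_tsv(self, tmp_path):
        chain = mcmc_run(np.array([0, 1, 2] * 10, dtype=np.int8), k=2,
                         n_iter=20, seed=0)
        rep = convergence_diagnostics(chain)
        path = tmp_path / "traces.tsv"
        rep.to_tsv(path)
        header = path.read_text().splitlines()[0].split("\t")
        for name in ("log_likelihood", "n_changepoints", "pi_1",
                     "alpha_2_0"):
            assert name in header


class TestWiggle:
    def test_fixed_step_format(self):
        prof = model.ProfileMatrix(
            np.column_stack([[0.1, 0.9, 0.5], [0.9, 0.1, 0.5]]))
        text = write_wiggle(prof, 1, "chr17", start=100)
        lines = text.splitlines()
        assert lines[0] == "fixedStep chrom=chr17 start=101 step=1 span=1"
        assert [float(x) for x in lines[1:]] == [0.1, 0.9, 0.5]

    def test_round_trip(self):
        rng = np.random.default_rng(1)
        col = rng.random(50)
        prof = model.ProfileMatrix(np.column_stack([col, 1 - col]))
        chrom, start, vals = read_wiggle(write_wiggle(prof, 2, "chrX",
                                                      start=41))
        assert (chrom, start) == ("chrX", 41)
        np.testing.assert_allclose(vals, 1 - col, atol=5e-7)

    def test_class_files_sum_to_one(self, tmp_path):
        chain = mcmc_run(np.array([0, 2] * 30, dtype=np.int8), k=3,
                         n_iter=60, seed=2)
        res = model.ChangepointResults(None, chain, burn_in=20)
        total = None
        for g in (1, 2, 3):
            _, _, vals = read_wiggle(res.to_wig(g, chrom="chr1"))
            total = vals if total is None else total + vals
        np.testing.assert_allclose(total, 1.0, atol=3e-6)


class TestModelFrontEnd:
    def test_fit_summary_mentions_key_quantities(self):
        res = ChangepointModel(np.array([0, 1, 0, 2] * 20, dtype=np.int8),
                               k=2).fit(n_iter=80, burn_in=40, seed=0)
        s = res.summary()
        assert "classes (k)          2" in s
        assert "mean changepoints" in s

    def test_burn_in_validation(self):
        m = ChangepointModel(np.array([0, 1, 2] * 5, dtype=np.int8), k=2)
        with pytest.raises(ValueError):
            m.fit(n_iter=10, burn_in=10, seed=0)
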