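"""Hierarchical SVI: log-joint correctness, optimisation behaviour,
variant comparison and parameter recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from goalweaver.task import TaskConfig
from goalweaver.planner import backward_induction
from goalweaver.choice import SubjectParams, dataset_log_likelihood, transform_params
from goalweaver.cohort import CohortSpec, PopulationParams, generate_dataset
from goalweaver.inference import (LikelihoodData, ModelVariant, PosteriorApprox,
                                  SVISettings, compare_variants, fit_svi,
                                  log_joint, recovery_report)

FAST = SVISettings(lr=2e-2, steps=800, mc_samples=4)


def _basic_only_records(pids=("p1",), n=6):
    rows = []
    for pid in pids:
        for i in range(n):
            rows.append({"participant": pid, "block": 0, "trial": i + 1,
                         "condition": "easy", "pts_a": 3 + i, "pts_b": 3,
                         "offer": "A", "response": "accept",
                         "g_choice": "undefined",
                         "pts_a_next": 4 + i, "pts_b_next": 3})
    return pd.DataFrame(rows)


@pytest.fixture(scope="module")
def toy_cohort(conditions):
    spec = CohortSpec(n_subjects=6, n_blocks=9,
                      blocks_per_condition=(3, 3, 3), seed=31)
    return generate_dataset(spec, conditions=conditions)


class TestLogJoint:
    def test_matches_hand_coded_density(self, toy_cohort):
        """Log-joint equals an independently assembled sum of scipy
        log-densities plus the scalar per-subject likelihood."""
        records, truth = toy_cohort
        records = records[records.participant.isin(["sub001", "sub002"])]
        subs = ["sub001", "sub002"]
        x = np.array([transform_params(SubjectParams(**truth["subjects"][p]))
                      for p in subs])
        mu = np.array([0.5, 0.4, 3.5, 0.1])
        sigma = np.array([0.6, 0.5, 0.8, 0.4])
        hyper = {"m": np.zeros(4), "s": np.ones(4), "lam": 1.3}
        got = log_joint(records, {"x": x, "mu": mu, "sigma": sigma}, hyper)

        want = stats.norm.logpdf(mu, 0.0, 1.0).sum()
        want += stats.halfcauchy.logpdf(sigma, scale=1.0).sum()
        want += stats.norm.logpdf(x, mu, 1.3 * sigma).sum()
        for p, xi in zip(subs, x):
            sp = SubjectParams(float(np.exp(xi[0])), float(xi[1]),
                               float(stats.logistic.cdf(xi[2])),
                               float(2 * stats.logistic.cdf(xi[3])))
            tb = backward_induction(gamma=sp.gamma, kappa=sp.kappa)
            want += dataset_log_likelihood(records[records.participant == p],
                                           sp, tb)
        assert got == pytest.approx(want, abs=1e-8)

    def test_zero_data_equals_prior(self):
        """Records with no classifiable trials reduce the log-joint to the
        hierarchical prior alone (half-Cauchy at sigma=1 contributes
        ln(1/pi) per coordinate)."""
        records = _basic_only_records()
        x = np.zeros((1, 1))
        hyper = {"m": np.zeros(1), "s": np.ones(1), "lam": 1.0}
        got = log_joint(records, {"x": x, "mu": np.zeros(1),
                                  "sigma": np.ones(1)}, hyper,
                        ModelVariant(("theta",)))
        want = (stats.norm.logpdf(0.0, 0.0, 1.0)      # mu
                + np.log(1 / np.pi)                   # half-Cauchy at 1
                + stats.norm.logpdf(0.0, 0.0, 1.0))   # x | mu, sigma
        assert got == pytest.approx(want, abs=1e-12)

    def test_dimension_mismatch_rejected(self, toy_cohort):
        records, _ = toy_cohort
        with pytest.raises(ValueError):
            log_joint(records, {"x": np.zeros((2, 4)), "mu": np.zeros(4),
                                "sigma": np.ones(4)},
                      {"m": np.zeros(4), "s": np.ones(4), "lam": 1.0})


class TestLikelihoodVectorisation:
    def test_batched_loglik_matches_scalar_path(self, toy_cohort):
        records, truth = toy_cohort
        ld = LikelihoodData(records, ModelVariant())
        X = np.array([transform_params(SubjectParams(**truth["subjects"][p]))
                      for p in ld.subjects])
        ll, _ = ld.loglik_and_grad(X[None], want_grad=False)
        for i, pid in enumerate(ld.subjects):
            sp = SubjectParams(**truth["subjects"][pid])
            tb = backward_induction(gamma=sp.gamma, kappa=sp.kappa)
            ref = dataset_log_likelihood(records[records.participant == pid],
                                         sp, tb)
            assert ll[0, i] == pytest.approx(ref, abs=1e-9)

    def test_gradient_matches_finite_differences(self, toy_cohort):
        records, truth = toy_cohort
        ld = LikelihoodData(records, ModelVariant())
        X = np.array([transform_params(SubjectParams(**truth["subjects"][p]))
                      for p in ld.subjects])[:2]
        ld2 = LikelihoodData(records[records.participant.isin(ld.subjects[:2])],
                             ModelVariant())
        _, grad = ld2.loglik_and_grad(X[None])
        eps = 1e-6
        for i in range(2):
            for j in range(4):
                Xp, Xm = X.copy(), X.copy()
                Xp[i, j] += eps
                Xm[i, j] -= eps
                num = (ld2.loglik_and_grad(Xp[None], want_grad=False)[0].sum()
                       - ld2.loglik_and_grad(Xm[None], want_grad=False)[0].sum()
                       ) / (2 * eps)
                assert grad[0, i, j] == pytest.approx(num, abs=1e-5)


class TestFitSVI:
    def test_seed_determinism(self, toy_cohort):
        records, _ = toy_cohort
        st = SVISettings(lr=2e-2, steps=120, mc_samples=3)
        a = fit_svi(records, ModelVariant(("beta", "theta")), st, seed=4)
        b = fit_svi(records, ModelVariant(("beta", "theta")), st, seed=4)
        assert np.array_equal(a.elbo_trace, b.elbo_trace)
        assert np.array_equal(a.subject_means, b.subject_means)

    def test_elbo_window_averages_increase(self, toy_cohort):
        records, _ = toy_cohort
        post = fit_svi(records, ModelVariant(("beta", "theta")),
                       SVISettings(lr=2e-2, steps=1500, mc_samples=4), seed=0)
        w = 500
        means = [post.elbo_trace[i:i + w].mean()
                 for i in range(0, len(post.elbo_trace) - w + 1, w)]
        assert all(b >= a - 1.0 for a, b in zip(means, means[1:]))
        assert means[-1] > means[0]

    def test_prior_recovery_sigma_location(self):
        """With a flat likelihood (no classifiable trials) the fitted
        ln-sigma location must sit near the mode of the half-Cauchy-plus-
        Jacobian density, which is ln(sigma) = 0."""
        records = _basic_only_records(("p1", "p2", "p3"), n=4)
        post = fit_svi(records, ModelVariant(("theta",)),
                       SVISettings(lr=2e-2, steps=2000, mc_samples=8), seed=1)
        d = post.d
        assert abs(post.group_mean[d]) < 0.5

    def test_subject_without_data_shrinks_to_group(self, conditions):
        """A subject with no classifiable trials gets (approximately) the
        group-level prior predictive, unlike a data-rich extreme subject."""
        spec = CohortSpec(n_subjects=3, n_blocks=12,
                          blocks_per_condition=(4, 4, 4), seed=8)
        pop = PopulationParams(mu=np.array([0.6, 2.5, 4.1, 0.1]),
                               sigma=np.array([0.2, 0.2, 0.2, 0.2]))
        records, _ = generate_dataset(spec, pop, conditions=conditions)
        empty = _basic_only_records(("empty",), n=10)
        records = pd.concat([records, empty], ignore_index=True)
        post = fit_svi(records, ModelVariant(("theta",)),
                       SVISettings(lr=2e-2, steps=1500, mc_samples=4), seed=0)
        i_empty = post.subjects.index("empty")
        group_loc = post.group_mean[0]
        dist_empty = abs(post.subject_means[i_empty, 0] - group_loc)
        others = [abs(post.subject_means[i, 0] - group_loc)
                  for i in range(len(post.subjects)) if i != i_empty]
        assert dist_empty < min(others)
        # and its posterior sd is the widest (prior-predictive width)
        sds = np.sqrt(post.subject_covs[:, 0, 0])
        assert sds[i_empty] == max(sds)

    def test_theta_sign_separation(self, conditions):
        """Cohorts generated at theta = +1 versus -1 yield group-theta
        posteriors with non-overlapping 90% intervals."""
        intervals = []
        for theta, seed in ((1.0, 41), (-1.0, 42)):
            mu = transform_params(SubjectParams(1.82, theta, 0.984, 1.05))
            pop = PopulationParams(mu=mu, sigma=np.array([0.3, 0.3, 0.3, 0.2]))
            spec = CohortSpec(n_subjects=6, n_blocks=9,
                              blocks_per_condition=(3, 3, 3), seed=seed)
            records, _ = generate_dataset(spec, pop, conditions=conditions)
            post = fit_svi(records, ModelVariant(("beta", "theta")), FAST, seed=0)
            j = post.param_labels.index("theta")
            loc = post.group_mean[j]
            sd = np.sqrt(post.group_cov[j, j])
            intervals.append((loc - 1.645 * sd, loc + 1.645 * sd))
        (lo_pos, hi_pos), (lo_neg, hi_neg) = intervals
        assert lo_pos > hi_neg

    def test_nonempty_records_required(self):
        with pytest.raises(ValueError):
            fit_svi(pd.DataFrame(columns=["participant", "block", "trial",
                                          "condition", "pts_a", "pts_b",
                                          "offer", "response", "g_choice",
                                          "pts_a_next", "pts_b_next"]))


class TestCompareVariants:
    def test_theta_free_beats_theta_fixed_on_theta_data(self, conditions):
        mu = transform_params(SubjectParams(1.82, 1.0, 0.984, 1.05))
        pop = PopulationParams(mu=mu, sigma=np.array([0.2, 0.2, 0.2, 0.2]))
        spec = CohortSpec(n_subjects=6, n_blocks=9,
                          blocks_per_condition=(3, 3, 3), seed=51)
        records, _ = generate_dataset(spec, pop, conditions=conditions)
        table = compare_variants(
            records,
            [ModelVariant(("beta", "theta")), ModelVariant(("beta",))],
            FAST, seed=0)
        assert table.iloc[0]["variant"] == "bt"

    def test_duplicate_variants_tie_exactly(self, toy_cohort):
        records, _ = toy_cohort
        st = SVISettings(lr=2e-2, steps=150, mc_samples=3)
        table = compare_variants(
            records, [ModelVariant(("theta",)), ModelVariant(("theta",))],
            st, seed=0)
        assert table.elbo.iloc[0] == table.elbo.iloc[1]

    def test_partitioned_variant_fits(self, toy_cohort):
        records, _ = toy_cohort
        post = fit_svi(records,
                       ModelVariant(("beta", "theta"), partition="by-segment"),
                       SVISettings(lr=2e-2, steps=150, mc_samples=3), seed=0)
        assert post.param_labels == ["beta[seg1-5]", "theta[seg1-5]",
                                     "beta[seg6-10]", "theta[seg6-10]",
                                     "beta[seg11-15]", "theta[seg11-15]"]
        assert np.isfinite(post.final_elbo())


class TestRecoveryReport:
    def test_perfect_posterior_zero_error(self, toy_cohort):
        records, truth = toy_cohort
        subjects = list(truth["subjects"])
        X = np.array([transform_params(SubjectParams(**truth["subjects"][p]))
                      for p in subjects])
        post = PosteriorApprox(
            variant=ModelVariant(), subjects=subjects,
            param_labels=list(("beta", "theta", "gamma", "kappa")),
            group_mean=np.zeros(8), group_cov=np.eye(8),
            subject_means=X, subject_covs=np.tile(0.01 * np.eye(4),
                                                  (len(subjects), 1, 1)),
            elbo_trace=np.zeros(1), hyper={}, converged=True)
        rep = recovery_report(truth["subjects"], post)
        assert np.allclose(rep.bias, 0.0) and np.allclose(rep.rmse, 0.0)
        assert (rep.coverage90 == 1.0).all()

    def test_subject_mismatch_rejected(self, toy_cohort):
        records, truth = toy_cohort
        post = fit_svi(records, ModelVariant(("theta",)),
                       SVISettings(lr=2e-2, steps=50, mc_samples=2), seed=0)
        with pytest.raises(ValueError):
            recovery_report({"nobody": truth["subjects"]["sub001"]}, post)
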