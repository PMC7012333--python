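"""FIML likelihood: closed-form cases, brute-force quadrature oracle,
and structural invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate
from scipy.stats import multivariate_normal, norm

import twinace as ta
from twinace.params import CholeskySet, CrossSexStructure, ThresholdModel
from twinace.prep import Member, PreparedFamily
from _oracles import make_pair as _pair, oracle_loglik as _oracle_loglik, random_chol as _random_chol


def _unit_thr(t=0.5, mu=0.0, beta=0.0):
    return ThresholdModel(threshold={"M": t, "F": t}, beta_age=beta,
                          dep_mean={"M": mu, "F": mu})


class TestFamilyLoglik:
    def test_fully_continuous_identity_covariance(self):
        chol = CholeskySet.homogeneous(
            a=np.zeros((2, 2)), c=np.zeros((2, 2)), e=np.eye(2))
        fam = _pair("MZF", None, 0.0, None, 0.0)
        ll = ta.family_loglik(fam, chol, CrossSexStructure(), _unit_thr())
        assert ll == pytest.approx(2 * norm.logpdf(0.0), abs=1e-12)

    def test_unreachable_threshold_contributes_log_one(self):
        chol = CholeskySet.homogeneous(
            a=np.zeros((2, 2)), c=np.zeros((2, 2)), e=np.eye(2))
        fam_with = _pair("MZF", 1, 0.3, None, None)
        fam_without = _pair("MZF", None, 0.3, None, None)
        thr = _unit_thr(t=-30.0)  # affected member essentially certain
        cross = CrossSexStructure()
        assert ta.family_loglik(fam_with, chol, cross, thr) == pytest.approx(
            ta.family_loglik(fam_without, chol, cross, thr), abs=1e-9)

    def test_matches_quadrature_oracle(self):
        """100 random complete families, |delta loglik| < 1e-6."""
        rng = np.random.default_rng(7)
        worst = 0.0
        for _ in range(100):
            chol = _random_chol(rng)
            thr = ThresholdModel(
                threshold={"M": rng.uniform(-1.2, 1.2), "F": rng.uniform(-1.2, 1.2)},
                beta_age=rng.uniform(-0.01, 0.01),
                dep_mean={"M": rng.normal(scale=0.3), "F": rng.normal(scale=0.3)})
            group = rng.choice(["MZM", "MZF", "DZM", "DZF", "DZOS"])
            fam = _pair(str(group), int(rng.integers(2)), float(rng.normal()),
                        int(rng.integers(2)), float(rng.normal()),
                        age=float(rng.uniform(20, 80)))
            cross = CrossSexStructure()
            mine = ta.family_loglik(fam, chol, cross, thr)
            oracle = _oracle_loglik(fam, chol, cross, thr)
            worst = max(worst, abs(mine - oracle))
        assert worst < 1e-6

    def test_partial_missingness_against_oracle(self):
        """One binary + one continuous observed: 1-d quadrature oracle."""
        rng = np.random.default_rng(3)
        from twinace.params import expected_pair_covariance
        for _ in range(20):
            chol = _random_chol(rng)
            thr = _unit_thr(t=float(rng.uniform(-1, 1)))
            fam = _pair("DZF", int(rng.integers(2)), None, None, float(rng.normal()))
            sigma = expected_pair_covariance(chol, "DZF", CrossSexStructure())
            # observed elements: d1 (index 0) and y2 (index 3)
            sub = sigma[np.ix_([0, 3], [0, 3])]
            tau = thr.threshold["F"]
            d = fam.members[0].d
            y2 = fam.members[1].y
            lo, hi = ((tau, 12.0) if d == 1 else (-12.0, tau))
            val, _ = integrate.quad(
                lambda l: multivariate_normal(mean=[0, 0], cov=sub).pdf([l, y2]),
                lo, hi, epsabs=1e-13)
            mine = ta.family_loglik(fam, chol, CrossSexStructure(), thr)
            assert mine == pytest.approx(np.log(val), abs=1e-7)

    def test_binary_outcomes_conserve_probability(self):
        rng = np.random.default_rng(5)
        chol = _random_chol(rng)
        thr = _unit_thr(t=0.8)
        cross = CrossSexStructure()
        y1, y2 = 0.4, -0.7
        total = 0.0
        base = ta.family_loglik(_pair("MZM", None, y1, None, y2), chol, cross, thr)
        for d1 in (0, 1):
            for d2 in (0, 1):
                ll = ta.family_loglik(_pair("MZM", d1, y1, d2, y2), chol, cross, thr)
                total += np.exp(ll - base)
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_member_swap_invariance_same_sex(self):
        rng = np.random.default_rng(9)
        chol = _random_chol(rng)
        thr = _unit_thr(t=0.3)
        cross = CrossSexStructure()
        a = ta.family_loglik(_pair("DZM", 1, 0.5, 0, -1.2), chol, cross, thr)
        b = ta.family_loglik(_pair("DZM", 0, -1.2, 1, 0.5), chol, cross, thr)
        assert a == pytest.approx(b, abs=1e-10)

    def test_gaussian_reduction_when_binaries_missing(self):
        """With the threshold trait removed the likelihood is the ordinary
        multivariate normal twin likelihood."""
        rng = np.random.default_rng(13)
        from twinace.params import expected_pair_covariance
        chol = _random_chol(rng)
        thr = _unit_thr(mu=0.2)
        fam = _pair("MZF", None, 0.7, None, -0.4)
        sigma = expected_pair_covariance(chol, "MZF", CrossSexStructure())
        ref = multivariate_normal(
            mean=[0.2, 0.2], cov=sigma[np.ix_([1, 3], [1, 3])]
        ).logpdf([0.7, -0.4])
        mine = ta.family_loglik(fam, chol, CrossSexStructure(), thr)
        assert mine == pytest.approx(ref, abs=1e-10)


class TestTotalMinus2ll:
    def test_duplicated_data_doubles(self, small_families):
        chol = ta.default_params().chol
        thr = ta.default_params().thresholds
        sub = small_families[:200]
        one = ta.total_minus2ll(sub, chol, CrossSexStructure(), thr)
        two = ta.total_minus2ll(sub + sub, chol, CrossSexStructure(), thr)
        assert two == pytest.approx(2 * one, rel=1e-12)

    def test_singletons_sum_of_marginals(self):
        rng = np.random.default_rng(1)
        chol = _random_chol(rng)
        thr = _unit_thr(t=0.6)
        fams = [
            PreparedFamily(family_id=str(i), group="SGL",
                           members=[Member(d=int(rng.integers(2)),
                                           y=float(rng.normal()),
                                           age=45.0, sex="F")])
            for i in range(10)
        ]
        total = ta.total_minus2ll(fams, chol, CrossSexStructure(), thr)
        parts = sum(ta.family_loglik(f, chol, CrossSexStructure(), thr) for f in fams)
        assert total == pytest.approx(-2 * parts, rel=1e-12)


@given(seed=st.integers(0, 10_000))
@settings(max_examples=40, deadline=None, derandomize=True)
def test_implied_covariance_positive_semidefinite(seed):
    rng = np.random.default_rng(seed)
    chol = _random_chol(rng, dep_scale=float(rng.uniform(0.5, 2.0)))
    for group in ("MZM", "MZF", "DZM", "DZF", "DZOS"):
        sigma = ta.expected_pair_covariance(chol, group, CrossSexStructure())
        assert np.min(np.linalg.eigvalsh(sigma)) > -1e-10
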