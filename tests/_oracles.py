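"""Independent brute-force oracles and random-parameter generators shared
by the likelihood tests.  Kept free of any twinace likelihood code paths:
the oracle integrates the joint density with scipy's adaptive quadrature
and scipy's own multivariate normal pdf."""

import numpy as np
from scipy import integrate
from scipy.stats import multivariate_normal

from twinace.params import GROUP_SEXES, CholeskySet, expected_pair_covariance
from twinace.prep import Member, PreparedFamily


def random_chol(rng, dep_scale=1.0) -> CholeskySet:
    """Random valid parameter set with unit liability variance."""
    chol = {comp: {} for comp in "ace"}
    for sex in ("M", "F"):
        w = rng.uniform(0.05, 1.0, 3)
        w = np.sqrt(w / w.sum())  # (a11, c11, e11) on the unit sphere
        a21, c21, e21 = rng.uniform(-0.4, 0.4, 3) * dep_scale
        a22, c22 = rng.uniform(0.05, 0.6, 2) * dep_scale
        e22 = rng.uniform(0.3, 0.8) * dep_scale
        chol["a"][sex] = np.array([[w[0], 0], [a21, a22]])
        chol["c"][sex] = np.array([[w[1], 0], [c21, c22]])
        chol["e"][sex] = np.array([[w[2], 0], [e21, e22]])
    return CholeskySet(a=chol["a"], c=chol["c"], e=chol["e"])


def make_pair(group, d1, y1, d2, y2, age=40.0) -> PreparedFamily:
    s1, s2 = GROUP_SEXES[group]
    return PreparedFamily(
        family_id="t", group=group,
        members=[Member(d=d1, y=y1, age=age, sex=s1),
                 Member(d=d2, y=y2, age=age, sex=s2)])


def oracle_loglik(family, chol, cross, thr) -> float:
    """Brute force: integrate the joint 4-d normal density over the
    liability rectangle at the observed continuous values."""
    sigma = expected_pair_covariance(chol, family.group, cross)
    s1, s2 = (m.sex for m in family.members)
    mu = np.array([0.0, thr.dep_mean[s1], 0.0, thr.dep_mean[s2]])
    y = np.array([family.members[0].y, family.members[1].y])
    taus = [thr.threshold[m.sex] + thr.beta_age * m.age for m in family.members]
    ds = [m.d for m in family.members]
    mvn = multivariate_normal(mean=mu, cov=sigma)

    lims = [((tau, 12.0) if d == 1 else (-12.0, tau))
            for tau, d in zip(taus, ds)]
    val, _ = integrate.dblquad(
        lambda l2, l1: mvn.pdf([l1, y[0], l2, y[1]]),
        lims[0][0], lims[0][1], lambda _: lims[1][0], lambda _: lims[1][1],
        epsabs=1e-13, epsrel=1e-11)
    return float(np.log(val))
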