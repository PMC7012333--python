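"""Variance-component inference: standardization, component correlations,
phenotypic-correlation bridges, profile CIs, report rendering."""

import numpy as np
import pytest

import twinace as ta
from twinace.params import CholeskySet
from twinace.report import VarianceDecomposition, profile_interval


def _chol(a, c, e):
    return CholeskySet(a={"F": np.array(a, dtype=float)},
                       c={"F": np.array(c, dtype=float)},
                       e={"F": np.array(e, dtype=float)})


class TestStandardize:
    def test_pure_genetic_gives_unit_heritability(self):
        chol = _chol(np.eye(2), np.zeros((2, 2)), np.zeros((2, 2)))
        props = ta.standardize(chol, "F")
        assert props["a"] == pytest.approx((1.0, 1.0))

    def test_three_four_five_paths(self):
        chol = _chol([[0.6, 0], [0, 0.5]], [[0, 0], [0, 0.5]],
                     [[0.8, 0], [0, 0.5]])
        props = ta.standardize(chol, "F")
        assert props["a"][0] == pytest.approx(0.36)
        assert props["e"][0] == pytest.approx(0.64)

    def test_proportions_sum_to_one(self, rng):
        for _ in range(30):
            a, c, e = (np.tril(rng.uniform(0.05, 0.8, (2, 2))) for _ in range(3))
            props = ta.standardize(_chol(a, c, e), "F")
            for j in (0, 1):
                assert sum(props[k][j] for k in "ace") == pytest.approx(1.0, abs=1e-12)

    def test_zero_total_variance_refused(self):
        chol = _chol([[1, 0], [0, 0]], np.zeros((2, 2)), np.zeros((2, 2)))
        with pytest.raises(ValueError, match="zero total"):
            ta.standardize(chol, "F")

    def test_invariant_to_column_sign_flip(self):
        a = np.array([[0.6, 0.0], [0.3, 0.4]])
        chol1 = _chol(a, np.zeros((2, 2)), [[0.8, 0], [0, 0.5]])
        chol2 = _chol(-a, np.zeros((2, 2)), [[0.8, 0], [0, 0.5]])
        # sign flip of a whole factor column leaves variances and bridges alone
        p1 = ta.standardize(chol1, "F")
        p2 = ta.standardize(chol2, "F")
        assert p1 == p2
        assert ta.component_correlation(chol1, "F", "a") == pytest.approx(
            ta.component_correlation(chol2, "F", "a"))


class TestComponentCorrelation:
    def test_no_cross_path_gives_zero(self):
        chol = _chol([[0.7, 0], [0.0, 0.5]], np.zeros((2, 2)),
                     [[0.714, 0], [0, 0.5]])
        assert ta.component_correlation(chol, "F", "a") == pytest.approx(0.0)

    def test_three_four_five_cross_path(self):
        # bivariate Cholesky: r = x21 / sqrt(x21^2 + x22^2) = 0.3/0.5
        chol = _chol([[0.7, 0], [0.3, 0.4]], np.zeros((2, 2)),
                     [[0.714, 0], [0, 0.5]])
        assert ta.component_correlation(chol, "F", "a") == pytest.approx(0.6)

    def test_zero_component_variance_undefined_not_zero(self):
        chol = _chol([[0.7, 0], [0, 0]], [[0.2, 0], [0, 0.5]],
                     [[0.685, 0], [0, 0.5]])
        assert ta.component_correlation(chol, "F", "a") is None

    def test_matches_simulated_factor_scores(self, rng):
        """Correlation of simulated latent component scores reproduces the
        path-algebra value."""
        x = np.array([[0.6, 0.0], [0.35, 0.45]])
        n = 1_000_000
        scores = rng.standard_normal((n, 2)) @ x.T
        emp = np.corrcoef(scores[:, 0], scores[:, 1])[0, 1]
        chol = _chol(x, np.zeros((2, 2)), [[0.8, 0], [0, 0.5]])
        assert ta.component_correlation(chol, "F", "a") == pytest.approx(emp, abs=0.005)


class TestDecomposeRph:
    def test_single_bridge(self):
        d = VarianceDecomposition(sex="F", a2=(0.25, 0.25), c2=(0.25, 0.25),
                                  e2=(0.5, 0.5), rA=1.0, rC=0.0, rE=0.0,
                                  r_ph=0.25)
        bridges = ta.decompose_rph(d)
        assert bridges["a"] == pytest.approx(0.25)
        assert bridges["c"] == bridges["e"] == 0.0

    def test_zero_correlations_zero_rph(self):
        d = VarianceDecomposition(sex="F", a2=(0.3, 0.3), c2=(0.3, 0.3),
                                  e2=(0.4, 0.4), rA=0.0, rC=0.0, rE=0.0,
                                  r_ph=0.0)
        assert sum(ta.decompose_rph(d).values()) == pytest.approx(0.0)

    def test_bridges_sum_to_model_implied_cross_trait_correlation(self):
        """Moment identity: the bridge sum equals the standardized
        within-person cross-trait covariance."""
        rng = np.random.default_rng(6)
        for _ in range(20):
            a, c, e = (np.tril(rng.uniform(0.05, 0.8, (2, 2))) for _ in range(3))
            chol = _chol(a, c, e)
            total = sum(chol.component(k, "F") for k in "ace")
            r_ph = total[0, 1] / np.sqrt(total[0, 0] * total[1, 1])
            props = ta.standardize(chol, "F")
            d = VarianceDecomposition(
                sex="F", a2=props["a"], c2=props["c"], e2=props["e"],
                rA=ta.component_correlation(chol, "F", "a"),
                rC=ta.component_correlation(chol, "F", "c"),
                rE=ta.component_correlation(chol, "F", "e"),
                r_ph=r_ph)
            assert sum(ta.decompose_rph(d).values()) == pytest.approx(r_ph, abs=1e-12)


class TestProfileInterval:
    def test_quadratic_likelihood_matches_wald(self):
        """Exactly quadratic -2LL: the profile CI is mean +/- 1.96 SE."""
        H = np.array([[4.0, 1.0], [1.0, 2.0]])  # information matrix
        mu = np.array([0.5, -0.2])

        def m2ll(x):
            d = np.asarray(x) - mu
            return float(d @ H @ d)

        bounds = [(-10, 10), (-10, 10)]
        lo, hi = profile_interval(m2ll, mu, 0, bounds)
        se = np.sqrt(np.linalg.inv(H)[0, 0])
        assert lo == pytest.approx(mu[0] - 1.959964 * se, abs=1e-3)
        assert hi == pytest.approx(mu[0] + 1.959964 * se, abs=1e-3)

    def test_boundary_parameter_one_sided(self):
        def m2ll(x):
            return float((x[0] - 0.0) ** 2 / 0.01)

        lo, hi = profile_interval(m2ll, np.array([0.0]), 0, [(0.0, 1.0)])
        assert lo == 0.0  # censored at the box edge
        # -2LL rises by 3.84 at x = sqrt(3.84 * 0.01)
        assert hi == pytest.approx(0.196, abs=1e-2)


class TestRenderReport:
    @pytest.fixture(scope="class")
    @staticmethod
    def artefacts(small_families):
        fits, comparisons, selected, trail = ta.fit_ladder(
            small_families, seed=1, n_restarts=1)
        pick = fits["HetACE"]
        decomps = [ta.decomposition_from_fit(pick, s) for s in ("M", "F")]
        return fits, comparisons, selected, trail, decomps

    def test_deterministic_rendering(self, artefacts):
        fits, comparisons, selected, trail, decomps = artefacts
        a = ta.render_report(fits, decomps, comparisons, selected, trail)
        b = ta.render_report(fits, decomps, comparisons, selected, trail)
        assert a == b

    def test_contains_single_selection(self, artefacts):
        fits, comparisons, selected, trail, decomps = artefacts
        text = ta.render_report(fits, decomps, comparisons, selected, trail)
        assert text.count("**Selected model:**") == 1
        assert selected in text

    def test_report_without_comparisons(self, artefacts):
        fits, _, _, _, decomps = artefacts
        text = ta.render_report(fits, decomps, [], "", [])
        assert "HomoACE" in text and "Comparisons" not in text


def test_profile_ci_brackets_estimate():
    """Profile CI of a threshold from a small singleton-only sample."""
    import warnings
    rng = np.random.default_rng(8)
    import pandas as pd
    n = 400
    df = pd.DataFrame({
        "family_id": [f"s{i}" for i in range(n)],
        "member_index": 1, "group": "SGL", "sex": "F",
        "age": rng.uniform(20, 70, n),
        "t2dm": (rng.standard_normal(n) > 0.6).astype(int),
        "bdi": rng.integers(0, 30, n),
    })
    fams = ta.pair_assembly(ta.transform_bdi(df))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # single group: A/C not separated
        res = ta.fit(fams, "HetACE", seed=0, n_restarts=1)
    lo, hi = ta.profile_ci(fams, res, "t_F")
    hat = res.x[res.layout.index("t_F")]
    assert lo < hat < hi
    assert hi - lo < 1.5  # informative at n = 400


def test_decomposition_from_fit_unit_liability(small_families):
    res = ta.fit(small_families, "HomoACE", seed=0, n_restarts=1)
    d = ta.decomposition_from_fit(res, "F")
    assert d.a2[0] + d.c2[0] + d.e2[0] == pytest.approx(1.0, abs=1e-9)
    assert sum(d.bridges.values()) == pytest.approx(d.r_ph, abs=1e-9)
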