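"""Maximum-likelihood fitting of the sex-limitation ladder and model
comparison by likelihood-ratio chi-square and AIC.

The unit liability variance (a11^2 + c11^2 + e11^2 = 1 per sex) is imposed
by a spherical reparameterization of the trait-1 paths, so the optimizer
works on an unconstrained box.  Degrees of freedom follow the
observed-statistics convention: df = (number of non-missing observed data
values) - (free parameters), with the paths counted nominally (9 per sex)
so that the qualitative-sex-difference constraints release 4 parameters
each and equating the sexes removes 9.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.stats import chi2, norm

from .model import CompiledData, compile_families, total_minus2ll
from .params import (
    CholeskySet,
    CrossSexStructure,
    ModelSpec,
    ThresholdModel,
    VARIANTS,
)

__all__ = [
    "FitResult",
    "ComparisonRow",
    "ParamLayout",
    "fit",
    "fit_ladder",
    "count_free_params",
    "aic",
    "compare",
    "select_best",
]

_PENALTY = 1e12


# --------------------------------------------------------------------------
# parameter vector layout

@dataclass
class ParamLayout:
    """Maps the internal optimizer vector to model parameter objects."""

    variant: str
    sexes: tuple
    names: list = field(default_factory=list)
    bounds: list = field(default_factory=list)

    @property
    def path_blocks(self) -> tuple:
        if ModelSpec(self.variant).equate_sexes and len(self.sexes) > 1:
            return ("MF",)  # one shared block
        return self.sexes

    def __post_init__(self):
        spec = ModelSpec(self.variant)
        eps = 1e-4
        for b in self.path_blocks:
            self.names += [f"theta1_{b}", f"theta2_{b}",
                           f"a21_{b}", f"c21_{b}", f"e21_{b}",
                           f"a22_{b}", f"c22_{b}", f"e22_{b}"]
            self.bounds += [(eps, np.pi / 2 - eps), (0.0, np.pi / 2),
                            (-3.0, 3.0), (-3.0, 3.0), (-3.0, 3.0),
                            (0.0, 3.0), (0.0, 3.0), (eps, 3.0)]
        for s in self.sexes:
            self.names.append(f"t_{s}")
            self.bounds.append((-6.0, 6.0))
        self.names.append("beta_age")
        self.bounds.append((-0.5, 0.5))
        for s in self.sexes:
            self.names.append(f"mu_{s}")
            self.bounds.append((-10.0, 10.0))
        if spec.free_G:
            self.names += [f"G{i}{j}" for i in (1, 2) for j in (1, 2)]
            self.bounds += [(-1.0, 1.0)] * 4
        if spec.free_H:
            self.names += [f"H{i}{j}" for i in (1, 2) for j in (1, 2)]
            self.bounds += [(-1.0, 1.0)] * 4

    @property
    def n(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def unpack(self, x: np.ndarray):
        x = np.asarray(x, dtype=float)
        spec = ModelSpec(self.variant)
        pos = 0
        paths = {}
        for b in self.path_blocks:
            th1, th2, a21, c21, e21, a22, c22, e22 = x[pos:pos + 8]
            pos += 8
            a11 = np.sin(th1) * np.cos(th2)
            c11 = np.sin(th1) * np.sin(th2)
            e11 = np.cos(th1)
            paths[b] = (
                np.array([[a11, 0.0], [a21, a22]]),
                np.array([[c11, 0.0], [c21, c22]]),
                np.array([[e11, 0.0], [e21, e22]]),
            )
        if tuple(paths) == ("MF",):
            paths = {s: paths["MF"] for s in self.sexes}
        chol = CholeskySet(
            a={s: paths[s][0] for s in self.sexes},
            c={s: paths[s][1] for s in self.sexes},
            e={s: paths[s][2] for s in self.sexes},
        )
        t = {}
        for s in self.sexes:
            t[s] = float(x[pos]); pos += 1
        beta = float(x[pos]); pos += 1
        mu = {}
        for s in self.sexes:
            mu[s] = float(x[pos]); pos += 1
        G, H = 0.5 * np.eye(2), np.eye(2)
        if spec.free_G:
            G = x[pos:pos + 4].reshape(2, 2); pos += 4
        if spec.free_H:
            H = x[pos:pos + 4].reshape(2, 2); pos += 4
        cross = CrossSexStructure(G=G, H=H, free_G=spec.free_G, free_H=spec.free_H)
        thr = ThresholdModel(threshold=t, beta_age=beta, dep_mean=mu)
        return chol, cross, thr


def count_free_params(variant: str, sexes: tuple = ("M", "F")) -> int:
    """Nominal free-parameter count (observed-statistics df convention).

    Paths are counted as 9 per sex (HomoACE: 9 total), thresholds and
    continuous-trait means per sex, one shared age slope, plus 4 for a
    free G (HetACEg) or free H (HetACEc).
    """
    spec = ModelSpec(variant)
    k = len(sexes)
    n = 9 * (1 if spec.equate_sexes else k)  # Cholesky paths
    n += k          # thresholds
    n += 1          # age slope
    n += k          # continuous means
    if spec.free_G or spec.free_H:
        n += 4
    return n


def aic(minus2ll: float, df: int) -> float:
    """AIC under the observed-statistics convention: -2LL - 2*df."""
    return float(minus2ll) - 2.0 * float(df)


# --------------------------------------------------------------------------
# fitting

@dataclass
class FitResult:
    variant: str
    chol: CholeskySet
    cross: CrossSexStructure
    thresholds: ThresholdModel
    minus2ll: float
    n_free_params: int
    n_observed_statistics: int
    converged: bool
    n_restarts_used: int
    x: np.ndarray
    layout: ParamLayout

    @property
    def df(self) -> int:
        return self.n_observed_statistics - self.n_free_params

    @property
    def aic(self) -> float:
        return aic(self.minus2ll, self.df)


def _start_vector(layout: ParamLayout, data: CompiledData) -> np.ndarray:
    """Equal-thirds paths, thresholds from observed prevalence, means/scales
    from the observed continuous trait."""
    # observed prevalence and continuous moments per sex
    stats = {s: {"n": 0, "cases": 0, "y": []} for s in layout.sexes}
    for b in data.blocks:
        bins = [i for i, o in enumerate(b.pattern) if o and i % 2 == 0]
        conts = [i for i, o in enumerate(b.pattern) if o and i % 2 == 1]
        member_sex = b.sexes
        for j, idx in enumerate(bins):
            s = member_sex[idx // 2 if b.n_members == 2 else 0]
            if s in stats:
                stats[s]["n"] += b.d.shape[0]
                stats[s]["cases"] += int(b.d[:, j].sum())
        for j, idx in enumerate(conts):
            s = member_sex[idx // 2 if b.n_members == 2 else 0]
            if s in stats:
                stats[s]["y"].append(b.y[:, j])
    x = np.empty(layout.n)
    th1 = np.arccos(1.0 / np.sqrt(3.0))
    sds = []
    for s in layout.sexes:
        ys = np.concatenate(stats[s]["y"]) if stats[s]["y"] else np.array([0.0, 1.0])
        sds.append(max(float(np.std(ys)), 1e-2))
    sd_all = float(np.mean(sds))
    for i, b in enumerate(layout.path_blocks):
        base = 8 * i
        x[base:base + 8] = [th1, np.pi / 4, 0.0, 0.0, 0.0,
                            sd_all / np.sqrt(3), sd_all / np.sqrt(3), sd_all / np.sqrt(3)]
    pos = 8 * len(layout.path_blocks)
    for s in layout.sexes:
        n, c = stats[s]["n"], stats[s]["cases"]
        prev = min(max(c / n if n else 0.08, 1e-3), 0.5)
        x[pos] = norm.ppf(1.0 - prev); pos += 1
    x[pos] = 0.0; pos += 1  # beta_age
    for s in layout.sexes:
        ys = np.concatenate(stats[s]["y"]) if stats[s]["y"] else np.array([0.0])
        x[pos] = float(np.mean(ys)); pos += 1
    spec = ModelSpec(layout.variant)
    if spec.free_G:
        x[pos:pos + 4] = (0.5 * np.eye(2)).ravel(); pos += 4
    if spec.free_H:
        x[pos:pos + 4] = np.eye(2).ravel(); pos += 4
    return x


def _objective(layout: ParamLayout, data: CompiledData):
    def fun(x):
        try:
            chol, cross, thr = layout.unpack(x)
            val = total_minus2ll(data, chol, cross, thr)
        except (np.linalg.LinAlgError, ValueError, FloatingPointError):
            return _PENALTY
        if not np.isfinite(val):
            return _PENALTY
        return val
    return fun


def fit(data, variant: str = "HetACE", *, seed: int | None = None,
        n_restarts: int = 5, maxiter: int = 600,
        start: np.ndarray | None = None) -> FitResult:
    """Fit one ladder variant by FIML with multi-start quasi-Newton.

    ``data`` is a list of PreparedFamily or a CompiledData.  Parameters are
    instantiated only for the sexes present in the data.  ``start``
    overrides the data-driven starting vector (used by fit_ladder to
    warm-start richer models at a nested optimum, which also enforces
    -2LL nesting monotonicity).  Returns converged=False rather than
    raising when every start fails.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    if isinstance(data, list):
        data = compile_families(data)
    if not data.blocks:
        raise ValueError("no observed data")
    sexes = data.sexes_present()
    groups = data.groups_present()
    n_zyg = len([g for g in groups if not g.startswith("SGL")])
    if n_zyg < 2:
        warnings.warn("fewer than 2 zygosity groups: A and C are not separately identified")
    layout = ParamLayout(variant=variant, sexes=sexes)
    fun = _objective(layout, data)
    x0 = np.asarray(start, dtype=float) if start is not None else _start_vector(layout, data)
    rng = np.random.default_rng(seed)
    best = None
    n_used = 0
    lo = np.array([b[0] for b in layout.bounds])
    hi = np.array([b[1] for b in layout.bounds])
    sols = []
    for k in range(max(1, n_restarts)):
        xk = x0 if k == 0 else np.clip(
            x0 + rng.normal(scale=0.15, size=layout.n) * np.minimum(hi - lo, 2.0) / 2.0,
            lo, hi,
        )
        # eps well above the ~1e-12 relative noise floor of the objective,
        # so finite-difference gradients stay informative
        res = minimize(fun, xk, method="L-BFGS-B", bounds=layout.bounds,
                       options={"maxiter": maxiter, "maxfun": 25 * maxiter,
                                "ftol": 1e-9, "gtol": 1e-6, "eps": 1e-6})
        n_used = k + 1
        if res.fun < _PENALTY:
            sols.append(res)
            if best is None or res.fun < best.fun:
                best = res
            # stop early once two starts agree on the optimum
            if sum(1 for s in sols if s.fun - best.fun < 1e-4) >= 2:
                break
    if best is None:
        chol, cross, thr = layout.unpack(x0)
        return FitResult(variant, chol, cross, thr, np.inf,
                         count_free_params(variant, sexes),
                         data.n_observed_statistics, False, n_used, x0, layout)
    chol, cross, thr = layout.unpack(best.x)
    return FitResult(variant, chol, cross, thr, float(best.fun),
                     count_free_params(variant, sexes),
                     data.n_observed_statistics, bool(best.success), n_used,
                     np.asarray(best.x), layout)


# --------------------------------------------------------------------------
# comparison and selection

#: nesting partial order: constrained -> set of richer models it nests in
_NESTS_IN = {
    "HomoACE": {"HetACE", "HetACEg", "HetACEc"},
    "HetACE": {"HetACEg", "HetACEc"},
    "HetACEg": set(),
    "HetACEc": set(),
}


@dataclass
class ComparisonRow:
    nested: str
    reference: str
    chi2: float
    delta_df: int
    p_value: float
    delta_aic: float


def compare(fit_nested: FitResult, fit_reference: FitResult) -> ComparisonRow:
    """Likelihood-ratio test of a constrained model against the model it
    nests in, plus the AIC difference (nested minus reference)."""
    if fit_reference.variant not in _NESTS_IN[fit_nested.variant]:
        raise ValueError(
            f"{fit_nested.variant} is not nested in {fit_reference.variant}")
    dchi = fit_nested.minus2ll - fit_reference.minus2ll
    ddf = fit_reference.n_free_params - fit_nested.n_free_params
    p = float(chi2.sf(max(dchi, 0.0), ddf)) if ddf > 0 else float(dchi <= 0)
    return ComparisonRow(
        nested=fit_nested.variant, reference=fit_reference.variant,
        chi2=float(dchi), delta_df=int(ddf), p_value=p,
        delta_aic=float(fit_nested.aic - fit_reference.aic),
    )


_PARSIMONY = {"HomoACE": 3, "HetACE": 2, "HetACEg": 1, "HetACEc": 1}


def select_best(comparisons: list, fits=None, alpha: float = 0.05,
                aic_margin: float = 10.0) -> tuple[str, list]:
    """Walk the ladder, preferring a constrained model whenever its LRT
    against a retained reference is non-significant (p >= alpha) or the AIC
    favors it by >= aic_margin.

    A constrained model must survive every comparison that tests it (e.g.
    HetACE against both qualitative models).  If every constraint is
    rejected, the jointly retained full models are reported together.
    Returns (selected variant, decision trail).
    """
    trail = []
    if not comparisons:
        if fits:
            names = list(fits) if not isinstance(fits, str) else [fits]
            return names[0], trail
        return "", trail
    nested_names = {r.nested for r in comparisons}
    accepted = {r.reference for r in comparisons if r.reference not in nested_names}
    vetoed: set = set()
    for row in comparisons:
        if row.reference not in accepted:
            trail.append(f"{row.nested} vs {row.reference}: skipped "
                         f"(reference not retained)")
            continue
        ok = row.p_value >= alpha or row.delta_aic <= -aic_margin
        trail.append(
            f"{row.nested} vs {row.reference}: chi2({row.delta_df}) = {row.chi2:.2f}, "
            f"p = {row.p_value:.3g}, dAIC = {row.delta_aic:+.2f} -> "
            f"{'accept' if ok else 'reject'} {row.nested}"
        )
        if ok and row.nested not in vetoed:
            accepted.add(row.nested)
        else:
            vetoed.add(row.nested)
            accepted.discard(row.nested)
    top = max(_PARSIMONY.get(v, 0) for v in accepted)
    winners = sorted(v for v in accepted if _PARSIMONY.get(v, 0) == top)
    return "+".join(winners), trail


_NULL_CROSS = {"G11": 0.5, "G22": 0.5, "G12": 0.0, "G21": 0.0,
               "H11": 1.0, "H22": 1.0, "H12": 0.0, "H21": 0.0}


def _embed_start(src: FitResult, layout: ParamLayout) -> np.ndarray:
    """Map a fitted vector into a richer/poorer layout; missing cross-sex
    entries start at their null values, equated path blocks at the
    across-sex average."""
    x = np.empty(layout.n)
    for i, name in enumerate(layout.names):
        if name in src.layout.names:
            x[i] = src.x[src.layout.index(name)]
        elif name in _NULL_CROSS:
            x[i] = _NULL_CROSS[name]
        elif name.endswith("_MF"):
            base = name[:-3]
            vals = [src.x[src.layout.index(f"{base}_{s}")]
                    for s in src.layout.sexes if f"{base}_{s}" in src.layout.names]
            x[i] = float(np.mean(vals))
        else:
            raise KeyError(f"cannot seed start value for {name}")
    lo = np.array([b[0] for b in layout.bounds])
    hi = np.array([b[1] for b in layout.bounds])
    return np.clip(x, lo, hi)


def fit_ladder(data, *, seed: int | None = None, n_restarts: int = 5):
    """Fit HetACEg, HetACEc, HetACE and HomoACE; run the paper-order
    comparisons (HetACE vs each qualitative model, HomoACE vs HetACE).

    The qualitative models are warm-started at the HetACE optimum (with G/H
    at their null values), so their -2LL can never exceed HetACE's."""
    if isinstance(data, list):
        data = compile_families(data)
    fits = {}
    fits["HetACE"] = fit(data, "HetACE", seed=seed, n_restarts=n_restarts)
    sexes = data.sexes_present()
    for v in ("HetACEg", "HetACEc", "HomoACE"):
        layout = ParamLayout(variant=v, sexes=sexes)
        start = _embed_start(fits["HetACE"], layout)
        fits[v] = fit(data, v, seed=seed, n_restarts=n_restarts, start=start)
        # a richer model must fit at least as well as the nested optimum
        if v != "HomoACE" and fits[v].minus2ll > fits["HetACE"].minus2ll:
            fits[v].minus2ll = fits["HetACE"].minus2ll
            fits[v].x = _embed_start(fits["HetACE"], layout)
            fits[v].chol, fits[v].cross, fits[v].thresholds = layout.unpack(fits[v].x)
    fits = {v: fits[v] for v in VARIANTS}
    comparisons = [
        compare(fits["HetACE"], fits["HetACEg"]),
        compare(fits["HetACE"], fits["HetACEc"]),
        compare(fits["HomoACE"], fits["HetACE"]),
    ]
    selected, trail = select_best(comparisons)
    return fits, comparisons, selected, trail
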