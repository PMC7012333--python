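"""Variance-component inference and reporting.

Turns fitted Cholesky paths into the quantities of scientific interest:
standardized variance proportions (a2, c2, e2) per trait and sex, the
component correlations rA/rC/rE between the traits, the decomposition of
the phenotypic correlation into component "bridges"
(bridge_X = sqrt(x2_trait1 * x2_trait2) * rX, summing to r_ph), and
profile-likelihood confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, minimize
from scipy.stats import chi2

from .fit import FitResult, _objective
from .model import compile_families
from .params import CholeskySet

__all__ = [
    "VarianceDecomposition",
    "standardize",
    "component_correlation",
    "decompose_rph",
    "decomposition_from_fit",
    "profile_interval",
    "profile_ci",
    "render_report",
]

_COMPONENTS = ("a", "c", "e")


def standardize(chol: CholeskySet, sex: str) -> dict:
    """Standardized variance proportions per trait.

    For trait j, x2_j = (X @ X.T)_jj / total_jj summed over A, C, E;
    proportions sum to 1 per trait by construction.
    """
    sigmas = {k: chol.component(k, sex) for k in _COMPONENTS}
    total = np.diag(sum(sigmas.values()))
    if np.any(total <= 0):
        raise ValueError("zero total variance for a trait")
    return {
        k: tuple(float(np.diag(s)[j] / total[j]) for j in (0, 1))
        for k, s in sigmas.items()
    }


def component_correlation(chol: CholeskySet, sex: str, component: str) -> float | None:
    """Correlation between the traits' latent factors for one component;
    None when either trait has no variance of that component (undefined,
    deliberately not reported as 0)."""
    s = chol.component(component, sex)
    v1, v2 = s[0, 0], s[1, 1]
    if v1 <= 1e-12 or v2 <= 1e-12:
        return None
    return float(s[0, 1] / np.sqrt(v1 * v2))


@dataclass
class VarianceDecomposition:
    sex: str
    a2: tuple
    c2: tuple
    e2: tuple
    rA: float | None
    rC: float | None
    rE: float | None
    r_ph: float
    bridges: dict = field(default_factory=dict)
    ci: dict = field(default_factory=dict)


def decompose_rph(decomp: VarianceDecomposition) -> dict:
    """Additive A/C/E bridges to the phenotypic correlation:
    bridge_X = sqrt(x2_t1 * x2_t2) * rX; they sum to r_ph."""
    out = {}
    for comp in _COMPONENTS:
        prop = getattr(decomp, f"{comp}2")
        r = getattr(decomp, f"r{comp.upper()}")
        out[comp] = 0.0 if r is None else float(np.sqrt(prop[0] * prop[1]) * r)
    return out


def decomposition_from_fit(fit: FitResult, sex: str) -> VarianceDecomposition:
    props = standardize(fit.chol, sex)
    rs = {c: component_correlation(fit.chol, sex, c) for c in _COMPONENTS}
    total = sum(fit.chol.component(c, sex) for c in _COMPONENTS)
    r_ph = float(total[0, 1] / np.sqrt(total[0, 0] * total[1, 1]))
    d = VarianceDecomposition(
        sex=sex, a2=props["a"], c2=props["c"], e2=props["e"],
        rA=rs["a"], rC=rs["c"], rE=rs["e"], r_ph=r_ph,
    )
    d.bridges = decompose_rph(d)
    return d


# --------------------------------------------------------------------------
# profile-likelihood intervals

def profile_interval(fun, x_hat, index: int, bounds, level: float = 0.95,
                     f_min: float | None = None) -> tuple[float, float]:
    """Profile CI of ``x[index]`` for an arbitrary -2LL function.

    At each trial value the remaining arguments are re-optimized; the
    bounds are where the profile -2LL exceeds its minimum by the chi2(1)
    quantile (3.84 at 95%).  Interval ends at a box boundary are returned
    censored at that boundary (one-sided interval).
    """
    x_hat = np.asarray(x_hat, dtype=float)
    q = float(chi2.ppf(level, 1))
    if f_min is None:
        f_min = fun(x_hat)
    target = f_min + q
    free = [i for i in range(x_hat.size) if i != index]

    def profile(v):
        if not free:
            return fun(np.array([v]))
        def sub(z):
            x = x_hat.copy()
            x[index] = v
            x[free] = z
            return fun(x)
        res = minimize(sub, x_hat[free], method="L-BFGS-B",
                       bounds=[bounds[i] for i in free],
                       options={"ftol": 1e-11, "maxiter": 300})
        return float(res.fun)

    lo_b, hi_b = bounds[index]
    out = []
    for direction, limit in ((-1.0, lo_b), (1.0, hi_b)):
        span = abs(limit - x_hat[index])
        if span <= 1e-12:
            out.append(float(limit))
            continue
        # expand until the profile crosses the target, then bisect
        step, prev, crossed = span / 8.0, x_hat[index], False
        v = x_hat[index]
        for _ in range(12):
            v = x_hat[index] + direction * min(step, span)
            if profile(v) > target:
                crossed = True
                break
            if abs(v - limit) < 1e-12:
                break
            prev = v
            step *= 1.8
        if not crossed:
            out.append(float(limit))
            continue
        g = lambda t: profile(t) - target
        a, b = (v, prev) if v < prev else (prev, v)
        out.append(float(brentq(g, a, b, xtol=1e-4)))
    return out[0], out[1]


def profile_ci(data, fit: FitResult, parameter: str, level: float = 0.95):
    """Profile CI of a named internal parameter of a converged fit.

    ``parameter`` is one of fit.layout.names (e.g. "t_F", "a21_F",
    "beta_age", "G11").
    """
    if not fit.converged:
        raise ValueError("profile CI requires a converged fit")
    if isinstance(data, list):
        data = compile_families(data)
    fun = _objective(fit.layout, data)
    idx = fit.layout.index(parameter)
    return profile_interval(fun, fit.x, idx, fit.layout.bounds, level=level,
                            f_min=fit.minus2ll)


# --------------------------------------------------------------------------
# rendering

def _fmt_pct(v: float) -> str:
    return f"{100 * v:.0f}%"


def render_report(fits: dict, decomps: list, comparisons: list,
                  selected: str = "", trail: list = ()) -> str:
    """Deterministic markdown report: ladder fit table, comparisons,
    per-sex standardized decompositions and phenotypic-correlation bridges."""
    lines = ["# Bivariate ACE sex-limitation model report", ""]
    lines.append("## Model ladder")
    lines.append("")
    lines.append("| model | -2LL | df | AIC | converged |")
    lines.append("|---|---|---|---|---|")
    for name, f in fits.items():
        lines.append(f"| {name} | {f.minus2ll:.2f} | {f.df} | {f.aic:.2f} "
                     f"| {f.converged} |")
    if comparisons:
        lines += ["", "## Comparisons", "",
                  "| nested | reference | chi2 | ddf | p | dAIC |", "|---|---|---|---|---|---|"]
        for c in comparisons:
            lines.append(f"| {c.nested} | {c.reference} | {c.chi2:.2f} "
                         f"| {c.delta_df} | {c.p_value:.3g} | {c.delta_aic:+.2f} |")
    if selected:
        lines += ["", f"**Selected model:** {selected}", ""]
        for t in trail:
            lines.append(f"- {t}")
    if decomps:
        lines += ["", "## Standardized variance components", "",
                  "| sex | trait | a2 | c2 | e2 |", "|---|---|---|---|---|"]
        for d in decomps:
            for j, trait in enumerate(("t2dm (liability)", "depression")):
                lines.append(f"| {d.sex} | {trait} | {_fmt_pct(d.a2[j])} "
                             f"| {_fmt_pct(d.c2[j])} | {_fmt_pct(d.e2[j])} |")
        lines += ["", "| sex | rA | rC | rE | r_ph | A-bridge | C-bridge | E-bridge |",
                  "|---|---|---|---|---|---|---|---|"]
        for d in decomps:
            def _f(v):
                return "undef" if v is None else f"{v:.2f}"
            lines.append(
                f"| {d.sex} | {_f(d.rA)} | {_f(d.rC)} | {_f(d.rE)} | {d.r_ph:.2f} "
                f"| {d.bridges.get('a', 0):.3f} | {d.bridges.get('c', 0):.3f} "
                f"| {d.bridges.get('e', 0):.3f} |")
    return "\n".join(lines) + "\n"
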