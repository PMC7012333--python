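"""Zygosity- and sex-stratified correlations.

Latent correlations (tetrachoric for binary-binary, polyserial for
binary-continuous) are maximum-likelihood estimates under a bivariate
normal with thresholds fixed at the normal quantiles of the observed
margins; their confidence intervals are profile-likelihood based, so they
respect the [-1, 1] boundary.  Continuous-continuous cells use the Pearson
product-moment correlation with its standard (Fisher-z) interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize_scalar
from scipy.stats import chi2, norm, pearsonr

from .bvn import bvn_cdf
from .prep import PreparedFamily

__all__ = [
    "CorrelationEstimate",
    "tetrachoric",
    "polyserial",
    "pearson",
    "stratified_correlations",
]

_RMAX = 0.9999
_CHI2_95 = float(chi2.ppf(0.95, 1))


@dataclass
class CorrelationEstimate:
    r: float
    ci_low: float
    ci_high: float
    kind: str          # tetrachoric | polyserial | pearson
    n: int             # sampling units (pairs for cross-twin cells)
    boundary: bool = False
    low_n: bool = False

    def __repr__(self):
        flag = " (boundary)" if self.boundary else ""
        return (f"{self.kind} r = {self.r:.3f} "
                f"[{self.ci_low:.3f}, {self.ci_high:.3f}], n = {self.n}{flag}")


def _profile_interval(m2ll, r_hat: float, lo: float = -_RMAX, hi: float = _RMAX):
    """Profile-likelihood 95% bounds of a scalar correlation: the points
    where the -2 log-likelihood rises by the chi2(1) 95% quantile."""
    f0 = m2ll(r_hat)
    target = f0 + _CHI2_95

    def g(r):
        return m2ll(r) - target

    ci_lo = lo if g(lo) <= 0 else brentq(g, lo, r_hat, xtol=1e-6)
    ci_hi = hi if g(hi) <= 0 else brentq(g, r_hat, hi, xtol=1e-6)
    return float(ci_lo), float(ci_hi)


def tetrachoric(counts) -> CorrelationEstimate:
    """ML tetrachoric correlation from a 2x2 table (rows: first variable
    0/1, columns: second variable 0/1), thresholds fixed at the margins."""
    t = np.asarray(counts, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("counts must be a non-negative 2x2 table")
    n = t.sum()
    if n == 0 or np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("tetrachoric correlation is not identified with a zero margin")
    boundary = bool(np.any(t == 0))
    if boundary:
        warnings.warn("empty cell: estimate lies at or near the boundary")
    h = norm.ppf(t[0].sum() / n)   # P(first = 0)
    k = norm.ppf(t[:, 0].sum() / n)

    def m2ll(r):
        p00 = float(bvn_cdf(h, k, r))
        p01 = float(norm.cdf(h)) - p00
        p10 = float(norm.cdf(k)) - p00
        p11 = 1.0 - float(norm.cdf(h)) - float(norm.cdf(k)) + p00
        p = np.array([p00, p01, p10, p11])
        p = np.maximum(p, 1e-12)
        return -2.0 * float(t.ravel() @ np.log(p))

    res = minimize_scalar(m2ll, bounds=(-_RMAX, _RMAX), method="bounded",
                          options={"xatol": 1e-8})
    r_hat = float(res.x)
    lo, hi = _profile_interval(m2ll, r_hat)
    return CorrelationEstimate(r=r_hat, ci_low=lo, ci_high=hi,
                               kind="tetrachoric", n=int(n), boundary=boundary)


def polyserial(d, y) -> CorrelationEstimate:
    """ML polyserial correlation between a binary indicator and a
    continuous variable (threshold fixed at the binary margin)."""
    d = np.asarray(d, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(d) | np.isnan(y))
    d, y = d[ok], y[ok]
    n = d.size
    if n < 10:
        raise ValueError("need at least 10 complete observations")
    if len(np.unique(d)) < 2:
        raise ValueError("both classes of the binary variable must be present")
    sy = float(np.std(y))
    if sy == 0:
        raise ValueError("continuous variable is constant")
    z = (y - float(np.mean(y))) / sy
    tau = float(norm.ppf(1.0 - d.mean()))  # P(d=1) above the threshold
    sgn = 1.0 - 2.0 * d  # +1 for d=0

    def m2ll(r):
        # latent | z ~ N(r z, 1 - r^2); the marginal density of z does not
        # involve r, so only the conditional tail term is profiled.
        s = np.sqrt(max(1.0 - r * r, 1e-12))
        return -2.0 * float(np.sum(norm.logcdf(sgn * (tau - r * z) / s)))

    res = minimize_scalar(m2ll, bounds=(-_RMAX, _RMAX), method="bounded",
                          options={"xatol": 1e-8})
    r_hat = float(res.x)
    boundary = abs(r_hat) >= _RMAX - 1e-4
    lo, hi = _profile_interval(m2ll, r_hat)
    return CorrelationEstimate(r=r_hat, ci_low=lo, ci_high=hi,
                               kind="polyserial", n=int(n), boundary=boundary)


def pearson(x, y) -> CorrelationEstimate:
    """Product-moment correlation with its standard 95% interval."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    res = pearsonr(x, y)
    ci = res.confidence_interval(0.95)
    return CorrelationEstimate(r=float(res.statistic), ci_low=float(ci.low),
                               ci_high=float(ci.high), kind="pearson", n=x.size)


def _safe(est_fun, *args, n_pairs=None, **kw):
    try:
        est = est_fun(*args, **kw)
    except ValueError:
        return None
    if n_pairs is not None:
        est.n = n_pairs
        est.low_n = n_pairs < 20
    else:
        est.low_n = est.n < 20
    return est


def stratified_correlations(families: list[PreparedFamily]) -> pd.DataFrame:
    """Twin-correlation table: per zygosity-sex group, the cross-twin
    within-trait and cross-trait correlations, plus pooled within-person
    (phenotypic) cross-trait correlations per sex.

    Cross-twin cross-trait cells are double-entered (twin 1 trait 1 vs
    twin 2 trait 2, pooled with the mirror pairing) with n counted as
    pairs.  Groups with fewer than 20 pairs are flagged low_n.
    """
    rows = []
    pair_groups: dict = {}
    for fam in families:
        if len(fam.members) == 2:
            pair_groups.setdefault(fam.group, []).append(fam.members)

    for group, pairs in sorted(pair_groups.items()):
        d1 = np.array([np.nan if p[0].d is None else p[0].d for p in pairs], dtype=float)
        d2 = np.array([np.nan if p[1].d is None else p[1].d for p in pairs], dtype=float)
        y1 = np.array([np.nan if p[0].y is None else p[0].y for p in pairs], dtype=float)
        y2 = np.array([np.nan if p[1].y is None else p[1].y for p in pairs], dtype=float)
        npairs = len(pairs)

        ok = ~(np.isnan(d1) | np.isnan(d2))
        if ok.sum():
            tab = np.array([[(1 - d1[ok]) @ (1 - d2[ok]), (1 - d1[ok]) @ d2[ok]],
                            [d1[ok] @ (1 - d2[ok]), d1[ok] @ d2[ok]]])
            est = _safe(tetrachoric, tab, n_pairs=int(ok.sum()))
            rows.append((group, "t2dm", "cross_twin", est))
        est = _safe(pearson, y1, y2)
        rows.append((group, "depression", "cross_twin", est))
        # double-entered cross-twin cross-trait
        dd = np.concatenate([d1, d2])
        yy = np.concatenate([y2, y1])
        est = _safe(polyserial, dd, yy, n_pairs=npairs)
        rows.append((group, "t2dm-depression", "cross_twin_cross_trait", est))

    # pooled phenotypic (within-person) correlation per sex
    for sex in ("M", "F"):
        d, y = [], []
        for fam in families:
            for m in fam.members:
                if m.sex == sex:
                    d.append(np.nan if m.d is None else m.d)
                    y.append(np.nan if m.y is None else m.y)
        est = _safe(polyserial, np.array(d), np.array(y))
        rows.append((f"all_{sex}", "t2dm-depression", "within_person", est))

    out = pd.DataFrame(
        [dict(group=g, traits=t, cell=c,
              r=np.nan if e is None else e.r,
              ci_low=np.nan if e is None else e.ci_low,
              ci_high=np.nan if e is None else e.ci_high,
              kind="" if e is None else e.kind,
              n=0 if e is None else e.n,
              low_n=False if e is None else e.low_n)
         for g, t, c, e in rows]
    )
    return out
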