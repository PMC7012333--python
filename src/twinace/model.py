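"""Joint ordinal-continuous FIML likelihood for twin families.

Each family contributes the marginal likelihood of its observed elements
of the vector (d1, y1, d2, y2): observed continuous elements enter through
their multivariate normal density, and observed binary elements through
the conditional (given the continuous elements) normal probability of the
liability orthant implied by the threshold model.  Conditioning on the
continuous elements is analytic, so no integral beyond the bivariate
normal CDF is ever needed.  Missing elements are marginalized out
(missing-at-random is assumed).

Families are compiled into blocks sharing (group, missingness pattern) so
one likelihood evaluation is a handful of vectorized operations rather
than a per-family loop.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .bvn import bvn_cdf
from .params import (
    CholeskySet,
    CrossSexStructure,
    ThresholdModel,
    expected_pair_covariance,
    within_person_covariance,
)
from .prep import PreparedFamily

__all__ = ["CompiledData", "compile_families", "family_loglik", "total_minus2ll", "block_loglik"]

_LOG_FLOOR = 1e-300
_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class _Block:
    group: str          # pair group or "SGL"
    sexes: tuple        # sex per member
    pattern: tuple      # observed mask over (d1, y1[, d2, y2])
    d: np.ndarray       # (n, n_bin) binary values
    y: np.ndarray       # (n, n_cont) continuous values
    age_bin: np.ndarray  # (n, n_bin) age of the member owning each binary
    n_members: int


@dataclass
class CompiledData:
    blocks: list
    n_families: int
    n_observed_statistics: int

    def groups_present(self):
        return sorted({b.group for b in self.blocks})

    def sexes_present(self):
        out = set()
        for b in self.blocks:
            out.update(b.sexes)
        return tuple(s for s in ("M", "F") if s in out)


def compile_families(families: list[PreparedFamily]) -> CompiledData:
    """Bucket families by (group/sex, observed pattern) into dense arrays."""
    buckets: dict = {}
    n_obs = 0
    for fam in families:
        k = len(fam.members)
        if k not in (1, 2):
            raise ValueError(f"family {fam.family_id}: needs 1 or 2 members")
        mask = tuple(fam.mask)
        n_obs += sum(mask)
        if not any(mask):
            continue  # nothing observed; contributes nothing
        sexes = tuple(m.sex for m in fam.members)
        group = fam.group if k == 2 else f"SGL{sexes[0]}"
        key = (group, sexes, mask)
        d_row, y_row, ab_row = [], [], []
        for m in fam.members:
            if m.d is not None:
                d_row.append(float(m.d))
                ab_row.append(m.age)
            if m.y is not None:
                y_row.append(m.y)
        buckets.setdefault(key, []).append((d_row, y_row, ab_row))
    blocks = []
    for (group, sexes, mask), rows in buckets.items():
        d = np.array([r[0] for r in rows], dtype=float)
        y = np.array([r[1] for r in rows], dtype=float)
        ab = np.array([r[2] for r in rows], dtype=float)
        blocks.append(
            _Block(group=group, sexes=sexes, pattern=mask, d=d, y=y,
                   age_bin=ab, n_members=len(sexes))
        )
    return CompiledData(blocks=blocks, n_families=len(families),
                        n_observed_statistics=n_obs)


def _mvn_logpdf_rows(y, mu, sigma):
    """Log-density of the rows of y under N(mu, sigma), small k."""
    k = sigma.shape[0]
    L = np.linalg.cholesky(sigma)
    dev = (y - mu).T  # (k, n)
    sol = np.linalg.solve(L, dev)
    quad = np.sum(sol ** 2, axis=0)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    return -0.5 * (k * _LOG2PI + logdet + quad)


def block_loglik(block: _Block, chol: CholeskySet, cross: CrossSexStructure,
                 thr: ThresholdModel) -> np.ndarray:
    """Per-family log-likelihood contributions of one compiled block."""
    if block.n_members == 2:
        sigma = expected_pair_covariance(chol, block.group, cross)
        mu = np.array([0.0, thr.dep_mean[block.sexes[0]],
                       0.0, thr.dep_mean[block.sexes[1]]])
        bin_idx_all, cont_idx_all = (0, 2), (1, 3)
        member_of = (0, 0, 1, 1)
    else:
        sex = block.sexes[0]
        sigma = within_person_covariance(chol, sex)
        mu = np.array([0.0, thr.dep_mean[sex]])
        bin_idx_all, cont_idx_all = (0,), (1,)
        member_of = (0, 0)

    obs = [i for i, o in enumerate(block.pattern) if o]
    bins = [i for i in obs if i in bin_idx_all]
    conts = [i for i in obs if i in cont_idx_all]
    n = block.d.shape[0] if len(bins) else block.y.shape[0]
    ll = np.zeros(n)

    sig_cc = sigma[np.ix_(conts, conts)] if conts else None
    if conts:
        ll += _mvn_logpdf_rows(block.y, mu[conts], sig_cc)

    if not bins:
        return ll

    sig_bb = sigma[np.ix_(bins, bins)]
    if conts:
        sig_bc = sigma[np.ix_(bins, conts)]
        solve = np.linalg.solve(sig_cc, sig_bc.T)      # (nc, nb)
        cond_cov = sig_bb - sig_bc @ solve
        cond_mean = mu[bins] + (block.y - mu[conts]) @ solve  # (n, nb)
    else:
        cond_cov = sig_bb
        cond_mean = np.broadcast_to(mu[bins], (n, len(bins)))

    # member-specific age-dependent thresholds
    tau = np.empty_like(block.d)
    for j, idx in enumerate(bins):
        sex = block.sexes[member_of[idx]]
        tau[:, j] = thr.threshold[sex] + thr.beta_age * block.age_bin[:, j]

    sd = np.sqrt(np.diag(cond_cov))
    z = (tau - cond_mean) / sd
    sgn = 1.0 - 2.0 * block.d  # +1 for d=0 (below threshold), -1 for d=1

    if len(bins) == 1:
        ll += norm.logcdf(sgn[:, 0] * z[:, 0])
        return ll

    rho = float(cond_cov[0, 1] / (sd[0] * sd[1]))
    rho = min(max(rho, -1.0), 1.0)
    u1, u2 = sgn[:, 0] * z[:, 0], sgn[:, 1] * z[:, 1]
    same = sgn[:, 0] * sgn[:, 1] > 0
    p = np.empty(n)
    if same.any():
        p[same] = bvn_cdf(u1[same], u2[same], rho)
    if (~same).any():
        p[~same] = bvn_cdf(u1[~same], u2[~same], -rho)
    if np.any(p < _LOG_FLOOR):
        warnings.warn("orthant probability underflow; log floored at 1e-300")
    ll += np.log(np.maximum(p, _LOG_FLOOR))
    return ll


def family_loglik(family: PreparedFamily, chol: CholeskySet,
                  cross: CrossSexStructure | None = None,
                  thr: ThresholdModel | None = None) -> float:
    """Log-likelihood contribution of a single family (convenience path)."""
    cross = cross or CrossSexStructure()
    if thr is None:
        raise ValueError("a ThresholdModel is required")
    data = compile_families([family])
    if not data.blocks:
        raise ValueError("family has no observed elements")
    return float(block_loglik(data.blocks[0], chol, cross, thr)[0])


def total_minus2ll(data: CompiledData | list, chol: CholeskySet,
                   cross: CrossSexStructure | None = None,
                   thr: ThresholdModel | None = None) -> float:
    """-2 log-likelihood of the whole sample (families independent)."""
    if isinstance(data, list):
        data = compile_families(data)
    cross = cross or CrossSexStructure()
    total = 0.0
    for block in data.blocks:
        total += float(np.sum(block_loglik(block, chol, cross, thr)))
    return -2.0 * total
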