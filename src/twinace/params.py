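"""Parameter containers for the bivariate ACE sex-limitation model.

Trait 1 is the liability of the binary trait (unit variance by convention,
so that the threshold model is identified); trait 2 is the continuous trait
(here, the log-transformed, age- and sex-regressed depression residual).
Paths are lower-triangular 2x2 Cholesky factors per sex, so each component
covariance x @ x.T is positive semi-definite by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "SEXES",
    "PAIR_GROUPS",
    "GROUP_SEXES",
    "CholeskySet",
    "CrossSexStructure",
    "ThresholdModel",
    "ModelSpec",
    "VARIANTS",
    "expected_pair_covariance",
    "within_person_covariance",
]

SEXES = ("M", "F")
PAIR_GROUPS = ("MZM", "MZF", "DZM", "DZF", "DZOS")
#: sexes of (member 1, member 2); opposite-sex pairs are ordered male-first
GROUP_SEXES = {
    "MZM": ("M", "M"),
    "MZF": ("F", "F"),
    "DZM": ("M", "M"),
    "DZF": ("F", "F"),
    "DZOS": ("M", "F"),
}

VARIANTS = ("HetACEg", "HetACEc", "HetACE", "HomoACE")


def _as_lower(x, name: str) -> np.ndarray:
    m = np.asarray(x, dtype=float)
    if m.shape != (2, 2):
        raise ValueError(f"{name} must be 2x2, got {m.shape}")
    if abs(m[0, 1]) > 1e-12:
        raise ValueError(f"{name} must be lower-triangular")
    return m


@dataclass(frozen=True)
class CholeskySet:
    """Per-sex lower-triangular path matrices for the A, C and E components."""

    a: Mapping[str, np.ndarray]
    c: Mapping[str, np.ndarray]
    e: Mapping[str, np.ndarray]

    def __post_init__(self):
        for comp in ("a", "c", "e"):
            d = {s: _as_lower(m, f"{comp}[{s}]") for s, m in getattr(self, comp).items()}
            object.__setattr__(self, comp, d)

    def sexes(self) -> tuple[str, ...]:
        return tuple(self.a)

    def component(self, comp: str, sex: str) -> np.ndarray:
        """Component covariance x @ x.T for comp in {'a','c','e'}."""
        x = getattr(self, comp)[sex]
        return x @ x.T

    def liability_variance(self, sex: str) -> float:
        return float(sum(self.component(k, sex)[0, 0] for k in ("a", "c", "e")))

    def validate(self, atol: float = 1e-6) -> None:
        for s in self.sexes():
            v = self.liability_variance(s)
            if abs(v - 1.0) > atol:
                raise ValueError(
                    f"liability variance must be 1 (sex {s}: a11^2+c11^2+e11^2 = {v:.6f})"
                )

    @staticmethod
    def homogeneous(a, c, e) -> "CholeskySet":
        """Same paths in both sexes (no quantitative sex differences)."""
        a, c, e = (np.asarray(m, dtype=float) for m in (a, c, e))
        return CholeskySet(a={"M": a, "F": a}, c={"M": c, "F": c}, e={"M": e, "F": e})


@dataclass(frozen=True)
class CrossSexStructure:
    """Cross-sex factor-correlation matrices for opposite-sex DZ pairs.

    ``G`` scales the cross-person additive-genetic block ``a_M @ G @ a_F.T``;
    under the null of no qualitative genetic sex differences G = 0.5*I, the
    value same-sex DZ pairs imply.  ``H`` plays the same role for the common
    environment with null H = I (fully shared household).
    """

    G: np.ndarray = field(default_factory=lambda: 0.5 * np.eye(2))
    H: np.ndarray = field(default_factory=lambda: np.eye(2))
    free_G: bool = False
    free_H: bool = False

    def __post_init__(self):
        for name in ("G", "H"):
            m = np.asarray(getattr(self, name), dtype=float)
            if m.shape != (2, 2):
                raise ValueError(f"{name} must be 2x2")
            if np.any(np.abs(m) > 1.0 + 1e-9):
                raise ValueError(f"{name} entries must lie in [-1, 1]")
            object.__setattr__(self, name, m)


@dataclass(frozen=True)
class ThresholdModel:
    """Liability thresholds and continuous-trait means.

    threshold: per-sex intercept in liability SD units.
    beta_age: slope of the threshold per year of age, shared across sexes.
    dep_mean: per-sex mean of the continuous trait.
    """

    threshold: Mapping[str, float]
    beta_age: float = 0.0
    dep_mean: Mapping[str, float] = field(default_factory=lambda: {"M": 0.0, "F": 0.0})

    def threshold_at(self, sex: str, age) -> np.ndarray:
        return self.threshold[sex] + self.beta_age * np.asarray(age, dtype=float)


@dataclass(frozen=True)
class ModelSpec:
    """One rung of the sex-limitation ladder.

    HetACEg: sex-specific paths, free cross-sex genetic correlations (G).
    HetACEc: sex-specific paths, free cross-sex common-environment correlations (H).
    HetACE:  sex-specific paths, G = 0.5*I and H = I (quantitative differences only).
    HomoACE: all paths equated across sexes.
    """

    variant: str

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; choose from {VARIANTS}")

    @property
    def free_G(self) -> bool:
        return self.variant == "HetACEg"

    @property
    def free_H(self) -> bool:
        return self.variant == "HetACEc"

    @property
    def equate_sexes(self) -> bool:
        return self.variant == "HomoACE"


def within_person_covariance(chol: CholeskySet, sex: str) -> np.ndarray:
    """Phenotypic covariance of (liability, continuous trait) for one person."""
    return sum(chol.component(k, sex) for k in ("a", "c", "e"))


def expected_pair_covariance(
    chol: CholeskySet,
    group: str,
    cross: CrossSexStructure | None = None,
) -> np.ndarray:
    """Model-implied 4x4 covariance of (liab1, y1, liab2, y2) for a twin pair.

    Cross-twin blocks follow the biometric sharing rules: MZ pairs share all
    additive-genetic and common-environment variance, same-sex DZ pairs share
    half the additive-genetic and all common-environment variance, and
    opposite-sex DZ pairs couple the sexes' factors through the G and H
    matrices.  The unique environment E is never shared.
    """
    if group not in GROUP_SEXES:
        raise ValueError(f"unknown zygosity-sex group {group!r}")
    cross = cross or CrossSexStructure()
    s1, s2 = GROUP_SEXES[group]
    w1 = within_person_covariance(chol, s1)
    w2 = within_person_covariance(chol, s2)
    if group.startswith("MZ"):
        x = chol.component("a", s1) + chol.component("c", s1)
    elif group == "DZOS":
        x = (
            chol.a["M"] @ cross.G @ chol.a["F"].T
            + chol.c["M"] @ cross.H @ chol.c["F"].T
        )
    else:
        x = 0.5 * chol.component("a", s1) + chol.component("c", s1)
    top = np.hstack([w1, x])
    bot = np.hstack([x.T, w2])
    return np.vstack([top, bot])
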