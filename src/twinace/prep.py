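"""Phenotype preparation: BDI residualization, glycemic classification,
self-report/biomarker agreement counts, and family assembly.

The analysis variables are (i) the binary self-reported T2DM status, which
enters the model through a liability threshold, and (ii) the continuous
depression score, transformed as log(BDI + 1) and residualized on age and
sex by ordinary least squares over the full sample.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import kurtosis

from .params import GROUP_SEXES

__all__ = [
    "Member",
    "PreparedFamily",
    "transform_bdi",
    "classify_glycemia",
    "venn_summary",
    "pair_assembly",
    "prepare_cohort",
]

log = logging.getLogger(__name__)

HBA1C_CUTOFF = 48.0  # mmol/mol (IFCC), inclusive
FPG_CUTOFF = 7.0     # mmol/L, inclusive


@dataclass
class Member:
    """One family member's model variables (None marks missing)."""

    d: int | None      # binary trait (1 = affected)
    y: float | None    # continuous residual
    age: float
    sex: str


@dataclass
class PreparedFamily:
    """Likelihood unit: 1-2 members; opposite-sex pairs ordered male-first."""

    family_id: str
    group: str  # MZM|MZF|DZM|DZF|DZOS|SGL
    members: list[Member] = field(default_factory=list)

    @property
    def mask(self) -> np.ndarray:
        """Observed-element mask over (d1, y1[, d2, y2])."""
        out = []
        for m in self.members:
            out += [m.d is not None, m.y is not None]
        return np.array(out, dtype=bool)


def transform_bdi(records: pd.DataFrame, transform: str = "log1p",
                  report_kurtosis: bool = True) -> pd.DataFrame:
    """Add column ``y``: residual of the (transformed) BDI score on age and sex.

    Residuals are from one OLS fit over every individual with non-missing
    BDI, age and sex (twins and singletons jointly), so they have mean zero
    by construction and are orthogonal to age and the sex indicator.
    """
    if transform not in ("log1p", "none"):
        raise ValueError("transform must be 'log1p' or 'none'")
    df = records.copy()
    obs = df["bdi"].notna()
    if not obs.any():
        raise ValueError("all BDI values missing; nothing to transform")
    if obs.sum() < 10:
        raise ValueError("need at least 10 non-missing BDI values")
    sub = df.loc[obs]
    if sub["age"].isna().any() or sub["sex"].isna().any():
        raise ValueError("age and sex must be non-missing wherever BDI is present")
    raw = sub["bdi"].to_numpy(dtype=float)
    if (raw < 0).any() or (raw > 63).any():
        raise ValueError("BDI scores must lie in [0, 63]")
    resp = np.log1p(raw) if transform == "log1p" else raw
    if np.ptp(resp) == 0:
        warnings.warn("constant BDI score; residuals are all zero")
        df.loc[obs, "y"] = 0.0
        return df
    X = sm.add_constant(
        np.column_stack([sub["age"].to_numpy(dtype=float),
                         (sub["sex"] == "F").to_numpy(dtype=float)])
    )
    res = sm.OLS(resp, X).fit()
    df.loc[obs, "y"] = res.resid
    if report_kurtosis:
        log.info(
            "BDI excess kurtosis: raw %.2f -> residual %.2f",
            kurtosis(raw, fisher=True), kurtosis(res.resid, fisher=True),
        )
    return df


def classify_glycemia(hba1c: float | None, fpg: float | None):
    """Diagnostic cross-classification: 1 above cutoff (HbA1c >= 48 mmol/mol
    or FPG >= 7.0 mmol/L), 0 if every available marker is below, None
    (indeterminate) when no biomarker is available."""
    h = None if hba1c is None or (isinstance(hba1c, float) and np.isnan(hba1c)) else float(hba1c)
    f = None if fpg is None or (isinstance(fpg, float) and np.isnan(fpg)) else float(fpg)
    if h is None and f is None:
        return None
    for v in (h, f):
        if v is not None and v < 0:
            raise ValueError("biomarker values must be non-negative")
    if (h is not None and h >= HBA1C_CUTOFF) or (f is not None and f >= FPG_CUTOFF):
        return 1
    return 0


def venn_summary(records: pd.DataFrame) -> dict:
    """Self-report x biomarker agreement, conditioning on sample availability.

    Returns, separately for self-reported cases and non-cases: the number
    with at least one biomarker available and, of those, the number above a
    diagnostic cutoff.
    """
    out = {}
    for label, flag in (("self_report_positive", 1), ("self_report_negative", 0)):
        sub = records[records["t2dm"] == flag] if len(records) else records
        n_sampled = n_above = 0
        for _, row in sub.iterrows():
            cls = classify_glycemia(row.get("hba1c"), row.get("fpg"))
            if cls is not None:
                n_sampled += 1
                n_above += cls
        out[label] = {"with_samples": n_sampled, "above_cutoff": n_above}
    return out


def _member_from_row(row) -> Member:
    d = row.get("t2dm")
    y = row.get("y")
    return Member(
        d=None if pd.isna(d) else int(d),
        y=None if pd.isna(y) else float(y),
        age=float(row["age"]),
        sex=str(row["sex"]),
    )


def pair_assembly(records: pd.DataFrame) -> list[PreparedFamily]:
    """Group records into families; singletons become one-member families.

    Opposite-sex pairs are reordered male-first (the covariance-block
    orientation convention); records with partially missing phenotypes are
    kept, with missingness handled downstream by FIML.
    """
    fams = []
    for fid, sub in records.groupby("family_id", sort=True):
        if len(sub) > 2:
            raise ValueError(f"family {fid} has more than 2 members")
        if len(sub) == 2 and sub["member_index"].nunique() != 2:
            raise ValueError(f"family {fid} has duplicate member_index")
        group = str(sub["group"].iloc[0])
        if group != "SGL" and group not in GROUP_SEXES:
            raise ValueError(f"family {fid}: unknown group {group!r}")
        sub = sub.sort_values("member_index")
        members = [_member_from_row(row) for _, row in sub.iterrows()]
        if group == "DZOS" and len(members) == 2 and members[0].sex == "F":
            members = members[::-1]
        if group != "SGL" and group != "DZOS":
            want = GROUP_SEXES.get(group)
            if want and any(m.sex != want[0] for m in members):
                raise ValueError(f"family {fid}: sex inconsistent with group {group}")
        fams.append(PreparedFamily(family_id=str(fid), group=group, members=members))
    return fams


def prepare_cohort(records: pd.DataFrame, transform: str = "log1p") -> list[PreparedFamily]:
    """Full preparation pipeline: BDI transform + residualization, then assembly."""
    return pair_assembly(transform_bdi(records, transform=transform))
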