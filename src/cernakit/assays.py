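"""Bench-assay computations: 2^-ddCT, melanin working curve, follicle density.

These are the small closed-form calculations of the validation and
phenotyping workflow: relative qPCR quantification against a reference gene
and a calibrator group, an ordinary-least-squares melanin standard curve
with inversion to content per gram of fiber, hair-follicle density from a
marked count over a fixed imaged area, and the two-group Student t-test
with the mean +/- SD reporting convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def ddct(ct: pd.DataFrame, calibrator_group: str = "A") -> pd.DataFrame:
    """Per-sample relative expression by the 2^-ddCT method.

    ``ct`` has columns sample_id, group, gene_id, role (target|reference),
    ct.  For each sample, dCT = CT_target - CT_reference (reference CTs
    averaged if several); ddCT subtracts the mean dCT of the calibrator
    group; the returned table has one row per (target gene, sample) with
    ``rel_expr`` = 2^-ddCT.
    """
    required = {"sample_id", "group", "gene_id", "role", "ct"}
    if not required <= set(ct.columns):
        raise ValueError(f"CT table must have columns {sorted(required)}")
    if (ct["ct"] <= 0).any():
        raise ValueError("CT values must be positive")
    ref = ct[ct["role"] == "reference"].groupby("sample_id")["ct"].mean()
    targets = ct[ct["role"] == "target"]
    missing = sorted(set(targets["sample_id"]) - set(ref.index))
    if missing:
        raise ValueError(f"missing reference CT for samples: {missing}")
    if not (ct["group"] == calibrator_group).any():
        raise ValueError(f"calibrator group {calibrator_group!r} is empty")
    rows = []
    for gene, sub in targets.groupby("gene_id"):
        dct = sub["ct"].to_numpy() - ref.loc[sub["sample_id"]].to_numpy()
        dct = pd.Series(dct, index=sub.index)
        calib = dct[sub["group"] == calibrator_group]
        if calib.empty:
            raise ValueError(
                f"calibrator group {calibrator_group!r} has no CT for gene {gene}"
            )
        ddct_vals = dct - calib.mean()
        for (_, row), dd in zip(sub.iterrows(), ddct_vals):
            rows.append((row["sample_id"], row["group"], gene, 2.0 ** (-dd)))
    return pd.DataFrame(rows, columns=["sample_id", "group", "gene_id", "rel_expr"])


@dataclass
class StandardCurve:
    slope: float  # absorbance per (mg/mL)
    intercept: float  # absorbance
    r2: float


def melanin_fit(concentrations, absorbances) -> StandardCurve:
    """OLS working curve absorbance = slope * conc + intercept."""
    conc = np.asarray(concentrations, dtype=float)
    absorb = np.asarray(absorbances, dtype=float)
    if conc.shape != absorb.shape or conc.ndim != 1:
        raise ValueError("concentrations and absorbances must be equal-length vectors")
    if np.unique(conc).size < 3:
        raise ValueError("need at least 3 distinct standard concentrations")
    fit = stats.linregress(conc, absorb)
    return StandardCurve(
        slope=float(fit.slope), intercept=float(fit.intercept), r2=float(fit.rvalue**2)
    )


def melanin_content(
    curve: StandardCurve,
    absorbance: float,
    fiber_mass_mg: float,
    volume_ml: float = 1.0,
) -> float:
    """Melanin content in mg per g fiber from an extract absorbance.

    The curve is inverted (conc = (A - intercept) / slope, floored at 0)
    and scaled by extract volume over fiber mass.  The default 1 mL volume
    matches the NaOH extraction protocol (1 mL of 1 mol/L NaOH per 15-30 mg
    fleece sample).
    """
    if curve.slope == 0:
        raise ValueError("curve slope must be nonzero")
    if fiber_mass_mg <= 0:
        raise ValueError("fiber mass must be positive")
    conc = (absorbance - curve.intercept) / curve.slope
    if conc < 0:
        warnings.warn("absorbance below curve intercept; concentration floored at 0",
                      stacklevel=2)
        conc = 0.0
    return conc * volume_ml / (fiber_mass_mg / 1000.0)


def follicle_density(marked_count: int, area_mm2: float = 9.26) -> float:
    """Hair follicles per mm^2 from a marked count over the imaged area.

    The default area is the single high-quality section image of 9.26 mm^2.
    """
    if marked_count < 0:
        raise ValueError("marked count must be nonnegative")
    if area_mm2 <= 0:
        raise ValueError("area must be positive")
    return marked_count / area_mm2


@dataclass
class GroupComparison:
    t: float
    p: float
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    stars: str

    def summary(self) -> str:
        return (
            f"A: {self.mean_a:.4g}±{self.sd_a:.4g}  "
            f"B: {self.mean_b:.4g}±{self.sd_b:.4g}  "
            f"t={self.t:.4g} p={self.p:.4g}{self.stars}"
        )


def two_group_test(a, b, welch: bool = False) -> GroupComparison:
    """Independent two-sample t-test with mean +/- SD reporting.

    Student's pooled-variance test by default (``welch`` switches to
    Welch's).  Two identical constant groups give t = 0, p = 1 by contract;
    significance stars follow * p<0.05, ** p<0.01.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            t, p = 0.0, 1.0
        else:
            t = float(np.inf) if b.mean() < a.mean() else float(-np.inf)
            p = 0.0
    else:
        res = stats.ttest_ind(a, b, equal_var=not welch)
        t, p = float(res.statistic), float(res.pvalue)
    stars = "**" if p < 0.01 else ("*" if p < 0.05 else "")
    return GroupComparison(
        t=t,
        p=p,
        mean_a=float(a.mean()),
        sd_a=float(a.std(ddof=1)),
        mean_b=float(b.mean()),
        sd_b=float(b.std(ddof=1)),
        stars=stars,
    )
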