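"""Cross-breed aCGH null distribution and the focal-gene outlier statistic.

Array CGH reports, per copy-number-variable site, log2 ratios of sample
DNA abundance against a common reference genome. Plotting one breed's
per-site mean log2 ratio against another's yields a null distribution
for how ordinary copy-number-variable sites co-vary between the breeds;
a focal gene whose point falls far from the fitted regression line — in
units of the null residual standard deviation — has differentiated
between the breeds more than the genome-wide background.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError, ValidationError
from .stats import RegressionFit, ols_fit

__all__ = ["AcghSite", "OutlierResult", "site_means", "cnv_to_log2", "outlier_z"]


@dataclass(frozen=True)
class AcghSite:
    """Per-sample log2 ratios and their per-breed means at one site."""

    site_id: str
    chrom: str
    start: int
    end: int
    log2_by_breed: dict
    mean_log2: dict

    def null_eligible(self, breed_x: str, breed_y: str) -> bool:
        """A site enters the null set only with data in both focal breeds."""
        return (len(self.log2_by_breed.get(breed_x, ())) > 0
                and len(self.log2_by_breed.get(breed_y, ())) > 0)


@dataclass(frozen=True)
class OutlierResult:
    """Residual z of a focal point against the null-site regression."""

    focal_label: str
    breed_x: str
    breed_y: str
    x_value: float
    y_value: float
    fit: RegressionFit
    residual: float
    z_score: float
    n_null_sites: int
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "focal_label": self.focal_label,
            "breed_x": self.breed_x, "breed_y": self.breed_y,
            "x_value": self.x_value, "y_value": self.y_value,
            "slope": self.fit.slope, "intercept": self.fit.intercept,
            "r_squared": self.fit.r_squared,
            "residual": self.residual,
            "residual_mean": self.fit.residual_mean,
            "residual_sd": self.fit.residual_sd,
            "z_score": self.z_score,
            "n_null_sites": self.n_null_sites,
            "degenerate": self.degenerate,
        }


def site_means(raw: pd.DataFrame) -> list[AcghSite]:
    """Aggregate a long-format per-sample aCGH table into per-site means.

    Expects columns site_id, chrom, start, end, breed, sample_id, log2.
    The mean log2 ratio per breed is the arithmetic mean over that
    breed's samples at the site.
    """
    required = {"site_id", "chrom", "start", "end", "breed", "log2"}
    missing = required - set(raw.columns)
    if missing:
        raise ValidationError(f"aCGH table missing columns: {sorted(missing)}")
    log2 = pd.to_numeric(raw["log2"], errors="coerce")
    bad = np.flatnonzero(log2.isna().to_numpy())
    if bad.size:
        raise ValidationError(f"non-numeric log2 ratio at row {bad[0]}")
    df = raw.assign(log2=log2)
    sites = []
    for (site_id, chrom, start, end), grp in df.groupby(
            ["site_id", "chrom", "start", "end"], sort=True):
        by_breed = {b: tuple(v) for b, v in grp.groupby("breed")["log2"]}
        means = {b: float(np.mean(v)) for b, v in by_breed.items()}
        sites.append(AcghSite(site_id=str(site_id), chrom=str(chrom),
                              start=int(start), end=int(end),
                              log2_by_breed=by_breed, mean_log2=means))
    return sites


def cnv_to_log2(mean_diploid_cn: float, reference_diploid_cn: float) -> float:
    """log2 ratio of a mean diploid copy number against the reference count.

    Converts ddPCR-derived copy numbers onto the aCGH scale. The
    reference diploid copy count must be supplied explicitly; there is
    no sensible silent default for an arbitrary gene.
    """
    if mean_diploid_cn <= 0 or reference_diploid_cn <= 0:
        raise InputError("copy numbers must be positive to take a log ratio")
    return math.log2(mean_diploid_cn / reference_diploid_cn)


def outlier_z(null_sites, focal_x: float, focal_y: float,
              breed_x: str, breed_y: str,
              focal_label: str = "focal") -> OutlierResult:
    """Residual z-score of a focal point against the cross-breed null fit.

    Fits OLS of ``breed_y`` site means on ``breed_x`` site means over
    the null-eligible sites only — the focal point never enters the
    fit — then standardizes the focal vertical residual against the
    null residuals: z = (residual − residual_mean) / residual_sd. With
    an intercept the null residual mean is ~0, so z is effectively the
    residual in null-SD units. Vertical residuals make z depend on
    which breed is on the y axis; run both orientations when the choice
    is not dictated by the data.
    """
    eligible = [s for s in null_sites if s.null_eligible(breed_x, breed_y)]
    if len(eligible) < 3:
        raise InputError(
            f"need >= 3 null sites with data in both {breed_x} and {breed_y}; "
            f"got {len(eligible)}")
    x = np.array([s.mean_log2[breed_x] for s in eligible])
    y = np.array([s.mean_log2[breed_y] for s in eligible])
    fit = ols_fit(x, y)
    residual = focal_y - float(fit.predict(focal_x))
    # a residual SD at floating-point rounding scale means the null sites
    # are collinear: z is undefined, not astronomically large
    tol = 1e-9 * (float(np.abs(y).max()) + 1.0)
    if fit.residual_sd <= tol:
        return OutlierResult(focal_label, breed_x, breed_y, focal_x, focal_y,
                             fit, residual,
                             0.0 if abs(residual) <= tol else math.inf,
                             len(eligible), degenerate=True)
    z = (residual - fit.residual_mean) / fit.residual_sd
    return OutlierResult(focal_label, breed_x, breed_y, focal_x, focal_y,
                         fit, residual, float(z), len(eligible))
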