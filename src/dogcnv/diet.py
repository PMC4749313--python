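"""Diet-group and per-breed copy-number comparisons.

Breeds are assigned diet categories per nutrient (starch, sugar,
phytanic acid); calls are pooled into a high and a low group and
compared with the robust rank-order test (difference in medians) and
the Fligner-Killeen test (difference in variances). The latitude
analysis uses absolute latitude of breed origin as a starch-intake
proxy: copy number is regressed on |latitude| and variance homogeneity
is tested between calls below and at-or-above a split latitude
(default 40°, the historical starch-intake boundary).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError, ValidationError
from .stats import (RegressionFit, TestResult, fligner_killeen_test,
                    fligner_policello_test, ols_fit)

__all__ = [
    "GroupComparison",
    "LatitudeAnalysis",
    "compare_by_diet",
    "breed_summary",
    "proportion_at_least",
    "latitude_analysis",
    "cladogram_overlay",
]


@dataclass(frozen=True)
class GroupComparison:
    """Two-group CNV comparison for one gene and one nutrient."""

    gene: str
    nutrient: str
    breeds_high: tuple[str, ...]
    breeds_low: tuple[str, ...]
    n_high: int
    n_low: int
    mean_high: float
    sd_high: float
    mean_low: float
    sd_low: float
    rro: TestResult
    fk: TestResult
    threshold: int | None = None
    proportion_high: float | None = None
    proportion_low: float | None = None

    def to_dict(self) -> dict:
        d = {
            "gene": self.gene, "nutrient": self.nutrient,
            "breeds_high": list(self.breeds_high), "breeds_low": list(self.breeds_low),
            "n_high": self.n_high, "n_low": self.n_low,
            "mean_high": round(self.mean_high, 1), "sd_high": round(self.sd_high, 1),
            "mean_low": round(self.mean_low, 1), "sd_low": round(self.sd_low, 1),
            "rro": self.rro.to_dict(), "fk": self.fk.to_dict(),
        }
        if self.threshold is not None:
            d["threshold"] = self.threshold
            d["proportion_high"] = round(self.proportion_high, 2)
            d["proportion_low"] = round(self.proportion_low, 2)
        return d


@dataclass(frozen=True)
class LatitudeAnalysis:
    """Regression of copy number on |latitude| plus a variance split."""

    fit: RegressionFit
    split_degrees: float
    n_below: int
    n_above: int
    mean_below: float
    sd_below: float
    mean_above: float
    sd_above: float
    fk: TestResult

    def to_dict(self) -> dict:
        return {
            "split_degrees": self.split_degrees,
            "slope": self.fit.slope, "intercept": self.fit.intercept,
            "r_squared": self.fit.r_squared, "p_slope": self.fit.p_slope,
            "n_below": self.n_below, "n_above": self.n_above,
            "mean_below": round(self.mean_below, 1), "sd_below": round(self.sd_below, 1),
            "mean_above": round(self.mean_above, 1), "sd_above": round(self.sd_above, 1),
            "fk": self.fk.to_dict(),
        }


def _group_values(calls, breeds, gene: str, nutrient: str, grouping: dict):
    """Split a gene's calls into (high_values, low_values, high_breeds, low_breeds).

    ``grouping`` maps a diet category ('high'/'moderate'/'low') to a side
    ('high' or 'low'); breeds whose category is unmapped are excluded.
    """
    category_of = {}
    for b in breeds:
        cat = b.diet_labels.get(nutrient)
        category_of[b.breed.lower()] = cat
    side_values: dict[str, list[int]] = {"high": [], "low": []}
    side_breeds: dict[str, set[str]] = {"high": set(), "low": set()}
    for call in calls:
        if call.gene != gene:
            continue
        key = call.breed.lower()
        if key not in category_of:
            raise ValidationError(f"breed {call.breed!r} has no metadata entry")
        cat = category_of[key]
        if cat is None:
            raise ValidationError(
                f"breed {call.breed!r} has no {nutrient} diet category")
        side = grouping.get(cat)
        if side is None:
            continue
        if side not in ("high", "low"):
            raise InputError(f"grouping maps {cat!r} to unknown side {side!r}")
        side_values[side].append(call.copy_number)
        side_breeds[side].add(call.breed)
    return side_values, side_breeds


def compare_by_diet(calls, breeds, gene: str, nutrient: str,
                    grouping: dict | None = None,
                    threshold: int | None = None) -> GroupComparison:
    """Compare copy number between high- and low-intake diet groups.

    Reports group means and standard deviations (n−1 denominator), the
    robust rank-order test on medians, the Fligner-Killeen test on
    variances, and optionally the per-group proportion of samples at or
    above ``threshold`` copies. The default grouping sends the 'high'
    and 'moderate' categories to the high-intake side and 'low' to the
    low-intake side.
    """
    grouping = grouping or {"high": "high", "moderate": "high", "low": "low"}
    side_values, side_breeds = _group_values(calls, breeds, gene, nutrient, grouping)
    hi = np.array(side_values["high"], dtype=float)
    lo = np.array(side_values["low"], dtype=float)
    if hi.size == 0 or lo.size == 0:
        raise InputError(
            f"empty diet group for {gene}/{nutrient}: "
            f"n_high={hi.size}, n_low={lo.size}")
    rro = fligner_policello_test(lo, hi)  # z > 0 when the high group is larger
    fk = fligner_killeen_test([hi, lo])
    prop_hi = prop_lo = None
    if threshold is not None:
        if threshold < 0:
            raise InputError("threshold must be >= 0")
        prop_hi = float(np.mean(hi >= threshold))
        prop_lo = float(np.mean(lo >= threshold))
    return GroupComparison(
        gene=gene, nutrient=nutrient,
        breeds_high=tuple(sorted(side_breeds["high"])),
        breeds_low=tuple(sorted(side_breeds["low"])),
        n_high=hi.size, n_low=lo.size,
        mean_high=float(hi.mean()), sd_high=float(hi.std(ddof=1)) if hi.size > 1 else 0.0,
        mean_low=float(lo.mean()), sd_low=float(lo.std(ddof=1)) if lo.size > 1 else 0.0,
        rro=rro, fk=fk, threshold=threshold,
        proportion_high=prop_hi, proportion_low=prop_lo,
    )


def breed_summary(calls, gene: str) -> pd.DataFrame:
    """Per-breed n, mean, SD table for one gene.

    SD uses the n−1 denominator and is NaN for single-call breeds.
    Breeds appear in descending mean order; means round to one decimal
    in the formatted column.
    """
    rows = [(c.breed, c.copy_number) for c in calls if c.gene == gene]
    if not rows:
        return pd.DataFrame(columns=["breed", "n", "mean", "sd", "formatted"])
    df = pd.DataFrame(rows, columns=["breed", "copy_number"])
    out = (df.groupby("breed")["copy_number"]
             .agg(n="size", mean="mean", sd=lambda v: v.std(ddof=1))
             .reset_index()
             .sort_values("mean", ascending=False, kind="stable")
             .reset_index(drop=True))
    out["formatted"] = [
        f"{m:.1f}±{s:.1f}" if not math.isnan(s) else f"{m:.1f}±NA"
        for m, s in zip(out["mean"], out["sd"])]
    return out


def proportion_at_least(calls, threshold: int, groups: dict) -> dict:
    """Fraction of calls at or above ``threshold`` copies, per named group.

    ``groups`` maps a group label to the breeds it contains; the result
    maps each label to an exact fraction (numerator/denominator kept as
    a float only at the end).
    """
    if threshold < 0:
        raise InputError("threshold must be >= 0")
    out = {}
    for label, group_breeds in groups.items():
        wanted = {b.lower() for b in group_breeds}
        values = [c.copy_number for c in calls if c.breed.lower() in wanted]
        out[label] = (sum(v >= threshold for v in values) / len(values)
                      if values else float("nan"))
    return out


def latitude_analysis(calls, breeds, gene: str = "AMY2B",
                      split_degrees: float = 40.0) -> LatitudeAnalysis:
    """Latitude as a starch-intake proxy: regression plus a variance split.

    Copy number is regressed on absolute latitude of breed origin; calls
    are then split at ``split_degrees`` of absolute latitude — strictly
    below on one side, at or above on the other — and the two groups'
    variances compared with Fligner-Killeen.
    """
    lat_of = {b.breed.lower(): abs(b.latitude_origin) for b in breeds}
    xs, ys = [], []
    for call in calls:
        if call.gene != gene:
            continue
        key = call.breed.lower()
        if key not in lat_of:
            raise ValidationError(f"breed {call.breed!r} has no latitude")
        xs.append(lat_of[key])
        ys.append(float(call.copy_number))
    x = np.array(xs)
    y = np.array(ys)
    if x.size < 3:
        raise InputError("need >= 3 calls with latitude")
    below = y[x < split_degrees]
    above = y[x >= split_degrees]
    if below.size == 0 or above.size == 0:
        raise InputError(
            f"latitude split at {split_degrees}° leaves an empty group "
            f"(n_below={below.size}, n_above={above.size})")
    fit = ols_fit(x, y)
    fk = fligner_killeen_test([below, above])
    return LatitudeAnalysis(
        fit=fit, split_degrees=split_degrees,
        n_below=below.size, n_above=above.size,
        mean_below=float(below.mean()),
        sd_below=float(below.std(ddof=1)) if below.size > 1 else 0.0,
        mean_above=float(above.mean()),
        sd_above=float(above.std(ddof=1)) if above.size > 1 else 0.0,
        fk=fk,
    )


def cladogram_overlay(tree, summary: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Attach per-breed mean CNV to the cladogram's leaf order.

    Purely descriptive: breeds are listed in the order the tree's leaves
    appear; breeds missing from the tree are appended at the end and
    returned as warnings. The clade path is the chain of internal-node
    labels from root to leaf (empty strings for unlabeled nodes omitted).
    """
    if summary.empty:
        return pd.DataFrame(columns=["breed", "clade_path", "mean"]), []
    by_breed = {r["breed"]: r["mean"] for _, r in summary.iterrows()}
    rows = []
    seen = set()
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label if leaf.taxon else None
        if label not in by_breed:
            continue
        path = [n.label for n in leaf.ancestor_iter() if n.label]
        rows.append({"breed": label, "clade_path": "/".join(reversed(path)),
                     "mean": by_breed[label]})
        seen.add(label)
    warnings = [b for b in by_breed if b not in seen]
    for b in warnings:
        rows.append({"breed": b, "clade_path": "", "mean": by_breed[b]})
    return pd.DataFrame(rows, columns=["breed", "clade_path", "mean"]), warnings
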