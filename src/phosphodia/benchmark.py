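"""Spike-in dilution-series benchmarking of a site quantification matrix.

Given a phosphosite × run abundance matrix produced from a dilution design
(e.g. spike amounts 2, 1, 0.5, 0.2, 0.1 units in triplicate), this module
computes the standard quantification-performance metrics: per-site CV%
within replicate groups, per-site linearity of abundance against spike
amount, per-level median measured ratio against the expected fold change,
and abundance-rank missing-value profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .sitequant import SiteQuantMatrix

__all__ = [
    "DilutionDesign",
    "cv_profile",
    "dilution_linearity",
    "ratio_accuracy",
    "missing_value_profile",
]

DEFAULT_AMOUNTS = (2.0, 1.0, 0.5, 0.2, 0.1)


@dataclass(frozen=True)
class DilutionDesign:
    """Spike amounts per level, replicate layout, and the reference level.

    ``levels`` lists (label, amount) with amounts strictly decreasing; the
    reference defaults to the largest amount so expected ratios against it
    are 1, 2, 4, 10, 20 for the default (2, 1, 0.5, 0.2, 0.1) design.
    """

    levels: tuple[tuple[str, float], ...] = tuple(
        (f"L{a:g}", a) for a in DEFAULT_AMOUNTS
    )
    replicates: int = 3
    reference: str | None = None

    def __post_init__(self) -> None:
        amounts = [a for _, a in self.levels]
        if any(a <= 0 for a in amounts):
            raise ValueError("spike amounts must be strictly positive")
        if any(b >= a for a, b in zip(amounts, amounts[1:])):
            raise ValueError("spike amounts must be strictly decreasing")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.reference is None:
            object.__setattr__(self, "reference", self.levels[0][0])
        elif self.reference not in dict(self.levels):
            raise ValueError(f"reference level {self.reference!r} not in design")

    @property
    def amounts(self) -> dict[str, float]:
        return dict(self.levels)

    @property
    def reference_amount(self) -> float:
        return self.amounts[self.reference]

    def run_ids(self, label: str) -> list[str]:
        """Column names of the replicates of one level: ``{label}_R{i}``."""
        return [f"{label}_R{i}" for i in range(1, self.replicates + 1)]

    def all_run_ids(self) -> list[str]:
        return [r for label, _ in self.levels for r in self.run_ids(label)]

    def expected_ratios(self) -> dict[str, float]:
        """Expected reference/level fold change per level."""
        ref = self.reference_amount
        return {label: ref / amount for label, amount in self.levels}


def _values(matrix: SiteQuantMatrix | pd.DataFrame) -> pd.DataFrame:
    return matrix.values if isinstance(matrix, SiteQuantMatrix) else matrix


def cv_profile(
    matrix: SiteQuantMatrix | pd.DataFrame,
    group: Sequence[str],
    log_space: bool = False,
) -> tuple[pd.Series, float]:
    """Per-site CV% over a replicate group, and the median CV%.

    CV% = 100 · sd / mean on raw abundances (n−1 denominator); sites with
    fewer than two observed values in the group are excluded.  With
    ``log_space`` the geometric CV, 100·sqrt(exp(var(ln x)) − 1), is used.
    """
    df = _values(matrix)[list(group)]
    n_obs = df.notna().sum(axis=1)
    df = df[n_obs >= 2]
    if log_space:
        var_ln = np.log(df).var(axis=1, ddof=1)
        cv = 100.0 * np.sqrt(np.expm1(var_ln))
    else:
        cv = 100.0 * df.std(axis=1, ddof=1) / df.mean(axis=1)
    cv.name = "cv_percent"
    return cv, float(cv.median()) if len(cv) else float("nan")


def dilution_linearity(
    matrix: SiteQuantMatrix | pd.DataFrame,
    design: DilutionDesign,
    log_log: bool = False,
) -> pd.DataFrame:
    """Per-site least-squares fit of mean abundance per level vs spike amount.

    Sites quantified in fewer than 3 levels are skipped (``skipped_reason``
    set).  Returns columns slope, intercept, r_squared, n_levels.  With
    ``log_log`` both axes are log10-transformed before fitting.
    """
    df = _values(matrix)
    level_means = pd.DataFrame(
        {label: df[design.run_ids(label)].mean(axis=1) for label, _ in design.levels}
    )
    amounts = np.array([a for _, a in design.levels])
    rows = []
    for site, means in level_means.iterrows():
        mask = means.notna().to_numpy()
        if mask.sum() < 3:
            rows.append(
                {
                    "site": site,
                    "slope": np.nan,
                    "intercept": np.nan,
                    "r_squared": np.nan,
                    "n_levels": int(mask.sum()),
                    "skipped_reason": "quantified at < 3 levels",
                }
            )
            continue
        x, y = amounts[mask], means.to_numpy()[mask]
        if log_log:
            x, y = np.log10(x), np.log10(y)
        if np.allclose(y, y[0]):
            slope, intercept, r2 = 0.0, float(y[0]), 0.0
        else:
            fit = stats.linregress(x, y)
            slope, intercept, r2 = fit.slope, fit.intercept, fit.rvalue**2
        rows.append(
            {
                "site": site,
                "slope": float(slope),
                "intercept": float(intercept),
                "r_squared": float(r2),
                "n_levels": int(mask.sum()),
                "skipped_reason": "",
            }
        )
    return pd.DataFrame(rows).set_index("site")


def ratio_accuracy(
    matrix: SiteQuantMatrix | pd.DataFrame, design: DilutionDesign
) -> pd.DataFrame:
    """Per-level median measured ratio (reference / level) against expected.

    Replicate abundances are averaged per level first; sites missing at a
    level (or at the reference) are excluded from that level's median.
    """
    df = _values(matrix)
    level_means = pd.DataFrame(
        {label: df[design.run_ids(label)].mean(axis=1) for label, _ in design.levels}
    )
    ref = level_means[design.reference]
    expected = design.expected_ratios()
    rows = []
    for label, _ in design.levels:
        ratio = ref / level_means[label]
        ratio = ratio[ratio.notna()]
        rows.append(
            {
                "level": label,
                "expected_ratio": expected[label],
                "median_ratio": float(ratio.median()) if len(ratio) else np.nan,
                "n_sites": int(len(ratio)),
            }
        )
    return pd.DataFrame(rows).set_index("level")


def missing_value_profile(
    matrix: SiteQuantMatrix | pd.DataFrame,
    replicate_sets: Sequence[str],
    n_groups: int = 3,
) -> pd.DataFrame:
    """Abundance-rank missing-value profile over a replicate group.

    Sites are ranked by mean abundance over observed values and split into
    ``n_groups`` nearly equal groups, G1 (lowest) … Gn (highest); group sizes
    differ by at most one.  Per group, the percentages of sites observed in
    all / some (>1 but not all) / exactly one / none of the replicates are
    reported along with the percentage of missing cells.
    """
    full = _values(matrix)
    df = full[list(replicate_sets)]
    if df.shape[1] < 2:
        raise ValueError("missing-value profile requires >= 2 replicate columns")
    # rank by mean over all observed values; fully missing sites rank lowest
    mean_abundance = full.mean(axis=1)
    order = (
        mean_abundance.reset_index(drop=True)
        .sort_values(kind="stable", na_position="first")
        .index
    )
    sites = df.index[order]
    splits = np.array_split(np.arange(len(sites)), n_groups)
    n_reps = df.shape[1]
    rows = []
    for g, idx in enumerate(splits, start=1):
        sub = df.loc[sites[idx]]
        observed = sub.notna().sum(axis=1)
        n = len(sub)
        n_cells = n * n_reps
        rows.append(
            {
                "group": f"G{g}",
                "n_sites": n,
                "pct_all_replicates": 100.0 * (observed == n_reps).sum() / n,
                "pct_some_replicates": 100.0
                * ((observed > 1) & (observed < n_reps)).sum()
                / n,
                "pct_one_replicate": 100.0 * (observed == 1).sum() / n,
                "pct_none": 100.0 * (observed == 0).sum() / n,
                "pct_missing_cells": 100.0 * sub.isna().sum().sum() / n_cells,
            }
        )
    return pd.DataFrame(rows).set_index("group")
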