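"""Phosphosite localization from fragment-ion evidence.

Positional isomers of a phosphopeptide (same sequence, same phospho count,
different S/T/Y positions) are distinguished by *site-determining ions*:
fragment ions whose theoretical m/z differs between two candidate
configurations.  Each configuration is scored against an observed peak list
with an Ascore-style cumulative-binomial model; configuration scores are
converted to per-site localization probabilities by marginalizing over
configurations, and sites meeting the confidence cutoff (0.75 for DDA and
library-based DIA, 0.99 for library-free DIA) are flagged class 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .masscalc import PHOSPHO_RESIDUES, Peptidoform, fragment_ladder

__all__ = [
    "IsomerConfiguration",
    "PeakList",
    "LocalizationResult",
    "CLASS1_CUTOFFS",
    "enumerate_isomers",
    "site_determining_ions",
    "score_isomers",
    "site_probabilities",
    "classify_class1",
    "localize",
]

#: class-1 probability cutoffs by acquisition/analysis mode (inclusive)
CLASS1_CUTOFFS: dict[str, float] = {"DDA": 0.75, "libDIA": 0.75, "dirDIA": 0.99}


@dataclass(frozen=True)
class IsomerConfiguration:
    """A candidate phospho placement: sorted 1-based S/T/Y positions."""

    stripped_sequence: str
    positions: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "positions", tuple(sorted(self.positions)))
        for p in self.positions:
            if self.stripped_sequence[p - 1] not in PHOSPHO_RESIDUES:
                raise ValueError(f"position {p} is not an S/T/Y residue")

    def peptidoform(self) -> Peptidoform:
        return Peptidoform(self.stripped_sequence).with_phospho(self.positions)


@dataclass(frozen=True)
class PeakList:
    """A centroided spectrum: (mz, intensity) pairs sorted by m/z."""

    peaks: tuple[tuple[float, float], ...]
    precursor_mz: float | None = None
    precursor_charge: int | None = None

    def __post_init__(self) -> None:
        pk = tuple(sorted((float(mz), float(i)) for mz, i in self.peaks))
        if any(mz <= 0 for mz, _ in pk):
            raise ValueError("peak m/z must be strictly positive")
        object.__setattr__(self, "peaks", pk)

    @property
    def mz(self) -> np.ndarray:
        return np.array([m for m, _ in self.peaks])

    @property
    def intensity(self) -> np.ndarray:
        return np.array([i for _, i in self.peaks])


@dataclass(frozen=True)
class LocalizationResult:
    configurations: tuple[IsomerConfiguration, ...]
    scores: Mapping[tuple[int, ...], float]
    configuration_probabilities: Mapping[tuple[int, ...], float]
    site_probability: Mapping[int, float]

    def class1_sites(self, mode: str = "libDIA") -> dict[int, bool]:
        return {
            site: classify_class1(p, mode) for site, p in self.site_probability.items()
        }


def sty_positions(sequence: str) -> tuple[int, ...]:
    return tuple(i for i, aa in enumerate(sequence, 1) if aa in PHOSPHO_RESIDUES)


def enumerate_isomers(stripped_sequence: str, k: int) -> list[IsomerConfiguration]:
    """All C(n_STY, k) phospho placements, in lexicographic position order."""
    if k < 1:
        raise ValueError("phospho count k must be >= 1")
    candidates = sty_positions(stripped_sequence)
    if k > len(candidates):
        raise ValueError(
            f"k={k} exceeds the {len(candidates)} S/T/Y candidate positions"
        )
    return [
        IsomerConfiguration(stripped_sequence, combo)
        for combo in combinations(candidates, k)
    ]


def site_determining_ions(
    config_a: IsomerConfiguration,
    config_b: IsomerConfiguration,
    series_set: Sequence[str] = ("b", "y"),
) -> dict[str, set[int]]:
    """Fragment indices whose theoretical m/z differs between two isomers.

    A b_i ion covers residues 1..i and so discriminates the configurations
    exactly when they place different phospho counts in that prefix; a y_i
    ion covers the C-terminal i residues, symmetrically.  Computed from the
    phospho position sets directly (no ladder evaluation).
    """
    if config_a.stripped_sequence != config_b.stripped_sequence:
        raise ValueError("configurations have different parent sequences")
    if len(config_a.positions) != len(config_b.positions):
        raise ValueError("configurations have different phospho counts")
    n = len(config_a.stripped_sequence)
    out: dict[str, set[int]] = {}
    for series in series_set:
        diff: set[int] = set()
        for i in range(1, n):
            if series == "b":
                in_a = sum(1 for p in config_a.positions if p <= i)
                in_b = sum(1 for p in config_b.positions if p <= i)
            else:
                in_a = sum(1 for p in config_a.positions if p > n - i)
                in_b = sum(1 for p in config_b.positions if p > n - i)
            if in_a != in_b:
                diff.add(i)
        out[series] = diff
    return out


def _top_peaks_per_window(peaks: PeakList, depth: int, window: float = 100.0) -> np.ndarray:
    """m/z values of the ``depth`` most intense peaks per ``window``-Th bin."""
    if not peaks.peaks:
        return np.empty(0)
    mz = peaks.mz
    inten = peaks.intensity
    keep: list[float] = []
    for w in np.unique(np.floor(mz / window)):
        mask = np.floor(mz / window) == w
        idx = np.argsort(inten[mask])[::-1][:depth]
        keep.extend(mz[mask][idx])
    return np.sort(np.array(keep))


def _binomial_score(k: int, n: int, p: float) -> float:
    """−10·log10 P(X ≥ k | n, p); 0 when k = 0."""
    if k <= 0 or n == 0:
        return 0.0
    logsf = stats.binom.logsf(k - 1, n, p)  # log P(X >= k)
    return float(-10.0 * logsf / math.log(10.0))


def score_isomers(
    peaks: PeakList,
    configurations: Sequence[IsomerConfiguration],
    tolerance: float = 0.05,
    depth: int = 10,
    include_neutral_loss: bool = False,
) -> dict[tuple[int, ...], float]:
    """Ascore-style configuration scores against a peak list.

    Peaks are reduced to the ``depth`` most intense per 100 Th window.  For
    each configuration the singly charged b/y ladder is matched within
    ±``tolerance`` Da; with k of n theoretical ions matched the score is
    −10·log10 of the binomial tail P(X ≥ k | n, p), p = depth·2·tolerance/100.
    """
    if not configurations:
        raise ValueError("no configurations to score")
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    kept = _top_peaks_per_window(peaks, depth)
    p_match = depth * (2.0 * tolerance) / 100.0
    scores: dict[tuple[int, ...], float] = {}
    for config in configurations:
        ladder = fragment_ladder(
            config.peptidoform(), ("b", "y"), 1, include_neutral_loss
        )
        theo = np.array([ion.mz for ion in ladder])
        n = len(theo)
        if kept.size:
            left = np.searchsorted(kept, theo - tolerance, side="left")
            right = np.searchsorted(kept, theo + tolerance, side="right")
            k = int(np.count_nonzero(right > left))
        else:
            k = 0
        scores[config.positions] = _binomial_score(k, n, p_match)
    return scores


def site_probabilities(
    scores: Mapping[tuple[int, ...], float],
) -> tuple[dict[tuple[int, ...], float], dict[int, float]]:
    """Configuration weights 10^(score/10), normalized; per-site marginals.

    Returns ``(configuration_probabilities, site_probability)``.  The site
    probabilities sum to the phospho count k.
    """
    if not scores:
        raise ValueError("no configuration scores")
    # subtract the max score before exponentiating to avoid overflow
    top = max(scores.values())
    weights = {c: 10.0 ** ((s - top) / 10.0) for c, s in scores.items()}
    total = sum(weights.values())
    config_prob = {c: w / total for c, w in weights.items()}
    site_prob: dict[int, float] = {}
    for config, prob in config_prob.items():
        for site in config:
            site_prob[site] = site_prob.get(site, 0.0) + prob
    return config_prob, dict(sorted(site_prob.items()))


def classify_class1(prob: float, mode: str = "libDIA") -> bool:
    """True iff ``prob`` meets the class-1 cutoff for ``mode`` (inclusive)."""
    if mode not in CLASS1_CUTOFFS:
        raise ValueError(f"unknown mode {mode!r}; expected one of {sorted(CLASS1_CUTOFFS)}")
    if not 0.0 <= prob <= 1.0:
        raise ValueError("probability must lie in [0, 1]")
    return prob >= CLASS1_CUTOFFS[mode]


def localize(
    peaks: PeakList,
    stripped_sequence: str,
    k: int,
    tolerance: float = 0.05,
    depth: int = 10,
) -> LocalizationResult:
    """Convenience wrapper: enumerate, score, and marginalize in one call."""
    configs = enumerate_isomers(stripped_sequence, k)
    scores = score_isomers(peaks, configs, tolerance=tolerance, depth=depth)
    config_prob, site_prob = site_probabilities(scores)
    return LocalizationResult(tuple(configs), scores, config_prob, site_prob)
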