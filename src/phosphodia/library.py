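"""Hybrid DDA+DIA spectral-library assembly, filtering, and iRT calibration.

A spectral library maps (modified sequence, precursor charge) keys to
annotated fragment spectra with normalized retention times (iRT).  Entries
are filtered by the fragment quality rules (m/z 300–1800, relative intensity
>= 5%, >= 3 residues, top 15 by intensity) and PSM quality thresholds before
DDA and DIA archives are merged into a hybrid library; duplicate precursors
keep the higher-scoring spectrum and are marked as shared.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .masscalc import Peptidoform, format_modified_sequence

__all__ = [
    "LibraryFragment",
    "LibraryEntry",
    "RtCalibration",
    "SpectralLibrary",
    "FRAGMENT_MZ_MIN",
    "FRAGMENT_MZ_MAX",
    "FRAGMENT_MIN_REL_INTENSITY",
    "FRAGMENT_MIN_RESIDUES",
    "FRAGMENT_TOP_N",
    "filter_fragments",
    "qc_filter_psms",
    "fit_irt_calibration",
    "merge_hybrid",
    "library_summary",
]

FRAGMENT_MZ_MIN = 300.0
FRAGMENT_MZ_MAX = 1800.0
FRAGMENT_MIN_REL_INTENSITY = 0.05
FRAGMENT_MIN_RESIDUES = 3
FRAGMENT_TOP_N = 15


@dataclass(frozen=True)
class LibraryFragment:
    series: str
    index: int
    charge: int
    mz: float
    relative_intensity: float
    n_residues: int
    neutral_loss: float = 0.0


@dataclass(frozen=True)
class LibraryEntry:
    peptidoform: Peptidoform
    precursor_mz: float
    precursor_charge: int
    irt: float
    fragments: tuple[LibraryFragment, ...]
    source: str = "DDA"  # DDA | DIA | both
    score: float = 0.0
    protein_accessions: tuple[str, ...] = ()
    site_probabilities: Mapping[int, float] | None = None

    @property
    def key(self) -> tuple[str, int]:
        return (format_modified_sequence(self.peptidoform), self.precursor_charge)


def _sort_fragments(frags: Iterable[LibraryFragment]) -> tuple[LibraryFragment, ...]:
    # descending intensity, ties by ascending m/z
    return tuple(sorted(frags, key=lambda f: (-f.relative_intensity, f.mz)))


def filter_fragments(entry: LibraryEntry) -> LibraryEntry:
    """Apply the library fragment quality rules to one entry.

    Drops fragments outside m/z 300–1800, below 5% relative intensity, or
    with fewer than three residues; keeps at most the 15 most intense
    survivors (intensity ties broken by ascending m/z).  Neutral-loss
    fragments are retained.  Surviving intensities are rescaled so the most
    intense fragment is 1; the operation is idempotent.
    """
    survivors = [
        f
        for f in entry.fragments
        if FRAGMENT_MZ_MIN <= f.mz <= FRAGMENT_MZ_MAX
        and f.relative_intensity >= FRAGMENT_MIN_REL_INTENSITY
        and f.n_residues >= FRAGMENT_MIN_RESIDUES
    ]
    survivors = list(_sort_fragments(survivors)[:FRAGMENT_TOP_N])
    if not survivors:
        warnings.warn(
            f"all fragments of {entry.key} removed by quality filtering", stacklevel=2
        )
        return replace(entry, fragments=())
    top = survivors[0].relative_intensity
    survivors = [
        replace(f, relative_intensity=f.relative_intensity / top) for f in survivors
    ]
    return replace(entry, fragments=tuple(survivors))


#: PSM quality thresholds (all inclusive)
PSM_MIN_SCORE = 40.0
PSM_MIN_DELTA_SCORE = 8.0
PSM_MIN_INTENSITY = 100.0
PSM_MIN_LENGTH = 7

_PSM_FIELDS = ("score", "delta_score", "intensity", "sequence")


def qc_filter_psms(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep PSMs meeting all quality thresholds.

    Requires columns ``score``, ``delta_score``, ``intensity``, ``sequence``.
    Returns ``(kept, rejected)``; ``rejected`` carries a ``reason`` column.
    Records with missing fields are rejected with the field named.
    """
    missing_cols = [c for c in _PSM_FIELDS if c not in records.columns]
    if missing_cols:
        raise ValueError(f"PSM table lacks required column(s): {missing_cols}")
    reasons = pd.Series("", index=records.index, dtype=object)

    def _flag(mask: pd.Series, reason: str) -> None:
        nonlocal reasons
        reasons[mask & (reasons == "")] = reason

    na = records[list(_PSM_FIELDS)].isna().any(axis=1)
    _flag(na, "missing field")
    _flag(~na & (records["score"] < PSM_MIN_SCORE), f"score < {PSM_MIN_SCORE:g}")
    _flag(
        ~na & (records["delta_score"] < PSM_MIN_DELTA_SCORE),
        f"delta score < {PSM_MIN_DELTA_SCORE:g}",
    )
    _flag(
        ~na & (records["intensity"] < PSM_MIN_INTENSITY),
        f"intensity < {PSM_MIN_INTENSITY:g}",
    )
    _flag(
        ~na & (records["sequence"].str.len() < PSM_MIN_LENGTH),
        f"peptide length < {PSM_MIN_LENGTH}",
    )
    rejected = records[reasons != ""].copy()
    rejected["reason"] = reasons[reasons != ""]
    return records[reasons == ""].copy(), rejected


@dataclass(frozen=True)
class RtCalibration:
    """Piecewise-linear mapping between iRT and measured retention time.

    ``boundaries`` are the n_segments+1 iRT knot positions; segment ``j``
    covers ``boundaries[j]..boundaries[j+1]`` with its own slope/intercept
    (RT = slope·iRT + intercept).
    """

    boundaries: tuple[float, ...]
    slopes: tuple[float, ...]
    intercepts: tuple[float, ...]
    r_squared: float

    @property
    def n_segments(self) -> int:
        return len(self.slopes)

    def _segment(self, irt: float) -> int:
        for j in range(self.n_segments - 1):
            if irt < self.boundaries[j + 1]:
                return j
        return self.n_segments - 1

    def predict(self, irt: float | np.ndarray) -> float | np.ndarray:
        """Measured RT predicted from iRT."""
        if np.ndim(irt) > 0:
            return np.array([self.predict(float(x)) for x in np.asarray(irt)])
        j = self._segment(float(irt))
        return self.slopes[j] * float(irt) + self.intercepts[j]

    def inverse(self, rt: float | np.ndarray) -> float | np.ndarray:
        """iRT recovered from measured RT (per-segment linear inversion)."""
        if np.ndim(rt) > 0:
            return np.array([self.inverse(float(x)) for x in np.asarray(rt)])
        # choose the segment whose RT span contains rt; fall back to nearest
        best_j, best_dist = 0, np.inf
        for j, (s, b) in enumerate(zip(self.slopes, self.intercepts)):
            if s == 0:
                continue
            irt = (float(rt) - b) / s
            lo, hi = self.boundaries[j], self.boundaries[j + 1]
            dist = 0.0 if lo <= irt <= hi else min(abs(irt - lo), abs(irt - hi))
            if dist < best_dist:
                best_j, best_dist = j, dist
        s, b = self.slopes[best_j], self.intercepts[best_j]
        return (float(rt) - b) / s


def fit_irt_calibration(
    points: Sequence[tuple[float, float]], n_segments: int = 1
) -> RtCalibration:
    """Least-squares segmented regression of measured RT on iRT.

    The default single segment is ordinary least squares.  With
    ``n_segments > 1``, knots are placed at iRT quantiles and each segment is
    fitted independently on its points (>= 3 points per segment required).
    """
    pts = sorted((float(i), float(r)) for i, r in points)
    if len(pts) < 2:
        raise ValueError("at least 2 calibration points required")
    irt = np.array([p[0] for p in pts])
    rt = np.array([p[1] for p in pts])
    if np.ptp(irt) == 0:
        raise ValueError("degenerate calibration: all iRT values identical")
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    qs = np.quantile(irt, np.linspace(0, 1, n_segments + 1))
    qs[0], qs[-1] = -np.inf, np.inf
    slopes, intercepts = [], []
    pred = np.empty_like(rt)
    for j in range(n_segments):
        mask = (irt >= qs[j]) & (irt < qs[j + 1]) if j < n_segments - 1 else irt >= qs[j]
        need = 2 if n_segments == 1 else 3
        if mask.sum() < need:
            raise ValueError(
                f"segment {j} has {int(mask.sum())} points; >= {need} required"
            )
        slope, intercept = np.polyfit(irt[mask], rt[mask], 1)
        slopes.append(float(slope))
        intercepts.append(float(intercept))
        pred[mask] = slope * irt[mask] + intercept
    ss_res = float(np.sum((rt - pred) ** 2))
    ss_tot = float(np.sum((rt - rt.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    boundaries = [float(irt.min())] + [
        float(np.quantile(irt, q)) for q in np.linspace(0, 1, n_segments + 1)[1:-1]
    ] + [float(irt.max())]
    return RtCalibration(tuple(boundaries), tuple(slopes), tuple(intercepts), r2)


@dataclass
class SpectralLibrary:
    """Library entries keyed by (modified sequence, precursor charge)."""

    entries: dict[tuple[str, int], LibraryEntry] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def provenance_counts(self) -> dict[str, int]:
        counts = {"DDA": 0, "DIA": 0, "both": 0}
        for e in self.entries.values():
            counts[e.source] += 1
        return counts


def merge_hybrid(
    dda_entries: Iterable[LibraryEntry], dia_entries: Iterable[LibraryEntry]
) -> SpectralLibrary:
    """Union of DDA and DIA archives keyed by (modified sequence, charge).

    Keys present in both keep the higher-scoring spectrum with source
    ``"both"``.
    """
    lib = SpectralLibrary()
    for entry in dda_entries:
        lib.entries[entry.key] = replace(entry, source="DDA")
    for entry in dia_entries:
        existing = lib.entries.get(entry.key)
        if existing is None:
            lib.entries[entry.key] = replace(entry, source="DIA")
        else:
            best = entry if entry.score > existing.score else existing
            lib.entries[entry.key] = replace(best, source="both")
    return lib


def library_summary(
    lib: SpectralLibrary,
    site_annotations: Mapping[tuple[str, int], Sequence[str]] | None = None,
    class1_cutoff: float = 0.75,
) -> dict:
    """Composition statistics: counts, pS/pT/pY fractions, class-1 sites.

    ``site_annotations`` optionally maps entry keys to protein-level site
    identifiers (e.g. ``"P00533-S1166"``); without it, sites are counted at
    peptide level as (modified sequence, position) pairs.
    """
    n_precursors = len(lib)
    modified_peptides = {key[0] for key in lib.entries}
    residue_counts = {"S": 0, "T": 0, "Y": 0}
    sites: set = set()
    n_class1 = 0
    for key, entry in lib.entries.items():
        seq = entry.peptidoform.stripped_sequence
        for pos in entry.peptidoform.phospho_positions:
            residue_counts[seq[pos - 1]] += 1
            prob = 1.0
            if entry.site_probabilities is not None:
                prob = entry.site_probabilities.get(pos, 1.0)
            if prob >= class1_cutoff:
                n_class1 += 1
        if site_annotations is not None and key in site_annotations:
            sites.update(site_annotations[key])
        else:
            sites.update((key[0], pos) for pos in entry.peptidoform.phospho_positions)
    proteins = {acc for e in lib.entries.values() for acc in e.protein_accessions}
    total_ph = sum(residue_counts.values())
    fractions = {
        f"p{aa}_fraction": (residue_counts[aa] / total_ph if total_ph else 0.0)
        for aa in "STY"
    }
    return {
        "n_precursors": n_precursors,
        "n_modified_peptides": len(modified_peptides),
        "n_phosphosites": len(sites),
        "n_proteins": len(proteins),
        "n_class1_phospho_groups": n_class1,
        "provenance": lib.provenance_counts,
        **fractions,
    }
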