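"""Phosphosite mapping and precursor-to-site/protein abundance roll-up.

Peptide-level phospho positions are mapped onto protein coordinates
("ACC-S1166"-style keys) using the protein sequence, and precursor areas are
aggregated: a phosphosite's abundance in a run is the *sum* of the areas of
all precursors containing that site at or above the localization-probability
cutoff; protein abundance is the sum over its stripped peptide sequences of
the *mean* precursor area.  Missing values are NaN, never zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .localization import CLASS1_CUTOFFS
from .masscalc import Peptidoform

__all__ = [
    "PrecursorRecord",
    "SiteKey",
    "SiteQuantMatrix",
    "map_sites_to_protein",
    "rollup_phosphosites",
    "rollup_proteins",
    "normalize_runs",
]


@dataclass(frozen=True)
class SiteKey:
    """A phosphosite in protein coordinates (1-based)."""

    accession: str
    residue: str
    position: int

    def __post_init__(self) -> None:
        if self.residue not in "STY":
            raise ValueError(f"site residue must be S/T/Y, got {self.residue!r}")
        if self.position < 1:
            raise ValueError("protein position must be >= 1")

    def __str__(self) -> str:
        return f"{self.accession}-{self.residue}{self.position}"

    @classmethod
    def parse(cls, text: str) -> "SiteKey":
        acc, _, site = text.rpartition("-")
        if not acc or site[0] not in "STY":
            raise ValueError(f"cannot parse site key {text!r}")
        return cls(acc, site[0], int(site[1:]))


@dataclass(frozen=True)
class PrecursorRecord:
    """One quantified precursor in one run."""

    run: str
    peptidoform: Peptidoform
    protein_group: str  # ";"-separated accessions; first is the keying accession
    quantity: float
    rt: float | None = None
    site_probabilities: Mapping[int, float] | None = None  # peptide coords
    mode: str = "libDIA"

    def __post_init__(self) -> None:
        if self.quantity < 0:
            raise ValueError("precursor quantity must be >= 0")
        if self.site_probabilities is not None:
            for pos, prob in self.site_probabilities.items():
                if not 0.0 <= prob <= 1.0:
                    raise ValueError(f"probability {prob} at {pos} outside [0, 1]")
                if not 1 <= pos <= len(self.peptidoform.stripped_sequence):
                    raise ValueError(f"site position {pos} outside peptide")

    @property
    def accessions(self) -> tuple[str, ...]:
        return tuple(a for a in self.protein_group.split(";") if a)

    def probability_for(self, peptide_position: int) -> float:
        """Localization probability for a phospho position; 1.0 when absent.

        Single-candidate peptides commonly carry no explicit probability; they
        are treated as fully localized.
        """
        if self.site_probabilities is None:
            return 1.0
        return self.site_probabilities.get(peptide_position, 1.0)


def map_sites_to_protein(
    pf: Peptidoform, protein_sequence: str, accession: str
) -> tuple[list[SiteKey], bool]:
    """Map the peptide's phospho positions onto protein coordinates.

    Returns ``(site_keys, multi_mapping)``.  All occurrences of the stripped
    sequence are located; keys are issued against the first occurrence and
    ``multi_mapping`` is True when the peptide occurs more than once.
    """
    seq = pf.stripped_sequence
    offsets = []
    start = protein_sequence.find(seq)
    while start != -1:
        offsets.append(start + 1)  # 1-based protein offset of peptide start
        start = protein_sequence.find(seq, start + 1)
    if not offsets:
        raise ValueError(f"peptide {seq!r} not found in protein {accession}")
    offset = offsets[0]
    keys = [
        SiteKey(accession, seq[p - 1], offset + p - 1) for p in pf.phospho_positions
    ]
    return keys, len(offsets) > 1


@dataclass
class SiteQuantMatrix:
    """Phosphosites × runs abundance table with per-site metadata.

    ``values`` holds abundances with NaN for missing (a site not quantified
    in a run is missing, never zero); ``meta`` carries the best localization
    probability, class-1 flags per mode, protein group, and multi-mapping
    flag per site.
    """

    values: pd.DataFrame
    meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def sites(self) -> list[str]:
        return list(self.values.index)

    @property
    def runs(self) -> list[str]:
        return list(self.values.columns)


def rollup_phosphosites(
    records: Iterable[PrecursorRecord],
    protein_sequences: Mapping[str, str],
    cutoff: float | None = None,
    mode: str = "libDIA",
) -> SiteQuantMatrix:
    """Sum precursor areas into phosphosite abundances per run.

    Every precursor containing a phosphosite with localization probability
    >= ``cutoff`` (default: the class-1 cutoff of ``mode``) contributes its
    full area to that site; multi-phospho precursors contribute to every
    qualifying constituent site.  Site keys are issued against the first
    accession of the protein group.
    """
    if cutoff is None:
        if mode not in CLASS1_CUTOFFS:
            raise ValueError(f"unknown mode {mode!r}")
        cutoff = CLASS1_CUTOFFS[mode]
    sums: dict[tuple[str, str], float] = {}
    best_prob: dict[str, float] = {}
    group_of: dict[str, str] = {}
    multimap: dict[str, bool] = {}
    runs: list[str] = []
    for rec in records:
        if rec.run not in runs:
            runs.append(rec.run)
        accession = rec.accessions[0]
        if accession not in protein_sequences:
            raise KeyError(f"no protein sequence for accession {accession!r}")
        keys, multi = map_sites_to_protein(
            rec.peptidoform, protein_sequences[accession], accession
        )
        for pep_pos, key in zip(rec.peptidoform.phospho_positions, keys):
            prob = rec.probability_for(pep_pos)
            skey = str(key)
            if prob > best_prob.get(skey, -1.0):
                best_prob[skey] = prob
            group_of.setdefault(skey, rec.protein_group)
            multimap[skey] = multimap.get(skey, False) or multi
            if prob >= cutoff:
                sums[(skey, rec.run)] = sums.get((skey, rec.run), 0.0) + rec.quantity
    sites = sorted(best_prob)
    values = pd.DataFrame(np.nan, index=sites, columns=runs, dtype=float)
    for (skey, run), total in sums.items():
        values.loc[skey, run] = total
    # drop sites that never met the cutoff in any run
    quantified = sorted({skey for (skey, _) in sums})
    values = values.loc[quantified]
    meta = pd.DataFrame(
        {
            "best_probability": [best_prob[s] for s in quantified],
            "protein_group": [group_of[s] for s in quantified],
            "multi_mapping": [multimap[s] for s in quantified],
        },
        index=quantified,
    )
    for m, cut in CLASS1_CUTOFFS.items():
        meta[f"class1_{m}"] = meta["best_probability"] >= cut
    return SiteQuantMatrix(values, meta)


def rollup_proteins(records: Iterable[PrecursorRecord]) -> pd.DataFrame:
    """Protein abundance per run: sum over peptides of mean precursor area.

    Precursor areas are first averaged within each stripped peptide sequence
    (across charges and modification states), then summed over the protein's
    peptides.  Proteins are keyed by the first accession of the group.
    Missing values are NaN.
    """
    rows = [
        {
            "protein": rec.accessions[0],
            "peptide": rec.peptidoform.stripped_sequence,
            "run": rec.run,
            "quantity": rec.quantity,
        }
        for rec in records
    ]
    if not rows:
        return pd.DataFrame()
    df = pd.DataFrame(rows)
    peptide_area = (
        df.groupby(["protein", "peptide", "run"], sort=False)["quantity"]
        .mean()
        .reset_index()
    )
    protein_area = peptide_area.groupby(["protein", "run"], sort=False)["quantity"].sum()
    out = protein_area.unstack("run")
    return out.reindex(columns=pd.unique(df["run"]))


def normalize_runs(
    matrix: SiteQuantMatrix | pd.DataFrame,
) -> tuple[SiteQuantMatrix | pd.DataFrame, pd.Series]:
    """Global median-centering in log2 space across runs.

    Scaling factors are computed from rows complete in all runs so every
    run's log2 median over those rows is equalized to their grand mean.
    Returns the scaled matrix and the per-run linear scale factors.
    """
    df = matrix.values if isinstance(matrix, SiteQuantMatrix) else matrix
    if df.shape[1] < 2:
        raise ValueError("normalization requires >= 2 runs")
    complete = df.dropna()
    if complete.empty:
        raise ValueError(
            "no rows complete in all runs; relax completeness or impute first"
        )
    log_medians = np.log2(complete).median(axis=0)
    target = log_medians.mean()
    factors = np.power(2.0, target - log_medians)
    scaled = df * factors
    if isinstance(matrix, SiteQuantMatrix):
        return SiteQuantMatrix(scaled, matrix.meta), factors
    return scaled, factors
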