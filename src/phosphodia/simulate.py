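"""Synthetic-data generators for the spike-in benchmark and statistics tests.

The generators emulate the 166-peptide synthetic-phosphopeptide benchmark:
random proteins, a panel of mono/di/tri-phosphopeptides drawn from their
tryptic peptides (default multiplicity counts 139/21/6), a five-level
dilution series (2, 1, 0.5, 0.2, 0.1 units) in triplicate with multiplicative
lognormal noise and abundance-dependent dropout, fragment spectra with known
true phosphosite configurations, and two-group log2 matrices with planted
effects.  Every generator is a pure function of (parameters, seed): the same
seed reproduces identical output.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .benchmark import DilutionDesign
from .localization import IsomerConfiguration, PeakList, enumerate_isomers, sty_positions
from .masscalc import (
    MONOISOTOPIC_RESIDUE_MASS,
    Peptidoform,
    format_modified_sequence,
    fragment_ladder,
    precursor_mz,
)
from .sitequant import PrecursorRecord, SiteQuantMatrix

__all__ = [
    "SimConfig",
    "DropoutModel",
    "PanelEntry",
    "DilutionGroundTruth",
    "make_fasta",
    "tryptic_peptides",
    "make_panel",
    "simulate_dilution_report",
    "simulate_isomer_spectra",
    "simulate_two_group_matrix",
    "noise_sigma",
    "dia_window_index",
]

_AMINO_ACIDS = sorted(MONOISOTOPIC_RESIDUE_MASS)

#: default multiplicity counts of the emulated spike-in panel (mono, di, tri)
DEFAULT_PANEL_COUNTS = (139, 21, 6)


@dataclass(frozen=True)
class DropoutModel:
    """Logistic detection model in log10 abundance.

    Detection probability = 1 / (1 + exp(−steepness·(log10(area) − midpoint)));
    a midpoint above the lowest level's typical abundance concentrates
    missingness in the lowest dilution.
    """

    midpoint: float
    steepness: float = 4.0

    def detection_probability(self, area: float | np.ndarray) -> float | np.ndarray:
        z = self.steepness * (np.log10(area) - self.midpoint)
        return 1.0 / (1.0 + np.exp(-z))


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters; the defaults are the emulated benchmark design."""

    n_proteins: int = 61
    protein_length_range: tuple[int, int] = (150, 400)
    panel_counts: tuple[int, int, int] = DEFAULT_PANEL_COUNTS
    dilution_amounts: tuple[float, ...] = (2.0, 1.0, 0.5, 0.2, 0.1)
    replicates: int = 3
    noise_cv: float = 0.05
    dropout: DropoutModel | None = None
    seed: int = 0

    def design(self) -> DilutionDesign:
        return DilutionDesign(
            tuple((f"L{a:g}", a) for a in self.dilution_amounts),
            replicates=self.replicates,
        )


def noise_sigma(cv: float) -> float:
    """Lognormal sigma giving multiplicative CV ``cv``: sqrt(ln(1 + cv²))."""
    return float(np.sqrt(np.log1p(cv * cv)))


def make_fasta(
    n: int, length_range: tuple[int, int] = (150, 400), seed: int = 0
) -> str:
    """FASTA text of ``n`` random proteins with UniProt-style headers.

    Residues are drawn uniformly; every protein is guaranteed at least one
    S/T/Y.  Headers are ``sp|SIM{i}|SIM{i}_TEST``.  Deterministic per seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = length_range
    rng = np.random.default_rng(seed)
    records = []
    for i in range(1, n + 1):
        length = int(rng.integers(lo, hi + 1))
        while True:
            seq = "".join(rng.choice(_AMINO_ACIDS, size=length))
            if set(seq) & set("STY"):
                break
        records.append(f">sp|SIM{i}|SIM{i}_TEST synthetic protein {i}\n{seq}\n")
    return "".join(records)


def tryptic_peptides(sequence: str) -> list[tuple[int, str]]:
    """Fully tryptic fragments (cleave after K/R, no proline rule, zero
    missed cleavages) as (1-based offset, peptide) pairs."""
    out = []
    start = 0
    for i, aa in enumerate(sequence):
        if aa in "KR" or i == len(sequence) - 1:
            out.append((start + 1, sequence[start : i + 1]))
            start = i + 1
    return out


@dataclass(frozen=True)
class PanelEntry:
    """One panel phosphopeptide with its true site configuration."""

    peptidoform: Peptidoform
    accession: str
    protein_offset: int  # 1-based position of peptide start in the protein
    true_positions: tuple[int, ...]  # peptide coordinates

    @property
    def n_phospho(self) -> int:
        return len(self.true_positions)

    @property
    def protein_site_positions(self) -> tuple[int, ...]:
        return tuple(self.protein_offset + p - 1 for p in self.true_positions)


def make_panel(
    fasta: str | Mapping[str, str],
    counts: tuple[int, int, int] = DEFAULT_PANEL_COUNTS,
    seed: int = 0,
    peptide_length_range: tuple[int, int] = (7, 25),
) -> list[PanelEntry]:
    """Draw a phosphopeptide panel with exact mono/di/tri multiplicities.

    Peptides are tryptic-like (K/R C-terminus unless protein C-terminal),
    length 7–25, and must carry at least as many S/T/Y residues as the
    multiplicity assigned; true configurations are drawn uniformly over the
    candidate position combinations.  Distinct peptides are used for
    distinct panel entries.
    """
    from .io import read_fasta_text  # local import to avoid a cycle

    proteins = read_fasta_text(fasta) if isinstance(fasta, str) else dict(fasta)
    lo, hi = peptide_length_range
    candidates: list[tuple[str, int, str]] = []  # (accession, offset, peptide)
    for acc, seq in proteins.items():
        for offset, pep in tryptic_peptides(seq):
            if lo <= len(pep) <= hi and sty_positions(pep):
                candidates.append((acc, offset, pep))
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(candidates))
    entries: list[PanelEntry] = []
    used: set[int] = set()
    # assign tri first (scarcest STY requirement), then di, then mono
    for multiplicity, count in ((3, counts[2]), (2, counts[1]), (1, counts[0])):
        taken = 0
        for idx in order:
            if taken == count:
                break
            if idx in used:
                continue
            acc, offset, pep = candidates[idx]
            sty = sty_positions(pep)
            if len(sty) < multiplicity:
                continue
            used.add(idx)
            combos = list(enumerate_isomers(pep, multiplicity))
            config = combos[int(rng.integers(len(combos)))]
            entries.append(
                PanelEntry(
                    Peptidoform(pep).with_phospho(config.positions),
                    acc,
                    offset,
                    config.positions,
                )
            )
            taken += 1
        if taken < count:
            raise ValueError(
                f"only {taken} of {count} peptides with >= {multiplicity} S/T/Y "
                "residues available; increase n_proteins or protein length"
            )
    # report in mono, di, tri order
    entries.sort(key=lambda e: (e.n_phospho, e.accession, e.protein_offset))
    return entries


@dataclass
class DilutionGroundTruth:
    """True parameters behind a simulated dilution report."""

    seed: int
    noise_cv: float
    amounts: dict[str, float]
    replicates: int
    base_abundance: dict[str, float]  # modified sequence -> base area at amount 1
    true_sites: dict[str, list[str]]  # modified sequence -> protein site keys
    dropout_events: list[tuple[str, str]] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)


def simulate_dilution_report(
    panel: Sequence[PanelEntry],
    design: DilutionDesign | None = None,
    noise_cv: float = 0.05,
    dropout: DropoutModel | None = None,
    seed: int = 0,
    mode: str = "libDIA",
) -> tuple[list[PrecursorRecord], DilutionGroundTruth]:
    """Precursor records for a spike-in dilution series with known truth.

    Per precursor, level, and replicate the area is
    ``base · amount · exp(N(0, σ))`` with σ chosen so the multiplicative CV
    equals ``noise_cv``; observations are then retained with the dropout
    model's detection probability (all retained when ``dropout`` is None).
    Localization probabilities are emitted as 1.0.
    """
    if design is None:
        design = DilutionDesign()
    rng = np.random.default_rng(seed)
    sigma = noise_sigma(noise_cv)
    base = {}
    charge = {}
    rt = {}
    true_sites = {}
    for entry in panel:
        mseq = format_modified_sequence(entry.peptidoform)
        base[mseq] = float(10.0 ** rng.normal(5.0, 0.5))
        charge[mseq] = int(rng.integers(2, 4))
        rt[mseq] = float(rng.uniform(5.0, 115.0))
        true_sites[mseq] = [
            f"{entry.accession}-{entry.peptidoform.stripped_sequence[p - 1]}{pp}"
            for p, pp in zip(entry.true_positions, entry.protein_site_positions)
        ]
    records: list[PrecursorRecord] = []
    dropped: list[tuple[str, str]] = []
    for entry in panel:
        mseq = format_modified_sequence(entry.peptidoform)
        pf = Peptidoform(
            entry.peptidoform.stripped_sequence,
            entry.peptidoform.modifications,
            charge[mseq],
        )
        probs = {p: 1.0 for p in entry.true_positions}
        for label, amount in design.levels:
            for run in design.run_ids(label):
                area = base[mseq] * amount * float(np.exp(rng.normal(0.0, sigma)))
                if dropout is not None:
                    if rng.uniform() >= dropout.detection_probability(area):
                        dropped.append((mseq, run))
                        continue
                records.append(
                    PrecursorRecord(
                        run=run,
                        peptidoform=pf,
                        protein_group=entry.accession,
                        quantity=area,
                        rt=rt[mseq] + float(rng.normal(0.0, 0.1)),
                        site_probabilities=probs,
                        mode=mode,
                    )
                )
    truth = DilutionGroundTruth(
        seed=seed,
        noise_cv=noise_cv,
        amounts=design.amounts,
        replicates=design.replicates,
        base_abundance=base,
        true_sites=true_sites,
        dropout_events=dropped,
    )
    return records, truth


def simulate_isomer_spectra(
    true_config: IsomerConfiguration,
    coverage: float = 1.0,
    n_noise_peaks: int = 0,
    seed: int = 0,
    restrict_to_non_discriminating: bool = False,
) -> tuple[PeakList, dict]:
    """A peak list for the true configuration's b/y ladder, with known truth.

    A ``coverage`` fraction of the singly charged b/y ions of the true
    configuration is sampled (all at 1.0), with lognormal intensities, plus
    ``n_noise_peaks`` uniform random noise peaks.  Ions discriminating the
    true configuration from any competing isomer are flagged in the returned
    ground truth; with ``restrict_to_non_discriminating`` only ions shared
    by all isomers are emitted (the fully ambiguous case).
    """
    if not 0.0 <= coverage <= 1.0:
        raise ValueError("coverage must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    seq = true_config.stripped_sequence
    k = len(true_config.positions)
    ladder = fragment_ladder(true_config.peptidoform(), ("b", "y"), 1, False)
    competitors = [
        c for c in enumerate_isomers(seq, k) if c.positions != true_config.positions
    ]
    discriminating: set[tuple[str, int]] = set()
    from .localization import site_determining_ions

    for comp in competitors:
        sdi = site_determining_ions(true_config, comp)
        for series, indices in sdi.items():
            discriminating.update((series, i) for i in indices)
    ions = list(ladder)
    if restrict_to_non_discriminating:
        ions = [f for f in ions if (f.series, f.index) not in discriminating]
    n_keep = int(round(coverage * len(ions)))
    keep_idx = sorted(rng.choice(len(ions), size=n_keep, replace=False))
    peaks = [
        (ions[i].mz, float(10.0 ** rng.normal(2.0, 0.3))) for i in keep_idx
    ]
    if n_noise_peaks:
        max_mz = max((f.mz for f in ladder), default=1000.0) + 200.0
        for _ in range(n_noise_peaks):
            peaks.append(
                (float(rng.uniform(100.0, max_mz)), float(10.0 ** rng.normal(1.0, 0.3)))
            )
    truth = {
        "true_positions": list(true_config.positions),
        "discriminating_ions": sorted(discriminating),
        "n_theoretical": len(ladder),
        "n_emitted": len(peaks),
        "seed": seed,
    }
    pf = true_config.peptidoform()
    return (
        PeakList(tuple(peaks), precursor_mz=precursor_mz(pf, 2), precursor_charge=2),
        truth,
    )


def simulate_two_group_matrix(
    n_sites: int,
    n_per_group: int = 3,
    n_changed: int = 0,
    effect_log2: float = 2.0,
    sd: float = 0.25,
    seed: int = 0,
    between_site_sd: float = 1.0,
) -> tuple[SiteQuantMatrix, dict]:
    """A log2 sites × samples matrix with a planted group-B shift.

    The first ``n_changed`` sites are shifted by ``effect_log2`` in group B;
    within-group noise is normal with standard deviation ``sd``.  Returns
    the matrix (columns ``A_R1.. B_Rn``) and the ground truth.
    """
    import pandas as pd

    if n_changed > n_sites:
        raise ValueError("n_changed must not exceed n_sites")
    rng = np.random.default_rng(seed)
    baseline = rng.normal(20.0, between_site_sd, size=n_sites)
    x = rng.normal(0.0, sd, size=(n_sites, 2 * n_per_group)) + baseline[:, None]
    x[:n_changed, n_per_group:] += effect_log2
    columns = [f"A_R{i}" for i in range(1, n_per_group + 1)] + [
        f"B_R{i}" for i in range(1, n_per_group + 1)
    ]
    index = [f"SIM{i // 10 + 1}-S{i + 1}" for i in range(n_sites)]
    values = pd.DataFrame(x, index=index, columns=columns)
    truth = {
        "seed": seed,
        "effect_log2": effect_log2,
        "sd": sd,
        "changed_sites": index[:n_changed],
        "labels": ["A"] * n_per_group + ["B"] * n_per_group,
    }
    return SiteQuantMatrix(values), truth


def dia_window_index(
    mz: float, low: float = 500.0, high: float = 1000.0, width: float = 10.0, overlap: float = 1.0
) -> int | None:
    """Descriptive DIA isolation-window index for a precursor m/z.

    Windows of ``width`` Th with ``overlap`` Th between neighbours tile
    ``low``–``high``; returns None outside the tiled range.
    """
    step = width - overlap
    if mz < low or mz > high:
        return None
    return int((mz - low) // step)
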