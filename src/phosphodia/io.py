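"""Readers and writers for the on-disk formats.

All tabular formats are tab-separated UTF-8 with "." decimals; missing cells
are empty strings (never "0" or "NA").  Site localization probabilities are
serialized with a small grammar: semicolon-separated ``RESIDUE+POSITION: prob``
pairs in peptide coordinates, e.g. ``"S2: 0.98; S6: 0.02"``.  Peak lists use
MGF; FASTA follows the UniProt convention (accession is the second
pipe-delimited header token of ``sp|...|...`` headers).
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from pyteomics import mgf as _mgf

from .library import LibraryEntry, LibraryFragment, SpectralLibrary
from .localization import PeakList
from .masscalc import (
    Peptidoform,
    format_modified_sequence,
    parse_modified_sequence,
    precursor_mz,
)
from .sitequant import PrecursorRecord, SiteQuantMatrix

__all__ = [
    "ReportSchema",
    "read_precursor_report",
    "write_precursor_report",
    "read_fasta",
    "read_fasta_text",
    "write_site_matrix",
    "read_site_matrix",
    "write_library",
    "read_library",
    "write_peaklists",
    "read_peaklists",
    "parse_probability_string",
    "format_probability_string",
    "load_config",
]

_CANONICAL_COLUMNS = {
    "run": "Run",
    "modified_sequence": "ModifiedSequence",
    "charge": "PrecursorCharge",
    "protein_group": "ProteinGroup",
    "quantity": "PrecursorArea",
    "rt": "RT",
    "site_probabilities": "SiteProbabilities",
    "mode": "Mode",
}


@dataclass(frozen=True)
class ReportSchema:
    """Column-name mapping from an external report dialect to canonical fields.

    ``overrides`` maps canonical field names (run, modified_sequence, charge,
    protein_group, quantity, rt, site_probabilities, mode) to the column
    names used in the file.  Unknown file columns are ignored on read.
    """

    overrides: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.overrides) - set(_CANONICAL_COLUMNS)
        if unknown:
            raise ValueError(f"unknown canonical field(s): {sorted(unknown)}")

    def column(self, canonical: str) -> str:
        return self.overrides.get(canonical, _CANONICAL_COLUMNS[canonical])


def parse_probability_string(text: str) -> dict[int, float]:
    """Parse ``"S2: 0.98; S6: 0.02"`` into {position: probability}."""
    out: dict[int, float] = {}
    text = text.strip()
    if not text:
        return out
    for part in text.split(";"):
        part = part.strip()
        token, _, value = part.partition(":")
        token = token.strip()
        if not token or token[0] not in "STY" or not token[1:].isdigit():
            raise ValueError(f"malformed probability token {part!r}")
        prob = float(value)
        if not 0.0 <= prob <= 1.0:
            raise ValueError(f"probability {prob} outside [0, 1] in {part!r}")
        out[int(token[1:])] = prob
    return out


def format_probability_string(pf: Peptidoform, probs: Mapping[int, float]) -> str:
    seq = pf.stripped_sequence
    return "; ".join(f"{seq[p - 1]}{p}: {probs[p]!r}" for p in sorted(probs))


def write_precursor_report(
    records: Iterable[PrecursorRecord], path: str | Path, schema: ReportSchema | None = None
) -> None:
    schema = schema or ReportSchema()
    rows = []
    for rec in records:
        rows.append(
            {
                schema.column("run"): rec.run,
                schema.column("modified_sequence"): format_modified_sequence(
                    rec.peptidoform
                ),
                schema.column("charge"): rec.peptidoform.charge or "",
                schema.column("protein_group"): rec.protein_group,
                schema.column("quantity"): repr(rec.quantity),
                schema.column("rt"): "" if rec.rt is None else repr(rec.rt),
                schema.column("site_probabilities"): (
                    ""
                    if rec.site_probabilities is None
                    else format_probability_string(rec.peptidoform, rec.site_probabilities)
                ),
                schema.column("mode"): rec.mode,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_precursor_report(
    path: str | Path, schema: ReportSchema | None = None
) -> list[PrecursorRecord]:
    """Read a long-format precursor report, validating each row.

    Raises ``ValueError`` naming a missing mapped column, or a malformed row
    with its line number (1-based, header is line 1).
    """
    schema = schema or ReportSchema()
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["run", "modified_sequence", "charge", "protein_group", "quantity"]
    for canonical in required:
        if schema.column(canonical) not in df.columns:
            raise ValueError(
                f"report lacks required column {schema.column(canonical)!r}"
            )
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        row_d = dict(zip(df.columns, row))

        def _get(canonical: str, default: str = "") -> str:
            return row_d.get(schema.column(canonical), default)

        try:
            quantity = float(_get("quantity"))
            if quantity < 0:
                raise ValueError(f"negative precursor area {quantity}")
            charge_text = _get("charge")
            charge = int(float(charge_text)) if charge_text else None
            pf = parse_modified_sequence(_get("modified_sequence"))
            pf = Peptidoform(pf.stripped_sequence, pf.modifications, charge)
            probs_text = _get("site_probabilities")
            probs = parse_probability_string(probs_text) if probs_text else None
            rt_text = _get("rt")
            records.append(
                PrecursorRecord(
                    run=_get("run"),
                    peptidoform=pf,
                    protein_group=_get("protein_group"),
                    quantity=quantity,
                    rt=float(rt_text) if rt_text else None,
                    site_probabilities=probs,
                    mode=_get("mode") or "libDIA",
                )
            )
        except (ValueError, KeyError) as exc:
            raise ValueError(f"{path}, line {i}: {exc}") from exc
    return records


def load_config(path: str | Path) -> dict:
    """Load a YAML config of CLI/default parameter overrides."""
    import yaml

    data = yaml.safe_load(Path(path).read_text())
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must be a mapping of parameter: value")
    return data


def read_fasta_text(text: str) -> dict[str, str]:
    """Parse FASTA text into an accession → sequence mapping."""
    handle = _io.StringIO(text)
    out: dict[str, str] = {}
    for record in SeqIO.parse(handle, "fasta"):
        parts = record.id.split("|")
        accession = parts[1] if len(parts) >= 3 and parts[0] in ("sp", "tr") else parts[0]
        if accession in out:
            raise ValueError(f"duplicate accession {accession!r} in FASTA")
        out[accession] = str(record.seq)
    if not out:
        raise ValueError("empty FASTA")
    return out


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file; accession per the UniProt header convention."""
    return read_fasta_text(Path(path).read_text())


def write_site_matrix(matrix: SiteQuantMatrix, path: str | Path) -> None:
    """Site × run TSV with "ACC-S123" row keys; missing cells empty."""
    df = matrix.values.copy()
    out = df.map(lambda v: "" if pd.isna(v) else repr(float(v)))
    out.index.name = "Site"
    joined = out.join(matrix.meta) if not matrix.meta.empty else out
    joined.to_csv(path, sep="\t")


def read_site_matrix(path: str | Path, run_columns: Sequence[str] | None = None) -> SiteQuantMatrix:
    df = pd.read_csv(path, sep="\t", index_col="Site", dtype=str, keep_default_na=False)
    meta_cols = [
        c
        for c in ("best_probability", "protein_group", "multi_mapping")
        if c in df.columns
    ] + [c for c in df.columns if c.startswith("class1_")]
    if run_columns is None:
        run_columns = [c for c in df.columns if c not in meta_cols]
    values = df[list(run_columns)].replace("", np.nan).astype(float)
    values.index.name = None
    meta = df[meta_cols].copy() if meta_cols else pd.DataFrame(index=df.index)
    meta.index.name = None
    if "best_probability" in meta:
        meta["best_probability"] = meta["best_probability"].astype(float)
    for col in meta.columns:
        if col.startswith("class1_") or col == "multi_mapping":
            meta[col] = meta[col] == "True"
    return SiteQuantMatrix(values, meta)


_LIBRARY_COLUMNS = [
    "ModifiedPeptide",
    "StrippedSequence",
    "PrecursorCharge",
    "PrecursorMz",
    "iRT",
    "ProteinAccessions",
    "FragmentType",
    "FragmentNumber",
    "FragmentCharge",
    "FragmentMz",
    "RelativeIntensity",
    "FragmentLossType",
    "Source",
    "Score",
]


def write_library(lib: SpectralLibrary | Iterable[LibraryEntry], path: str | Path) -> None:
    """Long-format library TSV, one row per fragment."""
    entries = lib.entries.values() if isinstance(lib, SpectralLibrary) else lib
    rows = []
    for entry in entries:
        mseq = format_modified_sequence(entry.peptidoform)
        for frag in entry.fragments:
            rows.append(
                {
                    "ModifiedPeptide": mseq,
                    "StrippedSequence": entry.peptidoform.stripped_sequence,
                    "PrecursorCharge": entry.precursor_charge,
                    "PrecursorMz": repr(entry.precursor_mz),
                    "iRT": repr(entry.irt),
                    "ProteinAccessions": ";".join(entry.protein_accessions),
                    "FragmentType": frag.series,
                    "FragmentNumber": frag.index,
                    "FragmentCharge": frag.charge,
                    "FragmentMz": repr(frag.mz),
                    "RelativeIntensity": repr(frag.relative_intensity),
                    "FragmentLossType": "H3PO4" if frag.neutral_loss else "noloss",
                    "Source": entry.source,
                    "Score": repr(entry.score),
                }
            )
    pd.DataFrame(rows, columns=_LIBRARY_COLUMNS).to_csv(path, sep="\t", index=False)


def read_library(
    path: str | Path, column_mapping: Mapping[str, str] | None = None
) -> SpectralLibrary:
    """Read a long-format library TSV (optionally mapping dialect columns)."""
    from .masscalc import PHOSPHO_NEUTRAL_LOSS

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if column_mapping:
        df = df.rename(columns={v: k for k, v in column_mapping.items()})
    missing = [c for c in _LIBRARY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"library TSV lacks column(s) {missing}")
    lib = SpectralLibrary()
    for (mseq, charge), group in df.groupby(
        ["ModifiedPeptide", "PrecursorCharge"], sort=False
    ):
        first = group.iloc[0]
        pf = parse_modified_sequence(mseq)
        frags = tuple(
            LibraryFragment(
                series=r.FragmentType,
                index=int(r.FragmentNumber),
                charge=int(r.FragmentCharge),
                mz=float(r.FragmentMz),
                relative_intensity=float(r.RelativeIntensity),
                n_residues=int(r.FragmentNumber),
                neutral_loss=PHOSPHO_NEUTRAL_LOSS if r.FragmentLossType == "H3PO4" else 0.0,
            )
            for r in group.itertuples(index=False)
        )
        entry = LibraryEntry(
            peptidoform=pf,
            precursor_mz=float(first["PrecursorMz"]),
            precursor_charge=int(charge),
            irt=float(first["iRT"]),
            fragments=tuple(
                sorted(frags, key=lambda f: (-f.relative_intensity, f.mz))
            ),
            source=first["Source"],
            score=float(first["Score"]),
            protein_accessions=tuple(
                a for a in first["ProteinAccessions"].split(";") if a
            ),
        )
        lib.entries[entry.key] = entry
    return lib


def write_peaklists(
    peaklists: Sequence[PeakList], path: str | Path, titles: Sequence[str] | None = None
) -> None:
    """Write peak lists as MGF (BEGIN IONS / END IONS blocks)."""
    spectra = []
    for i, pl in enumerate(peaklists):
        params: dict = {"title": titles[i] if titles else f"spectrum_{i + 1}"}
        if pl.precursor_mz is not None:
            params["pepmass"] = pl.precursor_mz
        if pl.precursor_charge is not None:
            params["charge"] = pl.precursor_charge
        spectra.append(
            {
                "params": params,
                "m/z array": pl.mz,
                "intensity array": pl.intensity,
            }
        )
    _mgf.write(spectra, str(path), file_mode="w")


def read_peaklists(path: str | Path) -> list[PeakList]:
    out = []
    with _mgf.MGF(str(path)) as reader:
        for spec in reader:
            params = spec.get("params", {})
            pepmass = params.get("pepmass")
            charge = params.get("charge")
            out.append(
                PeakList(
                    tuple(zip(spec["m/z array"], spec["intensity array"])),
                    precursor_mz=pepmass[0] if pepmass else None,
                    precursor_charge=int(charge[0]) if charge else None,
                )
            )
    return out
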