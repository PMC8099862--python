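"""Monoisotopic mass and m/z arithmetic for modified peptides.

The unit of identification throughout the package is the *peptidoform*: a
stripped amino-acid sequence plus positioned mass modifications, optionally
with a precursor charge.  This module computes peptide monoisotopic masses,
precursor m/z values, and b/y fragment-ion ladders, including the phosphate
neutral loss (H3PO4, 97.9769 Da) on phospho-containing fragments.

Modified sequences use an inline, search-engine-like dialect: a short code in
parentheses immediately after the modified residue, e.g. ``GS(ph)HQISLDNPDYQQDFFPK``
or ``_M(ox)AS(ph)K_`` (flanking underscores are ignored).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

__all__ = [
    "Peptidoform",
    "FragmentIon",
    "Modification",
    "MONOISOTOPIC_RESIDUE_MASS",
    "MOD_DELTAS",
    "WATER",
    "PROTON",
    "PHOSPHO_NEUTRAL_LOSS",
    "parse_modified_sequence",
    "format_modified_sequence",
    "peptide_mono_mass",
    "precursor_mz",
    "fragment_ladder",
]

# Standard IUPAC monoisotopic residue masses, 5-decimal precision.
MONOISOTOPIC_RESIDUE_MASS: dict[str, float] = {
    "G": 57.02146,
    "A": 71.03711,
    "S": 87.03203,
    "P": 97.05276,
    "V": 99.06841,
    "T": 101.04768,
    "C": 103.00919,
    "L": 113.08406,
    "I": 113.08406,
    "N": 114.04293,
    "D": 115.02694,
    "Q": 128.05858,
    "K": 128.09496,
    "E": 129.04259,
    "M": 131.04049,
    "H": 137.05891,
    "F": 147.06841,
    "R": 156.10111,
    "Y": 163.06333,
    "W": 186.07931,
}

WATER = 18.01056
PROTON = 1.007276
#: monoisotopic mass of H3PO4, lost from phosphorylated fragments
PHOSPHO_NEUTRAL_LOSS = 97.9769

#: variable-modification deltas (Da) by short code
MOD_DELTAS: dict[str, float] = {
    "ph": 79.96633,   # phosphorylation, S/T/Y only
    "ox": 15.99491,   # methionine oxidation
    "cam": 57.02146,  # carbamidomethyl cysteine
    "ac": 42.01057,   # acetylation
}

PHOSPHO_RESIDUES = frozenset("STY")


@dataclass(frozen=True, order=True)
class Modification:
    """A positioned mass modification (1-based residue index)."""

    position: int
    delta_mass: float
    label: str


@dataclass(frozen=True)
class Peptidoform:
    stripped_sequence: str
    modifications: tuple[Modification, ...] = ()
    charge: int | None = None

    def __post_init__(self) -> None:
        seq = self.stripped_sequence
        if not seq:
            raise ValueError("empty peptide sequence")
        bad = set(seq) - set(MONOISOTOPIC_RESIDUE_MASS)
        if bad:
            raise ValueError(f"non-canonical residue(s) {sorted(bad)} in {seq!r}")
        object.__setattr__(self, "modifications", tuple(sorted(self.modifications)))
        seen: set[tuple[int, str]] = set()
        for mod in self.modifications:
            if not 1 <= mod.position <= len(seq):
                raise ValueError(
                    f"modification position {mod.position} outside 1..{len(seq)}"
                )
            key = (mod.position, mod.label)
            if key in seen:
                raise ValueError(f"duplicate modification {mod.label} at {mod.position}")
            seen.add(key)
            if mod.label == "ph" and seq[mod.position - 1] not in PHOSPHO_RESIDUES:
                raise ValueError(
                    f"'ph' on non-STY residue {seq[mod.position - 1]}{mod.position}"
                )
        if self.charge is not None and self.charge < 1:
            raise ValueError("charge must be a positive integer")

    @property
    def n_phospho(self) -> int:
        return sum(1 for m in self.modifications if m.label == "ph")

    @property
    def phospho_positions(self) -> tuple[int, ...]:
        return tuple(m.position for m in self.modifications if m.label == "ph")

    def with_phospho(self, positions: Iterable[int]) -> "Peptidoform":
        """Return a copy whose phospho set is replaced by ``positions``."""
        keep = tuple(m for m in self.modifications if m.label != "ph")
        new = tuple(Modification(p, MOD_DELTAS["ph"], "ph") for p in positions)
        return replace(self, modifications=keep + new)


@dataclass(frozen=True)
class FragmentIon:
    """A b- or y-series fragment ion."""

    series: str          # "b" or "y"
    index: int           # 1-based cleavage index within the series
    charge: int
    mz: float
    n_residues: int
    neutral_loss: float = 0.0

    @property
    def neutral_mass(self) -> float:
        return self.charge * (self.mz - PROTON)

    @property
    def name(self) -> str:
        loss = "-H3PO4" if self.neutral_loss else ""
        return f"{self.series}{self.index}{loss}^{self.charge}"


_TOKEN_RE = re.compile(r"([A-Z])(?:\(([a-z]+)\))?")


def parse_modified_sequence(text: str) -> Peptidoform:
    """Parse an inline-modified sequence such as ``GS(ph)HQISLDNPDYQQDFFPK``.

    Flanking underscores are tolerated.  Raises ``ValueError`` on unknown
    modification codes, a ``(ph)`` on a non-STY residue, or an empty sequence.
    """
    text = text.strip().strip("_")
    if not text:
        raise ValueError("empty modified-sequence string")
    pos = 0
    residues: list[str] = []
    mods: list[Modification] = []
    for match in _TOKEN_RE.finditer(text):
        if match.start() != pos:
            raise ValueError(f"cannot parse modified sequence at {text[pos:]!r}")
        pos = match.end()
        residues.append(match.group(1))
        code = match.group(2)
        if code is not None:
            if code not in MOD_DELTAS:
                raise ValueError(f"unknown modification code {code!r}")
            mods.append(Modification(len(residues), MOD_DELTAS[code], code))
    if pos != len(text):
        raise ValueError(f"cannot parse modified sequence at {text[pos:]!r}")
    return Peptidoform("".join(residues), tuple(mods))


def format_modified_sequence(pf: Peptidoform) -> str:
    """Inverse of :func:`parse_modified_sequence` (no flanking underscores)."""
    by_pos: dict[int, list[str]] = {}
    for m in pf.modifications:
        by_pos.setdefault(m.position, []).append(m.label)
    out: list[str] = []
    for i, aa in enumerate(pf.stripped_sequence, start=1):
        out.append(aa)
        for label in by_pos.get(i, ()):
            out.append(f"({label})")
    return "".join(out)


def peptide_mono_mass(pf: Peptidoform | str) -> float:
    """Monoisotopic neutral mass: residue masses + water + modification deltas.

    Accepts a :class:`Peptidoform` or a (possibly modified) sequence string.
    """
    if isinstance(pf, str):
        pf = parse_modified_sequence(pf)
    mass = WATER + sum(MONOISOTOPIC_RESIDUE_MASS[a] for a in pf.stripped_sequence)
    return mass + sum(m.delta_mass for m in pf.modifications)


def precursor_mz(pf: Peptidoform | str, z: int | None = None) -> float:
    """(M + z·proton) / z for the peptidoform at charge ``z``."""
    if isinstance(pf, str):
        pf = parse_modified_sequence(pf)
    if z is None:
        z = pf.charge
    if z is None or z < 1:
        raise ValueError("charge must be >= 1")
    return (peptide_mono_mass(pf) + z * PROTON) / z


def _prefix_masses(pf: Peptidoform) -> list[float]:
    """Cumulative residue+mod mass of prefixes 1..n."""
    deltas = [0.0] * (len(pf.stripped_sequence) + 1)
    for m in pf.modifications:
        deltas[m.position] += m.delta_mass
    acc = 0.0
    out = []
    for i, aa in enumerate(pf.stripped_sequence, start=1):
        acc += MONOISOTOPIC_RESIDUE_MASS[aa] + deltas[i]
        out.append(acc)
    return out


def fragment_ladder(
    pf: Peptidoform | str,
    series_set: Sequence[str] = ("b", "y"),
    max_fragment_charge: int = 1,
    include_neutral_loss: bool = False,
) -> list[FragmentIon]:
    """All b/y fragment ions of ``pf`` at charges 1..max_fragment_charge.

    Modification deltas are carried by every fragment containing the modified
    position.  With ``include_neutral_loss``, each fragment carrying at least
    one phospho group gains a −97.9769 Da (H3PO4) variant.
    """
    if isinstance(pf, str):
        pf = parse_modified_sequence(pf)
    n = len(pf.stripped_sequence)
    if n < 2:
        raise ValueError("fragment ladder requires a peptide of length >= 2")
    for s in series_set:
        if s not in ("b", "y"):
            raise ValueError(f"unsupported fragment series {s!r}")
    prefix = _prefix_masses(pf)
    total = prefix[-1]  # residues + mods, no water
    ph_pos = set(pf.phospho_positions)
    ions: list[FragmentIon] = []
    for i in range(1, n):
        # b_i covers residues 1..i; y_i covers residues n-i+1..n
        neutral = {
            "b": prefix[i - 1],
            "y": total - prefix[n - i - 1] + WATER,
        }
        has_ph = {
            "b": any(p <= i for p in ph_pos),
            "y": any(p > n - i for p in ph_pos),
        }
        for series in series_set:
            for z in range(1, max_fragment_charge + 1):
                mz = (neutral[series] + z * PROTON) / z
                ions.append(FragmentIon(series, i, z, mz, i))
                if include_neutral_loss and has_ph[series]:
                    ions.append(
                        FragmentIon(
                            series,
                            i,
                            z,
                            mz - PHOSPHO_NEUTRAL_LOSS / z,
                            i,
                            neutral_loss=PHOSPHO_NEUTRAL_LOSS,
                        )
                    )
    return ions
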