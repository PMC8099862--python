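"""Differential phosphosite statistics and kinase-motif enrichment.

Two-group testing uses the SAM-style moderated t statistic
``d = (mean_A − mean_B) / (s_pooled·sqrt(1/nA + 1/nB) + s0)`` on log2
abundances, with the fudge factor ``s0`` damping the significance of
low-variance small effects, and a permutation-based FDR: the null |d|
distribution is pooled over group-label permutations (the observed labeling
and its mirror are excluded from the null pool), and
``q = mean null exceedances per permutation / observed exceedances``,
clipped and monotonized.  Site abundances can be normalized to protein
expression, and 13-mer sequence windows around phosphosites feed a
Fisher's-exact kinase-motif enrichment with Benjamini–Hochberg control.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .sitequant import SiteKey, SiteQuantMatrix

__all__ = [
    "DiffExpResult",
    "MotifWindow",
    "MotifPattern",
    "DEFAULT_MOTIFS",
    "s0_ttest",
    "permutation_fdr",
    "normalize_site_to_protein",
    "extract_motif_windows",
    "fisher_motif_enrichment",
]

MOTIF_WIDTH = 13
_FLANK = MOTIF_WIDTH // 2


def s0_ttest(
    group_a: Sequence[float], group_b: Sequence[float], s0: float = 0.1
) -> float:
    """SAM-style moderated two-sample t statistic on log2 values.

    With ``s0 = 0`` this reduces to the classical pooled two-sample t
    statistic (nA + nB − 2 degrees of freedom for the pooled variance).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 values")
    if s0 < 0:
        raise ValueError("s0 must be >= 0")
    na, nb = a.size, b.size
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    denom = np.sqrt(sp2) * np.sqrt(1.0 / na + 1.0 / nb) + s0
    return float((a.mean() - b.mean()) / denom)


def _d_stat_matrix(x: np.ndarray, cols_a: np.ndarray, cols_b: np.ndarray, s0: float) -> np.ndarray:
    """Row-wise d statistic for a sites × samples matrix."""
    a, b = x[:, cols_a], x[:, cols_b]
    na, nb = a.shape[1], b.shape[1]
    sp2 = ((na - 1) * a.var(1, ddof=1) + (nb - 1) * b.var(1, ddof=1)) / (na + nb - 2)
    return (a.mean(1) - b.mean(1)) / (np.sqrt(sp2) * np.sqrt(1.0 / na + 1.0 / nb) + s0)


@dataclass
class DiffExpResult:
    """Per-site differential-testing output (log2 scale)."""

    table: pd.DataFrame  # mean_a, mean_b, difference, statistic, q_value, significant
    s0: float
    n_permutations: int
    fdr_threshold: float
    skipped: pd.Index = field(default_factory=lambda: pd.Index([]))

    @property
    def significant_sites(self) -> list:
        return list(self.table.index[self.table["significant"]])


def _permutation_pool(
    n_a: int, n_b: int, n_permutations: int, rng: np.random.Generator
) -> list[tuple[int, ...]]:
    """Column index sets for group A under the null, excluding the observed
    labeling and its label-swap mirror."""
    n = n_a + n_b
    observed = tuple(range(n_a))
    mirror = tuple(range(n_a, n)) if n_a == n_b else None
    all_combos = [c for c in combinations(range(n), n_a) if c != observed and c != mirror]
    if n_permutations >= len(all_combos):
        return all_combos
    idx = rng.choice(len(all_combos), size=n_permutations, replace=False)
    return [all_combos[i] for i in sorted(idx)]


def permutation_fdr(
    matrix: SiteQuantMatrix | pd.DataFrame,
    labels: Sequence[str],
    s0: float = 0.1,
    n_permutations: int = 250,
    seed: int | None = None,
    fdr_threshold: float = 0.01,
) -> DiffExpResult:
    """SAM-style permutation FDR for a two-group comparison.

    ``labels`` assigns each matrix column to one of exactly two groups.
    Sites with missing values are skipped (complete-case testing).  When the
    number of distinct label assignments (minus the observed and its mirror)
    does not exceed ``n_permutations``, the pool is exhaustive and the result
    is seed-independent; otherwise ``seed`` selects a random subset.
    q(site) = [mean per-permutation count of |d_null| >= |d_obs|] /
    [count of observed |d| >= |d_obs|], clipped to [0, 1] and made monotone
    non-decreasing along decreasing |d|.
    """
    df = matrix.values if isinstance(matrix, SiteQuantMatrix) else matrix
    labels = np.asarray(labels)
    if labels.size != df.shape[1]:
        raise ValueError("one label per matrix column required")
    groups = pd.unique(labels)
    if len(groups) != 2:
        raise ValueError(f"exactly two groups required, got {list(groups)}")
    order = np.argsort(labels != groups[0], kind="stable")
    df = df.iloc[:, order]
    n_a = int((labels == groups[0]).sum())
    n_b = int((labels == groups[1]).sum())
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs >= 2 columns")

    complete = df.notna().all(axis=1)
    skipped = df.index[~complete]
    x = df[complete].to_numpy(dtype=float)
    n_sites, n = x.shape
    cols = np.arange(n)
    obs = _d_stat_matrix(x, cols[:n_a], cols[n_a:], s0)

    rng = np.random.default_rng(seed)
    pool = _permutation_pool(n_a, n_b, n_permutations, rng)
    null = np.empty((len(pool), n_sites))
    for j, combo in enumerate(pool):
        a_cols = np.array(combo)
        b_cols = np.setdiff1d(cols, a_cols)
        null[j] = _d_stat_matrix(x, a_cols, b_cols, s0)
    null_abs = np.sort(np.abs(null).ravel())

    abs_obs = np.abs(obs)
    rank_order = np.argsort(-abs_obs, kind="stable")
    q = np.empty(n_sites)
    for rank, i in enumerate(rank_order, start=1):
        n_null = null_abs.size - np.searchsorted(null_abs, abs_obs[i], side="left")
        q[i] = (n_null / len(pool)) / rank
    q = np.clip(q, 0.0, 1.0)
    q[rank_order] = np.maximum.accumulate(q[rank_order])

    mean_a = x[:, :n_a].mean(1)
    mean_b = x[:, n_a:].mean(1)
    table = pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "difference": mean_a - mean_b,
            "statistic": obs,
            "q_value": q,
            "significant": q < fdr_threshold,
        },
        index=df.index[complete],
    )
    return DiffExpResult(table, s0, len(pool), fdr_threshold, skipped)


def normalize_site_to_protein(
    site_matrix: SiteQuantMatrix | pd.DataFrame,
    protein_matrix: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.Series]:
    """Adjust site abundance for protein expression: log2(site) − log2(protein).

    Site rows are matched to protein rows via the accession of their
    "ACC-S123" key.  Sites whose protein is not quantified pass through as
    plain log2(site) with their ``adjusted`` flag False.
    """
    df = site_matrix.values if isinstance(site_matrix, SiteQuantMatrix) else site_matrix
    adjusted = pd.Series(False, index=df.index)
    out = np.log2(df)
    for site in df.index:
        acc = SiteKey.parse(str(site)).accession
        if acc in protein_matrix.index:
            prot = protein_matrix.loc[acc, df.columns]
            if prot.notna().any():
                out.loc[site] = np.log2(df.loc[site]) - np.log2(prot.astype(float))
                adjusted[site] = True
    return out, adjusted


@dataclass(frozen=True)
class MotifWindow:
    """A 13-mer sequence window centered on a phosphosite.

    Out-of-protein flanks are padded with ``_``; the center residue (index 6)
    is the phosphorylated S/T/Y.
    """

    sequence: str
    site: SiteKey

    def __post_init__(self) -> None:
        if len(self.sequence) != MOTIF_WIDTH:
            raise ValueError(f"window must be {MOTIF_WIDTH} residues")
        if self.sequence[_FLANK] not in "STY":
            raise ValueError("window center must be S, T, or Y")

    @property
    def center(self) -> str:
        return self.sequence[_FLANK]


def extract_motif_windows(
    sites: Iterable[SiteKey | str],
    protein_sequences: Mapping[str, str],
    width: int = MOTIF_WIDTH,
) -> list[MotifWindow]:
    """Sequence windows of ``width`` residues centered on each phosphosite."""
    if width != MOTIF_WIDTH:
        raise ValueError("only 13-mer windows are supported")
    windows = []
    for site in sites:
        key = SiteKey.parse(site) if isinstance(site, str) else site
        seq = protein_sequences[key.accession]
        pos = key.position  # 1-based
        if not 1 <= pos <= len(seq) or seq[pos - 1] != key.residue:
            raise ValueError(
                f"site {key}: protein residue at {pos} is "
                f"{seq[pos - 1] if 1 <= pos <= len(seq) else 'absent'}, "
                f"expected {key.residue}"
            )
        left = seq[max(0, pos - 1 - _FLANK) : pos - 1]
        right = seq[pos : pos + _FLANK]
        window = "_" * (_FLANK - len(left)) + left + seq[pos - 1] + right
        window = window + "_" * (MOTIF_WIDTH - len(window))
        windows.append(MotifWindow(window, key))
    return windows


@dataclass(frozen=True)
class MotifPattern:
    """Position-specific residue constraints on a 13-mer window.

    ``constraints`` maps offsets relative to the phosphosite (−6..+6) to the
    set of allowed residues at that offset; offset 0 constrains the
    phosphoacceptor itself.
    """

    name: str
    constraints: tuple[tuple[int, frozenset[str]], ...]

    @classmethod
    def build(cls, name: str, spec: Mapping[int, str]) -> "MotifPattern":
        items = tuple(
            sorted((int(off), frozenset(res)) for off, res in spec.items())
        )
        for off, _ in items:
            if not -_FLANK <= off <= _FLANK:
                raise ValueError(f"offset {off} outside ±{_FLANK}")
        return cls(name, items)

    def matches(self, window: MotifWindow | str) -> bool:
        seq = window.sequence if isinstance(window, MotifWindow) else window
        return all(seq[_FLANK + off] in residues for off, residues in self.constraints)


#: small editable set of canonical kinase-motif classes
DEFAULT_MOTIFS: tuple[MotifPattern, ...] = (
    MotifPattern.build("PKA (R-R-X-pS/pT)", {-3: "R", -2: "R", 0: "ST"}),
    MotifPattern.build("basophilic (R-X-X-pS/pT)", {-3: "RK", 0: "ST"}),
    MotifPattern.build("PKC (pS/pT-X-R/K)", {0: "ST", 2: "RK"}),
    MotifPattern.build("proline-directed (pS/pT-P)", {0: "ST", 1: "P"}),
    MotifPattern.build("CDK (pS/pT-P-X-K/R)", {0: "ST", 1: "P", 3: "KR"}),
    MotifPattern.build("CK2 (pS/pT-X-X-E/D)", {0: "ST", 3: "ED"}),
    MotifPattern.build("acidophilic (pS/pT-D/E)", {0: "ST", 1: "DE"}),
    MotifPattern.build("GSK3 (pS-X-X-X-pS)", {0: "S", 4: "ST"}),
    MotifPattern.build("SRC-family (E-E-I-pY)", {-3: "ED", 0: "Y"}),
    MotifPattern.build("pTyr-directed (pY-X-X-P)", {0: "Y", 3: "P"}),
)


def fisher_motif_enrichment(
    foreground: Sequence[MotifWindow | str],
    background: Sequence[MotifWindow | str],
    patterns: Sequence[MotifPattern] = DEFAULT_MOTIFS,
    fdr_threshold: float = 0.02,
) -> pd.DataFrame:
    """One-sided Fisher's exact motif enrichment with BH control.

    For each pattern a 2×2 table (match / non-match × foreground /
    background) is tested for enrichment of matches in the foreground;
    q-values are Benjamini–Hochberg and a pattern is enriched iff
    ``q < fdr_threshold``.
    """
    if not foreground or not background:
        raise ValueError("foreground and background must be non-empty")
    rows = []
    for pat in patterns:
        fg_match = sum(pat.matches(w) for w in foreground)
        bg_match = sum(pat.matches(w) for w in background)
        table = [
            [fg_match, len(foreground) - fg_match],
            [bg_match, len(background) - bg_match],
        ]
        odds, p = sps.fisher_exact(table, alternative="greater")
        rows.append(
            {
                "motif": pat.name,
                "fg_match": fg_match,
                "fg_total": len(foreground),
                "bg_match": bg_match,
                "bg_total": len(background),
                "odds_ratio": odds,
                "p_value": p,
            }
        )
    out = pd.DataFrame(rows).set_index("motif")
    out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
    out["enriched"] = out["q_value"] < fdr_threshold
    return out
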