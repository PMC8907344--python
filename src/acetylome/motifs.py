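"""Acetyl-site sequence-motif extraction and residue-enrichment heatmaps.

Motif extraction follows the greedy motif-x procedure: against a proteome
background of all K-centered windows, repeatedly fix the (position,
residue) with the smallest one-sided binomial enrichment p-value among
those below the significance threshold with at least ``min_occurrences``
foreground matches, restrict both foreground and background to matching
windows, and recurse; windows matched by an emitted motif are removed
before searching for the next motif, so motifs are mutually exclusive on
the foreground.  The background is position-specific because the recursion
conditions on previously fixed positions.

The residue heatmap is the complementary position-frequency view: for each
of the 20 residues at each flanking position, a two-sided Fisher exact test
of foreground vs. background counts, reported as sign x -log10(p) with
over-use positive and under-use negative; the always-K center column is
masked.

Padding characters ('-') never count as residue occurrences; windows
truncated by a protein terminus still contribute to the positions they
cover, and totals are per position.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .io import window_at

AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")
PAD = "-"


def _char_matrix(windows: Sequence[str]) -> np.ndarray:
    if not windows:
        return np.empty((0, 0), dtype="<U1")
    width = len(windows[0])
    for w in windows:
        if len(w) != width:
            raise ValidationError("all windows must have the same width")
    return np.array([list(w) for w in windows], dtype="<U1")


def _check_centered(matrix: np.ndarray) -> int:
    width = matrix.shape[1]
    if width % 2 != 1:
        raise ValidationError("window width must be odd (site-centered)")
    center = width // 2
    if matrix.size and not np.all(matrix[:, center] == "K"):
        raise ValidationError("every window must be centered on K")
    return center


def trim_windows(windows: Iterable[str], half_width: int) -> list[str]:
    """Trim site-centered windows to +/- half_width around the center."""
    out = []
    for w in windows:
        if len(w) % 2 != 1:
            raise ValidationError("window width must be odd")
        mid = len(w) // 2
        if mid < half_width:
            raise ValidationError("window narrower than the requested half-width")
        out.append(w[mid - half_width : mid + half_width + 1])
    return out


@dataclass(frozen=True)
class BackgroundModel:
    """Position-specific residue counts over a set of K-centered windows."""

    windows: tuple[str, ...]

    @classmethod
    def from_proteome(cls, proteome: Mapping[str, str], half_width: int) -> "BackgroundModel":
        """All K-centered windows of the proteome, '-'-padded at termini."""
        windows = [
            window_at(seq, pos + 1, half_width)
            for seq in proteome.values()
            for pos, residue in enumerate(seq)
            if residue == "K"
        ]
        if not windows:
            raise ValidationError("the proteome contains no lysines")
        return cls(windows=tuple(windows))

    @classmethod
    def from_windows(cls, windows: Iterable[str]) -> "BackgroundModel":
        windows = tuple(windows)
        if not windows:
            raise ValidationError("background window set must be non-empty")
        return cls(windows=windows)

    @cached_property
    def matrix(self) -> np.ndarray:
        m = _char_matrix(self.windows)
        _check_centered(m)
        return m

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    @property
    def half_width(self) -> int:
        return len(self.windows[0]) // 2

    def frequencies(self) -> pd.DataFrame:
        """Per-position residue frequencies (padding excluded); columns are
        offsets from the central K, rows the 20 residues; each column sums
        to 1 wherever any residue is observed."""
        m = self.matrix
        offsets = np.arange(m.shape[1]) - m.shape[1] // 2
        covered = (m != PAD).sum(axis=0).astype(float)
        data = {
            off: [
                (m[:, j] == aa).sum() / covered[j] if covered[j] else np.nan
                for aa in AMINO_ACIDS
            ]
            for j, off in enumerate(offsets)
        }
        return pd.DataFrame(data, index=list(AMINO_ACIDS))


@dataclass(frozen=True)
class MotifStep:
    """One greedy fixing step: the position/residue fixed and its evidence."""

    position: int  # offset from the central K, never 0
    residue: str
    p_value: float
    n_matching: int


@dataclass(frozen=True)
class Motif:
    """A fixed-position acetyl-site motif, e.g. ``KxxxxK(ac)``."""

    steps: tuple[MotifStep, ...]
    n_matching: int
    half_width: int

    @property
    def fixed(self) -> tuple[tuple[int, str], ...]:
        return tuple((s.position, s.residue) for s in self.steps)

    @property
    def p_values(self) -> tuple[float, ...]:
        return tuple(s.p_value for s in self.steps)

    @property
    def pattern(self) -> str:
        """Field notation: central K rendered K(ac), fixed residues as
        letters, free positions as x, trimmed to the motif's extent."""
        by_position = dict(self.fixed)
        lo = min(0, *by_position) if by_position else 0
        hi = max(0, *by_position) if by_position else 0
        parts = []
        for offset in range(lo, hi + 1):
            if offset == 0:
                parts.append("K(ac)")
            else:
                parts.append(by_position.get(offset, "x"))
        return "".join(parts)


def binomial_p(n: int, k: int, p0: float) -> float:
    """Upper-tail binomial p-value P(X >= k | X ~ Binomial(n, p0))."""
    if not 0 <= k <= n:
        raise ValidationError("need 0 <= k <= n")
    if not 0.0 <= p0 <= 1.0:
        raise ValidationError("need 0 <= p0 <= 1")
    if k == 0:
        return 1.0
    return float(stats.binom.sf(k - 1, n, p0))


def _candidate_table(
    fg: np.ndarray, bg: np.ndarray, center: int
) -> list[tuple[float, int, int, str]]:
    """(p, count, position_index, residue) for every non-center candidate."""
    fg_covered = (fg != PAD).sum(axis=0)
    bg_covered = (bg != PAD).sum(axis=0)
    out = []
    for j in range(fg.shape[1]):
        if j == center or fg_covered[j] == 0 or bg_covered[j] == 0:
            continue
        fg_col = fg[:, j]
        bg_col = bg[:, j]
        for aa in AMINO_ACIDS:
            k = int((fg_col == aa).sum())
            if k == 0:
                continue
            p0 = (bg_col == aa).sum() / bg_covered[j]
            p = binomial_p(int(fg_covered[j]), k, float(p0))
            out.append((p, k, j, aa))
    return out


def motifx_extract(
    foreground: Sequence[str],
    background: BackgroundModel | Sequence[str],
    p_threshold: float = 0.001,
    min_occurrences: int = 12,
) -> list[Motif]:
    """Greedy motif-x extraction on fixed-width K-centered windows.

    Ties are broken deterministically: smaller p, then larger foreground
    count, then leftmost position, then alphabetical residue.
    """
    if isinstance(background, BackgroundModel):
        bg_windows: Sequence[str] = background.windows
    else:
        bg_windows = tuple(background)
    fg_all = _char_matrix(list(foreground))
    if fg_all.size == 0:
        return []
    center = _check_centered(fg_all)
    bg_all = _char_matrix(list(bg_windows))
    if bg_all.shape[1] != fg_all.shape[1]:
        raise ValidationError(
            "background windows must match the foreground width "
            f"({bg_all.shape[1]} vs {fg_all.shape[1]}); use trim_windows()"
        )
    _check_centered(bg_all)

    motifs: list[Motif] = []
    remaining = np.ones(len(fg_all), dtype=bool)
    while remaining.any():
        fg = fg_all[remaining]
        bg = bg_all
        steps: list[MotifStep] = []
        while True:
            candidates = [
                c
                for c in _candidate_table(fg, bg, center)
                if c[0] < p_threshold and c[1] >= min_occurrences
            ]
            if not candidates:
                break
            p, k, j, aa = min(candidates, key=lambda c: (c[0], -c[1], c[2], c[3]))
            fg = fg[fg[:, j] == aa]
            bg = bg[bg[:, j] == aa]
            steps.append(
                MotifStep(position=j - center, residue=aa, p_value=p, n_matching=len(fg))
            )
        if not steps:
            break
        motifs.append(
            Motif(steps=tuple(steps), n_matching=len(fg), half_width=center)
        )
        # consume the matched windows: mutually exclusive motifs
        matched = np.ones(remaining.sum(), dtype=bool)
        sub = fg_all[remaining]
        for step in steps:
            matched &= sub[:, step.position + center] == step.residue
        indices = np.flatnonzero(remaining)
        remaining[indices[matched]] = False
    return motifs


def residue_heatmap(
    foreground: Sequence[str],
    background: BackgroundModel | Sequence[str],
) -> pd.DataFrame:
    """Signed -log10 Fisher-exact residue-by-position enrichment matrix.

    Rows are the 20 residues, columns the offsets from the central K; a
    cell is +(-log10 p) where the foreground over-uses the residue at that
    position relative to the background and -(-log10 p) where it under-uses
    it.  The center column (always K in the foreground) is NaN.
    """
    if isinstance(background, BackgroundModel):
        bg_windows: Sequence[str] = background.windows
    else:
        bg_windows = tuple(background)
    fg = _char_matrix(list(foreground))
    if fg.size == 0:
        raise ValidationError("foreground must be non-empty")
    center = _check_centered(fg)
    bg = _char_matrix(list(bg_windows))
    if bg.shape[1] != fg.shape[1]:
        raise ValidationError("background windows must match the foreground width")
    _check_centered(bg)

    offsets = np.arange(fg.shape[1]) - center
    fg_covered = (fg != PAD).sum(axis=0)
    bg_covered = (bg != PAD).sum(axis=0)
    matrix = np.full((len(AMINO_ACIDS), fg.shape[1]), np.nan)
    for j in range(fg.shape[1]):
        if j == center or fg_covered[j] == 0 or bg_covered[j] == 0:
            continue
        for i, aa in enumerate(AMINO_ACIDS):
            k_fg = int((fg[:, j] == aa).sum())
            k_bg = int((bg[:, j] == aa).sum())
            table = [
                [k_fg, int(fg_covered[j]) - k_fg],
                [k_bg, int(bg_covered[j]) - k_bg],
            ]
            p = float(stats.fisher_exact(table, alternative="two-sided")[1])
            fg_prop = k_fg / fg_covered[j]
            bg_prop = k_bg / bg_covered[j]
            sign = 0.0 if fg_prop == bg_prop else (1.0 if fg_prop > bg_prop else -1.0)
            matrix[i, j] = sign * (-np.log10(max(p, np.finfo(float).tiny)))
    return pd.DataFrame(matrix, index=list(AMINO_ACIDS), columns=offsets)
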