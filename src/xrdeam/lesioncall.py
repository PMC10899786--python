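"""Calling CPD positions from C>T mismatch frequencies.

Deaminated CPDs leave C>T (and tandem CC>TT) mismatches at the lesion, so
mismatch positions relative to the read ends locate the lesion relative to
the two incision sites. Position frequencies are tabulated per read length,
and positions are *called* when their frequency exceeds, by at least ``k``
sample standard deviations, the mean of a background taken from the
positions closest to the 5' incision site, where no CPD is expected. At the
default k = 4 the implied two-tailed normal tail probability is 6.3e-5.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .genome import PYRIMIDINES
from .refalign import AlignedRead, MismatchRecord

BASES = "ACGT"
SUBSTITUTION_TYPES = [f"{a}>{b}" for a in BASES for b in BASES if a != b]


def single_mismatch_reads(reads: Iterable[AlignedRead]) -> List[AlignedRead]:
    return [r for r in reads if r.n_mismatches == 1 and not r.has_indel]


def ct_reads(reads: Iterable[AlignedRead]) -> List[AlignedRead]:
    """Reads whose single mismatch is C>T (read-strand orientation)."""
    return [r for r in single_mismatch_reads(reads)
            if r.mismatches[0].ref == "C" and r.mismatches[0].alt == "T"]


def non_ct_reads(reads: Iterable[AlignedRead]) -> List[AlignedRead]:
    """Control channel: single mismatches that are not C>T."""
    return [r for r in single_mismatch_reads(reads)
            if not (r.mismatches[0].ref == "C" and r.mismatches[0].alt == "T")]


def mismatch_spectrum(reads: Sequence[AlignedRead]) -> pd.DataFrame:
    """Counts and fractions of the 12 substitution types among single-mismatch
    reads, read-strand oriented."""
    counts = {t: 0 for t in SUBSTITUTION_TYPES}
    for r in single_mismatch_reads(reads):
        m = r.mismatches[0]
        key = f"{m.ref}>{m.alt}"
        if key in counts:
            counts[key] += 1
    total = sum(counts.values())
    return pd.DataFrame({
        "count": pd.Series(counts),
        "fraction": pd.Series({t: c / total if total else np.nan
                               for t, c in counts.items()}),
    })


def context_spectrum(reads: Sequence[AlignedRead]) -> Tuple[pd.Series, float]:
    """Trinucleotide-context counts for C>T mismatches and the dipyrimidine
    fraction (a pyrimidine immediately 5' or 3' of the mismatched base).

    Contexts come from the genome flanks recorded on each mismatch, so read
    edges pose no problem. Returns ``(counts over the 16 NCN contexts,
    dipyrimidine_fraction)``.
    """
    contexts = {f"{a}C{b}": 0 for a in BASES for b in BASES}
    dipy = 0
    total = 0
    for r in ct_reads(reads):
        ctx = r.mismatches[0].context
        if len(ctx) != 3 or ctx[0] not in BASES or ctx[2] not in BASES:
            continue
        contexts[ctx] += 1
        total += 1
        if ctx[0] in PYRIMIDINES or ctx[2] in PYRIMIDINES:
            dipy += 1
    frac = dipy / total if total else float("nan")
    return pd.Series(contexts), frac


def _anchor_position(m: MismatchRecord, L: int, anchor: str) -> float:
    """Mismatch position on the chosen axis; half-integer for tandem records.

    3'-anchored: -1 is the first nucleotide before the 3' cut site.
    5'-anchored: +1 is the first nucleotide after the 5' cut site.
    """
    off = m.offset + 0.5 if m.is_tandem else float(m.offset)
    if anchor == "3prime":
        return off - L
    if anchor == "5prime":
        return off + 1
    raise ValueError(f"unknown anchor {anchor!r}")


@dataclass
class PositionFrequencyMatrix:
    """Mismatch-position counts and within-length frequencies, stratified by
    read length."""

    counts: pd.DataFrame   # index: read_length; columns: position
    anchor: str

    @property
    def frequencies(self) -> pd.DataFrame:
        totals = self.counts.sum(axis=1)
        return self.counts.div(totals.replace(0, np.nan), axis=0)

    def pooled(self) -> pd.Series:
        """Marginal frequency profile over all lengths."""
        total = self.counts.to_numpy().sum()
        return self.counts.sum(axis=0) / total


def position_matrix(reads: Sequence[AlignedRead], anchor: str = "3prime") -> PositionFrequencyMatrix:
    """Tabulate mismatch positions per read length on the chosen anchor axis.

    Accepts any reads with exactly one mismatch record (single C>T reads,
    tandem calls, or a control channel) -- filter upstream.
    """
    cells: Dict[Tuple[int, float], int] = {}
    for r in reads:
        if r.n_mismatches != 1:
            continue
        pos = _anchor_position(r.mismatches[0], r.length, anchor)
        cells[(r.length, pos)] = cells.get((r.length, pos), 0) + 1
    if not cells:
        return PositionFrequencyMatrix(pd.DataFrame(), anchor)
    lengths = sorted({L for L, _ in cells})
    positions = sorted({p for _, p in cells})
    mat = pd.DataFrame(0, index=lengths, columns=positions, dtype=int)
    for (L, p), c in cells.items():
        mat.loc[L, p] = c
    mat.index.name = "read_length"
    mat.columns.name = "position"
    return PositionFrequencyMatrix(mat, anchor)


def tail_probability(k: float = 4.0) -> float:
    """Two-tailed normal tail probability at the k-SD enrichment threshold."""
    return 2.0 * stats.norm.sf(k)


def call_enriched_positions(matrix: PositionFrequencyMatrix,
                            n_background: int = 10,
                            k: float = 4.0) -> pd.DataFrame:
    """Call lesion positions per read length against a 5'-anchored background.

    For each read length the background is the ``n_background`` positions of
    that length's frequency vector closest to the 5' end; its mean and sample
    (n-1) standard deviation set the threshold. A position is called when its
    frequency is >= mean + k*SD and strictly exceeds the mean (so a flat
    vector with SD 0 calls nothing); a degenerate zero-SD background is
    flagged in the output. Lengths too short to host the background are
    skipped.
    """
    rows = []
    counts = matrix.counts
    for L in counts.index:
        row = counts.loc[L]
        total = float(row.sum())
        if total == 0:
            continue
        observed = {float(p): float(c) / total for p, c in row.items() if c > 0}
        if matrix.anchor == "3prime":
            grid = {float(p) for p in range(-int(L), 0)}
        else:
            grid = {float(p) for p in range(1, int(L) + 1)}
        positions = sorted(grid | set(observed))  # ascending = 5'-most first
        if len(positions) < n_background + 1:
            continue
        bg = np.array([observed.get(p, 0.0) for p in positions[:n_background]])
        mu = float(bg.mean())
        sd = float(bg.std(ddof=1))
        if sd <= 1e-12:  # numerically identical background frequencies
            sd = 0.0
        for p in positions:
            f = observed.get(p, 0.0)
            excess = f - mu > 1e-12  # strict frequency excess over the mean
            z = (f - mu) / sd if sd > 0 else np.inf if excess else 0.0
            called = f > 0 and excess and f >= mu + k * sd
            rows.append((L, p, f, mu, sd, z, called, sd == 0.0))
    return pd.DataFrame(rows, columns=["read_length", "position", "frequency",
                                       "background_mean", "background_sd", "z",
                                       "called", "degenerate_background"])


def called_positions(calls: pd.DataFrame) -> Dict[int, List[float]]:
    """Map read length -> sorted list of called positions."""
    out: Dict[int, List[float]] = {}
    for row in calls[calls["called"]].itertuples(index=False):
        out.setdefault(int(row.read_length), []).append(float(row.position))
    return {L: sorted(v) for L, v in out.items()}
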