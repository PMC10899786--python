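"""Read-level quality filters for XR-seq alignments.

The filter cascade mirrors standard excision-fragment preprocessing:
indel-containing reads, reads with more than one mismatch (tandem candidates
are routed to :mod:`xrdeam.tandem` instead), reads containing N, reads
outside the species read-length range, and finally reads whose genomic 3'
flank is an adapter-homologous TGG (a mispriming signature). Rules are
applied in that fixed order; a read failing several rules is counted once,
under the first failing rule, so the report's counts are conserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .genome import GenomeSequence, PYRIMIDINES
from .refalign import AlignedRead, three_prime_flank, extract_context


@dataclass
class FilterReport:
    input: int = 0
    removed_indel: int = 0
    removed_multi_mismatch: int = 0
    removed_N: int = 0
    removed_length: int = 0
    removed_tgg: int = 0

    @property
    def removed(self) -> int:
        return (self.removed_indel + self.removed_multi_mismatch + self.removed_N
                + self.removed_length + self.removed_tgg)

    @property
    def retained(self) -> int:
        return self.input - self.removed

    def as_dict(self) -> Dict[str, int]:
        return {
            "input": self.input,
            "removed_indel": self.removed_indel,
            "removed_multi_mismatch": self.removed_multi_mismatch,
            "removed_N": self.removed_N,
            "removed_length": self.removed_length,
            "removed_tgg": self.removed_tgg,
            "retained": self.retained,
        }


def basic_filters(reads: Sequence[AlignedRead], length_range: Tuple[int, int],
                  report: Optional[FilterReport] = None,
                  max_mismatches: int = 1) -> Tuple[List[AlignedRead], FilterReport]:
    """Apply the indel / multi-mismatch / N / length rules, in that order."""
    if report is None:
        report = FilterReport()
    report.input += len(reads)
    lmin, lmax = length_range
    kept = []
    for r in reads:
        if r.has_indel:
            report.removed_indel += 1
        elif r.n_mismatches > max_mismatches:
            report.removed_multi_mismatch += 1
        elif r.has_N or "N" in r.sequence:
            report.removed_N += 1
        elif not lmin <= r.length <= lmax:
            report.removed_length += 1
        else:
            kept.append(r)
    return kept, report


def dipyrimidine_profile(reads: Sequence[AlignedRead]) -> pd.Series:
    """Dipyrimidine frequency per position relative to the 3' end.

    All reads must share one length L. A pyrimidine pair occupying read
    positions (p-1, p) is reported at p, the position of its 3' base, on the
    3'-anchored axis (-1 = last read base), so positions run -1 .. -(L-1).
    """
    if not reads:
        raise ValueError("no reads")
    L = reads[0].length
    if any(r.length != L for r in reads):
        raise ValueError("reads must share a single length")
    counts = np.zeros(L - 1)
    for r in reads:
        s = r.sequence
        for j in range(1, L):
            if s[j - 1] in PYRIMIDINES and s[j] in PYRIMIDINES:
                counts[j - 1] += 1
    positions = [j - L for j in range(1, L)]  # j=L-1 -> -1
    return pd.Series(counts / len(reads), index=positions).sort_index()


def length_scores(reads: Sequence[AlignedRead]) -> pd.DataFrame:
    """Per read length: the best 3'-anchored dipyrimidine frequency, the
    position attaining it, the read count, and score = frequency * count."""
    by_len: Dict[int, List[AlignedRead]] = {}
    for r in reads:
        by_len.setdefault(r.length, []).append(r)
    rows = []
    for L in sorted(by_len):
        prof = dipyrimidine_profile(by_len[L])
        best_pos = int(prof.idxmax())
        best = float(prof.max())
        n = len(by_len[L])
        rows.append((L, best_pos, best, n, best * n))
    return pd.DataFrame(rows, columns=["read_length", "best_position",
                                       "best_frequency", "n_reads", "score"]
                        ).set_index("read_length")


def derive_length_range_from_scores(scores: pd.Series,
                                    expected_length: Optional[int] = None,
                                    decline_fraction: float = 0.2) -> Tuple[int, int]:
    """Select the species read-length range from a length -> score table.

    The qualifying lengths are those whose score is at least
    ``decline_fraction`` of the maximum ("sharp decline" heuristic). Among
    the maximal contiguous runs of qualifying lengths, the run containing
    ``expected_length`` wins if one is given and present; otherwise the run
    holding the highest score, with ties broken toward longer lengths.
    """
    scores = scores.sort_index()
    if scores.empty:
        raise ValueError("no reads")
    threshold = decline_fraction * scores.max()
    qualifying = [int(L) for L, s in scores.items() if s >= threshold]
    runs: List[List[int]] = []
    for L in qualifying:
        if runs and L == runs[-1][-1] + 1:
            runs[-1].append(L)
        else:
            runs.append([L])
    if expected_length is not None:
        for run in runs:
            if run[0] <= expected_length <= run[-1]:
                return run[0], run[-1]
    # (max score in run, larger lengths win ties)
    best = max(runs, key=lambda run: (max(scores[L] for L in run), run[-1]))
    return best[0], best[-1]


def derive_length_range(reads: Sequence[AlignedRead],
                        expected_length: Optional[int] = None,
                        decline_fraction: float = 0.2) -> Tuple[int, int]:
    if not reads:
        raise ValueError("no reads")
    table = length_scores(reads)
    return derive_length_range_from_scores(table["score"], expected_length,
                                           decline_fraction)


def tgg_filter(reads: Sequence[AlignedRead], genome: GenomeSequence,
               motif: str = "TGG",
               report: Optional[FilterReport] = None,
               ) -> Tuple[List[AlignedRead], List[AlignedRead]]:
    """Remove reads whose genomic 3' flank equals ``motif`` (read orientation).

    Such reads are the mispriming signature: a fragment truncated at an
    internal adapter-homologous site leaves the motif immediately past its
    apparent 3' cut site. A flank that runs off the contig is N-padded and
    therefore never matches; the read is kept.
    """
    kept, removed = [], []
    w = len(motif)
    for r in reads:
        if three_prime_flank(r, genome, w) == motif:
            removed.append(r)
        else:
            kept.append(r)
    if report is not None:
        report.removed_tgg += len(removed)
    return kept, removed


def flank_motif_profile(reads: Sequence[AlignedRead], genome: GenomeSequence,
                        motif: str = "TGG", flank: int = 10) -> pd.DataFrame:
    """Motif frequency by position and read length, flanks included.

    Positions locate the motif's first base on the 3'-anchored axis:
    -1 is the last read base, +1 the first base past the 3' cut site, and
    positions below -L continue into the 5' flank. Returns a tidy frame
    (read_length, position, frequency, n_reads).
    """
    w = len(motif)
    counts: Dict[Tuple[int, int], int] = {}
    totals: Dict[int, int] = {}
    for r in reads:
        L = r.length
        totals[L] = totals.get(L, 0) + 1
        ext = extract_context(r, genome, flank)
        for idx in range(len(ext) - w + 1):
            if ext[idx:idx + w] == motif:
                ridx = idx - flank  # read coordinate of the motif's first base
                pos = ridx - L if ridx < L else ridx - L + 1
                counts[(L, pos)] = counts.get((L, pos), 0) + 1
    rows = [(L, pos, c / totals[L], totals[L]) for (L, pos), c in sorted(counts.items())]
    return pd.DataFrame(rows, columns=["read_length", "position", "frequency", "n_reads"])
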