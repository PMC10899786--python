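"""Aligning reads with tandem CC>TT deamination via revertant sequences.

A CC CPD whose two cytosines both deaminate reads as TT, i.e. two adjacent
mismatches. Seeded aligners (and this package's one-mismatch matcher) drop
such reads. The revertant strategy recovers them: every TT occurrence in the
read (overlapping occurrences included) yields a candidate *revertant* with
that TT restored to CC; a tandem mismatch is called when exactly one
revertant matches the genome exactly, at exactly one locus, and the original
read matches nowhere. The call's lesion coordinate is the half-base between
the two substituted bases.

The same machinery runs in control mode for any dinucleotide pair
(e.g. GG>AA), which should find essentially nothing in UV data.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

from .genome import GenomeSequence
from .refalign import AlignedRead, KmerIndex, MismatchRecord, make_aligned_read


def enumerate_revertants(sequence: str, src: str = "TT", dst: str = "CC"
                         ) -> List[Tuple[int, str]]:
    """All ``(offset, variant)`` with one ``src`` occurrence replaced by ``dst``.

    Overlapping occurrences each count: ``"TTT"`` yields variants at offsets
    0 and 1.
    """
    w = len(src)
    out = []
    i = sequence.find(src)
    while i != -1:
        out.append((i, sequence[:i] + dst + sequence[i + w:]))
        i = sequence.find(src, i + 1)
    return out


@dataclass
class TandemCall:
    read: AlignedRead          # placed read with its tandem MismatchRecord
    offset: int                # read index of the 5' base of the pair

    @property
    def lesion_halfbase(self) -> float:
        return self.offset + 0.5


def adjudicate(read_id: str, sequence: str, index: KmerIndex,
               src: str = "TT", dst: str = "CC"
               ) -> Tuple[Optional[TandemCall], str]:
    """Decide whether one tandem substitution explains a non-aligning read.

    Returns ``(call, "ok")`` or ``(None, reason)`` with reason one of
    ``no_variant_hit``, ``multi_variant_hit``, ``variant_multimapped``,
    ``original_aligned``. The original-sequence test is on *exact*
    occurrences only, mirroring the exact-matching contract of the revertant
    search.
    """
    if index.occurrence_count(sequence) > 0:
        return None, "original_aligned"
    hits = []
    for offset, variant in enumerate_revertants(sequence, src, dst):
        occ = index.find_all(variant, limit=2)
        if occ:
            hits.append((offset, occ))
    if not hits:
        return None, "no_variant_hit"
    if len(hits) > 1:
        return None, "multi_variant_hit"
    offset, occ = hits[0]
    if len(occ) > 1:
        return None, "variant_multimapped"
    contig, start, strand = occ[0]
    read = make_aligned_read(read_id, sequence, index.genome, contig, start, strand)
    # collapse the two adjacent single-base records into one tandem record
    L = len(sequence)
    tandem = MismatchRecord(
        offset=offset, position_rel_3prime=offset - L,
        ref=dst, alt=src, is_tandem=True,
        context=next((m.context for m in read.mismatches if m.offset == offset), ""),
    )
    read.mismatches = [tandem]
    return TandemCall(read=read, offset=offset), "ok"


def tandem_pipeline(
    reads: Sequence[Tuple[str, str]],
    index: KmerIndex,
    length_range: Tuple[int, int],
    motif: str = "TGG",
    src: str = "TT",
    dst: str = "CC",
) -> Tuple[List[TandemCall], Counter]:
    """Adjudicate raw reads and apply the standard read-level filters.

    ``reads`` are ``(read_id, sequence)`` pairs -- typically the reads that
    failed single-mismatch alignment or carried two mismatches. Calls then
    pass the species length-range filter and the 3' TGG mispriming filter,
    exactly as single-mismatch reads do. Returns the surviving calls plus a
    Counter of rejection/filter reasons.
    """
    from .readqc import tgg_filter  # deferred: readqc imports refalign only

    reasons: Counter = Counter()
    calls: List[TandemCall] = []
    lmin, lmax = length_range
    for read_id, sequence in reads:
        if len(sequence) < index.k:
            reasons["too_short"] += 1
            continue
        call, reason = adjudicate(read_id, sequence, index, src, dst)
        if call is None:
            reasons[reason] += 1
            continue
        if not lmin <= call.read.length <= lmax:
            reasons["length_range"] += 1
            continue
        calls.append(call)
    kept_reads, removed = tgg_filter([c.read for c in calls], index.genome, motif)
    reasons["tgg_flank"] += len(removed)
    kept_ids = {r.read_id for r in kept_reads}
    calls = [c for c in calls if c.read.read_id in kept_ids]
    reasons["called"] = len(calls)
    return calls, reasons


def calls_table(calls: Sequence[TandemCall]):
    """Tidy frame of tandem calls (one row per call)."""
    import pandas as pd

    rows = [(c.read.read_id, c.read.contig, c.read.start, c.read.end,
             c.read.strand, c.offset, c.lesion_halfbase, c.read.length)
            for c in calls]
    return pd.DataFrame(rows, columns=["read_id", "contig", "start", "end",
                                       "strand", "offset", "lesion_halfbase",
                                       "read_length"])
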