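"""Read placement and per-read mismatch extraction.

Two routes place reads on the reference:

* an internal exact / one-mismatch matcher over a k-mer index, suitable for
  the synthetic genomes this package simulates (a deliberately deterministic
  stand-in for an external seeded aligner at desk scale);
* SAM import (:func:`import_sam`) for reads aligned externally.

Either way the product is an :class:`AlignedRead` carrying read-orientation
sequence and a list of :class:`MismatchRecord` extracted by base-wise
comparison against the reference interval. All internal coordinates are
0-based half-open; SAM is converted on ingest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional, Tuple

from .genome import GenomeSequence, fetch, revcomp


@dataclass
class MismatchRecord:
    """One substitution inside a read.

    ``offset`` counts from the read's 5' end (0-based); ``position_rel_3prime``
    is negative, with -1 the last read base. Tandem records describe two
    adjacent substituted bases; their offset is the 5' base of the pair.
    ``context`` is the trinucleotide centred on the mismatched reference base,
    in read-strand orientation (N-padded at contig edges).
    """

    offset: int
    position_rel_3prime: int
    ref: str
    alt: str
    context: str = ""
    is_tandem: bool = False


@dataclass
class AlignedRead:
    read_id: str
    contig: str
    start: int
    end: int
    strand: str
    sequence: str
    mismatches: List[MismatchRecord] = field(default_factory=list)
    has_indel: bool = False
    has_N: bool = False

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def n_mismatches(self) -> int:
        return len(self.mismatches)


class KmerIndex:
    """Exact-occurrence index over the forward genome.

    Supports locating every occurrence of a query of length >= k on either
    strand. Minus-strand occurrences are reported at the forward-genome start
    of the matching interval.
    """

    def __init__(self, genome: GenomeSequence, k: int = 10):
        self.genome = genome
        self.k = k
        self._table: Dict[str, List[Tuple[str, int]]] = {}
        for contig, seq in genome.items():
            for i in range(len(seq) - k + 1):
                self._table.setdefault(seq[i:i + k], []).append((contig, i))

    def _forward_hits(self, query: str, limit: Optional[int]) -> List[Tuple[str, int]]:
        hits = []
        for contig, i in self._table.get(query[: self.k], ()):
            if self.genome[contig][i:i + len(query)] == query:
                hits.append((contig, i))
                if limit is not None and len(hits) >= limit:
                    break
        return hits

    def find_all(self, query: str, limit: Optional[int] = None) -> List[Tuple[str, int, str]]:
        """Occurrences of ``query`` on both strands as (contig, start, strand)."""
        if len(query) < self.k:
            raise ValueError(f"query shorter than index k={self.k}")
        out = [(c, i, "+") for c, i in self._forward_hits(query, limit)]
        if limit is None or len(out) < limit:
            rc = revcomp(query)
            rest = None if limit is None else limit - len(out)
            out += [(c, i, "-") for c, i in self._forward_hits(rc, rest)]
        return out

    def occurrence_count(self, query: str) -> int:
        """0, 1, or 2 (meaning >= 2)."""
        return len(self.find_all(query, limit=2))


def _mismatch_records(sequence: str, genome: GenomeSequence, contig: str,
                      start: int, end: int, strand: str) -> List[MismatchRecord]:
    """Base-wise comparison of a placed read against the reference interval."""
    L = len(sequence)
    ext = fetch(genome, contig, start - 1, end + 1)
    if strand == "-":
        ext = revcomp(ext)
    ref = ext[1:-1]
    records = []
    for i in range(L):
        if sequence[i] != ref[i]:
            records.append(MismatchRecord(
                offset=i, position_rel_3prime=i - L,
                ref=ref[i], alt=sequence[i], context=ext[i:i + 3],
            ))
    return records


def make_aligned_read(read_id: str, sequence: str, genome: GenomeSequence,
                      contig: str, start: int, strand: str) -> AlignedRead:
    """Construct an AlignedRead at a known placement, extracting mismatches."""
    end = start + len(sequence)
    return AlignedRead(
        read_id=read_id, contig=contig, start=start, end=end, strand=strand,
        sequence=sequence,
        mismatches=_mismatch_records(sequence, genome, contig, start, end, strand),
        has_N="N" in sequence,
    )


def _count_mismatches(sequence: str, genome: GenomeSequence, contig: str,
                      start: int, strand: str, cap: int) -> int:
    seq = genome[contig]
    end = start + len(sequence)
    if start < 0 or end > len(seq):
        return cap + 1
    ref = seq[start:end]
    probe = sequence if strand == "+" else revcomp(sequence)
    n = 0
    for a, b in zip(probe, ref):
        if a != b:
            n += 1
            if n > cap:
                break
    return n


def align_read(read_id: str, sequence: str, index: KmerIndex,
               max_mismatches: int = 1) -> Tuple[Optional[AlignedRead], str]:
    """Place one read; returns ``(aligned_or_None, reason)``.

    Exact placements are preferred; otherwise one-mismatch candidates are
    found by the pigeonhole principle (one read half must match exactly).
    A read is reported only when its best-scoring placement is unique;
    multi-mapping at the best score yields ``(None, "ambiguous")``.
    """
    L = len(sequence)
    if L < index.k:
        return None, "too_short"
    genome = index.genome
    exact = index.find_all(sequence, limit=2)
    if len(exact) == 1:
        contig, start, strand = exact[0]
        return make_aligned_read(read_id, sequence, genome, contig, start, strand), "ok"
    if len(exact) >= 2:
        return None, "ambiguous"
    if max_mismatches < 1:
        return None, "unaligned"

    half = L // 2
    parts = ((0, sequence[:half]), (half, sequence[half:]))
    candidates = set()
    for off, part in parts:
        if len(part) < index.k:
            continue
        for contig, ppos, strand in index.find_all(part, limit=64):
            if strand == "+":
                candidates.add((contig, ppos - off, "+"))
            else:
                # part matched as revcomp on the forward genome: the read's
                # forward-genome start is ppos - (L - off - len(part))
                candidates.add((contig, ppos - (L - off - len(part)), "-"))
    best: List[Tuple[str, int, str]] = []
    best_n = max_mismatches + 1
    for contig, start, strand in candidates:
        n = _count_mismatches(sequence, genome, contig, start, strand, max_mismatches)
        if n < best_n:
            best, best_n = [(contig, start, strand)], n
        elif n == best_n:
            best.append((contig, start, strand))
    if best_n > max_mismatches or not best:
        return None, "unaligned"
    if len(best) > 1:
        return None, "ambiguous"
    contig, start, strand = best[0]
    return make_aligned_read(read_id, sequence, genome, contig, start, strand), "ok"


_SUPPORTED_CIGAR = {0, 7, 8}  # M, =, X
_INDEL_CIGAR = {1, 2, 3}      # I, D, N


def import_sam(path, genome: GenomeSequence) -> Iterator[AlignedRead]:
    """Stream AlignedReads from a SAM file, extracting mismatches from the
    reference.

    Minus-strand records are re-expressed in read orientation, so mismatch
    offsets count from the read's 5' end. Records with indels or other
    unsupported CIGAR operations are yielded with ``has_indel`` set and no
    mismatch extraction (downstream filters drop them).
    """
    import pysam

    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.cigartuples is None:
                continue
            ops = {op for op, _ in rec.cigartuples}
            strand = "-" if rec.is_reverse else "+"
            if ops - _SUPPORTED_CIGAR:
                yield AlignedRead(
                    read_id=rec.query_name, contig=rec.reference_name,
                    start=rec.reference_start, end=rec.reference_end or rec.reference_start,
                    strand=strand, sequence=rec.get_forward_sequence() or "",
                    has_indel=True,
                )
                continue
            seq = rec.get_forward_sequence()  # original read orientation
            yield make_aligned_read(rec.query_name, seq, genome,
                                    rec.reference_name, rec.reference_start, strand)


def write_sam(reads, genome: GenomeSequence, path) -> None:
    """Write AlignedReads as a text SAM file (minimal dialect)."""
    import pysam

    names = list(genome)
    header = {"HD": {"VN": "1.6", "SO": "unsorted"},
              "SQ": [{"SN": c, "LN": len(genome[c])} for c in names]}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for r in reads:
            a = pysam.AlignedSegment(out.header)
            a.query_name = r.read_id
            a.reference_id = names.index(r.contig)
            a.reference_start = r.start
            a.cigarstring = f"{r.length}M"
            a.mapping_quality = 42
            a.flag = 16 if r.strand == "-" else 0
            a.query_sequence = revcomp(r.sequence) if r.strand == "-" else r.sequence
            out.write(a)


def extract_context(read: AlignedRead, genome: GenomeSequence, flank: int = 10) -> str:
    """Read sequence extended by genomic flanks, in read orientation.

    For minus-strand reads the expanded genomic interval is reverse
    complemented so the last ``flank`` bases are always past the read's 3'
    end. The *read* portion is the reference sequence (flanks come from the
    genome, so any mismatch bases inside the read are not preserved here);
    intervals leaving the contig are N-padded.
    """
    ext = fetch(genome, read.contig, read.start - flank, read.end + flank)
    return revcomp(ext) if read.strand == "-" else ext


def three_prime_flank(read: AlignedRead, genome: GenomeSequence, width: int = 3) -> str:
    """The ``width`` genomic bases immediately past the read's 3' end."""
    return extract_context(read, genome, flank=width)[-width:]
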