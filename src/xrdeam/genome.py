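"""Reference sequences and small sequence utilities.

A genome is represented as a plain ``dict`` mapping contig name to an
upper-case A/C/G/T/N string. This is deliberately simple: the package targets
desk-scale synthetic genomes and small references, not chromosome-scale
assemblies.
"""

from __future__ import annotations

from typing import Dict, Iterator, Tuple

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GenomeSequence = Dict[str, str]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

PYRIMIDINES = frozenset("CT")
PURINES = frozenset("AG")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


def load_fasta(path) -> GenomeSequence:
    """Read a FASTA file into a contig-name -> sequence dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(genome: GenomeSequence, path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


def fetch(genome: GenomeSequence, contig: str, start: int, end: int) -> str:
    """Return genome[contig][start:end], N-padded where the interval leaves the contig.

    Coordinates are 0-based half-open; negative ``start`` or ``end`` beyond the
    contig length are allowed and padded with N so the result always has length
    ``end - start``.
    """
    seq = genome[contig]
    left = max(start, 0)
    right = min(end, len(seq))
    if left >= right:
        return "N" * (end - start)
    return "N" * (left - start) + seq[left:right] + "N" * (end - right)


def dinucleotide_sites(seq: str, dinuc: str) -> Iterator[int]:
    """Yield every start offset of ``dinuc`` in ``seq`` (overlapping occurrences)."""
    i = seq.find(dinuc)
    while i != -1:
        yield i
        i = seq.find(dinuc, i + 1)


def is_dipyrimidine(pair: str) -> bool:
    return len(pair) == 2 and pair[0] in PYRIMIDINES and pair[1] in PYRIMIDINES


def gc_fraction(seqs) -> float:
    """GC fraction over an iterable of sequences, ignoring N."""
    gc = at = 0
    for s in seqs:
        gc += s.count("G") + s.count("C")
        at += s.count("A") + s.count("T")
    total = gc + at
    if total == 0:
        raise ValueError("no A/C/G/T bases")
    return gc / total


def contig_intervals(genome: GenomeSequence) -> Iterator[Tuple[str, int]]:
    for name, seq in genome.items():
        yield name, len(seq)
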