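"""End-to-end workflows over the synthetic fixture.

These helpers chain the stages the way a user would at the shell: simulate a
library, place reads (single-mismatch matcher plus the tandem revertant
route), apply the QC filters, and hand lesion-anchored reads to the incision
statistics. They are what the command-line interface, the examples, and the
acceptance analyses run.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import incision, lesioncall, readqc, refalign, simdata, tandem
from .genome import GenomeSequence
from .incision import IncisionRecord
from .readqc import FilterReport
from .refalign import AlignedRead, KmerIndex
from .simdata import SimConfig
from .tandem import TandemCall


@dataclass
class AlignmentResult:
    aligned: List[AlignedRead]
    unaligned: List[Tuple[str, str]]   # (read_id, sequence) for the tandem route
    reasons: Counter = field(default_factory=Counter)


def align_reads(reads: Sequence[Tuple[str, str]], index: KmerIndex,
                max_mismatches: int = 1) -> AlignmentResult:
    """Place every read with the internal exact/one-mismatch matcher."""
    res = AlignmentResult([], [])
    for read_id, seq in reads:
        if len(seq) < index.k:
            res.reasons["too_short"] += 1
            continue
        aread, reason = refalign.align_read(read_id, seq, index, max_mismatches)
        res.reasons[reason] += 1
        if aread is not None:
            res.aligned.append(aread)
        else:
            res.unaligned.append((read_id, seq))
    return res


@dataclass
class SingleMismatchAnalysis:
    kept: List[AlignedRead]            # QC-passed aligned reads
    ct: List[AlignedRead]              # ... whose single mismatch is C>T
    report: FilterReport
    records: List[IncisionRecord]      # incision records from the C>T channel


def single_mismatch_pipeline(reads: Sequence[Tuple[str, str]],
                             index: KmerIndex,
                             length_range: Tuple[int, int],
                             motif: str = "TGG") -> SingleMismatchAnalysis:
    """Align, QC-filter, and extract C>T incision records."""
    aln = align_reads(reads, index)
    kept, report = readqc.basic_filters(aln.aligned, length_range)
    kept, _ = readqc.tgg_filter(kept, index.genome, motif, report=report)
    ct = lesioncall.ct_reads(kept)
    records = incision.records_from_reads(ct, kind="single_CT")
    return SingleMismatchAnalysis(kept=kept, ct=ct, report=report, records=records)


def simulate_tandem_records(
    n_fragments: int,
    coupling: float,
    seed: int,
    genome_length: int = 100_000,
    p_misprime: float = 0.10,
    seq_error_rate: float = 0.001,
) -> List[IncisionRecord]:
    """Simulate a CC-lesion library with full tandem deamination and recover
    incision records end to end (revertant alignment + QC filters).

    This is the canonical route for studying incision coupling: tandem CC>TT
    mismatches pin the lesion exactly, so the recovered (d5, d3) pairs feed
    the coupling regression directly.
    """
    cfg = SimConfig(
        genome_length=genome_length,
        n_fragments=n_fragments,
        coupling=coupling,
        lesion_dinucleotide_mix={"CC": 1.0},
        p_tandem=1.0,
        p_deaminate=1.0,
        p_misprime=p_misprime,
        seq_error_rate=seq_error_rate,
        seed=seed,
    )
    genome = simdata.generate_genome(cfg)
    reads, _truth = simdata.generate_fragments(genome, cfg)
    index = KmerIndex(genome)
    calls, _reasons = tandem.tandem_pipeline(reads, index,
                                             cfg.effective_length_range())
    return incision.records_from_tandem_calls(calls)


def simulate_single_ct_records(
    n_fragments: int,
    coupling: float,
    seed: int,
    genome_length: int = 100_000,
    **overrides,
) -> Tuple[List[IncisionRecord], "SingleMismatchAnalysis", KmerIndex]:
    """Simulate a mixed-lesion library and recover single-C>T records."""
    cfg = SimConfig(genome_length=genome_length, n_fragments=n_fragments,
                    coupling=coupling, seed=seed, **overrides)
    genome = simdata.generate_genome(cfg)
    reads, _truth = simdata.generate_fragments(genome, cfg)
    index = KmerIndex(genome)
    analysis = single_mismatch_pipeline(reads, index, cfg.effective_length_range())
    return analysis.records, analysis, index
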