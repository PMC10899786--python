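"""Synthetic XR-seq fragments with known CPD lesions and ground truth.

The generator emulates the salient features of excision-repair sequencing
(XR-seq) libraries built from UV-irradiated cells:

* excised fragments whose lesion (a dipyrimidine) sits a sampled distance
  from the 3' end, with the 5' and 3' cut-site distances drawn from
  configurable categorical distributions;
* *coupling* between the two incision sites: each extra nucleotide of 5'
  cut-site distance above its mean shifts the 3' distance by ``-coupling``
  on average (the 5' incision happens first, the 3' incision compensates);
* cytosine deamination at the lesion -- a single C>T mismatch, or a tandem
  CC>TT mismatch when both cytosines of a CC lesion deaminate;
* background sequencing errors (never at the lesion dinucleotide, so truth
  labels stay unambiguous);
* mispriming: fragments lacking a 3' adapter can be rescued by PCR priming
  at an adapter-homologous TGG inside the fragment, which after in-silico
  adapter trimming yields a 3'-truncated read whose genomic 3' flank is TGG.

Every fragment is recorded in a ground-truth table so that the alignment,
filtering, lesion-calling, and incision-statistics stages downstream can be
validated against a known answer without any external data.

Distance bookkeeping
--------------------
The lesion is always a dinucleotide. Cut-site distances in the truth table
(and throughout the package) are measured to the *half-base* between the two
lesion bases, inclusive, so they are half-integers and satisfy
``d5 + d3 = L + 1`` where ``L`` is the untruncated fragment length. The
configuration distributions are over the integer components: a sampled 3'
value of 7 places the 3'-most lesion base 7 nt from the 3' end (inclusive),
i.e. a truth half-base distance of 7.5.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome import GenomeSequence, revcomp

LESION_TYPES = ("TT", "CT", "TC", "CC")

#: TruthTable column order (written as TSV with this header).
TRUTH_COLUMNS = [
    "fragment_id", "contig", "strand", "start", "end",
    "lesion_pos5", "lesion_pos3", "lesion_type", "deamination",
    "d5", "d3", "length", "read_length",
    "truncated", "truncation_offset", "n_errors", "error_offsets",
]


def _uniform_categorical(lo: int, hi: int) -> Dict[int, float]:
    n = hi - lo + 1
    return {v: 1.0 / n for v in range(lo, hi + 1)}


@dataclass
class BoundaryEffect:
    """Additive d5 shift for lesions whose distance to the nearest nucleosome
    dyad falls inside ``band`` (absolute distance, nt). The 3' distance
    compensates through the coupling rule, like any other d5 excursion."""

    band: Tuple[int, int] = (60, 73)
    shift: int = 0


@dataclass
class SimConfig:
    """Study conditions for the synthetic XR-seq library.

    Defaults emulate human CPD XR-seq at an early repair timepoint: reads of
    ~22-32 nt, lesion ~7.5 nt from the 3' end and ~20 nt from the 5' end,
    a TT-dominated lesion spectrum with ~10% CC CPDs, partial deamination,
    and a noticeable mispriming rate.
    """

    genome_length: int = 100_000
    gc_content: float = 0.41
    n_fragments: int = 10_000
    #: categorical over the integer 3' component (3'-most lesion base to 3' end, inclusive)
    d3_distribution: Dict[int, float] = field(default_factory=lambda: _uniform_categorical(6, 9))
    #: categorical over the integer 5' component before coupling/boundary shifts
    d5_base_distribution: Dict[int, float] = field(default_factory=lambda: _uniform_categorical(16, 23))
    #: fraction of a 5' excursion compensated by the 3' incision
    coupling: float = 0.46
    p_deaminate: float = 0.10
    #: P(both cytosines deaminate | lesion is CC)
    p_tandem: float = 0.15
    seq_error_rate: float = 0.001
    p_misprime: float = 0.10
    lesion_dinucleotide_mix: Dict[str, float] = field(
        default_factory=lambda: {"TT": 0.53, "CT": 0.185, "TC": 0.185, "CC": 0.10}
    )
    #: inclusive read-length hull; None derives it from the distance distributions
    length_range: Optional[Tuple[int, int]] = None
    seed: int = 0

    def validate(self) -> None:
        for name in ("gc_content", "coupling", "p_deaminate", "p_tandem",
                     "seq_error_rate", "p_misprime"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.genome_length < 1000:
            raise ValueError("genome_length must be >= 1000")
        for dist, label in ((self.d3_distribution, "d3_distribution"),
                            (self.d5_base_distribution, "d5_base_distribution")):
            if not dist or abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ValueError(f"{label} probabilities must sum to 1")
            if min(dist) < 1:
                raise ValueError(f"{label} support must be >= 1")
        mix = self.lesion_dinucleotide_mix
        if set(mix) - set(LESION_TYPES) or abs(sum(mix.values()) - 1.0) > 1e-9:
            raise ValueError("lesion_dinucleotide_mix must be over {TT,CT,TC,CC} and sum to 1")
        lmin, lmax = self.effective_length_range()
        if lmin < 1:
            raise ValueError("length range incompatible with distance distributions")

    def mean_d5(self) -> float:
        return sum(v * p for v, p in self.d5_base_distribution.items())

    def effective_length_range(self) -> Tuple[int, int]:
        """Inclusive hull of possible untruncated read lengths.

        ``L = d5 + d3`` in integer components; coupling plus dithered
        rounding can move d3 by up to ``ceil(coupling * half_width) + 1``.
        """
        if self.length_range is not None:
            return self.length_range
        d5v = list(self.d5_base_distribution)
        d3v = list(self.d3_distribution)
        mean5 = self.mean_d5()
        wiggle = int(np.ceil(self.coupling * max(abs(min(d5v) - mean5),
                                                 abs(max(d5v) - mean5)))) + 1
        lmin = min(d5v) + max(1, min(d3v) - wiggle)
        lmax = max(d5v) + max(d3v) + wiggle
        return lmin, lmax

    def replace(self, **kwargs) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)


def generate_genome(cfg: SimConfig, contig: str = "chr_sim") -> GenomeSequence:
    """I.i.d. genome with P(G)=P(C)=gc/2 and P(A)=P(T)=(1-gc)/2."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    gc = cfg.gc_content
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    bases = rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=cfg.genome_length, p=p)
    return {contig: bases.tobytes().decode("ascii")}


def _site_arrays(genome: GenomeSequence, margin: int) -> Dict[Tuple[str, str], List[Tuple[str, int]]]:
    """Genomic start positions of each lesion dinucleotide per (type, strand).

    A minus-strand lesion of read-orientation type ``d`` occupies a genomic
    ``revcomp(d)`` dinucleotide; positions are the lower genomic coordinate.
    """
    out: Dict[Tuple[str, str], List[Tuple[str, int]]] = {}
    for typ in LESION_TYPES:
        for strand, target in (("+", typ), ("-", revcomp(typ))):
            sites: List[Tuple[str, int]] = []
            for contig, seq in genome.items():
                hi = len(seq) - margin
                i = seq.find(target, margin)
                while i != -1 and i < hi:
                    sites.append((contig, i))
                    i = seq.find(target, i + 1)
            out[(typ, strand)] = sites
    return out


def apply_mispriming(seq: str, lmin: int, p_misprime: float, rng: np.random.Generator,
                     motif: str = "TGG") -> Tuple[str, bool, int]:
    """Possibly truncate a read at an internal adapter-homologous motif.

    With probability ``p_misprime``, if the motif occurs at a read offset
    ``j >= lmin`` (so truncating just 5' of it leaves at least ``lmin``
    bases), the read is cut to ``seq[:j]`` at the 3'-most such offset.
    Returns ``(sequence, truncated, nt_removed)``.
    """
    if p_misprime > 0 and rng.random() < p_misprime:
        j = seq.rfind(motif)
        while j >= 0 and j < lmin:
            j = seq.rfind(motif, 0, j + len(motif) - 1)
        if j >= lmin:
            return seq[:j], True, len(seq) - j
    return seq, False, 0


def generate_fragments(
    genome: GenomeSequence,
    cfg: SimConfig,
    dyads: Optional[pd.DataFrame] = None,
    boundary: Optional[BoundaryEffect] = None,
) -> Tuple[List[Tuple[str, str]], pd.DataFrame]:
    """Simulate excised fragments; returns ``(reads, truth)``.

    ``reads`` is a list of ``(read_id, sequence)`` in read orientation after
    deamination, sequencing error, and mispriming truncation. ``truth`` is the
    per-fragment ground-truth table (see :data:`TRUTH_COLUMNS`).

    The compensated 3' component uses randomized (dithered) rounding,
    ``floor(x + U[0,1))``: the result is integer-valued but its conditional
    mean equals ``d3_base - coupling * (d5 - mean_d5)`` exactly, so the
    downstream regression estimator of the coupling is unbiased.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed + 1)
    n = cfg.n_fragments
    lmin, _ = cfg.effective_length_range()

    d5_vals = np.array(sorted(cfg.d5_base_distribution))
    d5_p = np.array([cfg.d5_base_distribution[v] for v in d5_vals], dtype=float)
    d3_vals = np.array(sorted(cfg.d3_distribution))
    d3_p = np.array([cfg.d3_distribution[v] for v in d3_vals], dtype=float)
    mean_d5 = cfg.mean_d5()

    margin = int(d5_vals.max() + d3_vals.max() + 8)
    sites = _site_arrays(genome, margin)
    types = np.array(LESION_TYPES)
    mix_p = np.array([cfg.lesion_dinucleotide_mix.get(t, 0.0) for t in LESION_TYPES])
    type_draw = rng.choice(len(types), size=n, p=mix_p)
    strand_draw = rng.choice(np.array(["+", "-"]), size=n)
    for ti, si in {(t, s) for t, s in zip(type_draw, strand_draw)}:
        if not sites[(types[ti], si)]:
            raise ValueError(
                f"no {types[ti]} dipyrimidine available on strand {si} "
                f"(genome too small or composition degenerate)"
            )

    d5 = rng.choice(d5_vals, size=n, p=d5_p).astype(float)
    d3_base = rng.choice(d3_vals, size=n, p=d3_p).astype(float)

    # pick lesion loci
    contigs = np.empty(n, dtype=object)
    pos = np.empty(n, dtype=np.int64)
    for key, sl in sites.items():
        mask = (types[type_draw] == key[0]) & (strand_draw == key[1])
        k = int(mask.sum())
        if k == 0 or not sl:
            continue
        idx = rng.integers(0, len(sl), size=k)
        contigs[mask] = [sl[i][0] for i in idx]
        pos[mask] = [sl[i][1] for i in idx]

    # nucleosome-boundary modulation of the 5' distance
    if boundary is not None and boundary.shift != 0 and dyads is not None and len(dyads):
        lo, hi = boundary.band
        for contig, grp in dyads.groupby("contig"):
            dp = np.sort(grp["pos"].to_numpy())
            mask = contigs == contig
            if not mask.any():
                continue
            centers = pos[mask] + 0.5
            j = np.searchsorted(dp, centers)
            dist = np.full(mask.sum(), np.inf)
            left_ok = j > 0
            dist[left_ok] = np.abs(centers[left_ok] - dp[j[left_ok] - 1])
            right_ok = j < len(dp)
            dist[right_ok] = np.minimum(dist[right_ok], np.abs(dp[j[right_ok]] - centers[right_ok]))
            in_band = (dist >= lo) & (dist <= hi)
            tgt = np.where(mask)[0][in_band]
            d5[tgt] += boundary.shift

    # coupled 3' distance with dithered rounding, clipped to >= 1
    d3 = np.floor(d3_base - cfg.coupling * (d5 - mean_d5) + rng.random(n))
    d3 = np.maximum(d3, 1.0)
    length = (d5 + d3).astype(int)

    d5i = d5.astype(int)
    deam_u = rng.random(n)
    tandem_u = rng.random(n)
    side_u = rng.random(n)
    err_counts = rng.binomial(np.maximum(length - 2, 0), cfg.seq_error_rate)

    reads: List[Tuple[str, str]] = []
    rows = []
    other = {"A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG"}
    for i in range(n):
        typ = types[type_draw[i]]
        strand = strand_draw[i]
        contig = contigs[i]
        p = int(pos[i])
        L = int(length[i])
        a = d5i[i] - 1  # read index of the 5'-most lesion base
        if strand == "+":
            start = p - a
            end = start + L
            frag = genome[contig][start:end]
        else:
            end = p + d5i[i] + 1
            start = end - L
            frag = revcomp(genome[contig][start:end])

        # deamination at the lesion
        deam = "none"
        seq = frag
        if typ == "CC":
            if tandem_u[i] < cfg.p_tandem:
                deam = "tandem"
                seq = seq[:a] + "TT" + seq[a + 2:]
            elif deam_u[i] < cfg.p_deaminate:
                if side_u[i] < 0.5:
                    deam = "single_5prime_C"
                    seq = seq[:a] + "T" + seq[a + 1:]
                else:
                    deam = "single_3prime_C"
                    seq = seq[:a + 1] + "T" + seq[a + 2:]
        elif typ == "CT" and deam_u[i] < cfg.p_deaminate:
            deam = "single_5prime_C"
            seq = seq[:a] + "T" + seq[a + 1:]
        elif typ == "TC" and deam_u[i] < cfg.p_deaminate:
            deam = "single_3prime_C"
            seq = seq[:a + 1] + "T" + seq[a + 2:]

        # sequencing errors, never at the lesion dinucleotide
        err_offsets: List[int] = []
        if err_counts[i]:
            eligible = [j for j in range(L) if j != a and j != a + 1]
            picks = rng.choice(len(eligible), size=min(err_counts[i], len(eligible)),
                               replace=False)
            for k in picks:
                j = eligible[k]
                seq = seq[:j] + other[seq[j]][rng.integers(0, 3)] + seq[j + 1:]
                err_offsets.append(j)

        seq, truncated, trunc = apply_mispriming(seq, lmin, cfg.p_misprime, rng)

        fid = f"frag{i}"
        reads.append((fid, seq))
        rows.append((
            fid, contig, strand, start, end,
            p, p + 1, typ, deam,
            d5i[i] + 0.5, d3[i] + 0.5, L, len(seq),
            truncated, trunc, len(err_offsets),
            ",".join(map(str, sorted(err_offsets))),
        ))

    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    return reads, truth


def read_interval(row) -> Tuple[int, int]:
    """Genomic interval of the *sequenced* read (after any 3' truncation)."""
    if row["strand"] == "+":
        return int(row["start"]), int(row["end"]) - int(row["truncation_offset"])
    return int(row["start"]) + int(row["truncation_offset"]), int(row["end"])


def generate_dyads(genome: GenomeSequence, spacing: int = 200, jitter: int = 20,
                   seed: int = 0) -> pd.DataFrame:
    """Nucleosome dyads tiled at ``spacing`` with uniform positional jitter."""
    if spacing <= 147:
        raise ValueError("spacing must exceed the 147-bp nucleosome core")
    rng = np.random.default_rng(seed)
    frames = []
    for contig, seq in genome.items():
        base = np.arange(spacing, len(seq) - spacing, spacing)
        if jitter:
            base = base + rng.integers(-jitter, jitter + 1, size=len(base))
        frames.append(pd.DataFrame({"contig": contig, "pos": base}))
    return pd.concat(frames, ignore_index=True)


def generate_blacklist(genome: GenomeSequence, n_regions: int = 5, width: int = 500,
                       seed: int = 0) -> pd.DataFrame:
    """A handful of random excludable intervals, BED-style (0-based half-open)."""
    rng = np.random.default_rng(seed)
    frames = []
    for contig, seq in genome.items():
        starts = np.sort(rng.integers(0, max(len(seq) - width, 1), size=n_regions))
        frames.append(pd.DataFrame({"contig": contig, "start": starts,
                                    "end": starts + width}))
    return pd.concat(frames, ignore_index=True)


def engineered_mispriming_dataset(
    n_fragments: int = 200,
    n_truncated: int = 80,
    read_length: int = 26,
    lmin: int = 20,
    seed: int = 0,
):
    """A genome engineered so the TGG filter is exact (synthetic construction).

    The background genome contains no GG dinucleotide, so TGG can never follow
    an untruncated fragment end by chance; TGG motifs are injected only inside
    a chosen subset of fragments, which mispriming then truncates (p=1).
    Returns ``(genome, aligned_reads, truth)`` where ``aligned_reads`` are
    :class:`~xrdeam.refalign.AlignedRead` at their true loci and ``truth``
    flags exactly the truncated set.
    """
    from .refalign import AlignedRead  # local import avoids a cycle

    rng = np.random.default_rng(seed)
    stride = read_length + 10
    glen = n_fragments * stride + 2 * stride
    bases = rng.choice(list("ACGT"), size=glen, p=[0.3, 0.2, 0.2, 0.3])
    seq = list(bases)
    for i in range(1, glen):  # strip every GG from the background
        if seq[i] == "G" and seq[i - 1] == "G":
            seq[i] = rng.choice(list("ACT"))
    starts = [stride + i * stride for i in range(n_fragments)]
    truncate = set(rng.choice(n_fragments, size=n_truncated, replace=False).tolist())
    for i in sorted(truncate):
        j = int(rng.integers(lmin, read_length - 3 + 1))
        s = starts[i] + j
        seq[s:s + 3] = list("TGG")
    genome = {"chr_eng": "".join(seq)}

    reads = []
    rows = []
    for i, s in enumerate(starts):
        frag = genome["chr_eng"][s:s + read_length]
        out, truncated, trunc = apply_mispriming(frag, lmin, 1.0, rng)
        assert truncated == (i in truncate)
        reads.append(AlignedRead(read_id=f"eng{i}", contig="chr_eng", start=s,
                                 end=s + len(out), strand="+", sequence=out))
        rows.append((f"eng{i}", truncated, trunc))
    truth = pd.DataFrame(rows, columns=["fragment_id", "truncated", "truncation_offset"])
    return genome, reads, truth


# ---------------------------------------------------------------------------
# on-disk outputs

def write_fastq(reads: Sequence[Tuple[str, str]], path) -> None:
    records = []
    for rid, seq in reads:
        rec = SeqRecord(Seq(seq), id=rid, description="")
        rec.letter_annotations["phred_quality"] = [40] * len(seq)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def write_sam(reads: Sequence[Tuple[str, str]], truth: pd.DataFrame,
              genome: GenomeSequence, path) -> None:
    """True alignments of the simulated reads, as a text SAM file."""
    import pysam

    names = list(genome)
    header = {"HD": {"VN": "1.6", "SO": "unsorted"},
              "SQ": [{"SN": c, "LN": len(genome[c])} for c in names]}
    seqs = dict(reads)
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for row in truth.itertuples(index=False):
            seq = seqs[row.fragment_id]
            if not seq:
                continue
            a = pysam.AlignedSegment(out.header)
            a.query_name = row.fragment_id
            a.reference_id = names.index(row.contig)
            rstart, rend = read_interval(row._asdict())
            a.reference_start = rstart
            a.cigarstring = f"{len(seq)}M"
            a.mapping_quality = 42
            if row.strand == "-":
                a.flag = 16
                a.query_sequence = revcomp(seq)
            else:
                a.flag = 0
                a.query_sequence = seq
            out.write(a)


def write_bed(df: pd.DataFrame, path, point: bool = False) -> None:
    """Write intervals (contig/start/end) or dyad points (contig/pos) as BED."""
    if point:
        out = pd.DataFrame({"contig": df["contig"], "start": df["pos"],
                            "end": df["pos"] + 1})
    else:
        out = df[["contig", "start", "end"]]
    out.to_csv(path, sep="\t", header=False, index=False)


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def load_truth(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
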