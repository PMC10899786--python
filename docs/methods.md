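# Methods

## Distance conventions

The lesion is a dipyrimidine, i.e. always two bases. All cut-site distances
are *inclusive* of the lesion position: a single mismatch at 0-based read
offset `i` in a read of length `L` gives `d5 = i + 1`, `d3 = L − i`; a
tandem CC>TT pair at offsets `(i, i+1)` is measured to the half-base between
its bases, `d5 = i + 1.5`, `d3 = L − i − 0.5`. Both satisfy
`d5 + d3 = L + 1`, which `IncisionRecord` enforces at construction. In the
simulator's ground truth the distances are always half-base (the true lesion
is the dinucleotide), so the configuration distributions are over integer
components: a sampled 3′ value of 7 puts the 3′-most lesion base 7 nt from
the 3′ end, a truth distance of 7.5.

A consequence worth knowing: when only one cytosine of a CC lesion
deaminates, the observed mismatch sits 0.5 nt to either side of the true
lesion centre, and the ±0.5 errors in measured d5 and d3 are perfectly
anti-correlated (their sum is pinned by the read length). Coupling estimated
from single mismatches is therefore biased away from zero relative to the
tandem-mismatch estimate — visible in the package's own simulations, where a
mixed single-mismatch channel yields a steeper d3-on-d5 slope than the
generator's coupling, while the tandem channel recovers it.

## The synthetic generator

`simdata.SimConfig` defaults describe a human-like early-repair-timepoint
library:

| parameter | default | rationale |
|---|---|---|
| genome_length / gc_content | 100 kb / 0.41 | i.i.d. genome, human-like GC |
| d5 base distribution | uniform 16–23 (mean 19.5) | mean 5′ distance ~19.4 nt |
| d3 distribution | uniform 6–9 (mean 7.5) | mean 3′ distance ~7.4 nt; lesion near the 3′ end |
| coupling | 0.46 | human tandem-mismatch estimate |
| lesion mix | TT .53 / CC .10 / CT .185 / TC .185 | measured CPD spectrum (TT-dominated, ~10% CC) |
| p_deaminate / p_tandem | 0.10 / 0.15 | partial deamination at an early timepoint |
| seq_error_rate | 0.001 | per-base substitution noise |
| p_misprime | 0.10 | a noticeable truncated-read population |

Generation order per fragment: lesion type and strand → a genomic site of
that dinucleotide → d5 from its base distribution (plus any
nucleosome-boundary shift) → compensated d3 → fragment sequence in read
orientation → deamination at the lesion → sequencing errors (never on the
lesion dinucleotide, keeping truth labels unambiguous) → mispriming
truncation.

**Coupling injection and rounding.** The 3′ component is
`d3 = d3_base − c·(d5 − mean_d5)`, rounded to an integer because incisions
fall between bases. Deterministic rounding on an integer lattice would bias
the recovered slope (with a width-8 uniform d5 support, half-away-from-zero
rounding turns c = 0.46 into a measured ~0.52), so the generator uses
randomized rounding, `floor(x + U[0,1))`: the result is integer yet its
conditional mean equals the target exactly, making the regression estimator
unbiased. Clipping at d3 ≥ 1 exists as a guard but is unreachable under the
default supports.

**Coupling is injected on the 3′ side** (d3 compensates the d5 draw),
reflecting that the 5′ incision occurs first; the nucleosome-boundary shift
is applied to d5 *before* the compensation, so boundary excursions are
partially coupled like any other.

**Mispriming.** With probability `p_misprime`, a read containing TGG at
offset ≥ Lmin is truncated just 5′ of its 3′-most eligible TGG, so the
genomic bases past the new 3′ end are TGG — the signature the flank filter
keys on. Truncation operates on the *read* sequence (post-deamination),
mirroring the physical process: in rare cases a deamination- or error-created
TGG triggers truncation whose genomic flank is not TGG, and such reads escape
the filter. This residue is intentional; the filter is exact only on the
engineered genome (`engineered_mispriming_dataset`), whose background
contains no GG so a TGG can never follow an untruncated fragment end.

**Default length range.** The simulator's default read-length range is the
hull implied by its distance distributions, not a species preset: filtering
inside the simulated support would truncate the joint (d5, d3) distribution
and bias the coupling estimator. Species ranges (human 22–30, Arabidopsis
24–30, yeast 22–25, E. coli 11–13) are available as CLI presets and as the
data-driven `derive_length_range`, which scores each length by its best
3′-anchored dipyrimidine frequency times its read count and keeps the
contiguous run above a configurable fraction (default 0.2) of the maximum —
a documented heuristic standing in for a by-inspection choice; ties favour
longer lengths, and an expected length disambiguates multimodal score
tables.

**What the generator does not emulate:** PCR amplification depth and
duplicates, adapter chemistry, quality-score structure, UV dose response,
repair kinetics over time, genome repeat structure (the genome is i.i.d., so
multi-mapping is far rarer than in real genomes), and sequence-dependent
incision preferences (no HYV bias is injected — the HYV machinery is
validated against composition nulls and engineered genomes instead). Passing
tests therefore demonstrate correctness of the estimators under the stated
generative model, not performance on real libraries.

## Alignment

The internal matcher indexes the forward genome with 10-mers and supports
exact occurrence location on both strands; one-mismatch placements come from
the pigeonhole principle (one read half must match exactly). Exact hits are
preferred; a read is reported only when its best placement is unique, and
multi-mapping reads are dropped deterministically. This is a stand-in for an
external seeded aligner at desk scale, not an emulation of its scoring. Reads
needing two substitutions — tandem deamination — are recovered only by the
revertant route, deliberately mirroring how seeded aligners drop them.

Tandem adjudication follows a strict contract: among all TT→CC revertants
(overlapping TTs each count), exactly one must have ≥1 exact hit, that
variant must hit exactly once, and the original read must have zero exact
hits. The original-read test is literal exact matching: a read whose
original sequence aligns elsewhere *with one mismatch* can still be called.
Rejection reasons (`no_variant_hit`, `multi_variant_hit`,
`variant_multimapped`, `original_aligned`) are tallied per run.

## Filters

Filter order is fixed and reported per rule (a read failing several rules is
counted once, under the first): indels, >1 mismatch, N bases, length range,
then the TGG flank. The flank is retrieved strand-aware from the genome so
"3′" always means past the read's 3′ end in read orientation; a flank that
runs off the contig is N-padded and never matches (read kept, by design).

## Lesion calling

Per read length, the C>T position-frequency vector spans every position
valid for that length (unobserved positions count as zero). The background
is the 10 positions nearest the 5′ end; the call threshold is
`mean + 4·SD` with the *sample* (n−1) SD — the choice is configurable since
either convention is defensible. A background with numerically identical
frequencies is treated as degenerate (SD 0): calls then require strict
frequency excess over the mean and are flagged as degenerate in the output.
Background positions are taken within the same per-length vector, matching
the stratified presentation of the analysis, rather than pooled across
lengths.

## Incision statistics

* **Contribution decomposition** anchors every per-length mean at the
  minimum read length, weights by read-length frequency, and normalizes the
  two sums to 100%. Because the anchor is an extreme length, a sparsely
  populated tail length can dominate; `min_reads` (default 1, i.e. the
  strict definition) drops under-populated lengths first. Run it on a
  validated length range.
* **Coupling regression** is ordinary least squares with one point per read
  (no deduplication of repeated (d5, d3) pairs), slope p-value two-sided.
  `coupling_percent = −100 × slope` is defined only for the d3-on-d5 target.
* **Shuffle control** permutes d5 without replacement, keeps each d3 with
  its record, and recomputes `L = d5 + d3 − 1`; both multisets are preserved.
  Shuffling across lesion kinds (half-integer with integer distances) is
  refused rather than silently producing half-integer lengths.
* **HYV profile**: an HYV occurrence is reported at its Y base on a
  5′-anchored axis (+1 = first read base, 0 = last flank base; the incision
  signal sits at 0). Significance uses the six 5′-most profile positions as
  background with the same 4-SD rule. In the mismatch-anchored, per-d5
  stratified variant, positions within 2 nt of the lesion are omitted
  (configurable) because dipyrimidine-forming sequences bias composition
  there.
* **Composition matrix**: information content is the relative entropy of the
  per-position base frequencies against the background implied by the input
  sequences' overall GC (q_G = q_C = GC/2); no small-sample correction is
  applied. Profile sequences are the *genomic* bases of the expanded
  interval (read body included), so mismatch bases inside reads do not enter
  composition profiles.

## Nucleosome proximity

Dyads are excluded when their ±73 nt footprint (`[d−73, d+74)`) overlaps a
blacklist interval. Lesions within ±500 bp of a dyad are binned by
strand-aligned signed distance; a lesion near two dyads enters both bins but
is counted once in the grand mean (the double-count alternative is a
documented ambiguity; the single-count default is used throughout). Each
bin's d5 and d3 samples are tested against the scalar grand mean with a
one-sample two-tailed t-test at a fixed 5e-5 cutoff, no multiple-testing
correction — the fixed cutoff *is* the procedure. Zero-variance bins off the
grand mean are flagged with p reported as 0 (underflow sentinel).

## Problem sizes and determinism

The test suite runs on libraries of 2,000–100,000 fragments over 30–100 kb
genomes; the acceptance script uses 100,000 fragments per condition, the
scale at which the coupling estimator's Monte-Carlo standard error is ~0.17
percentage points. Every stochastic component takes an explicit seed
(numpy `default_rng`), pipeline re-runs are byte-identical, and the CLI
records seeds and record counts in per-stage JSON manifests.

## Known limitations

* The internal aligner handles substitutions only (no gaps, no quality
  scores); indel-containing SAM imports are flagged and excluded.
* Reads with more than one tandem event, or mixed single+tandem mismatches,
  are out of scope and end as adjudication rejections.
* The engineered-exactness of the TGG filter does not transfer to realistic
  genomes, where a fragment can legitimately end just 5′ of a genomic TGG;
  on real data the filter trades a small false-positive rate for removing
  the mispriming artifact, and the stricter TG variant removes more of both.
* Dyad-profile bins for tandem (half-base) lesion coordinates round
  half-distances to the nearest even integer bin; the analysis is intended
  for the single-C>T channel, as in the source analyses.
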