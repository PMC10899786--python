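# xrdeam

Locating UV lesions inside excision-repair sequencing (XR-seq) reads from
cytosine-deamination mismatches, and analysing how nucleotide excision
repair (NER) chooses its incision sites.

## The problem

NER removes a helix-distorting lesion — for UV damage, typically a
cyclobutane pyrimidine dimer (CPD) at a dipyrimidine — by cutting the
damaged strand on both sides and releasing a short fragment (~22–30 nt in
human). XR-seq sequences those fragments, so each read's 5′ and 3′ ends are
the two incision sites. The catch is that the lesion's position *within*
the fragment is normally unknown, which blocks any per-fragment analysis of
incision-site choice.

Cytosines inside a CPD deaminate orders of magnitude faster than in intact
DNA. A deaminated cytosine is read as T, so a CPD that contains a C leaves a
diagnostic C>T alignment mismatch at the lesion — or a tandem CC>TT mismatch
when both bases of a CC lesion deaminate. `xrdeam` exploits this signature
to pin the lesion at single-nucleotide (or half-base) resolution and then
quantifies incision-site behaviour.

## What the package computes

With the lesion at read offset *i* in a read of length *L*, the
lesion-inclusive cut-site distances are

```
d5 = i + 1          d3 = L − i          d5 + d3 = L + 1
```

(half-integers, measured to the half-base between the two substituted bases,
for tandem CC>TT). On top of these records the package implements:

* **Lesion calling** — C>T position frequencies stratified by read length;
  a position is called when its frequency exceeds by ≥ 4 sample standard
  deviations the mean of the 10 positions nearest the 5′ end, where no CPD
  is expected (two-tailed normal bound 6.3e-5).
* **Mispriming (TGG) filter** — fragments lacking a 3′ adapter can be
  rescued by PCR priming at an internal adapter-homologous TGG; adapter
  trimming then truncates them. Reads whose genomic 3′ flank is TGG are
  removed before every downstream analysis.
* **Tandem revertant alignment** — reads with CC>TT mismatches defeat
  seeded aligners; each TT in the read is restored to CC and the read is
  called when exactly one such revertant matches the genome exactly, at
  exactly one locus, while the original matches nowhere.
* **Contribution decomposition** — how much of the read-length variability
  each incision site explains: per-length mean-distance differences against
  the shortest length, weighted by read-length frequency, summed per side.
* **Incision coupling** — OLS of d3 on d5; the coupling percentage is
  −100 × slope, the fraction of a 5′ excursion compensated by the 3′
  incision. Exactly slope(L ~ d5) = 1 + slope(d3 ~ d5). A shuffle control
  (permute d5, recompute L) restores slope 1.00 / coupling 0%.
* **5′ sequence context** — HYV motif profile (H = not G, Y = C/T,
  V = not T; the incision falls between Y and V) and GC-normalized
  composition / information-content matrices.
* **Nucleosome proximity** — mean d5/d3 binned by strand-aligned
  lesion-to-dyad distance (±500 bp), blacklist-filtered dyads, per-bin
  two-tailed t-tests against the grand mean at a fixed 5e-5 cutoff.

Everything is exercised end to end on a synthetic generator
(`xrdeam.simdata`) that emulates XR-seq libraries with known ground truth:
configurable cut-distance distributions, 5′→3′ coupling, per-lesion
deamination (single and tandem), background sequencing error, and
mispriming truncation at internal TGG sites.

## Worked example

```
$ python examples/03_tandem_and_coupling.py
tandem incision records recovered: 28655
OLS d3 ~ d5: slope -0.462, p = 0.00e+00
coupling = -100 x slope = 46.2%
OLS length ~ d5: slope 0.538 (identity: 1 + d3-slope = 0.538)
shuffled control coupling: 0.29% (independence restores ~0%)
read-length variability: 88% from the 5' incision, 12% from the 3' incision
```

30,000 synthetic CC-lesion fragments are simulated with a generator that
compensates 46% of every 5′ incision excursion on the 3′ side. The tandem
revertant route recovers ~96% of them; the regression of 3′ on 5′ cut-site
distance recovers the injected coupling (46.2%), the length regression obeys
the arithmetic identity, and permuting the 5′ distances destroys the
coupling, as it must for independent incisions. The other scripts in
`examples/` walk through lesion calling, the mispriming filter on an
engineered genome, and the nucleosome-boundary profile.

A thin CLI chains the stages on files
(`xrdeam simulate | align | qc | call | tandem | incision | nucprox | all`),
driven by one YAML config; each stage writes TSVs plus a JSON manifest with
seeds and record counts, and re-runs are byte-identical under fixed seeds.

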