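"""The synthetic library generator: composition, truth bookkeeping, events."""

import numpy as np
import pandas as pd
import pytest

from xrdeam import SimConfig, generate_fragments, generate_genome, revcomp
from xrdeam.simdata import (
    apply_mispriming,
    engineered_mispriming_dataset,
    generate_blacklist,
    generate_dyads,
    read_interval,
)


class TestGenerateGenome:
    def test_gc_zero_is_at_only(self):
        cfg = SimConfig(genome_length=5000, gc_content=0.0, seed=1)
        (seq,) = generate_genome(cfg).values()
        assert set(seq) <= {"A", "T"}

    def test_gc_observed_matches_target(self):
        n = 100_000
        cfg = SimConfig(genome_length=n, gc_content=0.5, seed=2)
        (seq,) = generate_genome(cfg).values()
        gc = (seq.count("G") + seq.count("C")) / n
        assert abs(gc - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_tgg_frequency_matches_base_product(self):
        # P(TGG) = P(T) P(G)^2 = 0.3 * 0.2 * 0.2 at gc=0.4
        n = 200_000
        cfg = SimConfig(genome_length=n, gc_content=0.4, seed=3)
        (seq,) = generate_genome(cfg).values()
        count = sum(1 for i in range(n - 2) if seq[i:i + 3] == "TGG")
        expected = 0.012
        se = np.sqrt(expected * (1 - expected) / (n - 2))
        assert abs(count / (n - 2) - expected) < 4 * se

    def test_invalid_gc_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(gc_content=1.5).validate()

    def test_reproducible_under_seed(self):
        cfg = SimConfig(genome_length=2000, seed=11)
        assert generate_genome(cfg) == generate_genome(cfg)


class TestTruthTable:
    def test_distance_identity_every_fragment(self, sim_bundle):
        _, _, _, truth = sim_bundle
        assert np.allclose(truth["d5"] + truth["d3"] - 1, truth["length"])

    def test_truth_distances_are_halfbase(self, sim_bundle):
        _, _, _, truth = sim_bundle
        assert ((truth["d5"] % 1) == 0.5).all()
        assert ((truth["d3"] % 1) == 0.5).all()

    def test_lesion_matches_genome_and_strand(self, sim_bundle):
        _, genome, _, truth = sim_bundle
        for row in truth.head(300).itertuples(index=False):
            pair = genome[row.contig][row.lesion_pos5:row.lesion_pos3 + 1]
            if row.strand == "-":
                pair = revcomp(pair)
            assert pair == row.lesion_type
            assert row.start <= row.lesion_pos5 < row.lesion_pos3 < row.end

    def test_truncation_only_shortens_three_prime_side(self, sim_bundle):
        _, _, reads, truth = sim_bundle
        lengths = {rid: len(seq) for rid, seq in reads}
        trunc = truth[truth["truncated"]]
        assert len(trunc) > 0
        assert (trunc["read_length"]
                == trunc["length"] - trunc["truncation_offset"]).all()
        for row in truth.head(200).itertuples(index=False):
            assert lengths[row.fragment_id] == row.read_length
            rstart, rend = read_interval(row._asdict())
            assert rend - rstart == row.read_length


class TestDeaminationAndErrors:
    def test_every_read_has_one_ct_when_forced(self):
        """p_deaminate=1 on a pure-CT lesion mix: exactly one C>T per read."""
        cfg = SimConfig(genome_length=20_000, n_fragments=400,
                        lesion_dinucleotide_mix={"CT": 1.0}, p_deaminate=1.0,
                        seq_error_rate=0.0, p_misprime=0.0, seed=4)
        genome = generate_genome(cfg)
        reads, truth = generate_fragments(genome, cfg)
        seqs = dict(reads)
        for row in truth.itertuples(index=False):
            source = genome[row.contig][row.start:row.end]
            if row.strand == "-":
                source = revcomp(source)
            diffs = [(a, b) for a, b in zip(seqs[row.fragment_id], source) if a != b]
            assert diffs == [("T", "C")]

    def test_single_ct_fraction_matches_analytic_value(self):
        p, pt = 0.3, 0.2
        mix = {"TT": 0.4, "CT": 0.2, "TC": 0.2, "CC": 0.2}
        cfg = SimConfig(genome_length=60_000, n_fragments=20_000,
                        lesion_dinucleotide_mix=mix, p_deaminate=p, p_tandem=pt,
                        seq_error_rate=0.0, p_misprime=0.0, seed=5)
        genome = generate_genome(cfg)
        _, truth = generate_fragments(genome, cfg)
        observed = truth["deamination"].str.startswith("single").mean()
        expected = (mix["CT"] + mix["TC"]) * p + mix["CC"] * (1 - pt) * p
        se = np.sqrt(expected * (1 - expected) / len(truth))
        assert abs(observed - expected) < 4 * se

    def test_errors_never_hit_lesion(self, sim_bundle):
        _, _, _, truth = sim_bundle
        errs = truth[truth["n_errors"] > 0]
        assert len(errs) > 0
        for row in errs.itertuples(index=False):
            a = row.d5 - 1.5  # read index of the 5' lesion base
            offs = {int(x) for x in row.error_offsets.split(",")}
            assert not offs & {int(a), int(a) + 1}


class TestCoupling:
    def test_independent_when_coupling_zero(self):
        cfg = SimConfig(genome_length=60_000, n_fragments=20_000, coupling=0.0,
                        p_misprime=0.0, seed=6)
        genome = generate_genome(cfg)
        _, truth = generate_fragments(genome, cfg)
        r = np.corrcoef(truth["d5"], truth["d3"])[0, 1]
        assert abs(r) < 4 / np.sqrt(len(truth))

    def test_full_coupling_shrinks_length_variance(self):
        base = dict(genome_length=60_000, n_fragments=20_000, p_misprime=0.0)
        truths = {}
        for c in (0.0, 1.0):
            cfg = SimConfig(coupling=c, seed=8, **base)
            _, truths[c] = generate_fragments(generate_genome(cfg), cfg)
        # at c=1 only the dither survives in L; variance collapses
        assert truths[1.0]["length"].var() < 0.3 * truths[0.0]["length"].var()


class TestMispriming:
    def test_no_misprime_leaves_reads_unchanged(self, rng):
        seq = "ACGTACGTACGTACGTACGTTGGA"
        assert apply_mispriming(seq, 10, 0.0, rng) == (seq, False, 0)

    def test_truncates_before_three_prime_most_eligible_tgg(self, rng):
        seq = "A" * 18 + "ACTGGA"  # TGG at offset 20
        out, truncated, removed = apply_mispriming(seq, 10, 1.0, rng)
        assert truncated and out == "A" * 18 + "AC" and removed == 4
        # the bases just past the new 3' end are the TGG
        assert seq[len(out):len(out) + 3] == "TGG"

    def test_no_eligible_tgg_is_a_noop(self, rng):
        seq = "TGG" + "A" * 20  # truncating here would leave < lmin bases
        assert apply_mispriming(seq, 10, 1.0, rng)[1] is False

    def test_engineered_genome_filter_is_exact(self):
        from xrdeam.readqc import tgg_filter

        genome, reads, truth = engineered_mispriming_dataset(
            n_fragments=150, n_truncated=60, seed=9)
        kept, removed = tgg_filter(reads, genome)
        removed_ids = {r.read_id for r in removed}
        truncated_ids = set(truth.loc[truth["truncated"], "fragment_id"])
        assert removed_ids == truncated_ids


class TestDyadsAndBoundary:
    def test_dyad_count_matches_spacing(self):
        cfg = SimConfig(genome_length=100_000, seed=1)
        genome = generate_genome(cfg)
        dyads = generate_dyads(genome, spacing=200, jitter=0, seed=0)
        assert abs(len(dyads) - 500) <= 3

    def test_spacing_must_exceed_core(self):
        with pytest.raises(ValueError):
            generate_dyads({"c": "A" * 1000}, spacing=100)

    def test_boundary_shift_elevates_in_band_d5(self):
        from xrdeam.simdata import BoundaryEffect

        cfg = SimConfig(genome_length=100_000, n_fragments=30_000, coupling=0.0,
                        p_misprime=0.0, seed=10)
        genome = generate_genome(cfg)
        dyads = generate_dyads(genome, spacing=250, jitter=0, seed=0)
        _, truth = generate_fragments(
            genome, cfg, dyads=dyads, boundary=BoundaryEffect(band=(60, 73), shift=1))
        dp = np.sort(dyads["pos"].to_numpy())
        center = (truth["lesion_pos5"] + truth["lesion_pos3"]) / 2
        j = np.searchsorted(dp, center)
        left = np.abs(center - dp[np.clip(j - 1, 0, len(dp) - 1)])
        right = np.abs(dp[np.clip(j, 0, len(dp) - 1)] - center)
        dist = np.minimum(left, right)
        in_band = (dist >= 60) & (dist <= 73)
        gap = truth.loc[in_band, "d5"].mean() - truth.loc[~in_band, "d5"].mean()
        assert abs(gap - 1.0) < 0.1

    def test_blacklist_regions_inside_genome(self):
        genome = {"c": "A" * 10_000}
        bl = generate_blacklist(genome, n_regions=4, width=300, seed=2)
        assert (bl["start"] >= 0).all() and (bl["end"] <= 10_000).all()


def test_missing_dinucleotide_rejected():
    cfg = SimConfig(genome_length=2_000, gc_content=0.0, n_fragments=10,
                    lesion_dinucleotide_mix={"CC": 1.0}, seed=1)
    genome = generate_genome(cfg)  # A/T only: no CC anywhere
    with pytest.raises(ValueError, match="no CC"):
        generate_fragments(genome, cfg)
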