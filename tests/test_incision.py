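"""Cut-site records, contribution decomposition, coupling, HYV, composition."""

import numpy as np
import pytest

from xrdeam import (
    IncisionRecord,
    contribution_decomposition,
    coupling_regression,
    shuffle_control,
)
from xrdeam.incision import (
    composition_matrix,
    hyv_profile,
    records_from_reads,
    records_from_tandem_calls,
)
from xrdeam.refalign import AlignedRead, MismatchRecord
from xrdeam.tandem import TandemCall


def _rec(d5, d3, rid="r", kind="truth"):
    return IncisionRecord(rid, kind, float(d5), float(d3), int(d5 + d3 - 1))


def _ct_read(length, offset, rid="r"):
    m = MismatchRecord(offset=offset, position_rel_3prime=offset - length,
                       ref="C", alt="T")
    return AlignedRead(rid, "c", 100, 100 + length, "+", "A" * length,
                       mismatches=[m])


class TestRecords:
    def test_single_mismatch_arithmetic(self):
        (rec,) = records_from_reads([_ct_read(26, 19)])
        assert (rec.d5, rec.d3, rec.length) == (20.0, 7.0, 26)

    def test_tandem_halfbase_arithmetic(self):
        read = _ct_read(26, 19)
        read.mismatches[0].is_tandem = True
        read.mismatches[0].ref, read.mismatches[0].alt = "CC", "TT"
        (rec,) = records_from_tandem_calls([TandemCall(read=read, offset=19)])
        assert (rec.d5, rec.d3) == (20.5, 6.5)

    def test_identity_enforced_at_construction(self):
        with pytest.raises(ValueError):
            IncisionRecord("x", "truth", 20.0, 7.0, 27)

    def test_lesion_genomic_coordinates_by_strand(self):
        plus = _ct_read(26, 19)
        (rp,) = records_from_reads([plus])
        assert rp.lesion_pos == 119          # start + offset
        minus = _ct_read(26, 19)
        minus.strand = "-"
        (rm,) = records_from_reads([minus])
        assert rm.lesion_pos == 126 - 1 - 19  # end - 1 - offset


class TestContributionDecomposition:
    def test_hand_computed_example(self):
        # lengths 24 (2 reads) and 26 (2 reads); d3 grows by 1, d5 by 1
        records = [_rec(17, 8), _rec(18, 7), _rec(18, 9), _rec(19, 8)]
        res = contribution_decomposition(records)
        # delta5(26) = 18.5 - 17.5 = 1, delta3(26) = 8.5 - 7.5 = 1, weights .5/.5
        assert res.s5 == pytest.approx(0.5)
        assert res.s3 == pytest.approx(0.5)
        assert res.pct5 == pytest.approx(50.0)

    def test_fixed_d3_loads_everything_on_5prime(self):
        rng = np.random.default_rng(2)
        records = [_rec(d5, 7) for d5 in rng.integers(15, 24, size=4000)]
        res = contribution_decomposition(records)
        assert res.pct3 == pytest.approx(0.0, abs=1e-9)
        assert res.pct5 == pytest.approx(100.0, abs=1e-9)

    def test_symmetric_generator_splits_evenly(self):
        rng = np.random.default_rng(3)
        records = [_rec(a, b) for a, b in zip(rng.integers(10, 18, size=40_000),
                                              rng.integers(10, 18, size=40_000))]
        res = contribution_decomposition(records)
        assert abs(res.pct5 - 50.0) < 3.0

    def test_single_length_is_na(self):
        res = contribution_decomposition([_rec(17, 8), _rec(18, 7)])
        assert np.isnan(res.pct5)

    def test_min_reads_drops_sparse_anchor_length(self):
        # a lone record at an extreme length would anchor the deltas
        records = [_rec(10, 3, rid="stray")]
        records += [_rec(17, 8, rid=f"a{i}") for i in range(50)]
        records += [_rec(19, 8, rid=f"b{i}") for i in range(50)]
        res = contribution_decomposition(records, min_reads=10)
        assert list(res.table.index) == [24, 26]
        assert res.pct5 == pytest.approx(100.0)


class TestCouplingRegression:
    def test_exact_compensation_gives_full_coupling(self):
        records = [_rec(d5, 27 - d5) for d5 in range(15, 25)]
        fit = coupling_regression(records)
        assert fit.slope == pytest.approx(-1.0)
        assert fit.coupling_percent == pytest.approx(100.0)

    def test_independence_gives_zero_coupling_and_unit_length_slope(self):
        rng = np.random.default_rng(4)
        records = [_rec(a, b) for a, b in zip(rng.integers(15, 24, size=30_000),
                                              rng.integers(5, 10, size=30_000))]
        d3fit = coupling_regression(records)
        lfit = coupling_regression(records, "read_length_vs_d5")
        assert abs(d3fit.coupling_percent) < 3 * 100 * d3fit.stderr
        assert abs(lfit.slope - 1.0) < 3 * lfit.stderr

    def test_length_slope_identity(self):
        rng = np.random.default_rng(5)
        d5 = rng.integers(15, 24, size=500)
        d3 = np.maximum(1, 8 - 0.3 * (d5 - 19) + rng.normal(0, 1, 500)).round()
        records = [_rec(a, b) for a, b in zip(d5, d3)]
        s_l = coupling_regression(records, "read_length_vs_d5").slope
        s_3 = coupling_regression(records, "d3_vs_d5").slope
        assert s_l == pytest.approx(1.0 + s_3, abs=1e-9)

    def test_zero_variance_d5_is_an_error(self):
        with pytest.raises(ValueError, match="zero variance"):
            coupling_regression([_rec(20, d3) for d3 in (6, 7, 8)])

    def test_coupling_percent_only_for_d3_target(self):
        records = [_rec(d5, 27 - d5) for d5 in range(15, 25)]
        fit = coupling_regression(records, "read_length_vs_d5")
        with pytest.raises(ValueError):
            fit.coupling_percent


class TestShuffleControl:
    def test_multisets_preserved_and_lengths_recomputed(self):
        rng = np.random.default_rng(6)
        records = [_rec(a, b) for a, b in zip(rng.integers(15, 24, size=500),
                                              rng.integers(5, 10, size=500))]
        shuffled = shuffle_control(records, seed=9)
        assert sorted(r.d5 for r in shuffled) == sorted(r.d5 for r in records)
        assert sorted(r.d3 for r in shuffled) == sorted(r.d3 for r in records)
        for r in shuffled:
            assert r.length == r.d5 + r.d3 - 1

    def test_constant_d5_is_identity(self):
        records = [_rec(20, d3) for d3 in (6, 7, 8, 9)]
        shuffled = shuffle_control(records, seed=1)
        assert [(r.d5, r.d3, r.length) for r in shuffled] == \
            [(r.d5, r.d3, r.length) for r in records]


class TestHyvProfile:
    def _reads_on(self, genome, starts, length, strand="+"):
        return [AlignedRead(f"r{i}", "c", s, s + length, strand,
                            genome["c"][s:s + length]) for i, s in enumerate(starts)]

    def test_incision_site_signal_when_preceded_by_at(self):
        # every read preceded by "AT" and starting with "A": HYV = (A)(T)(A)
        genome = {"c": ("GCGG" * 4 + "ATACGCGCGCGCGCGG") * 20}
        unit = 32
        starts = [i * unit + 18 for i in range(15)]
        for s in starts:
            assert genome["c"][s - 2:s + 1] == "ATA"  # (H, Y, V) = (A, T, A)
        reads = self._reads_on(genome, starts, 12)
        prof = hyv_profile(reads, genome, flank=8)
        row = prof[prof["position"] == 0]
        assert row["frequency"].iloc[0] == 1.0

    def test_gg_upstream_gives_zero(self):
        genome = {"c": ("GG" + "ACGTACGTACGTACGTACGTACGAA") * 20}
        unit = 27
        starts = [i * unit + 2 for i in range(15)]
        reads = self._reads_on(genome, starts, 12)
        prof = hyv_profile(reads, genome, flank=8)
        assert prof.loc[prof["position"] == 0, "frequency"].iloc[0] == 0.0

    def test_random_genome_matches_class_product(self):
        from xrdeam import SimConfig, generate_genome

        cfg = SimConfig(genome_length=60_000, gc_content=0.5, seed=31)
        genome = {"c": generate_genome(cfg)["chr_sim"]}
        rng = np.random.default_rng(7)
        starts = rng.integers(50, 59_900, size=3000)
        reads = self._reads_on(genome, starts, 25)
        prof = hyv_profile(reads, genome, flank=10)
        # P(H)P(Y)P(V) = 0.75 * 0.5 * 0.75
        assert np.allclose(prof["frequency"], 0.28125, atol=0.035)


class TestCompositionMatrix:
    def test_information_content_values(self):
        # genome engineered for GC 0.5 so the background is uniform
        genome = {"c": "ATCG" + "AC" + "GT" + "ATCG"}
        r1 = AlignedRead("a", "c", 4, 6, "+", "AC")   # positions 1-2: A,C
        r2 = AlignedRead("b", "c", 6, 8, "+", "GT")   # G,T at same offsets? no
        mat = composition_matrix([r1, r2], genome, flank=0)
        # position 1: bases {A, G} -> f = (.5, 0, .5, 0): 1 bit vs uniform
        p1 = mat.set_index("position").loc[1]
        assert p1["information"] == pytest.approx(1.0)
        assert mat.attrs["gc_content"] == 0.5

    def test_single_base_position_is_two_bits(self):
        # identical reads with GC 0.5, so the background stays uniform
        genome = {"c": "AAAA" + "CGTA" + "TTTT"}
        reads = [AlignedRead(str(i), "c", 4, 8, "+", "CGTA") for i in range(3)]
        mat = composition_matrix(reads, genome, flank=0).set_index("position")
        assert mat.loc[1, "information"] == pytest.approx(2.0)

    def test_background_equal_frequencies_zero_bits(self):
        genome = {"c": "ACGTACGTACGTACGT"}
        reads = [AlignedRead(str(i), "c", i, i + 1, "+", genome["c"][i])
                 for i in range(8)]
        mat = composition_matrix(reads, genome, flank=0).set_index("position")
        assert mat.loc[1, "information"] == pytest.approx(0.0, abs=1e-12)
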