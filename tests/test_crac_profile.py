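import numpy as np
import pytest

from craclash import (
    BindingSite,
    NucleotideTrack,
    Read,
    ReferenceSet,
    SimulationConfig,
    build_coverage,
    build_mutation_profile,
    call_peaks,
    filter_reads,
    flag_control_peaks,
    map_reads,
    simulate_crac_reads,
    snorna_enrichment,
)
from craclash.crac_profile import Alignment, Peak, _coverage_counts


def brute_force_placements(read_seq, ref, max_mismatches):
    """Independent oracle: every ungapped placement by direct comparison."""
    out = []
    for rna_id, seq in ref.rnas.items():
        for s in range(len(seq) - len(read_seq) + 1):
            mm = [s + k + 1 for k in range(len(read_seq))
                  if seq[s + k] != read_seq[k]]
            if len(mm) <= max_mismatches:
                out.append((rna_id, s + 1, tuple(mm)))
    return out


class TestFilterReads:
    def test_boundary_inclusive(self):
        reads = [Read(f"r{n}", "A" * n) for n in (16, 17, 18)]
        assert [len(r) for r in filter_reads(reads, 17)] == [17, 18]

    def test_min_one_is_identity_and_empty_ok(self):
        reads = [Read("a", "ACGU")]
        assert filter_reads(reads, 1) == reads
        assert filter_reads([], 17) == []


class TestMapReads:
    def test_exact_unique_20mer(self, tiny_ref):
        read = Read("x", tiny_ref.rnas["r1"][30:50])
        (a,) = map_reads([read], tiny_ref)
        assert (a.rna_id, a.start, a.end) == ("r1", 31, 50)
        assert a.mismatches == () and a.deletions == ()

    def test_multimapper_discarded(self):
        seg = "ACGUGGCCAUGGCAUCGAUC"
        ref = ReferenceSet(rnas={"r1": "U" * 10 + seg + "U" * 10 + seg + "U" * 5})
        assert map_reads([Read("x", seg)], ref) == []

    def test_substitution_recorded_and_matches_bruteforce(self, tiny_ref):
        start = 61  # 1-based
        orig = tiny_ref.rnas["r1"][start - 1 : start + 19]
        sub = "A" if orig[9] != "A" else "C"
        read_seq = orig[:9] + sub + orig[10:]
        (a,) = map_reads([Read("x", read_seq)], tiny_ref, max_mismatches=2)
        oracle = brute_force_placements(read_seq, tiny_ref, 2)
        assert (a.rna_id, a.start, a.mismatches) in [
            (r, s, mm) for r, s, mm in oracle
        ]
        assert a.mismatches == (start + 9,)

    def test_single_deletion_recovered(self, tiny_ref):
        # delete a position whose base differs from both neighbors
        seq = tiny_ref.rnas["r1"]
        pos = next(p for p in range(100, 130)
                   if seq[p - 2] != seq[p - 1] != seq[p])
        full = seq[pos - 11 : pos + 10]  # 21 nt covering pos
        read_seq = full[:10] + full[11:]  # drop the base at pos
        (a,) = map_reads([Read("x", read_seq)], tiny_ref)
        assert a.deletions == (pos,)
        assert a.mismatches == ()
        assert a.end - a.start + 1 == len(read_seq) + 1

    def test_short_reads_dropped(self, tiny_ref):
        assert map_reads([Read("x", "ACGU")], tiny_ref,
                         min_aligned_length=17) == []


class TestCoverage:
    def test_single_read_unit_normalization(self, tiny_ref):
        a = Alignment("x", "r1", 5, 24)
        cov = build_coverage([a], tiny_ref)["r1"].values
        assert np.all(cov[4:24] == 1e6)
        assert cov.sum() == 20 * 1e6

    def test_replication_invariance(self, tiny_ref):
        alns = [Alignment("a", "r1", 5, 24), Alignment("b", "r1", 15, 34)]
        one = build_coverage(alns, tiny_ref)
        three = build_coverage(alns * 3, tiny_ref)
        for rna_id in one:
            np.testing.assert_allclose(one[rna_id].values, three[rna_id].values)

    def test_hand_computed_hits_per_million(self, tiny_ref):
        alns = [Alignment(f"c{i}", "r1", 40, 59) for i in range(4)]
        alns += [Alignment(f"o{i}", "r2", 1, 20) for i in range(6)]
        cov = build_coverage(alns, tiny_ref)
        assert cov["r1"].values[45] == pytest.approx(4 * 1e6 / 10)

    def test_total_reads_normalization_option(self, tiny_ref):
        a = [Alignment("x", "r1", 5, 24)]
        per_raw = build_coverage(a, tiny_ref, total_reads=100)
        assert per_raw["r1"].values[10] == pytest.approx(1e6 / 100)

    def test_empty_alignments_error(self, tiny_ref):
        with pytest.raises(ValueError, match="hits-per-million"):
            build_coverage([], tiny_ref)

    def test_conservation_of_hits(self, tiny_ref):
        rng = np.random.default_rng(3)
        alns = [Alignment(f"r{i}", "r1", int(s), int(s) + 19)
                for i, s in enumerate(rng.integers(1, 180, size=50))]
        counts = _coverage_counts(alns, tiny_ref)
        assert sum(c.sum() for c in counts.values()) == sum(
            a.aligned_length for a in alns)


class TestMutationProfile:
    def test_error_free_tracks_are_zero(self, tiny_ref, quiet_cfg):
        sites = [BindingSite("r1", 50, 80, 1.0, 60)]
        reads, _ = simulate_crac_reads(tiny_ref, sites, quiet_cfg)
        alns = map_reads(reads, tiny_ref)
        counts, rates = build_mutation_profile(alns, tiny_ref)
        assert all(t.values.sum() == 0 for t in counts.values())
        assert all(t.values.sum() == 0 for t in rates.values())

    def test_rate_is_count_over_coverage(self, tiny_ref):
        alns = [Alignment(f"m{i}", "r1", 10, 29, mismatches=(15,))
                for i in range(30)]
        alns += [Alignment(f"c{i}", "r1", 10, 29) for i in range(70)]
        counts, rates = build_mutation_profile(alns, tiny_ref)
        assert counts["r1"].values[14] == 30
        assert rates["r1"].values[14] == pytest.approx(0.3)

    def test_deletion_counts_like_substitution(self, tiny_ref):
        a = [Alignment("d", "r1", 10, 30, deletions=(15,)),
             Alignment("s", "r1", 10, 29, mismatches=(15,))]
        counts, _ = build_mutation_profile(a, tiny_ref)
        assert counts["r1"].values[14] == 2


class TestCallPeaks:
    def track(self, values, rna_id="r"):
        return {rna_id: NucleotideTrack(rna_id, np.asarray(values, float),
                                        "coverage_hpm")}

    def test_hand_computed_fixture(self):
        peaks = call_peaks(self.track([0, 100, 100, 0, 4, 0]), 0.05)
        assert [(p.start, p.end) for p in peaks] == [(2, 3)]
        assert peaks[0].relative_height == 1.0
        assert peaks[0].max_height_hpm == 100

    def test_scale_invariance(self):
        v = [0, 3, 50, 100, 40, 0, 7, 0]
        a = call_peaks(self.track(v), 0.05)
        b = call_peaks(self.track([x * 7 for x in v]), 0.05)
        assert [(p.start, p.end, p.relative_height) for p in a] == \
            [(p.start, p.end, p.relative_height) for p in b]

    def test_threshold_one_keeps_only_maximum(self):
        peaks = call_peaks(self.track([1, 5, 2, 5, 0]), 1.0)
        assert [(p.start, p.end) for p in peaks] == [(2, 2), (4, 4)]

    def test_all_zero_track_yields_no_peaks(self):
        assert call_peaks(self.track([0, 0, 0]), 0.05) == []

    def test_scope_restricts_threshold_and_calls(self):
        tracks = {
            "big": NucleotideTrack("big", np.array([1000.0, 0, 0]), "coverage_hpm"),
            "small": NucleotideTrack("small", np.array([30.0, 0, 0]), "coverage_hpm"),
        }
        scoped = call_peaks(tracks, 0.05, scope_rna_ids=["small"])
        assert [(p.rna_id, p.start) for p in scoped] == [("small", 1)]
        both = call_peaks(tracks, 0.05)
        assert all(p.rna_id == "big" for p in both)  # 30 < 5% of 1000

    def test_peak_partition_property(self):
        rng = np.random.default_rng(1)
        v = rng.integers(0, 50, size=300).astype(float)
        peaks = call_peaks(self.track(v), 0.3)
        thr = 0.3 * v.max()
        member_of = np.zeros(len(v), dtype=int)
        for p in peaks:
            member_of[p.start - 1 : p.end] += 1
            assert np.all(v[p.start - 1 : p.end] >= thr)
        assert np.array_equal(member_of == 1, v >= thr)


class TestControlFlag:
    def peak(self, s, e, rna="r"):
        return Peak(rna, s, e, 10.0, 1.0)

    def test_identical_peak_flagged(self):
        out = flag_control_peaks([self.peak(5, 14)], [self.peak(5, 14)])
        assert out[0].control_flag

    def test_disjoint_unflagged(self):
        out = flag_control_peaks([self.peak(5, 14)], [self.peak(50, 60)])
        assert not out[0].control_flag

    def test_half_overlap_boundary_inclusive(self):
        # 10-nt peak, 5 nt inside control, fraction 0.5 -> flagged
        out = flag_control_peaks([self.peak(1, 10)], [self.peak(6, 20)], 0.5)
        assert out[0].control_flag
        out = flag_control_peaks([self.peak(1, 10)], [self.peak(7, 20)], 0.5)
        assert not out[0].control_flag

    def test_union_of_controls_counts(self):
        # controls cover 3 + 3 = 6 of 10 nucleotides
        out = flag_control_peaks([self.peak(1, 10)],
                                 [self.peak(1, 3), self.peak(8, 10)], 0.6)
        assert out[0].control_flag
        out2 = flag_control_peaks([self.peak(1, 10)],
                                  [self.peak(1, 3), self.peak(8, 10)], 0.7)
        assert not out2[0].control_flag


class TestEnrichment:
    def test_hand_computed_relative_values(self, tiny_ref):
        ref = ReferenceSet(
            rnas={"rr": "A" * 100, "s1": "C" * 50, "s2": "G" * 50},
            classes={"rr": "rRNA", "s1": "snoRNA", "s2": "snoRNA"},
        )
        alns = [Alignment(f"a{i}", "s1", 1, 20) for i in range(300)]
        alns += [Alignment(f"b{i}", "s2", 1, 20) for i in range(100)]
        alns += [Alignment(f"c{i}", "rr", 1, 20) for i in range(9600)]
        df = snorna_enrichment(alns, ref).set_index("rna_id")
        assert df.loc["s1", "rpm"] == pytest.approx(30000)
        assert df.loc["s2", "rpm"] == pytest.approx(10000)
        assert df.loc["s1", "relative"] == pytest.approx(1.0)
        assert df.loc["s2", "relative"] == pytest.approx(1 / 3)

    def test_no_snorna_reads_gives_zeros(self, tiny_ref):
        alns = [Alignment("a", "r1", 1, 20)]
        df = snorna_enrichment(alns, tiny_ref)
        assert (df["relative"] == 0).all()

    def test_single_active_snorna_is_one(self, tiny_ref):
        alns = [Alignment("a", "r2", 1, 20)]
        df = snorna_enrichment(alns, tiny_ref).set_index("rna_id")
        assert df.loc["r2", "relative"] == 1.0
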