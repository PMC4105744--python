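import numpy as np
import pytest
from scipy import stats

from craclash import (
    BindingSite,
    ReferenceSet,
    SimulationConfig,
    generate_reference,
    plant_interaction,
    revcomp,
    simulate_chimeric_reads,
    simulate_crac_reads,
    write_fastq,
)
from craclash.synthetic_data import TruthRecord, PlantedDuplex


class TestGenerateReference:
    def test_deterministic_under_fixed_seed(self):
        a = generate_reference(1, [("r1", 100, "rRNA")])
        b = generate_reference(1, [("r1", 100, "rRNA")])
        assert a.rnas == b.rnas

    def test_different_seeds_differ(self):
        a = generate_reference(1, [("r1", 100, "rRNA")])
        b = generate_reference(2, [("r1", 100, "rRNA")])
        assert a.rnas["r1"] != b.rnas["r1"]

    def test_extreme_gc_content(self):
        ref = generate_reference(0, [("r1", 200, "other")], gc_content=1.0)
        assert set(ref.rnas["r1"]) <= {"G", "C"}

    def test_duplicate_id_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            generate_reference(0, [("r1", 10, "rRNA"), ("r1", 10, "rRNA")])


class TestPlantInteraction:
    def test_reverse_complement_planted(self):
        ref = ReferenceSet(rnas={"t": "AAAGGGGAAAAA", "q": "A" * 20})
        ref2, truth = plant_interaction(ref, ("t", 4), ("q", 8), 4)
        assert ref2.rnas["q"][7:11] == "CCCC"
        d = truth.duplexes[0]
        assert (d.t_start, d.t_end, d.q_start, d.q_end) == (4, 7, 8, 11)

    def test_planted_length_bookkeeping(self):
        ref = generate_reference(5, [("t", 200, "rRNA"), ("q", 200, "snoRNA")])
        ref2, truth = plant_interaction(ref, ("t", 50), ("q", 120), 19)
        d = truth.duplexes[0]
        assert d.length == 19
        assert d.q_end - d.q_start + 1 == 19
        assert revcomp(ref2.rnas["t"][d.t_start - 1 : d.t_end]) == \
            ref2.rnas["q"][d.q_start - 1 : d.q_end]

    def test_wobble_count_is_exact(self):
        # all-G target: every position eligible, round(0.5*20)=10 wobbles
        ref = ReferenceSet(rnas={"t": "G" * 30, "q": "A" * 40})
        ref2, truth = plant_interaction(ref, ("t", 5), ("q", 5), 20,
                                        gu_fraction=0.5, seed=3)
        planted = ref2.rnas["q"][4:24]
        assert planted.count("U") == 10 and planted.count("C") == 10
        assert len(truth.duplexes[0].wobble_positions) == 10

    def test_flank_guards_block_helix_extension(self):
        ref = generate_reference(5, [("t", 200, "rRNA"), ("q", 200, "snoRNA")])
        ref2, truth = plant_interaction(ref, ("t", 50), ("q", 120), 19)
        d = truth.duplexes[0]
        for rna, s, e in (("t", d.t_start, d.t_end), ("q", d.q_start, d.q_end)):
            seq = ref2.rnas[rna]
            assert seq[s - 3 : s - 1] == "AA" and seq[e : e + 2] == "AA"

    def test_same_rna_overlap_rejected(self):
        ref = ReferenceSet(rnas={"x": "A" * 100})
        with pytest.raises(ValueError, match="overlap"):
            plant_interaction(ref, ("x", 10), ("x", 20), 15)

    def test_out_of_bounds_rejected(self):
        ref = ReferenceSet(rnas={"t": "A" * 30, "q": "A" * 30})
        with pytest.raises(ValueError, match="bounds"):
            plant_interaction(ref, ("t", 20), ("q", 1), 15)


class TestSimulateCracReads:
    def test_error_free_reads_are_exact_substrings(self, tiny_ref, quiet_cfg):
        sites = [BindingSite("r1", 50, 80, 1.0, 60)]
        reads, truth = simulate_crac_reads(tiny_ref, sites, quiet_cfg)
        assert len(reads) == quiet_cfg.n_reads
        for read, t in zip(reads, truth.reads):
            assert read.seq == tiny_ref.rnas[t.rna_id][t.start - 1 : t.end]

    def test_crosslink_rate_converges(self, tiny_ref):
        cfg = SimulationConfig(seed=11, n_reads=10_000, crosslink_rate=0.3,
                               background_error_rate=0.0)
        sites = [BindingSite("r1", 50, 80, 1.0, 65)]
        _, truth = simulate_crac_reads(tiny_ref, sites, cfg)
        covering = [t for t in truth.reads if t.start <= 65 <= t.end]
        k = sum(t.crosslink_mutated for t in covering)
        n = len(covering)
        # binomial 99% CI around the nominal rate
        lo, hi = stats.binom.interval(0.99, n, 0.3)
        assert lo <= k <= hi

    def test_mixture_weights_respected(self, tiny_ref):
        cfg = SimulationConfig(seed=12, n_reads=10_000, crosslink_rate=0.0,
                               background_error_rate=0.0)
        sites = [BindingSite("r1", 20, 40, 9.0, 30),
                 BindingSite("r2", 60, 80, 1.0, 70)]
        _, truth = simulate_crac_reads(tiny_ref, sites, cfg)
        counts = np.array([
            sum(t.site_index == 0 for t in truth.reads),
            sum(t.site_index == 1 for t in truth.reads),
        ])
        chi2 = stats.chisquare(counts, f_exp=np.array([0.9, 0.1]) * counts.sum())
        assert chi2.pvalue > 0.01

    def test_truncation_at_rna_end_flagged(self, tiny_ref):
        cfg = SimulationConfig(seed=13, n_reads=500, crosslink_rate=0.0,
                               background_error_rate=0.0,
                               read_length_range=(30, 30))
        sites = [BindingSite("r2", 130, 150, 1.0, 140)]  # r2 is 150 nt
        reads, truth = simulate_crac_reads(tiny_ref, sites, cfg)
        truncated = [t for t in truth.reads if t.truncated]
        assert truncated, "reads starting near the 3' end must truncate"
        for t in truncated:
            assert t.end == 150

    def test_fixed_seed_reproduces_fastq_bytes(self, tiny_ref, tmp_path, quiet_cfg):
        sites = [BindingSite("r1", 50, 80, 1.0, 60)]
        outputs = []
        for run in range(2):
            reads, _ = simulate_crac_reads(tiny_ref, sites, quiet_cfg)
            path = tmp_path / f"run{run}.fastq"
            write_fastq(reads, path)
            outputs.append(path.read_bytes())
        assert outputs[0] == outputs[1]


class TestSimulateChimericReads:
    def make_duplex_truth(self, seed=21):
        ref = generate_reference(seed, [("t", 300, "rRNA"), ("q", 300, "snoRNA")])
        ref, truth = plant_interaction(ref, ("t", 100), ("q", 200), 19, seed=seed)
        return ref, truth

    def test_zero_fraction_emits_nothing(self):
        ref, truth = self.make_duplex_truth()
        cfg = SimulationConfig(seed=1, n_reads=1000, chimera_fraction=0.0)
        reads, _ = simulate_chimeric_reads(ref, truth, cfg)
        assert reads == []

    def test_arm_bookkeeping(self):
        ref, truth = self.make_duplex_truth()
        cfg = SimulationConfig(seed=2, read_length_range=(20, 20),
                               background_error_rate=0.0)
        reads, rt = simulate_chimeric_reads(ref, truth, cfg, n_chimeras=50)
        for read, t in zip(reads, rt.reads):
            a_rna, a_start, a_end = t.arm_a
            b_rna, b_start, b_end = t.arm_b
            assert len(read.seq) == (a_end - a_start + 1) + (b_end - b_start + 1)
            assert t.junction == a_end - a_start + 2
            assert read.seq == (ref.rnas[a_rna][a_start - 1 : a_end]
                                + ref.rnas[b_rna][b_start - 1 : b_end])
            assert {a_rna, b_rna} == {"t", "q"}

    def test_requires_planted_duplex(self):
        ref = generate_reference(1, [("t", 100, "rRNA")])
        with pytest.raises(ValueError, match="duplex"):
            simulate_chimeric_reads(ref, TruthRecord(), SimulationConfig(seed=1))


class TestSimulationConfig:
    @pytest.mark.parametrize("kwargs", [
        {"crosslink_rate": 1.5},
        {"gc_content": -0.1},
        {"read_length_range": (0, 5)},
        {"read_length_range": (10, 5)},
        {"n_reads": -1},
    ])
    def test_validation(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(seed=0, **kwargs)
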