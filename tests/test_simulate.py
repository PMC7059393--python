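"""Generator statistics: labeling, drift, bottleneck, reads, assays."""

from __future__ import annotations

import math

import numpy as np
import pytest

from clonotrace.core import LEFT_PRIMER as L, RIGHT_PRIMER as R, DEFAULT_TAGS
from clonotrace.simulate import (
    FastqRecord,
    Founder,
    Integration,
    PopulationState,
    SimConfig,
    SimulationExtinct,
    assign_founder_patterns,
    generate_amplicon_reads,
    initial_state,
    simulate_differentiation_bottleneck,
    simulate_dilution_assay,
    simulate_labeling,
    simulate_methylation_reads,
    simulate_passaging,
)

from conftest import make_founders, uniform_state


class TestLabeling:
    def test_huge_moi_everyone_survives(self):
        assert len(simulate_labeling(100, moi=50.0, seed=0)) == 100

    def test_survivor_count_matches_zero_class(self):
        n, moi = 10_000, 1.0
        survivors = len(simulate_labeling(n, moi, seed=1))
        p = 1 - math.exp(-moi)
        sd = math.sqrt(n * p * (1 - p))
        assert abs(survivors - n * p) < 3 * sd

    def test_low_moi_single_integration(self):
        founders = simulate_labeling(100_000, moi=0.01, seed=2)
        single = sum(len(f.integrations) == 1 for f in founders)
        # closed form: P(k=1 | k>=1) = moi e^-moi / (1 - e^-moi)
        p1 = 0.01 * math.exp(-0.01) / (1 - math.exp(-0.01))
        assert p1 > 0.99
        assert single / len(founders) >= 0.99

    def test_fitness_defaults_and_lognormal(self):
        neutral = simulate_labeling(200, 1.0, fitness_sd=0.0, seed=3)
        assert all(f.fitness == 1.0 for f in neutral)
        varied = simulate_labeling(200, 1.0, fitness_sd=0.5, seed=3)
        assert len({f.fitness for f in varied}) > 100

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            simulate_labeling(0, 1.0)
        with pytest.raises(ValueError):
            simulate_labeling(10, 0.0)


class TestPassaging:
    def test_infinite_bottleneck_preserves_fractions(self, rng):
        state = uniform_state(10, rng, cells_per_clone=30)
        traj = simulate_passaging(state, 4, bottleneck_size=None,
                                  growth_factor=3.0, seed=0)
        first, last = traj[0].fractions(), traj[-1].fractions()
        assert last.keys() == first.keys()
        for f in first:
            assert last[f] == pytest.approx(first[f])

    def test_trajectory_includes_input_and_increments_passage(self, rng):
        state = uniform_state(5, rng)
        traj = simulate_passaging(state, 3, 100, seed=0)
        assert traj[0] is state
        assert [s.passage for s in traj] == [0, 1, 2, 3]
        assert all(s.total_cells == 100 for s in traj[1:])

    def test_two_clone_fixation_probability_half(self, rng):
        """P(fixation in one passage at bottleneck 2) = 0.5 exactly
        (multinomial(2; 1/2, 1/2) hits (2,0) or (0,2) with prob 1/2)."""
        f1, f2 = make_founders(2, rng)
        fixed = 0
        n_runs = 2000
        for s in range(n_runs):
            state = PopulationState(0, {f1: 1, f2: 1})
            end = simulate_passaging(state, 1, 2, seed=s)[-1]
            if len(end.alive()) == 1:
                fixed += 1
        sd = math.sqrt(n_runs * 0.25)
        assert abs(fixed - 0.5 * n_runs) < 3 * sd

    def test_heterozygosity_decays_wright_fisher(self, rng):
        """E[1 - sum p_i^2] shrinks by (1 - 1/N) per passage under neutrality."""
        N, n_passages, n_reps = 100, 3, 600
        het = np.zeros(n_passages + 1)
        for rep in range(n_reps):
            state = uniform_state(20, rng, cells_per_clone=5)
            traj = simulate_passaging(state, n_passages, N, seed=1000 + rep)
            for t, s in enumerate(traj):
                p = np.array(list(s.fractions().values()))
                het[t] += 1 - (p ** 2).sum()
        het /= n_reps
        for t in range(1, n_passages + 1):
            expected = het[0] * (1 - 1 / N) ** t
            assert het[t] == pytest.approx(expected, rel=0.05)

    def test_extinct_population_raises(self, rng):
        f, = make_founders(1, rng)
        with pytest.raises(SimulationExtinct) as err:
            simulate_passaging(PopulationState(4, {f: 0}), 1, 10, seed=0)
        assert err.value.passage == 4


class TestDifferentiationBottleneck:
    def test_recruit_all_preserves_fractions(self, rng):
        state = uniform_state(10, rng, cells_per_clone=10)
        out = simulate_differentiation_bottleneck(state, 100, seed=0)
        assert out.fractions() == state.fractions()

    def test_recruit_three_richness_bounded(self, rng):
        state = uniform_state(1000, rng, cells_per_clone=1)
        for s in range(20):
            out = simulate_differentiation_bottleneck(state, 3, seed=s)
            assert len(out.alive()) <= 3
            assert out.total_cells == 3

    def test_invalid_recruitment(self, rng):
        state = uniform_state(3, rng, cells_per_clone=1)
        with pytest.raises(ValueError):
            simulate_differentiation_bottleneck(state, 4, seed=0)
        with pytest.raises(ValueError):
            simulate_differentiation_bottleneck(state, 0, seed=0)


class TestAmpliconReads:
    def test_error_free_reads_contain_exact_barcode(self, rng):
        state = uniform_state(5, rng)
        reads, truth = generate_amplicon_reads(state, read_count=50,
                                               seq_error_rate=0.0, seed=0)
        tag_seq = {t.name: t.sequence for t in DEFAULT_TAGS}
        by_id = dict(zip(truth.read_id, zip(truth.color, truth.umi)))
        for r in reads:
            color, umi = by_id[r.id]
            assert L + tag_seq[color] + umi + R in r.sequence

    def test_truth_ids_match_read_ids(self, rng):
        state = uniform_state(3, rng)
        reads, truth = generate_amplicon_reads(state, read_count=40, seed=1)
        assert [r.id for r in reads] == list(truth.read_id)

    def test_single_clone_recovered_at_100pct(self, rng):
        import clonotrace as ct

        state = uniform_state(1, rng)
        reads, _ = generate_amplicon_reads(state, read_count=500, seed=2)
        calls, _ = ct.process_reads([ct.ReadRecord(r.id, r.sequence)
                                     for r in reads])
        table = ct.count_clones([c for c in calls if c.assigned])
        assert table.richness == 1
        assert list(table.fractions().values()) == [100.0]

    def test_uniform_clone_fractions_multinomial(self, rng):
        state = uniform_state(10, rng, cells_per_clone=50)
        n = 100_000
        _, truth = generate_amplicon_reads(state, read_count=n, seed=3)
        counts = truth.groupby("umi").size()
        sd = math.sqrt(n * 0.1 * 0.9)
        assert len(counts) == 10
        assert (abs(counts - n / 10) < 3 * sd).all()

    def test_seed_determinism_byte_identical(self, rng):
        state = uniform_state(4, rng)
        r1, t1 = generate_amplicon_reads(state, read_count=100,
                                         seq_error_rate=0.05, seed=9)
        r2, t2 = generate_amplicon_reads(state, read_count=100,
                                         seq_error_rate=0.05, seed=9)
        assert [x.to_fastq() for x in r1] == [x.to_fastq() for x in r2]
        assert t1.equals(t2)

    def test_multi_integration_founder_contributes_all_barcodes(self, rng):
        f, = make_founders(1, rng, integrations_per_founder=3)
        state = PopulationState(0, {f: 10})
        _, truth = generate_amplicon_reads(state, read_count=3000, seed=4)
        assert set(truth.umi) == {i.umi for i in f.integrations}

    def test_empty_population_rejected(self, rng):
        f, = make_founders(1, rng)
        with pytest.raises(ValueError):
            generate_amplicon_reads(PopulationState(0, {f: 0}), seed=0)


class TestDilutionAssay:
    def test_zero_frequency_all_negative(self):
        df = simulate_dilution_assay(0.0, seed=0)
        assert (df.wells_positive == 0).all()

    def test_saturating_dose_all_positive(self):
        df = simulate_dilution_assay(1.0, doses=(30,), seed=1)
        assert df.wells_positive.iloc[0] == 96

    def test_mean_positive_fraction_matches_closed_form(self):
        """dose 10 at f=0.058: P(positive) = 1 - e^(-0.58) ~= 0.440."""
        total = 0
        n_seeds = 500
        for s in range(n_seeds):
            df = simulate_dilution_assay(0.058, seed=s)
            total += int(df.loc[df.dose == 10, "wells_positive"].iloc[0])
        p = 1 - math.exp(-0.58)
        mean_frac = total / (n_seeds * 96)
        sd = math.sqrt(p * (1 - p) / (n_seeds * 96))
        assert abs(mean_frac - p) < 4 * sd


class TestMethylationReads:
    def test_zero_flip_rate_reproduces_founder_patterns(self, rng):
        state = uniform_state(4, rng, passage=5)
        pats = assign_founder_patterns(list(state.abundances), 7, seed=0)
        reads = simulate_methylation_reads(state, 7, pats, 0.0, 200, seed=1)
        allowed = {"".join(map(str, p)) for p in pats.values()}
        assert {r.pattern for r in reads} <= allowed

    def test_symmetric_flip_limit_half_methylated(self, rng):
        state = uniform_state(1, rng, passage=200)
        pats = assign_founder_patterns(list(state.abundances), 20, seed=0)
        reads = simulate_methylation_reads(state, 20, pats, 0.4, 5000, seed=2)
        mat = np.array([[int(c) for c in r.pattern] for r in reads])
        assert abs(mat.mean() - 0.5) < 0.02

    def test_ninety_ten_mixture_top_pattern_share(self, rng):
        f1, f2 = make_founders(2, rng)
        state = PopulationState(3, {f1: 900, f2: 100})
        pats = {f1.id: np.ones(7, dtype=np.uint8),
                f2.id: np.zeros(7, dtype=np.uint8)}
        n = 10_000
        reads = simulate_methylation_reads(state, 7, pats, 0.0, n, seed=3)
        top = sum(r.pattern == "1111111" for r in reads)
        sd = math.sqrt(n * 0.9 * 0.1)
        assert abs(top - 0.9 * n) < 3 * sd

    def test_missing_pattern_rejected(self, rng):
        state = uniform_state(2, rng, passage=1)
        with pytest.raises(ValueError, match="no methylation pattern"):
            simulate_methylation_reads(state, 7, {}, 0.0, 10, seed=0)


def test_sim_config_validation_and_roundtrip():
    cfg = SimConfig(seed=7, seq_error_rate=0.01)
    assert SimConfig.from_dict(cfg.to_dict()) == cfg
    with pytest.raises(ValueError):
        SimConfig(seq_error_rate=0.3)
    with pytest.raises(ValueError):
        SimConfig(n_founders=0)
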