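"""Clone counting, UMI collapse, Shannon diversity, trajectories."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import clonotrace as ct
from clonotrace.clones import (
    AbundanceTable,
    collapse_errors,
    count_clones,
    shannon,
    shannon_from_counts,
    table_from_truth,
    top_k_share,
    trajectory,
)
from clonotrace.core import CloneLabel, SampleMeta, random_dna
from clonotrace.extract import BarcodeCall
from clonotrace.simulate import (
    PopulationState,
    generate_amplicon_reads,
    simulate_differentiation_bottleneck,
    simulate_passaging,
)

from conftest import make_founders, uniform_state
from oracles import collapse_all_pairs, top_k_sort_and_sum


def call(read_id, color="mCherry", umi="A" * 16):
    return BarcodeCall(read_id, color, umi, 0, 0)


def table(counts_by_umi, color="mCherry", sample=None):
    return AbundanceTable({CloneLabel(color, u): n
                           for u, n in counts_by_umi.items()}, sample)


class TestCountClones:
    def test_single_clone_three_reads(self):
        t = count_clones([call(f"r{i}") for i in range(3)])
        assert t.counts == {CloneLabel("mCherry", "A" * 16): 3}
        assert list(t.fractions().values()) == [100.0]

    def test_same_umi_different_colors_are_distinct(self):
        t = count_clones([call("a", "mCherry"), call("b", "Venus")])
        assert t.richness == 2

    def test_empty_and_unassigned_rejected(self):
        with pytest.raises(ValueError):
            count_clones([])
        with pytest.raises(ValueError):
            count_clones([call("a", ct.UNASSIGNED)])

    def test_counts_equal_truth_allocation(self, rng):
        state = uniform_state(8, rng)
        reads, truth = generate_amplicon_reads(state, read_count=2000, seed=0)
        calls, _ = ct.process_reads([ct.ReadRecord(r.id, r.sequence)
                                     for r in reads])
        t = count_clones([c for c in calls if c.assigned])
        assert t.counts == table_from_truth(truth).counts


class TestCollapseErrors:
    def test_zero_radius_identity(self):
        t = table({"A" * 16: 10, "C" + "A" * 15: 1})
        assert collapse_errors(t, max_hamming=0).counts == t.counts

    def test_small_neighbor_absorbed(self):
        t = table({"A" * 16: 1000, "T" + "A" * 15: 5})
        out = collapse_errors(t)
        assert out.counts == {CloneLabel("mCherry", "A" * 16): 1005}

    def test_count_ratio_blocks_absorption(self):
        t = table({"A" * 16: 100, "T" + "A" * 15: 50})
        out = collapse_errors(t)  # 50 > 0.1 * 100: kept
        assert out.richness == 2

    def test_different_colors_never_merge(self):
        t = AbundanceTable({CloneLabel("mCherry", "A" * 16): 1000,
                            CloneLabel("Venus", "A" * 16): 1})
        assert collapse_errors(t).richness == 2

    def _clustered_table(self, rng, n_centers=30, n_clones=200):
        counts = {}
        centers = []
        while len(counts) < n_centers:
            u = random_dna(rng, 16)
            label = CloneLabel("mCherry", u)
            if label not in counts:
                counts[label] = int(rng.integers(200, 2000))
                centers.append(u)
        while len(counts) < n_clones:
            base = centers[rng.integers(0, len(centers))]
            i = int(rng.integers(0, 16))
            b = "ACGT"[rng.integers(0, 4)]
            mutant = CloneLabel("mCherry", base[:i] + b + base[i + 1:])
            if mutant not in counts:
                counts[mutant] = int(rng.integers(1, 40))
        return AbundanceTable(counts)

    @pytest.mark.parametrize("max_hamming", [1, 2])
    def test_matches_all_pairs_oracle(self, rng, max_hamming):
        for _ in range(3):
            t = self._clustered_table(rng)
            got = collapse_errors(t, max_hamming=max_hamming)
            exp = collapse_all_pairs(t.counts, max_hamming, 0.1)
            assert got.counts == exp

    def test_total_conserved_and_richness_monotone(self, rng):
        t = self._clustered_table(rng)
        out = collapse_errors(t)
        assert out.total == t.total
        assert out.richness <= t.richness
        assert sum(out.fractions().values()) == pytest.approx(100.0, abs=1e-9)


class TestShannon:
    def test_single_clone_zero(self):
        d = shannon(table({"A" * 16: 50}))
        assert d.shannon_H == 0.0
        assert d.evenness == 1.0

    def test_eight_equal_clones_ln8(self):
        t = table({random_dna(np.random.default_rng(i), 16): 10
                   for i in range(8)})
        assert t.richness == 8
        d = shannon(t)
        assert d.shannon_H == pytest.approx(math.log(8), abs=1e-12)
        assert d.evenness == pytest.approx(1.0)

    def test_half_quarter_quarter(self):
        d = shannon(table({"A" * 16: 2, "C" * 16: 1, "G" * 16: 1}))
        assert d.shannon_H == pytest.approx(1.5 * math.log(2), abs=1e-12)

    def test_matches_skbio_on_random_tables(self, rng):
        """Cross-check against the community diversity implementation."""
        from skbio.diversity.alpha import shannon as skbio_shannon

        for _ in range(20):
            counts = rng.integers(1, 500, size=rng.integers(2, 40))
            h = shannon_from_counts(dict(enumerate(map(int, counts))))
            assert h == pytest.approx(skbio_shannon(counts, base=math.e),
                                      rel=1e-12)

    def test_log_base_option(self):
        t = table({"A" * 16: 1, "C" * 16: 1})
        assert shannon(t, base=2).shannon_H == pytest.approx(1.0)

    @given(st.lists(st.integers(min_value=1, max_value=10_000),
                    min_size=1, max_size=50))
    def test_bounds_and_uniform_maximum(self, counts):
        h = shannon_from_counts(dict(enumerate(counts)))
        assert 0.0 <= h <= math.log(len(counts)) + 1e-12
        uniform = shannon_from_counts({i: 7 for i in range(len(counts))})
        assert h <= uniform + 1e-12


class TestTopKShare:
    def test_constructed_fractions(self):
        t = table({"A" * 16: 40, "C" * 16: 30, "G" * 16: 15, "T" * 16: 10,
                   "AC" * 8: 5})
        assert top_k_share(t, 3) == pytest.approx(85.0)

    def test_k_at_least_richness_is_100(self):
        t = table({"A" * 16: 3, "C" * 16: 1})
        assert top_k_share(t, 10) == pytest.approx(100.0)

    def test_matches_sort_and_sum_oracle(self, rng):
        for _ in range(20):
            counts = {CloneLabel("Venus", random_dna(rng, 16)): int(c)
                      for c in rng.integers(1, 1000, size=30)}
            t = AbundanceTable(counts)
            k = int(rng.integers(1, 8))
            assert top_k_share(t, k) == pytest.approx(
                top_k_sort_and_sum(counts, k))


class TestTrajectory:
    def _meta(self, passage):
        return SampleMeta("d1", "MSC", passage)

    def test_single_table_identity_reshape(self):
        t = table({"A" * 16: 3, "C" * 16: 1}, sample=self._meta(2))
        df = trajectory([t])
        assert set(df.fraction) == {75.0, 25.0}
        assert (df.passage == 2).all()

    def test_zero_fill_for_absent_clone(self):
        t2 = table({"A" * 16: 1, "C" * 16: 1}, sample=self._meta(2))
        t4 = table({"A" * 16: 1}, sample=self._meta(4))
        df = trajectory([t2, t4])
        row = df[(df.passage == 4) & (df.umi == "C" * 16)]
        assert len(row) == 1
        assert row.fraction.iloc[0] == 0.0
        sums = df.groupby("passage").fraction.sum()
        assert np.allclose(sums, 100.0)

    def test_duplicate_passages_rejected(self):
        t = table({"A" * 16: 1}, sample=self._meta(2))
        with pytest.raises(ValueError):
            trajectory([t, t])

    def test_fractions_match_simulator_truth(self, rng):
        state = uniform_state(6, rng)
        traj_states = simulate_passaging(state, 3, 300, seed=5)
        tables = []
        for st_ in traj_states:
            reads, truth = generate_amplicon_reads(st_, read_count=3000,
                                                   seed=st_.passage)
            calls, _ = ct.process_reads([ct.ReadRecord(r.id, r.sequence)
                                         for r in reads])
            t = count_clones([c for c in calls if c.assigned],
                             self._meta(st_.passage))
            tables.append(t)
            assert t.counts == table_from_truth(truth).counts
        df = trajectory(tables)
        assert np.allclose(df.groupby("passage").fraction.sum(), 100.0)


class TestDriftProperties:
    def test_mean_shannon_nonincreasing_under_neutral_drift(self, rng):
        """Neutral Wright-Fisher drift erodes diversity on average."""
        n_reps, n_passages = 200, 8
        h = np.zeros(n_passages + 1)
        for rep in range(n_reps):
            state = uniform_state(100, rng, cells_per_clone=5)
            traj = simulate_passaging(state, n_passages, 500, seed=3000 + rep)
            for t, s in enumerate(traj):
                h[t] += shannon_from_counts(
                    {f.id: c for f, c in s.alive().items()})
        h /= n_reps
        assert (np.diff(h) <= 1e-9).all()

    def test_differentiation_bottleneck_sharper_than_any_neutral_passage(self, rng):
        """A 3-founder recruitment drops H more in one step than any neutral
        passage at bottleneck >= 100, and drives top-3 share to 100%."""
        state = uniform_state(200, rng, cells_per_clone=5)
        neutral = simulate_passaging(state, 6, 100, seed=11)
        hs = [shannon_from_counts({f.id: c for f, c in s.alive().items()})
              for s in neutral]
        neutral_drops = -np.diff(hs)
        squeezed = simulate_differentiation_bottleneck(neutral[-1], 3, seed=12)
        h_before = hs[-1]
        h_after = shannon_from_counts(
            {f.id: c for f, c in squeezed.alive().items()})
        assert h_before - h_after > neutral_drops.max()
        counts = {CloneLabel(i.color, i.umi): c
                  for f, c in squeezed.alive().items()
                  for i in f.integrations}
        assert top_k_share(AbundanceTable(counts), 3) == pytest.approx(100.0)
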