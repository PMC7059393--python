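"""Clone abundance tables, UMI error collapse and diversity trajectories.

A clone is a (color, UMI) pair; its abundance in a sample is the number of
barcode reads carrying it, reported as a percentage of all assigned barcode
reads.  Diversity is summarised by the Shannon index
``H = -sum_i p_i ln p_i`` over clone proportions, together with richness,
Pielou evenness ``H / ln(richness)`` and the cumulative share of the top-k
clones (k = 3 mirrors the dominance summaries used for oligoclonal
populations).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core import CloneLabel, SampleMeta, UNASSIGNED, hamming
from .extract import BarcodeCall


@dataclass
class AbundanceTable:
    """Per-sample clone read counts with derived percent fractions."""

    counts: dict[CloneLabel, int]
    sample: Optional[SampleMeta] = None

    def __post_init__(self) -> None:
        if any(c < 1 for c in self.counts.values()):
            raise ValueError("counts must be >= 1 for present clones")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def richness(self) -> int:
        return len(self.counts)

    def fractions(self) -> dict[CloneLabel, float]:
        """Percent of total barcode reads per clone (sums to 100)."""
        tot = self.total
        return {c: 100.0 * n / tot for c, n in self.counts.items()}

    def to_frame(self) -> pd.DataFrame:
        fr = self.fractions()
        rows = sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0]))
        return pd.DataFrame(
            [(f"{c.color}:{c.umi}", c.color, c.umi, n, fr[c]) for c, n in rows],
            columns=["clone_id", "color", "umi", "count", "fraction"],
        )


@dataclass
class DiversityResult:
    shannon_H: float
    richness: int
    evenness: float
    top_k_share: float
    k: int = 3


def count_clones(calls: Sequence[BarcodeCall],
                 sample: Optional[SampleMeta] = None) -> AbundanceTable:
    """Tabulate assigned barcode calls into clone counts."""
    if not calls:
        raise ValueError("no barcode calls to count")
    counts: dict[CloneLabel, int] = {}
    for call in calls:
        if call.color == UNASSIGNED:
            raise ValueError(f"call {call.read_id} has no assigned color")
        label = CloneLabel(call.color, call.umi)
        counts[label] = counts.get(label, 0) + 1
    return AbundanceTable(counts, sample)


def collapse_errors(table: AbundanceTable, max_hamming: int = 1,
                    count_ratio: float = 0.1) -> AbundanceTable:
    """Directional collapse of sequencing-error UMIs into abundant parents.

    Clone ``a`` is absorbed into clone ``b`` iff they share a color,
    ``Hamming(umi_a, umi_b) <= max_hamming`` and
    ``count_a <= count_ratio * count_b`` (counts as observed, before any
    absorption).  Parents are visited from most to least abundant; a clone
    absorbed once is neither a parent nor absorbed again.  Total reads are
    conserved.
    """
    if max_hamming < 0:
        raise ValueError("max_hamming must be >= 0")
    if max_hamming == 0:
        return AbundanceTable(dict(table.counts), table.sample)
    order = sorted(table.counts, key=lambda c: (-table.counts[c], c))
    absorbed: dict[CloneLabel, CloneLabel] = {}
    if max_hamming == 1:
        # enumerate single-substitution neighbours of each parent UMI instead
        # of scanning all pairs; identical greedy semantics
        present = set(table.counts)
        for parent in order:
            if parent in absorbed:
                continue
            p_count = table.counts[parent]
            for i in range(len(parent.umi)):
                for b in "ACGT":
                    if b == parent.umi[i]:
                        continue
                    child = CloneLabel(parent.color,
                                       parent.umi[:i] + b + parent.umi[i + 1:])
                    if (child in present and child not in absorbed
                            and child != parent
                            and table.counts[child] <= count_ratio * p_count):
                        absorbed[child] = parent
    else:
        for parent in order:
            if parent in absorbed:
                continue
            p_count = table.counts[parent]
            for child in order:
                if child is parent or child in absorbed:
                    continue
                if child.color != parent.color:
                    continue
                if table.counts[child] > count_ratio * p_count:
                    continue
                if hamming(child.umi, parent.umi) <= max_hamming:
                    absorbed[child] = parent
    new_counts: dict[CloneLabel, int] = {}
    for clone, n in table.counts.items():
        target = absorbed.get(clone, clone)
        new_counts[target] = new_counts.get(target, 0) + n
    return AbundanceTable(new_counts, table.sample)


def shannon_from_counts(counts: Mapping, base: Optional[float] = None) -> float:
    """Shannon index of an abundance map, natural log by default.

    This single implementation serves both clone tables and methylation
    pattern tables, so identical abundance vectors give identical H
    regardless of what keys them.
    """
    values = np.array([v for v in counts.values() if v > 0], dtype=float)
    if values.size == 0:
        raise ValueError("no positive abundances")
    p = values / values.sum()
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= math.log(base)
    return max(h, 0.0)


def shannon(table: AbundanceTable, k: int = 3,
            base: Optional[float] = None) -> DiversityResult:
    """Diversity summary of one sample."""
    h = shannon_from_counts(table.counts, base)
    rich = table.richness
    if rich > 1:
        log_r = math.log(rich) if base is None else math.log(rich) / math.log(base)
        evenness = h / log_r
    else:
        evenness = 1.0
    return DiversityResult(h, rich, evenness, top_k_share(table, k), k)


def top_k_share(table: AbundanceTable, k: int = 3) -> float:
    """Cumulative percent of the k most abundant clones (ties: label order)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    fr = table.fractions()
    ordered = sorted(fr.items(), key=lambda kv: (-kv[1], kv[0]))
    return float(sum(v for _, v in ordered[:k]))


def trajectory(tables: Sequence[AbundanceTable]) -> pd.DataFrame:
    """Area-plot-ready long table across passages of one donor/cell type.

    Every clone observed anywhere gets a row at every passage (fraction 0
    when absent), and per-passage fractions sum to 100.
    """
    if not tables:
        raise ValueError("no abundance tables")
    metas = [t.sample for t in tables]
    if any(m is None for m in metas):
        raise ValueError("trajectory requires sample metadata on every table")
    if len({(m.donor, m.cell_type) for m in metas}) != 1:
        raise ValueError("tables must share donor and cell_type")
    passages = [m.passage for m in metas]
    if len(set(passages)) != len(passages):
        raise ValueError("duplicate passages in trajectory")
    if passages != sorted(passages):
        raise ValueError("passages must be strictly increasing")

    all_clones = sorted({c for t in tables for c in t.counts})
    rows = []
    for t in tables:
        fr = t.fractions()
        for c in all_clones:
            rows.append((t.sample.passage, f"{c.color}:{c.umi}", c.color, c.umi,
                         fr.get(c, 0.0)))
    return pd.DataFrame(rows, columns=["passage", "clone_id", "color", "umi",
                                       "fraction"])


def diversity_frame(tables: Sequence[AbundanceTable], k: int = 3) -> pd.DataFrame:
    rows = []
    for t in tables:
        d = shannon(t, k)
        m = t.sample
        rows.append((m.donor if m else "", m.cell_type if m else "",
                     m.passage if m else -1, d.shannon_H, d.richness,
                     d.evenness, d.top_k_share))
    return pd.DataFrame(rows, columns=["donor", "cell_type", "passage",
                                       "shannon_H", "richness", "evenness",
                                       f"top{k}_share"])


def table_from_truth(truth: pd.DataFrame,
                     sample: Optional[SampleMeta] = None) -> AbundanceTable:
    """Ground-truth abundance table from a simulator truth table."""
    counts = truth.groupby(["color", "umi"]).size()
    return AbundanceTable(
        {CloneLabel(c, u): int(n) for (c, u), n in counts.items()}, sample)
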