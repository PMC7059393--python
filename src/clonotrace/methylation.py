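"""Per-read DNA methylation pattern (epiallele) analysis.

Bisulfite amplicon sequencing reports, for every read, the binary
methylation state of each CpG in a targeted region.  Because methylation
changes accrue stochastically and largely independently at neighbouring
CpGs, a pattern shared by many reads can betray a dominant clone — this
module tabulates pattern frequencies, per-CpG mean methylation (beta
values), and early-vs-late pattern dominance, mirroring the clone-abundance
machinery (the Shannon index implementation is shared).

Default amplicons: senescence-associated regions in GRM7 (22 CpGs) and CASR
(7 CpGs), and the age-associated region in PDE4C (26 CpGs).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

from .core import SampleMeta
from .clones import shannon_from_counts


class AmpliconDef(NamedTuple):
    name: str
    n_cpgs: int


DEFAULT_AMPLICONS: tuple[AmpliconDef, ...] = (
    AmpliconDef("GRM7", 22),
    AmpliconDef("CASR", 7),
    AmpliconDef("PDE4C", 26),
)

MISSING = "."


class MethylationRead(NamedTuple):
    """One sequencing read's CpG states: '1' methylated, '0' not, '.' missing."""

    read_id: str
    amplicon: str
    pattern: str


@dataclass
class PatternTable:
    """Counts of distinct complete methylation patterns in one sample."""

    amplicon: str
    counts: dict[str, int]
    sample: Optional[SampleMeta] = None
    n_cpgs: Optional[int] = None

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def fractions(self) -> dict[str, float]:
        tot = self.total
        return {p: 100.0 * n / tot for p, n in self.counts.items()}

    def ordered(self) -> list[tuple[str, int]]:
        """Patterns by descending count, then lexicographic."""
        return sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0]))

    def to_frame(self) -> pd.DataFrame:
        fr = self.fractions()
        return pd.DataFrame(
            [(p, n, fr[p]) for p, n in self.ordered()],
            columns=["pattern", "count", "fraction"],
        )


def tabulate_patterns(reads: Sequence[MethylationRead],
                      sample: Optional[SampleMeta] = None,
                      drop_incomplete: bool = True,
                      impute_missing_as: Optional[str] = None) -> PatternTable:
    """Count exact pattern strings over the reads of one amplicon.

    Reads with missing CpG calls ('.') are dropped by default, since pattern
    identity requires complete strings; alternatively missing states can be
    imputed with a fixed state via ``impute_missing_as`` ('0' or '1').
    """
    if not reads:
        raise ValueError("no methylation reads")
    amplicons = {r.amplicon for r in reads}
    if len(amplicons) != 1:
        raise ValueError(f"reads span multiple amplicons: {sorted(amplicons)}")
    lengths = {len(r.pattern) for r in reads}
    if len(lengths) != 1:
        raise ValueError("inconsistent pattern lengths within amplicon")
    counts: dict[str, int] = {}
    for r in reads:
        pat = r.pattern
        if MISSING in pat:
            if impute_missing_as is not None:
                pat = pat.replace(MISSING, impute_missing_as)
            elif drop_incomplete:
                continue
            else:
                raise ValueError(f"read {r.read_id} has missing CpG calls")
        if set(pat) - {"0", "1"}:
            raise ValueError(f"read {r.read_id} has invalid pattern {pat!r}")
        counts[pat] = counts.get(pat, 0) + 1
    if not counts:
        raise ValueError("no complete patterns to tabulate")
    return PatternTable(reads[0].amplicon, counts, sample, lengths.pop())


def mean_methylation(table: PatternTable) -> np.ndarray:
    """Read-weighted per-CpG mean methylation (beta values in [0, 1])."""
    if not table.counts:
        raise ValueError("empty pattern table")
    pats = list(table.counts)
    mat = np.array([[int(c) for c in p] for p in pats], dtype=float)
    w = np.array([table.counts[p] for p in pats], dtype=float)
    return (w @ mat) / w.sum()


@dataclass
class DominanceReport:
    amplicon: str
    top_patterns_early: list[tuple[str, float]]
    top_patterns_late: list[tuple[str, float]]
    change: float            # late top pattern's share, late minus early (points)
    shannon_early: float
    shannon_late: float
    dominant: bool
    threshold: float


def pattern_dominance(early: PatternTable, late: PatternTable, top_n: int = 1,
                      threshold: float = 25.0) -> DominanceReport:
    """Compare pattern composition between an early and a late sample.

    Reports the top-n pattern shares in each sample, the change in the late
    sample's top pattern (its late share minus its share in the early
    sample), and pattern Shannon diversity for both.  A dominance event is
    flagged when the late top pattern's share strictly exceeds ``threshold``
    percent *and* increased relative to early.  The default threshold is a
    pipeline convention (no quantitative criterion exists for a pattern
    "becoming dominant").
    """
    if early.amplicon != late.amplicon:
        raise ValueError(
            f"amplicon mismatch: {early.amplicon} vs {late.amplicon}")
    fr_early, fr_late = early.fractions(), late.fractions()
    top_early = [(p, fr_early[p]) for p, _ in early.ordered()[:top_n]]
    top_late = [(p, fr_late[p]) for p, _ in late.ordered()[:top_n]]
    top_pat, top_share = top_late[0]
    change = top_share - fr_early.get(top_pat, 0.0)
    dominant = top_share > threshold and change > 0
    return DominanceReport(
        early.amplicon, top_early, top_late, change,
        shannon_from_counts(early.counts), shannon_from_counts(late.counts),
        dominant, threshold,
    )


def pattern_trajectory(tables: Sequence[PatternTable]) -> pd.DataFrame:
    """Long-format pattern-fraction trajectory with zero-fill across passages."""
    if not tables:
        raise ValueError("no pattern tables")
    if len({t.amplicon for t in tables}) != 1:
        raise ValueError("tables must share one amplicon")
    if any(t.sample is None for t in tables):
        raise ValueError("pattern trajectory requires sample metadata")
    passages = [t.sample.passage for t in tables]
    if len(set(passages)) != len(passages):
        raise ValueError("duplicate passages")
    if passages != sorted(passages):
        raise ValueError("passages must be strictly increasing")
    all_pats = sorted({p for t in tables for p in t.counts})
    rows = []
    for t in tables:
        fr = t.fractions()
        for p in all_pats:
            rows.append((t.sample.passage, p, fr.get(p, 0.0)))
    return pd.DataFrame(rows, columns=["passage", "pattern", "fraction"])


def reads_from_frame(df: pd.DataFrame) -> list[MethylationRead]:
    """Methylation reads from a TSV table (read_id, amplicon, pattern)."""
    return [MethylationRead(str(r.read_id), str(r.amplicon), str(r.pattern))
            for r in df.itertuples()]
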