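"""Synthetic experiments with the statistical structure the pipeline assumes.

The generator emulates the experimental design of multicolor lentiviral
barcoding of cultured stromal/pluripotent cells:

* labeling — each cell receives ``k ~ Poisson(MOI)`` vector integrations;
  puromycin selection removes the ``k = 0`` class, so founders carry a
  zero-truncated Poisson number of (color, UMI) barcodes;
* serial passaging — deterministic fitness-weighted growth followed by a
  multinomial bottleneck of fixed size (Wright–Fisher resampling), the
  mechanism behind gradual diversity loss during culture expansion;
* a differentiation bottleneck — a small number of cells sampled without
  replacement seed the derived population (the iPSC→iMSC transition);
* amplicon sequencing of the barcode cassette with i.i.d. substitution
  errors, plus a truth table mapping every read to its integration;
* limiting-dilution well outcomes under the single-hit Poisson model;
* per-read CpG methylation patterns inherited from clone founders with
  per-passage stochastic flips (epimutation).

Every function takes an explicit seed or ``numpy.random.Generator``;
identical inputs give byte-identical outputs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    BARCODE_LENGTH,
    LEFT_PRIMER,
    RIGHT_PRIMER,
    TAG_LENGTH,
    UMI_LENGTH,
    CloneLabel,
    ColorTag,
    DEFAULT_TAGS,
    random_dna,
)

_BASE_CODES = np.frombuffer(b"ACGT", dtype=np.uint8)


class SimulationExtinct(RuntimeError):
    """Raised when the simulated population hits zero cells."""

    def __init__(self, passage: int):
        super().__init__(f"population extinct at passage {passage}")
        self.passage = passage


@dataclass(frozen=True)
class Integration:
    """One proviral copy: the color of its vector and its random UMI."""

    color: str
    umi: str

    @property
    def label(self) -> CloneLabel:
        return CloneLabel(self.color, self.umi)


@dataclass(frozen=True)
class Founder:
    """A transduced cell surviving selection, with >= 1 integrations."""

    id: str
    integrations: tuple[Integration, ...]
    fitness: float = 1.0

    def __post_init__(self) -> None:
        if not self.integrations:
            raise ValueError("founder must carry at least one integration")
        if self.fitness <= 0:
            raise ValueError("fitness must be positive")


@dataclass
class PopulationState:
    """Clone cell counts at one passage."""

    passage: int
    abundances: dict[Founder, int]

    def __post_init__(self) -> None:
        if self.passage < 0:
            raise ValueError("passage must be >= 0")
        if any(c < 0 for c in self.abundances.values()):
            raise ValueError("cell counts must be non-negative")

    @property
    def total_cells(self) -> int:
        return sum(self.abundances.values())

    def fractions(self) -> dict[Founder, float]:
        tot = self.total_cells
        return {f: c / tot for f, c in self.abundances.items() if c > 0}

    def alive(self) -> dict[Founder, int]:
        return {f: c for f, c in self.abundances.items() if c > 0}


@dataclass
class SimConfig:
    """All knobs of one synthetic experiment, JSON-serializable."""

    n_founders: int = 200
    moi: float = 1.0
    n_passages: int = 6
    bottleneck_size: int = 500
    growth_factor: float = 4.0
    fitness_sd: float = 0.0
    seq_error_rate: float = 0.0
    read_count: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_founders, self.n_passages, self.bottleneck_size,
               self.read_count) <= 0:
            raise ValueError("counts must be positive")
        if self.moi <= 0 or self.growth_factor < 1 or self.fitness_sd < 0:
            raise ValueError("invalid rate parameter")
        if not 0 <= self.seq_error_rate < 0.25:
            raise ValueError("seq_error_rate must be in [0, 0.25)")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        return cls(**dict(d))


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def simulate_labeling(n_cells: int, moi: float, tags: Sequence[ColorTag] = DEFAULT_TAGS,
                      fitness_sd: float = 0.0, seed=0) -> list[Founder]:
    """Transduce ``n_cells`` at the given MOI and apply puromycin selection.

    Integration counts are Poisson(moi); cells with zero integrations die
    under selection, so survivors carry a zero-truncated Poisson copy number
    and the expected survivor count is ``n_cells * (1 - exp(-moi))``.  Colors
    are uniform per integration, UMIs uniform over 4^16.  Fitness multipliers
    are lognormal with log-sd ``fitness_sd`` (exactly 1.0 when it is 0).
    """
    if n_cells <= 0 or moi <= 0:
        raise ValueError("n_cells and moi must be positive")
    rng = _rng(seed)
    copy_numbers = rng.poisson(moi, size=n_cells)
    founders: list[Founder] = []
    tag_names = [t.name for t in tags]
    for i, k in enumerate(copy_numbers):
        if k == 0:
            continue  # puromycin death
        ints = tuple(
            Integration(tag_names[rng.integers(0, len(tag_names))],
                        random_dna(rng, UMI_LENGTH))
            for _ in range(k)
        )
        fit = float(rng.lognormal(0.0, fitness_sd)) if fitness_sd > 0 else 1.0
        founders.append(Founder(f"F{i:05d}", ints, fit))
    return founders


def initial_state(founders: Sequence[Founder], cells_per_founder: int = 1) -> PopulationState:
    return PopulationState(0, {f: cells_per_founder for f in founders})


def simulate_passaging(state: PopulationState, n_passages: int,
                       bottleneck_size: Optional[int], growth_factor: float = 4.0,
                       seed=0) -> list[PopulationState]:
    """Serial passaging: fitness-weighted growth then a multinomial bottleneck.

    Each passage, clone ``i`` grows deterministically to
    ``count_i * growth_factor * fitness_i`` (in expectation), then
    ``bottleneck_size`` cells are resampled multinomially from the grown
    fractions — Wright–Fisher drift, under which expected heterozygosity
    decays by ``(1 - 1/bottleneck_size)`` per passage in the neutral case.
    ``bottleneck_size=None`` skips resampling (the infinite-bottleneck limit,
    preserving fractions exactly under neutral fitness).

    Returns the trajectory including the input state.
    """
    if bottleneck_size is not None and bottleneck_size <= 0:
        raise ValueError("bottleneck_size must be positive (or None)")
    rng = _rng(seed)
    traj = [state]
    cur = state
    for _ in range(n_passages):
        alive = cur.alive()
        if not alive:
            raise SimulationExtinct(cur.passage)
        founders = list(alive)
        grown = np.array([alive[f] * growth_factor * f.fitness for f in founders])
        if bottleneck_size is None:
            new_counts = {f: int(round(g)) for f, g in zip(founders, grown)}
        else:
            p = grown / grown.sum()
            draws = rng.multinomial(bottleneck_size, p)
            new_counts = {f: int(d) for f, d in zip(founders, draws) if d > 0}
        cur = PopulationState(cur.passage + 1, new_counts)
        traj.append(cur)
    return traj


def simulate_differentiation_bottleneck(state: PopulationState, n_recruited: int,
                                        seed=0) -> PopulationState:
    """Sample ``n_recruited`` cells without replacement to seed a new lineage.

    Models the oligoclonal onset of differentiation: only the recruited
    cells' clones survive into the derived population.
    """
    total = state.total_cells
    if not 0 < n_recruited <= total:
        raise ValueError(f"n_recruited must be in (0, {total}], got {n_recruited}")
    rng = _rng(seed)
    alive = state.alive()
    founders = list(alive)
    counts = np.array([alive[f] for f in founders])
    drawn = rng.multivariate_hypergeometric(counts, n_recruited)
    new = {f: int(d) for f, d in zip(founders, drawn) if d > 0}
    return PopulationState(state.passage, new)


@dataclass
class FastqRecord:
    id: str
    sequence: str
    quality: str

    def to_fastq(self) -> str:
        return f"@{self.id}\n{self.sequence}\n+\n{self.quality}\n"


def generate_amplicon_reads(state: PopulationState, tags: Sequence[ColorTag] = DEFAULT_TAGS,
                            read_count: int = 10_000, seq_error_rate: float = 0.0,
                            seed=0, flank_length: int = 20,
                            ) -> tuple[list[FastqRecord], pd.DataFrame]:
    """Sequence the barcode amplicon of a population.

    Each read is ``left-flank + ACCATCTAGA + tag + UMI + CTCGAGACTG +
    right-flank`` with i.i.d. substitution errors at ``seq_error_rate`` per
    base over the whole read.  Reads are allocated to integrations with
    probability proportional to clone cell count (a founder with m
    integrations contributes m amplifiable barcodes, each weighted by its
    cell count).  Returns the reads and a truth table with one row per read:
    (read_id, founder_id, color, umi).
    """
    if read_count <= 0:
        raise ValueError("read_count must be positive")
    if not 0 <= seq_error_rate < 0.25:
        raise ValueError("seq_error_rate must be in [0, 0.25)")
    alive = state.alive()
    if not alive:
        raise ValueError("cannot sequence an empty population")
    rng = _rng(seed)

    tag_seq = {t.name: t.sequence for t in tags}
    units: list[tuple[Founder, Integration]] = [
        (f, integ) for f in alive for integ in f.integrations
    ]
    weights = np.array([alive[f] for f, _ in units], dtype=float)
    weights /= weights.sum()
    assignment = rng.choice(len(units), size=read_count, p=weights)

    read_len = 2 * flank_length + len(LEFT_PRIMER) + BARCODE_LENGTH + len(RIGHT_PRIMER)
    # Assemble all reads as a uint8 matrix of base codes, then mutate in bulk.
    core_by_unit = np.empty((len(units), read_len - 2 * flank_length), dtype=np.uint8)
    for u, (f, integ) in enumerate(units):
        s = LEFT_PRIMER + tag_seq[integ.color] + integ.umi + RIGHT_PRIMER
        core_by_unit[u] = np.frombuffer(s.encode(), dtype=np.uint8)
    mat = np.empty((read_count, read_len), dtype=np.uint8)
    mat[:, :flank_length] = _BASE_CODES[rng.integers(0, 4, (read_count, flank_length))]
    mat[:, flank_length:read_len - flank_length] = core_by_unit[assignment]
    mat[:, read_len - flank_length:] = _BASE_CODES[
        rng.integers(0, 4, (read_count, flank_length))]

    if seq_error_rate > 0:
        err = rng.random((read_count, read_len)) < seq_error_rate
        # substitute with one of the three other bases, uniformly
        idx = np.searchsorted(_BASE_CODES, mat[err])
        shift = rng.integers(1, 4, size=idx.size)
        mat[err] = _BASE_CODES[(idx + shift) % 4]

    qual = "I" * read_len
    reads = [
        FastqRecord(f"read{i:06d}", mat[i].tobytes().decode(), qual)
        for i in range(read_count)
    ]
    truth = pd.DataFrame({
        "read_id": [r.id for r in reads],
        "founder_id": [units[a][0].id for a in assignment],
        "color": [units[a][1].color for a in assignment],
        "umi": [units[a][1].umi for a in assignment],
    })
    return reads, truth


def simulate_dilution_assay(true_f: float, doses: Sequence[float] = (30, 10, 3, 1),
                            wells_per_dose: int = 96, seed=0) -> pd.DataFrame:
    """Limiting-dilution outcomes under the single-hit Poisson model.

    With cells per well Poisson-distributed around the nominal dose ``d`` and
    clonogenic frequency ``f``, a well is positive with probability
    ``1 - exp(-f*d)``; positives per dose are binomial.
    Returns a design table (dose, wells_tested, wells_positive).
    """
    if not 0 <= true_f <= 1:
        raise ValueError("true_f must be in [0, 1]")
    if any(d <= 0 for d in doses):
        raise ValueError("doses must be positive")
    rng = _rng(seed)
    p_pos = 1.0 - np.exp(-true_f * np.asarray(doses, dtype=float))
    positives = rng.binomial(wells_per_dose, p_pos)
    return pd.DataFrame({
        "dose": list(doses),
        "wells_tested": wells_per_dose,
        "wells_positive": positives.astype(int),
    })


def assign_founder_patterns(founders: Sequence[Founder], n_cpgs: int, seed=0,
                            distinct: bool = True) -> dict[str, np.ndarray]:
    """Draw one random binary CpG pattern per founder (Bernoulli 0.5 per CpG)."""
    rng = _rng(seed)
    patterns: dict[str, np.ndarray] = {}
    seen: set[bytes] = set()
    for f in founders:
        while True:
            pat = rng.integers(0, 2, size=n_cpgs).astype(np.uint8)
            if not distinct or pat.tobytes() not in seen or len(seen) >= 2 ** n_cpgs:
                break
        seen.add(pat.tobytes())
        patterns[f.id] = pat
    return patterns


def simulate_methylation_reads(state: PopulationState, n_cpgs: int,
                               founder_patterns: Mapping[str, np.ndarray],
                               flip_rate: float, n_reads: int, seed=0,
                               amplicon: str = "amplicon"):
    """Per-read CpG methylation patterns for a clonal population.

    Each read samples a clone proportionally to its abundance and reports the
    founder's pattern after independent per-CpG flips.  With per-passage flip
    probability ``r`` accumulated over the state's ``passage`` count ``t``,
    the probability a CpG differs from the founder state is the two-state
    Markov-chain value ``(1 - (1 - 2r)^t) / 2``.
    """
    from .methylation import MethylationRead  # avoid import cycle at module load

    if n_cpgs < 1:
        raise ValueError("n_cpgs must be >= 1")
    if not 0 <= flip_rate <= 1:
        raise ValueError("flip_rate must be in [0, 1]")
    alive = state.alive()
    if not alive:
        raise ValueError("cannot sample reads from an empty population")
    founders = list(alive)
    for f in founders:
        if f.id not in founder_patterns:
            raise ValueError(f"founder {f.id} has no methylation pattern")
        if len(founder_patterns[f.id]) != n_cpgs:
            raise ValueError(f"pattern for {f.id} has wrong length")
    rng = _rng(seed)
    p = np.array([alive[f] for f in founders], dtype=float)
    p /= p.sum()
    choice = rng.choice(len(founders), size=n_reads, p=p)
    base = np.stack([np.asarray(founder_patterns[f.id], dtype=np.uint8)
                     for f in founders])
    mat = base[choice]
    p_flip = (1.0 - (1.0 - 2.0 * flip_rate) ** state.passage) / 2.0
    if p_flip > 0:
        flips = rng.random(mat.shape) < p_flip
        mat = mat ^ flips.astype(np.uint8)
    digits = mat + ord("0")
    return [
        MethylationRead(f"mread{i:06d}", amplicon, digits[i].tobytes().decode())
        for i in range(n_reads)
    ]


# ---------------------------------------------------------------------------
# plain-text writers (headers name columns; byte-stable for fixed inputs)

def write_fastq(reads: Sequence[FastqRecord], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(r.to_fastq())


def write_truth_table(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def trajectory_frame(states: Sequence[PopulationState]) -> pd.DataFrame:
    """Long-format truth trajectory: (passage, founder_id, cells, fraction)."""
    rows = []
    for st in states:
        tot = st.total_cells
        for f, c in sorted(st.alive().items(), key=lambda kv: kv[0].id):
            rows.append((st.passage, f.id, c, 100.0 * c / tot))
    return pd.DataFrame(rows, columns=["passage", "founder_id", "cells", "fraction"])
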