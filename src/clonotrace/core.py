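"""Shared domain types and constants for RGB barcode clonal tracking.

The barcode cassette carried by each lentiviral construct is a 31-nt insert
flanked by fixed PCR primer sequences::

    ... ACCATCTAGA  [15-nt color tag][16-nt random UMI]  CTCGAGACTG ...

The color tag identifies which fluorophore vector (mCherry / Venus /
Cerulean) the integration came from; the random UMI makes each integration
event unique.  A clone is therefore labelled by the (color, UMI) pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence

import numpy as np

LEFT_PRIMER = "ACCATCTAGA"
RIGHT_PRIMER = "CTCGAGACTG"
TAG_LENGTH = 15
UMI_LENGTH = 16
BARCODE_LENGTH = TAG_LENGTH + UMI_LENGTH

UNASSIGNED = "UNASSIGNED"

_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings."""
    if len(a) != len(b):
        raise ValueError(f"hamming() needs equal lengths, got {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


class ColorTag(NamedTuple):
    """A fluorophore label and its color-specific tag sequence."""

    name: str
    sequence: str


class CloneLabel(NamedTuple):
    """The unit of clonal tracking: one lentiviral integration event."""

    color: str
    umi: str


@dataclass(frozen=True)
class SampleMeta:
    """Provenance of one sequencing sample along a culture trajectory."""

    donor: str
    cell_type: str  # MSC, iPSC or iMSC
    passage: int
    day: Optional[int] = None

    def __post_init__(self) -> None:
        if self.passage < 0:
            raise ValueError(f"passage must be non-negative, got {self.passage}")
        if self.cell_type not in {"MSC", "iPSC", "iMSC"}:
            raise ValueError(f"unknown cell_type {self.cell_type!r}")


# Invented compliant defaults: the construct's real color-specific sequences
# are vendor/lab configuration, so tags are user-supplied; these three are
# pairwise Hamming-separated by >= 11 (far above 2 x the default mismatch
# tolerance of 2), which guarantees unambiguous color calls.
DEFAULT_TAGS: tuple[ColorTag, ...] = (
    ColorTag("mCherry", "ACTGCCAACGGTTAG"),
    ColorTag("Venus", "GTACTTGGCACAGCT"),
    ColorTag("Cerulean", "TGATAGCGTTCCAGA"),
)


def validate_tags(tags: Sequence[ColorTag], max_mismatch: int = 2,
                  tag_length: int = TAG_LENGTH) -> None:
    """Check tag lengths and the pairwise-separation precondition.

    Color calling tolerates up to ``max_mismatch`` mismatches, so any two tags
    must differ at more than ``2 * max_mismatch`` positions for at most one
    tag to be callable on any read.
    """
    names = [t.name for t in tags]
    if len(set(names)) != len(names):
        raise ValueError("duplicate tag names")
    for t in tags:
        if len(t.sequence) != tag_length:
            raise ValueError(
                f"tag {t.name} has length {len(t.sequence)}, expected {tag_length}")
        if set(t.sequence) - set(_BASES):
            raise ValueError(f"tag {t.name} has non-ACGT characters")
    for i, a in enumerate(tags):
        for b in tags[i + 1:]:
            d = hamming(a.sequence, b.sequence)
            if d <= 2 * max_mismatch:
                raise ValueError(
                    f"tags {a.name}/{b.name} separated by Hamming {d}, "
                    f"need > {2 * max_mismatch}")


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=length))


def random_tags(rng: np.random.Generator, names: Iterable[str],
                tag_length: int = TAG_LENGTH, max_mismatch: int = 2,
                max_tries: int = 1000) -> tuple[ColorTag, ...]:
    """Invent a compliant tag set: pairwise Hamming > 2*max_mismatch."""
    tags: list[ColorTag] = []
    for name in names:
        for _ in range(max_tries):
            cand = random_dna(rng, tag_length)
            if all(hamming(cand, t.sequence) > 2 * max_mismatch for t in tags):
                tags.append(ColorTag(name, cand))
                break
        else:  # pragma: no cover - would need pathological parameters
            raise RuntimeError("could not generate separated tags")
    out = tuple(tags)
    validate_tags(out, max_mismatch, tag_length)
    return out
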