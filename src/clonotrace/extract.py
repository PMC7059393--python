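"""Barcode extraction from amplicon reads.

The 31-nt barcode sits between two fixed 10-nt primers.  ``trim_linked``
locates the best ordered placement of both primers allowing up to
``floor(max_error_rate * len(primer))`` edits each (substitutions and
indels), the linked-adapter convention of standard read trimmers, and
returns the sequence strictly between them.  ``call_color`` then matches the
first 15 nt against the color tags by Hamming distance, and ``extract_umi``
takes the following 16 nt.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple, Optional, Sequence, Union

import numpy as np

from .core import (
    LEFT_PRIMER,
    RIGHT_PRIMER,
    TAG_LENGTH,
    UMI_LENGTH,
    UNASSIGNED,
    ColorTag,
    DEFAULT_TAGS,
    hamming,
    revcomp,
)


class ReadRecord(NamedTuple):
    id: str
    sequence: str
    mate: str = "forward"  # or "reverse"


class TrimResult(NamedTuple):
    inner: str
    edits: int       # total edit distance over both delimiters
    start: int       # inner start (0-based, on the matched orientation)
    end: int         # inner end (half-open)


@dataclass
class BarcodeCall:
    read_id: str
    color: str
    umi: str
    tag_mismatches: int
    trim_edits: int

    @property
    def assigned(self) -> bool:
        return self.color != UNASSIGNED and len(self.umi) == UMI_LENGTH


@dataclass
class ExtractionStats:
    total_reads: int = 0
    trimmed: int = 0
    no_barcode: int = 0
    unassigned_color: int = 0
    assigned: int = 0

    def validate(self) -> None:
        assert self.trimmed + self.no_barcode == self.total_reads
        assert self.assigned + self.unassigned_color == self.trimmed

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def _semiglobal_end_scores(pattern: str, text: str) -> np.ndarray:
    """Min edit distance of ``pattern`` vs any substring of ``text`` ending at j.

    Returns an array of length ``len(text)+1``; entry j is the best score over
    substrings text[i:j] for any i <= j.
    """
    m, n = len(pattern), len(text)
    prev = np.zeros(n + 1, dtype=np.int32)  # row 0: free start anywhere
    for i in range(1, m + 1):
        cur = np.empty(n + 1, dtype=np.int32)
        cur[0] = i
        pc = pattern[i - 1]
        for j in range(1, n + 1):
            cur[j] = min(
                prev[j - 1] + (pc != text[j - 1]),
                prev[j] + 1,      # delete pattern char
                cur[j - 1] + 1,   # insert text char
            )
        prev = cur
    return prev


def _placement(seq: str, left: str, right: str, k_left: int, k_right: int
               ) -> Optional[TrimResult]:
    """Best ordered (left, right) delimiter placement by total edit distance.

    Ties are broken by smallest inner start, then shortest inner.
    """
    n = len(seq)
    left_end = _semiglobal_end_scores(left, seq)
    # right-start scores via the reversed problem
    right_rev = _semiglobal_end_scores(right[::-1], seq[::-1])
    right_start = right_rev[::-1]  # right_start[j]: best over substrings starting at j

    # suffix minima of right_start with earliest position achieving them
    best_s = np.empty(n + 1, dtype=np.int64)
    best_s_pos = np.empty(n + 1, dtype=np.int64)
    best = np.iinfo(np.int64).max
    pos = -1
    for j in range(n, -1, -1):
        if right_start[j] < best:  # strict: keep the *earliest* among equals
            best, pos = int(right_start[j]), j
        elif right_start[j] == best:
            pos = j
        best_s[j], best_s_pos[j] = best, pos

    found: Optional[TrimResult] = None
    for e in range(n + 1):
        if left_end[e] > k_left:
            continue
        s = int(best_s_pos[e])
        if best_s[e] > k_right:
            continue
        total = int(left_end[e] + best_s[e])
        if found is None or total < found.edits:
            found = TrimResult(seq[e:s], total, e, s)
        # equal scores: earlier e already seen wins; for same e, best_s_pos
        # is the earliest (shortest inner) by construction
    return found


def trim_linked(read: Union[ReadRecord, str], left: str = LEFT_PRIMER,
                right: str = RIGHT_PRIMER, max_error_rate: float = 0.2
                ) -> Optional[TrimResult]:
    """Locate the linked delimiters and return the inner sequence.

    Allows ``floor(max_error_rate * len(adapter))`` edits per adapter
    (2 for the default 10-mers at rate 0.2).  Returns ``None`` when either
    delimiter is not found within tolerance.  Reverse-orientation mates are
    reverse-complemented before matching.
    """
    if not left or not right:
        raise ValueError("delimiters must be non-empty")
    if not 0 <= max_error_rate < 0.5:
        raise ValueError("max_error_rate must be in [0, 0.5)")
    if isinstance(read, ReadRecord):
        seq = revcomp(read.sequence) if read.mate == "reverse" else read.sequence
    else:
        seq = read
    k_left = int(max_error_rate * len(left))
    k_right = int(max_error_rate * len(right))

    # fast path: exact ordered occurrences are always optimal (score 0);
    # first exact left occurrence has the smallest end, first exact right
    # after it gives the shortest inner.
    i = seq.find(left)
    while i != -1:
        e = i + len(left)
        s = seq.find(right, e)
        if s != -1:
            return TrimResult(seq[e:s], 0, e, s)
        i = seq.find(left, i + 1)

    return _placement(seq, left, right, k_left, k_right)


def call_color(inner: str, tags: Sequence[ColorTag] = DEFAULT_TAGS,
               max_mismatch: int = 2) -> tuple[str, int]:
    """Assign the color tag matching the first 15 nt within ``max_mismatch``.

    Tag separation (pairwise Hamming > 2*max_mismatch) guarantees at most one
    tag can be within tolerance.  Short inners are UNASSIGNED with the tag
    length as the mismatch count.
    """
    tag_len = len(tags[0].sequence)
    if len(inner) < tag_len:
        return UNASSIGNED, tag_len
    prefix = inner[:tag_len]
    best_name, best_d = UNASSIGNED, tag_len + 1
    for t in tags:
        d = hamming(prefix, t.sequence)
        if d < best_d:
            best_name, best_d = t.name, d
    if best_d <= max_mismatch:
        return best_name, best_d
    return UNASSIGNED, best_d


def extract_umi(inner: str) -> Optional[str]:
    """The 16-nt UMI at positions 16..31 (1-based) of the inner sequence."""
    if len(inner) < TAG_LENGTH + UMI_LENGTH:
        return None
    return inner[TAG_LENGTH:TAG_LENGTH + UMI_LENGTH]


def read_fastq(path) -> Iterator[ReadRecord]:
    """Stream a (optionally gzipped) FASTQ file as ReadRecords.

    Parsing is delegated to Biopython; malformed records raise a ValueError
    naming the record index.
    """
    from Bio import SeqIO

    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        records = SeqIO.parse(fh, "fastq")
        idx = 0
        while True:
            try:
                rec = next(records)
            except StopIteration:
                return
            except ValueError as err:
                raise ValueError(
                    f"malformed FASTQ record at index {idx} in {path}: {err}"
                ) from err
            yield ReadRecord(rec.id, str(rec.seq).upper())
            idx += 1


def process_reads(reads: Iterable[ReadRecord], tags: Sequence[ColorTag] = DEFAULT_TAGS,
                  max_error_rate: float = 0.2, max_mismatch: int = 2,
                  left: str = LEFT_PRIMER, right: str = RIGHT_PRIMER,
                  ) -> tuple[list[BarcodeCall], ExtractionStats]:
    """Trim, call colors and extract UMIs for a stream of reads.

    Reads whose delimiters are not found count as ``no_barcode`` and yield no
    call; trimmed reads without a confident color or a full-length UMI count
    as ``unassigned_color``.  Deterministic for fixed input.
    """
    calls: list[BarcodeCall] = []
    stats = ExtractionStats()
    for read in reads:
        stats.total_reads += 1
        trim = trim_linked(read, left, right, max_error_rate)
        if trim is None:
            stats.no_barcode += 1
            continue
        stats.trimmed += 1
        color, mism = call_color(trim.inner, tags, max_mismatch)
        umi = extract_umi(trim.inner)
        call = BarcodeCall(read.id, color if umi is not None else UNASSIGNED,
                           umi or "", mism, trim.edits)
        if call.assigned:
            stats.assigned += 1
        else:
            stats.unassigned_color += 1
        calls.append(call)
    stats.validate()
    return calls, stats


def process_fastq(path, tags: Sequence[ColorTag] = DEFAULT_TAGS,
                  path2=None, **kwargs) -> tuple[list[BarcodeCall], ExtractionStats]:
    """File-level wrapper around :func:`process_reads`.

    With a second (mate-2) file, mate 2 is matched on its reverse complement
    and used only for read ids that produced no barcode from mate 1
    (mate-1 priority deduplication).
    """
    calls, stats = process_reads(read_fastq(path), tags, **kwargs)
    if path2 is None:
        return calls, stats
    have = {c.read_id for c in calls}
    mate2 = (ReadRecord(r.id, r.sequence, "reverse")
             for r in read_fastq(path2) if r.id not in have)
    calls2, stats2 = process_reads(mate2, tags, **kwargs)
    merged = ExtractionStats(
        total_reads=stats.total_reads,
        trimmed=stats.trimmed + stats2.trimmed,
        no_barcode=stats.no_barcode - stats2.trimmed,
        unassigned_color=stats.unassigned_color + stats2.unassigned_color,
        assigned=stats.assigned + stats2.assigned,
    )
    merged.validate()
    return calls + calls2, merged


def calls_frame(calls: Sequence[BarcodeCall]):
    import pandas as pd

    return pd.DataFrame(
        [(c.read_id, c.color, c.umi, c.tag_mismatches, c.trim_edits) for c in calls],
        columns=["read_id", "color", "umi", "tag_mismatches", "trim_edits"],
    )
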