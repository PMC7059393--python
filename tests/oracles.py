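"""Independent brute-force oracles used to validate the implementation.

Each oracle re-derives the expected result from first principles (exhaustive
enumeration, closed forms, or a third-party library), never calling the code
path under test.
"""

from __future__ import annotations

import numpy as np

from clonotrace.core import CloneLabel


def brute_force_trim(seq: str, left: str, right: str, k: int = 2):
    """Exhaustively enumerate ordered delimiter placements.

    Scores every (substring, substring) pair with Levenshtein distance
    (edlib), keeps placements with per-delimiter distance <= k, and minimises
    total distance with ties broken by smallest inner start then smallest
    inner end.  Substrings whose length differs from the delimiter by more
    than k are skipped (their distance necessarily exceeds k).
    Returns (total_edits, inner_start, inner_end) or None.
    """
    import edlib

    n = len(seq)

    def placements(pat):
        out = {}
        for a in range(n + 1):
            for b in range(a, n + 1):
                if abs((b - a) - len(pat)) > k:
                    continue
                d = edlib.align(pat, seq[a:b], mode="NW")["editDistance"]
                if d <= k:
                    key = (a, b)
                    out[key] = min(out.get(key, k + 1), d)
        return out

    best = None
    rights = placements(right)
    for (la, lb), ld in placements(left).items():
        for (ra, rb), rd in rights.items():
            if ra >= lb:
                cand = (ld + rd, lb, ra)
                if best is None or cand < best:
                    best = cand
    return best


def nearest_tag(inner: str, tags, max_mismatch: int):
    """Exhaustive nearest-tag-with-threshold color call."""
    tag_len = len(tags[0].sequence)
    if len(inner) < tag_len:
        return "UNASSIGNED", tag_len
    prefix = inner[:tag_len]
    dists = sorted(
        (sum(a != b for a, b in zip(prefix, t.sequence)), t.name) for t in tags
    )
    d, name = dists[0]
    return (name, d) if d <= max_mismatch else ("UNASSIGNED", d)


def collapse_all_pairs(counts: dict, max_hamming: int, count_ratio: float) -> dict:
    """Directional UMI collapse by explicit ordered-pair testing.

    Parents are visited from most to least abundant (ties by label); every
    other clone of the same color within the Hamming radius and below the
    count-ratio bound is absorbed; absorbed clones are inert afterwards.
    """
    def ham(a, b):
        return sum(x != y for x, y in zip(a, b))

    order = sorted(counts, key=lambda c: (-counts[c], c))
    parent_of = {}
    for p in order:
        if p in parent_of:
            continue
        for c in order:
            if c == p or c in parent_of or c.color != p.color:
                continue
            if counts[c] <= count_ratio * counts[p] and \
                    ham(c.umi, p.umi) <= max_hamming:
                parent_of[c] = p
    out = {}
    for c, n in counts.items():
        t = parent_of.get(c, c)
        out[t] = out.get(t, 0) + n
    return out


def top_k_sort_and_sum(counts: dict, k: int) -> float:
    """Sort fractions descending and sum the first k."""
    total = sum(counts.values())
    fr = sorted((100.0 * v / total for v in counts.values()), reverse=True)
    return sum(fr[:k])


def grid_search_mle(doses, tested, positive, n_grid: int = 100_000,
                    f_max: float = 1.0):
    """Argmax of the single-hit log likelihood on a dense grid."""
    f = np.linspace(f_max / n_grid, f_max, n_grid)
    d = np.asarray(doses, float)
    t = np.asarray(tested, float)
    pos = np.asarray(positive, float)
    lam = np.outer(f, d)
    with np.errstate(divide="ignore"):
        ll = (-(t - pos) * lam + pos * np.log1p(-np.exp(-lam))).sum(axis=1)
    return float(f[np.argmax(ll)])


def truncated_poisson_p1(lam: float, k_max: int = 200) -> float:
    """P(k=1 | k>=1) by explicit Poisson pmf summation."""
    from scipy.stats import poisson

    ks = np.arange(1, k_max + 1)
    pmf = poisson.pmf(ks, lam)
    return float(pmf[0] / pmf.sum())


def mean_betas_per_read(reads_patterns: list[str]) -> np.ndarray:
    """Per-CpG mean methylation by averaging over individual reads."""
    mat = np.array([[int(c) for c in p] for p in reads_patterns], float)
    return mat.mean(axis=0)
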