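"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately re-derive quantities from first principles (exhaustive
enumeration, double loops) and stay independent of the package's vectorized
implementations.
"""

from itertools import combinations
from math import comb

import numpy as np


def scan_inframe_instances(coding_seq: str, codon: str) -> list[int]:
    """Codon indices of in-frame occurrences via a sliding-window scan."""
    return [
        i // 3
        for i in range(0, len(coding_seq) - 2, 3)
        if coding_seq[i : i + 3] == codon
    ]


def ks_d_statistic(x, y) -> float:
    """Two-sample K-S D via explicit ECDF evaluation."""
    x, y = np.sort(np.asarray(x, float)), np.sort(np.asarray(y, float))
    pts = np.concatenate([x, y])
    fx = np.searchsorted(x, pts, side="right") / len(x)
    fy = np.searchsorted(y, pts, side="right") / len(y)
    return float(np.max(np.abs(fx - fy)))


def ks_exact_p(x, y, eps: float = 1e-12) -> float:
    """Exact two-sample K-S p by enumeration over all label arrangements."""
    x, y = list(x), list(y)
    pooled = x + y
    n1 = len(x)
    d_obs = ks_d_statistic(x, y)
    idx = range(len(pooled))
    hits = total = 0
    for pick in combinations(idx, n1):
        xs = [pooled[i] for i in pick]
        ys = [pooled[i] for i in idx if i not in pick]
        total += 1
        if ks_d_statistic(xs, ys) >= d_obs - eps:
            hits += 1
    return hits / total


def hypergeom_upper_tail_enum(background: set, set_a: set, size_b: int, k_obs: int) -> float:
    """P(overlap >= k_obs) by enumerating all draws of size_b from background."""
    bg = sorted(background)
    hits = total = 0
    for draw in combinations(bg, size_b):
        total += 1
        if len(set(draw) & set_a) >= k_obs:
            hits += 1
    return hits / total


def metacodon_raw_bruteforce(codon, orfs, shifted_counts, edge_exclusion=7, width=21):
    """Double loop over instances x window positions.

    ``shifted_counts``: dict (orf_id, position) -> count in the 28-mer frame.
    """
    raw = [0] * width
    for orf_id, orf in orfs.items():
        seq = orf.coding_seq
        n = len(seq) // 3
        for ci in range(edge_exclusion, n - edge_exclusion):
            if seq[3 * ci : 3 * ci + 3] != codon:
                continue
            c = 3 * ci
            for i in range(width):
                raw[i] += shifted_counts.get((orf_id, c - 21 + i), 0)
    return raw


def footprint_length_oracle(read: str, ref: str):
    """All footprint lengths consistent with read = ref prefix + poly-A tail.

    A footprint of any positive length is a candidate (a read ending in an
    adenosine can always hide a shorter footprint whose tail begins on a
    genomic A).  Returns the unique consistent length, or None when several
    lengths are consistent (ambiguous), or raises ValueError when none is.
    """
    consistent = [
        t
        for t in range(1, len(read) + 1)
        if read[:t] == ref[:t] and all(ch == "A" for ch in read[t:])
    ]
    if not consistent:
        raise ValueError("no consistent footprint length")
    if len(consistent) > 1:
        return None
    return consistent[0]
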