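"""Independent reference implementations used only to check the package.

Each oracle is deliberately written the slow, obvious way (exhaustive
enumeration, O(n^3) clustering, closed forms) and shares no code with the
implementation under test.
"""

from __future__ import annotations

import itertools
import math
import re

import numpy as np

_IUPAC = {
    "A": {"A"},
    "C": {"C"},
    "G": {"G"},
    "T": {"T"},
    "R": {"A", "G"},
    "Y": {"C", "T"},
    "S": {"C", "G"},
    "W": {"A", "T"},
    "K": {"G", "T"},
    "M": {"A", "C"},
    "B": {"C", "G", "T"},
    "D": {"A", "G", "T"},
    "H": {"A", "C", "T"},
    "V": {"A", "C", "G"},
    "N": {"A", "C", "G", "T", "N"},
}


def _parse_spec(spec: str) -> list[list]:
    """Parse WORD(N{a,b}WORD)* variants into [word, (a,b), word, ...] lists."""
    variants = []
    for var in spec.split("|"):
        parts: list = []
        for token in re.findall(r"N\{\d+,\d+\}|[A-Z]+?(?=N\{|$)|[A-Z]+", var.strip()):
            m = re.fullmatch(r"N\{(\d+),(\d+)\}", token)
            if m:
                parts.append((int(m.group(1)), int(m.group(2))))
            else:
                parts.append(token.upper().replace("U", "T"))
        variants.append(parts)
    return variants


def _word_at(seq: str, pos: int, word: str) -> bool:
    if pos + len(word) > len(seq):
        return False
    return all(seq[pos + i] in _IUPAC[word[i]] for i in range(len(word)))


def brute_force_covered(seq: str, spec: str) -> set[int]:
    """Covered word positions by enumerating every (start, gap-vector)."""
    seq = seq.upper()
    covered: set[int] = set()
    for chain in _parse_spec(spec):
        words = [c for c in chain if isinstance(c, str)]
        gaps = [c for c in chain if isinstance(c, tuple)]

        def recurse(pos: int, k: int, spans: list[tuple[int, int]]) -> None:
            if k == len(words):
                for s, e in spans:
                    covered.update(range(s, e))
                return
            word = words[k]
            if k == 0:
                starts = [pos]
            else:
                lo, hi = gaps[k - 1]
                starts = range(pos + lo, pos + hi + 1)
            for s in starts:
                if _word_at(seq, s, word):
                    recurse(s + len(word), k + 1, spans + [(s, s + len(word))])

        for start in range(len(seq)):
            recurse(start, 0, [])
    return covered


def hypergeom_upper_tail_enumeration(
    n_a: int, n_b: int, k: int, universe: int
) -> float:
    """P(|A ∩ B| >= k) by enumerating every B of size n_b (A fixed)."""
    a_mask = (1 << n_a) - 1  # first n_a elements are in A
    hits = 0
    total = 0
    for combo in itertools.combinations(range(universe), n_b):
        b_mask = 0
        for el in combo:
            b_mask |= 1 << el
        total += 1
        if bin(a_mask & b_mask).count("1") >= k:
            hits += 1
    return hits / total if total else 1.0


def average_linkage_reference(points: np.ndarray) -> list[float]:
    """Merge heights of average-linkage clustering (Euclidean), O(n^3)."""
    n = len(points)
    clusters: list[list[int]] = [[i] for i in range(n)]
    dist = {
        (i, j): float(np.linalg.norm(points[i] - points[j]))
        for i in range(n)
        for j in range(i + 1, n)
    }

    def cluster_dist(a: list[int], b: list[int]) -> float:
        return sum(
            dist[(min(i, j), max(i, j))] for i in a for j in b
        ) / (len(a) * len(b))

    heights = []
    while len(clusters) > 1:
        best = None
        best_d = math.inf
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = cluster_dist(clusters[i], clusters[j])
                if d < best_d - 1e-12:
                    best_d = d
                    best = (i, j)
        i, j = best
        heights.append(best_d)
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return heights


def binomial_lrt_pvalue(counts_a, counts_b) -> float:
    """Pooled binomial likelihood-ratio test, chi-square(1) reference."""
    from scipy.stats import chi2

    def ll(k, n):
        k, n = float(k), float(n)
        if k == 0 or k == n:
            p = max(min(k / n, 1 - 1e-12), 1e-12)
        else:
            p = k / n
        return k * math.log(p) + (n - k) * math.log(1 - p)

    kA = sum(c[0] for c in counts_a)
    nA = kA + sum(c[1] for c in counts_a)
    kB = sum(c[0] for c in counts_b)
    nB = kB + sum(c[1] for c in counts_b)
    p_pool = min(max((kA + kB) / (nA + nB), 1e-12), 1 - 1e-12)
    ll0 = (kA + kB) * math.log(p_pool) + (nA + nB - kA - kB) * math.log(1 - p_pool)
    lr = 2 * (ll(kA, nA) + ll(kB, nB) - ll0)
    return float(chi2.sf(max(lr, 0.0), df=1))
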