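"""Independent brute-force reference implementations used as oracles.

Everything here is written in the most direct way possible (explicit
loops, textbook formulas) and stays independent of the library code it
checks.
"""

import itertools
import math

import numpy as np

COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def revcomp_str(s: str) -> str:
    return "".join(COMP[b] for b in reversed(s))


def scan_oracle(seq: str, matrix, threshold: float):
    """Exhaustive per-window scoring on both strands.

    Returns a set of (start, strand, round(score, 9)) tuples.  Windows
    containing non-ACGT characters are skipped.
    """
    L = len(matrix)
    col = {"A": 0, "C": 1, "G": 2, "T": 3}
    hits = set()
    for i in range(len(seq) - L + 1):
        win = seq[i : i + L]
        if any(b not in col for b in win):
            continue
        fwd = sum(matrix[j][col[b]] for j, b in enumerate(win))
        rev = sum(matrix[j][col[b]] for j, b in enumerate(revcomp_str(win)))
        if fwd >= threshold:
            hits.add((i, "+", round(fwd, 9)))
        if rev >= threshold:
            hits.add((i, "-", round(rev, 9)))
    return hits


def pearson_oracle(x, y) -> float:
    x, y = list(map(float, x)), list(map(float, y))
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


def cv_oracle(xs) -> float:
    xs = list(map(float, xs))
    n = len(xs)
    m = sum(xs) / n
    sd = math.sqrt(sum((x - m) ** 2 for x in xs) / n)
    return sd / m


def rms_oracle(u, U) -> float:
    d = np.asarray(u, float).ravel() - np.asarray(U, float).ravel()
    return math.sqrt(sum(v * v for v in d) / len(d))


def ks_oracle(a, b) -> float:
    a, b = sorted(a), sorted(b)
    pts = sorted(set(a) | set(b))
    best = 0.0
    for p in pts:
        fa = sum(1 for x in a if x <= p) / len(a)
        fb = sum(1 for x in b if x <= p) / len(b)
        best = max(best, abs(fa - fb))
    return best


def bin_energy_oracle(sites, length, width):
    """sites: (start, E) pairs on one locus; start-containment rule."""
    n_bins = (length + width - 1) // width
    out = [0.0] * n_bins
    for start, E in sites:
        out[start // width] += E
    for b in range(n_bins):
        out[b] /= min(width, length - b * width)
    return out


def overlap_events_oracle(intervals):
    """Number of unordered intersecting pairs among (start, end) tuples."""
    n = 0
    for (a1, b1), (a2, b2) in itertools.combinations(intervals, 2):
        if a1 < b2 and a2 < b1:
            n += 1
    return n


def optimal_assignment_oracle(old_sites, new_sites, vicinity_fn):
    """Minimum-total-displacement matching of old to new sites.

    Exact matches are fixed first (as the tracker does); the remaining
    old sites are matched, over all injective assignments to same-TF
    new sites overlapping their vicinity, minimising total |dstart|.
    Returns (persist_pairs, move_pairs, deaths, births) as sets.
    """
    exact = {}
    used_new = set()
    for i, s in enumerate(old_sites):
        for j, t in enumerate(new_sites):
            if j in used_new:
                continue
            if (s.tf, s.locus, s.start, s.length, s.strand) == (
                t.tf,
                t.locus,
                t.start,
                t.length,
                t.strand,
            ):
                exact[i] = j
                used_new.add(j)
                break
    free_old = [i for i in range(len(old_sites)) if i not in exact]
    free_new = [j for j in range(len(new_sites)) if j not in used_new]

    def candidates(i):
        s = old_sites[i]
        va, vb = vicinity_fn(s)
        out = []
        for j in free_new:
            t = new_sites[j]
            if t.tf == s.tf and t.locus == s.locus and t.start < vb and va < t.end:
                out.append(j)
        return out

    best = None
    cand = {i: candidates(i) for i in free_old}
    # enumerate all partial injective assignments
    def rec(idx, assign, cost):
        nonlocal best
        if idx == len(free_old):
            key = (-len(assign), cost)
            if best is None or key < best[0]:
                best = (key, dict(assign))
            return
        i = free_old[idx]
        rec(idx + 1, assign, cost)  # i dies
        for j in cand[i]:
            if j not in assign.values():
                assign[i] = j
                rec(idx + 1, assign, cost + abs(old_sites[i].start - new_sites[j].start))
                del assign[i]

    rec(0, {}, 0.0)
    moves = best[1]
    deaths = {i for i in free_old if i not in moves}
    births = {j for j in free_new if j not in moves.values()}
    return set(exact.items()), set(moves.items()), deaths, births
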