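"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's own algorithms: alignment scoring is
done by exhaustive enumeration, matchings by exhaustive search, contact
counts by double loops.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def enumerate_global_alignments(a: str, b: str):
    """Yield every global alignment (gapped_a, gapped_b) of two strings."""
    if not a and not b:
        yield "", ""
        return
    if a:
        for ga, gb in enumerate_global_alignments(a[1:], b):
            yield a[0] + ga, "-" + gb
    if b:
        for ga, gb in enumerate_global_alignments(a, b[1:]):
            yield "-" + ga, b[0] + gb
    if a and b:
        for ga, gb in enumerate_global_alignments(a[1:], b[1:]):
            yield a[0] + ga, b[0] + gb


def score_alignment(ga: str, gb: str, score, gap_open: float,
                    gap_extend: float) -> float:
    """Score a gapped alignment with affine gaps:
    a gap of length L costs gap_open + (L-1) * gap_extend."""
    total = 0.0
    in_gap_a = in_gap_b = False
    for x, y in zip(ga, gb):
        if x == "-":
            total -= gap_extend if in_gap_a else gap_open
            in_gap_a, in_gap_b = True, False
        elif y == "-":
            total -= gap_extend if in_gap_b else gap_open
            in_gap_b, in_gap_a = True, False
        else:
            total += score(x, y)
            in_gap_a = in_gap_b = False
    return total


def best_alignment_score(a: str, b: str, score, gap_open: float,
                         gap_extend: float) -> float:
    return max(
        score_alignment(ga, gb, score, gap_open, gap_extend)
        for ga, gb in enumerate_global_alignments(a, b))


def min_weight_sg_matching(points: list[np.ndarray], cutoff: float):
    """Exhaustive maximum-cardinality, minimum-total-distance matching of SG
    points under a distance cutoff.  Returns a set of index pairs."""
    n = len(points)
    edges = [
        (i, j, float(np.linalg.norm(points[i] - points[j])))
        for i in range(n) for j in range(i + 1, n)
        if np.linalg.norm(points[i] - points[j]) <= cutoff]
    best: tuple[int, float, frozenset] = (0, math.inf, frozenset())
    for r in range(len(edges), -1, -1):
        for combo in itertools.combinations(edges, r):
            used = [x for i, j, _ in combo for x in (i, j)]
            if len(set(used)) != len(used):
                continue
            total = sum(d for _, _, d in combo)
            cand = (len(combo), total)
            if (cand[0] > best[0]) or (cand[0] == best[0] and total < best[1]):
                best = (len(combo), total,
                        frozenset((i, j) for i, j, _ in combo))
    return best[2]


def brute_force_contacts(coords_a: np.ndarray, coords_b: np.ndarray,
                         cutoff: float) -> int:
    count = 0
    for pa in coords_a:
        for pb in coords_b:
            if math.dist(pa, pb) <= cutoff:
                count += 1
    return count


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform-ish proper rotation from QR decomposition."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q = q @ np.diag(np.sign(np.diag(r)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def expand_a3m_columns(rows: list[str]) -> list[str]:
    """Naive a3m -> aligned expansion: walk all rows column-by-column,
    flushing pending insertions greedily before each match column."""
    # split each row into (pre-insert, match, insert, match, ...) streams
    streams = []
    for row in rows:
        toks: list[tuple[str, str]] = []  # (kind, char)
        for c in row:
            if c == "-" or c.isupper() or c.isdigit():
                toks.append(("M", c))
            else:
                toks.append(("I", c.upper()))
        streams.append(toks)
    out = ["" for _ in rows]
    pos = [0 for _ in rows]
    while any(p < len(s) for p, s in zip(pos, streams)):
        # emit insertion columns while any stream has a pending insertion
        if any(p < len(s) and s[p][0] == "I" for p, s in zip(pos, streams)):
            for k, (p, s) in enumerate(zip(pos, streams)):
                if p < len(s) and s[p][0] == "I":
                    out[k] += s[p][1]
                    pos[k] += 1
                else:
                    out[k] += "-"
        else:
            for k, (p, s) in enumerate(zip(pos, streams)):
                out[k] += s[p][1]
                pos[k] += 1
    return out
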