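"""Independent reference implementations used only by the tests.

These deliberately avoid the package's own code paths: exact-rational Fisher
tails from first principles, literal subset enumeration for tiny universes,
and a brute-force edge filter for subnetwork projection.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction


def fisher_oracle(a: int, b: int, c: int, d: int, sidedness: str) -> Fraction:
    """Exact Fisher p as a rational, by scanning the overlap support."""
    N, K, n = a + b + c + d, a + b, a + c
    kmin, kmax = max(0, n + K - N), min(K, n)
    weights = {k: math.comb(K, k) * math.comb(N - K, n - k)
               for k in range(kmin, kmax + 1)}
    total = math.comb(N, n)
    if sidedness == "greater":
        num = sum(w for k, w in weights.items() if k >= a)
    elif sidedness == "less":
        num = sum(w for k, w in weights.items() if k <= a)
    elif sidedness == "two_sided":
        point = weights[a]
        num = sum(w for w in weights.values() if w <= point)
    else:
        raise ValueError(sidedness)
    return Fraction(num, total)


def fisher_subset_enumeration(a: int, b: int, c: int, d: int,
                              sidedness: str) -> Fraction:
    """Literal enumeration of every comparator draw (tiny N only).

    Counts, over all C(N, n) subsets of the universe, how many overlap the
    fixed set by at least / at most / "as improbably as" the observed count.
    """
    N, K, n = a + b + c + d, a + b, a + c
    universe = range(N)
    fixed = set(range(K))
    tally: dict[int, int] = {}
    for draw in itertools.combinations(universe, n):
        k = len(fixed.intersection(draw))
        tally[k] = tally.get(k, 0) + 1
    total = math.comb(N, n)
    if sidedness == "greater":
        num = sum(v for k, v in tally.items() if k >= a)
    elif sidedness == "less":
        num = sum(v for k, v in tally.items() if k <= a)
    elif sidedness == "two_sided":
        point = tally[a]
        num = sum(v for v in tally.values() if v <= point)
    else:
        raise ValueError(sidedness)
    return Fraction(num, total)


def all_tables(max_n: int):
    """Every 2x2 table (a,b,c,d) with 1 <= a+b+c+d <= max_n."""
    for N in range(1, max_n + 1):
        for a in range(N + 1):
            for b in range(N - a + 1):
                for c in range(N - a - b + 1):
                    yield a, b, c, N - a - b - c


def project_bruteforce(edges, expressed: set, fingerprint: set):
    """Reference subnetwork projection: filter the edge list directly."""
    keep = set(expressed) | set(fingerprint)
    kept_edges = {frozenset((u, v)) for u, v in edges
                  if u in keep or v in keep}
    nodes = {x for e in kept_edges for x in e}
    classes = {}
    for node in nodes:
        if node in fingerprint:
            classes[node] = "fingerprint"
        elif node in expressed:
            classes[node] = "expressed"
        else:
            classes[node] = "partner"
    return nodes, kept_edges, classes
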