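"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: adjacency is
rebuilt from raw triple tuples, alignment scores come from a separate
Gotoh dynamic program, and optimal alignments are enumerated outright
for very short strings.
"""

from __future__ import annotations

import itertools
import math


# --- neighborhood / coincident-set oracle ----------------------------------

GENE_ATTACHED = {
    "located_in_cellular_component",
    "performs",
    "involves_in_biological_process",
    "involves_in_metabolic_pathway",
    "encodes_enzyme_type",
}


def brute_coincident(
    triples: list[tuple[str, str, str, str, str]],
    g1: str,
    g2: str,
    excluded_categories: frozenset[str] = frozenset({"trait"}),
    include_protein_hop: bool = True,
) -> tuple[int, int, set[str]]:
    """C and D for a gene pair from raw (head, head_cat, rel, tail, tail_cat)
    tuples, by plain set arithmetic over an undirected adjacency dict."""
    category: dict[str, str] = {}
    adjacency: dict[str, set[str]] = {}
    for h, hc, _r, t, tc in triples:
        category[h] = hc
        category[t] = tc
        adjacency.setdefault(h, set()).add(t)
        adjacency.setdefault(t, set()).add(h)

    def hood(gene: str) -> set[str]:
        nbrs = set(adjacency.get(gene, set()))
        if include_protein_hop:
            proteins = {
                x
                for h, hc, r, t, tc in triples
                if r == "corresponding_to"
                for x, xc in ((h, hc), (t, tc))
                if gene in (h, t) and xc == "protein"
            }
            for p in proteins:
                nbrs |= adjacency.get(p, set())
        nbrs.discard(gene)
        return {x for x in nbrs if category[x] not in excluded_categories}

    k = hood(g1) & hood(g2)
    return len(k), len({category[x] for x in k}), k


# --- F1 sweep oracle --------------------------------------------------------


def brute_f1(scores: list[float], labels: list[bool], threshold: float) -> float:
    tp = sum(1 for s, l in zip(scores, labels) if s >= threshold and l)
    fp = sum(1 for s, l in zip(scores, labels) if s >= threshold and not l)
    fn = sum(1 for s, l in zip(scores, labels) if s < threshold and l)
    if tp == 0:
        return 0.0
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    return 2 * precision * recall / (precision + recall)


def brute_best_threshold(scores: list[float], labels: list[bool]) -> tuple[float, float]:
    """Exhaustive F1 evaluation at every distinct score; smallest winner."""
    best_t, best_f1 = None, -1.0
    for t in sorted(set(scores)):
        f1 = brute_f1(scores, labels, t)
        if f1 > best_f1:
            best_t, best_f1 = t, f1
    return best_t, best_f1


# --- alignment oracles ------------------------------------------------------


def gotoh_score(
    a: str,
    b: str,
    sub,
    gap_open: float,
    gap_extend: float,
) -> float:
    """Optimal global alignment score, affine gaps (a gap of length L costs
    gap_open + gap_extend * (L - 1)), end gaps penalized. ``sub(x, y)``
    returns the substitution score."""
    n, m = len(a), len(b)
    neg = -math.inf
    M = [[neg] * (m + 1) for _ in range(n + 1)]
    X = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in b (consumes a)
    Y = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in a (consumes b)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -(gap_open + gap_extend * (i - 1))
    for j in range(1, m + 1):
        Y[0][j] = -(gap_open + gap_extend * (j - 1))
    for i in range(n + 1):
        for j in range(m + 1):
            if i > 0 and j > 0:
                M[i][j] = sub(a[i - 1], b[j - 1]) + max(
                    M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]
                )
            if i > 0 and (j > 0 or i > 1):
                X[i][j] = max(
                    X[i][j],
                    M[i - 1][j] - gap_open,
                    X[i - 1][j] - gap_extend,
                    Y[i - 1][j] - gap_open,
                )
            if j > 0 and (i > 0 or j > 1):
                Y[i][j] = max(
                    Y[i][j],
                    M[i][j - 1] - gap_open,
                    X[i][j - 1] - gap_open,
                    Y[i][j - 1] - gap_extend,
                )
    return max(M[n][m], X[n][m], Y[n][m])


def enumerate_alignments(a: str, b: str):
    """Yield every global alignment as a list of (x, y) columns, where one
    of x, y may be '-'. Gap-gap columns are impossible by construction."""
    if not a and not b:
        yield []
        return
    if a:
        for rest in enumerate_alignments(a[1:], b):
            yield [(a[0], "-")] + rest
    if b:
        for rest in enumerate_alignments(a, b[1:]):
            yield [("-", b[0])] + rest
    if a and b:
        for rest in enumerate_alignments(a[1:], b[1:]):
            yield [(a[0], b[0])] + rest


def score_alignment(columns, sub, gap_open: float, gap_extend: float) -> float:
    score = 0.0
    prev_gap = None  # which side the previous column's gap was on
    for x, y in columns:
        if x == "-" or y == "-":
            side = "x" if x == "-" else "y"
            score -= gap_extend if prev_gap == side else gap_open
            prev_gap = side
        else:
            score += sub(x, y)
            prev_gap = None
    return score


def identity_of(columns) -> float:
    identical = sum(1 for x, y in columns if x == y and x != "-")
    return 100.0 * identical / len(columns)


def optimal_identities(a: str, b: str, sub, gap_open, gap_extend) -> set[float]:
    """Identities attained by *every* optimal-score alignment (tiny inputs)."""
    scored = [
        (score_alignment(c, sub, gap_open, gap_extend), identity_of(c))
        for c in enumerate_alignments(a, b)
    ]
    best = max(s for s, _ in scored)
    return {round(i, 9) for s, i in scored if abs(s - best) < 1e-9}, best


def dense_rank_oracle(scores: dict[str, float]) -> dict[str, int]:
    """Sort-and-scan dense ranking, highest score first."""
    distinct = sorted(set(scores.values()), reverse=True)
    position = {v: i + 1 for i, v in enumerate(distinct)}
    return {g: position[v] for g, v in scores.items()}
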