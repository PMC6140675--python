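"""Independent reference implementations used only to check the package.

These deliberately re-derive results through different code paths: the
local aligner is a plain-Python three-state DP with explicit predecessor
enumeration; the ORF oracle translates frames with Biopython's own
translator and parses stop-delimited segments as strings; the additive-tree
generator produces metrics that neighbor joining must recover exactly.
"""

from __future__ import annotations

import random

from Bio.Seq import Seq

NEG = float("-inf")


def sw_score_oracle(query, subject, score, gap_open, gap_extend):
    """Optimal local alignment score; a gap of length L costs open + L*ext.

    ``score`` is a callable (a, b) -> substitution score. Three-state DP:
    M ends in a substitution column, X ends in a gap consuming the query,
    Y ends in a gap consuming the subject; every transition that starts a
    gap (including switching gap sides) pays the opening penalty.
    """
    n, m = len(query), len(subject)
    open_cost = gap_open + gap_extend
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = score(query[i - 1], subject[j - 1])
            M[i][j] = s + max(
                0.0, M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]
            )
            X[i][j] = max(
                M[i - 1][j] - open_cost,
                X[i - 1][j] - gap_extend,
                Y[i - 1][j] - open_cost,
            )
            Y[i][j] = max(
                M[i][j - 1] - open_cost,
                Y[i][j - 1] - gap_extend,
                X[i][j - 1] - open_cost,
            )
            best = max(best, M[i][j])
    return best


def orf_oracle(seq, min_len=5):
    """All ORFs on both strands as (start, end, strand, frame, peptide, class).

    Coordinates are 0-based half-open on the reported strand. Input must be
    unambiguous A/C/G/T.
    """
    out = []
    for strand in "+-":
        oriented = seq if strand == "+" else str(Seq(seq).reverse_complement())
        for frame in range(3):
            n_codons = (len(oriented) - frame) // 3
            aa = str(
                Seq(oriented[frame : frame + 3 * n_codons]).translate()
            )
            segments = []  # (codon_start, codon_end_exclusive, has_stop)
            start = 0
            for k, ch in enumerate(aa):
                if ch == "*":
                    segments.append((start, k + 1, True))
                    start = k + 1
            if start < len(aa):
                segments.append((start, len(aa), False))
            for c0, c1, has_stop in segments:
                body = aa[c0 : c1 - 1] if has_stop else aa[c0:c1]
                m = body.find("M")
                if m >= 0:
                    pep = body[m:]
                    cls = "complete" if has_stop else "three_prime_partial"
                    lo = c0 + m
                else:
                    if has_stop and c0 != 0:
                        continue  # interior stop-to-stop stretch with no start
                    pep = body
                    cls = "five_prime_partial" if has_stop else "internal"
                    lo = c0
                if len(pep) >= min_len:
                    out.append(
                        (frame + 3 * lo, frame + 3 * c1, strand, frame, pep, cls)
                    )
    return sorted(out)


def random_additive_tree(n_leaves, seed):
    """A random binary tree metric: returns (labels, distance dict).

    Leaves are added one at a time by splitting a uniformly chosen existing
    edge; all branch lengths are positive integers, so the resulting metric
    is strictly additive and NJ must recover it exactly.
    """
    rnd = random.Random(seed)
    # adjacency with edge lengths; nodes 0..; leaves tracked separately
    edges = {}

    def add_edge(a, b, w):
        edges.setdefault(a, {})[b] = w
        edges.setdefault(b, {})[a] = w

    labels = [f"L{i}" for i in range(n_leaves)]
    add_edge("L0", "L1", rnd.randint(1, 10))
    internal = 0
    for leaf in labels[2:]:
        all_edges = [
            (a, b) for a in edges for b in edges[a] if str(a) < str(b)
        ]
        a, b = rnd.choice(all_edges)
        w = edges[a].pop(b)
        edges[b].pop(a)
        mid = f"I{internal}"
        internal += 1
        w1 = rnd.randint(1, max(1, w - 1)) if w > 1 else 1
        add_edge(a, mid, min(w1, w))
        add_edge(mid, b, max(w - w1, 1))
        add_edge(mid, leaf, rnd.randint(1, 10))
    # all-pairs shortest paths between leaves (tree: unique path)
    dist = {}
    for src in labels:
        seen = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, w in edges[u].items():
                if v not in seen:
                    seen[v] = seen[u] + w
                    stack.append(v)
        for dst in labels:
            dist[(src, dst)] = float(seen[dst])
    return labels, dist
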