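"""COI-barcode distances, threshold species delimitation, and NJ trees.

Distances are uncorrected p-distances — the proportion of differing sites
among sites where both sequences carry an unambiguous nucleotide (pairwise
deletion of gaps and N; complete deletion of any column containing a gap or
N is available as an option). This matches the barcoding convention of
quoting raw percent divergence, where ~3% in COI is the usual crustacean
species boundary.

Species delimitation is single-linkage clustering at a distance cutoff:
taxa joined by any chain of pairs at or below the cutoff form one putative
species. The neighbor-joining tree is an auxiliary desk-scale visualisation
of the distance structure — it is a distance method, not a substitute for
maximum-likelihood phylogenetics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from Bio import SeqIO

_UNAMBIG = set("ACGT")


@dataclass
class CoiAlignment:
    taxa: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise ValueError("one row per taxon required")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("taxa must be unique")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("alignment rows must have equal length")

    @classmethod
    def read(cls, path) -> "CoiAlignment":
        taxa, rows = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            taxa.append(rec.id)
            rows.append(str(rec.seq).upper())
        return cls(taxa=taxa, rows=rows)


@dataclass
class DistanceMatrix:
    taxa: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        if self.d.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("matrix shape must match taxa")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(self.d < 0) or np.any(self.d > 1):
            raise ValueError("p-distances must lie in [0, 1]")

    def get(self, a: str, b: str) -> float:
        return float(self.d[self.taxa.index(a), self.taxa.index(b)])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.d, index=self.taxa, columns=self.taxa)


def p_distance(a: str, b: str) -> float:
    """Mismatches / comparable sites, gaps and ambiguities pairwise-deleted.

    A site is comparable iff both characters are one of A, C, G, T. Raises
    ``ValueError`` when no site is comparable (the distance is undefined).
    """
    if len(a) != len(b):
        raise ValueError("aligned rows must have equal length")
    comparable = 0
    mismatch = 0
    for x, y in zip(a.upper(), b.upper()):
        if x in _UNAMBIG and y in _UNAMBIG:
            comparable += 1
            if x != y:
                mismatch += 1
    if comparable == 0:
        raise ValueError("no comparable sites; p-distance undefined")
    return mismatch / comparable


def distance_matrix(
    aln: CoiAlignment, complete_deletion: bool = False
) -> DistanceMatrix:
    """All pairwise p-distances.

    With ``complete_deletion`` every column containing any gap or ambiguity
    in any row is removed before computing distances.
    """
    rows = aln.rows
    if len(rows) < 2:
        raise ValueError("need at least two sequences")
    if complete_deletion:
        keep = [
            j
            for j in range(len(rows[0]))
            if all(r[j] in _UNAMBIG for r in rows)
        ]
        rows = ["".join(r[j] for j in keep) for r in rows]
    n = len(rows)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = p_distance(rows[i], rows[j])
    return DistanceMatrix(taxa=list(aln.taxa), d=d)


def group_range(
    m: DistanceMatrix, group_a: list[str], group_b: list[str]
) -> tuple[float, float]:
    """(min, max) p-distance over all cross-group pairs."""
    if not group_a or not group_b:
        raise ValueError("groups must be non-empty")
    if set(group_a) & set(group_b):
        raise ValueError("groups must be disjoint")
    ia = [m.taxa.index(t) for t in group_a]
    ib = [m.taxa.index(t) for t in group_b]
    vals = m.d[np.ix_(ia, ib)]
    return float(vals.min()), float(vals.max())


def threshold_clusters(
    m: DistanceMatrix, cutoff: float = 0.03
) -> list[list[str]]:
    """Single-linkage species clusters at a p-distance cutoff.

    Connected components of the graph joining pairs with d <= cutoff;
    clusters are sorted by their smallest member label, members sorted
    within each cluster.
    """
    if not 0 < cutoff < 1:
        raise ValueError("cutoff must lie in (0, 1)")
    adj = csr_matrix((m.d <= cutoff).astype(int))
    n_comp, labels = connected_components(adj, directed=False)
    clusters: dict[int, list[str]] = {}
    for taxon, lab in zip(m.taxa, labels):
        clusters.setdefault(int(lab), []).append(taxon)
    out = [sorted(members) for members in clusters.values()]
    out.sort(key=lambda c: c[0])
    return out


def flag_misidentified(
    m: DistanceMatrix,
    species_of: dict[str, str],
    cutoff: float = 0.03,
) -> list[tuple[str, str, str]]:
    """Flag sequences whose nearest cluster carries a different label.

    For each taxon, clusters are formed at ``cutoff`` (the taxon itself is
    excluded from its own cluster membership when averaging); the nearest
    cluster by mean distance is found, and if the majority species label of
    that cluster differs from the taxon's own label, the taxon is reported
    as (taxon, own_label, majority_label_of_nearest_cluster).
    """
    clusters = threshold_clusters(m, cutoff)
    flags = []
    for taxon in m.taxa:
        own = species_of.get(taxon)
        if own is None:
            continue
        best_mean, best_members = None, None
        for members in clusters:
            others = [t for t in members if t != taxon]
            if not others:
                continue
            mean = float(
                np.mean([m.get(taxon, t) for t in others])
            )
            if best_mean is None or mean < best_mean:
                best_mean, best_members = mean, others
        if best_members is None:
            continue
        labels = [species_of.get(t) for t in best_members]
        labels = [l for l in labels if l is not None]
        if not labels:
            continue
        top_count = max(labels.count(l) for l in set(labels))
        top = sorted(l for l in set(labels) if labels.count(l) == top_count)
        # flag only when a different label strictly outvotes the taxon's own
        if own not in top:
            flags.append((taxon, own, top[0]))
    return flags


def nj_tree(m: DistanceMatrix) -> str:
    """Neighbor-joining tree as an unrooted Newick string.

    Standard agglomeration: at each step the pair (i, j) minimising
    Q(i, j) = (r - 2) d(i, j) - R_i - R_j is joined (R_i is the row sum,
    r the number of active nodes); branch lengths follow the usual
    half-difference formula and negative lengths are clamped to zero. Ties
    in Q break on the lexicographically smallest (sorted) pair of cluster
    representatives, making the output deterministic. NJ reconstructs any
    additive (tree-like) metric exactly.
    """
    n = len(m.taxa)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    d = {i: {j: float(m.d[i, j]) for j in range(n) if j != i} for i in range(n)}
    newick = {i: m.taxa[i] for i in range(n)}
    rep = {i: m.taxa[i] for i in range(n)}  # smallest leaf label per cluster
    active = list(range(n))
    next_id = n
    while len(active) > 2:
        r = len(active)
        rowsum = {i: sum(d[i][j] for j in active if j != i) for i in active}
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                q = (r - 2) * d[i][j] - rowsum[i] - rowsum[j]
                pair_key = tuple(sorted((rep[i], rep[j])))
                if best is None or (q, pair_key) < (best[0], best[1]):
                    best = (q, pair_key, i, j)
        _, _, i, j = best
        dij = d[i][j]
        li = 0.5 * dij + (rowsum[i] - rowsum[j]) / (2 * (r - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        u = next_id
        next_id += 1
        d[u] = {}
        for k in active:
            if k in (i, j):
                continue
            duk = 0.5 * (d[i][k] + d[j][k] - dij)
            d[u][k] = d[k][u] = max(duk, 0.0)
        newick[u] = f"({newick[i]}:{li:.12g},{newick[j]}:{lj:.12g})"
        rep[u] = min(rep[i], rep[j])
        active = [k for k in active if k not in (i, j)]
        active.append(u)
    i, j = active
    lij = max(d[i][j], 0.0)
    # unrooted output: attach the last two clusters at a single node
    return f"({newick[i]}:{lij / 2:.12g},{newick[j]}:{lij / 2:.12g});"
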