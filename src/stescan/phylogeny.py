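"""Distance phylogenetics for the cohort overview tree.

Keeps to the simple, classical toolkit appropriate for a taxonomic
overview rather than a rigorous species tree: p-distances (proportion of
differing sites) with pairwise deletion of gap/ambiguous sites, classical
neighbor-joining (Saitou-Nei Q-criterion), and nonparametric bootstrap
over alignment columns for edge support.

Determinism: NJ tie-breaks on the lexicographically smallest leaf label
carried by each cluster, so the same matrix always yields the same tree.
Negative NJ branch lengths are clamped to zero with the deficit moved to
the sibling edge (the sum across the joined pair is preserved).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from Bio import Phylo, SeqIO
from Bio.Phylo.BaseTree import Clade, Tree

from ._seq import encode


def _normalize_alignment(alignment) -> list[tuple[str, str]]:
    """Accept [(name, seq)], {name: seq} or SeqRecords; check equal lengths."""
    if hasattr(alignment, "items"):
        pairs = [(str(k), str(v)) for k, v in alignment.items()]
    else:
        pairs = []
        for item in alignment:
            if hasattr(item, "seq"):
                pairs.append((str(item.id), str(item.seq)))
            else:
                name, seq = item
                pairs.append((str(name), str(seq)))
    if len(pairs) < 2:
        raise ValueError("need at least 2 sequences")
    lengths = {len(s) for _, s in pairs}
    if len(lengths) != 1:
        raise ValueError(f"sequences are not aligned: lengths {sorted(lengths)}")
    return pairs


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray            # symmetric, zero diagonal, entries in [0, 1]
    comparable: np.ndarray        # per-pair count of sites surviving deletion

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match labels")


def p_distance_matrix(alignment) -> DistanceMatrix:
    """Pairwise p-distances with pairwise deletion.

    For each pair, alignment columns where either sequence carries a gap
    or ambiguous base are excluded; the distance is differing sites over
    comparable sites. A pair with zero comparable sites is an error.
    """
    pairs = _normalize_alignment(alignment)
    labels = [name for name, _ in pairs]
    codes = np.stack([encode(seq) for _, seq in pairs])
    valid = codes < 4
    n = len(labels)
    dist = np.zeros((n, n))
    comp = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            c = int(both.sum())
            if c == 0:
                raise ValueError(
                    f"no comparable sites between {labels[i]!r} and {labels[j]!r}"
                )
            d = float(((codes[i] != codes[j]) & both).sum() / c)
            dist[i, j] = dist[j, i] = d
            comp[i, j] = comp[j, i] = c
    return DistanceMatrix(labels, dist, comp)


def neighbor_joining(dm: DistanceMatrix) -> Tree:
    """Classical neighbor-joining; returns an unrooted (trifurcating) tree."""
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    D = dm.matrix.astype(float).copy()
    clades = [Clade(name=label) for label in dm.labels]
    reps = list(dm.labels)  # lexicographic tie-break keys
    active = list(range(n))

    def join(i: int, j: int, li: float, lj: float) -> int:
        ci, cj = clades[i], clades[j]
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        ci.branch_length = max(li, 0.0)
        cj.branch_length = max(lj, 0.0)
        parent = Clade(clades=[ci, cj])
        clades.append(parent)
        reps.append(min(reps[i], reps[j]))
        return len(clades) - 1

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        best = None
        for a in range(m):
            for b in range(a + 1, m):
                if q[a, b] <= qmin + 1e-12:
                    key = tuple(sorted((reps[active[a]], reps[active[b]])))
                    if best is None or key < best[0]:
                        best = (key, a, b)
        _, a, b = best
        i, j = active[a], active[b]
        d_ij = D[i, j]
        li = d_ij / 2 + (r[a] - r[b]) / (2 * (m - 2))
        lj = d_ij - li
        u = join(i, j, li, lj)
        # grow D for the new node
        newrow = np.zeros(len(clades))
        for c in active:
            if c in (i, j):
                continue
            newrow[c] = max(0.0, (D[i, c] + D[j, c] - d_ij) / 2)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[u, : u] = newrow[: u]
        D[: u, u] = newrow[: u]
        active = [c for c in active if c not in (i, j)] + [u]

    i, j, k = sorted(active, key=lambda c: reps[c])
    la = (D[i, j] + D[i, k] - D[j, k]) / 2
    lb = (D[i, j] + D[j, k] - D[i, k]) / 2
    lc = (D[i, k] + D[j, k] - D[i, j]) / 2
    for idx, length in ((i, la), (j, lb), (k, lc)):
        clades[idx].branch_length = max(0.0, length)
    root = Clade(clades=[clades[i], clades[j], clades[k]])
    return Tree(root=root, rooted=False)


def bipartitions(tree: Tree) -> set[frozenset[str]]:
    """Non-trivial bipartitions of an unrooted tree, canonicalized.

    Each internal edge splits the leaves in two; the side NOT containing
    the lexicographically first leaf is used as the canonical key.
    """
    leaves = sorted(t.name for t in tree.get_terminals())
    ref = leaves[0]
    all_leaves = set(leaves)
    splits: set[frozenset[str]] = set()
    for clade in tree.get_nonterminals():
        if clade is tree.root:
            continue
        side = {t.name for t in clade.get_terminals()}
        if len(side) < 2 or len(all_leaves - side) < 2:
            continue
        if ref in side:
            side = all_leaves - side
        splits.add(frozenset(side))
    return splits


def bootstrap_support(alignment, n_boot: int = 1000, seed: int = 0) -> Tree:
    """NJ tree with bootstrap support on internal edges.

    Columns are resampled with replacement ``n_boot`` times; support for
    each original bipartition is the percentage of replicate trees that
    contain it, written to ``clade.confidence``. ``n_boot=0`` returns the
    plain tree with no support annotations.
    """
    pairs = _normalize_alignment(alignment)
    tree = neighbor_joining(p_distance_matrix(pairs))
    if n_boot == 0:
        return tree
    length = len(pairs[0][1])
    names = [name for name, _ in pairs]
    chars = np.stack([np.frombuffer(s.encode(), dtype=np.uint8) for _, s in pairs])
    rng = np.random.default_rng(seed)
    counts: dict[frozenset[str], int] = {split: 0 for split in bipartitions(tree)}
    for _ in range(n_boot):
        cols = rng.integers(0, length, size=length)
        resampled = [
            (name, chars[i, cols].tobytes().decode()) for i, name in enumerate(names)
        ]
        rep_splits = bipartitions(neighbor_joining(p_distance_matrix(resampled)))
        for split in counts:
            if split in rep_splits:
                counts[split] += 1
    all_leaves = {t.name for t in tree.get_terminals()}
    ref = min(all_leaves)
    for clade in tree.get_nonterminals():
        if clade is tree.root:
            continue
        side = {t.name for t in clade.get_terminals()}
        if len(side) < 2 or len(all_leaves - side) < 2:
            continue
        key = frozenset(all_leaves - side if ref in side else side)
        clade.confidence = round(100 * counts[key] / n_boot)
    return tree


def write_newick(tree: Tree, path) -> None:
    """Write a tree as Newick with supports as internal-node labels."""
    Phylo.write(tree, str(path), "newick")


def read_alignment_fasta(path) -> list[tuple[str, str]]:
    """Read an aligned FASTA into (name, sequence) pairs."""
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def extract_gene(genome, gene_name: str) -> str | None:
    """Pull a named gene's sequence from an annotated genome, if present."""
    from .genome_io import extract_region

    for feat in genome.features:
        if feat.name.lower() == gene_name.lower():
            return extract_region(genome, feat.interval, feat.strand)
    return None
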