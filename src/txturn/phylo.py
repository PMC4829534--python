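"""Transcriptome-sharing phylogenies.

Taxa that share more transcribed windows are "closer": a phi (binary
Pearson) correlation matrix over the presence/absence columns is turned
into a Manhattan distance matrix over correlation profiles, and a
neighbor-joining tree summarizes the proximity structure.  Bootstrap
support comes from resampling windows with replacement and rerunning the
whole correlation -> distance -> NJ pipeline.  Terminal branch lengths can
be partitioned into a sampling-robust component (shared across independent
read subsets) and a sampling-variance component (discordant between them).

Trees are scikit-bio ``TreeNode`` objects, unrooted (degree-3 root),
branch lengths >= 0, bootstrap supports stored as internal node names.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import spearmanr
from skbio import TreeNode

from .presence import PresenceMatrix
from .windows import CountMatrix


@dataclass
class CorrelationMatrix:
    """Taxa x taxa correlations with a per-entry degeneracy flag.

    ``flagged[i, j]`` marks entries where phi was undefined (a zero-variance
    column) and the conventional value 0 was recorded instead.
    """

    values: pd.DataFrame
    method: str
    flagged: pd.DataFrame | None = None
    zero_variance_taxa: tuple = ()


def correlation_matrix(presence_or_counts, method: str = "phi") -> CorrelationMatrix:
    """Pairwise taxon correlation of window coverage.

    method="phi": Pearson correlation of the two binary presence columns,
    computed from the 2x2 contingency table
    phi = (n11*n00 - n10*n01) / sqrt(n1. * n0. * n.1 * n.0).
    A column that is all-0 or all-1 has no variance; phi involving it is
    undefined and recorded as 0 with a warning and a flag.

    method="spearman": rank correlation on raw per-taxon counts
    (pass a CountMatrix or a windows x taxa count DataFrame).
    """
    if method not in ("phi", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    if method == "spearman":
        if isinstance(presence_or_counts, CountMatrix):
            mat = presence_or_counts.aggregate_taxa()
        elif isinstance(presence_or_counts, PresenceMatrix):
            mat = presence_or_counts.values
        else:
            mat = presence_or_counts
        if mat.shape[1] < 2 or mat.shape[0] < 2:
            raise ValueError("need >= 2 taxa and >= 2 windows")
        rho = spearmanr(mat.to_numpy()).statistic
        if np.ndim(rho) == 0:  # scipy collapses the 2-column case to a scalar
            rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
        vals = pd.DataFrame(rho, index=mat.columns, columns=mat.columns)
        np.fill_diagonal(vals.values, 1.0)
        return CorrelationMatrix(values=vals, method="spearman")

    if isinstance(presence_or_counts, PresenceMatrix):
        X = presence_or_counts.values
    else:
        X = presence_or_counts
    if X.shape[1] < 2 or X.shape[0] < 2:
        raise ValueError("need >= 2 taxa and >= 2 windows")
    taxa = list(X.columns)
    B = X.to_numpy(dtype=np.float64)
    n = B.shape[0]
    ones = B.sum(axis=0)            # n.1 per taxon
    zeros = n - ones                # n.0 per taxon
    n11 = B.T @ B
    n10 = ones[:, None] - n11       # focal 1, other 0
    n01 = ones[None, :] - n11
    n00 = n - n11 - n10 - n01
    denom = np.sqrt(
        np.outer(ones, np.ones_like(ones)) * np.outer(zeros, np.ones_like(zeros))
        * np.outer(np.ones_like(ones), ones) * np.outer(np.ones_like(zeros), zeros)
    )
    degenerate = (ones == 0) | (ones == n)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = (n11 * n00 - n10 * n01) / denom
    flagged = np.zeros_like(phi, dtype=bool)
    if degenerate.any():
        bad = [t for t, d in zip(taxa, degenerate) if d]
        warnings.warn(
            f"phi undefined for zero-variance taxa {bad}; recording 0",
            RuntimeWarning, stacklevel=2,
        )
        flagged[degenerate, :] = True
        flagged[:, degenerate] = True
        phi[flagged] = 0.0
    np.fill_diagonal(phi, 1.0)
    np.fill_diagonal(flagged, False)
    vals = pd.DataFrame(phi, index=taxa, columns=taxa)
    return CorrelationMatrix(
        values=vals, method="phi",
        flagged=pd.DataFrame(flagged, index=taxa, columns=taxa),
        zero_variance_taxa=tuple(t for t, d in zip(taxa, degenerate) if d),
    )


def manhattan_distances(corr: CorrelationMatrix) -> pd.DataFrame:
    """Manhattan (city-block) distance between correlation profiles:
    d(i,j) = sum_k |corr(i,k) - corr(j,k)|.

    Columns k whose entries are flagged degenerate for both i and j are
    excluded from that pair's sum; this keeps degenerate simulations from
    injecting arbitrary zeros into every distance.
    """
    V = corr.values.to_numpy(dtype=np.float64)
    taxa = list(corr.values.columns)
    if corr.flagged is not None and corr.flagged.to_numpy().any():
        F = corr.flagged.to_numpy()
        m = len(taxa)
        D = np.zeros((m, m))
        for i in range(m):
            for j in range(i + 1, m):
                use = ~(F[i] & F[j])
                D[i, j] = D[j, i] = np.abs(V[i, use] - V[j, use]).sum()
    else:
        D = cdist(V, V, metric="cityblock")
    np.fill_diagonal(D, 0.0)
    return pd.DataFrame(D, index=taxa, columns=taxa)


def neighbor_joining(dist: pd.DataFrame) -> TreeNode:
    """Saitou-Nei neighbor joining with the Studier-Keppler Q-criterion.

    Deterministic: among equal-minimal Q values the lexicographically
    smallest (label_i, label_j) pair is joined.  Negative branch lengths
    are clamped to 0 and listed in the returned tree's ``clamped``
    attribute.  The result is unrooted, represented with a degree-3 root.

    Exact on additive distance matrices: returns the generating topology
    and branch lengths.
    """
    labels = list(dist.columns)
    D = dist.to_numpy(dtype=np.float64).copy()
    if len(labels) < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    if np.isnan(D).any():
        raise ValueError("distance matrix contains NaN")
    nodes = [TreeNode(name=t) for t in labels]
    # sort keys: leaf label for leaves, smallest contained leaf label for
    # internal nodes -- gives a stable lexicographic tie-break
    keys = list(labels)
    clamped: list = []

    def _set_len(node: TreeNode, length: float, other: str) -> None:
        if length < -1e-12:
            clamped.append((node_key(node), other, float(length)))
            length = 0.0
        node.length = max(0.0, float(length))

    def node_key(node: TreeNode) -> str:
        return keys[nodes.index(node)]

    while len(nodes) > 3:
        r = len(nodes)
        R = D.sum(axis=1)
        Q = (r - 2) * D - R[:, None] - R[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        best = None
        for i in range(r):
            for j in range(i + 1, r):
                if Q[i, j] <= qmin + 1e-12 * max(1.0, abs(qmin)):
                    pair = tuple(sorted((keys[i], keys[j])))
                    if best is None or pair < best[0]:
                        best = (pair, i, j)
        _, i, j = best
        li = 0.5 * D[i, j] + (R[i] - R[j]) / (2.0 * (r - 2))
        lj = D[i, j] - li
        u = TreeNode()
        _set_len(nodes[i], li, keys[j])
        _set_len(nodes[j], lj, keys[i])
        u.extend([nodes[i], nodes[j]])
        dnew = 0.5 * (D[i] + D[j] - D[i, j])
        keep = [k for k in range(r) if k not in (i, j)]
        D = np.vstack([D[np.ix_(keep, keep)], dnew[keep][None, :]])
        D = np.hstack([D, np.append(dnew[keep], 0.0)[:, None]])
        new_key = min(keys[i], keys[j])
        nodes = [nodes[k] for k in keep] + [u]
        keys = [keys[k] for k in keep] + [new_key]

    # final three-way join: three-point formulas
    (a, b, c) = range(3)
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    root = TreeNode()
    for node, length, others in (
        (nodes[a], la, (keys[b], keys[c])),
        (nodes[b], lb, (keys[a], keys[c])),
        (nodes[c], lc, (keys[a], keys[b])),
    ):
        _set_len(node, length, "|".join(others))
        root.append(node)
    root.clamped = clamped
    return root


def bipartitions(tree: TreeNode) -> set:
    """Non-trivial bipartitions of the leaf set, one frozenset per internal
    edge, canonicalized to the side not containing the lexicographically
    smallest leaf."""
    leaves = frozenset(t.name for t in tree.tips())
    ref = min(leaves)
    out = set()
    for node in tree.non_tips(include_self=False):
        clade = frozenset(t.name for t in node.tips())
        side = clade if ref not in clade else leaves - clade
        if 2 <= len(side) <= len(leaves) - 2:
            out.add(side)
    return out


def robinson_foulds(t1: TreeNode, t2: TreeNode) -> int:
    """Unweighted Robinson-Foulds distance (symmetric difference of
    bipartition sets)."""
    b1, b2 = bipartitions(t1), bipartitions(t2)
    return len(b1 ^ b2)


def build_sharing_tree(presence: PresenceMatrix, method: str = "phi") -> TreeNode:
    """Full pipeline: correlation -> Manhattan distances -> NJ."""
    corr = correlation_matrix(presence, method=method)
    dist = manhattan_distances(corr)
    return neighbor_joining(dist)


def bootstrap_supports(presence: PresenceMatrix, n_boot: int = 1000,
                       seed: int = 0, method: str = "phi",
                       min_support: float = 70.0):
    """Attach bootstrap supports to the point-estimate sharing tree.

    Windows are resampled with replacement ``n_boot`` times; the complete
    correlation -> distance -> NJ pipeline is rerun on each replicate.
    Support of an internal node is the percentage of replicates whose tree
    contains the same bipartition.  Supports annotate the point tree's
    internal node names; nodes below ``min_support`` are listed in the
    returned report (the conventional reporting cut-off is 70%).

    Returns (tree, report) where report has columns bipartition, support,
    below_cutoff.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    point = build_sharing_tree(presence, method=method)
    target = {}
    for node in point.non_tips(include_self=False):
        leaves = frozenset(t.name for t in point.tips())
        clade = frozenset(t.name for t in node.tips())
        side = clade if min(leaves) not in clade else leaves - clade
        if 2 <= len(side) <= len(leaves) - 2:
            target[node] = side
    hits = {node: 0 for node in target}
    n = presence.n_windows
    vals = presence.values
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for _ in range(n_boot):
            idx = rng.integers(0, n, size=n)
            resampled = PresenceMatrix(
                values=vals.iloc[idx].reset_index(drop=True),
                tau=presence.tau, mask_provenance=presence.mask_provenance,
            )
            bp = bipartitions(build_sharing_tree(resampled, method=method))
            for node, side in target.items():
                if side in bp:
                    hits[node] += 1
    rows = []
    for node, side in target.items():
        support = 100.0 * hits[node] / n_boot
        node.name = f"{support:g}"
        rows.append({"bipartition": "|".join(sorted(side)),
                     "support": support,
                     "below_cutoff": support < min_support})
    report = pd.DataFrame(rows, columns=["bipartition", "support", "below_cutoff"])
    return point, report


@dataclass
class VariancePartition:
    """Sampling-robust vs sampling-variable split of terminal branches.

    For each taxon, the robust component is the minimum terminal branch
    length across replicate trees (the portion every independent read
    subset agrees on); the variable component is the mean minus that
    minimum.  The overall sampling-variance percentage is
    100 * sum(variable) / sum(mean) over terminal branches.
    """

    per_taxon: pd.DataFrame  # mean, robust, variable
    percent_variable: float
    replicate_trees: list = field(default_factory=list)


def terminal_branch_lengths(tree: TreeNode) -> pd.Series:
    return pd.Series({t.name: float(t.length or 0.0) for t in tree.tips()})


def partition_branch_variance(replicate_presences: list,
                              method: str = "phi") -> VariancePartition:
    """Partition terminal branch lengths into robust and sampling-variance
    components from independent replicate presence matrices."""
    if len(replicate_presences) < 2:
        raise ValueError("need >= 2 replicate sets")
    taxa = set(map(tuple, (p.taxa for p in replicate_presences)))
    if len(taxa) != 1:
        raise ValueError("replicate sets have mismatched taxa")
    trees = [build_sharing_tree(p, method=method) for p in replicate_presences]
    lengths = pd.DataFrame([terminal_branch_lengths(t) for t in trees])
    mean = lengths.mean(axis=0)
    robust = lengths.min(axis=0)
    variable = mean - robust
    per_taxon = pd.DataFrame({"mean": mean, "robust": robust,
                              "variable": variable})
    total_mean = float(mean.sum())
    pct = 100.0 * float(variable.sum()) / total_mean if total_mean > 0 else 0.0
    return VariancePartition(per_taxon=per_taxon, percent_variable=pct,
                             replicate_trees=trees)


def split_replicates(fragments: pd.DataFrame, n_sets: int, set_size: int,
                     seed: int) -> list:
    """Disjoint random partition of fragments into ``n_sets`` subsets of
    ``set_size`` per sample, without replacement.

    Each fragment row is one (paired-end) sequencing unit, so mates never
    split across sets.  Returns a list of fragment DataFrames.
    """
    rng = np.random.default_rng(seed)
    sets: list = [[] for _ in range(n_sets)]
    for s, grp in fragments.groupby("sample_id", sort=False):
        total = len(grp)
        if n_sets * set_size > total:
            raise ValueError(
                f"sample {s!r}: {n_sets} sets of {set_size} exceed {total} fragments"
            )
        perm = rng.permutation(total)
        for k in range(n_sets):
            take = perm[k * set_size:(k + 1) * set_size]
            sets[k].append(grp.iloc[np.sort(take)])
    return [pd.concat(parts, ignore_index=True) for parts in sets]


def split_replicate_counts(counts: CountMatrix, n_sets: int, set_size: int,
                           seed: int) -> list:
    """As ``split_replicates`` but operating on a CountMatrix: each sample
    column is partitioned into ``n_sets`` disjoint multivariate-
    hypergeometric draws of ``set_size`` fragments."""
    rng = np.random.default_rng(seed)
    outs = [dict() for _ in range(n_sets)]
    for s in counts.counts.columns:
        col = counts.counts[s].to_numpy().copy()
        total = int(col.sum())
        if n_sets * set_size > total:
            raise ValueError(
                f"sample {s!r}: {n_sets} sets of {set_size} exceed {total} fragments"
            )
        remaining = col
        for k in range(n_sets):
            draw = rng.multivariate_hypergeometric(remaining, set_size)
            outs[k][s] = draw
            remaining = remaining - draw
    return [
        CountMatrix(counts=pd.DataFrame(o, index=counts.counts.index),
                    samples=counts.samples.copy())
        for o in outs
    ]
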