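"""Beta diversity: rarefaction, UniFrac, Bray-Curtis, PCoA, PERMANOVA.

Unweighted UniFrac between two samples is the fraction of observed
branch length unique to one of them: the presence/absence profiles are
propagated from the leaves up the tree, and the distance is

    d(i, j) = sum of lengths of edges leading to exactly one sample's
              taxa / sum of lengths of edges leading to either,

with presence meaning count > 0 (conventionally after rarefaction to a
common depth).  PERMANOVA compares between- versus within-group squared
distances through a pseudo-F ratio whose null distribution is obtained
by permuting sample labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.linalg import eigh
from skbio import DistanceMatrix, TreeNode

from .tables import TaxonTable, RelAbundanceTable, align_to_tree


def rarefy(table: TaxonTable, depth: int, seed: int = 0) -> TaxonTable:
    """Subsample each sample without replacement to exactly ``depth`` reads.

    Samples with fewer than ``depth`` reads are dropped with a warning;
    if none remain, an error is raised.  The per-taxon draw is exactly
    multivariate hypergeometric.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    sizes = table.library_sizes
    keep = sizes[sizes >= depth].index
    dropped = [s for s in table.sample_ids if s not in set(keep)]
    if not len(keep):
        raise ValueError(f"all samples have fewer than {depth} reads")
    if dropped:
        warnings.warn(f"dropping {len(dropped)} sample(s) below depth {depth}: {dropped}")
    sub = table.counts.loc[keep]
    out = np.empty_like(sub.to_numpy())
    for i, (_, row) in enumerate(sub.iterrows()):
        out[i] = rng.multivariate_hypergeometric(row.to_numpy(), depth)
    return TaxonTable(pd.DataFrame(out, index=sub.index, columns=sub.columns))


def _edge_incidence(tree: TreeNode, taxa: list[str]):
    """Boolean (edges x taxa) incidence of descendant leaves, plus lengths."""
    pos = {t: i for i, t in enumerate(taxa)}
    rows, lengths = [], []
    below: dict[int, np.ndarray] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            vec = np.zeros(len(taxa), dtype=bool)
            if node.name in pos:
                vec[pos[node.name]] = True
        else:
            vec = np.zeros(len(taxa), dtype=bool)
            for child in node.children:
                vec |= below[id(child)]
        below[id(node)] = vec
        if node.parent is not None:  # the root has no edge above it
            rows.append(vec)
            lengths.append(float(node.length or 0.0))
    return np.asarray(rows), np.asarray(lengths)


def unweighted_unifrac(tree: TreeNode, table: TaxonTable,
                       strict: bool = True) -> DistanceMatrix:
    """Pairwise unweighted UniFrac distances for all samples in the table."""
    table = align_to_tree(table, tree, strict=strict)
    incidence, lengths = _edge_incidence(tree, table.taxon_ids)
    presence = table.counts.to_numpy() > 0  # samples x taxa
    # edge "leads to" a sample iff any descendant leaf is present in it
    on_path = presence @ incidence.T > 0  # samples x edges
    weighted = on_path * lengths
    shared = weighted @ on_path.T  # sum of lengths of edges on both paths
    totals = weighted.sum(axis=1)
    union = totals[:, None] + totals[None, :] - shared
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - shared / union
    d[union == 0] = 0.0
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 1.0)
    return DistanceMatrix(d, ids=table.sample_ids)


def bray_curtis(rel: RelAbundanceTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity, 1 - sum of elementwise minima on the simplex."""
    d = squareform(pdist(rel.fractions.to_numpy(dtype=float), metric="braycurtis"))
    return DistanceMatrix(d, ids=rel.sample_ids)


@dataclass(frozen=True)
class OrdinationResult:
    """PCoA embedding: coordinates, all eigenvalues (descending), and the
    proportion of positive-eigenvalue variance explained by each retained
    axis.  Negative eigenvalues are reported, not corrected."""

    samples: pd.DataFrame
    eigvals: np.ndarray
    proportion_explained: np.ndarray


def pcoa(dm: DistanceMatrix) -> OrdinationResult:
    """Classical metric scaling via Gower centering of -0.5 * d^2."""
    d2 = np.asarray(dm.data, dtype=float) ** 2
    n = d2.shape[0]
    centerer = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * centerer @ d2 @ centerer
    vals, vecs = eigh((b + b.T) / 2.0)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    tol = max(np.abs(vals).max(), 1.0e-300) * 1e-10
    retained = vals > tol
    coords = vecs[:, retained] * np.sqrt(vals[retained])
    pos_sum = vals[vals > 0].sum()
    prop = vals[retained] / pos_sum if pos_sum > 0 else np.zeros(retained.sum())
    cols = [f"PC{i + 1}" for i in range(int(retained.sum()))]
    return OrdinationResult(
        samples=pd.DataFrame(coords, index=list(dm.ids), columns=cols),
        eigvals=vals,
        proportion_explained=prop,
    )


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_f: float
    p_value: float
    n_permutations: int
    seed: int

    def __post_init__(self):
        assert self.p_value >= 1.0 / (self.n_permutations + 1)


def _groups_as_series(groups, ids) -> pd.Series:
    if isinstance(groups, pd.DataFrame):
        groups = groups["group"]
    groups = pd.Series(groups)
    missing = [s for s in ids if s not in groups.index]
    if missing:
        raise ValueError(f"samples missing from metadata: {missing}")
    return groups.loc[list(ids)]


def permanova(dm: DistanceMatrix, groups, n_perm: int = 999,
              seed: int = 0) -> PermanovaResult:
    """Permutation MANOVA on a distance matrix.

    pseudo-F = ((SS_total - SS_within) / (k - 1)) / (SS_within / (N - k))
    with SS_total = (1/N) sum_{i<j} d_ij^2 and SS_within the analogous
    per-group average; the p-value counts permuted statistics >= the
    observed one under the +1 convention, so p is never reported as 0.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    labels = _groups_as_series(groups, dm.ids)
    counts = labels.value_counts()
    if len(counts) < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    if (counts < 2).any():
        small = list(counts[counts < 2].index)
        raise ValueError(f"every group needs >= 2 samples; too small: {small}")

    d2 = np.asarray(dm.data, dtype=float) ** 2
    n = d2.shape[0]
    k = len(counts)
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    codes = pd.Categorical(labels).codes.astype(np.int64)
    sizes = np.bincount(codes).astype(float)

    def ss_within(c):
        ss = 0.0
        for g in range(k):
            mask = (c == g).astype(float)
            ss += (mask @ d2 @ mask) / (2.0 * sizes[g])
        return ss

    def f_stat(c):
        ssw = ss_within(c)
        if ssw == 0:
            return np.inf
        return ((ss_total - ssw) / (k - 1)) / (ssw / (n - k))

    f_obs = f_stat(codes)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if f_stat(rng.permutation(codes)) >= f_obs:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return PermanovaResult(pseudo_f=float(f_obs), p_value=float(p),
                           n_permutations=n_perm, seed=seed)
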