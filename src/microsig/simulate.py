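"""Synthetic 16S-like data with known ground truth.

Every downstream stage of the pipeline is testable without a download:
this module generates random phylogenies, two-group differential count
tables that emulate a genotype contrast (log-normal base abundances,
multiplicative effects on planted signature taxa, multinomial
sampling), and post-transplant "sink" samples drawn from convex
mixtures of source communities plus an unknown source.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

from .tables import TaxonTable, RelAbundanceTable, validate_tree

DEFAULT_GROUPS = ("WT", "KD")


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the two-group community generator.

    Defaults are desk-scale: 60 taxa, 10 samples per group at depth
    5,000 reads with 5 signature taxa planted at fold change 4 on a
    log-normal (sigma 1.5) base community.
    """

    n_taxa: int = 60
    n_samples_per_group: int = 10
    depth: int = 5000
    n_signature_taxa: int = 5
    fold_change: float = 4.0
    base_lognormal_sigma: float = 1.5
    seed: int = 0
    group_labels: tuple[str, str] = DEFAULT_GROUPS

    def __post_init__(self):
        if self.n_taxa < 2:
            raise ValueError("n_taxa must be >= 2")
        if self.n_signature_taxa > self.n_taxa:
            raise ValueError("n_signature_taxa must be <= n_taxa")
        if self.depth < 100:
            raise ValueError("depth must be >= 100")
        if self.fold_change <= 0:
            raise ValueError("fold_change must be > 0")
        if self.base_lognormal_sigma <= 0:
            raise ValueError("base_lognormal_sigma must be > 0")
        if self.n_samples_per_group < 1:
            raise ValueError("n_samples_per_group must be >= 1")
        if len(self.group_labels) != 2 or len(set(self.group_labels)) != 2:
            raise ValueError("group_labels must be two distinct labels")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator planted, for recovery tests.

    ``signature_taxa``/``directions`` describe the differential taxa of
    a two-group table (empty when fold_change == 1); ``expected_fractions``
    holds the post-renormalisation population fractions per group, so
    recovery checks against realised (compositionally closed) effects
    are exact.  ``mixing`` holds the true per-sink source proportions
    (columns: source labels then ``Unknown``) for FMT sinks.
    """

    signature_taxa: tuple[str, ...] = ()
    directions: dict = field(default_factory=dict)
    expected_fractions: pd.DataFrame | None = None
    mixing: pd.DataFrame | None = None


def _taxon_ids(n: int) -> list[str]:
    width = len(str(n - 1))
    return [f"t{str(i).zfill(width)}" for i in range(n)]


def simulate_tree(n_taxa: int, seed: int = 0) -> TreeNode:
    """Random rooted tree by sequential leaf attachment.

    Starting from a two-leaf cherry, each new leaf splits a uniformly
    chosen existing edge; every branch length is then drawn i.i.d.
    Exponential(mean 1).  Deterministic given the seed.
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    rng = np.random.default_rng(seed)
    names = _taxon_ids(n_taxa)
    root = TreeNode()
    first, second = TreeNode(name=names[0]), TreeNode(name=names[1])
    root.extend([first, second])
    attachable = [first, second]  # non-root nodes, i.e. edges
    for name in names[2:]:
        target = attachable[rng.integers(len(attachable))]
        parent = target.parent
        inner = TreeNode()
        leaf = TreeNode(name=name)
        parent.remove(target)
        inner.extend([target, leaf])
        parent.append(inner)
        attachable.extend([inner, leaf])
    for node in root.postorder(include_self=False):
        node.length = float(rng.exponential(1.0))
    root.length = None
    return validate_tree(root)


def simulate_two_group_tables(
    config: SyntheticConfig,
) -> tuple[TaxonTable, pd.DataFrame, GroundTruth]:
    """Two-group multinomial count table with planted differential taxa.

    Base taxon weights are LogNormal(0, sigma) normalised to a
    population profile for group A; group B multiplies the planted taxa
    by ``fold_change`` and renormalises.  Each sample is a
    Multinomial(depth, group profile) draw.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    taxa = _taxon_ids(cfg.n_taxa)
    w = rng.lognormal(mean=0.0, sigma=cfg.base_lognormal_sigma, size=cfg.n_taxa)
    p_a = w / w.sum()
    # Plant the signature among subdominant (bottom-third abundance) taxa:
    # scaling a large slice of the community and renormalising would shift
    # every other taxon's relative abundance, leaving no true null taxa.
    pool = np.argsort(w)[:max(cfg.n_signature_taxa, cfg.n_taxa // 3)]
    sig_idx = np.sort(rng.choice(pool, size=cfg.n_signature_taxa, replace=False))
    w_b = w.copy()
    w_b[sig_idx] *= cfg.fold_change
    p_b = w_b / w_b.sum()

    label_a, label_b = cfg.group_labels
    n = cfg.n_samples_per_group
    rows, sample_ids, groups = [], [], []
    for label, p in ((label_a, p_a), (label_b, p_b)):
        counts = rng.multinomial(cfg.depth, p, size=n)
        for j in range(n):
            rows.append(counts[j])
            sample_ids.append(f"{label}_{j + 1:02d}")
            groups.append(label)
    table = TaxonTable(pd.DataFrame(np.asarray(rows), index=sample_ids, columns=taxa))
    meta = pd.DataFrame({"group": groups}, index=pd.Index(sample_ids, name="sample_id"))

    if cfg.fold_change == 1.0:
        signature, directions = (), {}
    else:
        enriched = label_b if cfg.fold_change > 1 else label_a
        signature = tuple(taxa[i] for i in sig_idx)
        directions = {t: enriched for t in signature}
    expected = pd.DataFrame([p_a, p_b], index=[label_a, label_b], columns=taxa)
    truth = GroundTruth(signature_taxa=signature, directions=directions,
                        expected_fractions=expected)
    return table, meta, truth


def simulate_fmt_sinks(
    source_profiles: pd.DataFrame,
    mixing,
    unknown_profile: pd.Series,
    depth: int,
    n_sinks: int,
    seed: int = 0,
    sink_prefix: str = "sink",
) -> tuple[TaxonTable, GroundTruth]:
    """Multinomial sink samples from a convex mixture of sources.

    ``source_profiles`` is a (K sources x taxa) relative-abundance frame,
    ``unknown_profile`` a relative-abundance row on the same taxon axis,
    and ``mixing`` one simplex vector of length K+1 (last entry = the
    unknown source's share), or one such vector per sink.
    """
    profiles = source_profiles.to_numpy(dtype=float)
    if not np.allclose(profiles.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("source profiles must each sum to 1")
    if list(unknown_profile.index) != list(source_profiles.columns):
        raise ValueError("unknown_profile must share the source taxon axis")
    unk = unknown_profile.to_numpy(dtype=float)
    if not np.isclose(unk.sum(), 1.0, atol=1e-8):
        raise ValueError("unknown_profile must sum to 1")
    k = profiles.shape[0]
    mix = np.atleast_2d(np.asarray(mixing, dtype=float))
    if mix.shape[0] == 1:
        mix = np.repeat(mix, n_sinks, axis=0)
    if mix.shape != (n_sinks, k + 1):
        raise ValueError(f"mixing must have shape ({n_sinks}, {k + 1})")
    if (mix < 0).any() or not np.allclose(mix.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("mixing vectors must lie on the simplex")

    rng = np.random.default_rng(seed)
    p_sinks = mix[:, :k] @ profiles + np.outer(mix[:, k], unk)
    counts = np.vstack([rng.multinomial(depth, p_sinks[i]) for i in range(n_sinks)])
    ids = [f"{sink_prefix}_{i + 1:02d}" for i in range(n_sinks)]
    table = TaxonTable(pd.DataFrame(counts, index=ids,
                                    columns=source_profiles.columns))
    labels = list(source_profiles.index) + ["Unknown"]
    truth = GroundTruth(mixing=pd.DataFrame(mix, index=ids, columns=labels))
    return table, truth
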