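"""Bayesian microbial source tracking with an unknown source.

Each read of a sink sample carries a latent source assignment z among K
known sources plus an "Unknown" source.  Known-source likelihoods are
Dirichlet-smoothed training profiles, fixed during inference; the
unknown source's profile is learned from the sink reads currently
assigned to it.  A collapsed Gibbs sampler sweeps the reads; for a read
of taxon t,

    P(z = v)  propto  P(t | v) * (c_v + beta),

with P(t|v) = (n_t^v + alpha_known) / (N^v + alpha_known * T) for a
known source v and (m_t + alpha_unknown) / (M + alpha_unknown * T) for
the unknown source, where m_t / M count the sink reads currently
assigned Unknown (excluding the read being updated) and c_v the sink
reads currently assigned to v.  Posterior source proportions are the
assignment fractions averaged over retained draws across restarted
chains.  Defaults (alpha_known = 0.001, alpha_unknown = 0.1, beta = 10,
burn-in 100, 25 draws at thinning 10, 10 restarts, sink rarefaction to
1,000 reads) follow published practice for this sampler.
"""

from __future__ import annotations

from dataclasses import dataclass

import numba
import numpy as np
import pandas as pd

from .tables import TaxonTable


@dataclass(frozen=True)
class SourceModel:
    """Pooled training counts per known source plus smoothing parameters."""

    counts: pd.DataFrame  # sources x taxa, pooled integer counts
    alpha_known: float = 0.001
    alpha_unknown: float = 0.1
    beta: float = 10.0

    def __post_init__(self):
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("source counts must be non-negative")
        if self.alpha_known <= 0 or self.alpha_unknown <= 0 or self.beta <= 0:
            raise ValueError("alpha_known, alpha_unknown and beta must be > 0")

    @property
    def source_labels(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.columns)

    def smoothed_profiles(self) -> pd.DataFrame:
        """(n_t^v + alpha) / (N^v + alpha * T), the fixed known likelihoods."""
        c = self.counts.to_numpy(dtype=float)
        t = c.shape[1]
        smoothed = (c + self.alpha_known) / \
            (c.sum(axis=1, keepdims=True) + self.alpha_known * t)
        return pd.DataFrame(smoothed, index=self.counts.index,
                            columns=self.counts.columns)


def fit_sources(table: TaxonTable, metadata, source_groups,
                alpha_known: float = 0.001, alpha_unknown: float = 0.1,
                beta: float = 10.0) -> SourceModel:
    """Pool counts within each source label to form the training model."""
    if isinstance(metadata, pd.DataFrame):
        metadata = metadata["group"]
    labels = pd.Series(metadata)
    rows = {}
    for group in source_groups:
        members = labels.index[labels == group]
        members = [s for s in members if s in table.counts.index]
        if not members:
            raise ValueError(f"source group {group!r} has no samples")
        rows[group] = table.counts.loc[members].sum(axis=0)
    counts = pd.DataFrame(rows).T
    return SourceModel(counts=counts, alpha_known=alpha_known,
                       alpha_unknown=alpha_unknown, beta=beta)


@numba.njit(cache=False)
def _gibbs_chain(read_taxa, known_like, alpha_unknown, beta, n_taxa,
                 n_burnin, n_draws, thinning, seed):  # pragma: no cover - jitted
    np.random.seed(seed)
    n_known = known_like.shape[0]
    n_sources = n_known + 1
    n_reads = read_taxa.size
    z = np.empty(n_reads, dtype=np.int64)
    c = np.zeros(n_sources)
    m = np.zeros(n_taxa)
    m_total = 0.0
    probs = np.empty(n_sources)
    # progressive warm start: assign reads sequentially from the same
    # collapsed conditional, growing the counts as we go (a cold uniform
    # init parks ~1/(K+1) of the reads in the unknown source, whose
    # self-reinforcing profile then drains very slowly)
    for i in range(n_reads):
        t = read_taxa[i]
        total = 0.0
        for v in range(n_known):
            p = known_like[v, t] * (c[v] + beta)
            probs[v] = p
            total += p
        p_unk = (m[t] + alpha_unknown) / (m_total + alpha_unknown * n_taxa) \
            * (c[n_known] + beta)
        probs[n_known] = p_unk
        total += p_unk
        u = np.random.random() * total
        acc = 0.0
        v_new = n_known
        for v in range(n_sources):
            acc += probs[v]
            if u <= acc:
                v_new = v
                break
        z[i] = v_new
        c[v_new] += 1.0
        if v_new == n_known:
            m[t] += 1.0
            m_total += 1.0
    draws = np.zeros((n_draws, n_sources))
    d_i = 0
    for sweep in range(n_burnin + n_draws * thinning):
        for i in range(n_reads):
            t = read_taxa[i]
            v_old = z[i]
            c[v_old] -= 1.0
            if v_old == n_known:
                m[t] -= 1.0
                m_total -= 1.0
            total = 0.0
            for v in range(n_known):
                p = known_like[v, t] * (c[v] + beta)
                probs[v] = p
                total += p
            p_unk = (m[t] + alpha_unknown) / (m_total + alpha_unknown * n_taxa) \
                * (c[n_known] + beta)
            probs[n_known] = p_unk
            total += p_unk
            u = np.random.random() * total
            acc = 0.0
            v_new = n_known
            for v in range(n_sources):
                acc += probs[v]
                if u <= acc:
                    v_new = v
                    break
            z[i] = v_new
            c[v_new] += 1.0
            if v_new == n_known:
                m[t] += 1.0
                m_total += 1.0
        if sweep >= n_burnin and (sweep - n_burnin + 1) % thinning == 0:
            for v in range(n_sources):
                draws[d_i, v] = c[v] / n_reads
            d_i += 1
    return draws


@dataclass(frozen=True)
class SourceProportions:
    """Posterior source proportions for one sink sample."""

    labels: tuple[str, ...]   # known source labels then "Unknown"
    mean: pd.Series
    sd: pd.Series
    draws: np.ndarray         # retained draws x sources

    def __post_init__(self):
        assert abs(float(self.mean.sum()) - 1.0) < 1e-6


def _canonical_order(counts: np.ndarray) -> list[int]:
    """Content-based source ordering, invariant under relabelling."""
    return sorted(range(counts.shape[0]), key=lambda i: counts[i].tobytes())


def track(sink, model: SourceModel, n_burnin: int = 100, n_draws: int = 25,
          thinning: int = 10, n_restarts: int = 10,
          rarefy_depth: int | None = 1000, seed: int = 0) -> SourceProportions:
    """Posterior source proportions of one sink sample.

    ``sink`` is a pandas Series of counts over the model's taxon axis.
    Sinks deeper than ``rarefy_depth`` are subsampled without
    replacement to bound chain length (pass ``None`` to disable).
    Restarted chains use seeds derived from ``seed``; draws are pooled
    across restarts.
    """
    if n_burnin < 0 or n_draws < 1 or thinning < 1 or n_restarts < 1:
        raise ValueError("chain parameters must be positive")
    sink = pd.Series(sink).reindex(model.taxon_ids)
    if sink.isna().any():
        raise ValueError("sink taxa must be a subset of the model's taxon axis")
    counts = sink.to_numpy(dtype=np.int64)
    if (counts < 0).any():
        raise ValueError("sink counts must be non-negative")
    depth = int(counts.sum())
    if depth == 0:
        raise ValueError("sink has zero reads")

    ss = np.random.SeedSequence(seed)
    state = ss.generate_state(n_restarts + 1, dtype=np.uint64)
    if rarefy_depth is not None and depth > rarefy_depth:
        rng = np.random.default_rng(int(state[0] % (2**31)))
        counts = rng.multivariate_hypergeometric(counts, rarefy_depth)

    order = _canonical_order(model.counts.to_numpy())
    like = model.smoothed_profiles().to_numpy(dtype=float)[order]
    read_taxa = np.repeat(np.arange(len(model.taxon_ids), dtype=np.int64), counts)
    n_known = like.shape[0]
    all_draws = np.empty((n_restarts * n_draws, n_known + 1))
    for r in range(n_restarts):
        chain_seed = int(state[r + 1] % (2**31))
        all_draws[r * n_draws:(r + 1) * n_draws] = _gibbs_chain(
            read_taxa, like, model.alpha_unknown, model.beta,
            len(model.taxon_ids), n_burnin, n_draws, thinning, chain_seed)

    # undo the canonical ordering
    unorder = np.empty(n_known + 1, dtype=np.int64)
    for pos, src in enumerate(order):
        unorder[src] = pos
    unorder[n_known] = n_known
    all_draws = all_draws[:, unorder]
    labels = tuple(model.source_labels) + ("Unknown",)
    mean = pd.Series(all_draws.mean(axis=0), index=labels)
    sd = pd.Series(all_draws.std(axis=0, ddof=1) if all_draws.shape[0] > 1
                   else np.zeros(n_known + 1), index=labels)
    return SourceProportions(labels=labels, mean=mean, sd=sd, draws=all_draws)


def track_all(sinks: TaxonTable, model: SourceModel, seed: int = 0,
              **kwargs) -> pd.DataFrame:
    """Track every sample of a sink table; rows are posterior means.

    Per-sink seeds are derived from ``seed`` so sinks are independent
    but the whole run is reproducible.
    """
    state = np.random.SeedSequence(seed).generate_state(len(sinks.sample_ids),
                                                        dtype=np.uint64)
    rows = {}
    for i, sample in enumerate(sinks.sample_ids):
        props = track(sinks.counts.loc[sample], model,
                      seed=int(state[i] % (2**31)), **kwargs)
        rows[sample] = props.mean
    return pd.DataFrame(rows).T


def summarize_by_population(proportions: pd.DataFrame, arms) -> pd.DataFrame:
    """Average posterior-mean proportions within each FMT arm.

    ``proportions`` has one row per sink (columns: sources + Unknown);
    ``arms`` maps sink id to arm label.  Means of simplex rows stay on
    the simplex.
    """
    if isinstance(arms, pd.DataFrame):
        arms = arms["group"]
    arms = pd.Series(arms).loc[proportions.index]
    out = proportions.groupby(arms).mean()
    if out.empty:
        raise ValueError("no arms to summarise")
    return out
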