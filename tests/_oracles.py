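"""Independent oracles and benchmark computations.

Shared by the acceptance test suite and ``scripts/acceptance.py``.  Each
oracle is deliberately naive (per-pair path enumeration, exhaustive
label enumeration, brute-force cutoff search) and independent of the
vectorised implementations it checks.
"""

from __future__ import annotations

import json
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

import microsig as ms


# ---------------------------------------------------------------------------
# UniFrac: brute-force per-edge oracle
# ---------------------------------------------------------------------------

def unifrac_brute(tree, table: ms.TaxonTable) -> np.ndarray:
    """Per-pair unweighted UniFrac by explicit edge enumeration."""
    presence = table.counts.to_numpy() > 0
    taxa = table.taxon_ids
    edges = []  # (length, set of descendant taxon ids)
    for node in tree.traverse(include_self=False):
        tips = {t.name for t in node.tips()} if not node.is_tip() else {node.name}
        edges.append((float(node.length or 0.0), tips))
    n = presence.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        set_i = {t for k, t in enumerate(taxa) if presence[i, k]}
        for j in range(i + 1, n):
            set_j = {t for k, t in enumerate(taxa) if presence[j, k]}
            unique = union = 0.0
            for length, tips in edges:
                in_i = bool(tips & set_i)
                in_j = bool(tips & set_j)
                if in_i or in_j:
                    union += length
                    if in_i != in_j:
                        unique += length
            d[i, j] = d[j, i] = unique / union if union > 0 else 0.0
    return d


def unifrac_oracle_max_diff(n_trees: int, seed: int, n_leaves: int = 8,
                            n_samples: int = 4) -> float:
    """Max |implementation - brute force| over random trees and profiles."""
    root = np.random.SeedSequence(seed).generate_state(n_trees)
    worst = 0.0
    for k in range(n_trees):
        s = int(root[k] % (2**31))
        tree = ms.simulate_tree(n_leaves, seed=s)
        rng = np.random.default_rng(s)
        counts = rng.integers(0, 2, size=(n_samples, n_leaves))
        taxa = [t.name for t in tree.tips()]
        table = ms.TaxonTable(pd.DataFrame(
            counts, index=[f"s{i}" for i in range(n_samples)], columns=taxa))
        impl = ms.unweighted_unifrac(tree, table).data
        brute = unifrac_brute(tree, table)
        worst = max(worst, float(np.abs(impl - brute).max()))
    return worst


# ---------------------------------------------------------------------------
# AUC == U / (n1 * n2) identity
# ---------------------------------------------------------------------------

def pair_count_u(pos: np.ndarray, neg: np.ndarray) -> float:
    """Mann-Whitney U by brute-force pair counting with half-credit ties."""
    u = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                u += 1.0
            elif p == q:
                u += 0.5
    return u


def auc_identity_max_diff(n_instances: int, seed: int) -> float:
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        n1 = int(rng.integers(2, 11))
        n2 = int(rng.integers(2, 11))
        if rng.random() < 0.5:  # heavy ties
            vals = rng.integers(0, 5, size=n1 + n2) / 4.0
        else:
            vals = rng.normal(size=n1 + n2)
        labels = np.array(["pos"] * n1 + ["neg"] * n2)
        rng.shuffle(labels)
        _, auc = ms.roc_auc(vals, labels, positive="pos")
        u = pair_count_u(vals[labels == "pos"], vals[labels == "neg"])
        worst = max(worst, abs(auc - u / (n1 * n2)))
    return worst


# ---------------------------------------------------------------------------
# Mann-Whitney exact p: full-enumeration oracle
# ---------------------------------------------------------------------------

def mwu_enumeration_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided exact p by enumerating all group-label assignments."""
    pooled = np.concatenate([a, b])
    na, n = len(a), len(pooled)
    ranks = stats.rankdata(pooled)
    u_obs = ranks[:na].sum() - na * (na + 1) / 2
    idx = np.array(list(combinations(range(n), na)))
    us = ranks[idx].sum(axis=1) - na * (na + 1) / 2
    p_le = np.mean(us <= u_obs)
    p_ge = np.mean(us >= u_obs)
    return min(1.0, 2.0 * min(p_le, p_ge))


def mwu_oracle_max_diff(n_draws: int, seed: int, n_per_group: int = 8) -> float:
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_draws):
        a = rng.normal(size=n_per_group)
        b = rng.normal(size=n_per_group) + rng.normal() * 0.5
        _, p_impl = ms.mann_whitney(a, b)
        worst = max(worst, abs(p_impl - mwu_enumeration_p(a, b)))
    return worst


# ---------------------------------------------------------------------------
# PERMANOVA null calibration
# ---------------------------------------------------------------------------

def permanova_null_rejection_rate(n_runs: int, seed: int, n_perm: int = 199,
                                  n_per_group: int = 6, alpha: float = 0.05) -> float:
    """Type-I error rate on structureless Euclidean data."""
    root = np.random.SeedSequence(seed).generate_state(n_runs)
    ids = [f"s{i}" for i in range(2 * n_per_group)]
    groups = pd.Series(["A"] * n_per_group + ["B"] * n_per_group, index=ids)
    rejections = 0
    for k in range(n_runs):
        s = int(root[k] % (2**31))
        rng = np.random.default_rng(s)
        points = rng.normal(size=(2 * n_per_group, 5))
        dm = DistanceMatrix(squareform(pdist(points)), ids=ids)
        res = ms.permanova(dm, groups, n_perm=n_perm, seed=s)
        if res.p_value < alpha:
            rejections += 1
    return rejections / n_runs


def permanova_brute_f(dm: DistanceMatrix, groups: pd.Series) -> float:
    """Pseudo-F straight from its definition, double loops and all."""
    labels = groups.loc[list(dm.ids)].to_numpy()
    n = len(dm.ids)
    d2 = dm.data**2
    ss_total = sum(d2[i, j] for i in range(n) for j in range(i + 1, n)) / n
    ss_within = 0.0
    uniq = sorted(set(labels))
    for g in uniq:
        members = [i for i in range(n) if labels[i] == g]
        ss_g = sum(d2[i, j] for ii, i in enumerate(members)
                   for j in members[ii + 1:])
        ss_within += ss_g / len(members)
    k = len(uniq)
    return ((ss_total - ss_within) / (k - 1)) / (ss_within / (n - k))


# ---------------------------------------------------------------------------
# Screen recovery and end-to-end discrimination on synthetic cohorts
# ---------------------------------------------------------------------------

STUDY_CONFIG = dict(n_taxa=60, n_samples_per_group=10, depth=5000,
                    n_signature_taxa=5, fold_change=4.0,
                    base_lognormal_sigma=1.5)


def screen_recovery_rates(n_seeds: int, seed: int) -> tuple[float, float]:
    """(planted, null) pass-rate averages over seeded synthetic cohorts."""
    root = np.random.SeedSequence(seed).generate_state(n_seeds)
    planted_rates, null_rates = [], []
    for k in range(n_seeds):
        s = int(root[k] % (2**31))
        table, meta, truth = ms.simulate_two_group_tables(
            ms.SyntheticConfig(seed=s, **STUDY_CONFIG))
        res = ms.effect_size(table.to_relative(), meta["group"], seed=s)
        passed = res.frame["passed"]
        planted = list(truth.signature_taxa)
        null = [t for t in passed.index if t not in truth.signature_taxa]
        planted_rates.append(passed.loc[planted].mean())
        null_rates.append(passed.loc[null].mean())
    return float(np.mean(planted_rates)), float(np.mean(null_rates))


def endtoend_discrimination(n_runs: int, seed: int,
                            auc_floor: float = 0.9,
                            acc_floor: float = 0.8) -> dict:
    """Panel -> index -> ROC/LOO on seeded synthetic cohorts.

    Returns the fraction of runs clearing both floors plus the median
    AUC and LOO accuracy across runs (empty panels count as failures).
    """
    root = np.random.SeedSequence(seed).generate_state(n_runs)
    aucs, accs, successes = [], [], 0
    for k in range(n_runs):
        s = int(root[k] % (2**31))
        table, meta, truth = ms.simulate_two_group_tables(
            ms.SyntheticConfig(seed=s, **STUDY_CONFIG))
        rel = table.to_relative()
        res = ms.effect_size(rel, meta["group"], seed=s)
        panel = ms.select_signature(res, group="KD")
        if len(panel) == 0:
            continue
        report = ms.index_report(rel, panel, meta["group"])
        aucs.append(report.auc)
        accs.append(report.loo.accuracy)
        if report.auc >= auc_floor and report.loo.accuracy >= acc_floor:
            successes += 1
    return {
        "success_fraction": successes / n_runs,
        "median_auc": float(np.median(aucs)) if aucs else 0.0,
        "median_loo_accuracy": float(np.median(accs)) if accs else 0.0,
    }


# ---------------------------------------------------------------------------
# Source-tracking recovery benchmarks
# ---------------------------------------------------------------------------

def _lognormal_profile(rng, n, sigma=1.5):
    w = rng.lognormal(0.0, sigma, n)
    return w / w.sum()


def sourcetracking_benchmarks(seed: int, n_sinks: int = 10,
                              mix=(0.7, 0.2, 0.1), sink_depth: int = 20000,
                              n_taxa: int = 60) -> dict:
    """Three recovery scenarios for the Gibbs sampler.

    mixture: sinks drawn from ``mix`` over two distinct communities plus
    an unknown source, tracked at sampler defaults; reports the largest
    absolute error of the sink-averaged posterior means.
    pure: a sink identical to source 1's profile (disjoint-support
    sources, depth 1e4) — reports the posterior mean of source 1.
    unknown: a sink supported only on taxa absent from both sources —
    reports the posterior mean of Unknown.
    """
    rng = np.random.default_rng(seed)
    taxa = [f"t{i:03d}" for i in range(n_taxa)]

    # mixture scenario: two independent lognormal source communities
    profiles = pd.DataFrame([_lognormal_profile(rng, n_taxa),
                             _lognormal_profile(rng, n_taxa)],
                            index=["src1", "src2"], columns=taxa)
    unknown = pd.Series(_lognormal_profile(rng, n_taxa), index=taxa)
    train = pd.DataFrame(
        [rng.multinomial(50000, profiles.loc["src1"]),
         rng.multinomial(50000, profiles.loc["src2"])],
        index=["train1", "train2"], columns=taxa)
    meta = pd.DataFrame({"group": ["src1", "src2"]}, index=["train1", "train2"])
    model = ms.fit_sources(ms.TaxonTable(train), meta, ["src1", "src2"])
    sinks, _ = ms.simulate_fmt_sinks(profiles, list(mix), unknown,
                                     depth=sink_depth, n_sinks=n_sinks,
                                     seed=int(rng.integers(2**31)))
    props = ms.track_all(sinks, model, seed=int(rng.integers(2**31)))
    averaged = props.mean(axis=0).to_numpy()
    mixture_err = float(np.abs(averaged - np.asarray(mix)).max())

    # pure scenario: disjoint-support sources, sink == source 1 profile
    half = n_taxa // 2
    p1 = np.concatenate([_lognormal_profile(rng, half), np.zeros(n_taxa - half)])
    p2 = np.concatenate([np.zeros(half), _lognormal_profile(rng, n_taxa - half)])
    disjoint = pd.DataFrame([p1, p2], index=["src1", "src2"], columns=taxa)
    train2 = pd.DataFrame([np.rint(p1 * 100000), np.rint(p2 * 100000)],
                          index=["train1", "train2"], columns=taxa).astype(int)
    model2 = ms.fit_sources(ms.TaxonTable(train2), meta, ["src1", "src2"])
    pure_sink = pd.Series(np.rint(p1 * 10000).astype(int), index=taxa)
    pure = ms.track(pure_sink, model2, rarefy_depth=None,
                    seed=int(rng.integers(2**31)))
    pure_recovery = float(pure.mean["src1"])

    # unknown scenario: sink on taxa absent from every known source
    extra = [f"u{i:02d}" for i in range(10)]
    all_taxa = taxa + extra
    train3 = train2.reindex(columns=all_taxa, fill_value=0)
    model3 = ms.fit_sources(ms.TaxonTable(train3), meta, ["src1", "src2"])
    w = _lognormal_profile(rng, len(extra), sigma=1.0)
    unk_sink = pd.Series(np.concatenate([np.zeros(n_taxa),
                                         np.rint(w * 10000)]).astype(int),
                         index=all_taxa)
    unk = ms.track(unk_sink, model3, rarefy_depth=None,
                   seed=int(rng.integers(2**31)))
    unknown_recovery = float(unk.mean["Unknown"])

    return {"mixture_max_abs_error": mixture_err,
            "pure_source_recovery": pure_recovery,
            "unknown_recovery": unknown_recovery,
            "n_sinks": n_sinks}


# ---------------------------------------------------------------------------
# Leave-one-out: exhaustive cutoff-search oracle
# ---------------------------------------------------------------------------

def loo_oracle(values: np.ndarray, labels, positive: str):
    """Fold predictions via plain exhaustive search over every cutoff.

    Candidates are, in increasing order, a point below the minimum, the
    midpoints between adjacent distinct training values, and a point
    above the maximum; training accuracy decides, first optimum wins.
    """
    y = np.asarray(pd.Series(labels) == positive)
    x = np.asarray(values, dtype=float)
    preds = np.empty(x.size, dtype=bool)
    for i in range(x.size):
        tr_x = np.delete(x, i)
        tr_y = np.delete(y, i)
        d = np.unique(tr_x)
        if d.size == 1:
            cands = [d[0] - 0.5, d[0] + 0.5]
        else:
            cands = ([d[0] - (d[1] - d[0]) / 2]
                     + [(d[k] + d[k + 1]) / 2 for k in range(d.size - 1)]
                     + [d[-1] + (d[-1] - d[-2]) / 2])
        best_acc, best_c = -1.0, None
        for c in cands:
            acc = np.mean((tr_x >= c) == tr_y)
            if acc > best_acc:
                best_acc, best_c = acc, c
        preds[i] = x[i] >= best_c
    accuracy = float(np.mean(preds == y))
    return preds, accuracy


def loo_oracle_agreement(n_instances: int, seed: int) -> float:
    """Fraction of random 8-sample instances with identical fold predictions."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_instances):
        if rng.random() < 0.3:  # tied values exercise the tie-break rule
            x = rng.integers(0, 5, size=8) / 4.0
        else:
            x = rng.normal(size=8)
        labels = np.array(["P"] * 4 + ["N"] * 4)
        rng.shuffle(labels)
        impl = ms.loo_cutoff_cv(x, labels, positive="P")
        oracle_preds, oracle_acc = loo_oracle(x, labels, "P")
        if (impl.predictions == oracle_preds).all() \
                and impl.accuracy == oracle_acc:
            agree += 1
    return agree / n_instances


# ---------------------------------------------------------------------------
# Pipeline determinism
# ---------------------------------------------------------------------------

SMALL_PIPELINE = dict(
    simulate=dict(n_taxa=40, n_samples_per_group=6, depth=2000,
                  n_signature_taxa=4, fold_change=4.0),
    rarefy_depth=1000,
    permanova_n_perm=99,
    sinks=dict(n_per_arm=2, depth=5000),
    track=dict(n_restarts=2, n_draws=10, n_burnin=50, thinning=5,
               rarefy_depth=500),
)


def pipeline_determinism(workdir, seed: int) -> tuple[bool, int]:
    """Run the full pipeline twice; compare outputs byte for byte.

    The manifest is a log (it records wall-clock times) and is compared
    through its output-checksum map instead.  Returns (identical, number
    of outputs).
    """
    workdir = Path(workdir)
    manifests = []
    for run_id in ("run1", "run2"):
        cfg = ms.PipelineConfig(outdir=str(workdir / run_id), seed=seed,
                                **{k: dict(v) if isinstance(v, dict) else v
                                   for k, v in SMALL_PIPELINE.items()})
        manifests.append(ms.run_pipeline(cfg))
    m1, m2 = manifests
    same = m1.outputs == m2.outputs and len(m1.outputs) > 0
    for name in m1.outputs:
        b1 = (workdir / "run1" / name).read_bytes()
        b2 = (workdir / "run2" / name).read_bytes()
        same = same and b1 == b2
    return same, len(m1.outputs)
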