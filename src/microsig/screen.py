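"""Differential-taxon screening with an LDA-style effect size.

The screen mirrors the two stages of the LEfSe procedure for a
two-class design: a tie-corrected Kruskal-Wallis test per taxon, then a
bootstrap effect-size score on parts-per-million-scaled relative
abundances, reported on a log10 scale.  In the two-class, per-taxon
setting the one-dimensional LDA projection reduces to the between-group
mean difference, so the effect score here is the bootstrap-averaged
absolute mean difference in ppm; with that scaling the conventional
"log10 score > 2" threshold corresponds to a 100 ppm mean difference.
A taxon passes when its Kruskal-Wallis p-value is below ``alpha`` and
its log10 effect exceeds ``threshold``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .tables import RelAbundanceTable

PPM = 1.0e6


def _two_group_indices(rel: RelAbundanceTable, groups) -> tuple[str, str, np.ndarray, np.ndarray]:
    if isinstance(groups, pd.DataFrame):
        groups = groups["group"]
    labels = pd.Series(groups).loc[rel.sample_ids]
    uniq = sorted(set(labels))
    if len(uniq) != 2:
        raise ValueError(f"screen requires exactly 2 groups, got {uniq}")

    def members(g):  # canonical (id-sorted) order, so results do not depend
        pos = np.flatnonzero((labels == g).to_numpy())  # on row order
        return pos[np.argsort(np.asarray(rel.sample_ids, dtype=object)[pos])]

    idx_a, idx_b = members(uniq[0]), members(uniq[1])
    if min(len(idx_a), len(idx_b)) < 2:
        raise ValueError("each group needs >= 2 samples")
    return uniq[0], uniq[1], idx_a, idx_b


def kruskal_wallis_screen(rel: RelAbundanceTable, groups,
                          alpha: float = 0.05) -> pd.DataFrame:
    """Per-taxon Kruskal-Wallis H with tie-corrected ranks.

    Returns a frame indexed by taxon with columns ``kw_h``, ``kw_p``,
    ``significant`` (p < alpha) and ``degenerate`` (taxon constant
    across all samples; p = 1 by convention).
    """
    label_a, label_b, idx_a, idx_b = _two_group_indices(rel, groups)
    x = rel.fractions.to_numpy(dtype=float)
    n = x.shape[0]
    ranks = stats.rankdata(x, axis=0)
    h_num = np.zeros(x.shape[1])
    for idx in (idx_a, idx_b):
        r_g = ranks[idx].sum(axis=0)
        h_num += r_g**2 / len(idx)
    h = 12.0 / (n * (n + 1)) * h_num - 3.0 * (n + 1)
    # tie correction: 1 - sum(t^3 - t) / (N^3 - N), per taxon
    correction = np.empty(x.shape[1])
    for j in range(x.shape[1]):
        _, t = np.unique(x[:, j], return_counts=True)
        correction[j] = 1.0 - (t**3 - t).sum() / (n**3 - n)
    degenerate = correction == 0.0
    h = np.where(degenerate, 0.0, h / np.where(degenerate, 1.0, correction))
    p = np.where(degenerate, 1.0, stats.chi2.sf(h, df=1))
    return pd.DataFrame(
        {"kw_h": h, "kw_p": p, "significant": p < alpha, "degenerate": degenerate},
        index=rel.taxon_ids,
    )


@dataclass(frozen=True)
class EffectSizeResult:
    """Per-taxon screen outcome plus the parameters that produced it."""

    frame: pd.DataFrame  # columns: kw_p, effect_log10, enriched_group, passed
    group_labels: tuple[str, str]
    alpha: float
    threshold: float
    n_boot: int
    boot_fraction: float
    seed: int


@dataclass(frozen=True)
class SignaturePanel:
    """Taxa defining the signature index, all enriched in one group."""

    taxa: tuple[str, ...]
    enriched_group: str
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("panel taxa must be unique")

    def __len__(self) -> int:
        return len(self.taxa)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# enriched_group={self.enriched_group}\n")
            for key, val in sorted(self.provenance.items()):
                fh.write(f"# {key}={val}\n")
            for taxon in self.taxa:
                fh.write(taxon + "\n")

    @classmethod
    def load(cls, path) -> "SignaturePanel":
        taxa, meta = [], {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    key, _, val = line[1:].strip().partition("=")
                    meta[key.strip()] = val.strip()
                else:
                    taxa.append(line)
        group = meta.pop("enriched_group", "")
        return cls(taxa=tuple(taxa), enriched_group=group, provenance=meta)


def effect_size(rel: RelAbundanceTable, groups, n_boot: int = 30,
                boot_fraction: float = 2.0 / 3.0, seed: int = 0,
                alpha: float = 0.05, threshold: float = 2.0,
                floor_ppm: float = 1.0, bh_correct: bool = False) -> EffectSizeResult:
    """Bootstrap effect-size screen on ppm-scaled relative abundances.

    Per bootstrap replicate, each group is resampled with replacement at
    ``boot_fraction`` of its size and the absolute between-group mean
    difference recorded per taxon; ``effect_log10`` is the log10 of the
    bootstrap-mean difference floored at ``floor_ppm``.  ``bh_correct``
    applies Benjamini-Hochberg to the Kruskal-Wallis p-values before the
    alpha cut (off by default, matching LEfSe behaviour).
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    label_a, label_b, idx_a, idx_b = _two_group_indices(rel, groups)
    size_a = int(round(len(idx_a) * boot_fraction))
    size_b = int(round(len(idx_b) * boot_fraction))
    if size_a < 1 or size_b < 1:
        raise ValueError("boot_fraction too small: a group resample would be empty")

    ppm = rel.fractions.to_numpy(dtype=float) * PPM
    rng = np.random.default_rng(seed)
    diff_sum = np.zeros(ppm.shape[1])
    for _ in range(n_boot):
        take_a = idx_a[rng.integers(0, len(idx_a), size=size_a)]
        take_b = idx_b[rng.integers(0, len(idx_b), size=size_b)]
        diff_sum += np.abs(ppm[take_a].mean(axis=0) - ppm[take_b].mean(axis=0))
    effect = np.log10(np.maximum(diff_sum / n_boot, floor_ppm))

    mean_a = ppm[idx_a].mean(axis=0)
    mean_b = ppm[idx_b].mean(axis=0)
    enriched = np.where(mean_a > mean_b, label_a,
                        np.where(mean_b > mean_a, label_b, None))

    kw = kruskal_wallis_screen(rel, groups, alpha=alpha)
    pvals = kw["kw_p"].to_numpy()
    if bh_correct:
        pvals = stats.false_discovery_control(pvals, method="bh")
    passed = (pvals < alpha) & (effect > threshold)
    frame = pd.DataFrame(
        {"kw_p": pvals, "effect_log10": effect,
         "enriched_group": enriched, "passed": passed},
        index=rel.taxon_ids,
    )
    return EffectSizeResult(frame=frame, group_labels=(label_a, label_b),
                            alpha=alpha, threshold=threshold, n_boot=n_boot,
                            boot_fraction=boot_fraction, seed=seed)


def select_signature(res: EffectSizeResult, group: str,
                     threshold: float | None = None) -> SignaturePanel:
    """Taxa passing the screen and enriched in ``group``, by effect desc."""
    thr = res.threshold if threshold is None else threshold
    frame = res.frame
    mask = (frame["kw_p"] < res.alpha) & (frame["effect_log10"] > thr) \
        & (frame["enriched_group"] == group)
    chosen = frame[mask].sort_values("effect_log10", ascending=False)
    if chosen.empty:
        warnings.warn(f"signature screen selected no taxa for group {group!r}")
    provenance = {
        "alpha": res.alpha, "threshold": thr, "n_boot": res.n_boot,
        "boot_fraction": round(res.boot_fraction, 6), "seed": res.seed,
    }
    return SignaturePanel(taxa=tuple(chosen.index), enriched_group=group,
                          provenance=provenance)
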