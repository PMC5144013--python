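"""Generate the synthetic study data: two-group cohort, tree, FMT sinks.

Emulates a genotype-contrast 16S experiment: 10 wild-type (WT) and 10
knockdown (KD) mouse fecal communities of 60 taxa at 5,000 reads each,
with 5 signature taxa planted at fold change 4 in KD, plus a random
phylogeny over the taxa.  Post-FMT "sink" samples are convex mixtures
of the two group profiles and an unseen community (70% donor / 20%
recipient / 10% unknown).  Everything is written under results/data/.

Run from the repository root:  python analysis/01_simulate_cohorts.py
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

import microsig as ms

SEED = 20160
OUT = Path("results/data")


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = ms.SyntheticConfig(seed=SEED)
    table, meta, truth = ms.simulate_two_group_tables(cfg)
    tree = ms.simulate_tree(cfg.n_taxa, seed=SEED)

    ms.write_taxon_table(table, OUT / "table.tsv")
    ms.write_sample_metadata(meta, OUT / "metadata.tsv")
    ms.write_tree(tree, OUT / "tree.nwk")
    with open(OUT / "truth.json", "w") as fh:
        json.dump({"signature_taxa": list(truth.signature_taxa),
                   "directions": truth.directions}, fh, indent=2, sort_keys=True)

    rel = table.to_relative()
    profiles = rel.fractions.groupby(meta["group"]).mean()
    profiles = profiles.div(profiles.sum(axis=1), axis=0)
    rng = np.random.default_rng(SEED + 1)
    unk = rng.lognormal(0, 1.5, profiles.shape[1])
    unknown_profile = pd.Series(unk / unk.sum(), index=profiles.columns)

    frames, truths = [], []
    for donor, recipient in (("KD", "WT"), ("WT", "KD")):
        vec = [{donor: 0.7, recipient: 0.2}[g] for g in profiles.index] + [0.1]
        sinks, sink_truth = ms.simulate_fmt_sinks(
            profiles, vec, unknown_profile, depth=20000, n_sinks=5,
            seed=SEED + 2, sink_prefix=f"{donor}_to_{recipient}")
        frames.append(sinks.counts)
        truths.append(sink_truth.mixing)
    ms.write_taxon_table(ms.TaxonTable(pd.concat(frames)), OUT / "sinks.tsv")
    pd.concat(truths).to_csv(OUT / "sink_truth.tsv", sep="\t",
                             index_label="sample_id")

    print(f"cohort: {len(table.sample_ids)} samples x {len(table.taxon_ids)} "
          f"taxa at depth {cfg.depth}")
    print(f"planted signature ({len(truth.signature_taxa)} taxa, "
          f"fold {cfg.fold_change} in KD): {', '.join(truth.signature_taxa)}")
    print(f"sinks: 10 samples (two FMT arms, 0.7/0.2/0.1 mixing) at depth 20000")
    print(f"wrote {OUT}/table.tsv, metadata.tsv, tree.nwk, truth.json, "
          f"sinks.tsv, sink_truth.tsv")


if __name__ == "__main__":
    main()
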