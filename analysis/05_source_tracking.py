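"""Bayesian source tracking of the post-FMT sink samples.

The pre-FMT cohort samples, pooled by genotype, serve as the two known
source communities; each sink's reads are attributed to WT, KD or an
unknown source by the collapsed Gibbs sampler, and posterior means are
averaged within each FMT arm.  Estimates are compared with the
generator's true mixing proportions (0.7 donor / 0.2 recipient / 0.1
unknown).

Run after 01_simulate_cohorts.py:  python analysis/05_source_tracking.py
"""

from pathlib import Path

import pandas as pd

import microsig as ms

SEED = 20164
DATA = Path("results/data")
OUT = Path("results/source_tracking")


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    table = ms.read_taxon_table(DATA / "table.tsv")
    meta = ms.read_sample_metadata(DATA / "metadata.tsv")
    sinks = ms.read_taxon_table(DATA / "sinks.tsv")
    truth = pd.read_csv(DATA / "sink_truth.tsv", sep="\t", index_col=0)

    model = ms.fit_sources(table, meta["group"], ["WT", "KD"])
    props = ms.track_all(sinks, model, seed=SEED)
    props.to_csv(OUT / "sink_proportions.tsv", sep="\t",
                 index_label="sample_id")

    arms = pd.Series({s: s.rsplit("_", 1)[0] for s in props.index})
    summary = ms.summarize_by_population(props, arms)
    summary.to_csv(OUT / "arm_summary.tsv", sep="\t", index_label="arm")

    print("per-arm mean posterior source proportions:")
    print(summary.round(3).to_string())
    err = (props[truth.columns] - truth).abs().to_numpy().max()
    print(f"max abs error vs true mixing across all sinks/sources: {err:.3f}")
    unk_err = (props["Unknown"] - truth["Unknown"]).abs().max()
    print(f"unknown fraction recovered within {unk_err:.3f} of the true 0.10")
    for arm in summary.index:
        donor, recipient = arm.split("_to_")
        print(f"finding: in {arm} sinks the {donor} (donor) share "
              f"({summary.loc[arm, donor]:.0%}) exceeds the {recipient} "
              f"(recipient) share ({summary.loc[arm, recipient]:.0%})")
    print("note: the WT and KD sources share their base community (only 5 "
          "subdominant taxa differ), so reads from the shared flora are "
          "genuinely ambiguous and the posterior splits them between the "
          "two sources; attribution is much sharper for distinct source "
          "communities (see tests and scripts/acceptance.py)")


if __name__ == "__main__":
    main()
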