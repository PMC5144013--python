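"""Signature index: group comparison, ROC/AUC, leave-one-out validation.

The per-sample index is the summed relative abundance of the panel
taxa.  Groups are compared with a two-sided Mann-Whitney U test, the
index's discriminative power is summarised by the ROC AUC, and
leave-one-out cross-validation refits the optimal cutoff on each
training fold to estimate out-of-sample accuracy/sensitivity/
specificity.

Run after 03_screen_signature.py:  python analysis/04_index_validation.py
"""

import json
from pathlib import Path

import microsig as ms

DATA = Path("results/data")
OUT = Path("results/index")


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    table = ms.read_taxon_table(DATA / "table.tsv")
    meta = ms.read_sample_metadata(DATA / "metadata.tsv")
    panel = ms.SignaturePanel.load(Path("results/screen/panel.txt"))

    report = ms.index_report(table.to_relative(), panel, meta["group"])
    report.index.to_csv(OUT / "index.tsv", sep="\t", index_label="sample_id")
    report.roc_points.to_csv(OUT / "roc.tsv", sep="\t", index=False)
    with open(OUT / "report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)

    stats = report.group_stats
    for group in stats.index:
        print(f"{group}: median index {stats.loc[group, 'median']:.3f} "
              f"(IQR {stats.loc[group, 'iqr']:.3f})")
    print(f"Mann-Whitney U = {report.u_statistic:.1f}, "
          f"two-sided p = {report.p_value:.2g}")
    print(f"ROC AUC = {report.auc:.3f} (positive class: {report.positive_group})")
    print(f"LOO cutoff CV: accuracy {report.loo.accuracy:.0%}, "
          f"sensitivity {report.loo.sensitivity:.0%}, "
          f"specificity {report.loo.specificity:.0%}")


if __name__ == "__main__":
    main()
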