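"""Differential-taxon screen and signature panel selection.

Kruskal-Wallis + bootstrap effect size (log10 ppm scale, threshold 2)
on the cohort's relative abundances, then selection of the KD-enriched
panel.  The selected panel is compared against the generator's planted
ground truth.

Run after 01_simulate_cohorts.py:  python analysis/03_screen_signature.py
"""

import json
from pathlib import Path

import microsig as ms

SEED = 20162
DATA = Path("results/data")
OUT = Path("results/screen")


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    table = ms.read_taxon_table(DATA / "table.tsv")
    meta = ms.read_sample_metadata(DATA / "metadata.tsv")
    truth = json.loads((DATA / "truth.json").read_text())

    rel = table.to_relative()
    res = ms.effect_size(rel, meta["group"], seed=SEED)
    res.frame.to_csv(OUT / "screen.tsv", sep="\t", index_label="taxon")

    panel = ms.select_signature(res, group="KD")
    panel.save(OUT / "panel.txt")

    n_sig = int(res.frame["passed"].sum())
    print(f"screen: {n_sig} of {len(res.frame)} taxa pass "
          f"(alpha={res.alpha}, log10 effect > {res.threshold})")
    print(f"KD-enriched panel ({len(panel)} taxa): {', '.join(panel.taxa)}")

    planted = set(truth["signature_taxa"])
    found = set(panel.taxa)
    print(f"vs ground truth: {len(found & planted)}/{len(planted)} planted "
          f"taxa recovered, {len(found - planted)} false positive(s)")


if __name__ == "__main__":
    main()
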