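#!/usr/bin/env python
"""CpG-density enrichment of tissue-specific and variable probe sets.

Hypergeometric tests of each probe subset (tissue-specific probes; variable
loci per tissue at SD > 0.1) against the analyzed population, per density
class (LC / IC / HC), with direction chosen by the observed overlap relative
to its expectation.
"""

from pathlib import Path

import pandas as pd

from methmatch.enrichment import enrichment_scan, enrichment_table
from methmatch.io import write_results
from methmatch.tissue import tissue_specificity_table
from methmatch.variability import variability_table, variable_loci

import _shared

ROOT = Path(__file__).resolve().parent.parent / "results"

if __name__ == "__main__":
    data = _shared.load_clean_cohort()
    spec = tissue_specificity_table(data)
    var = variability_table(data).set_index("probe_id")

    subsets = {
        "tissue_specific": spec.loc[spec["spec_class"] != "none", "probe_id"],
        "variable_a_sd01": variable_loci(var["sd_a"], 0.1),
        "variable_b_sd01": variable_loci(var["sd_b"], 0.1),
    }
    out = ROOT / "enrichment"
    out.mkdir(parents=True, exist_ok=True)
    frames = []
    for name, subset in subsets.items():
        if len(subset) == 0:
            print(f"{name}: empty subset, skipped")
            continue
        table = enrichment_table(enrichment_scan(subset, data.annotation))
        table.insert(0, "subset", name)
        frames.append(table)
        lc = table.set_index("category").loc["LC"]
        print(f"{name} (n = {len(subset)}): LC {lc['direction']} p = {lc['p']:.3g} "
              f"({int(lc['overlap'])} LC probes, {lc['expected']:.1f} expected)")
    write_results(pd.concat(frames, ignore_index=True), out / "enrichment.tsv")
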