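#!/usr/bin/env python
"""Inter-individual variability and its concordance between tissues.

Per probe: beta range and SD per tissue, Brown-Forsythe test of equal
variance on M-values with BH adjustment, the +/-20% variance-concordance
band, and the cross-tissue Pearson correlation of matched subject values
with Storey q-values.
"""

import json
from pathlib import Path

from methmatch.io import write_results
from methmatch.pipeline import percentage
from methmatch.variability import variability_table

import _shared

ROOT = Path(__file__).resolve().parent.parent / "results"

if __name__ == "__main__":
    data = _shared.load_clean_cohort()
    table = variability_table(data)

    out = ROOT / "variability"
    out.mkdir(parents=True, exist_ok=True)
    write_results(table, out / "variability.tsv")

    n = len(table)
    sig = table["levene_p_bh"] < 0.05
    b_larger = table["var_t_b"] > table["var_t_a"]
    within = int((table["concordance"] == "within_band").sum())
    summary = {
        "n_probes": n,
        "mean_range_a": table["range_a"].mean(),
        "mean_range_b": table["range_b"].mean(),
        "variable_sd_gt_01": {"a": int((table["sd_a"] > 0.1).sum()),
                              "b": int((table["sd_b"] > 0.1).sum())},
        "variable_sd_gt_03": {"a": int((table["sd_a"] > 0.3).sum()),
                              "b": int((table["sd_b"] > 0.3).sum())},
        "unequal_variance_bh": {"n": int(sig.sum()), "pct": percentage(int(sig.sum()), n),
                                "larger_in_a": int((sig & ~b_larger).sum()),
                                "larger_in_b": int((sig & b_larger).sum())},
        "unequal_variance_unadjusted": int((table["levene_p"] < 0.05).sum()),
        "band": {"within": within, "outside": n - within},
        "cross_r_gt_05": int((table["cross_r"].abs() > 0.5).sum()),
        "cross_r_q_le_025": int((table["cross_r_q"] <= 0.25).sum()),
        "cross_r_q_le_005": int((table["cross_r_q"] <= 0.05).sum()),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))

    print(f"mean beta range: tissue A {summary['mean_range_a']:.3f} vs "
          f"tissue B {summary['mean_range_b']:.3f}")
    print(f"variable loci (SD > 0.1): A {summary['variable_sd_gt_01']['a']}, "
          f"B {summary['variable_sd_gt_01']['b']}")
    u = summary["unequal_variance_bh"]
    print(f"unequal variance (Levene BH < 0.05): {u['n']} ({u['pct']}%), "
          f"{u['larger_in_a']} larger in A, {u['larger_in_b']} larger in B "
          f"(unadjusted p < 0.05: {summary['unequal_variance_unadjusted']})")
    print(f"variance band: {within} within +/-20%, {n - within} outside")
    print(f"cross-tissue |r| > 0.5: {summary['cross_r_gt_05']} probes "
          f"({summary['cross_r_q_le_025']} at q <= 0.25, "
          f"{summary['cross_r_q_le_005']} at q <= 0.05)")
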