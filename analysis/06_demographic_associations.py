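#!/usr/bin/env python
"""Probe-wise demographic association scans, per tissue.

Rank-sum tests for sex and ethnicity, Pearson correlation for age, BMI and
alcohol; Storey q-values; p-value-distribution diagnostics (left skew
signals likely association even when no probe survives q <= 0.05).
"""

import json
from pathlib import Path

from methmatch.demographics import association_scan
from methmatch.io import write_results

import _shared

ROOT = Path(__file__).resolve().parent.parent / "results"
VARIABLES = ["sex", "ethnicity", "age", "bmi", "alcohol"]

if __name__ == "__main__":
    data = _shared.load_clean_cohort()
    out = ROOT / "associations"
    out.mkdir(parents=True, exist_ok=True)
    diagnostics = {}
    for label, tissue in (("tissue_a", data.tissue_a), ("tissue_b", data.tissue_b)):
        scan = association_scan(tissue, data.samples, VARIABLES)
        write_results(scan.results, out / f"associations_{label}.tsv")
        diagnostics[label] = {v: d.to_dict() for v, d in scan.diagnostics.items()}
        print(f"{label}:")
        for var in VARIABLES:
            sub = scan.results[scan.results["variable"] == var]
            n_sig = int(sub["significant"].sum())
            n_eff = int((sub["significant"] & sub["large_effect"]).sum())
            frac = scan.diagnostics[var].frac_below_05
            print(f"  {var:10s} {n_sig:3d} probes at q <= 0.05 "
                  f"({n_eff} with |delta beta| > 5%); "
                  f"fraction of raw p < 0.05: {frac:.3f}")
    (out / "diagnostics.json").write_text(json.dumps(diagnostics, indent=2))
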