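#!/usr/bin/env python
"""Probe-level quality control on the simulated cohort.

Loads the cohort written by 01_simulate_cohort.py, aligns the two tissues,
removes SNP-overlapping, sex-chromosome, polymorphic, zero-heavy and
detection-failing probes, and replaces residual zero betas with the tissue
minimum. Writes the filtered matrices and a JSON report to results/qc/.
"""

import json
from pathlib import Path

from methmatch.datamodel import align_matched
from methmatch.io import (read_annotation, read_beta_matrix, read_sample_sheet,
                          write_beta_matrix)
from methmatch.qc import apply_qc

ROOT = Path(__file__).resolve().parent.parent / "results"

if __name__ == "__main__":
    cohort = ROOT / "cohort"
    a = read_beta_matrix(cohort / "beta_a.tsv", cohort / "detection_a.tsv", tissue="A")
    b = read_beta_matrix(cohort / "beta_b.tsv", cohort / "detection_b.tsv", tissue="B")
    data = align_matched(a, b, read_sample_sheet(cohort / "samples.tsv"),
                         read_annotation(cohort / "annotation.tsv"))
    clean, report = apply_qc(data)

    out = ROOT / "qc"
    out.mkdir(parents=True, exist_ok=True)
    write_beta_matrix(clean.tissue_a, out / "beta_a_filtered.tsv")
    write_beta_matrix(clean.tissue_b, out / "beta_b_filtered.tsv")
    (out / "qc_report.json").write_text(json.dumps(report.to_dict(), indent=2))

    print(f"input probes: {report.n_input}")
    for reason, probes in report.removed.items():
        print(f"  removed {len(probes):3d} for {reason}")
    print(f"retained: {report.n_retained} probes, {clean.n_subjects} subjects")
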