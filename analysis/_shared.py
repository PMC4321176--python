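"""Shared loading helper for the analysis drivers."""

from pathlib import Path

from methmatch.datamodel import MatchedDataset, align_matched
from methmatch.io import read_annotation, read_beta_matrix, read_sample_sheet
from methmatch.qc import apply_qc

ROOT = Path(__file__).resolve().parent.parent / "results"


def load_clean_cohort() -> MatchedDataset:
    """Load the simulated cohort and re-apply QC (cheap and deterministic)."""
    cohort = ROOT / "cohort"
    if not (cohort / "beta_a.tsv").exists():
        raise SystemExit("run analysis/01_simulate_cohort.py first")
    a = read_beta_matrix(cohort / "beta_a.tsv", cohort / "detection_a.tsv", tissue="A")
    b = read_beta_matrix(cohort / "beta_b.tsv", cohort / "detection_b.tsv", tissue="B")
    data = align_matched(a, b, read_sample_sheet(cohort / "samples.tsv"),
                         read_annotation(cohort / "annotation.tsv"))
    clean, _ = apply_qc(data)
    return clean
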