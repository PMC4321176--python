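#!/usr/bin/env python
"""Generate the synthetic matched cohort used by the downstream analyses.

Writes the four standard input files (beta matrices with detection p-values
for both tissues, sample sheet, probe annotation) plus the planted-truth
table to results/cohort/. 25 subjects, 998 clean probes plus 55 injected
QC-artifact probes.
"""

from pathlib import Path

from methmatch.cli import main as cli

OUT = Path(__file__).resolve().parent.parent / "results" / "cohort"

if __name__ == "__main__":
    cli(["simulate", "--seed", "1", "--out", str(OUT)], standalone_mode=False)
    print(f"cohort files in {OUT}")
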