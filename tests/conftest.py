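import numpy as np
import pandas as pd
import pytest

from methmatch import PipelineConfig, SimulationConfig, generate, run_pipeline
from methmatch.datamodel import BetaMatrix, MatchedDataset


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (25 subjects x 2 tissues, 998 clean probes)."""
    return generate(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def default_run():
    """Full pipeline result on the default synthetic cohort."""
    return run_pipeline(PipelineConfig(simulation=SimulationConfig(seed=1)))


@pytest.fixture(scope="session")
def small_config():
    """A fast small cohort for end-to-end plumbing tests."""
    return SimulationConfig(
        n_probes=150,
        seed=11,
        planted_assoc={"sex": {"n_probes": 10, "effect": 0.15}},
        qc_artifacts={"snp_overlap": 3, "sex_chromosome": 2, "polymorphic_cpg": 2,
                      "zero_heavy": 2, "detection_failure": 2},
    )


def make_matched(beta_a, beta_b, probe_ids=None, subjects=None, classes=None):
    """Build a minimal MatchedDataset from two probe x subject arrays."""
    beta_a = np.asarray(beta_a, dtype=float)
    beta_b = np.asarray(beta_b, dtype=float)
    n, ns = beta_a.shape
    probe_ids = probe_ids or [f"p{i}" for i in range(n)]
    subjects = subjects or [f"S{j}" for j in range(ns)]
    ann = pd.DataFrame(
        {
            "chromosome": ["chr1"] * n,
            "gene_symbol": [""] * n,
            "cpg_class": classes if classes is not None else ["HC"] * n,
            "gc_content": [0.6] * n,
            "obs_exp_cpg_ratio": [0.8] * n,
            "island_length": [600] * n,
            "snp_overlap": [False] * n,
            "polymorphic_cpg": [False] * n,
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    samples = pd.DataFrame(
        [
            {"sample_id": f"{s}_{t}", "subject_id": s, "tissue": t, "age": 30 + j,
             "sex": "male" if j % 2 else "female", "ethnicity": "caucasian",
             "bmi": 25.0, "alcohol": 1.0}
            for j, s in enumerate(subjects)
            for t in ("A", "B")
        ]
    )
    mk = lambda arr, t: BetaMatrix(
        pd.DataFrame(arr, index=pd.Index(probe_ids, name="probe_id"), columns=subjects),
        tissue=t,
    )
    return MatchedDataset(mk(beta_a, "A"), mk(beta_b, "B"), ann, samples, list(subjects))
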