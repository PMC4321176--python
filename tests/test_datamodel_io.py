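"""Data containers, CpG-class derivation, and delimited-text round trips."""

import numpy as np
import pandas as pd
import pytest

from methmatch.datamodel import BetaMatrix, align_matched, derive_cpg_class
from methmatch.io import (read_beta_matrix, read_results, write_beta_matrix,
                          write_results)
from methmatch.simulate import SimulationConfig, generate


def oracle_cpg_class(gc, oe, ln):
    """Independent restatement of the density rules as a truth table."""
    hc = (gc > 0.55) and (oe > 0.75) and (ln > 500)
    ic = (gc > 0.50) and (oe > 0.48) and (ln > 200)
    return "HC" if hc else ("IC" if ic else "LC")


@pytest.mark.parametrize(
    "gc,oe,ln,expected",
    [
        (0.60, 0.80, 600, "HC"),
        (0.52, 0.50, 300, "IC"),
        (0.40, 0.20, 100, "LC"),
        (0.55, 0.80, 600, "IC"),   # strict: gc exactly 0.55 fails the HC clause
        (0.56, 0.76, 501, "HC"),
        (0.56, 0.76, 500, "IC"),   # length exactly 500 fails HC, passes IC
        (0.50, 0.48, 200, "LC"),   # strict on every IC clause
    ],
)
def test_cpg_class_examples(gc, oe, ln, expected):
    assert derive_cpg_class(gc, oe, ln) == expected


def test_cpg_class_matches_truth_table_oracle():
    """Exhaustive agreement with the rule-by-rule oracle on a boundary grid."""
    for gc in (0.40, 0.50, 0.501, 0.55, 0.551, 0.70):
        for oe in (0.30, 0.48, 0.481, 0.75, 0.751, 1.0):
            for ln in (100, 200, 201, 500, 501, 900):
                assert derive_cpg_class(gc, oe, ln) == oracle_cpg_class(gc, oe, ln)


def test_cpg_class_rejects_negative_and_missing():
    with pytest.raises(ValueError):
        derive_cpg_class(-0.1, 0.8, 600)
    with pytest.raises(ValueError, match="uncategorized"):
        derive_cpg_class(float("nan"), 0.8, 600)


class TestBetaMatrix:
    def test_rejects_out_of_range_value_naming_cell(self):
        df = pd.DataFrame([[0.2, 1.2]], index=["cg1"], columns=["s1", "s2"])
        with pytest.raises(ValueError, match="cg1.*s2"):
            BetaMatrix(df)

    def test_rejects_duplicate_ids(self):
        df = pd.DataFrame([[0.2], [0.3]], index=["cg1", "cg1"], columns=["s1"])
        with pytest.raises(ValueError, match="duplicate probe"):
            BetaMatrix(df)

    def test_rejects_detection_shape_mismatch(self):
        beta = pd.DataFrame([[0.2, 0.3]], index=["cg1"], columns=["s1", "s2"])
        det = pd.DataFrame([[0.01]], index=["cg1"], columns=["s1"])
        with pytest.raises(ValueError, match="shape"):
            BetaMatrix(beta, det)


def test_read_beta_matrix_small_fixture(tmp_path):
    path = tmp_path / "beta.tsv"
    path.write_text(
        "probe_id\ts1\ts2\ncg1\t0.1\t0.2\ncg2\t0.3\t0.4\ncg3\t0.5\t0.6\n"
    )
    m = read_beta_matrix(path)
    assert list(m.probe_ids) == ["cg1", "cg2", "cg3"]
    assert list(m.sample_ids) == ["s1", "s2"]
    assert m.beta.to_numpy().tolist() == [[0.1, 0.2], [0.3, 0.4], [0.5, 0.6]]


def test_read_beta_matrix_rejects_bound_violation(tmp_path):
    path = tmp_path / "beta.tsv"
    path.write_text("probe_id\ts1\ncg1\t1.2\n")
    with pytest.raises(ValueError, match="cg1"):
        read_beta_matrix(path)


def test_beta_matrix_round_trip_full_cohort(tmp_path):
    """Write/read a 998 x 25 synthetic matrix: values survive bitwise."""
    data, _ = generate(SimulationConfig(seed=3, qc_artifacts={}))
    out = tmp_path / "a.tsv"
    write_beta_matrix(data.tissue_a, out)
    back = read_beta_matrix(out)
    assert back.probe_ids.equals(data.tissue_a.probe_ids)
    np.testing.assert_allclose(
        back.beta.to_numpy(), data.tissue_a.beta.to_numpy(), rtol=1e-9, atol=0
    )


def test_write_results_deterministic(tmp_path):
    table = pd.DataFrame({"probe_id": ["a", "b", "c"], "x": [0.1, 1 / 3, 2 / 7]})
    p1, p2 = tmp_path / "t1.tsv", tmp_path / "t2.tsv"
    write_results(table, p1)
    write_results(table, p2)
    assert p1.read_bytes() == p2.read_bytes()
    assert len(p1.read_text().splitlines()) == 4  # header + 3 rows
    back = read_results(p1)
    assert list(back["probe_id"]) == ["a", "b", "c"]
    np.testing.assert_allclose(back["x"], table["x"], rtol=1e-9)


def test_write_results_rejects_empty(tmp_path):
    with pytest.raises(ValueError):
        write_results(pd.DataFrame(), tmp_path / "empty.tsv")


class TestAlignMatched:
    def _parts(self, seed=5):
        cfg = SimulationConfig(
            n_probes=40, seed=seed, qc_artifacts={},
            planted_assoc={"sex": {"n_probes": 4, "effect": 0.15}},
        )
        data, _ = generate(cfg)
        return data

    def test_scrambled_probe_order_realigned(self):
        data = self._parts()
        rng = np.random.default_rng(0)
        perm = rng.permutation(data.n_probes)
        b_scrambled = BetaMatrix(
            data.tissue_b.beta.iloc[perm],
            data.tissue_b.detection_p.iloc[perm],
            tissue="B",
        )
        # columns must be sample ids as in the sample sheet for re-alignment
        a = data.tissue_a.beta.copy()
        a.columns = [f"{s}_A" for s in data.subject_order]
        b = b_scrambled.beta.copy()
        b.columns = [f"{s}_B" for s in data.subject_order]
        aligned = align_matched(
            BetaMatrix(a, tissue="A"), BetaMatrix(b, tissue="B"),
            data.samples, data.annotation,
        )
        assert aligned.tissue_a.probe_ids.equals(aligned.tissue_b.probe_ids)
        assert aligned.n_subjects == data.n_subjects
        pd.testing.assert_frame_equal(
            aligned.tissue_b.beta, data.tissue_b.beta, check_names=False
        )

    def test_subject_missing_one_tissue_dropped_with_warning(self):
        data = self._parts()
        a = data.tissue_a.beta.copy()
        a.columns = [f"{s}_A" for s in data.subject_order]
        b = data.tissue_b.beta.iloc[:, :-1].copy()
        b.columns = [f"{s}_B" for s in data.subject_order[:-1]]
        with pytest.warns(UserWarning, match="dropping 1 subject"):
            aligned = align_matched(
                BetaMatrix(a, tissue="A"), BetaMatrix(b, tissue="B"),
                data.samples, data.annotation,
            )
        assert aligned.n_subjects == data.n_subjects - 1

    def test_no_overlap_errors(self):
        data = self._parts()
        a = data.tissue_a.beta.copy()
        a.index = [f"other{i}" for i in range(len(a))]
        a.columns = [f"{s}_A" for s in data.subject_order]
        b = data.tissue_b.beta.copy()
        b.columns = [f"{s}_B" for s in data.subject_order]
        with pytest.raises(ValueError, match="no overlapping probes"):
            align_matched(BetaMatrix(a), BetaMatrix(b), data.samples, data.annotation)
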