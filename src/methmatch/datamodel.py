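"""Core containers for matched two-tissue methylation data.

A cohort is represented as two probe x sample beta-value matrices (one per
tissue), aligned so that column *j* in both matrices belongs to the same
subject and row *i* to the same CpG probe, together with a probe annotation
table (CpG-density class, SNP/polymorphism flags, chromosome) and a sample
sheet (subject id, tissue, demographics).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CPG_CLASSES = ("HC", "IC", "LC", "uncategorized")

#: annotation columns expected by downstream stages
ANNOTATION_COLUMNS = [
    "chromosome",
    "gene_symbol",
    "cpg_class",
    "gc_content",
    "obs_exp_cpg_ratio",
    "island_length",
    "snp_overlap",
    "polymorphic_cpg",
]

SAMPLE_COLUMNS = ["sample_id", "subject_id", "tissue", "age", "sex", "ethnicity", "bmi", "alcohol"]


def derive_cpg_class(gc_content: float, obs_exp: float, length: float) -> str:
    """Classify a CpG island context as high / intermediate / low density.

    High density (HC): GC content > 0.55, observed/expected CpG ratio > 0.75
    and island length > 500 bp. Intermediate (IC): GC > 0.50, obs/exp > 0.48
    and length > 200 bp. Everything else is low density (LC). Inequalities
    are strict, and the HC rule takes precedence where both rules hold.

    Parameters
    ----------
    gc_content : GC fraction of the island, in [0, 1].
    obs_exp : observed/expected CpG dinucleotide ratio, >= 0.
    length : island length in base pairs.

    Returns
    -------
    One of ``"HC"``, ``"IC"``, ``"LC"``.
    """
    for name, v in (("gc_content", gc_content), ("obs_exp", obs_exp), ("length", length)):
        if v is None or (isinstance(v, float) and np.isnan(v)):
            raise ValueError(f"derive_cpg_class: missing metric {name!r}; "
                             "callers should assign 'uncategorized' instead")
        if v < 0:
            raise ValueError(f"derive_cpg_class: negative {name} ({v})")
    if gc_content > 0.55 and obs_exp > 0.75 and length > 500:
        return "HC"
    if gc_content > 0.50 and obs_exp > 0.48 and length > 200:
        return "IC"
    return "LC"


@dataclass
class BetaMatrix:
    """Probe x sample methylation fractions for one tissue.

    ``beta`` is a DataFrame with probe ids as the index and sample ids as
    columns; all values lie in [0, 1]. ``detection_p`` (optional) is a
    same-shaped matrix of detection p-values: large values mean the probe's
    signal was indistinguishable from array background in that sample.
    """

    beta: pd.DataFrame
    detection_p: pd.DataFrame | None = None
    tissue: str = ""

    def __post_init__(self) -> None:
        if self.beta.index.has_duplicates:
            dups = self.beta.index[self.beta.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate probe ids: {dups[:5]}")
        if self.beta.columns.has_duplicates:
            dups = self.beta.columns[self.beta.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups[:5]}")
        vals = self.beta.to_numpy(dtype=float)
        bad = ~((vals >= 0.0) & (vals <= 1.0))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"beta value out of [0, 1] at probe {self.beta.index[i]!r}, "
                f"sample {self.beta.columns[j]!r}: {vals[i, j]!r}"
            )
        if self.detection_p is not None:
            if self.detection_p.shape != self.beta.shape:
                raise ValueError(
                    f"detection matrix shape {self.detection_p.shape} does not "
                    f"match beta matrix shape {self.beta.shape}"
                )
            self.detection_p = self.detection_p.reindex(
                index=self.beta.index, columns=self.beta.columns
            )
            if self.detection_p.isna().any().any():
                raise ValueError("detection matrix ids do not match beta matrix ids")

    @property
    def probe_ids(self) -> pd.Index:
        return self.beta.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.beta.columns

    @property
    def n_probes(self) -> int:
        return self.beta.shape[0]

    @property
    def n_samples(self) -> int:
        return self.beta.shape[1]

    def subset_probes(self, probe_ids) -> "BetaMatrix":
        det = self.detection_p.loc[probe_ids] if self.detection_p is not None else None
        return BetaMatrix(self.beta.loc[probe_ids], det, tissue=self.tissue)


@dataclass
class MatchedDataset:
    """Two subject-aligned :class:`BetaMatrix` objects plus metadata.

    Invariants: both tissues carry the same probes in the same order; column
    *j* of both matrices belongs to ``subject_order[j]``; ``annotation``
    covers every probe.
    """

    tissue_a: BetaMatrix
    tissue_b: BetaMatrix
    annotation: pd.DataFrame
    samples: pd.DataFrame
    subject_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.tissue_a.probe_ids.equals(self.tissue_b.probe_ids):
            raise ValueError("tissue matrices do not share an identical probe order")
        n = self.tissue_a.n_samples
        if self.tissue_b.n_samples != n or len(self.subject_order) != n:
            raise ValueError("subject alignment broken: column counts differ")
        missing = self.tissue_a.probe_ids.difference(self.annotation.index)
        if len(missing):
            raise ValueError(f"annotation missing {len(missing)} probes, e.g. {list(missing[:3])}")
        # keep annotation in probe order, restricted to the analyzed universe
        self.annotation = self.annotation.loc[self.tissue_a.probe_ids]

    @property
    def probe_ids(self) -> pd.Index:
        return self.tissue_a.probe_ids

    @property
    def n_probes(self) -> int:
        return self.tissue_a.n_probes

    @property
    def n_subjects(self) -> int:
        return len(self.subject_order)

    def subset_probes(self, probe_ids) -> "MatchedDataset":
        return MatchedDataset(
            self.tissue_a.subset_probes(probe_ids),
            self.tissue_b.subset_probes(probe_ids),
            self.annotation.loc[probe_ids],
            self.samples,
            list(self.subject_order),
        )


def align_matched(
    a: BetaMatrix,
    b: BetaMatrix,
    samples: pd.DataFrame,
    annotation: pd.DataFrame,
) -> MatchedDataset:
    """Align two tissue matrices into a matched dataset.

    Probes are reordered to their common order (following tissue A's order);
    subjects present in both tissues are retained, and subjects missing one
    tissue are dropped with a warning. Sample columns are relabelled by
    subject id.
    """
    common = a.probe_ids.intersection(b.probe_ids)
    if len(common) == 0:
        raise ValueError("no overlapping probes between the two tissues")
    order = a.probe_ids[a.probe_ids.isin(common)]

    smap = samples.set_index("sample_id") if "sample_id" in samples.columns else samples
    tissues = sorted(smap["tissue"].unique())
    if len(tissues) != 2:
        raise ValueError(f"sample sheet must describe exactly 2 tissues, got {tissues}")
    t_a, t_b = tissues

    def subjects_of(m: BetaMatrix, tissue: str) -> dict[str, str]:
        out = {}
        for sid in m.sample_ids:
            if sid not in smap.index:
                raise ValueError(f"sample {sid!r} absent from sample sheet")
            if smap.at[sid, "tissue"] != tissue:
                continue
            out[smap.at[sid, "subject_id"]] = sid
        return out

    subj_a = subjects_of(a, t_a)
    subj_b = subjects_of(b, t_b)
    shared = [s for s in subj_a if s in subj_b]
    if not shared:
        raise ValueError("no subjects present in both tissues")
    dropped = sorted(set(subj_a) ^ set(subj_b))
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} subject(s) missing one tissue: {dropped}",
            stacklevel=2,
        )

    def rebuild(m: BetaMatrix, mapping: dict[str, str], tissue: str) -> BetaMatrix:
        cols = [mapping[s] for s in shared]
        beta = m.beta.loc[order, cols]
        beta.columns = shared
        det = None
        if m.detection_p is not None:
            det = m.detection_p.loc[order, cols]
            det.columns = shared
        return BetaMatrix(beta, det, tissue=tissue)

    return MatchedDataset(
        rebuild(a, subj_a, t_a),
        rebuild(b, subj_b, t_b),
        annotation,
        samples,
        shared,
    )
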