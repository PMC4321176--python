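"""Probe-level quality control for matched two-tissue methylation data.

Filters remove probes that (1) overlap a SNP, (2) sit on a sex chromosome,
(3) contain a polymorphic CpG, (4) are zero in more than ``max_zero_subjects``
subjects in either tissue, or (5) fail background detection in more than
``max_detection_failures`` subjects in either tissue. A probe failing any
enabled rule is removed from both tissues, because every downstream statistic
is matched. Remaining exact-zero measurements are then replaced by the
smallest strictly positive value observed in that tissue.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamodel import BetaMatrix, MatchedDataset

SEX_CHROMOSOMES = {"x", "y", "chrx", "chry"}


@dataclass
class QCConfig:
    """Filtering thresholds.

    ``max_zero_subjects`` defaults to ``n_subjects - 2`` at run time: a probe
    is dropped when *more than* that many subjects have beta exactly 0.
    ``max_detection_failures`` is the strict count of subjects allowed with
    detection p-value above ``detection_alpha`` before a probe is dropped.
    """

    drop_snp_probes: bool = True
    drop_sex_chromosomes: bool = True
    drop_polymorphic: bool = True
    max_zero_subjects: int | None = None  # None -> n_subjects - 2
    max_detection_failures: int = 3
    detection_alpha: float = 0.05
    use_detection: bool = True

    def resolved_max_zero(self, n_subjects: int) -> int:
        mz = n_subjects - 2 if self.max_zero_subjects is None else self.max_zero_subjects
        if mz < 0 or mz > n_subjects:
            raise ValueError(f"max_zero_subjects {mz} outside [0, {n_subjects}]")
        return mz


@dataclass
class QCReport:
    removed: dict[str, list[str]] = field(default_factory=dict)
    n_input: int = 0
    n_retained: int = 0

    @property
    def removed_union(self) -> set[str]:
        out: set[str] = set()
        for probes in self.removed.values():
            out.update(probes)
        return out

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "n_removed": len(self.removed_union),
            "removed": {k: sorted(v) for k, v in self.removed.items()},
        }


def _is_sex_chromosome(chrom) -> bool:
    return isinstance(chrom, str) and chrom.strip().lower() in SEX_CHROMOSOMES


def filter_probes(data: MatchedDataset, config: QCConfig | None = None) -> tuple[MatchedDataset, QCReport]:
    """Apply probe-level filters; returns the filtered dataset and a report."""
    config = config or QCConfig()
    ann = data.annotation
    report = QCReport(n_input=data.n_probes)
    max_zero = config.resolved_max_zero(data.n_subjects)

    if config.drop_snp_probes:
        hit = ann.index[ann["snp_overlap"].astype(bool)]
        if len(hit):
            report.removed["snp_overlap"] = list(hit)
    if config.drop_sex_chromosomes:
        hit = ann.index[ann["chromosome"].map(_is_sex_chromosome)]
        if len(hit):
            report.removed["sex_chromosome"] = list(hit)
    if config.drop_polymorphic:
        hit = ann.index[ann["polymorphic_cpg"].astype(bool)]
        if len(hit):
            report.removed["polymorphic_cpg"] = list(hit)

    zero_a = (data.tissue_a.beta.to_numpy() == 0.0).sum(axis=1)
    zero_b = (data.tissue_b.beta.to_numpy() == 0.0).sum(axis=1)
    hit = data.probe_ids[(zero_a > max_zero) | (zero_b > max_zero)]
    if len(hit):
        report.removed["zero_prevalence"] = list(hit)

    if config.use_detection:
        if data.tissue_a.detection_p is None or data.tissue_b.detection_p is None:
            raise ValueError(
                "detection p-value matrix absent; pass use_detection=False to "
                "skip the background-detection filter"
            )
        fail_a = (data.tissue_a.detection_p.to_numpy() > config.detection_alpha).sum(axis=1)
        fail_b = (data.tissue_b.detection_p.to_numpy() > config.detection_alpha).sum(axis=1)
        hit = data.probe_ids[
            (fail_a > config.max_detection_failures) | (fail_b > config.max_detection_failures)
        ]
        if len(hit):
            report.removed["detection_failure"] = list(hit)

    removed = report.removed_union
    keep = data.probe_ids[~data.probe_ids.isin(removed)]
    report.n_retained = len(keep)
    if report.n_retained == 0:
        raise ValueError("quality control removed every probe")
    return data.subset_probes(keep), report


def replace_zeros(matrix: BetaMatrix) -> BetaMatrix:
    """Replace exact-zero betas by the tissue-wide minimum positive beta."""
    vals = matrix.beta.to_numpy(dtype=float)
    positive = vals[vals > 0]
    if positive.size == 0:
        raise ValueError("all-zero beta matrix: no positive value to substitute")
    if not (vals == 0.0).any():
        return matrix
    floor = positive.min()
    beta = matrix.beta.where(matrix.beta != 0.0, floor)
    return BetaMatrix(beta, matrix.detection_p, tissue=matrix.tissue)


def apply_qc(data: MatchedDataset, config: QCConfig | None = None) -> tuple[MatchedDataset, QCReport]:
    """Full QC: filter probes, then replace residual zeros per tissue."""
    filtered, report = filter_probes(data, config)
    out = MatchedDataset(
        replace_zeros(filtered.tissue_a),
        replace_zeros(filtered.tissue_b),
        filtered.annotation,
        filtered.samples,
        filtered.subject_order,
    )
    return out, report


__all__ = ["QCConfig", "QCReport", "filter_probes", "replace_zeros", "apply_qc"]
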