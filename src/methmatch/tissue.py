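"""Between-tissue methylation differences: paired tests, delta-beta classes,
methylation categories, one-way intraclass correlation, and sample-wise
correlation structure.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datamodel import CPG_CLASSES, MatchedDataset

SMALLEST_P = np.nextafter(0.0, 1.0)


def paired_ttest(x, y) -> tuple[float, float]:
    """Two-tailed paired t-test on matched measurements.

    Equivalent to a one-sample t-test on the differences d = y - x with
    t = mean(d) / (sd(d)/sqrt(n)) and n - 1 degrees of freedom.

    Degenerate cases: all differences zero -> (0, 1); constant nonzero
    difference (zero spread) -> t is signed infinity and p is the smallest
    positive float, so the probe sorts to the top rather than propagating NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired_ttest: unequal lengths")
    n = x.size
    if n < 3:
        raise ValueError(f"paired_ttest needs n >= 3 pairs, got {n}")
    d = y - x
    sd = d.std(ddof=1)
    # constant differences (to float precision): degenerate branches
    if sd <= 1e-12 * max(1.0, abs(d[0])):
        if d[0] == 0.0:
            return 0.0, 1.0
        return math.copysign(math.inf, d[0]), SMALLEST_P
    t = d.mean() / (sd / math.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return float(t), float(p)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def classify_specificity(
    p_bh: float,
    delta_beta: float,
    p_threshold: float = 0.001,
    delta_threshold: float = 0.2,
    high_delta_threshold: float = 0.4,
) -> str:
    """Label a probe's tissue specificity from its adjusted p and delta-beta.

    ``highly_tissue_specific``: p < 0.001 and |delta| > 0.4;
    ``tissue_specific``: p < 0.001 and |delta| > 0.2; else ``none``.
    """
    if p_bh < p_threshold and abs(delta_beta) > high_delta_threshold:
        return "highly_tissue_specific"
    if p_bh < p_threshold and abs(delta_beta) > delta_threshold:
        return "tissue_specific"
    return "none"


def methylation_category(mean_beta: float) -> str:
    """hypomethylated (<0.20), heterogeneous ([0.20, 0.80]), hypermethylated (>0.80)."""
    if not 0.0 <= mean_beta <= 1.0:
        raise ValueError(f"mean beta {mean_beta} outside [0, 1]")
    if mean_beta < 0.20:
        return "hypomethylated"
    if mean_beta > 0.80:
        return "hypermethylated"
    return "heterogeneous"


def icc_oneway(a, b) -> float:
    """One-way consistency intraclass correlation for two measurements/subject.

    From the one-way ANOVA table with subject as the grouping factor and
    k = 2 measurements (one per tissue):

        ICC = (MS_between_subjects - MS_within_subjects)
            / (MS_between_subjects + MS_within_subjects)

    MS_between_subjects reflects inter-individual spread; MS_within_subjects
    reflects the per-subject between-tissue difference, so ICC approaches -1
    when the tissues differ far more than the individuals do, and +1 when
    individuals differ but the tissues agree. Bounded in [-1, 1] for k = 2.

    Returns NaN when the total variance is zero (ICC undefined).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("icc_oneway needs n >= 2 matched pairs")
    n = a.size
    subj_mean = (a + b) / 2.0
    grand = subj_mean.mean()
    ss_between = 2.0 * np.sum((subj_mean - grand) ** 2)
    ss_within = np.sum((a - subj_mean) ** 2) + np.sum((b - subj_mean) ** 2)
    if ss_between + ss_within == 0.0:
        return float("nan")
    ms_between = ss_between / (n - 1)  # df = n - 1
    ms_within = ss_within / n          # df = n (k - 1) = n
    return float((ms_between - ms_within) / (ms_between + ms_within))


def tissue_specificity_table(
    data: MatchedDataset,
    p_threshold: float = 0.001,
    delta_threshold: float = 0.2,
    high_delta_threshold: float = 0.4,
) -> pd.DataFrame:
    """Per-probe tissue-specificity statistics for a matched dataset.

    delta_beta is mean(tissue B) - mean(tissue A).
    """
    A = data.tissue_a.beta.to_numpy(dtype=float)
    B = data.tissue_b.beta.to_numpy(dtype=float)
    stats_rows = [paired_ttest(A[i], B[i]) for i in range(A.shape[0])]
    t_stat = np.array([r[0] for r in stats_rows])
    p_raw = np.array([r[1] for r in stats_rows])
    p_bh = bh_adjust(p_raw)
    mean_a = A.mean(axis=1)
    mean_b = B.mean(axis=1)
    delta = mean_b - mean_a
    icc = np.array([icc_oneway(A[i], B[i]) for i in range(A.shape[0])])
    spec = [
        classify_specificity(pb, d, p_threshold, delta_threshold, high_delta_threshold)
        for pb, d in zip(p_bh, delta)
    ]
    return pd.DataFrame(
        {
            "probe_id": data.probe_ids,
            "cpg_class": data.annotation["cpg_class"].to_numpy(),
            "mean_beta_a": mean_a,
            "mean_beta_b": mean_b,
            "delta_beta": delta,
            "t_stat": t_stat,
            "p_raw": p_raw,
            "p_bh": p_bh,
            "spec_class": spec,
            "icc": icc,
            "category_a": [methylation_category(m) for m in mean_a],
            "category_b": [methylation_category(m) for m in mean_b],
        }
    ).reset_index(drop=True)


@dataclass
class CorrelationSummary:
    """Sample-wise Pearson correlation structure of a matched dataset."""

    within_a: np.ndarray
    within_b: np.ndarray
    between: np.ndarray
    between_mode: str
    between_by_class: dict[str, float] = field(default_factory=dict)

    @property
    def mean_within_a(self) -> float:
        return float(np.mean(self.within_a))

    @property
    def mean_within_b(self) -> float:
        return float(np.mean(self.within_b))

    @property
    def mean_between(self) -> float:
        return float(np.mean(self.between))


def _upper_triangle(corr: np.ndarray) -> np.ndarray:
    iu = np.triu_indices_from(corr, k=1)
    return corr[iu]


def _matched_between(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    out = []
    for j in range(A.shape[1]):
        a, b = A[:, j], B[:, j]
        if a.std() == 0 or b.std() == 0:
            warnings.warn(f"zero-variance profile at subject column {j}; pair skipped",
                          stacklevel=2)
            continue
        out.append(np.corrcoef(a, b)[0, 1])
    return np.asarray(out)


def samplewise_correlations(data: MatchedDataset, between_mode: str = "matched") -> CorrelationSummary:
    """Pearson correlations of whole-sample methylation profiles.

    Within-tissue coefficients cover every unordered sample pair inside a
    tissue (n(n-1)/2 per tissue, computed over probes). Between-tissue
    coefficients pair each subject's tissue-A profile with the same subject's
    tissue-B profile (``matched``) or with every tissue-B profile (``all``).
    Per-CpG-class between-tissue means are computed on probe subsets.
    """
    if data.n_subjects < 2 or data.n_probes < 2:
        raise ValueError("need at least 2 subjects and 2 probes")
    A = data.tissue_a.beta.to_numpy(dtype=float)
    B = data.tissue_b.beta.to_numpy(dtype=float)
    within_a = _upper_triangle(np.corrcoef(A, rowvar=False))
    within_b = _upper_triangle(np.corrcoef(B, rowvar=False))
    if between_mode == "matched":
        between = _matched_between(A, B)
    elif between_mode == "all":
        n = A.shape[1]
        cross = np.corrcoef(A, B, rowvar=False)[:n, n:]
        between = cross.ravel()
    else:
        raise ValueError(f"unknown between_mode {between_mode!r}")

    by_class: dict[str, float] = {}
    classes = data.annotation["cpg_class"]
    for cls in CPG_CLASSES:
        mask = (classes == cls).to_numpy()
        if mask.sum() < 2:
            continue
        vals = _matched_between(A[mask], B[mask])
        if len(vals):
            by_class[cls] = float(np.mean(vals))
    return CorrelationSummary(within_a, within_b, between, between_mode, by_class)


def global_tissue_test(data: MatchedDataset) -> dict:
    """Global between-tissue shift: exact Wilcoxon signed-rank on subject means.

    Each subject is reduced to its mean beta over all retained probes in each
    tissue; the two-tailed exact signed-rank test is applied to the 25 paired
    means (zero differences dropped, per the signed-rank convention).
    """
    if data.n_subjects < 5:
        raise ValueError("global test needs at least 5 subjects")
    mean_a = data.tissue_a.beta.mean(axis=0).to_numpy()
    mean_b = data.tissue_b.beta.mean(axis=0).to_numpy()
    d = mean_b - mean_a
    nz = d[d != 0.0]
    result = {
        "subject_means_a": mean_a,
        "subject_means_b": mean_b,
        "n_subjects": data.n_subjects,
        "n_b_greater": int((d > 0).sum()),
        "n_zero_differences": int((d == 0).sum()),
    }
    if nz.size == 0:
        result.update(statistic=float("nan"), p=float("nan"), defined=False)
        return result
    try:
        stat, p = stats.wilcoxon(nz, alternative="two-sided", method="exact")
    except ValueError:  # ties prevent the exact distribution
        stat, p = stats.wilcoxon(nz, alternative="two-sided", method="approx")
    result.update(statistic=float(stat), p=float(p), defined=True)
    return result
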