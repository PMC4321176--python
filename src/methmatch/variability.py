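"""Inter-individual variability and its concordance across tissues.

Per probe and tissue: beta range, SD, and variance on a variance-stabilized
scale; Levene/Brown-Forsythe tests of equal variance between tissues; a
+/-20% variance-concordance band; and probe-wise cross-tissue Pearson
correlation with q-value FDR.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import MatchedDataset
from .demographics import storey_qvalue
from .tissue import bh_adjust


def mean_normalize(values) -> np.ndarray:
    """Center per-subject values on their mean; outputs sum to zero."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("mean_normalize needs n >= 2")
    return v - v.mean()


def probe_range(values) -> float:
    """Inter-individual beta range, max - min."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("probe_range needs n >= 2")
    return float(v.max() - v.min())


def beta_transform(beta, mode: str = "logit") -> np.ndarray:
    """Variance-stabilizing transform for beta values in (0, 1).

    ``logit`` (default): log2(beta / (1 - beta)), the M-value; spreads out the
    compressed variance near 0 and 1. ``arcsine``: arcsin(sqrt(beta)). Both
    are strictly monotone on (0, 1).
    """
    b = np.asarray(beta, dtype=float)
    if np.any((b <= 0.0) | (b >= 1.0)):
        raise ValueError(
            "beta_transform requires values strictly inside (0, 1); replace "
            "exact zeros first (qc.replace_zeros) and cap exact ones symmetrically"
        )
    if mode == "logit":
        return np.log2(b / (1.0 - b))
    if mode == "arcsine":
        return np.arcsin(np.sqrt(b))
    raise ValueError(f"unknown transform mode {mode!r}")


def inverse_beta_transform(values, mode: str = "logit") -> np.ndarray:
    v = np.asarray(values, dtype=float)
    if mode == "logit":
        e = np.exp2(v)
        return e / (1.0 + e)
    if mode == "arcsine":
        return np.sin(v) ** 2
    raise ValueError(f"unknown transform mode {mode!r}")


def levene_test(group_a, group_b, center: str = "median") -> tuple[float, float]:
    """Levene's test of equal variance between two groups.

    The W statistic is a one-way ANOVA F on absolute deviations from each
    group's center, with (1, n_a + n_b - 2) degrees of freedom. The default
    median center is the Brown-Forsythe variant. Zero spread in both groups
    gives (0, 1).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("levene_test needs n >= 3 per group")
    cfun = np.median if center == "median" else np.mean
    if np.all(np.abs(a - cfun(a)) == 0) and np.all(np.abs(b - cfun(b)) == 0):
        return 0.0, 1.0
    stat, p = stats.levene(a, b, center=center)
    return float(stat), float(p)


def variance_concordance(var_a: float, var_b: float, band: float = 0.20) -> str:
    """Classify variance agreement: is var_b within +/-band of var_a?

    ``within_band`` iff var_b in [(1-band)*var_a, (1+band)*var_a], closed.
    """
    if var_a < 0 or var_b < 0:
        raise ValueError("variances must be nonnegative")
    if var_a == 0:
        warnings.warn("reference variance is zero; classified outside_band", stacklevel=2)
        return "outside_band"
    lo, hi = (1.0 - band) * var_a, (1.0 + band) * var_a
    return "within_band" if lo <= var_b <= hi else "outside_band"


def variable_loci(sds: pd.Series, threshold: float) -> pd.Index:
    """Probes whose raw-beta SD strictly exceeds the cutoff."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return sds.index[sds > threshold]


def cross_tissue_probe_correlation(data: MatchedDataset) -> pd.DataFrame:
    """Probe-wise Pearson correlation of matched subject values across tissues.

    Measures whether an individual's relative methylation level at a probe is
    preserved from one tissue to the other. Probes with zero variance in
    either tissue get NaN and are excluded from the q-value computation.
    """
    if data.n_subjects < 4:
        raise ValueError("need at least 4 subjects")
    A = data.tissue_a.beta.to_numpy(dtype=float)
    B = data.tissue_b.beta.to_numpy(dtype=float)
    r = np.full(A.shape[0], np.nan)
    p = np.full(A.shape[0], np.nan)
    for i in range(A.shape[0]):
        if A[i].std() == 0 or B[i].std() == 0:
            continue
        res = stats.pearsonr(A[i], B[i])
        r[i], p[i] = res.statistic, res.pvalue
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.sum():
        q[ok], _ = storey_qvalue(p[ok])
    return pd.DataFrame(
        {"probe_id": data.probe_ids, "cross_r": r, "cross_p": p, "cross_r_q": q}
    ).reset_index(drop=True)


def variability_table(
    data: MatchedDataset,
    transform: str = "logit",
    band: float = 0.20,
    levene_center: str = "median",
    band_scale: str = "transformed",
) -> pd.DataFrame:
    """Per-probe variability statistics for a matched dataset.

    Ranges and SDs are on the raw beta scale; variances entering the Levene
    test and the concordance band are on the transformed scale (set
    ``band_scale="raw"`` for a raw-beta sensitivity analysis). The variance
    ratio is tissue B over tissue A.
    """
    A = data.tissue_a.beta.to_numpy(dtype=float)
    B = data.tissue_b.beta.to_numpy(dtype=float)
    TA = beta_transform(A, mode=transform)
    TB = beta_transform(B, mode=transform)
    n = A.shape[0]
    lev = [levene_test(TA[i], TB[i], center=levene_center) for i in range(n)]
    levene_stat = np.array([v[0] for v in lev])
    levene_p = np.array([v[1] for v in lev])
    var_t_a = TA.var(axis=1, ddof=1)
    var_t_b = TB.var(axis=1, ddof=1)
    band_a, band_b = (var_t_a, var_t_b) if band_scale == "transformed" else (
        A.var(axis=1, ddof=1), B.var(axis=1, ddof=1))
    conc = [variance_concordance(band_a[i], band_b[i], band) for i in range(n)]
    cross = cross_tissue_probe_correlation(data)
    table = pd.DataFrame(
        {
            "probe_id": data.probe_ids,
            "cpg_class": data.annotation["cpg_class"].to_numpy(),
            "range_a": A.max(axis=1) - A.min(axis=1),
            "range_b": B.max(axis=1) - B.min(axis=1),
            "sd_a": A.std(axis=1, ddof=1),
            "sd_b": B.std(axis=1, ddof=1),
            "var_t_a": var_t_a,
            "var_t_b": var_t_b,
            "variance_ratio": var_t_b / var_t_a,
            "levene_stat": levene_stat,
            "levene_p": levene_p,
            "levene_p_bh": bh_adjust(levene_p),
            "concordance": conc,
        }
    ).reset_index(drop=True)
    return table.merge(cross, on="probe_id")
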