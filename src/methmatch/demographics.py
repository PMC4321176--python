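"""Probe-wise association of methylation with demographic variables.

Categorical variables (sex, ethnicity) use the two-tailed Wilcoxon rank-sum
test; continuous variables (age, BMI, alcohol) use two-tailed Pearson
correlation. Multiple testing is controlled with Storey's q-value, and the
shape of each variable's raw p-value distribution is summarized because a
left-skewed distribution signals a likely real association even when no
single probe survives FDR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import BetaMatrix

DEFAULT_TESTS = {
    "sex": "ranksum",
    "ethnicity": "ranksum",
    "age": "pearson",
    "bmi": "pearson",
    "alcohol": "pearson",
}


def ranksum_association(betas, groups) -> tuple[float, float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test for a binary variable.

    Exact null distribution when the combined n <= 50 and there are no ties,
    normal approximation with continuity correction otherwise. The effect is
    the difference of group mean betas (second sorted level minus first).
    """
    b = np.asarray(betas, dtype=float)
    g = np.asarray(groups)
    levels = sorted(pd.unique(g))
    if len(levels) != 2:
        raise ValueError(f"groups must be binary, got levels {levels}")
    x = b[g == levels[0]]
    y = b[g == levels[1]]
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 members")
    effect = float(y.mean() - x.mean())
    if np.all(b == b[0]):
        return float(x.size * y.size / 2.0), 1.0, effect
    ties = len(np.unique(b)) < b.size
    method = "exact" if (b.size <= 50 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue), effect


def pearson_association(betas, covariate) -> tuple[float, float]:
    """Two-tailed Pearson correlation with p from the t transformation."""
    b = np.asarray(betas, dtype=float)
    c = np.asarray(covariate, dtype=float)
    if b.size != c.size or b.size < 4:
        raise ValueError("pearson_association needs n >= 4 matched values")
    if np.all(c == c[0]):
        raise ValueError("constant covariate")
    if np.all(b == b[0]):
        return 0.0, 1.0
    res = stats.pearsonr(b, c)
    return float(res.statistic), float(res.pvalue)


def storey_qvalue(p, lambda_grid=None, pi0: float | None = None) -> tuple[np.ndarray, float]:
    """Storey q-values with smoother-based estimation of the null proportion.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) is evaluated on a grid
    (default 0.05, 0.10, ..., 0.95); a cubic polynomial fit over the grid is
    evaluated at the largest lambda and clamped to (0, 1]. For small inputs
    (m < 100) a fixed lambda = 0.5 keeps the estimate stable. q-values follow
    the step-up rule q_(i) = min_{j >= i} min(1, pi0 * m * p_(j) / j) and are
    returned in input order. With pi0 = 1 this reduces exactly to
    Benjamini-Hochberg.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    m = p.size
    if pi0 is None:
        if m < 100:
            lam = 0.5
            pi0 = (p > lam).sum() / (m * (1.0 - lam))
        else:
            grid = np.arange(0.05, 0.951, 0.05) if lambda_grid is None else np.asarray(lambda_grid)
            pi0_lam = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in grid])
            coef = np.polyfit(grid, pi0_lam, deg=3)
            pi0 = float(np.polyval(coef, grid.max()))
    pi0 = min(max(float(pi0), np.finfo(float).tiny), 1.0)
    order = np.argsort(p, kind="mergesort")
    q_sorted = np.minimum(pi0 * m * p[order] / np.arange(1, m + 1), 1.0)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = q_sorted
    return q, pi0


@dataclass
class PvalueDiagnostics:
    """Shape summary of one variable's raw p-value distribution."""

    variable: str
    histogram: np.ndarray  # 20 bins of width 0.05
    frac_below_05: float
    ks_stat: float
    pi0_hat: float

    def to_dict(self) -> dict:
        return {
            "variable": self.variable,
            "histogram": self.histogram.tolist(),
            "frac_below_05": self.frac_below_05,
            "ks_stat": self.ks_stat,
            "pi0_hat": self.pi0_hat,
        }


@dataclass
class AssociationScan:
    results: pd.DataFrame
    diagnostics: dict[str, PvalueDiagnostics] = field(default_factory=dict)


def _diagnostics(variable: str, p: np.ndarray, pi0: float) -> PvalueDiagnostics:
    hist, _ = np.histogram(p, bins=np.linspace(0, 1, 21))
    ks = stats.kstest(p, "uniform").statistic
    return PvalueDiagnostics(variable, hist, float((p < 0.05).mean()), float(ks), pi0)


def association_scan(
    tissue: BetaMatrix,
    samples: pd.DataFrame,
    variables,
    tests: dict[str, str] | None = None,
    q_threshold: float = 0.05,
    effect_threshold: float = 0.05,
) -> AssociationScan:
    """Scan every probe of one tissue for association with each variable.

    ``samples`` must be indexed (or indexable) by subject id matching the
    tissue's column order. For categorical variables the effect is the group
    mean-beta difference; for continuous variables it is the fitted beta
    difference between the smallest and largest covariate value under the
    least-squares line, so the "delta beta > 5%" filter has one meaning for
    both kinds of test.
    """
    tests = {**DEFAULT_TESTS, **(tests or {})}
    meta = samples.set_index("subject_id") if "subject_id" in samples.columns else samples
    meta = meta.loc[~meta.index.duplicated()]
    meta = meta.loc[list(tissue.sample_ids)]
    B = tissue.beta.to_numpy(dtype=float)
    frames = []
    diagnostics: dict[str, PvalueDiagnostics] = {}
    for var in variables:
        if var not in meta.columns:
            raise ValueError(f"variable {var!r} absent from sample sheet")
        values = meta[var]
        kind = tests.get(var, "pearson")
        if kind == "ranksum" and values.nunique() < 2:
            warnings.warn(f"variable {var!r} has a single level; skipped", stacklevel=2)
            continue
        stat = np.empty(B.shape[0])
        p = np.empty(B.shape[0])
        eff = np.empty(B.shape[0])
        if kind == "ranksum":
            g = values.to_numpy()
            for i in range(B.shape[0]):
                stat[i], p[i], eff[i] = ranksum_association(B[i], g)
        elif kind == "pearson":
            c = values.to_numpy(dtype=float)
            span = c.max() - c.min()
            for i in range(B.shape[0]):
                stat[i], p[i] = pearson_association(B[i], c)
                slope = stat[i] * B[i].std(ddof=1) / c.std(ddof=1)
                eff[i] = slope * span
        else:
            raise ValueError(f"unknown test {kind!r} for variable {var!r}")
        q, pi0 = storey_qvalue(p)
        frames.append(
            pd.DataFrame(
                {
                    "probe_id": tissue.probe_ids,
                    "variable": var,
                    "test": kind,
                    "statistic": stat,
                    "effect": eff,
                    "p": p,
                    "q": q,
                    "significant": q <= q_threshold,
                    "large_effect": np.abs(eff) > effect_threshold,
                }
            ).reset_index(drop=True)
        )
        diagnostics[var] = _diagnostics(var, p, pi0)
    if not frames:
        raise ValueError("no testable variables")
    return AssociationScan(pd.concat(frames, ignore_index=True), diagnostics)
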