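"""End-to-end pipeline: QC -> tissue specificity -> variability ->
CpG-density enrichment -> demographic associations, with a machine-readable
run summary."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from . import demographics, enrichment, qc, tissue, variability
from .datamodel import MatchedDataset
from .io import write_results
from .simulate import SimulationConfig, generate, truth_recovery_report


def percentage(count: int, total: int) -> float:
    """100 * count / total, rounded half-up to one decimal place."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= count <= total:
        raise ValueError(f"count {count} outside [0, {total}]")
    exact = Decimal(100 * count) / Decimal(total)
    return float(exact.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class PipelineConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    qc: qc.QCConfig = field(default_factory=qc.QCConfig)
    between_mode: str = "matched"
    transform: str = "logit"
    band: float = 0.20
    sd_thresholds: tuple = (0.1, 0.3)
    variables: tuple = ("sex", "ethnicity", "age", "bmi", "alcohol")


@dataclass
class PipelineResult:
    data: MatchedDataset
    truth: pd.DataFrame | None
    qc_report: qc.QCReport
    tissue_table: pd.DataFrame
    correlations: tissue.CorrelationSummary
    global_test: dict
    variability_table: pd.DataFrame
    enrichment_tables: dict[str, pd.DataFrame]
    association_scans: dict[str, demographics.AssociationScan]
    summary: dict

    def recovery_report(self) -> dict:
        if self.truth is None:
            raise ValueError("no truth table: pipeline was run on real input data")
        # demographic effects are planted in tissue B; score that scan
        assoc = self.association_scans["tissue_b"].results
        return truth_recovery_report(
            self.truth,
            {"tissue": self.tissue_table, "variability": self.variability_table,
             "associations": assoc},
        )


def _class_counts(series: pd.Series, total: int) -> dict:
    out = {}
    for value, count in series.value_counts().items():
        out[str(value)] = {"n": int(count), "pct": percentage(int(count), total)}
    return out


def build_summary(
    config: PipelineConfig,
    qc_report: qc.QCReport,
    tissue_table: pd.DataFrame,
    correlations: tissue.CorrelationSummary,
    global_test: dict,
    var_table: pd.DataFrame,
    enrichment_tables: dict[str, pd.DataFrame],
    association_scans: dict[str, demographics.AssociationScan],
) -> dict:
    n = len(tissue_table)
    spec_counts = (tissue_table["spec_class"] != "none").sum()
    high_counts = (tissue_table["spec_class"] == "highly_tissue_specific").sum()
    sig_p_only = (tissue_table["p_bh"] < 0.001).sum()
    levene_sig = var_table["levene_p_bh"] < 0.05
    b_larger = var_table["var_t_b"] > var_table["var_t_a"]
    within = (var_table["concordance"] == "within_band").sum()
    summary = {
        "n_probes_analyzed": n,
        "n_input_probes": qc_report.n_input,
        "qc_removed": {k: len(v) for k, v in qc_report.removed.items()},
        "methylation_categories": {
            "tissue_a": _class_counts(tissue_table["category_a"], n),
            "tissue_b": _class_counts(tissue_table["category_b"], n),
        },
        "tissue_specific": {
            "significant_p_only": {"n": int(sig_p_only), "pct": percentage(int(sig_p_only), n)},
            "tissue_specific": {"n": int(spec_counts), "pct": percentage(int(spec_counts), n)},
            "highly_tissue_specific": {"n": int(high_counts), "pct": percentage(int(high_counts), n)},
        },
        "correlations": {
            "mean_within_a": correlations.mean_within_a,
            "mean_within_b": correlations.mean_within_b,
            "mean_between": correlations.mean_between,
            "between_mode": correlations.between_mode,
            "between_by_class": correlations.between_by_class,
        },
        "global_test": {k: v for k, v in global_test.items()
                        if not isinstance(v, np.ndarray)},
        "variable_loci": {
            f"sd_gt_{thr}": {
                t: {"n": int(cnt), "pct": percentage(int(cnt), n)}
                for t, cnt in (
                    ("tissue_a", (var_table["sd_a"] > thr).sum()),
                    ("tissue_b", (var_table["sd_b"] > thr).sum()),
                )
            }
            for thr in config.sd_thresholds
        },
        "unequal_variance": {
            "n": int(levene_sig.sum()),
            "pct": percentage(int(levene_sig.sum()), n),
            "n_unadjusted_p05": int((var_table["levene_p"] < 0.05).sum()),
            "larger_in_a": int((levene_sig & ~b_larger).sum()),
            "larger_in_b": int((levene_sig & b_larger).sum()),
        },
        "variance_band": {
            "within": int(within),
            "outside": int(n - within),
        },
        "cross_tissue_correlation": {
            "n_abs_r_gt_05": int((var_table["cross_r"].abs() > 0.5).sum()),
            "n_q_le_025": int((var_table["cross_r_q"] <= 0.25).sum()),
            "n_q_le_005": int((var_table["cross_r_q"] <= 0.05).sum()),
        },
        "enrichment": {k: v.to_dict(orient="records") for k, v in enrichment_tables.items()},
        "associations": {
            t: {
                var: {
                    "n_significant": int(
                        scan.results.query("variable == @var")["significant"].sum()
                    ),
                    "n_large_effect": int(
                        scan.results.query("variable == @var and significant")[
                            "large_effect"
                        ].sum()
                    ),
                    "diagnostics": scan.diagnostics[var].to_dict(),
                }
                for var in scan.diagnostics
            }
            for t, scan in association_scans.items()
        },
    }
    return summary


def run_pipeline(
    config: PipelineConfig | None = None,
    data: MatchedDataset | None = None,
    truth: pd.DataFrame | None = None,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Run every stage on a matched dataset (simulated when none is given)."""
    config = config or PipelineConfig()
    if data is None:
        data, truth = generate(config.simulation)
    clean, qc_report = qc.apply_qc(data, config.qc)

    tissue_table = tissue.tissue_specificity_table(clean)
    correlations = tissue.samplewise_correlations(clean, between_mode=config.between_mode)
    global_test = tissue.global_tissue_test(clean)
    var_table = variability.variability_table(
        clean, transform=config.transform, band=config.band
    )

    enrichment_tables: dict[str, pd.DataFrame] = {}
    spec_set = tissue_table.loc[tissue_table["spec_class"] != "none", "probe_id"]
    if len(spec_set):
        enrichment_tables["tissue_specific"] = enrichment.enrichment_table(
            enrichment.enrichment_scan(spec_set, clean.annotation)
        )
    low, _high = config.sd_thresholds[0], config.sd_thresholds[-1]
    for label, col in (("variable_a", "sd_a"), ("variable_b", "sd_b")):
        loci = variability.variable_loci(
            var_table.set_index("probe_id")[col], low
        )
        if len(loci):
            enrichment_tables[label] = enrichment.enrichment_table(
                enrichment.enrichment_scan(loci, clean.annotation)
            )

    association_scans = {
        "tissue_a": demographics.association_scan(clean.tissue_a, clean.samples, config.variables),
        "tissue_b": demographics.association_scan(clean.tissue_b, clean.samples, config.variables),
    }

    summary = build_summary(
        config, qc_report, tissue_table, correlations, global_test, var_table,
        enrichment_tables, association_scans,
    )
    result = PipelineResult(
        clean, truth, qc_report, tissue_table, correlations, global_test,
        var_table, enrichment_tables, association_scans, summary,
    )
    if outdir is not None:
        _write_outputs(result, Path(outdir))
    return result


def _write_outputs(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    write_results(result.tissue_table, outdir / "tissue_specificity.tsv")
    write_results(result.variability_table, outdir / "variability.tsv")
    for name, table in result.enrichment_tables.items():
        write_results(table, outdir / f"enrichment_{name}.tsv")
    for name, scan in result.association_scans.items():
        write_results(scan.results, outdir / f"associations_{name}.tsv")
    with open(outdir / "qc_report.json", "w") as fh:
        json.dump(result.qc_report.to_dict(), fh, indent=2)
    with open(outdir / "run_summary.json", "w") as fh:
        json.dump(result.summary, fh, indent=2, default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
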