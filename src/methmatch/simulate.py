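"""Synthetic matched two-tissue methylation cohorts with a planted truth table.

The generator emulates the structure the analysis assumes: a small cohort
(default 25 subjects) measured in two tissues at ~1,000 autosomal promoter
CpGs with bimodal methylation; a minority of probes with genuine tissue
differences concentrated in low-CpG-density regions; a minority with
tissue-discordant variance; planted demographic associations; a small global
tissue offset; and quality-control artifact probes (SNP-flagged,
sex-chromosome, polymorphic, zero-heavy, detection-failing) appended so the
filters have something to remove.

All effects are planted on the logit2 (M-value) scale, where variance
manipulation is well defined near the beta bounds; values are inverse
transformed and clipped to (1e-6, 1 - 1e-6), except injected QC zeros which
are exact zeros.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import ANNOTATION_COLUMNS, BetaMatrix, MatchedDataset, derive_cpg_class
from .variability import beta_transform, inverse_beta_transform

EPS = 1e-6
BETA_FLOOR, BETA_CEIL = 0.03, 0.97  # feasible range for planted target means


@dataclass
class SimulationConfig:
    """Study-condition parameters for one synthetic cohort.

    Class proportions and effect fractions echo a 998-probe promoter panel:
    ~21% low-density (LC), ~14% intermediate (IC), ~50% high-density (HC) and
    ~15% uncategorized probes; ~18% of probes tissue-specific with
    |delta beta| in [0.2, 0.6] and a 2x bias toward LC; ~15% of probes with a
    3-fold (or 1/3) between-tissue variance ratio; a +0.02 global tissue-B
    offset; 50 sex-associated probes of effect 0.15 planted in tissue B.
    """

    n_subjects: int = 25
    n_probes: int = 998
    seed: int = 0
    class_proportions: dict = field(
        default_factory=lambda: {"LC": 0.21, "IC": 0.14, "HC": 0.50, "uncategorized": 0.15}
    )
    frac_tissue_specific: float = 0.18
    delta_beta_range: tuple = (0.2, 0.6)
    lc_specificity_bias: float = 2.0
    frac_variance_discordant: float = 0.15
    variance_ratios: tuple = (1.0 / 3.0, 3.0)
    #: draw probabilities for variance_ratios; more ratio-1/3 (tissue-A-larger)
    #: probes than ratio-3 probes makes tissue A the more variable tissue
    variance_ratio_probs: tuple = (0.6, 0.4)
    global_offset: float = 0.02
    planted_assoc: dict = field(default_factory=lambda: {"sex": {"n_probes": 50, "effect": 0.15}})
    noise_sd: float = 0.35
    subject_sd: float = 0.20
    probe_dispersion_sigma: float = 0.35
    #: global noise-scale per tissue: the buccal-like tissue A carries more
    #: inter-individual variability overall
    tissue_noise_scale: tuple = (1.6, 1.0)
    #: baseline-mean components: low (hypo), mid (heterogeneous), high (hyper)
    mixture_components: tuple = ((0.03, 0.14), (0.20, 0.80), (0.86, 0.97))
    #: per-class component weights: high-density islands are mostly
    #: unmethylated; low-density contexts carry more intermediate/high
    #: methylation
    class_mixture_weights: dict = field(
        default_factory=lambda: {
            "HC": (0.78, 0.08, 0.14),
            "IC": (0.58, 0.17, 0.25),
            "LC": (0.22, 0.48, 0.30),
            "uncategorized": (0.62, 0.13, 0.25),
        }
    )
    qc_artifacts: dict = field(
        default_factory=lambda: {
            "snp_overlap": 20,
            "sex_chromosome": 15,
            "polymorphic_cpg": 10,
            "zero_heavy": 5,
            "detection_failure": 5,
        }
    )
    tissue_names: tuple = ("A", "B")

    def validate(self) -> None:
        if abs(sum(self.class_proportions.values()) - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        for frac in (self.frac_tissue_specific, self.frac_variance_discordant):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("effect fractions must be in [0, 1]")
        n_planted = sum(v["n_probes"] for v in self.planted_assoc.values())
        if n_planted > self.n_probes:
            raise ValueError(
                f"planted association probes ({n_planted}) exceed n_probes ({self.n_probes})"
            )
        if self.n_subjects < 5:
            raise ValueError("need at least 5 subjects")


def _allocate_classes(proportions: dict, n: int, rng: np.random.Generator) -> np.ndarray:
    """Largest-remainder allocation of probes to CpG classes, then shuffled."""
    names = list(proportions)
    raw = np.array([proportions[c] * n for c in names])
    counts = np.floor(raw).astype(int)
    remainder = raw - counts
    for i in np.argsort(-remainder)[: n - counts.sum()]:
        counts[i] += 1
    labels = np.repeat(names, counts)
    rng.shuffle(labels)
    return labels


def _class_metrics(cls: str, rng: np.random.Generator) -> tuple:
    """Island metrics consistent with the density-class thresholds."""
    if cls == "HC":
        return rng.uniform(0.56, 0.75), rng.uniform(0.76, 1.1), rng.integers(501, 2000)
    if cls == "IC":
        # satisfies the IC rule but deliberately fails at least one HC clause
        return rng.uniform(0.505, 0.55), rng.uniform(0.49, 0.75), rng.integers(201, 1500)
    if cls == "LC":
        return rng.uniform(0.30, 0.50), rng.uniform(0.1, 0.48), rng.integers(50, 200)
    return np.nan, np.nan, np.nan


def _feasible_shift(mean: np.ndarray, magnitude: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Signed shifts keeping mean + shift inside the feasible beta range."""
    up_ok = mean + magnitude <= BETA_CEIL
    dn_ok = mean - magnitude >= BETA_FLOOR
    sign = np.where(rng.random(mean.size) < 0.5, 1.0, -1.0)
    sign = np.where(up_ok & ~dn_ok, 1.0, sign)
    sign = np.where(dn_ok & ~up_ok, -1.0, sign)
    # neither direction feasible: shrink the magnitude to the larger headroom
    neither = ~up_ok & ~dn_ok
    if neither.any():
        head_up = BETA_CEIL - mean[neither]
        head_dn = mean[neither] - BETA_FLOOR
        use_up = head_up >= head_dn
        magnitude = magnitude.copy()
        magnitude[neither] = np.where(use_up, head_up, head_dn)
        sign[neither] = np.where(use_up, 1.0, -1.0)
    return sign * magnitude


def generate(config: SimulationConfig) -> tuple[MatchedDataset, pd.DataFrame]:
    """Generate a matched dataset plus a per-probe truth table.

    The truth table covers the clean probes and the appended QC artifacts
    (``artifact`` column names the injected defect, empty for clean probes).
    Same config and seed give byte-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, ns = config.n_probes, config.n_subjects
    t_a, t_b = config.tissue_names

    # --- probe universe and annotation -----------------------------------
    classes = _allocate_classes(config.class_proportions, n, rng)

    # baseline mean beta: bimodal mixture with class-dependent weights
    lows = np.array([lo for lo, _ in config.mixture_components])
    highs = np.array([hi for _, hi in config.mixture_components])
    comp = np.empty(n, dtype=int)
    for cls, w in config.class_mixture_weights.items():
        mask = classes == cls
        w = np.asarray(w, dtype=float)
        comp[mask] = rng.choice(len(w), size=mask.sum(), p=w / w.sum())
    mean_a = rng.uniform(lows[comp], highs[comp])

    # tissue-specific probes, biased toward LC
    n_ts = int(round(config.frac_tissue_specific * n))
    weights_ts = np.where(classes == "LC", config.lc_specificity_bias, 1.0)
    ts_idx = rng.choice(n, size=n_ts, replace=False, p=weights_ts / weights_ts.sum())
    is_ts = np.zeros(n, dtype=bool)
    is_ts[ts_idx] = True
    magnitude = rng.uniform(*config.delta_beta_range, size=n_ts)
    delta = np.zeros(n)
    delta[ts_idx] = _feasible_shift(mean_a[ts_idx], magnitude, rng)
    mean_b = np.clip(mean_a + config.global_offset + delta, EPS, 1 - EPS)

    # variance-discordant probes (ratio applied to tissue-B noise variance)
    n_vd = int(round(config.frac_variance_discordant * n))
    vd_idx = rng.choice(n, size=n_vd, replace=False)
    is_vd = np.zeros(n, dtype=bool)
    is_vd[vd_idx] = True
    ratio = np.ones(n)
    ratio[vd_idx] = rng.choice(
        config.variance_ratios, size=n_vd, p=np.asarray(config.variance_ratio_probs)
    )

    # --- subjects ---------------------------------------------------------
    subjects = [f"S{j + 1:03d}" for j in range(ns)]
    n_male = int(round(ns * 15 / 25))
    sex = np.array(["male"] * n_male + ["female"] * (ns - n_male))
    n_cauc = int(round(ns * 18 / 25))
    ethnicity = np.array(["caucasian"] * n_cauc + ["non_caucasian"] * (ns - n_cauc))
    rng.shuffle(sex)
    rng.shuffle(ethnicity)
    age = rng.integers(26, 46, size=ns).astype(float)
    bmi = np.clip(np.exp(rng.normal(np.log(26.0), 0.22, size=ns)), 18.2, 47.9)
    alcohol = np.round(rng.gamma(1.5, 2.0, size=ns), 1)
    demo = pd.DataFrame(
        {"subject_id": subjects, "age": age, "sex": sex, "ethnicity": ethnicity,
         "bmi": bmi, "alcohol": alcohol}
    )

    # --- planted demographic associations (in tissue B) -------------------
    assoc_var = np.array([""] * n, dtype=object)
    assoc_effect = np.zeros(n)
    available = rng.permutation(n)
    cursor = 0
    group_masks = {}
    for var, spec in config.planted_assoc.items():
        k, eff = spec["n_probes"], spec["effect"]
        idx = available[cursor: cursor + k]
        cursor += k
        assoc_var[idx] = var
        col = demo[var]
        if col.dtype == object:
            levels = sorted(col.unique())
            group_masks[var] = (col == levels[-1]).to_numpy()
        else:
            group_masks[var] = (col > col.median()).to_numpy()
        assoc_effect[idx] = _feasible_shift(mean_b[idx], np.full(k, eff), rng)

    # --- values on the logit2 scale ---------------------------------------
    scale_a, scale_b = config.tissue_noise_scale
    mu_a = beta_transform(np.clip(mean_a, EPS, 1 - EPS))[:, None] * np.ones((1, ns))
    mu_b = beta_transform(mean_b)[:, None] * np.ones((1, ns))
    for var, mask in group_masks.items():
        rows = assoc_var == var
        target = np.clip(mean_b[rows, None] + assoc_effect[rows, None], EPS, 1 - EPS)
        mu_b[rows] = np.where(mask[None, :], beta_transform(target), mu_b[rows])

    # per-probe dispersion multiplier, shared across tissues (heavy-tailed
    # inter-individual variability); deviations = dispersion * (subject + noise)
    disp = np.exp(rng.normal(0.0, config.probe_dispersion_sigma, size=n))
    subj_eff = rng.normal(0.0, config.subject_sd, size=(n, ns))
    noise_a = rng.normal(0.0, config.noise_sd * scale_a, size=(n, ns))
    noise_b = rng.normal(0.0, config.noise_sd * scale_b, size=(n, ns))
    dev_a = disp[:, None] * (subj_eff + noise_a)
    dev_b = disp[:, None] * (subj_eff + noise_b)
    # variance-discordant probes: boost the deviations of whichever tissue the
    # planted ratio makes more variable, so the realized B/A variance ratio on
    # the transformed scale equals the planted ratio exactly
    var_a_unit = config.subject_sd**2 + (config.noise_sd * scale_a) ** 2
    var_b_unit = config.subject_sd**2 + (config.noise_sd * scale_b) ** 2
    boost_b = is_vd & (ratio > 1.0)
    boost_a = is_vd & (ratio < 1.0)
    scale_vec_b = np.where(boost_b, np.sqrt(ratio * var_a_unit / var_b_unit), 1.0)
    scale_vec_a = np.where(boost_a, np.sqrt(var_b_unit / (ratio * var_a_unit)), 1.0)
    dev_a *= scale_vec_a[:, None]
    dev_b *= scale_vec_b[:, None]
    beta_a = np.clip(inverse_beta_transform(mu_a + dev_a), EPS, 1 - EPS)
    beta_b = np.clip(inverse_beta_transform(mu_b + dev_b), EPS, 1 - EPS)

    probe_ids = [f"cg{i + 1:06d}" for i in range(n)]
    ann_rows = []
    for i, cls in enumerate(classes):
        gc, oe, ln = _class_metrics(cls, rng)
        derived = cls if cls == "uncategorized" else derive_cpg_class(gc, oe, ln)
        ann_rows.append(
            dict(probe_id=probe_ids[i], chromosome=f"chr{rng.integers(1, 23)}",
                 gene_symbol=f"GENE{i // 3 + 1}", cpg_class=derived, gc_content=gc,
                 obs_exp_cpg_ratio=oe, island_length=ln,
                 snp_overlap=False, polymorphic_cpg=False)
        )

    det_a = rng.uniform(0.0, 0.01, size=(n, ns))
    det_b = rng.uniform(0.0, 0.01, size=(n, ns))

    truth = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "cpg_class": [r["cpg_class"] for r in ann_rows],
            "baseline_mean": mean_a,
            "is_tissue_specific": is_ts,
            "true_delta_beta": mean_b - mean_a,
            "is_variance_discordant": is_vd,
            "true_variance_ratio": ratio,
            "associated_variable": assoc_var,
            "true_effect": assoc_effect,
            "artifact": [""] * n,
        }
    )

    # --- QC artifact probes ----------------------------------------------
    art_beta_a, art_beta_b, art_det_a, art_det_b = [], [], [], []
    art_ann, art_truth = [], []
    art_i = 0
    for reason, count in config.qc_artifacts.items():
        for _ in range(count):
            art_i += 1
            pid = f"qc{art_i:06d}"
            m = rng.uniform(0.1, 0.9)
            base = beta_transform(np.full((2, ns), m)) + rng.normal(
                0.0, config.noise_sd, size=(2, ns))
            va, vb = np.clip(inverse_beta_transform(base), EPS, 1 - EPS)
            da = rng.uniform(0.0, 0.01, size=ns)
            db = rng.uniform(0.0, 0.01, size=ns)
            cls = rng.choice(["HC", "IC", "LC", "uncategorized"])
            gc, oe, ln = _class_metrics(cls, rng)
            row = dict(probe_id=pid, chromosome=f"chr{rng.integers(1, 23)}",
                       gene_symbol=f"QCGENE{art_i}", cpg_class=cls, gc_content=gc,
                       obs_exp_cpg_ratio=oe, island_length=ln,
                       snp_overlap=False, polymorphic_cpg=False)
            if reason == "snp_overlap":
                row["snp_overlap"] = True
            elif reason == "sex_chromosome":
                row["chromosome"] = str(rng.choice(["chrX", "chrY", "X"]))
            elif reason == "polymorphic_cpg":
                row["polymorphic_cpg"] = True
            elif reason == "zero_heavy":
                # zero in all but one subject in tissue A (> n_subjects - 2)
                va = va.copy()
                va[: ns - 1] = 0.0
            elif reason == "detection_failure":
                fail = rng.choice(ns, size=4, replace=False)
                da = da.copy()
                da[fail] = rng.uniform(0.2, 0.9, size=4)
            else:
                raise ValueError(f"unknown artifact kind {reason!r}")
            art_beta_a.append(va)
            art_beta_b.append(vb)
            art_det_a.append(da)
            art_det_b.append(db)
            art_ann.append(row)
            art_truth.append(
                dict(probe_id=pid, cpg_class=row["cpg_class"], baseline_mean=m,
                     is_tissue_specific=False, true_delta_beta=0.0,
                     is_variance_discordant=False, true_variance_ratio=1.0,
                     associated_variable="", true_effect=0.0, artifact=reason)
            )

    if art_ann:
        beta_a = np.vstack([beta_a] + art_beta_a)
        beta_b = np.vstack([beta_b] + art_beta_b)
        det_a = np.vstack([det_a] + art_det_a)
        det_b = np.vstack([det_b] + art_det_b)
        probe_ids = probe_ids + [r["probe_id"] for r in art_ann]
        ann_rows += art_ann
        truth = pd.concat([truth, pd.DataFrame(art_truth)], ignore_index=True)

    annotation = pd.DataFrame(ann_rows).set_index("probe_id")[ANNOTATION_COLUMNS]
    samples = pd.concat(
        [
            demo.assign(sample_id=[f"{s}_{t}" for s in subjects], tissue=t)
            for t in (t_a, t_b)
        ],
        ignore_index=True,
    )[["sample_id", "subject_id", "tissue", "age", "sex", "ethnicity", "bmi", "alcohol"]]

    def matrix(vals, det, tissue):
        return BetaMatrix(
            pd.DataFrame(vals, index=pd.Index(probe_ids, name="probe_id"), columns=subjects),
            pd.DataFrame(det, index=pd.Index(probe_ids, name="probe_id"), columns=subjects),
            tissue=tissue,
        )

    data = MatchedDataset(
        matrix(beta_a, det_a, t_a),
        matrix(beta_b, det_b, t_b),
        annotation,
        samples,
        subjects,
    )
    return data, truth


def truth_recovery_report(truth: pd.DataFrame, results: dict[str, pd.DataFrame]) -> dict:
    """Sensitivity/specificity of pipeline calls against the planted truth.

    ``results`` may contain a ``tissue`` table (tissue_specificity_table
    output), a ``variability`` table, and an ``associations`` table. Only the
    probes shared with the truth table's clean universe are scored.
    """
    truth = truth.set_index("probe_id") if "probe_id" in truth.columns else truth
    report: dict[str, dict] = {}

    def rates(called: pd.Series, positive: pd.Series) -> dict:
        if not called.index.equals(positive.index):
            raise ValueError("probe universe mismatch between truth and results")
        tp = int((called & positive).sum())
        fp = int((called & ~positive).sum())
        fn = int((~called & positive).sum())
        tn = int((~called & ~positive).sum())
        return {
            "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
            "specificity": tn / (tn + fp) if tn + fp else float("nan"),
            "false_discovery_rate": fp / (tp + fp) if tp + fp else float("nan"),
            "n_called": tp + fp,
            "n_true": tp + fn,
        }

    if "tissue" in results:
        tab = results["tissue"].set_index("probe_id")
        tr = truth.loc[tab.index]
        called = tab["spec_class"] != "none"
        report["tissue_specific"] = rates(called, tr["is_tissue_specific"])
    if "variability" in results:
        tab = results["variability"].set_index("probe_id")
        tr = truth.loc[tab.index]
        called = tab["levene_p_bh"] < 0.05
        report["variance_discordant"] = rates(called, tr["is_variance_discordant"])
    if "associations" in results:
        tab = results["associations"]
        for var in tab["variable"].unique():
            sub = tab[tab["variable"] == var].set_index("probe_id")
            tr = truth.loc[sub.index]
            report[f"assoc_{var}"] = rates(sub["significant"], tr["associated_variable"] == var)
    if not report:
        raise ValueError("no recognized result tables supplied")
    return report
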