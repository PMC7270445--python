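"""Orchestration: the study's analysis tables on any conforming dataset.

Five report stages mirror the study's published tables:

* ``stage_descriptives`` — cohort characteristics split by vitamin D
  deficiency at each trimester, with two-sample t tests, plus paired
  first-vs-third-trimester comparisons;
* ``stage_status_anthro`` — newborn anthropometry by third-trimester
  vitamin D category with covariate-adjusted model p-values;
* ``stage_grs_association`` — the nine GRS association tests (3 score
  schemes x 3 serum outcomes), flagged against a Bonferroni family of 9;
* ``stage_interaction`` — the eighteen GRS x 25(OH)D product-term tests
  (3 schemes x 2 exposures x 3 outcomes), flagged against a family of
  18, with the stratified head-circumference companion display;
* ``stage_per_snp`` — per-SNP dominant-model associations with serum
  25(OH)D.

Covariate adjustment sets are per-stage configuration (each table uses
its own published set); the pipeline never silently unifies them.
``run_all`` writes every report as TSV plus a JSON run manifest and is
byte-deterministic given a seed and inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort_io import CohortDataset, load_cohort
from .genetics import grs_frame, qc_report, snp_qc, GROUP_LABELS
from .phenotyping import SMALL_HC_CUTOFF, derived_phenotypes
from .simulate import GeneratorConfig, generate
from .stats import (
    bonferroni,
    fit_linear,
    fit_logistic,
    interaction_fit,
    linear_f_test,
    paired_t,
    two_sample_t,
)

logger = logging.getLogger(__name__)

#: per-stage covariate adjustment sets (column names of the analysis frame)
DEFAULT_ADJUSTMENTS = {
    "status_anthro": ["age", "prepreg_bmi", "preterm", "outdoor_activity", "supplement"],
    "grs_association": ["age", "prepreg_bmi", "supplement", "outdoor_activity", "mountainous"],
    "interaction": ["age", "prepreg_bmi", "supplement", "gestational_age_birth", "male"],
    "per_snp": ["age", "prepreg_bmi", "supplement", "outdoor_activity", "mountainous"],
}

_SERUM_OUTCOMES = [("vitd_t1", "25(OH)D T1"), ("vitd_t3", "25(OH)D T3"),
                   ("delta_25ohd", "change in 25(OH)D")]
_ANTHRO_OUTCOMES = [("birth_weight", "birth weight (g)"),
                    ("birth_length", "birth length (cm)"),
                    ("head_circumference", "head circumference (cm)")]


@dataclass
class RunConfig:
    """Inputs, adjustment sets and multiplicity families for one run."""

    phenotypes: Optional[str] = None
    genotypes: Optional[str] = None
    manifest: Optional[str] = None
    generator: Optional[GeneratorConfig] = None
    adjustments: dict[str, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_ADJUSTMENTS.items()}
    )
    alpha_family: float = 0.05
    association_m: int = 9
    interaction_m: int = 18
    outdir: str = "vdgrs_run"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        gen = raw.pop("generator", None)
        config = cls(**raw)
        if gen is not None:
            config.generator = GeneratorConfig(**gen)
        return config


def analysis_frame(dataset: CohortDataset) -> pd.DataFrame:
    """One row per mother-infant pair with scores, categories and dummies."""
    frame = dataset.to_frame()
    frame = frame.merge(grs_frame(dataset.participants, dataset.manifest), on="sample_id")
    derived = derived_phenotypes(dataset.participants, dataset.neonates)
    frame = frame.merge(
        derived.drop(columns=["prepreg_bmi"], errors="ignore"), on="sample_id"
    )
    frame["mountainous"] = (frame["geography"] == "mountainous").astype(float)
    frame["male"] = (frame["sex"] == "male").astype(float)
    frame["supplement"] = frame["supplement_use"].map(
        {True: 1.0, False: 0.0, None: np.nan}
    ).astype(float)
    frame["preterm"] = (frame["gestational_age_birth"] < 37.0).astype(float)
    return frame


def _mean_sd(series: pd.Series) -> tuple[float, float, int]:
    vals = pd.to_numeric(series, errors="coerce").dropna()
    if len(vals) == 0:
        return float("nan"), float("nan"), 0
    sd = float(vals.std(ddof=1)) if len(vals) > 1 else float("nan")
    return float(vals.mean()), sd, int(len(vals))


# ---------------------------------------------------------------------------
# stages

_DESCRIPTIVE_VARS = [
    ("age", "Age, years"),
    ("height", "Height, cm"),
    ("prepreg_bmi", "Pre-pregnancy BMI, kg/m2"),
    ("muac", "MUAC, cm"),
    ("outdoor_activity", "Outdoor activity, hours/day"),
    ("systolic_t1", "Systolic BP T1, mmHg"),
    ("systolic_t3", "Systolic BP T3, mmHg"),
    ("weight_t1", "Body weight T1, kg"),
    ("weight_t3", "Body weight T3, kg"),
    ("hb_t1", "Haemoglobin T1, g/dL"),
    ("hb_t3", "Haemoglobin T3, g/dL"),
    ("birth_weight", "Birth weight, g"),
    ("birth_length", "Birth length, cm"),
    ("head_circumference", "Head circumference, cm"),
    ("gestational_age_birth", "GA at birth, weeks"),
]

_PAIRED_VARS = [
    ("systolic_t1", "systolic_t3", "Systolic BP, mmHg"),
    ("weight_t1", "weight_t3", "Body weight, kg"),
    ("muac", "muac_t3", "MUAC, cm"),
    ("hb_t1", "hb_t3", "Haemoglobin, g/dL"),
]


def stage_descriptives(dataset: CohortDataset) -> dict[str, pd.DataFrame]:
    """Cohort characteristics by vitamin D deficiency, plus paired visits.

    Mothers are split into deficient (<12 ng/mL) versus normal (>=12)
    at each trimester and compared variable-by-variable with Student t
    tests; groups with fewer than 3 observations skip the comparison.
    """
    frame = analysis_frame(dataset)
    by_status = {}
    for visit in ("t1", "t3"):
        cat = frame[f"vitd_{visit}_cat"]
        deficient = frame[cat == "deficient"]
        normal = frame[cat.isin(["insufficient", "sufficient"])]
        rows = []
        for column, label in _DESCRIPTIVE_VARS:
            m_d, sd_d, n_d = _mean_sd(deficient[column])
            m_n, sd_n, n_n = _mean_sd(normal[column])
            p = np.nan
            if n_d >= 3 and n_n >= 3:
                try:
                    _, p = two_sample_t(deficient[column], normal[column])
                except ValueError as err:
                    logger.warning("descriptives %s %s: %s", visit, column, err)
            else:
                logger.warning(
                    "descriptives %s %s: group too small (n=%d/%d); skipped",
                    visit, column, n_d, n_n,
                )
            rows.append(
                {
                    "variable": label,
                    "n_deficient": n_d, "mean_deficient": m_d, "sd_deficient": sd_d,
                    "n_normal": n_n, "mean_normal": m_n, "sd_normal": sd_n,
                    "p": p,
                }
            )
        by_status[visit] = pd.DataFrame(rows)
    paired_rows = []
    for col1, col3, label in _PAIRED_VARS:
        m1, sd1, _ = _mean_sd(frame[col1])
        m3, sd3, n = _mean_sd(frame[col3])
        p = np.nan
        try:
            _, p = paired_t(frame[col1], frame[col3])
        except ValueError as err:
            logger.warning("descriptives paired %s: %s", label, err)
        paired_rows.append(
            {"variable": label, "mean_t1": m1, "sd_t1": sd1,
             "mean_t3": m3, "sd_t3": sd3, "n": n, "p": p}
        )
    return {
        "by_status_t1": by_status["t1"],
        "by_status_t3": by_status["t3"],
        "paired": pd.DataFrame(paired_rows),
    }


def stage_status_anthro(
    dataset: CohortDataset,
    adjustments: Optional[list[str]] = None,
) -> pd.DataFrame:
    """Newborn anthropometry by third-trimester vitamin D category.

    For each outcome: per-category means +- SD, an adjusted
    general-linear-model p-value (partial F test of the two category
    dummies), and companion logistic Wald p-values for the binary
    adverse label.  The third trimester is the canonical grouping visit.
    """
    adjustments = adjustments if adjustments is not None else DEFAULT_ADJUSTMENTS["status_anthro"]
    frame = analysis_frame(dataset)
    cat = frame["vitd_t3_cat"]
    categories = ["sufficient", "insufficient", "deficient"]
    present = [c for c in categories if (cat == c).sum() > 0]
    dummies = pd.DataFrame(
        {f"status_{c}": (cat == c).astype(float) for c in categories[1:]}
    )
    rows = []
    binary_map = {
        "birth_weight": ("birth_weight_cat", "low"),
        "birth_length": ("birth_length_cat", "short"),
        "head_circumference": ("head_circ_cat", "small"),
    }
    for outcome, label in _ANTHRO_OUTCOMES:
        row: dict = {"outcome": label}
        for c in categories:
            m, sd, n = _mean_sd(frame.loc[cat == c, outcome])
            row[f"mean_{c}"], row[f"sd_{c}"], row[f"n_{c}"] = m, sd, n
        if len(present) < 2:
            logger.warning("status_anthro %s: single category; model skipped", outcome)
            row["glm_p"] = np.nan
        else:
            covs = frame[adjustments].astype(float)
            X_full = pd.concat([dummies, covs], axis=1)
            _, p, n_used = linear_f_test(frame[outcome], X_full, covs)
            row["glm_p"] = p
            row["glm_n"] = n_used
            cat_col, adverse = binary_map[outcome]
            y_bin = (frame[cat_col] == adverse).astype(float)
            y_bin[frame[cat_col].isna()] = np.nan
            try:
                fit = fit_logistic(y_bin, X_full, adjustment_set=adjustments)
                for c in categories[1:]:
                    row[f"logistic_p_{c}"] = fit[f"status_{c}"]["p"]
            except ValueError as err:
                logger.warning("status_anthro %s logistic: %s", outcome, err)
        rows.append(row)
    return pd.DataFrame(rows)


def stage_grs_association(
    dataset: CohortDataset,
    adjustments: Optional[list[str]] = None,
    alpha_family: float = 0.05,
) -> pd.DataFrame:
    """GRS association with serum 25(OH)D: 3 schemes x 3 outcomes.

    Each of the nine tests contrasts the dichotomized GRS groups on a
    serum outcome with covariate adjustment; p-values are flagged
    against the Bonferroni family of nine tests.
    """
    adjustments = adjustments if adjustments is not None else DEFAULT_ADJUSTMENTS["grs_association"]
    frame = analysis_frame(dataset)
    family = bonferroni(alpha_family, 9, name="grs_association")
    rows = []
    for scheme in ("vitd", "synthesis", "metabolism"):
        low_label, high_label = GROUP_LABELS[scheme]
        group = frame[f"{scheme}_group"]
        high = (group == high_label).astype(float)
        high[group.isna()] = np.nan
        for outcome, outcome_label in _SERUM_OUTCOMES:
            row: dict = {"scheme": scheme, "outcome": outcome_label}
            for side, label in (("low", low_label), ("high", high_label)):
                m, sd, n = _mean_sd(frame.loc[group == label, outcome])
                row[f"group_{side}"] = label
                row[f"mean_{side}"], row[f"sd_{side}"], row[f"n_{side}"] = m, sd, n
            X = pd.concat(
                [high.rename("grs_high"), frame[adjustments].astype(float)], axis=1
            )
            try:
                fit = fit_linear(frame[outcome], X, adjustment_set=adjustments)
                term = fit["grs_high"]
                row.update(beta=term["beta"], se=term["se"], p=term["p"],
                           n_used=fit.n_used)
                row["bonferroni_significant"] = family.significant(term["p"])
            except ValueError as err:
                logger.warning("grs_association %s/%s: %s", scheme, outcome, err)
                row.update(beta=np.nan, se=np.nan, p=np.nan,
                           bonferroni_significant=False)
            row["bonferroni_threshold"] = family.threshold_display
            rows.append(row)
    return pd.DataFrame(rows)


def stage_interaction(
    dataset: CohortDataset,
    adjustments: Optional[list[str]] = None,
    alpha_family: float = 0.05,
) -> dict[str, pd.DataFrame]:
    """GRS x 25(OH)D product terms on newborn anthropometry (18 tests).

    The GRS enters as the continuous risk-allele count.  The companion
    display stratifies third-trimester 25(OH)D by total-GRS group
    within head-circumference strata (<35 vs >=35 cm).
    """
    adjustments = adjustments if adjustments is not None else DEFAULT_ADJUSTMENTS["interaction"]
    frame = analysis_frame(dataset)
    family = bonferroni(alpha_family, 18, name="interaction")
    rows = []
    for scheme in ("vitd", "synthesis", "metabolism"):
        score = frame[f"{scheme}_grs"].astype(float)
        for exposure, exposure_label in (("vitd_t1", "25(OH)D T1"),
                                         ("vitd_t3", "25(OH)D T3")):
            for outcome, outcome_label in _ANTHRO_OUTCOMES:
                row: dict = {
                    "scheme": scheme,
                    "exposure": exposure_label,
                    "outcome": outcome_label,
                }
                try:
                    fit = interaction_fit(
                        frame[outcome], score, frame[exposure],
                        covariates=frame[adjustments].astype(float),
                        grs_name=f"{scheme}_grs", exposure_name=exposure,
                    )
                    term = fit[f"{scheme}_grs:{exposure}"]
                    row.update(beta=term["beta"], se=term["se"], p=term["p"],
                               n_used=fit.n_used)
                    row["bonferroni_significant"] = family.significant(term["p"])
                except ValueError as err:
                    logger.warning("interaction %s/%s/%s: %s",
                                   scheme, exposure, outcome, err)
                    row.update(beta=np.nan, se=np.nan, p=np.nan,
                               bonferroni_significant=False)
                row["bonferroni_threshold"] = family.threshold_display
                rows.append(row)
    # stratified companion: T3 25(OH)D by total-GRS group within HC strata
    strata_rows = []
    hc = frame["head_circumference"]
    for stratum, mask in (
        (f"<{SMALL_HC_CUTOFF:g} cm", hc < SMALL_HC_CUTOFF),
        (f">={SMALL_HC_CUTOFF:g} cm", hc >= SMALL_HC_CUTOFF),
    ):
        sub = frame[mask]
        low_label, high_label = GROUP_LABELS["vitd"]
        for label in (low_label, high_label):
            m, sd, n = _mean_sd(sub.loc[sub["vitd_group"] == label, "vitd_t3"])
            strata_rows.append(
                {"hc_stratum": stratum, "grs_group": label,
                 "mean_vitd_t3": m, "sd": sd, "n": n}
            )
        try:
            _, p = two_sample_t(
                sub.loc[sub["vitd_group"] == low_label, "vitd_t3"],
                sub.loc[sub["vitd_group"] == high_label, "vitd_t3"],
            )
        except ValueError:
            p = np.nan
        strata_rows[-1]["p_between_groups"] = p
    return {
        "product_terms": pd.DataFrame(rows),
        "stratified_hc": pd.DataFrame(strata_rows),
    }


def stage_per_snp(
    dataset: CohortDataset,
    adjustments: Optional[list[str]] = None,
) -> pd.DataFrame:
    """Per-SNP dominant-model associations with serum 25(OH)D.

    For each SNP, risk-allele carriers (1-2 copies) are contrasted with
    non-carriers on each serum outcome with covariate adjustment.
    Monomorphic SNPs are skipped with a warning.
    """
    from .genetics import dominant_carrier

    adjustments = adjustments if adjustments is not None else DEFAULT_ADJUSTMENTS["per_snp"]
    frame = analysis_frame(dataset).set_index("sample_id", drop=False)
    rows = []
    for spec in dataset.manifest:
        carrier = pd.Series(
            {
                p.sample_id: dominant_carrier(p.genotypes.get(spec.rsid), spec)
                for p in dataset.participants
            }
        ).reindex(frame.index)
        carrier_f = carrier.map({True: 1.0, False: 0.0}).astype(float)
        called = carrier_f.dropna()
        if called.nunique() < 2:
            logger.warning("per_snp %s: monomorphic under dominant coding; skipped",
                           spec.rsid)
            continue
        row: dict = {"rsid": spec.rsid, "gene": spec.gene,
                     "risk_allele": spec.risk_allele,
                     "n_carrier": int(called.sum()),
                     "n_noncarrier": int((called == 0).sum())}
        for outcome, outcome_label in _SERUM_OUTCOMES:
            key = outcome.replace("vitd_", "").replace("delta_25ohd", "change")
            m_c, _, _ = _mean_sd(frame.loc[carrier_f == 1.0, outcome])
            m_nc, _, _ = _mean_sd(frame.loc[carrier_f == 0.0, outcome])
            row[f"mean_carrier_{key}"] = m_c
            row[f"mean_noncarrier_{key}"] = m_nc
            X = pd.concat(
                [carrier_f.rename("carrier"), frame[adjustments].astype(float)],
                axis=1,
            )
            try:
                fit = fit_linear(frame[outcome], X, adjustment_set=adjustments)
                row[f"beta_{key}"] = fit["carrier"]["beta"]
                row[f"p_{key}"] = fit["carrier"]["p"]
            except ValueError as err:
                logger.warning("per_snp %s/%s: %s", spec.rsid, outcome, err)
                row[f"beta_{key}"] = np.nan
                row[f"p_{key}"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# orchestration

def _write_tsv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, sep="\t", index=False, lineterminator="\n")


def run_all(config: RunConfig) -> Path:
    """Run every stage and write reports plus a JSON run manifest.

    The dataset comes either from the configured input files or from
    the synthetic generator.  Rerunning with the same seed and inputs
    reproduces every report byte-for-byte.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if config.generator is not None:
        dataset = generate(config.generator, seed=config.seed)
    elif config.phenotypes and config.genotypes:
        dataset = load_cohort(config.phenotypes, config.genotypes, config.manifest)
    else:
        raise ValueError("RunConfig needs either a generator or input file paths")

    manifest: dict = {
        "package": "vdgrs",
        "version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "alpha_family": config.alpha_family,
        "adjustments": config.adjustments,
        "accounting": dataset.accounting,
        "stages": {},
    }
    config_text = json.dumps(
        {k: v for k, v in config.__dict__.items()
         if k not in ("generator", "outdir")},
        sort_keys=True, default=str,
    )
    if config.generator is not None:
        config_text += json.dumps(config.generator.__dict__, sort_keys=True, default=str)
    manifest["config_sha256"] = hashlib.sha256(config_text.encode()).hexdigest()

    qc = qc_report(snp_qc(dataset.participants, dataset.manifest))
    _write_tsv(qc, outdir / "snp_qc.tsv")
    manifest["stages"]["snp_qc"] = {"rows": len(qc)}

    derived = derived_phenotypes(dataset.participants, dataset.neonates)
    derived.to_csv(outdir / "derived_phenotypes.csv", index=False, lineterminator="\n")

    descriptives = stage_descriptives(dataset)
    for name, frame in descriptives.items():
        _write_tsv(frame, outdir / f"descriptives_{name}.tsv")
    manifest["stages"]["descriptives"] = {
        name: {"rows": len(frame)} for name, frame in descriptives.items()
    }

    status = stage_status_anthro(dataset, config.adjustments.get("status_anthro"))
    _write_tsv(status, outdir / "status_anthro.tsv")
    manifest["stages"]["status_anthro"] = {"rows": len(status)}

    association = stage_grs_association(
        dataset, config.adjustments.get("grs_association"), config.alpha_family
    )
    _write_tsv(association, outdir / "grs_association.tsv")
    manifest["stages"]["grs_association"] = {
        "rows": len(association), "family_m": config.association_m,
    }

    interaction = stage_interaction(
        dataset, config.adjustments.get("interaction"), config.alpha_family
    )
    _write_tsv(interaction["product_terms"], outdir / "interaction.tsv")
    _write_tsv(interaction["stratified_hc"], outdir / "interaction_stratified_hc.tsv")
    manifest["stages"]["interaction"] = {
        "rows": len(interaction["product_terms"]), "family_m": config.interaction_m,
    }

    per_snp = stage_per_snp(dataset, config.adjustments.get("per_snp"))
    _write_tsv(per_snp, outdir / "per_snp.tsv")
    manifest["stages"]["per_snp"] = {"rows": len(per_snp)}

    (outdir / "run_manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return outdir
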