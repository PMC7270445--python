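"""Seeded synthetic pregnancy-cohort generator.

Emulates the statistical structure the analysis pipeline assumes, so
every stage can run and be tested without access to any real cohort:

* six biallelic SNPs drawn independently under Hardy-Weinberg
  equilibrium at configurable risk-allele frequencies (defaults span
  0.18-0.39);
* first- and third-trimester serum 25(OH)D drawn jointly with a
  configurable correlation (default 0.425); the third-trimester mean is
  lowered by a per-risk-allele decrement applied to the centred total
  GRS, so the configured ``t3_mean`` remains the population mean;
* maternal covariates and neonatal outcomes drawn from configurable
  normal distributions (defaults set to the reference cohort's printed
  means and SDs);
* a head-circumference gene-environment interaction: the outcome mean
  is shifted by ``gamma_interaction x (GRS - E[GRS]) x (T3 - t3_mean)``;
* an enrolment -> dropout -> low-DNA-yield exclusion flow applied
  uniformly at random (default 239 enrolled, 53 dropped, 3 excluded,
  leaving 183 analyzable mother-infant pairs).

All randomness comes from one ``numpy.random.default_rng(seed)``
instance; an identical seed yields a bit-identical cohort.

The default per-allele third-trimester decrement (1.82 ng/mL) is a
calibration, not an estimate: it is chosen so that the expected
contrast between the dichotomized GRS groups (<=3 vs >=4 risk alleles)
reproduces the reference cohort's printed third-trimester group
difference of 4.61 ng/mL given the default allele frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .cohort_io import CohortDataset, NeonatalRecord, Participant, SnpSpec, default_manifest

#: default risk-allele frequencies; range matches the reference panel's 0.18-0.39
DEFAULT_FREQS = {
    "rs12785878": 0.28,
    "rs12794714": 0.39,
    "rs2282679": 0.27,
    "rs6013897": 0.22,
    "rs2228570": 0.35,
    "rs7975232": 0.18,
}


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic cohort; defaults are the study conditions."""

    seed: int = 0
    n_enrolled: int = 239
    dropout_n: int = 53
    low_dna_n: int = 3
    freqs: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_FREQS))
    beta_snp: float = 1.82        # ng/mL T3 decrement per risk allele
    t1_mean: float = 14.00        # ng/mL
    t1_sd: float = 6.97
    t3_mean: float = 21.21        # ng/mL (population mean at T3)
    t3_sd: float = 9.5            # environmental component SD
    t1_t3_corr: float = 0.425
    age_mean: float = 29.7
    age_sd: float = 5.68
    height_mean: float = 154.5
    height_sd: float = 5.9
    bmi_mean: float = 23.45       # pre-pregnancy, kg/m^2
    bmi_sd: float = 4.56
    muac_mean: float = 27.02
    muac_sd: float = 3.81
    outdoor_mean: float = 61.0    # hours/day-equivalent activity score
    outdoor_sd: float = 50.0
    ga_mean: float = 38.88        # gestational age at birth, weeks
    ga_sd: float = 1.91
    supplement_rate: float = 0.35
    bw_mean: float = 3204.87      # birth weight, g
    bw_sd: float = 494.99
    bl_mean: float = 48.56        # birth length, cm
    bl_sd: float = 2.87
    hc_mean: float = 33.89        # head circumference, cm
    hc_sd: float = 2.52
    gamma_interaction: float = 0.08  # hc cm per (risk allele x ng/mL)
    missing_rate: float = 0.0

    def validate(self) -> None:
        if self.n_enrolled < 1:
            raise ValueError("n_enrolled must be positive")
        if self.dropout_n < 0 or self.low_dna_n < 0:
            raise ValueError("flow counts must be non-negative")
        if self.dropout_n + self.low_dna_n >= self.n_enrolled:
            raise ValueError("dropout_n + low_dna_n must be < n_enrolled")
        for rsid, p in self.freqs.items():
            if not 0 < p <= 0.5:
                raise ValueError(f"{rsid}: allele frequency {p} outside (0, 0.5]")
        for name in (
            "t1_sd", "t3_sd", "age_sd", "height_sd", "bmi_sd", "muac_sd",
            "outdoor_sd", "ga_sd", "bw_sd", "bl_sd", "hc_sd",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not -1 <= self.t1_t3_corr <= 1:
            raise ValueError("t1_t3_corr must be in [-1, 1]")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")

    @property
    def expected_grs(self) -> float:
        """Population mean of the total risk-allele count, 2 * sum of freqs."""
        return 2.0 * sum(self.freqs.values())


def draw_genotypes(
    rng: np.random.Generator, manifest: list[SnpSpec], config: GeneratorConfig, n: int
) -> np.ndarray:
    """Risk-allele counts (n x n_snps) under HWE at the configured frequencies."""
    counts = np.empty((n, len(manifest)), dtype=int)
    for j, spec in enumerate(manifest):
        p = config.freqs[spec.rsid]
        counts[:, j] = rng.binomial(2, p, size=n)
    return counts


def _pair(count: int, spec: SnpSpec) -> tuple[str, str]:
    if count == 2:
        return (spec.risk_allele, spec.risk_allele)
    if count == 1:
        return (spec.risk_allele, spec.other_allele)
    return (spec.other_allele, spec.other_allele)


def generate(
    config: Optional[GeneratorConfig] = None, seed: Optional[int] = None
) -> CohortDataset:
    """Simulate the full cohort flow and return the analyzable dataset.

    The returned dataset's ``accounting`` reports the flow: enrolled,
    dropped, completed, excluded for low DNA yield, analyzable.
    """
    config = config or GeneratorConfig()
    if seed is not None:
        config = GeneratorConfig(**{**config.__dict__, "seed": seed})
    config.validate()
    rng = np.random.default_rng(config.seed)
    manifest = default_manifest()
    missing_freq = set(config.freqs) ^ {s.rsid for s in manifest}
    if missing_freq:
        raise ValueError(f"freqs must cover exactly the manifest SNPs; mismatch: {missing_freq}")

    n = config.n_enrolled
    counts = draw_genotypes(rng, manifest, config, n)
    grs = counts.sum(axis=1)
    grs_centred = grs - config.expected_grs

    age = rng.normal(config.age_mean, config.age_sd, n)
    height = rng.normal(config.height_mean, config.height_sd, n)
    bmi = np.clip(rng.normal(config.bmi_mean, config.bmi_sd, n), 14.0, None)
    weight = bmi * (height / 100.0) ** 2
    muac = rng.normal(config.muac_mean, config.muac_sd, n)
    outdoor = np.clip(rng.normal(config.outdoor_mean, config.outdoor_sd, n), 0.0, None)
    geography = rng.random(n) < 0.5
    supplement = rng.random(n) < config.supplement_rate
    ga_birth = rng.normal(config.ga_mean, config.ga_sd, n)

    # serum 25(OH)D: bivariate-normal environmental part, genetic decrement at T3
    t1 = rng.normal(config.t1_mean, config.t1_sd, n)
    rho = config.t1_t3_corr
    t3 = (
        config.t3_mean
        + rho * (config.t3_sd / config.t1_sd) * (t1 - config.t1_mean)
        + float(np.sqrt(1 - rho * rho)) * config.t3_sd * rng.standard_normal(n)
        - config.beta_snp * grs_centred
    )
    t1 = np.clip(t1, 0.1, None)
    t3 = np.clip(t3, 0.1, None)

    # within-mother visit series for the descriptive paired comparisons
    systolic_t1 = rng.normal(107.08, 10.84, n)
    systolic_t3 = systolic_t1 + rng.normal(4.43, 8.0, n)
    weight_t1 = weight + rng.normal(0.4, 1.2, n)
    weight_t3 = weight_t1 + rng.normal(7.61, 3.0, n)
    muac_t3 = muac + rng.normal(0.80, 1.8, n)
    hb_t1 = rng.normal(11.58, 1.39, n)
    hb_t3 = hb_t1 + rng.normal(0.23, 1.3, n)

    sex = np.where(rng.random(n) < 0.5, "male", "female")
    bw = rng.normal(config.bw_mean, config.bw_sd, n)
    bl = rng.normal(config.bl_mean, config.bl_sd, n)
    hc = (
        config.hc_mean
        + config.gamma_interaction * grs_centred * (t3 - config.t3_mean)
        + rng.normal(0.0, config.hc_sd, n)
    )
    bw = np.clip(bw, 500.0, None)
    bl = np.clip(bl, 30.0, None)
    hc = np.clip(hc, 20.0, None)

    # flow: dropouts never deliver in study; low-DNA completers lack genotypes
    order = rng.permutation(n)
    dropped = set(order[: config.dropout_n])
    low_dna = set(order[config.dropout_n : config.dropout_n + config.low_dna_n])

    miss_t1 = rng.random(n) < config.missing_rate
    miss_t3 = rng.random(n) < config.missing_rate

    participants: list[Participant] = []
    neonates: list[NeonatalRecord] = []
    for i in range(n):
        if i in dropped or i in low_dna:
            continue
        sample = f"S{i + 1:04d}"
        genotypes = {
            spec.rsid: _pair(int(counts[i, j]), spec)
            for j, spec in enumerate(manifest)
        }
        participants.append(
            Participant(
                sample_id=sample,
                age=float(age[i]),
                height=float(height[i]),
                prepreg_weight=float(weight[i]),
                prepreg_bmi=float(bmi[i]),
                muac=float(muac[i]),
                geography="mountainous" if geography[i] else "coastal",
                outdoor_activity=float(outdoor[i]),
                supplement_use=bool(supplement[i]),
                vitd_t1=None if miss_t1[i] else float(t1[i]),
                vitd_t3=None if miss_t3[i] else float(t3[i]),
                gestational_age_birth=float(ga_birth[i]),
                systolic_t1=float(systolic_t1[i]),
                systolic_t3=float(systolic_t3[i]),
                weight_t1=float(weight_t1[i]),
                weight_t3=float(weight_t3[i]),
                muac_t3=float(muac_t3[i]),
                hb_t1=float(hb_t1[i]),
                hb_t3=float(hb_t3[i]),
                genotypes=genotypes,
            )
        )
        neonates.append(
            NeonatalRecord(
                sample_id=sample,
                sex=str(sex[i]),
                birth_weight=float(bw[i]),
                birth_length=float(bl[i]),
                head_circumference=float(hc[i]),
            )
        )

    accounting = {
        "enrolled": n,
        "dropped": config.dropout_n,
        "completed": n - config.dropout_n,
        "low_dna_excluded": config.low_dna_n,
        "analyzable": len(participants),
    }
    return CohortDataset(
        participants=participants,
        neonates=neonates,
        manifest=manifest,
        accounting=accounting,
    )


def checkerboard_fixture() -> CohortDataset:
    """Hand-written 12-mother dataset exercising every classification path.

    Covers all three vitamin D categories at both visits, all adverse
    and normal anthropometry labels, homozygous/heterozygous genotypes,
    one missing genotype and one missed third-trimester visit.
    """
    manifest = default_manifest()
    risk = {s.rsid: s.risk_allele for s in manifest}
    other = {s.rsid: s.other_allele for s in manifest}

    def geno(counts: dict[str, int]) -> dict[str, Optional[tuple[str, str]]]:
        out: dict[str, Optional[tuple[str, str]]] = {}
        for spec in manifest:
            c = counts.get(spec.rsid, 0)
            if c < 0:
                out[spec.rsid] = None
            elif c == 2:
                out[spec.rsid] = (risk[spec.rsid], risk[spec.rsid])
            elif c == 1:
                out[spec.rsid] = (risk[spec.rsid], other[spec.rsid])
            else:
                out[spec.rsid] = (other[spec.rsid], other[spec.rsid])
        return out

    # (t1, t3, grs counts per snp, birth weight, length, head circ)
    rows = [
        ("C01", 5.0, 11.0, {"rs12785878": 2, "rs12794714": 2, "rs2282679": 2,
                            "rs6013897": 2, "rs2228570": 2, "rs7975232": 2},
         2300.0, 46.0, 31.0),   # deficient both; all-adverse baby; GRS 12
        ("C02", 11.9, 12.0, {"rs12785878": 1}, 2499.0, 50.0, 35.0),
        ("C03", 12.0, 19.99, {"rs12794714": 1, "rs2282679": 1}, 2500.0, 49.9, 34.9),
        ("C04", 19.99, 20.0, {"rs2282679": 2, "rs6013897": 1}, 3200.0, 50.5, 35.5),
        ("C05", 20.0, 28.0, {"rs2228570": 2, "rs7975232": 2}, 3600.0, 52.0, 36.0),
        ("C06", 25.0, 24.0, {}, 3204.87, 48.56, 33.89),  # sufficient; GRS 0
        ("C07", 8.0, 22.0, {"rs12785878": 1, "rs12794714": 1, "rs2282679": 1,
                            "rs6013897": 1, "rs2228570": 1, "rs7975232": 1},
         3100.0, 49.0, 34.0),   # all-het; GRS 6
        ("C08", 15.0, 15.0, {"rs12785878": 2, "rs2282679": 2}, 2800.0, 51.0, 33.0),
        ("C09", 18.0, None, {"rs6013897": 2}, 3300.0, 47.0, 36.5),  # missed T3
        ("C10", 9.5, 14.0, {"rs12794714": -1, "rs2228570": 1},
         2450.0, 48.0, 35.2),   # missing genotype at rs12794714
        ("C11", 22.5, 30.0, {"rs7975232": 1}, 4100.0, 53.0, 37.0),
        ("C12", 13.0, 21.0, {"rs12785878": 1, "rs6013897": 1}, 2950.0, 50.0, 34.5),
    ]
    participants, neonates = [], []
    for i, (sid, t1, t3, counts, bw, bl, hc) in enumerate(rows):
        participants.append(
            Participant(
                sample_id=sid,
                age=25.0 + i,
                height=150.0 + i,
                prepreg_weight=50.0 + i,
                prepreg_bmi=(50.0 + i) / ((150.0 + i) / 100.0) ** 2,
                muac=25.0 + 0.5 * i,
                geography="mountainous" if i % 2 == 0 else "coastal",
                outdoor_activity=30.0 + 5.0 * i,
                supplement_use=i % 3 == 0,
                vitd_t1=t1,
                vitd_t3=t3,
                gestational_age_birth=37.0 + 0.3 * i,
                genotypes=geno(counts),
            )
        )
        neonates.append(
            NeonatalRecord(
                sample_id=sid,
                sex="male" if i % 2 == 0 else "female",
                birth_weight=bw,
                birth_length=bl,
                head_circumference=hc,
            )
        )
    accounting = {
        "enrolled": 12, "dropped": 0, "completed": 12,
        "low_dna_excluded": 0, "analyzable": 12,
    }
    return CohortDataset(
        participants=participants,
        neonates=neonates,
        manifest=manifest,
        accounting=accounting,
    )
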