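"""Allele coding, per-SNP QC and genetic risk score construction.

The genetic risk score (GRS) is an unweighted count of 25(OH)D-lowering
alleles.  Three schemes are derived from one six-SNP panel:

* ``vitd`` — all six SNPs (score range 0-12);
* ``synthesis`` — the two synthesis-pathway SNPs, DHCR7 and CYP2R1 (0-4);
* ``metabolism`` — the four metabolism-pathway SNPs, GC, CYP24A1 and the
  two VDR variants (0-8).

Because the two pathway groups partition the panel, a complete profile
always satisfies ``vitd = synthesis + metabolism``.  Each score is
dichotomized at a fixed cut-point for group comparisons: total score
<=3 vs >=4, synthesis <2 vs >=2, metabolism <=3 vs >=4.

Missing genotypes propagate: by default a scheme's score is missing if
any constituent genotype is missing (complete-case).  An optional
proportional rescaling mode (sum scaled by n_snps/n_called) is provided
for sensitivity analyses but is off by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort_io import Genotype, Participant, SnpSpec

logger = logging.getLogger(__name__)

SCHEMES = ("vitd", "synthesis", "metabolism")

#: dichotomization cut-points: score >= cut -> "high" group
_CUTS = {"vitd": 4, "synthesis": 2, "metabolism": 4}
#: printed group labels, (low, high)
GROUP_LABELS = {
    "vitd": ("≤3", "≥4"),        # <=3, >=4
    "synthesis": ("<2", "≥2"),        # <2,  >=2
    "metabolism": ("≤3", "≥4"),  # <=3, >=4
}


@dataclass(frozen=True)
class SnpQc:
    """Per-SNP quality control summary."""

    rsid: str
    n_called: int
    maf: float
    hwe_chi2: float
    hwe_p: float

    def passes(self, alpha: float = 0.05) -> bool:
        return self.hwe_p > alpha


@dataclass(frozen=True)
class GrsProfile:
    """The three risk-allele counts and group labels for one sample."""

    sample_id: str
    vitd_grs: Optional[int]
    synthesis_grs: Optional[int]
    metabolism_grs: Optional[int]
    vitd_group: Optional[str]
    synthesis_group: Optional[str]
    metabolism_group: Optional[str]
    complete: bool


def count_risk_alleles(genotype: Genotype, spec: SnpSpec) -> Optional[int]:
    """Number of copies of the 25(OH)D-lowering allele in a call (0/1/2)."""
    if genotype is None:
        return None
    return sum(1 for allele in genotype if allele == spec.risk_allele)


def dominant_carrier(genotype: Genotype, spec: SnpSpec) -> Optional[bool]:
    """Dominant-model indicator: carries at least one risk allele."""
    count = count_risk_alleles(genotype, spec)
    return None if count is None else count >= 1


def compute_maf(genotypes: Iterable[Genotype]) -> float:
    """Minor allele frequency among called genotypes at one SNP.

    The frequency of the rarer allele; always <= 0.5 and invariant to
    which allele label is designated "risk".  Raises on zero calls.
    """
    counts: dict[str, int] = {}
    n_alleles = 0
    for pair in genotypes:
        if pair is None:
            continue
        for allele in pair:
            counts[allele] = counts.get(allele, 0) + 1
            n_alleles += 1
    if n_alleles == 0:
        raise ValueError("compute_maf: no called genotypes")
    if len(counts) == 1:
        return 0.0
    return min(counts.values()) / n_alleles


def hwe_test(n_aa: int, n_ab: int, n_bb: int) -> tuple[float, float]:
    """Pearson 1-df chi-square test of Hardy-Weinberg equilibrium.

    Expected genotype counts (p^2 n, 2pq n, q^2 n) are computed from the
    observed allele frequency p; the p-value is the upper tail of
    chi-square with one degree of freedom.  A monomorphic SNP returns
    (0.0, 1.0) by convention so QC never divides by zero.
    """
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise ValueError("hwe_test: needs at least one genotype")
    p = (2 * n_aa + n_ab) / (2 * n)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        logger.info("hwe_test: monomorphic SNP; chi2=0, p=1 by convention")
        return 0.0, 1.0
    expected = np.array([p * p * n, 2 * p * q * n, q * q * n])
    observed = np.array([n_aa, n_ab, n_bb], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return chi2, float(sps.chi2.sf(chi2, df=1))


def snp_qc(
    participants: Sequence[Participant], manifest: Sequence[SnpSpec]
) -> list[SnpQc]:
    """MAF and HWE for every manifest SNP over the cohort's called genotypes."""
    out = []
    for spec in manifest:
        calls = [p.genotypes.get(spec.rsid) for p in participants]
        called = [c for c in calls if c is not None]
        counts = {0: 0, 1: 0, 2: 0}
        for pair in called:
            counts[sum(1 for a in pair if a == spec.risk_allele)] += 1
        # hwe_test takes (hom_A, het, hom_a) in terms of either labelling
        chi2, p = hwe_test(counts[2], counts[1], counts[0])
        out.append(
            SnpQc(
                rsid=spec.rsid,
                n_called=len(called),
                maf=compute_maf(called),
                hwe_chi2=chi2,
                hwe_p=p,
            )
        )
    return out


def qc_report(qc: Sequence[SnpQc], alpha: float = 0.05) -> pd.DataFrame:
    frame = pd.DataFrame(
        [
            {
                "rsid": q.rsid,
                "n_called": q.n_called,
                "maf": q.maf,
                "hwe_chi2": q.hwe_chi2,
                "hwe_p": q.hwe_p,
                "hwe_pass": q.passes(alpha),
            }
            for q in qc
        ]
    )
    return frame


def _scheme_specs(manifest: Sequence[SnpSpec], scheme: str) -> list[SnpSpec]:
    if scheme == "vitd":
        return list(manifest)
    if scheme in ("synthesis", "metabolism"):
        return [spec for spec in manifest if spec.group == scheme]
    raise ValueError(f"unknown GRS scheme {scheme!r}; expected one of {SCHEMES}")


def build_grs(
    participant: Participant,
    manifest: Sequence[SnpSpec],
    scheme: str = "vitd",
    rescale_missing: bool = False,
) -> Optional[float]:
    """Sum of risk-allele counts over the scheme's SNPs.

    Complete-case by default: any missing constituent genotype makes the
    score missing.  With ``rescale_missing`` the observed sum is scaled
    by n_snps/n_called instead (returns a float).
    """
    specs = _scheme_specs(manifest, scheme)
    counts = [
        count_risk_alleles(participant.genotypes.get(spec.rsid), spec)
        for spec in specs
    ]
    called = [c for c in counts if c is not None]
    if len(called) == len(counts):
        return int(sum(called))
    if rescale_missing and called:
        return sum(called) * len(counts) / len(called)
    return None


def dichotomize_grs(score: Optional[float], scheme: str) -> Optional[str]:
    """Group label for a score: low/high at the scheme's fixed cut-point."""
    if scheme not in _CUTS:
        raise ValueError(f"unknown GRS scheme {scheme!r}; expected one of {SCHEMES}")
    if score is None:
        return None
    low, high = GROUP_LABELS[scheme]
    return high if score >= _CUTS[scheme] else low


def build_profile(
    participant: Participant, manifest: Sequence[SnpSpec]
) -> GrsProfile:
    """All three scores and group labels for one participant."""
    scores = {s: build_grs(participant, manifest, s) for s in SCHEMES}
    return GrsProfile(
        sample_id=participant.sample_id,
        vitd_grs=scores["vitd"],
        synthesis_grs=scores["synthesis"],
        metabolism_grs=scores["metabolism"],
        vitd_group=dichotomize_grs(scores["vitd"], "vitd"),
        synthesis_group=dichotomize_grs(scores["synthesis"], "synthesis"),
        metabolism_group=dichotomize_grs(scores["metabolism"], "metabolism"),
        complete=all(v is not None for v in scores.values()),
    )


def grs_frame(
    participants: Sequence[Participant], manifest: Sequence[SnpSpec]
) -> pd.DataFrame:
    """GRS profiles for a cohort as a DataFrame keyed by sample_id."""
    profiles = [build_profile(p, manifest) for p in participants]
    return pd.DataFrame(
        [
            {
                "sample_id": pr.sample_id,
                "vitd_grs": pr.vitd_grs,
                "synthesis_grs": pr.synthesis_grs,
                "metabolism_grs": pr.metabolism_grs,
                "vitd_group": pr.vitd_group,
                "synthesis_group": pr.synthesis_group,
                "metabolism_group": pr.metabolism_group,
                "complete": pr.complete,
            }
            for pr in profiles
        ]
    )
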