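"""Reading, writing and joining of cohort files.

Three plain-text inputs describe a cohort:

* a SNP manifest (TSV or YAML) naming each variant, its gene, the
  25(OH)D-lowering ("risk") allele, the other allele, and whether the
  gene acts in vitamin D *synthesis* or *metabolism*;
* a long-format genotype table (TSV: sample_id, rsid, allele1, allele2),
  or alternatively a VCF restricted to the manifest variants;
* a phenotype CSV, one row per mother, carrying maternal covariates,
  per-trimester serum 25(OH)D (ng/mL) and the neonatal measurements.

The manifest is the single source of truth for allele coding: the risk
allele is configuration, never inferred from data, and loading fails if
any manifest row leaves it blank.  Missing values propagate as ``None`` /
``NaN``; nothing is ever imputed here.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field, fields as dc_fields
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

VALID_GROUPS = ("synthesis", "metabolism")
_NUCLEOTIDES = frozenset("ACGT")

#: an unordered biallelic genotype call, or None when missing
Genotype = Optional[tuple[str, str]]


class CohortIOError(ValueError):
    """Raised on malformed or inconsistent cohort input files."""


@dataclass(frozen=True)
class SnpSpec:
    """One manifest row: a biallelic SNP and its risk-allele coding."""

    rsid: str
    gene: str
    risk_allele: str
    other_allele: str
    group: str  # "synthesis" or "metabolism"

    def __post_init__(self) -> None:
        if self.group not in VALID_GROUPS:
            raise CohortIOError(
                f"{self.rsid}: unknown group {self.group!r}; "
                f"expected one of {VALID_GROUPS}"
            )
        for name in ("risk_allele", "other_allele"):
            allele = getattr(self, name)
            if allele not in _NUCLEOTIDES:
                raise CohortIOError(
                    f"{self.rsid}: {name} must be a single nucleotide, got {allele!r}"
                )
        if self.risk_allele == self.other_allele:
            raise CohortIOError(f"{self.rsid}: risk and other allele are identical")

    @property
    def alleles(self) -> frozenset[str]:
        return frozenset((self.risk_allele, self.other_allele))


@dataclass
class Participant:
    """Maternal record: covariates, per-trimester 25(OH)D and genotypes.

    25(OH)D values are ng/mL; ``None`` marks a missed visit.  Optional
    per-visit measurements (blood pressure, body weight, MUAC,
    haemoglobin) support the descriptive paired comparisons and may be
    absent entirely.
    """

    sample_id: str
    age: Optional[float] = None                 # years
    height: Optional[float] = None              # cm
    prepreg_weight: Optional[float] = None      # kg
    prepreg_bmi: Optional[float] = None         # kg/m^2
    muac: Optional[float] = None                # cm, at enrolment
    geography: Optional[str] = None             # "mountainous" | "coastal"
    outdoor_activity: Optional[float] = None    # hours/day equivalent
    supplement_use: Optional[bool] = None
    vitd_t1: Optional[float] = None             # ng/mL, first trimester
    vitd_t3: Optional[float] = None             # ng/mL, third trimester
    gestational_age_birth: Optional[float] = None  # weeks
    systolic_t1: Optional[float] = None
    systolic_t3: Optional[float] = None
    weight_t1: Optional[float] = None
    weight_t3: Optional[float] = None
    muac_t3: Optional[float] = None
    hb_t1: Optional[float] = None
    hb_t3: Optional[float] = None
    genotypes: dict[str, Genotype] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("vitd_t1", "vitd_t3"):
            value = getattr(self, name)
            if value is not None and value < 0:
                raise CohortIOError(f"{self.sample_id}: negative {name} ({value})")


@dataclass
class NeonatalRecord:
    """Anthropometry recorded at birth."""

    sample_id: str
    sex: Optional[str] = None          # "male" | "female"
    birth_weight: Optional[float] = None       # g
    birth_length: Optional[float] = None       # cm
    head_circumference: Optional[float] = None  # cm

    def __post_init__(self) -> None:
        for name in ("birth_weight", "birth_length", "head_circumference"):
            value = getattr(self, name)
            if value is not None and value <= 0:
                raise CohortIOError(
                    f"{self.sample_id}: non-positive {name} ({value})"
                )


@dataclass
class CohortDataset:
    """The joined analyzable cohort: mother-infant pairs plus the manifest."""

    participants: list[Participant]
    neonates: list[NeonatalRecord]
    manifest: list[SnpSpec]
    accounting: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.participants)

    def neonate_of(self, sample_id: str) -> NeonatalRecord:
        for record in self.neonates:
            if record.sample_id == sample_id:
                return record
        raise KeyError(sample_id)

    def to_frame(self) -> pd.DataFrame:
        """Flatten mothers + neonates into one row-per-pair DataFrame.

        Genotypes are not included; use :mod:`vdgrs.genetics` to derive
        scores and merge on ``sample_id``.
        """
        neo = {record.sample_id: record for record in self.neonates}
        rows = []
        for mother in self.participants:
            row = {
                f.name: getattr(mother, f.name)
                for f in dc_fields(mother)
                if f.name != "genotypes"
            }
            baby = neo.get(mother.sample_id)
            if baby is not None:
                row.update(
                    sex=baby.sex,
                    birth_weight=baby.birth_weight,
                    birth_length=baby.birth_length,
                    head_circumference=baby.head_circumference,
                )
            rows.append(row)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# manifest

_MANIFEST_COLUMNS = ("rsid", "gene", "risk_allele", "other_allele", "group")


def _specs_from_records(records: Iterable[Mapping[str, str]]) -> list[SnpSpec]:
    specs: list[SnpSpec] = []
    seen: set[str] = set()
    for record in records:
        missing = [c for c in _MANIFEST_COLUMNS if not str(record.get(c, "") or "").strip()]
        if missing:
            raise CohortIOError(
                f"manifest row {record!r} missing field(s): {', '.join(missing)}"
            )
        spec = SnpSpec(
            rsid=str(record["rsid"]).strip(),
            gene=str(record["gene"]).strip(),
            risk_allele=str(record["risk_allele"]).strip().upper(),
            other_allele=str(record["other_allele"]).strip().upper(),
            group=str(record["group"]).strip().lower(),
        )
        if spec.rsid in seen:
            raise CohortIOError(f"duplicate rsID in manifest: {spec.rsid}")
        seen.add(spec.rsid)
        specs.append(spec)
    if not specs:
        raise CohortIOError("manifest contains no SNP records")
    return specs


def read_manifest(path: str | Path) -> list[SnpSpec]:
    """Read a SNP manifest (TSV or YAML) into validated :class:`SnpSpec` rows.

    TSV needs a header with columns ``rsid, gene, risk_allele,
    other_allele, group``; YAML is a list of mappings with the same keys.
    Duplicate rsIDs, unknown pathway groups and absent risk alleles are
    hard errors — the allele coding must be explicit.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".yml", ".yaml"):
        records = yaml.safe_load(path.read_text())
        if not records:
            raise CohortIOError(f"empty manifest: {path}")
        return _specs_from_records(records)
    with path.open(newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        rows = list(reader)
    if not rows:
        raise CohortIOError(f"empty manifest: {path}")
    return _specs_from_records(rows)


def default_manifest() -> list[SnpSpec]:
    """The bundled six-SNP vitamin D panel.

    Two synthesis-pathway variants (DHCR7 rs12785878, CYP2R1 rs12794714)
    and four metabolism-pathway variants (GC rs2282679, CYP24A1
    rs6013897, VDR rs2228570/FokI and rs7975232/ApaI).  Risk alleles are
    the conventional 25(OH)D-lowering alleles from the GWAS literature
    and are configuration: edit a copy of the bundled TSV to change them.
    """
    with resources.as_file(
        resources.files("vdgrs.data").joinpath("default_manifest.tsv")
    ) as path:
        return read_manifest(path)


def write_manifest(specs: Iterable[SnpSpec], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(_MANIFEST_COLUMNS)
        for spec in specs:
            writer.writerow(
                [spec.rsid, spec.gene, spec.risk_allele, spec.other_allele, spec.group]
            )


# ---------------------------------------------------------------------------
# genotypes

def read_genotypes(
    path: str | Path, manifest: list[SnpSpec]
) -> dict[str, dict[str, Genotype]]:
    """Read a long-format genotype TSV into per-sample genotype maps.

    Expected columns: ``sample_id, rsid, allele1, allele2`` (header
    required).  Calls whose alleles are not in the manifest's allele set
    for that SNP are stored as missing with a logged warning; rsIDs not
    in the manifest are ignored.  A sample with no valid manifest call
    is dropped with a warning.
    """
    path = Path(path)
    by_rsid = {spec.rsid: spec for spec in manifest}
    calls: dict[str, dict[str, Genotype]] = {}
    with path.open(newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        required = {"sample_id", "rsid", "allele1", "allele2"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise CohortIOError(
                f"genotype TSV must have columns {sorted(required)}, "
                f"found {reader.fieldnames}"
            )
        for row in reader:
            rsid = row["rsid"].strip()
            spec = by_rsid.get(rsid)
            if spec is None:
                continue
            sample = row["sample_id"].strip()
            pair = (row["allele1"].strip().upper(), row["allele2"].strip().upper())
            store = calls.setdefault(sample, {})
            if pair[0] in ("", ".", "N") or pair[1] in ("", ".", "N"):
                store[rsid] = None
            elif set(pair) <= spec.alleles:
                store[rsid] = pair
            else:
                logger.warning(
                    "sample %s: alleles %s at %s not in manifest set %s; "
                    "recorded as missing",
                    sample, "/".join(pair), rsid, sorted(spec.alleles),
                )
                store[rsid] = None
    for sample in [s for s, g in calls.items() if not g]:
        logger.warning("sample %s has no manifest SNP present; excluded", sample)
        del calls[sample]
    return calls


def read_genotypes_vcf(
    path: str | Path, manifest: list[SnpSpec]
) -> dict[str, dict[str, Genotype]]:
    """VCF convenience adapter: GT fields only, restricted to manifest rsIDs.

    Each biallelic record whose ID matches a manifest rsID contributes
    one call per sample; REF/ALT must match the manifest allele set or
    the whole site is skipped with a warning.  Requires ``cyvcf2``.
    """
    from cyvcf2 import VCF  # optional dependency

    by_rsid = {spec.rsid: spec for spec in manifest}
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    calls: dict[str, dict[str, Genotype]] = {s: {} for s in samples}
    for variant in vcf:
        spec = by_rsid.get(variant.ID)
        if spec is None:
            continue
        if len(variant.ALT) != 1:
            logger.warning("%s: not biallelic; skipped", variant.ID)
            continue
        site_alleles = (variant.REF.upper(), variant.ALT[0].upper())
        if set(site_alleles) != set(spec.alleles):
            logger.warning(
                "%s: VCF alleles %s differ from manifest %s; skipped",
                variant.ID, site_alleles, sorted(spec.alleles),
            )
            continue
        for sample, gt in zip(samples, variant.genotypes):
            a1, a2 = gt[0], gt[1]
            if a1 < 0 or a2 < 0:
                calls[sample][variant.ID] = None
            else:
                calls[sample][variant.ID] = (site_alleles[a1], site_alleles[a2])
    return {s: g for s, g in calls.items() if g}


def write_genotypes(
    calls: Mapping[str, Mapping[str, Genotype]], path: str | Path
) -> None:
    with Path(path).open("w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["sample_id", "rsid", "allele1", "allele2"])
        for sample in calls:
            for rsid, pair in calls[sample].items():
                if pair is None:
                    writer.writerow([sample, rsid, ".", "."])
                else:
                    writer.writerow([sample, rsid, pair[0], pair[1]])


# ---------------------------------------------------------------------------
# phenotypes

_FLOAT_FIELDS = (
    "age", "height", "prepreg_weight", "prepreg_bmi", "muac",
    "outdoor_activity", "vitd_t1", "vitd_t3", "gestational_age_birth",
    "systolic_t1", "systolic_t3", "weight_t1", "weight_t3", "muac_t3",
    "hb_t1", "hb_t3",
)
_NEONATAL_FIELDS = ("birth_weight", "birth_length", "head_circumference")


def _parse_float(raw: Optional[str]) -> Optional[float]:
    if raw is None or str(raw).strip() == "":
        return None
    value = float(raw)
    return None if math.isnan(value) else value


def _parse_bool(raw: Optional[str]) -> Optional[bool]:
    if raw is None or str(raw).strip() == "":
        return None
    text = str(raw).strip().lower()
    if text in ("1", "true", "yes", "y"):
        return True
    if text in ("0", "false", "no", "n"):
        return False
    raise CohortIOError(f"cannot parse boolean value {raw!r}")


def read_phenotypes(
    path: str | Path,
) -> tuple[list[Participant], list[NeonatalRecord]]:
    """Read the one-row-per-mother phenotype CSV.

    Maternal columns mirror :class:`Participant` field names; neonatal
    columns are ``sex, birth_weight, birth_length, head_circumference``.
    Empty numeric cells become ``None`` (never 0).  Negative 25(OH)D or
    non-positive anthropometry is a hard error.
    """
    path = Path(path)
    participants: list[Participant] = []
    neonates: list[NeonatalRecord] = []
    with path.open(newline="") as handle:
        reader = csv.DictReader(handle)
        if reader.fieldnames is None or "sample_id" not in reader.fieldnames:
            raise CohortIOError(f"{path}: phenotype CSV needs a sample_id column")
        for row in reader:
            sample = row["sample_id"].strip()
            kwargs = {
                name: _parse_float(row.get(name)) for name in _FLOAT_FIELDS
            }
            participants.append(
                Participant(
                    sample_id=sample,
                    geography=(row.get("geography") or "").strip() or None,
                    supplement_use=_parse_bool(row.get("supplement_use")),
                    **kwargs,
                )
            )
            neo_values = {
                name: _parse_float(row.get(name)) for name in _NEONATAL_FIELDS
            }
            if any(v is not None for v in neo_values.values()) or row.get("sex"):
                neonates.append(
                    NeonatalRecord(
                        sample_id=sample,
                        sex=(row.get("sex") or "").strip() or None,
                        **neo_values,
                    )
                )
    return participants, neonates


def write_phenotypes(
    participants: Iterable[Participant],
    neonates: Iterable[NeonatalRecord],
    path: str | Path,
) -> None:
    neo = {record.sample_id: record for record in neonates}
    columns = (
        ["sample_id"]
        + list(_FLOAT_FIELDS)
        + ["geography", "supplement_use", "sex"]
        + list(_NEONATAL_FIELDS)
    )

    def fmt(value):
        if value is None:
            return ""
        if isinstance(value, bool):
            return "1" if value else "0"
        return repr(value) if isinstance(value, float) else str(value)

    with Path(path).open("w", newline="") as handle:
        writer = csv.writer(handle, lineterminator="\n")
        writer.writerow(columns)
        for mother in participants:
            baby = neo.get(mother.sample_id)
            row = [mother.sample_id]
            row += [fmt(getattr(mother, name)) for name in _FLOAT_FIELDS]
            row += [fmt(mother.geography), fmt(mother.supplement_use)]
            if baby is None:
                row += ["", "", "", ""]
            else:
                row += [fmt(baby.sex)]
                row += [fmt(getattr(baby, name)) for name in _NEONATAL_FIELDS]
            writer.writerow(row)


# ---------------------------------------------------------------------------
# assembly

def assemble(
    participants: list[Participant],
    neonates: list[NeonatalRecord],
    genotypes: Mapping[str, Mapping[str, Genotype]],
    manifest: list[SnpSpec],
) -> CohortDataset:
    """Inner-join mothers, neonates and genotypes on sample_id.

    The analyzable set is the intersection of the three ID sets; the
    returned dataset's ``accounting`` dict reports how many records each
    source contributed and how many survived the join.  Never fabricates
    records: analyzable <= min of the three input counts.
    """
    ids_m = [p.sample_id for p in participants]
    if len(ids_m) != len(set(ids_m)):
        dupes = sorted({i for i in ids_m if ids_m.count(i) > 1})
        raise CohortIOError(f"duplicate sample_id among mothers: {dupes}")
    ids_n = [r.sample_id for r in neonates]
    if len(ids_n) != len(set(ids_n)):
        dupes = sorted({i for i in ids_n if ids_n.count(i) > 1})
        raise CohortIOError(f"duplicate sample_id among neonates: {dupes}")

    analyzable = set(ids_m) & set(ids_n) & set(genotypes)
    if not analyzable:
        logger.warning("assemble: no sample_id shared by all three inputs")
    kept_mothers = []
    for mother in participants:
        if mother.sample_id in analyzable:
            mother.genotypes = {
                spec.rsid: genotypes[mother.sample_id].get(spec.rsid)
                for spec in manifest
            }
            kept_mothers.append(mother)
    kept_neonates = [r for r in neonates if r.sample_id in analyzable]
    accounting = {
        "mothers": len(ids_m),
        "neonates": len(ids_n),
        "genotyped": len(genotypes),
        "no_genotype": len(set(ids_m) - set(genotypes)),
        "analyzable": len(kept_mothers),
    }
    return CohortDataset(
        participants=kept_mothers,
        neonates=kept_neonates,
        manifest=list(manifest),
        accounting=accounting,
    )


def load_cohort(
    phenotype_path: str | Path,
    genotype_path: str | Path,
    manifest_path: str | Path | None = None,
) -> CohortDataset:
    """One-call loader: manifest (or the bundled default) + phenotypes + genotypes."""
    manifest = (
        default_manifest() if manifest_path is None else read_manifest(manifest_path)
    )
    participants, neonates = read_phenotypes(phenotype_path)
    genotype_path = Path(genotype_path)
    if genotype_path.suffix.lower() in (".vcf", ".gz"):
        genotypes = read_genotypes_vcf(genotype_path, manifest)
    else:
        genotypes = read_genotypes(genotype_path, manifest)
    return assemble(participants, neonates, genotypes, manifest)


def write_cohort(dataset: CohortDataset, outdir: str | Path) -> dict[str, Path]:
    """Write manifest/genotypes/phenotypes so the cohort round-trips."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "manifest": outdir / "manifest.tsv",
        "genotypes": outdir / "genotypes.tsv",
        "phenotypes": outdir / "phenotypes.csv",
    }
    write_manifest(dataset.manifest, paths["manifest"])
    write_genotypes(
        {p.sample_id: p.genotypes for p in dataset.participants}, paths["genotypes"]
    )
    write_phenotypes(dataset.participants, dataset.neonates, paths["phenotypes"])
    return paths
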