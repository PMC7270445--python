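"""File round-trips, validation and the analyzable-set join."""

import logging
import textwrap

import pytest

from vdgrs.cohort_io import (
    CohortIOError,
    NeonatalRecord,
    Participant,
    SnpSpec,
    assemble,
    read_genotypes,
    read_manifest,
    read_phenotypes,
    write_cohort,
    load_cohort,
)
from vdgrs.simulate import GeneratorConfig, generate


class TestManifest:
    def test_default_manifest_pathway_split(self, manifest):
        assert len(manifest) == 6
        groups = [spec.group for spec in manifest]
        assert groups.count("synthesis") == 2
        assert groups.count("metabolism") == 4
        assert len({spec.rsid for spec in manifest}) == 6

    def test_cyp2r1_risk_allele_is_a(self, specs_by_rsid):
        # A-allele carriers have lower 25(OH)D at this variant
        assert specs_by_rsid["rs12794714"].risk_allele == "A"
        assert specs_by_rsid["rs7975232"].risk_allele == "A"

    def test_duplicate_rsid_rejected(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text(
            "rsid\tgene\trisk_allele\tother_allele\tgroup\n"
            "rs1\tG1\tA\tG\tsynthesis\n"
            "rs1\tG1\tA\tG\tsynthesis\n"
        )
        with pytest.raises(CohortIOError, match="duplicate"):
            read_manifest(path)

    def test_unknown_group_rejected(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text(
            "rsid\tgene\trisk_allele\tother_allele\tgroup\n"
            "rs1\tG1\tA\tG\ttransport\n"
        )
        with pytest.raises(CohortIOError, match="group"):
            read_manifest(path)

    def test_empty_manifest_rejected(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("")
        with pytest.raises(CohortIOError, match="empty"):
            read_manifest(path)

    def test_missing_risk_allele_rejected(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text(
            "rsid\tgene\trisk_allele\tother_allele\tgroup\n"
            "rs1\tG1\t\tG\tsynthesis\n"
        )
        with pytest.raises(CohortIOError, match="risk_allele"):
            read_manifest(path)

    def test_yaml_manifest(self, tmp_path):
        path = tmp_path / "m.yaml"
        path.write_text(
            "- {rsid: rs2282679, gene: GC, risk_allele: C, other_allele: A, group: metabolism}\n"
        )
        specs = read_manifest(path)
        assert specs[0].alleles == frozenset("AC")

    def test_identical_alleles_rejected(self):
        with pytest.raises(CohortIOError, match="identical"):
            SnpSpec("rs1", "G1", "A", "A", "synthesis")


class TestGenotypes:
    def test_valid_and_invalid_calls(self, tmp_path, manifest, caplog):
        path = tmp_path / "g.tsv"
        path.write_text(
            "sample_id\trsid\tallele1\tallele2\n"
            "S001\trs2282679\tA\tC\n"
            "S002\trs2282679\tT\tC\n"  # T not in manifest set {A,C}
            "S001\trs9999999\tA\tC\n"  # not in manifest: ignored
        )
        with caplog.at_level(logging.WARNING):
            calls = read_genotypes(path, manifest)
        assert calls["S001"]["rs2282679"] == ("A", "C")
        assert calls["S002"]["rs2282679"] is None
        assert "not in manifest set" in caplog.text

    def test_sample_with_no_manifest_snp_excluded(self, tmp_path, manifest, caplog):
        path = tmp_path / "g.tsv"
        path.write_text(
            "sample_id\trsid\tallele1\tallele2\n"
            "S009\trs9999999\tA\tC\n"   # only a non-manifest variant
            "S010\trs2282679\t.\t.\n"   # explicit missing call: kept as missing
        )
        with caplog.at_level(logging.WARNING):
            calls = read_genotypes(path, manifest)
        assert "S009" not in calls
        assert calls["S010"]["rs2282679"] is None

    def test_vcf_het_call(self, tmp_path, manifest):
        cyvcf2 = pytest.importorskip("cyvcf2")  # noqa: F841
        from vdgrs.cohort_io import read_genotypes_vcf

        vcf = tmp_path / "g.vcf"
        vcf.write_text(textwrap.dedent("""\
            ##fileformat=VCFv4.2
            ##contig=<ID=20>
            ##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
            #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS001\tS002
            20\t1000\trs6013897\tT\tA\t.\tPASS\t.\tGT\t0/1\t1/1
            """))
        calls = read_genotypes_vcf(vcf, manifest)
        assert sorted(calls["S001"]["rs6013897"]) == ["A", "T"]
        assert calls["S002"]["rs6013897"] == ("A", "A")


class TestPhenotypes:
    HEADER = "sample_id,age,vitd_t1,vitd_t3,sex,birth_weight,birth_length,head_circumference\n"

    def test_well_formed_rows(self, tmp_path):
        path = tmp_path / "p.csv"
        path.write_text(
            self.HEADER
            + "S001,28,12.5,21.0,male,3100,49,34\n"
            + "S002,31,9.1,15.2,female,2900,50,35\n"
            + "S003,25,20.0,28.4,male,3600,52,36\n"
        )
        mothers, babies = read_phenotypes(path)
        assert len(mothers) == 3 and len(babies) == 3
        assert mothers[0].vitd_t1 == 12.5

    def test_missing_cell_becomes_none(self, tmp_path):
        path = tmp_path / "p.csv"
        path.write_text(self.HEADER + "S001,28,12.5,,male,3100,49,34\n")
        mothers, _ = read_phenotypes(path)
        assert mothers[0].vitd_t3 is None

    def test_negative_birth_weight_rejected(self, tmp_path):
        path = tmp_path / "p.csv"
        path.write_text(self.HEADER + "S001,28,12.5,21.0,male,-5,49,34\n")
        with pytest.raises(CohortIOError, match="birth_weight"):
            read_phenotypes(path)

    def test_negative_vitd_rejected(self, tmp_path):
        path = tmp_path / "p.csv"
        path.write_text(self.HEADER + "S001,28,-1,21.0,male,3100,49,34\n")
        with pytest.raises(CohortIOError, match="vitd_t1"):
            read_phenotypes(path)


class TestAssemble:
    def _mothers(self, n, prefix="S"):
        return [Participant(sample_id=f"{prefix}{i:03d}", vitd_t1=10.0) for i in range(n)]

    def _babies(self, n, prefix="S"):
        return [
            NeonatalRecord(sample_id=f"{prefix}{i:03d}", birth_weight=3000.0)
            for i in range(n)
        ]

    def test_low_dna_exclusion_accounting(self, manifest):
        # 186 completers, 3 of whom lack genotypes -> 183 analyzable pairs
        mothers = self._mothers(186)
        babies = self._babies(186)
        genotypes = {
            m.sample_id: {"rs2282679": ("A", "C")} for m in mothers[:183]
        }
        ds = assemble(mothers, babies, genotypes, manifest)
        assert ds.accounting["analyzable"] == 183
        assert ds.accounting["no_genotype"] == 3
        assert len(ds) == 183

    def test_disjoint_ids_yield_empty_join(self, manifest, caplog):
        with caplog.at_level(logging.WARNING):
            ds = assemble(
                self._mothers(5, "A"), self._babies(5, "B"), {}, manifest
            )
        assert len(ds) == 0
        assert "no sample_id" in caplog.text

    def test_matched_ids_all_kept(self, manifest):
        mothers = self._mothers(10)
        genotypes = {m.sample_id: {"rs2282679": ("A", "C")} for m in mothers}
        ds = assemble(mothers, self._babies(10), genotypes, manifest)
        assert len(ds) == 10

    def test_duplicate_mother_id_rejected(self, manifest):
        mothers = self._mothers(3) + self._mothers(1)
        with pytest.raises(CohortIOError, match="duplicate"):
            assemble(mothers, self._babies(3), {}, manifest)

    def test_never_fabricates_records(self, manifest):
        mothers = self._mothers(8)
        babies = self._babies(5)
        genotypes = {m.sample_id: {"rs2282679": ("A", "C")} for m in mothers[:6]}
        ds = assemble(mothers, babies, genotypes, manifest)
        assert len(ds) <= min(len(mothers), len(babies), len(genotypes))


class TestRoundTrip:
    def test_cohort_files_round_trip_exactly(self, tmp_path):
        ds = generate(GeneratorConfig(seed=3, n_enrolled=40, dropout_n=5, low_dna_n=1))
        paths = write_cohort(ds, tmp_path)
        back = load_cohort(paths["phenotypes"], paths["genotypes"], paths["manifest"])
        assert len(back) == len(ds)
        by_id = {p.sample_id: p for p in back.participants}
        for original in ds.participants:
            copy = by_id[original.sample_id]
            assert copy.vitd_t1 == original.vitd_t1  # full float precision
            assert copy.vitd_t3 == original.vitd_t3
            assert copy.age == original.age
            assert copy.genotypes == original.genotypes
            assert copy.supplement_use == original.supplement_use
        for original, copy in zip(
            sorted(ds.neonates, key=lambda r: r.sample_id),
            sorted(back.neonates, key=lambda r: r.sample_id),
        ):
            assert copy.birth_weight == original.birth_weight
            assert copy.sex == original.sex
        assert back.manifest == ds.manifest
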