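"""Candidate filter semantics, spectrum summaries, sibling analyses."""

import numpy as np
import pytest

from enuscreen import (
    ScreenCohort,
    classify_deleterious,
    filter_enu_candidates,
    load_variants,
    sib_shared_variants,
    simulate_sib_group,
    spectrum_summary,
    stemcell_origin_test,
    write_cohort,
)
from enuscreen.filtering import SibGroup, VariantRecord, VcfParseError, SampleIdError


def _rec(pos, genotypes, depths=None, csq="nonsynonymous", gene="gA"):
    return VariantRecord(
        chrom="1", pos=pos, ref="T", alt="C",
        genotypes=genotypes,
        depths=depths or {s: 50 for s in genotypes},
        gene_id=gene, csq_class=csq, sub_class="T/A->C/G",
    )


class TestFilterRules:
    def test_shared_unique_and_depth_rules(self):
        records = [
            _rec(100, {"m1": "het", "m2": "het", "m3": "hom_ref"}),       # shared
            _rec(200, {"m1": "het", "m2": "hom_ref", "m3": "hom_ref"},
                 depths={"m1": 5, "m2": 60, "m3": 60}),                   # low depth
            _rec(300, {"m1": "het", "m2": "hom_ref", "m3": "hom_ref"},
                 depths={"m1": 6, "m2": 60, "m3": 60}),                   # boundary: keep
            _rec(400, {"m1": "hom_alt", "m2": "hom_ref", "m3": "hom_ref"}),  # not het
            _rec(500, {"m1": "het", "m2": "missing", "m3": "hom_ref"}),   # missing != presence
        ]
        out = filter_enu_candidates(records, min_depth=6)
        assert [(c.pos, c.mouse_id) for c in out.candidates] == [(300, "m1"), (500, "m1")]
        reasons = {rec.pos: reason for rec, reason in out.removed}
        assert reasons == {100: "shared", 200: "low_depth", 400: "not_het"}

    def test_removal_reasons_partition_input(self, artifact_records, artifact_candidates):
        assert len(artifact_candidates.candidates) + len(artifact_candidates.removed) == len(
            artifact_records
        )
        counts = artifact_candidates.removal_counts()
        assert set(counts) == {"shared", "not_het", "low_depth"}
        assert sum(counts.values()) == len(artifact_candidates.removed)

    def test_filter_is_idempotent(self, artifact_candidates):
        again = filter_enu_candidates(artifact_candidates.to_records(), min_depth=6)
        assert len(again.removed) == 0
        assert {(c.chrom, c.pos, c.mouse_id) for c in again.candidates} == {
            (c.chrom, c.pos, c.mouse_id) for c in artifact_candidates.candidates
        }

    def test_truth_table_oracle(self, artifact_cohort, artifact_candidates):
        truth = artifact_cohort.truth_table().set_index("key")
        retained_keys = {
            f"{c.chrom}:{c.pos}:{c.ref}:{c.alt}" for c in artifact_candidates.candidates
        }
        # every retained variant is a genuine singleton (ENU or de novo)
        assert set(truth.loc[sorted(retained_keys)].origin) <= {"ENU", "de_novo"}
        # every multi-carrier artifact was removed
        artifact_keys = set(truth[truth.origin == "artifact"].index)
        assert not (artifact_keys & retained_keys)
        # 100% recall of unique ENU variants with carrier depth >= 6
        expected = {
            v.key
            for m in artifact_cohort.mice
            for v in m.variants
            if v.origin == "ENU"
            and v.depths[m.mouse_id] >= 6
            and truth.loc[v.key, "n_carriers"] == 1
        }
        assert expected <= retained_keys


class TestDeleteriousClassification:
    @pytest.mark.parametrize(
        "csq,expected",
        [
            ("nonsynonymous", True), ("missense", True), ("stopgain", True),
            ("nonsense", True), ("splice", True), ("INDEL", True), ("frameshift", True),
            ("synonymous", False), ("UTR", False), ("stoploss", False),
            ("intergenic", False),
        ],
    )
    def test_class_gate(self, csq, expected):
        assert classify_deleterious(csq) is expected

    def test_stoploss_toggle(self):
        assert classify_deleterious("stoploss", include_stoploss=True) is True

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError, match="unknown consequence"):
            classify_deleterious("mystery")


class TestSpectrumSummary:
    def test_fractions_and_per_mouse_accounting(self, artifact_cohort, artifact_candidates):
        sexes = {m.mouse_id: m.sex for m in artifact_cohort.mice}
        s = spectrum_summary(artifact_candidates, sexes)
        assert float(s.class_fractions.sum()) == pytest.approx(1.0, abs=1e-9)
        assert float(s.sub_fractions.sum()) == pytest.approx(1.0, abs=1e-9)
        assert int(s.class_counts.sum()) == len(artifact_candidates)
        assert int(s.per_mouse.sum()) == len(artifact_candidates)
        assert s.mean_per_mouse > 0

    def test_all_male_cohort_has_no_x_candidates(self, annotation_small, spectrum):
        from enuscreen import ScreenConfig, simulate_screen

        cfg = ScreenConfig(n_g1_mice=12, female_fraction=0.0, artifact_rate=0.0,
                           de_novo_rate=0.0, seed=3)
        cohort = simulate_screen(cfg, spectrum, annotation_small)
        assert all(m.sex == "M" for m in cohort.mice)
        assert not any(v.chrom == "X" for m in cohort.mice for v in m.variants)


class TestSibAnalyses:
    def _sib_records(self):
        return [
            _rec(100, {"s1": "het", "s2": "het", "u1": "hom_ref"}),  # within-pair share
            _rec(200, {"s1": "het", "u1": "het", "s2": "hom_ref"}),  # crosses group boundary
            _rec(300, {"s1": "het", "s2": "hom_ref", "u1": "hom_ref"}),  # private
            _rec(400, {"s1": "het", "s2": "het", "u1": "hom_ref"}, csq="synonymous"),
        ]

    def test_shared_within_group_only(self):
        group = SibGroup("p1", ("s1", "s2"))
        shared = sib_shared_variants(self._sib_records(), [group])
        assert [(s.record.pos, s.protein_altering) for s in shared] == [
            (100, True), (400, False)
        ]

    def test_overlapping_groups_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            sib_shared_variants([], [SibGroup("a", ("s1", "s2")), SibGroup("b", ("s2", "s3"))])

    def test_stemcell_boundary_is_strict(self):
        # 1 shared of min 10 candidates -> fraction exactly 0.10 -> not plausible
        records = [_rec(100 + i, {"s1": "het", "s2": "hom_ref"}) for i in range(9)]
        records += [_rec(300 + i, {"s2": "het", "s1": "hom_ref"}) for i in range(9)]
        records.append(_rec(500, {"s1": "het", "s2": "het"}))
        r = stemcell_origin_test(SibGroup("p1", ("s1", "s2")), records)
        assert r.fraction == pytest.approx(0.10)
        assert r.plausible is False

    def test_zero_candidate_member_is_error(self):
        records = [_rec(100, {"s1": "het", "s2": "hom_ref"})]
        with pytest.raises(ValueError, match="zero candidate"):
            stemcell_origin_test(SibGroup("p1", ("s1", "s2")), records)

    def test_simulated_stem_cell_sibs_share_half(self, annotation_small, spectrum, tmp_path):
        from enuscreen import ScreenConfig

        cfg = ScreenConfig(seed=0)
        sibs = simulate_sib_group(cfg, spectrum, annotation_small, 2,
                                  same_stem_cell=True, seed=42)
        cohort = ScreenCohort(mice=sibs, artifacts=[], annotation=annotation_small,
                              config=cfg, spectrum=spectrum)
        paths = write_cohort(cohort, tmp_path / "c.vcf", tmp_path / "t.tsv",
                             tmp_path / "a.tsv")
        records = load_variants(paths["vcf"], annotation=annotation_small)
        r = stemcell_origin_test(SibGroup("sib", tuple(m.mouse_id for m in sibs)), records)
        n = min(r.member_counts.values())
        assert r.fraction == pytest.approx(0.5, abs=3 * np.sqrt(0.25 / n))
        assert r.plausible is True
        # and independent sibs share essentially nothing
        indep = simulate_sib_group(cfg, spectrum, annotation_small, 2,
                                   same_stem_cell=False, seed=43)
        cohort2 = ScreenCohort(mice=indep, artifacts=[], annotation=annotation_small,
                               config=cfg, spectrum=spectrum)
        paths2 = write_cohort(cohort2, tmp_path / "c2.vcf", tmp_path / "t2.tsv",
                              tmp_path / "a2.tsv")
        r2 = stemcell_origin_test(
            SibGroup("sib", tuple(m.mouse_id for m in indep)),
            load_variants(paths2["vcf"], annotation=annotation_small),
        )
        assert r2.fraction < 0.05 and r2.plausible is False


class TestLoaderErrors:
    def test_multiallelic_rejected(self, tmp_path):
        vcf = tmp_path / "m.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n##contig=<ID=1>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="d">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tm1\n"
            "1\t100\t.\tA\tC,G\t.\tPASS\t.\tGT:DP\t0/1:30\n"
        )
        with pytest.raises(VcfParseError, match="multi-allelic"):
            load_variants(vcf)

    def test_sample_mismatch_rejected(self, artifact_cohort_files, annotation_small):
        with pytest.raises(SampleIdError):
            load_variants(artifact_cohort_files["vcf"], annotation=annotation_small,
                          expected_samples=["nobody"])
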