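"""Generator contracts: mutation load, spectrum, sex rules, determinism."""

import numpy as np
import pytest

from enuscreen import (
    ScreenConfig,
    SpectrumConfig,
    build_annotation,
    simulate_g1_mouse,
    simulate_rescue_pedigree,
    simulate_screen,
    write_cohort,
)
from enuscreen.linkage import informative_meioses
from enuscreen.simulate import CONSEQUENCE_CLASSES, SUBSTITUTION_CLASSES


class TestBuildAnnotation:
    def test_full_universe_size_and_length(self):
        ann = build_annotation(20586, seed=0)
        assert ann.n_genes == 20586
        assert ann.total_cds_length > 0
        assert abs(float(ann.probabilities().sum()) - 1.0) < 1e-9

    def test_single_gene_has_probability_one(self):
        ann = build_annotation(1, seed=0)
        assert ann.n_genes == 1
        assert float(ann.probabilities().iloc[0]) == pytest.approx(1.0)

    def test_same_seed_gives_identical_tables(self):
        a = build_annotation(300, seed=5).to_frame()
        b = build_annotation(300, seed=5).to_frame()
        assert a.equals(b)

    def test_giant_gene_outlier_present(self):
        ann = build_annotation(500, seed=1)
        assert max(g.cds_length for g in ann.genes) == 100_000

    def test_rejects_nonpositive_gene_count(self):
        with pytest.raises(ValueError):
            build_annotation(0)


class TestMutationLoad:
    def test_mean_exonic_variants_near_lambda(self, mouse_pool):
        counts = [len(m.variants) for m in mouse_pool]
        # Poisson(65): mean recovered to within 0.5 over ~2,000 genomes
        assert np.mean(counts) == pytest.approx(65.0, abs=0.5)

    def test_males_carry_no_x_linked_enu_variants(self, mouse_pool):
        for m in mouse_pool:
            if m.sex == "M":
                assert not any(v.chrom == "X" for v in m.variants)
        females_x = sum(
            1 for m in mouse_pool if m.sex == "F" for v in m.variants if v.chrom == "X"
        )
        assert females_x > 0  # females do carry paternal X mutations

    def test_deleterious_load_tracks_class_mix(self, annotation_small):
        # deleterious classes summing to 0.5 -> ~32.5 deleterious per mouse
        spec = SpectrumConfig(class_probs={
            "nonsynonymous": 0.43, "splice": 0.02, "stopgain": 0.02, "INDEL": 0.03,
            "UTR": 0.31, "synonymous": 0.15, "stoploss": 0.04,
        })
        cfg = ScreenConfig(de_novo_rate=0.0)
        rng = np.random.default_rng(9)
        dels = []
        for i in range(400):
            m = simulate_g1_mouse(cfg, spec, annotation_small, "F", rng, f"d{i}")
            dels.append(sum(v.deleterious for v in m.variants))
        se = np.std(dels, ddof=1) / np.sqrt(len(dels))
        assert np.mean(dels) == pytest.approx(32.5, abs=3 * se)

    def test_empty_annotation_rejected(self, spectrum):
        from enuscreen.simulate import Annotation

        with pytest.raises(ValueError):
            Annotation([])


class TestSpectrumFrequencies:
    def test_class_and_substitution_frequencies_match_config(self, mouse_pool, spectrum):
        variants = [v for m in mouse_pool for v in m.variants]
        assert len(variants) > 100_000
        n = len(variants)
        for cls in CONSEQUENCE_CLASSES:
            p = spectrum.class_probs[cls]
            obs = sum(1 for v in variants if v.csq_class == cls) / n
            se = np.sqrt(p * (1 - p) / n)
            assert abs(obs - p) <= 3 * se + 1e-12, cls
        snvs = [v for v in variants if v.sub_class is not None]
        for sub in SUBSTITUTION_CLASSES:
            p = spectrum.substitution_probs[sub]
            obs = sum(1 for v in snvs if v.sub_class == sub) / len(snvs)
            se = np.sqrt(p * (1 - p) / len(snvs))
            assert abs(obs - p) <= 3 * se + 1e-12, sub


class TestRescueModel:
    def test_full_penetrance_rescue_equivalence(self, annotation_small, spectrum):
        suppressors = {g: 1.0 for g in annotation_small.gene_ids[:20]}
        cfg = ScreenConfig(n_g1_mice=200, suppressor_genes=suppressors,
                           phenocopy_rate=0.0, artifact_rate=0.0, seed=13)
        cohort = simulate_screen(cfg, spectrum, annotation_small)
        for m in cohort.mice:
            carries = any(
                v.gene_id in suppressors and v.deleterious for v in m.variants
            )
            assert m.rescue_status == carries

    def test_phenocopy_rate_recovered_without_suppressors(self, annotation_small):
        spec = SpectrumConfig(exonic_rate_lambda=1.0)  # variant load irrelevant here
        cfg = ScreenConfig(n_g1_mice=3000, phenocopy_rate=0.02,
                           artifact_rate=0.0, de_novo_rate=0.0, seed=17)
        cohort = simulate_screen(cfg, spec, annotation_small)
        frac = np.mean([m.rescue_status for m in cohort.mice])
        se = np.sqrt(0.02 * 0.98 / 3000)
        assert frac == pytest.approx(0.02, abs=3 * se)

    def test_rescue_selected_cohort_is_all_rescues_and_enriched(self, annotation_small):
        from enuscreen import simulate_rescue_cohort

        spec = SpectrumConfig(exonic_rate_lambda=30.0)
        suppressors = {g: 1.0 for g in annotation_small.gene_ids[:40]}
        cfg = ScreenConfig(n_g1_mice=25, suppressor_genes=suppressors,
                           phenocopy_rate=0.0, artifact_rate=0.0, seed=31)
        cohort, screened = simulate_rescue_cohort(cfg, spec, annotation_small)
        assert len(cohort.mice) == 25 and screened >= 25
        assert all(m.rescue_status for m in cohort.mice)
        # with zero phenocopies every selected mouse carries a suppressor hit
        for m in cohort.mice:
            assert any(v.gene_id in suppressors and v.deleterious for v in m.variants)

    def test_unknown_suppressor_gene_rejected(self, annotation_small, spectrum):
        cfg = ScreenConfig(n_g1_mice=2, suppressor_genes={"nope": 0.5}, seed=1)
        with pytest.raises(ValueError, match="suppressor"):
            simulate_screen(cfg, spectrum, annotation_small)


class TestArtifactsAndTruth:
    def test_artifact_variants_have_multiple_carriers(self, artifact_cohort):
        truth = artifact_cohort.truth_table()
        artifacts = truth[truth.origin == "artifact"]
        assert len(artifacts) > 0
        assert (artifacts.n_carriers >= 2).all()

    def test_enu_variants_are_single_founder(self, artifact_cohort):
        truth = artifact_cohort.truth_table()
        assert (truth[truth.origin == "ENU"].n_carriers == 1).all()

    def test_no_variant_lost_in_serialization(self, artifact_cohort):
        per_mouse_total = sum(len(m.variants) for m in artifact_cohort.mice)
        truth = artifact_cohort.truth_table()
        merged_carrier_total = int(
            truth[truth.origin.isin(["ENU", "de_novo"])].n_carriers.sum()
        )
        assert merged_carrier_total == per_mouse_total


class TestDeterminism:
    def test_fixed_seed_byte_identical_outputs(self, artifact_cohort, tmp_path):
        a, b = tmp_path / "a", tmp_path / "b"
        a.mkdir(), b.mkdir()
        for d in (a, b):
            write_cohort(artifact_cohort, d / "c.vcf", d / "t.tsv", d / "g.tsv")
        assert (a / "c.vcf").read_bytes() == (b / "c.vcf").read_bytes()
        assert (a / "t.tsv").read_bytes() == (b / "t.tsv").read_bytes()

    def test_extending_cohort_preserves_earlier_mice(self, annotation_small, spectrum):
        cfg10 = ScreenConfig(n_g1_mice=10, artifact_rate=0.0, seed=23)
        cfg12 = ScreenConfig(n_g1_mice=12, artifact_rate=0.0, seed=23)
        c10 = simulate_screen(cfg10, spectrum, annotation_small)
        c12 = simulate_screen(cfg12, spectrum, annotation_small)
        for m10, m12 in zip(c10.mice, c12.mice):
            assert [(v.chrom, v.pos, v.alt) for v in m10.variants] == [
                (v.chrom, v.pos, v.alt) for v in m12.variants
            ]


class TestRescuePedigree:
    def test_complete_linkage_yields_no_recombinants(self):
        ped = simulate_rescue_pedigree("F0", 10, 0.0, generations=3,
                                       rng=np.random.default_rng(3))
        tally = informative_meioses(ped)
        assert tally.r == 0 and tally.n > 0

    def test_recombination_fraction_recovered(self):
        ped = simulate_rescue_pedigree("F0", 14, 0.141, generations=4,
                                       rng=np.random.default_rng(5))
        tally = informative_meioses(ped)
        assert tally.n > 1000
        frac = tally.r / tally.n
        se = np.sqrt(0.141 * 0.859 / tally.n)
        assert frac == pytest.approx(0.141, abs=3 * se)

    def test_free_recombination_decouples_marker(self):
        ped = simulate_rescue_pedigree("F0", 2000, 0.5, generations=1,
                                       rng=np.random.default_rng(8))
        tally = informative_meioses(ped)
        assert tally.r / tally.n == pytest.approx(0.5, abs=3 * np.sqrt(0.25 / tally.n))

    @pytest.mark.parametrize("theta", [-0.01, 0.51])
    def test_invalid_theta_rejected(self, theta):
        with pytest.raises(ValueError):
            simulate_rescue_pedigree("F0", 5, theta)


class TestVcfRoundTrip:
    def test_sample_columns_and_format(self, artifact_cohort_files, artifact_cohort):
        text = open(artifact_cohort_files["vcf"]).read()
        header = [l for l in text.splitlines() if l.startswith("#CHROM")][0]
        assert header.split("\t")[9:] == artifact_cohort.mouse_ids
        assert "##FORMAT=<ID=GT" in text and "##FORMAT=<ID=DP" in text
        assert "0/1:" in text  # heterozygous encoding

    def test_round_trip_preserves_variants(self, artifact_cohort, artifact_records):
        sim = {
            (v.chrom, v.pos, v.ref, v.alt, v.carriers)
            for v in artifact_cohort.all_variants()
        }
        loaded = {
            (r.chrom, r.pos, r.ref, r.alt, tuple(sorted(r.het_carriers())))
            for r in artifact_records
        }
        assert sim == loaded
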