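"""Kinship coefficients, couple simulator and the demonstration cohort fixture."""

import filecmp
import os

import numpy as np
import pytest

from couplescreen.filters import filter_parent_variants
from couplescreen.fixture import build_table1_fixture, write_fixture
from couplescreen.matching import match_all
from couplescreen.synthetic import (PedigreeRelation, SimulationConfig,
                                    expected_shared_genes, kinship_coefficient,
                                    simulate_couple)
from couplescreen.variants import write_annotated_vcf
from conftest import screen_family


class TestKinship:
    def test_unrelated_zero(self):
        assert kinship_coefficient(PedigreeRelation("unrelated")) == 0.0

    def test_first_cousins_one_sixteenth(self):
        assert kinship_coefficient(PedigreeRelation("first_cousins")) == 1 / 16

    def test_double_first_cousins_path_counting_oracle(self):
        # four connecting loops of 4 meioses each, (1/2)^5 per loop
        oracle = sum(0.5 ** (4 + 1) for _ in range(4))
        assert kinship_coefficient(
            PedigreeRelation("double_first_cousins")) == oracle == 1 / 8

    def test_custom_paths(self):
        assert kinship_coefficient(
            PedigreeRelation("custom", custom_paths=(2, 2))) == 0.25  # siblings
        with pytest.raises(ValueError):
            PedigreeRelation("custom", custom_paths=(1,))
        with pytest.raises(ValueError):
            PedigreeRelation("custom")


class TestExpectedSharedGenes:
    def test_chance_sharing_single_common_variant(self):
        cfg = SimulationConfig(n_background_variants=1,
                               maf_spectrum=((0.5, 1.0),), kinship=0.0)
        assert expected_shared_genes(cfg) == pytest.approx(0.5)  # 2*0.5*0.5

    def test_first_cousin_private_variants_closed_form(self):
        cfg = SimulationConfig(n_background_variants=64,
                               maf_spectrum=((0.0, 1.0),), kinship=1 / 16)
        assert expected_shared_genes(cfg) == pytest.approx(4.0)

    def test_planted_candidates_add_one_each(self):
        cfg = SimulationConfig(n_background_variants=0,
                               planted_candidates=(("A", "shared_hom"),
                                                   ("B", "compound_het")))
        assert expected_shared_genes(cfg) == 2.0


class TestSimulateCouple:
    def test_no_sharing_mechanism_yields_zero_shared(self):
        cfg = SimulationConfig(n_background_variants=30,
                               maf_spectrum=((0.0, 1.0),), kinship=0.0, seed=1)
        _, _, truth = simulate_couple(cfg)
        assert truth == []

    def test_planted_candidates_recovered_by_pipeline(self):
        cfg = SimulationConfig(n_background_variants=16, seed=3,
                               planted_candidates=(("GENEA", "shared_hom"),
                                                   ("GENEB", "compound_het")))
        mother, father, truth = simulate_couple(cfg)
        cands = {(c.gene, c.mode.value)
                 for c in match_all(filter_parent_variants(mother),
                                    filter_parent_variants(father))}
        assert ("GENEA", "shared_hom") in cands
        assert ("GENEB", "compound_het") in cands

    def test_recovery_complete_over_100_seeds(self):
        planted = (("GENEA", "shared_hom"), ("GENEB", "compound_het"))
        for seed in range(100):
            cfg = SimulationConfig(n_background_variants=16, seed=seed,
                                   planted_candidates=planted)
            mother, father, truth = simulate_couple(cfg)
            cands = {(c.gene, c.mode.value)
                     for c in match_all(filter_parent_variants(mother),
                                        filter_parent_variants(father))}
            assert set(planted) <= cands, seed
            # false candidates only from background sharing
            extra = {g for g, _ in cands} - {g for g, _ in planted}
            assert all(g.startswith("BG") for g in extra)

    def test_empirical_shared_count_matches_closed_form(self):
        base = dict(n_background_variants=64, maf_spectrum=((1e-6, 1.0),),
                    kinship=1 / 16)
        expected = expected_shared_genes(SimulationConfig(**base))
        sizes = [len(simulate_couple(SimulationConfig(**base, seed=s))[2])
                 for s in range(2000)]
        mean = np.mean(sizes)
        se = np.std(sizes, ddof=1) / np.sqrt(len(sizes))
        assert abs(mean - expected) < 3 * se

    def test_identical_seed_byte_identical_vcfs(self, tmp_path):
        cfg = SimulationConfig(seed=7)
        for tag in ("a", "b"):
            mother, father, _ = simulate_couple(cfg)
            write_annotated_vcf(str(tmp_path / f"m_{tag}.vcf"), mother,
                                sample_ids=["MOTHER"])
            write_annotated_vcf(str(tmp_path / f"f_{tag}.vcf"), father,
                                sample_ids=["FATHER"])
        assert (tmp_path / "m_a.vcf").read_bytes() == (tmp_path / "m_b.vcf").read_bytes()
        assert (tmp_path / "f_a.vcf").read_bytes() == (tmp_path / "f_b.vcf").read_bytes()

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(kinship=0.3)
        with pytest.raises(ValueError):
            SimulationConfig(maf_spectrum=((0.1, 0.5),))
        with pytest.raises(ValueError):
            SimulationConfig(planted_candidates=(("G", "trans_het"),))


class TestCohortFixture:
    def test_cohort_size_and_consanguinity(self, cohort):
        assert len(cohort.families) == 13
        assert sum(f.is_consanguineous for f in cohort.families) == 8

    def test_family4_carries_the_splice_variant_in_both_parents(self, cohort):
        fam4 = cohort.families[3]
        for parent in (fam4.mother, fam4.father):
            hits = [r for r in parent if r.variant.gene == "UNC13D"]
            assert len(hits) == 1
            assert hits[0].variant.hgvs_c == "c.2447+1G>T"
            assert hits[0].variant.transcript == "NM_199242"

    def test_family9_yields_no_candidate_after_full_pipeline(self, cohort):
        fam9 = cohort.families[8]
        report = screen_family(fam9)
        assert report.candidates == ()
        assert report.summary_tier == "no_finding"

    def test_fixture_build_is_deterministic(self, tmp_path):
        a, b = tmp_path / "a", tmp_path / "b"
        write_fixture(build_table1_fixture(), str(a))
        write_fixture(build_table1_fixture(), str(b))
        for root, _, files in os.walk(a):
            rel = os.path.relpath(root, a)
            for f in files:
                pa, pb = os.path.join(root, f), os.path.join(b, rel, f)
                assert filecmp.cmp(pa, pb, shallow=False), (rel, f)

    def test_manifest_records_the_transcript_discrepancy(self, cohort):
        notes = " ".join(cohort.manifest["notes"])
        assert "c.1274T>C" in notes and "c.1436T>C" in notes
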