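"""Synthetic cohort generator: determinism, feasibility, internal
consistency of planted annotations, the MNV planting oracle, and the
age-shift property of somatic carriers."""

import numpy as np
import pytest
from Bio.Seq import Seq

from ptriage import io as pio
from ptriage.genes import TranscriptModel
from ptriage.simulate import (
    CohortConfig,
    InfeasibleConfigError,
    ScenarioSpec,
    draw_ages,
    generate_cohort,
    plant_mnv_pair,
)
from ptriage.triage import wilcoxon_rank_sum

SMALL = CohortConfig(
    n_samples=120,
    scenarios=[
        ScenarioSpec("true_lof_unexplained", n_variants=1, carriers=2),
        ScenarioSpec("last_exon_25", n_variants=1, carriers=2),
        ScenarioSpec("cis_rescue_haplotype", n_variants=1, carriers=5),
    ],
    n_background_clinvar=6,
    seed=11,
)


class TestDeterminism:
    def test_same_seed_gives_identical_bytes(self, tmp_path):
        generate_cohort(SMALL, out_dir=tmp_path / "a")
        generate_cohort(SMALL, out_dir=tmp_path / "b")
        for f in pio.COHORT_FILES.values():
            pa, pb = tmp_path / "a" / f, tmp_path / "b" / f
            if pa.exists():
                assert pa.read_bytes() == pb.read_bytes(), f

    def test_different_seed_differs(self, tmp_path):
        import dataclasses

        generate_cohort(SMALL, out_dir=tmp_path / "a")
        generate_cohort(
            dataclasses.replace(SMALL, seed=12), out_dir=tmp_path / "c"
        )
        assert (tmp_path / "a" / "cohort.vcf").read_bytes() != (
            tmp_path / "c" / "cohort.vcf"
        ).read_bytes()


class TestFeasibility:
    def test_more_carriers_than_samples_rejected_before_output(self, tmp_path):
        bad = CohortConfig(
            n_samples=10,
            scenarios=[ScenarioSpec("true_lof_unexplained", n_variants=4,
                                    carriers=5)],
            seed=0,
        )
        out = tmp_path / "never"
        with pytest.raises(InfeasibleConfigError):
            generate_cohort(bad, out_dir=out)
        assert not out.exists()

    def test_project_cluster_needs_project_samples(self, tmp_path):
        bad = CohortConfig(
            n_samples=40,
            excluded_project_fraction=0.05,
            scenarios=[ScenarioSpec("project_cluster", n_variants=2, carriers=5)],
            seed=0,
        )
        with pytest.raises(InfeasibleConfigError):
            generate_cohort(bad, out_dir=tmp_path / "never")

    def test_zero_scenarios_give_empty_cohort(self, tmp_path):
        empty = CohortConfig(
            n_samples=20, scenarios=[], n_background_clinvar=0, seed=0
        )
        c = generate_cohort(empty, out_dir=tmp_path / "e")
        assert c.variants == []
        assert len(c.truth) == 0
        assert (tmp_path / "e" / "cohort.vcf").exists()
        assert len(c.samples) == 20


class TestAnnotationConsistency:
    def test_cds_offsets_match_gene_models(self, cohort):
        for v in cohort.variants:
            for csq in v.consequences:
                if csq.cds_offset is None:
                    continue
                tx = cohort.transcripts[csq.transcript_id]
                if v.is_snv:
                    assert tx.cds_offset_of(v.pos) == csq.cds_offset
                assert 1 <= csq.cds_offset <= tx.cds_length

    def test_reference_matches_planted_alleles(self, cohort):
        for v in cohort.variants:
            seq = cohort.reference[v.contig]
            assert seq[v.pos - 1 : v.pos - 1 + len(v.ref)] == v.ref

    def test_pext_intervals_are_exons(self, cohort):
        for gene, track in cohort.pext.items():
            exons = {
                ex
                for t in cohort.transcripts.values()
                if t.gene == gene
                for ex in t.exons
            }
            for iv in track.exon_scores:
                assert iv in exons

    def test_ancestry_counts_sum_to_ac(self, cohort):
        for v in cohort.variants:
            assert sum(v.ac_by_ancestry.values()) == v.total_ac

    def test_truth_covers_every_planted_plof(self, cohort):
        truth_ids = set(cohort.truth["variant_id"])
        plof_ids = {
            v.variant_id
            for v in cohort.variants
            if v.loftee == "HC" and any(c.is_plof for c in v.consequences)
        }
        assert plof_ids <= truth_ids

    def test_planted_variants_are_rare(self, cohort):
        cis = set(
            cohort.truth.loc[
                cohort.truth["scenario"] == "cis_rescue_haplotype", "variant_id"
            ]
        )
        for row in cohort.truth.itertuples(index=False):
            v = next(
                x for x in cohort.variants if x.variant_id == row.variant_id
            )
            if row.variant_id not in cis and row.scenario != "sqtl_exon":
                assert v.ac_genomes <= 5

    def test_somatic_carriers_have_intermediate_ab(self, cohort):
        somatic = cohort.truth.loc[
            cohort.truth["scenario"] == "somatic_low_ab_ch", "variant_id"
        ]
        assert len(somatic)
        for vid in somatic:
            for call in cohort.genotypes[vid].values():
                if call.is_carrier:
                    ab = call.allele_balance()
                    assert 0.25 < ab < 0.35

    def test_project_cluster_carriers_restricted(self, cohort):
        ids = cohort.truth.loc[
            cohort.truth["scenario"] == "project_cluster", "variant_id"
        ]
        by_id = cohort.samples_by_id
        assert len(ids)
        for vid in ids:
            carriers = [
                c.sample_id
                for c in cohort.genotypes[vid].values()
                if c.is_carrier
            ]
            assert carriers
            assert all(
                by_id[s].project == "cell_line_cohort" for s in carriers
            )

    def test_cis_haplotype_split(self, cohort):
        cis = cohort.truth.loc[
            cohort.truth["scenario"] == "cis_rescue_haplotype", "variant_id"
        ].tolist()
        assert len(cis) == 2
        by_id = cohort.samples_by_id
        carrier_sets = []
        for vid in cis:
            carriers = {
                c.sample_id for c in cohort.genotypes[vid].values() if c.is_carrier
            }
            carrier_sets.append(carriers)
        assert carrier_sets[0] == carrier_sets[1]
        assert len(carrier_sets[0]) == 35
        groups = [by_id[s].ancestry_group for s in carrier_sets[0]]
        assert groups.count("eas") == 34
        assert groups.count("amr") == 1


class TestMnvPlanting:
    def _tiny_tx(self, codon: str) -> tuple[TranscriptModel, str]:
        seq = "NNNN" + "ATG" + codon + "TAA" + "NNNN"
        tx = TranscriptModel(
            "t", "g", "c", "+", exons=[(5, 13)], cds=[(5, 13)]
        )
        return tx, seq

    def test_agrees_with_codon_table_enumeration(self):
        """For every codon, the planter succeeds exactly when brute-force
        enumeration (via an independent translation oracle) finds a
        (stop-alone, non-stop-jointly) SNV pair."""
        bases = "ACGT"
        for c1 in bases:
            for c2 in bases:
                for c3 in bases:
                    codon = c1 + c2 + c3
                    # oracle: enumerate singles and partners, translating
                    # with Biopython
                    exists = False
                    for p1 in range(3):
                        for b1 in bases:
                            if b1 == codon[p1]:
                                continue
                            single = codon[:p1] + b1 + codon[p1 + 1 :]
                            if str(Seq(single).translate()) != "*":
                                continue
                            for p2 in range(3):
                                if p2 == p1:
                                    continue
                                for b2 in bases:
                                    if b2 == single[p2]:
                                        continue
                                    joint = single[:p2] + b2 + single[p2 + 1 :]
                                    if str(Seq(joint).translate()) != "*":
                                        exists = True
                    tx, seq = self._tiny_tx(codon)
                    if exists:
                        (pos1, r1, a1), (pos2, r2, a2) = plant_mnv_pair(tx, seq, 1)
                        # verify the returned plant with the oracle
                        s = list(codon)
                        s[pos1 - 8] = a1
                        assert str(Seq("".join(s)).translate()) == "*"
                        s[pos2 - 8] = a2
                        assert str(Seq("".join(s)).translate()) != "*"
                    else:
                        with pytest.raises(ValueError):
                            plant_mnv_pair(tx, seq, 1)

    def test_minus_strand_symmetry(self):
        codon = "CGA"
        from ptriage.genes import reverse_complement

        seq = "NNNN" + "TTA" + reverse_complement(codon) + "CAT" + "NNNN"
        tx = TranscriptModel("t", "g", "c", "-", exons=[(5, 13)], cds=[(5, 13)])
        assert tx.codon_at(seq, 1) == codon
        (p1, r1, a1), (p2, r2, a2) = plant_mnv_pair(tx, seq, 1)
        # genomic alleles must match the reference strand
        assert seq[p1 - 1] == r1 and seq[p2 - 1] == r2

    def test_codon_index_out_of_range(self):
        tx, seq = self._tiny_tx("CGA")
        with pytest.raises(ValueError):
            plant_mnv_pair(tx, seq, 5)


class TestAges:
    def test_truncated_to_range(self):
        rng = np.random.default_rng(0)
        ages = draw_ages(rng, 5000)
        assert ages.min() >= 18 and ages.max() <= 95

    def test_somatic_age_shift_detectable(self):
        """Shifted carrier ages stochastically dominate cohort ages: the
        one-sided rank-sum test rejects at alpha=0.05 in >=90% of seeds at
        the default effect size (+15 years, 10 carriers)."""
        rejections = 0
        n_seeds = 200
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            cohort_ages = draw_ages(rng, 490)
            carrier_ages = draw_ages(rng, 10, mean=70.0)
            _, p_two = wilcoxon_rank_sum(carrier_ages, cohort_ages)
            # one-sided: carriers older
            if p_two / 2 < 0.05 and carrier_ages.mean() > cohort_ages.mean():
                rejections += 1
        assert rejections / n_seeds >= 0.90
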