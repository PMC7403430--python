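"""Ground-truth generators: marginal exactness, determinism, planted effects."""

import numpy as np
import pandas as pd
import pytest

from fusionscape.gene_model import distance_to_start_codon, exon_boundary_class
from fusionscape.landscape import wilcoxon_compare
from fusionscape.synthetic import (
    DepthLaw,
    ExpressionEffects,
    InfeasibleSpecError,
    SyntheticCohortSpec,
    TranscriptConfig,
    default_cohort_spec,
    gen_cohort,
    gen_expression,
    gen_fusion_candidates,
    gen_gene_models,
    gen_pileups,
)


class TestGenCohort:
    def test_default_marginals_exact(self):
        table, truth = gen_cohort(default_cohort_spec(seed=3))
        assert len(table) == 252
        assert (table["fusion"] == "yes").sum() == 7
        assert (table["hypermutation"] == "yes").sum() == 27
        assert (table["hypomethylation"] == "yes").sum() == 52
        assert (table["hypomethylation"] == "NA").sum() == 252 - 136
        assert truth.statuses.sum().to_dict() == {
            "fusion": 7, "hypermutation": 27, "hypomethylation": 52,
        }

    def test_disjoint_mode_positive_sets_disjoint(self):
        table, truth = gen_cohort(default_cohort_spec(seed=11))
        positive = truth.statuses.astype(int)
        assert positive.sum(axis=1).max() == 1

    def test_same_seed_identical(self):
        a, _ = gen_cohort(default_cohort_spec(seed=5))
        b, _ = gen_cohort(default_cohort_spec(seed=5))
        pd.testing.assert_frame_equal(a, b)

    def test_different_seed_differs(self):
        a, _ = gen_cohort(default_cohort_spec(seed=5))
        b, _ = gen_cohort(default_cohort_spec(seed=6))
        assert not a.equals(b)

    def test_infeasible_disjoint_spec_rejected(self):
        spec = SyntheticCohortSpec(
            n_patients=10,
            alteration_counts={"A": 6, "B": 6},
            assayed_counts={"A": 10, "B": 10},
            cohort_labels=[("c", 1.0)],
        )
        with pytest.raises(InfeasibleSpecError):
            gen_cohort(spec)

    def test_count_exceeding_assayed_rejected(self):
        spec = SyntheticCohortSpec(
            n_patients=10,
            alteration_counts={"A": 6},
            assayed_counts={"A": 5},
            cohort_labels=[("c", 1.0)],
        )
        with pytest.raises(InfeasibleSpecError):
            gen_cohort(spec)

    def test_independent_and_nested_modes(self):
        spec = SyntheticCohortSpec(
            n_patients=30,
            alteration_counts={"A": 10, "B": 5},
            assayed_counts={"A": 30, "B": 30},
            overlap_mode="nested",
            cohort_labels=[("c", 1.0)],
            seed=2,
        )
        _, truth = gen_cohort(spec)
        a = set(truth.statuses.index[truth.statuses["A"]])
        b = set(truth.statuses.index[truth.statuses["B"]])
        assert b <= a  # nested: smaller positive set inside the larger
        spec.overlap_mode = "independent"
        table, _ = gen_cohort(spec)
        assert (table["A"] == "yes").sum() == 10


class TestGenGeneModels:
    def test_mgmt_fixture_acceptor_offset_is_12(self, models_by_name):
        mgmt = models_by_name["MGMT"]
        exon2_acceptor = mgmt.exons[1][0] if mgmt.strand == "+" else mgmt.exons[1][1]
        assert exon_boundary_class(mgmt, exon2_acceptor) == "acceptor_boundary"
        assert distance_to_start_codon(mgmt, exon2_acceptor) == 12

    def test_offset_configurable(self):
        models = gen_gene_models(
            [TranscriptConfig("MGMT", [100, 500], utr5_length=100 + 27, cds_length=300)]
        )
        acceptor = models[0].exons[1][0]
        assert distance_to_start_codon(models[0], acceptor) == 27

    def test_single_exon_cds_at_base_one_has_no_utr(self):
        (m,) = gen_gene_models([TranscriptConfig("X", [300], utr5_length=0, cds_length=300)])
        assert distance_to_start_codon(m, m.exons[0][0]) == 0

    def test_cds_start_outside_exons_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            gen_gene_models([TranscriptConfig("X", [100], utr5_length=100, cds_length=3)])


class TestGenFusionCandidates:
    def test_one_true_plus_one_decoy_per_class(self, default_models):
        table = gen_fusion_candidates(default_models, n_true=1, seed=0)
        assert len(table) == 5
        assert (table["TruthClass"] == "true").sum() == 1
        assert set(table["TruthClass"]) == {
            "true", "normal_tissue", "mitochondrial", "uncharacterized", "paralog",
        }

    def test_mitochondrial_decoy_has_mt_prefix(self, default_models):
        table = gen_fusion_candidates(default_models, n_true=0, seed=0)
        mito = table[table["TruthClass"] == "mitochondrial"]
        assert mito["LeftGene"].str.startswith("MT-").all()

    def test_true_breakpoints_on_exon_boundaries(self, default_models, models_by_name):
        table = gen_fusion_candidates(default_models, n_true=8, seed=0)
        for row in table[table["TruthClass"] == "true"].itertuples():
            left = models_by_name[row.LeftGene]
            right = models_by_name[row.RightGene]
            lpos = int(row.LeftBreakpoint.split(":")[1])
            rpos = int(row.RightBreakpoint.split(":")[1])
            assert exon_boundary_class(left, lpos) == "donor_boundary"
            assert exon_boundary_class(right, rpos) == "acceptor_boundary"

    def test_seed_determinism(self, default_models):
        a = gen_fusion_candidates(default_models, n_true=3, seed=9)
        b = gen_fusion_candidates(default_models, n_true=3, seed=9)
        pd.testing.assert_frame_equal(a, b)


class TestGenPileups:
    def test_wildtype_has_zero_variant_reads(self):
        table = gen_pileups(
            {"S1": {"IDH1_R132": "wildtype"}}, DepthLaw(100, "constant"), seed=0
        )
        row = table.iloc[0]
        depth = row[list("ACGT")].sum()
        assert depth == 100
        assert depth - row[row["ref"]] == 0

    def test_mutant_allele_fraction_concentrates(self):
        # Binomial(1000, 0.5)/1000 lies in [0.45, 0.55] except with tiny probability
        table = gen_pileups(
            {"S1": {"IDH1_R132": "mutant"}},
            DepthLaw(1000, "constant", allele_fraction=0.5),
            seed=1,
        )
        row = table.iloc[0]
        depth = row[list("ACGT")].sum()
        vaf = (depth - row[row["ref"]]) / depth
        assert 0.45 <= vaf <= 0.55

    def test_constant_depth_4_below_availability_cutoff(self):
        from fusionscape.variant_status import call_cohort_hotspots, read_pileup

        table = gen_pileups(
            {f"S{i}": {"IDH1_R132": "mutant"} for i in range(10)},
            DepthLaw(4, "constant"),
            seed=0,
        )
        calls = call_cohort_hotspots(
            [s for s in _sites_from_frame(table)]
        )
        assert (calls["status"] == "NA").all()


def _sites_from_frame(frame):
    from fusionscape.variant_status import PileupSite

    return [
        PileupSite(r.sample_id, str(r.chrom), int(r.pos), r.ref,
                   {b: int(getattr(r, b)) for b in "ACGT"})
        for r in frame.itertuples(index=False)
    ]


class TestGenExpression:
    @staticmethod
    def _toy_cohort(n=100, n_pos=50, seed=0):
        spec = SyntheticCohortSpec(
            n_patients=n,
            alteration_counts={"fusion": n_pos},
            assayed_counts={"fusion": n},
            cohort_labels=[("c", 1.0)],
            seed=seed,
        )
        return gen_cohort(spec)[0]

    def test_zero_noise_identical_within_class(self):
        cohort = self._toy_cohort()
        expr = gen_expression(
            cohort, ExpressionEffects(noise_sd=0.0, batch_sd=0.0), seed=0
        )
        pos = expr[cohort.set_index("patient_id")["fusion"] == "yes"]
        neg = expr[cohort.set_index("patient_id")["fusion"] == "no"]
        assert pos.nunique() == 1 and neg.nunique() == 1
        assert pos.iloc[0] > neg.iloc[0]

    def test_two_sd_shift_detected_in_most_seeds(self):
        """Wilcoxon at n=50 per group rejects a 2-SD shift almost always."""
        effects = ExpressionEffects(fusion_shift=2.0, noise_sd=1.0, batch_sd=0.0)
        rejected = 0
        for seed in range(100):
            cohort = self._toy_cohort(seed=seed)
            expr = gen_expression(cohort, effects, seed=seed)
            grouped = cohort.set_index("patient_id")["fusion"]
            _, p = wilcoxon_compare(expr[grouped == "yes"], expr[grouped == "no"])
            rejected += p < 0.05
        assert rejected >= 95
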