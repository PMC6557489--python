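"""Site scanning, relative affinity, and mutagenesis design."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from crmdecode.sequence_sites import (
    AlignmentMatrix,
    BindingSite,
    CRMRecord,
    ConfigurationError,
    MutationPlan,
    PlanIntegrityError,
    apply_mutation_plan,
    design_site_mutation,
    read_count_matrix,
    read_fasta,
    reverse_complement,
    scan_sites,
    write_count_matrix,
    write_fasta,
)

from conftest import random_matrix


class TestScan:
    def test_no_match_above_threshold(self, sharp_matrix):
        crm = CRMRecord("polyT", "T" * 40)
        assert scan_sites(crm, [sharp_matrix], q_min=0.01) == []

    def test_consensus_recovered_with_q_one(self, sharp_matrix):
        seq = "T" * 10 + sharp_matrix.consensus + "T" * 10
        sites = scan_sites(CRMRecord("c", seq), [sharp_matrix], 0.01)
        assert [(s.start, s.q) for s in sites] == [(10, 1.0)]
        assert sites[0].strand == "+"
        assert sites[0].end - sites[0].start == len(sharp_matrix)

    def test_single_mismatch_q_is_frequency_ratio(self):
        # position 3 frequencies (with pseudocount 0): A 0.7, C 0.1
        counts = np.array(
            [[100, 0, 0, 0]] * 3 + [[70, 10, 10, 10]] + [[100, 0, 0, 0]] * 2,
            dtype=float,
        )
        mat = AlignmentMatrix("TFZ", counts, pseudocount=0.0)
        site = "AAA" + "C" + "AA"
        q = mat.site_affinity(site)
        assert q == pytest.approx(0.1 / 0.7, rel=1e-12)
        seq = "G" * 5 + site + "G" * 5
        sites = scan_sites(CRMRecord("c", seq), [mat], q_min=0.01)
        hit = [s for s in sites if s.start == 5]
        assert hit and hit[0].q == pytest.approx(0.1 / 0.7, rel=1e-12)

    def test_q_reproducible_by_direct_product(self, soft_matrix):
        rng = np.random.default_rng(7)
        seq = "".join(rng.choice(list("ACGT"), 80))
        for s in scan_sites(CRMRecord("c", seq), [soft_matrix], 0.001):
            assert 0 < s.q <= 1
            assert s.q == pytest.approx(soft_matrix.site_affinity(s.site_seq), rel=1e-12)

    def test_window_with_n_yields_no_site(self, sharp_matrix):
        cons = sharp_matrix.consensus
        broken = cons[:3] + "N" + cons[4:]
        crm = CRMRecord("c", "T" * 5 + broken + "T" * 5)
        assert scan_sites(crm, [sharp_matrix], 1e-9) == []

    def test_empty_matrix_list_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            scan_sites(CRMRecord("c", "ACGT" * 5), [], 0.01)

    def test_sequence_shorter_than_matrix_empty_result(self, sharp_matrix):
        assert scan_sites(CRMRecord("c", "ACG"), [sharp_matrix], 0.01) == []

    def test_reverse_complement_symmetry(self, soft_matrix):
        rng = np.random.default_rng(11)
        seq = "".join(rng.choice(list("ACGT"), 100))
        fwd = scan_sites(CRMRecord("c", seq), [soft_matrix], 0.005)
        rev = scan_sites(
            CRMRecord("c", reverse_complement(seq)), [soft_matrix], 0.005
        )
        L = len(seq)
        mirrored = sorted(
            (L - s.end, L - s.start, "-" if s.strand == "+" else "+", round(s.q, 10))
            for s in fwd
        )
        got = sorted((s.start, s.end, s.strand, round(s.q, 10)) for s in rev)
        assert got == mirrored


class TestMutagenesis:
    def test_lowest_base_alphabetical_tie_break(self):
        counts = np.array([[70, 10, 10, 10]] * 4, dtype=float)
        mat = AlignmentMatrix("T1", counts)
        lo, lo2 = mat.lowest_bases(0, exclude="A")
        assert (lo, lo2) == ("C", "G")

    def test_single_site_plan_kills_site(self, sharp_matrix):
        seq = "T" * 12 + sharp_matrix.consensus + "T" * 12
        crm = CRMRecord("c", seq)
        target = scan_sites(crm, [sharp_matrix], 0.01)[0]
        plan = design_site_mutation(crm, target, [sharp_matrix], 0.01)
        assert len(plan.edits) == len(sharp_matrix)
        mut = apply_mutation_plan(crm, plan)
        assert scan_sites(mut, [sharp_matrix], 0.01) == []
        assert len(mut) == len(crm)

    def test_minus_strand_site_ablated(self, sharp_matrix):
        seq = "T" * 9 + reverse_complement(sharp_matrix.consensus) + "T" * 9
        crm = CRMRecord("c", seq)
        (target,) = scan_sites(crm, [sharp_matrix], 0.01)
        assert target.strand == "-"
        plan = design_site_mutation(crm, target, [sharp_matrix], 0.01)
        mut = apply_mutation_plan(crm, plan)
        assert scan_sites(mut, [sharp_matrix], 0.01) == []

    def test_non_overlapping_sites_untouched(self, sharp_matrix, soft_matrix):
        seq = (
            "T" * 8
            + soft_matrix.consensus
            + "T" * 8
            + sharp_matrix.consensus
            + "T" * 8
        )
        crm = CRMRecord("c", seq)
        sites = scan_sites(crm, [sharp_matrix, soft_matrix], 0.01)
        target = [s for s in sites if s.tf_name == "TFX"][0]
        plan = design_site_mutation(crm, target, [sharp_matrix, soft_matrix], 0.01)
        mut = apply_mutation_plan(crm, plan)
        kept = [
            s for s in scan_sites(mut, [sharp_matrix, soft_matrix], 0.01)
            if not s.overlaps(target)
        ]
        before = [
            s for s in sites if not s.overlaps(target)
        ]
        assert {(s.key, round(s.q, 12)) for s in kept} == {
            (s.key, round(s.q, 12)) for s in before
        }

    @pytest.mark.parametrize("seed", range(30))
    def test_random_planted_sites_property(self, seed):
        """Designed mutants drop the target below threshold and never create
        new sites, across random matrices and backgrounds."""
        rng = np.random.default_rng(seed)
        mats = [random_matrix(rng, f"TF{k}", int(rng.integers(5, 9))) for k in range(2)]
        from crmdecode.synthetic_data import simulate_crm

        pos = int(rng.integers(10, 40))
        strand = "+" if rng.random() < 0.5 else "-"
        crm, _ = simulate_crm(
            80, [(mats[0], pos, strand)], seed=int(rng.integers(2**31))
        )
        wt = scan_sites(crm, mats, 0.01)
        target = [s for s in wt if s.tf_name == "TF0" and s.start == pos][0]
        plan = design_site_mutation(crm, target, mats, 0.01)
        mut = apply_mutation_plan(crm, plan)
        after = scan_sites(mut, mats, 0.01)
        wt_keys = {s.key for s in wt}
        assert all(s.key in wt_keys for s in after), "new site created"
        assert not any(
            s.key == target.key for s in after
        ), "target survived above threshold"

    def test_apply_empty_plan_is_identity(self, sharp_matrix):
        crm = CRMRecord("c", "ACGTACGTACGT")
        site = BindingSite("TFX", 0, 6, "+", "ACGTAC", 0.5, 0.0)
        plan = MutationPlan(site, ())
        assert apply_mutation_plan(crm, plan).sequence == crm.sequence

    def test_apply_single_edit(self):
        crm = CRMRecord("c", "AAAAAAAAAA")
        site = BindingSite("TFX", 2, 8, "+", "AAAAAA", 1.0, 0.0)
        plan = MutationPlan(site, ((5, "A", "T"),))
        mut = apply_mutation_plan(crm, plan)
        assert mut.sequence == "AAAAATAAAA"

    def test_apply_mismatched_plan_is_integrity_error(self):
        crm = CRMRecord("c", "AAAAAAAAAA")
        site = BindingSite("TFX", 2, 8, "+", "AAAAAA", 1.0, 0.0)
        plan = MutationPlan(site, ((5, "G", "T"),))
        with pytest.raises(PlanIntegrityError):
            apply_mutation_plan(crm, plan)

    def test_edit_outside_site_rejected(self):
        site = BindingSite("TFX", 2, 8, "+", "AAAAAA", 1.0, 0.0)
        with pytest.raises(ConfigurationError):
            MutationPlan(site, ((9, "A", "T"),))


class TestMatrixInvariants:
    def test_background_must_sum_to_one(self):
        with pytest.raises(ConfigurationError):
            AlignmentMatrix(
                "bad", np.ones((5, 4)), background=(0.5, 0.5, 0.5, 0.5)
            )

    def test_minimum_length(self):
        with pytest.raises(ConfigurationError):
            AlignmentMatrix("short", np.ones((3, 4)))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_affinity_bounded_and_consensus_maximal(self, seed):
        rng = np.random.default_rng(seed)
        mat = random_matrix(rng, length=6)
        site = "".join(rng.choice(list("ACGT"), 6))
        q = mat.site_affinity(site)
        assert 0 < q <= 1
        assert mat.site_affinity(mat.consensus) == pytest.approx(1.0)


class TestIO:
    def test_fasta_roundtrip_with_roles(self, tmp_path):
        recs = [
            CRMRecord("prom", "ACGTACGTAC", "promoter"),
            CRMRecord("crm7", "GGGTTTACGT", "distal_crm"),
        ]
        p = tmp_path / "crms.fasta"
        write_fasta(recs, p)
        back = read_fasta(p)
        assert [(r.id, r.sequence, r.role) for r in back] == [
            (r.id, r.sequence, r.role) for r in recs
        ]

    def test_jaspar_style_roundtrip(self, tmp_path, soft_matrix):
        p = tmp_path / "m.jaspar"
        write_count_matrix(soft_matrix, p)
        back = read_count_matrix(p)
        assert back.tf_name == soft_matrix.tf_name
        np.testing.assert_allclose(back.counts, soft_matrix.counts)

    def test_transfac_style_rows(self, tmp_path):
        p = tmp_path / "m.transfac"
        p.write_text(
            "ID dummy_TF\nPO A C G T\n"
            "01 70 10 15 5\n02 60 20 10 10\n03 80 5 10 5\n"
            "04 70 10 10 10\n05 65 15 10 10\n//\n"
        )
        mat = read_count_matrix(p)
        assert mat.tf_name == "dummy_TF"
        assert mat.counts.shape == (5, 4)
        np.testing.assert_allclose(mat.counts[0], [70, 10, 15, 5])
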