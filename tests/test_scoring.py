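import random

import numpy as np
import pytest

from interomap import scoring as SC
from interomap.structures import Contact

from .oracles import gotoh_global_score

AA = "ACDEFGHIKLMNPQRSTVWY"


class TestAlignToTemplate:
    def test_identical_sequences_gap_free(self):
        aln = SC.align_to_template("ACDEFGH", "ACDEFGH")
        assert aln.template_row == aln.candidate_row == "ACDEFGH"
        assert aln.mapping() == {i: i for i in range(1, 8)}

    def test_internal_deletion_gives_one_gap_block(self):
        template = "ACDEFGHIKLMNPQRSTVWYACDEFGHIKL"
        candidate = template[:10] + template[13:]  # 3-residue internal deletion
        aln = SC.align_to_template(candidate, template)
        assert aln.candidate_row.count("-") == 3
        assert "-" not in aln.template_row
        mapping = aln.mapping()
        assert [p for p, c in mapping.items() if c is None] == [11, 12, 13]

    def test_score_matches_needleman_wunsch_oracle(self):
        rng = random.Random(3)
        for _ in range(8):
            a = "".join(rng.choice(AA) for _ in range(20))
            b = "".join(rng.choice(AA) for _ in range(20))
            aln = SC.align_to_template(a, b)
            assert aln.score == pytest.approx(gotoh_global_score(b, a), abs=1e-6)


class TestMapTemplateContacts:
    def test_identity_alignments_preserve_positions(self):
        aln_a = SC.align_to_template("ASDFGH", "ASDFGH")
        aln_b = SC.align_to_template("QWERTY", "QWERTY")
        contacts = [Contact(2, 5, "vdw", 4.0)]
        out = SC.map_template_contacts(aln_a, aln_b, contacts)
        assert (out[0].cand_pos_a, out[0].cand_pos_b) == (2, 5)
        assert (out[0].cand_aa_a, out[0].cand_aa_b) == ("S", "T")

    def test_deletion_over_contact_marks_gap(self):
        template = "ACDEFGHIKLMNPQRSTVWY"
        candidate = template[:4] + template[7:]  # removes positions 5-7
        aln_a = SC.align_to_template(candidate, template)
        aln_b = SC.align_to_template(template, template)
        out = SC.map_template_contacts(aln_a, aln_b, [Contact(6, 1, "hbond", 3.0)])
        assert out[0].gapped and out[0].cand_pos_a is None

    def test_point_substitution_maps_to_mutant_residue(self):
        # receptor-ligand analog: the template's serine contact position
        # carries a tryptophan in the candidate (the S->W disease change)
        template = "GILKSDNPQT"
        candidate = "GILKWDNPQT"
        aln_a = SC.align_to_template(candidate, template)
        aln_b = SC.align_to_template("MLVAL", "MLVAL")
        out = SC.map_template_contacts(aln_a, aln_b, [Contact(5, 2, "vdw", 3.9)])
        assert out[0].template_aa_a == "S" and out[0].cand_aa_a == "W"
        assert out[0].cand_pos_a == 5

    def test_contact_outside_template_fails(self):
        aln = SC.align_to_template("ACDEF", "ACDEF")
        with pytest.raises(ValueError, match="library inconsistency"):
            SC.map_template_contacts(aln, aln, [Contact(9, 1, "vdw", 3.0)])


def hand_potentials():
    vdw = {(a, b): 0.0 for a in AA for b in AA}
    sf = dict(vdw)
    sim = {(a, b): (5.0 if a == b else -1.0) for a in AA for b in AA}
    vdw[("L", "L")] = 2.0
    sf[("S", "Q")] = sf[("Q", "S")] = 3.0
    return SC.PotentialTable(vdw=vdw, sf=sf, sim=sim)


def contact(pos_a, pos_b, kind, taa, tab, caa, cab, pa, pb):
    return SC.AlignedContact(pos_a, pos_b, kind, taa, tab, caa, cab, pa, pb)


class TestScoreCandidate:
    def test_hand_sum_on_three_contact_fixture(self):
        contacts = [
            contact(1, 1, "vdw", "L", "L", "L", "L", 1, 1),
            contact(2, 2, "hbond", "S", "Q", "S", "Q", 2, 2),
            contact(3, 3, "vdw", "A", "A", "G", "A", 3, 3),
        ]
        bd = SC.score_candidate(contacts, {1, 2}, {1, 2}, hand_potentials())
        # by hand: e_vdw = 2.0 + 0.0; e_sf = 3.0
        # e_sim = (5+5) + (5+5) + (-1+5) = 24; e_cons = 2 couple-conserved
        assert bd.e_vdw == pytest.approx(2.0)
        assert bd.e_sf == pytest.approx(3.0)
        assert bd.e_sim == pytest.approx(24.0)
        assert bd.e_cons == pytest.approx(2.0)
        assert bd.e_tot == pytest.approx(31.0)

    def test_all_gapped_contacts(self):
        contacts = [
            contact(1, 1, "vdw", "L", "L", None, "L", None, 1),
            contact(2, 2, "hbond", "S", "Q", None, None, None, None),
        ]
        bd = SC.score_candidate(contacts, set(), set(), hand_potentials(), gap_penalty=-4.0)
        assert bd.e_vdw == bd.e_sf == 0.0
        assert bd.e_sim == pytest.approx(-8.0)

    def test_unknown_residue_scores_zero(self):
        contacts = [contact(1, 1, "vdw", "L", "L", "X", "L", 1, 1)]
        bd = SC.score_candidate(contacts, set(), set(), hand_potentials())
        assert bd.e_vdw == 0.0


class TestZScore:
    def test_score_at_mean_is_zero(self):
        bg = list(range(100))
        assert SC.zscore(float(np.mean(bg)), bg) == pytest.approx(0.0)

    def test_two_sd_above_mean(self):
        rng = np.random.default_rng(0)
        bg = rng.normal(10, 2, size=500)
        target = float(bg.mean() + 2 * bg.std(ddof=1))
        assert SC.zscore(target, bg) == pytest.approx(2.0)

    def test_closed_form_small_sample(self):
        bg = [1, 2, 3, 4, 5] * 6  # 30 values, sd preserved by repetition
        z = SC.zscore(6.0, bg)
        sd = np.std(bg, ddof=1)
        assert z == pytest.approx((6 - 3) / sd)

    def test_degenerate_background_fails(self):
        with pytest.raises(ValueError, match="degenerate"):
            SC.zscore(1.0, [2.0] * 50)


class TestColumnConservation:
    def test_identical_rows_fully_conserved(self):
        fr = SC.column_conservation(["ASDF", "ASDF", "ASDF"])
        assert np.allclose(fr, 1.0)

    def test_counting_oracle_mixed_column(self):
        # template S; non-template rows S, S, A -> 2/3
        msa = ["S", "S", "S", "A"]
        assert SC.column_conservation(msa)[0] == pytest.approx(2 / 3)

    def test_all_gap_column_not_conserved(self):
        msa = ["AS", "A-", "A-"]
        assert SC.column_conservation(msa)[1] == 0.0

    def test_single_row_msa_all_zero(self):
        assert np.allclose(SC.column_conservation(["ASDF"]), 0.0)


class TestInferFamilyPPIs:
    def test_implanted_pairs_fully_recovered(self, inferred, template_fixture):
        candidates, _family = inferred
        accepted = {(c.protein_a_id, c.protein_b_id) for c in candidates if c.accepted}
        assert accepted == template_fixture.true_pairs  # precision = recall = 1

    def test_decoy_pairs_rejected_by_zscore(self, template, seq_db, template_fixture):
        # admit decoys into the families (no E-value filter) and let the
        # Z >= 3 acceptance alone separate implants from decoys
        from interomap import homology as H

        fams = {}
        for role, seq in (("A", template.seq_a), ("B", template.seq_b)):
            hits = H.search_homologs(seq, seq_db, query_chain=f"t:{role}")
            fams[role] = H.build_family("t", role, hits, evalue_max=float("inf"))
        candidates, _fam = SC.infer_family_ppis(
            template, fams["A"], fams["B"], seq_db, SC.ScoringConfig(seed=11)
        )
        accepted = {(c.protein_a_id, c.protein_b_id) for c in candidates if c.accepted}
        assert accepted == template_fixture.true_pairs

    def test_additivity_of_total(self, inferred):
        candidates, _ = inferred
        for c in candidates:
            b = c.breakdown
            assert b.e_tot == b.e_vdw + b.e_sf + b.e_sim + b.e_cons

    def test_self_template_pair_attains_max_e_sim(self, template, seq_db, families):
        # score the template's own sequences through the same path
        config = SC.ScoringConfig(seed=5)
        pot = SC.PotentialTable.default()
        aln_a = SC.align_to_template(template.seq_a, template.seq_a)
        aln_b = SC.align_to_template(template.seq_b, template.seq_b)
        mapped = SC.map_template_contacts(aln_a, aln_b, template.contacts)
        self_bd = SC.score_candidate(mapped, set(), set(), pot)
        candidates, _ = SC.infer_family_ppis(
            template, families["A"], families["B"], seq_db, config
        )
        assert all(c.breakdown.e_sim <= self_bd.e_sim + 1e-9 for c in candidates)

    def test_acceptance_monotone_in_z_min(self, template, families, seq_db):
        sets = []
        for z_min in (1.0, 3.0, 5.0):
            cands, _ = SC.infer_family_ppis(
                template, families["A"], families["B"], seq_db,
                SC.ScoringConfig(seed=3, z_min=z_min),
            )
            sets.append({(c.protein_a_id, c.protein_b_id) for c in cands if c.accepted})
        assert sets[2] <= sets[1] <= sets[0]

    def test_infinite_z_min_accepts_nothing(self, template, families, seq_db):
        cands, fam = SC.infer_family_ppis(
            template, families["A"], families["B"], seq_db,
            SC.ScoringConfig(seed=3, z_min=float("inf")),
        )
        assert not any(c.accepted for c in cands)
        assert fam.accepted == []

    def test_deterministic_under_seed(self, template, families, seq_db):
        runs = []
        for _ in range(2):
            cands, _ = SC.infer_family_ppis(
                template, families["A"], families["B"], seq_db,
                SC.ScoringConfig(seed=17),
            )
            runs.append([(c.protein_a_id, c.protein_b_id, c.z, c.accepted) for c in cands])
        assert runs[0] == runs[1]

    def test_empty_family_gives_empty_result(self, template, families, seq_db):
        from interomap.homology import HomologFamily

        empty = HomologFamily("tpl1", "B", [])
        cands, fam = SC.infer_family_ppis(template, families["A"], empty, seq_db)
        assert cands == [] and fam is None
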