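import numpy as np
import pytest

from _oracles import brute_force_dimer, nn_tm_oracle
from taxsig import (
    DesignConstraints,
    Label,
    PanelAssemblyError,
    PrimerSpec,
    SignatureSite,
    TmConditions,
    ValidationError,
    assemble_panel,
    bases_compatible,
    design_allele_specific_forward,
    design_conserved_pair,
    dimer_score,
    find_signature_sites,
    reference_panel,
    reverse_complement,
    tm,
)
from taxsig.primer_design import A397F_SEQ, C357F_SEQ, R502_SEQ


@pytest.fixture(scope="module")
def fixture_site(fixture_data):
    aln, part, _ = fixture_data
    (site,) = find_signature_sites(aln, part)
    return site


class TestTm:
    NO_MG = TmConditions(mg_mM=0.0)

    @pytest.mark.parametrize("seq", [A397F_SEQ, C357F_SEQ, R502_SEQ, "ATCGATCGAT"])
    def test_matches_hand_summation_oracle(self, seq):
        assert tm(seq, self.NO_MG) == pytest.approx(nn_tm_oracle(seq), abs=0.5)

    def test_duplex_symmetry(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            s = "".join(rng.choice(list("ACGT"), size=int(rng.integers(10, 30))))
            for cond in (None, self.NO_MG):
                assert tm(s, cond) == pytest.approx(tm(reverse_complement(s), cond), abs=1e-6)

    def test_gc_extension_raises_tm_for_primer_like_sequences(self):
        # holds for moderate-GC oligos; extreme GC content can reverse it
        rng = np.random.default_rng(12345)
        checked = 0
        while checked < 120:
            n = int(rng.integers(8, 28))
            s = "".join(rng.choice(list("ACGT"), size=n))
            if (s.count("G") + s.count("C")) / len(s) > 0.55:
                continue
            checked += 1
            for base in ("G", "C"):
                assert tm(s + base) >= tm(s) - 1e-9

    def test_ambiguity_rejected(self):
        with pytest.raises(ValidationError):
            tm("ACGTNACGTACG")

    def test_too_short_rejected(self):
        with pytest.raises(ValidationError):
            tm("ACGTACG")


class TestDimerScore:
    def test_no_complementarity_scores_zero(self):
        assert dimer_score("A" * 20, "A" * 20).score == 0

    def test_perfect_duplex_scores_double_length(self):
        p = A397F_SEQ
        assert dimer_score(p, reverse_complement(p)).score == 2 * len(p)

    def test_symmetric_and_matches_bruteforce(self):
        rng = np.random.default_rng(3)
        for _ in range(40):
            s = "".join(rng.choice(list("ACGT"), size=int(rng.integers(15, 28))))
            t = "".join(rng.choice(list("ACGT"), size=int(rng.integers(15, 28))))
            hit = dimer_score(s, t)
            assert hit.score == dimer_score(t, s).score
            assert hit.score == brute_force_dimer(s, t)

    def test_published_panel_scores_frozen(self):
        """Pairwise scores of the published triplex, cross-checked brute-force.

        C357F's 3'-terminal TTTG pairs A397F's internal CAAA, a doubled
        4-run; the other two pairs stay low, consistent with the blank
        no-template strip.
        """
        seqs = {"A397F": A397F_SEQ, "C357F": C357F_SEQ, "R502": R502_SEQ}
        expected = {("A397F", "C357F"): 8, ("A397F", "R502"): 4, ("C357F", "R502"): 6}
        for (na, nb), want in expected.items():
            got = dimer_score(seqs[na], seqs[nb]).score
            assert got == want
            assert got == brute_force_dimer(seqs[na], seqs[nb])

    def test_illustration_shows_duplex(self):
        hit = dimer_score(A397F_SEQ, C357F_SEQ)
        assert "5'-" in hit.illustration and "3'-" in hit.illustration


class TestDesignSpecificForward:
    def test_candidates_anchor_on_signature(self, fixture_data, fixture_site):
        aln, part, _ = fixture_data
        result = design_allele_specific_forward(aln, part, fixture_site)
        assert len(result) > 0
        top = result[0]
        assert top.three_prime_base == fixture_site.target_allele == "T"
        assert top.aln_end == fixture_site.column
        for cand in result:
            assert cand.aln_end == fixture_site.column
            assert cand.three_prime_base == "T"

    def test_exact_length_20_reproduces_published_primer(self, fixture_data, fixture_site):
        aln, part, _ = fixture_data
        result = design_allele_specific_forward(
            aln, part, fixture_site, DesignConstraints(length_range=(20, 20))
        )
        assert [c.residues for c in result] == [A397F_SEQ]

    def test_candidates_incompatible_with_every_background_base(self, fixture_data, fixture_site):
        aln, part, _ = fixture_data
        result = design_allele_specific_forward(aln, part, fixture_site)
        col = fixture_site.column
        informative_bg = {
            aln.get(i).residues[col - 1]
            for i in part.background_ids
            if aln.get(i).residues[col - 1] in "ACGT"
        }
        for cand in result:
            assert all(not bases_compatible(cand.three_prime_base, b) for b in informative_bg)

    def test_degenerate_target_footprint_yields_empty_with_reasons(self):
        from taxsig import Alignment, SequenceRecord, TaxonPartition

        # targets disagree everywhere except the diagnostic last column
        recs = (
            SequenceRecord(id="t0", residues="ACGTACGTACGTACGTACGTT"),
            SequenceRecord(id="t1", residues="CGTACGTACGTACGTACGTAT"),
            SequenceRecord(id="b0", residues="ACGTACGTACGTACGTACGTA"),
        )
        aln = Alignment(records=recs)
        part = TaxonPartition(target_ids=frozenset({"t0", "t1"}), background_ids=frozenset({"b0"}))
        (site,) = find_signature_sites(aln, part)
        result = design_allele_specific_forward(aln, part, site)
        assert len(result) == 0
        assert result.rejections  # machine-readable reason summary

    def test_deterministic(self, fixture_data, fixture_site):
        aln, part, _ = fixture_data
        a = design_allele_specific_forward(aln, part, fixture_site)
        b = design_allele_specific_forward(aln, part, fixture_site)
        assert a.candidates == b.candidates


class TestDesignConservedPair:
    def test_some_pair_lies_in_designated_windows(self, default_cfg, fixture_data, fixture_site):
        aln, part, _ = fixture_data
        specific = design_allele_specific_forward(aln, part, fixture_site)[0]
        pairs = design_conserved_pair(aln, part, specific)
        assert len(pairs) > 0
        cw, rw = default_cfg.control_window, default_cfg.reverse_window
        assert any(
            cw[0] <= ctrl.aln_start and ctrl.aln_end <= cw[1]
            and rw[0] <= rev.aln_start and rev.aln_end <= rw[1]
            for ctrl, rev in pairs
        )

    def test_pair_geometry_and_product_arithmetic(self, fixture_data, fixture_site):
        aln, part, _ = fixture_data
        specific = design_allele_specific_forward(aln, part, fixture_site)[0]
        c = DesignConstraints()
        for ctrl, rev in design_conserved_pair(aln, part, specific, c):
            assert ctrl.aln_start < specific.aln_start
            assert rev.aln_start > specific.aln_end
            specific_product = rev.aln_end - specific.aln_start + 1
            control_product = rev.aln_end - ctrl.aln_start + 1
            # size difference is exactly the forward-start offset
            assert control_product - specific_product == specific.aln_start - ctrl.aln_start
            assert control_product - specific_product >= c.min_product_len_gap

    def test_reverse_primer_is_revcomp_of_plus_strand(self, fixture_data, fixture_site, default_cfg):
        aln, part, _ = fixture_data
        specific = design_allele_specific_forward(aln, part, fixture_site)[0]
        pairs = design_conserved_pair(aln, part, specific)
        rw = default_cfg.reverse_window
        full = [rev for _, rev in pairs if (rev.aln_start, rev.aln_end) == rw]
        assert full and full[0].residues == R502_SEQ

    def test_everywhere_divergent_alignment_yields_empty(self):
        from taxsig import Alignment, SequenceRecord, TaxonPartition

        rng = np.random.default_rng(9)
        rows = []
        # every column gets a distinct base in at least one record
        for i in range(4):
            rows.append("".join("ACGT"[(j + i) % 4] for j in range(60)))
        recs = tuple(SequenceRecord(id=f"r{i}", residues=s) for i, s in enumerate(rows))
        aln = Alignment(records=recs)
        part = TaxonPartition(
            target_ids=frozenset({"r0", "r1"}), background_ids=frozenset({"r2", "r3"})
        )
        specific = PrimerSpec(
            name="sp", residues="ACGTACGTACGTACGTAC", strand="forward",
            aln_start=20, aln_end=37,
        )
        result = design_conserved_pair(aln, part, specific)
        assert len(result) == 0
        assert result.rejections


class TestAssemblePanel:
    def test_published_coordinates_assemble(self, ref_panel):
        assert ref_panel.forward_start_offset == 21
        assert ref_panel.expected_control_len - ref_panel.expected_specific_len == 21
        labels = {p.label for p in ref_panel.primers}
        assert labels == {Label.DIG, Label.FAM, Label.BIOTIN}

    def test_duplicate_labels_rejected(self, ref_panel):
        with pytest.raises(PanelAssemblyError, match="distinct"):
            assemble_panel(
                ref_panel.specific_fwd,
                ref_panel.control_fwd,
                ref_panel.shared_rev,
                ref_panel.signature,
                labels={"specific": Label.DIG, "control": Label.DIG},
            )

    def test_wrong_order_rejected(self, ref_panel):
        with pytest.raises(PanelAssemblyError, match="order"):
            assemble_panel(
                ref_panel.specific_fwd,
                ref_panel.control_fwd.__class__(
                    name="late", residues=ref_panel.control_fwd.residues,
                    strand="forward", aln_start=400, aln_end=419,
                ),
                ref_panel.shared_rev,
                ref_panel.signature,
            )

    def test_dimer_threshold_enforced(self, ref_panel):
        with pytest.raises(PanelAssemblyError, match="dimer"):
            assemble_panel(
                ref_panel.specific_fwd,
                ref_panel.control_fwd,
                ref_panel.shared_rev,
                ref_panel.signature,
                max_dimer_score=7,  # A397F/C357F score 8
            )

    def test_full_design_pipeline_assembles(self, fixture_data, fixture_site):
        aln, part, _ = fixture_data
        c = DesignConstraints()
        specific = design_allele_specific_forward(aln, part, fixture_site, c)[0]
        ctrl, rev = design_conserved_pair(aln, part, specific, c)[0]
        panel = assemble_panel(specific, ctrl, rev, fixture_site, max_dimer_score=c.max_dimer_score)
        assert panel.specific_fwd.label == Label.DIG
        assert panel.shared_rev.label == Label.BIOTIN
        assert panel.expected_control_len - panel.expected_specific_len == panel.forward_start_offset
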