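"""Donor/U1 register and SELEX PWM scanning."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from splice_rescue import (
    DonorContext,
    PwmModel,
    U1Register,
    compare_variant_motifs,
    donor_context,
    get_oligo,
    load_pwm,
    scan_pwm,
    u1_mismatches,
)
from splice_rescue.oligos import AssembledRegion, assemble_tiled_region


class TestDonorContext:
    def test_wild_type_context_from_printed_oligo(self, wt_region):
        assert donor_context(wt_region).sequence == "CAAGUAAGU"

    def test_mutant_context_from_printed_oligo(self, fd_region):
        assert donor_context(fd_region).sequence == "CAAGUAAGC"

    def test_substitution_turns_wild_type_into_mutant(self, wt_region):
        ctx = donor_context(wt_region, variant=(6, "C"))
        assert ctx.sequence == "CAAGUAAGC"

    def test_consensus_context(self):
        region = AssembledRegion("CAGGUAAGUCCC", boundary_offset=3)
        assert donor_context(region).sequence == "CAGGUAAGU"

    def test_window_past_sequence_end_errors(self):
        region = AssembledRegion("CAGGUAAG", boundary_offset=3)  # only +1..+5
        with pytest.raises(IndexError):
            donor_context(region)


class TestU1Mismatches:
    @pytest.mark.parametrize("policy", ["wc_plus_gu", "wc_only"])
    def test_ikbkap_fixtures(self, wt_region, fd_region, policy):
        """WT pairs everywhere but -1; the +6 C adds a second mismatch."""
        reg = U1Register(wobble_policy=policy)
        wt = u1_mismatches(donor_context(wt_region), reg)
        fd = u1_mismatches(donor_context(fd_region), reg)
        assert set(wt.mismatch_positions) == {-1}
        assert set(fd.mismatch_positions) == {-1, 6}
        assert fd.mismatch_positions >= wt.mismatch_positions
        assert set(fd.mismatch_positions - wt.mismatch_positions) == {6}

    def test_consensus_is_fully_paired(self):
        mm = u1_mismatches(DonorContext("CAGGUAAGU"))
        assert mm.mismatch_positions == frozenset()
        assert mm.n_paired == 9

    def test_mismatch_and_paired_partition_all_nine_positions(self):
        mm = u1_mismatches(DonorContext("AAAAAAAAA"))
        assert mm.mismatch_positions | mm.paired_positions == frozenset(
            (-3, -2, -1, 1, 2, 3, 4, 5, 6)
        )

    @given(st.text(alphabet="ACGU", min_size=9, max_size=9))
    @settings(derandomize=True, max_examples=100)
    def test_wobble_policy_monotonicity(self, seq):
        """wc_only never reports fewer mismatches than wc_plus_gu."""
        ctx = DonorContext(seq)
        strict = u1_mismatches(ctx, U1Register(wobble_policy="wc_only"))
        loose = u1_mismatches(ctx, U1Register(wobble_policy="wc_plus_gu"))
        assert strict.mismatch_positions >= loose.mismatch_positions

    def test_wobble_counts_gu_as_pairing(self):
        # +5 pairs template C; +4 pairs template U, so G at +4 is a wobble
        ctx = DonorContext("CAGGUAGGU")
        assert 4 in u1_mismatches(ctx, U1Register(wobble_policy="wc_only")).mismatch_positions
        assert 4 not in u1_mismatches(ctx).mismatch_positions


def brute_force_scan(region, pwm, window):
    """Independent re-implementation: enumerate every L-mer by string ops."""
    hits = []
    base = {"A": 0, "C": 1, "G": 2, "U": 3}
    for p in range(window[0], window[1] + 1):
        if p == 0:
            continue
        i = region.boundary_offset + (p - 1 if p > 0 else p)
        if i < 0 or i + pwm.length > len(region.sequence):
            continue
        lmer = region.sequence[i : i + pwm.length]
        score = sum(float(pwm.matrix[k][base[c]]) for k, c in enumerate(lmer))
        if score >= pwm.threshold:
            hits.append((p, lmer, round(score, 6)))
    return hits


class TestPwmScan:
    def test_bundled_srsf6_matrix_shape_and_threshold(self, srsf6):
        assert srsf6.length == 6
        assert srsf6.threshold == pytest.approx(2.676)
        assert "ESEfinder" in srsf6.provenance

    def test_scan_matches_brute_force_on_fd_region(self, fd_region, srsf6):
        hits = scan_pwm(fd_region, srsf6, (-100, 100))
        expected = brute_force_scan(fd_region, srsf6, (-100, 100))
        assert [(h.start, h.sequence, round(h.score, 6)) for h in hits] == expected

    def test_site_b_and_site_c_motifs_detected(self, fd_region, srsf6):
        """The intronic enhancer at +45 (UGUGUG) and the +58 site score
        above the ESEfinder threshold."""
        starts = {h.start: h for h in scan_pwm(fd_region, srsf6, (-100, 100))}
        assert 45 in starts and starts[45].sequence == "UGUGUG"
        assert starts[45].score == pytest.approx(3.00, abs=0.005)
        assert 58 in starts and starts[58].sequence == "UAAGUA"

    def test_top_hit_in_site_b_span_starts_at_45(self, fd_region, srsf6):
        sub = scan_pwm(fd_region, srsf6, (29, 48), include_subthreshold=True)
        best = max(sub, key=lambda h: h.score)
        assert (best.start, best.sequence, best.above_threshold) == (45, "UGUGUG", True)

    def test_poly_a_scores_below_threshold(self, srsf6):
        region = AssembledRegion("GUAAG" + "A" * 50, boundary_offset=0)
        assert scan_pwm(region, srsf6, (1, 50)) == []

    def test_threshold_equality_is_a_hit(self):
        pwm = PwmModel("toy", np.zeros((2, 4)), 0.0, "synthetic toy matrix")
        region = AssembledRegion("GUAAGAC", boundary_offset=0)
        hits = scan_pwm(region, pwm, (1, 3))
        assert [h.start for h in hits] == [1, 2, 3]

    def test_translation_covariance(self, srsf6):
        seq = "GUAAGCGCCAUUGUACUGUUUGCGACUAGUUAGCUUGUGAUUUAUGUGUGAAG"
        r1 = AssembledRegion("C" * 4 + seq, boundary_offset=4)
        r2 = AssembledRegion("C" * 11 + seq, boundary_offset=11)
        h1 = scan_pwm(r1, srsf6, (1, 40))
        h2 = scan_pwm(r2, srsf6, (1, 40))
        assert [(h.start, h.sequence) for h in h1] == [(h.start, h.sequence) for h in h2]

    def test_window_outside_sequence_warns_and_returns_empty(self, fd_region, srsf6):
        with pytest.warns(UserWarning, match="outside"):
            assert scan_pwm(fd_region, srsf6, (200, 300)) == []


class TestVariantComparison:
    def test_site_b_mutant_substitution_positions(self):
        """site-b(mt) differs at oligo positions 18, 20, 21, 22 (1-based),
        i.e. intron +46, +48, +49, +50 when tiled at +29."""
        ref = AssembledRegion(get_oligo("oAM156").sequence, boundary_offset=-28)
        alt = AssembledRegion(get_oligo("oAM167").sequence, boundary_offset=-28)
        pwm = load_pwm("SRSF6")
        cmpr = compare_variant_motifs(ref, alt, pwm, (29, 53))
        assert cmpr.substituted_positions == [46, 48, 49, 50]

    def test_identical_sequences_report_nothing(self, fd_region, srsf6):
        cmpr = compare_variant_motifs(fd_region, fd_region, srsf6)
        assert cmpr.substituted_positions == []
        assert cmpr.lost_hits == []
        assert all(
            cmpr.alt_scores[h.start] == pytest.approx(h.score) for h in cmpr.ref_hits
        )

    def test_loss_classification_on_controlled_matrix(self):
        # matrix rewards GGG only; mutating the middle G destroys the hit
        m = np.full((3, 4), -2.0)
        m[:, 2] = 1.0  # G column
        pwm = PwmModel("toy", m, 3.0, "synthetic toy matrix")
        ref = AssembledRegion("GUAAGGGA", boundary_offset=0)
        alt = AssembledRegion("GUAAGCGA", boundary_offset=0)
        cmpr = compare_variant_motifs(ref, alt, pwm, (1, 6))
        assert [h.start for h in cmpr.ref_hits] == [5]
        assert [h.start for h in cmpr.lost_hits] == [5]

    def test_length_mismatch_errors(self, fd_region, srsf6):
        alt = AssembledRegion(fd_region.sequence[:-1], boundary_offset=8)
        with pytest.raises(ValueError, match="length"):
            compare_variant_motifs(fd_region, alt, srsf6)
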