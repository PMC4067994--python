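import numpy as np
import pytest

from otocnv import (
    PanelError,
    call_cohort,
    detect_conversions,
    diagnose_strc_locus,
    normalize_by_batch,
    segment_calls,
    simulate_cohort,
    SimulationConfig,
    SpikeEvent,
)

from conftest import make_ratio_matrix


def strc_vals(gene_ratio, partner_ratio, exons=range(19, 30)):
    vals = {f"STRC_{k}": gene_ratio for k in exons}
    vals.update({f"PSTRC_{k}": partner_ratio for k in exons})
    return vals


class TestDetectConversions:
    def test_biallelic_signature_one_event(self, panel):
        rm = make_ratio_matrix(panel, {"A": strc_vals(0.0, 2.0)})
        calls = segment_calls(rm, panel, "A")
        events, residual = detect_conversions(calls, panel)
        assert len(events) == 1
        ev = events[0]
        assert (ev.gene, ev.pseudogene, ev.alleles) == ("STRC", "PSTRC", 2)
        assert ev.exon_span == (19, 29)
        # the deletion+duplication pair is consumed, not reported twice
        assert not [c for c in residual if c.gene in ("STRC", "PSTRC")]

    def test_plain_deletion_stays_residual(self, panel):
        rm = make_ratio_matrix(panel, {"A": strc_vals(0.0, 1.0)})
        calls = segment_calls(rm, panel, "A")
        events, residual = detect_conversions(calls, panel)
        assert events == []
        assert [c.cnv_class for c in residual if c.gene == "STRC"] == ["deletion"]

    def test_monoallelic_conversion(self, panel):
        rm = make_ratio_matrix(panel, {"A": strc_vals(0.5, 1.5)})
        events, residual = detect_conversions(
            segment_calls(rm, panel, "A"), panel
        )
        assert len(events) == 1 and events[0].alleles == 1

    @pytest.mark.parametrize(
        "gene_cn,partner_cn,expected_alleles",
        [(0, 4, 2), (1, 3, 1), (0, 3, None), (1, 4, None)],
    )
    def test_zygosity_pairings_follow_reciprocity(
        self, panel, gene_cn, partner_cn, expected_alleles
    ):
        """Enumerate deletion-zygosity x partner-gain pairings: only the
        copy-conserving combinations (loss == gain) become conversions."""
        rm = make_ratio_matrix(panel, {"A": strc_vals(gene_cn / 2, partner_cn / 2)})
        events, _ = detect_conversions(segment_calls(rm, panel, "A"), panel)
        if expected_alleles is None:
            assert events == []
        else:
            assert len(events) == 1 and events[0].alleles == expected_alleles

    def test_copy_conservation_for_emitted_events(self, panel):
        rm = make_ratio_matrix(panel, {"A": strc_vals(0.05, 1.98)})
        events, _ = detect_conversions(segment_calls(rm, panel, "A"), panel)
        (ev,) = events
        dele, dup = ev.evidence
        gene_cn = 2 * dele.mean_ratio
        partner_cn = 2 * dup.mean_ratio
        assert gene_cn + partner_cn == pytest.approx(4.0, abs=0.6)

    def test_partial_overlap_below_frac_not_matched(self, panel):
        # gene-side deletion of 10 exons, pseudogene gain on only 5 partners
        vals = {f"STRC_{k}": 0.0 for k in range(11, 21)}
        vals.update({f"PSTRC_{k}": 2.0 for k in range(11, 16)})
        events, residual = detect_conversions(
            segment_calls(make_ratio_matrix(panel, {"A": vals}), panel, "A"), panel
        )
        assert events == []
        assert {c.cnv_class for c in residual if c.gene in ("STRC", "PSTRC")} == {
            "deletion",
            "duplication",
        }

    def test_simulated_biallelic_conversion_detected(self, panel):
        ev = [SpikeEvent("S003", "STRC", (19, 29), "conversion", 2)]
        dm, _ = simulate_cohort(
            SimulationConfig(n_samples=24, seed=5, events=ev), panel
        )
        calls = call_cohort(normalize_by_batch(dm), panel)
        events, residual = detect_conversions(calls, panel)
        assert len(events) == 1 and events[0].alleles == 2
        assert not [c for c in residual if c.gene in ("STRC", "PSTRC")]


class TestStrcLocus:
    def run(self, panel, per_sample):
        rm = make_ratio_matrix(panel, per_sample)
        calls = call_cohort(rm, panel)
        events, residual = detect_conversions(calls, panel)
        return residual, events

    def test_hom_contiguous_deletion_is_dis(self, panel):
        vals = {f"STRC_{k}": 0.0 for k in range(1, 30)}
        vals.update({f"PSTRC_{k}": 0.0 for k in range(1, 30)})
        vals.update({f"CATSPER2_{k}": 0.0 for k in (1, 2, 3)})
        residual, events = self.run(panel, {"A": vals})
        d = diagnose_strc_locus(residual, events, "A", panel)
        assert d.strc_status == ("deleted", "deleted")
        assert d.catsper2_involved and d.dis

    def test_catsper2_only_deletion_not_dis(self, panel):
        vals = {f"CATSPER2_{k}": 0.0 for k in (1, 2, 3)}
        vals.update({f"PSTRC_{k}": 0.0 for k in range(1, 30)})
        residual, events = self.run(panel, {"A": vals})
        d = diagnose_strc_locus(residual, events, "A", panel)
        assert d.strc_status == ("intact", "intact")
        assert d.catsper2_involved and not d.dis

    def test_biallelic_conversion_not_dis(self, panel):
        residual, events = self.run(panel, {"A": strc_vals(0.0, 2.0)})
        d = diagnose_strc_locus(residual, events, "A", panel)
        assert d.strc_status == ("converted", "converted")
        assert not d.catsper2_involved and not d.dis

    def test_het_deletion_single_allele(self, panel):
        residual, events = self.run(panel, {"A": strc_vals(0.5, 1.0, range(1, 30))})
        d = diagnose_strc_locus(residual, events, "A", panel)
        assert sorted(d.strc_status) == ["deleted", "intact"]
        assert not d.dis

    def test_strc_absent_from_panel_rejected(self, tiny_panel):
        with pytest.raises(PanelError, match="absent"):
            diagnose_strc_locus([], [], "A", tiny_panel)
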