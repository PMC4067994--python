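import numpy as np
import pandas as pd
import pytest

from otocnv import (
    PanelError,
    SmallVariant,
    carrier_frequency,
    classify_causative,
    records_from_calls,
    summarize_cohort,
    cohort_records,
)
from otocnv.calling import CnvCall
from otocnv.conversions import ConversionEvent
from otocnv.diagnostics import round_half_away
from otocnv.fixture import _COLUMNS


def call(sample, gene, cls="deletion", zyg="het", chrom="chr1", flags=()):
    return CnvCall(
        sample_id=sample,
        gene=gene,
        chrom=chrom,
        start=0,
        end=1000,
        exon_first=1,
        exon_last=2,
        cnv_class=cls,
        zygosity=zyg,
        mean_ratio={"het": 0.5, "hom": 0.0}.get(zyg, 1.5),
        n_targets=2,
        flags=frozenset(flags),
    )


def snv(sample, gene, zyg="het", pathogenic=True):
    return SmallVariant(sample, gene, "chr1", 100, "A", "G", zyg, pathogenic)


def conv(sample, gene="STRC", alleles=1):
    ev_del = call(sample, gene, "deletion", "het" if alleles == 1 else "hom")
    ev_dup = call(sample, "PSTRC", "duplication", "het")
    return ConversionEvent(sample, gene, "PSTRC", (19, 29), alleles, (ev_del, ev_dup))


class TestClassifyCausative:
    def get(self, assignments, sample, gene):
        return next(a for a in assignments if (a.sample_id, a.gene) == (sample, gene))

    def test_hom_deletion_is_hom_cnv(self, panel):
        a = classify_causative([call("P1", "OTOA", zyg="hom")], [], [], panel)
        assert self.get(a, "P1", "OTOA").category == "hom_cnv"

    def test_het_cnv_plus_het_pathogenic_snv(self, panel):
        a = classify_causative(
            [call("P2", "TMC1")], [], [snv("P2", "TMC1")], panel
        )
        assert self.get(a, "P2", "TMC1").category == "hemizygous_cnv_plus_snv"

    def test_deletion_opposite_conversion_is_biallelic(self, panel):
        a = classify_causative([call("P3", "STRC")], [conv("P3")], [], panel)
        assert self.get(a, "P3", "STRC").category == "biallelic_cnv"

    def test_biallelic_conversion_alone_is_biallelic(self, panel):
        a = classify_causative([], [conv("P4", alleles=2)], [], panel)
        assert self.get(a, "P4", "STRC").category == "biallelic_cnv"

    def test_lone_het_deletion_in_recessive_gene_is_carrier(self, panel):
        a = classify_causative([call("P5", "OTOA")], [], [], panel)
        got = self.get(a, "P5", "OTOA")
        assert got.category == "carrier_only"
        assert not got.inheritance_consistent

    def test_ad_gene_het_cnv_gets_review_flag(self, panel):
        a = classify_causative([call("P6", "MYH9", chrom="chr22")], [], [], panel)
        got = self.get(a, "P6", "MYH9")
        assert got.category == "carrier_only"
        assert "ad_review" in got.flags
        assert {"in_frame", "out_of_frame"} & got.flags

    def test_contiguous_flag_category(self, panel):
        calls = [
            call("P7", "MYH9", chrom="chr22", flags=["multi_gene_contiguous"]),
            call("P7", "TRIOBP", chrom="chr22", flags=["multi_gene_contiguous"]),
        ]
        a = classify_causative(calls, [], [], panel)
        assert self.get(a, "P7", "TRIOBP").category == "contiguous_multi_gene"

    def test_non_pathogenic_snv_does_not_phase(self, panel):
        a = classify_causative(
            [call("P8", "TMC1")], [], [snv("P8", "TMC1", pathogenic=False)], panel
        )
        assert self.get(a, "P8", "TMC1").category == "carrier_only"

    def test_snv_in_unknown_gene_rejected(self, panel):
        with pytest.raises(PanelError, match="absent from panel"):
            classify_causative([], [], [snv("P9", "NOTAGENE")], panel)


class TestSummarize:
    def test_empty_records_all_zero(self):
        empty = pd.DataFrame(columns=_COLUMNS).astype({"causative": bool})
        s = summarize_cohort(empty, 100, 10)
        assert s.scalars["n_cnvs"] == 0
        assert s.scalars["overall_cnv_carrier_pct"] == 0.0
        assert s.table.empty

    def test_diagnosed_exceeding_tested_rejected(self):
        with pytest.raises(PanelError):
            summarize_cohort(cohort_records(), 100, 200)

    def test_counting_matches_brute_force_oracle(self):
        rng = np.random.default_rng(21)
        genes = ["G1", "G2", "G3"]
        rows = []
        for i in range(200):
            rows.append(
                (
                    f"P{rng.integers(0, 80):03d}",
                    rng.choice(genes),
                    rng.choice(["deletion", "conversion", "duplication"]),
                    bool(rng.integers(0, 2)),
                    "hom_cnv",
                    "het",
                    False,
                )
            )
        df = pd.DataFrame(rows, columns=_COLUMNS)
        s = summarize_cohort(df, 500, 400)
        for gene in genes:
            sub = [r for r in rows if r[1] == gene]
            assert s.table.loc[gene, "total"] == len(sub)
            assert s.table.loc[gene, "causative"] == sum(1 for r in sub if r[3])
            assert s.table.loc[gene, "deletion"] == sum(
                1 for r in sub if r[2] == "deletion"
            )
        assert s.scalars["n_patients_with_cnv"] == len({r[0] for r in rows})

    @pytest.mark.parametrize(
        "x,d,expected",
        [(143 / 686 * 100, 1, 20.8), (12.587, 0, 13.0), (0.5, 0, 1.0), (-0.5, 0, -1.0)],
    )
    def test_rounding_half_away_from_zero(self, x, d, expected):
        assert round_half_away(x, d) == expected


class TestCarrierFrequency:
    def test_printed_example(self):
        df = cohort_records()
        assert carrier_frequency(df, 686, "STRC", "deletion") == pytest.approx(
            65 / 1372
        )

    def test_no_events_zero(self):
        assert carrier_frequency(pd.DataFrame(columns=_COLUMNS), 10, "STRC", "deletion") == 0

    def test_zero_samples_rejected(self):
        with pytest.raises(PanelError):
            carrier_frequency(pd.DataFrame(columns=_COLUMNS), 0, "STRC", "deletion")

    def test_calls_and_records_agree(self, panel):
        calls = [
            call("P1", "STRC", zyg="hom"),
            call("P2", "STRC"),
            call("P3", "STRC", cls="duplication"),
        ]
        convs = [conv("P4", alleles=2)]
        assignments = classify_causative(calls, convs, [], panel)
        records = records_from_calls(calls, convs, assignments)
        for cls, expected in [("deletion", 3), ("duplication", 1), ("conversion", 2)]:
            assert carrier_frequency(calls + convs, 50, "STRC", cls) == pytest.approx(
                expected / 100
            )
            assert carrier_frequency(records, 50, "STRC", cls) == pytest.approx(
                expected / 100
            )
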