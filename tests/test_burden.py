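import numpy as np
import pytest
from scipy import stats

from otocnv import (
    PanelError,
    RepeatAnnotation,
    compare_burden,
    count_repeats,
    read_repeatmasker_out,
)
from otocnv.burden import GeneBurden


def ann(chrom, start, end, family, ident=None):
    return RepeatAnnotation(chrom, start, end, family, ident)


GENES = {"G1": ("chr1", 1000, 5000), "G2": ("chr1", 10000, 12000)}


class TestCountRepeats:
    def test_no_overlap_all_zero(self):
        burdens = count_repeats(GENES, [ann("chr1", 6000, 7000, "Alu")])
        assert all(sum(b.counts.values()) == 0 for b in burdens)

    def test_one_bp_overlap_counts(self):
        burdens = count_repeats(GENES, [ann("chr1", 999, 1001, "L1")])
        b = next(b for b in burdens if b.gene == "G1")
        assert b.counts["L1"] == 1

    @pytest.mark.parametrize("identity,expected", [(96.0, 1), (94.0, 0)])
    def test_segdup_identity_threshold(self, identity, expected):
        burdens = count_repeats(
            GENES, [ann("chr1", 2000, 3000, "segdup", identity)]
        )
        b = next(b for b in burdens if b.gene == "G1")
        assert b.counts["segdup"] == expected

    def test_matches_all_pairs_overlap_oracle(self):
        rng = np.random.default_rng(13)
        genes = {
            f"g{i}": ("chr1", int(s), int(s) + int(l))
            for i, (s, l) in enumerate(
                zip(rng.integers(0, 10**5, 15), rng.integers(500, 5000, 15))
            )
        }
        annotations = [
            ann("chr1", int(s), int(s) + int(l), fam)
            for s, l, fam in zip(
                rng.integers(0, 10**5, 80),
                rng.integers(50, 2000, 80),
                rng.choice(["Alu", "L1", "simple_repeat"], 80),
            )
        ]
        burdens = {b.gene: b for b in count_repeats(genes, annotations)}
        for g, (chrom, gs, ge) in genes.items():
            for fam in ("Alu", "L1", "simple_repeat"):
                expected = sum(
                    1
                    for a in annotations
                    if a.family == fam and a.start < ge and gs < a.end
                )
                assert burdens[g].counts[fam] == expected, (g, fam)

    def test_normalization_scales_with_length(self):
        b1 = GeneBurden("g", 2000, {"Alu": 4})
        b2 = GeneBurden("g", 4000, {"Alu": 4})
        assert b1.normalized["Alu"] == 2 * b2.normalized["Alu"]

    def test_zero_length_gene_rejected(self):
        with pytest.raises(PanelError):
            GeneBurden("g", 0, {"Alu": 1})


def welch_formula(x, y):
    """Textbook Welch t and two-sided p, independent of scipy.ttest_ind."""
    nx, ny = len(x), len(y)
    vx, vy = np.var(x, ddof=1), np.var(y, ddof=1)
    t = (np.mean(x) - np.mean(y)) / np.sqrt(vx / nx + vy / ny)
    df = (vx / nx + vy / ny) ** 2 / (
        (vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1)
    )
    p = 2 * stats.t.sf(abs(t), df)
    return t, p


def burdens_from_vectors(x, y):
    """Genes of 1 kb so the per-kb Alu burden equals the raw vector value."""

    def mk(name, v, assoc):
        counts = {"Alu": int(v), "L1": 0, "segdup": 0, "simple_repeat": 0}
        return GeneBurden(name, 1000, counts, cnv_associated=assoc)

    return [mk(f"a{i}", v, True) for i, v in enumerate(x)] + [
        mk(f"b{i}", v, False) for i, v in enumerate(y)
    ]


class TestCompareBurden:
    def test_identical_groups_t0_p1(self):
        x = [1, 2, 3, 4]
        cmp_ = compare_burden(burdens_from_vectors(x, x), ("Alu",))[0]
        assert cmp_.t_statistic == pytest.approx(0.0)
        assert cmp_.p_value == pytest.approx(1.0)

    def test_hand_vectors_match_textbook_welch(self):
        x, y = [3, 5, 4, 6, 5], [1, 2, 2, 1]
        cmp_ = compare_burden(burdens_from_vectors(x, y), ("Alu",))[0]
        t, p = welch_formula(np.array(x), np.array(y))
        assert cmp_.t_statistic == pytest.approx(t, abs=1e-10)
        assert cmp_.p_value == pytest.approx(p, abs=1e-10)

    def test_random_vectors_match_formula(self):
        rng = np.random.default_rng(31)
        for _ in range(10):
            x = rng.integers(0, 30, rng.integers(3, 12))
            y = rng.integers(0, 30, rng.integers(3, 12))
            if np.var(x) == 0 or np.var(y) == 0:
                continue
            cmp_ = compare_burden(burdens_from_vectors(x, y), ("Alu",))[0]
            t, p = welch_formula(x.astype(float), y.astype(float))
            assert cmp_.t_statistic == pytest.approx(t, abs=1e-10)
            assert cmp_.p_value == pytest.approx(p, abs=1e-10)

    def test_twofold_enrichment_detected_most_seeds(self):
        hits = 0
        n_draws = 100
        for seed in range(n_draws):
            rng = np.random.default_rng(1000 + seed)
            x = rng.poisson(20, 20)
            y = rng.poisson(10, 20)
            p = compare_burden(burdens_from_vectors(x, y), ("Alu",))[0].p_value
            hits += p < 0.05
        assert hits >= 0.9 * n_draws

    def test_alu_plus_l1_class(self):
        b = GeneBurden("g", 2000, {"Alu": 3, "L1": 1, "segdup": 0, "simple_repeat": 0})
        assert b.normalized_for("Alu+L1") == pytest.approx(4 * 1000 / 2000)

    def test_paired_requires_equal_sizes(self):
        with pytest.raises(PanelError, match="equal"):
            compare_burden(
                burdens_from_vectors([1, 2, 3], [1, 2]), ("Alu",), test_kind="paired"
            )

    def test_small_group_rejected(self):
        with pytest.raises(PanelError, match=">= 2"):
            compare_burden(burdens_from_vectors([1], [1, 2]), ("Alu",))


def test_repeatmasker_out_parser(tmp_path):
    text = (
        "   SW  perc perc perc  query      position in query           matching"
        "       repeat              position in  repeat\n"
        "score  div. del. ins.  sequence    begin     end    (left)    repeat"
        "         class/family         begin  end (left)   ID\n"
        "\n"
        "  463   1.3  0.6  1.7  chr1        10001   10468 (248945954) + (TAACCC)n"
        "      Simple_repeat            1  463    (0)      1\n"
        " 2271  11.5  0.1  0.5  chr1        11505   11675 (248944747) - AluY"
        "           SINE/Alu               1  171    (0)      2\n"
        " 1234  15.0  0.2  0.2  chr1        12000   12500 (0) + L1PA7"
        "          LINE/L1                1  500    (0)      3\n"
    )
    p = tmp_path / "rm.out"
    p.write_text(text)
    anns = read_repeatmasker_out(p)
    assert [a.family for a in anns] == ["simple_repeat", "Alu", "L1"]
    assert anns[0].start == 10000 and anns[0].end == 10468  # 1-based inclusive in
    assert anns[1].identity_pct == pytest.approx(100 - 11.5)
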