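"""Repetitive-element burden of panel genes.

Segmental duplications, Alu and L1 elements are the substrates of the
recombination and repair mechanisms (NAHR, NHEJ) that generate CNVs, so
genes sitting in repeat-dense neighbourhoods are CNV-prone.  This module
counts elements overlapping each gene span, normalizes per kb of gene
length, and compares CNV-associated genes against the rest of the panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from intervaltree import IntervalTree
from scipy import stats

from .panel import PanelDefinition, PanelError, RepeatAnnotation

SEGDUP_MIN_IDENTITY = 95.0  # percent homology below which segdups are ignored
COUNT_FAMILIES = ("segdup", "Alu", "L1", "simple_repeat")


@dataclass
class GeneBurden:
    gene: str
    length_bp: int
    counts: dict[str, int]
    cnv_associated: bool = False

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise PanelError(f"gene {self.gene} has zero length")
        if any(v < 0 for v in self.counts.values()):
            raise PanelError("negative repeat count")

    @property
    def normalized(self) -> dict[str, float]:
        """Counts per kb of gene span."""
        return {k: v * 1000.0 / self.length_bp for k, v in self.counts.items()}

    def normalized_for(self, element_class: str) -> float:
        if element_class == "Alu+L1":
            return (self.counts["Alu"] + self.counts["L1"]) * 1000.0 / self.length_bp
        return self.normalized[element_class]


@dataclass(frozen=True)
class BurdenComparison:
    element_class: str
    n_cnv_genes: int
    n_other_genes: int
    t_statistic: float
    p_value: float
    test_kind: str  # welch_two_sample | paired


def count_repeats(
    gene_intervals: dict[str, tuple[str, int, int]] | PanelDefinition,
    annotations: list[RepeatAnnotation],
    cnv_genes: set[str] | None = None,
    min_segdup_identity: float = SEGDUP_MIN_IDENTITY,
    flank: int = 0,
) -> list[GeneBurden]:
    """Count elements overlapping each gene span by >= 1 bp.

    Segdups only count when their identity exceeds ``min_segdup_identity``
    (recombination needs high homology); segdups without an identity value
    are kept.  Gene spans default to min-start..max-end of the gene's panel
    targets; ``flank`` widens each span symmetrically.
    """
    if isinstance(gene_intervals, PanelDefinition):
        gene_intervals = {
            g: gene_intervals.gene_span(g) for g in gene_intervals.gene_symbols()
        }
    trees: dict[str, IntervalTree] = {}
    for a in annotations:
        if a.family == "segdup" and a.identity_pct is not None:
            if a.identity_pct <= min_segdup_identity:
                continue
        trees.setdefault(a.chrom, IntervalTree()).addi(a.start, a.end, a.family)
    out = []
    cnv_genes = cnv_genes or set()
    for gene, (chrom, start, end) in gene_intervals.items():
        lo, hi = start - flank, end + flank
        counts = {f: 0 for f in COUNT_FAMILIES}
        if chrom in trees:
            for iv in trees[chrom].overlap(lo, hi):
                if iv.data in counts:
                    counts[iv.data] += 1
        out.append(
            GeneBurden(
                gene=gene,
                length_bp=hi - lo,
                counts=counts,
                cnv_associated=gene in cnv_genes,
            )
        )
    return out


def compare_burden(
    burdens: list[GeneBurden],
    element_classes: tuple[str, ...] = ("Alu", "L1", "Alu+L1", "simple_repeat"),
    test_kind: str = "welch_two_sample",
) -> list[BurdenComparison]:
    """Two-sided t-tests on per-kb burdens, CNV-associated vs other genes.

    Default is Welch's unequal-variance two-sample test: the two gene groups
    are unequal in size and have no natural pairing.  ``paired`` mode
    (requiring equal group sizes, paired by list order) is retained for
    fidelity experiments.
    """
    a = [b for b in burdens if b.cnv_associated]
    o = [b for b in burdens if not b.cnv_associated]
    if len(a) < 2 or len(o) < 2:
        raise PanelError("each group needs >= 2 genes for a variance estimate")
    out = []
    for cls in element_classes:
        x = np.array([b.normalized_for(cls) for b in a])
        y = np.array([b.normalized_for(cls) for b in o])
        if test_kind == "welch_two_sample":
            t, p = stats.ttest_ind(x, y, equal_var=False)
        elif test_kind == "paired":
            if len(x) != len(y):
                raise PanelError("paired test needs equal group sizes")
            t, p = stats.ttest_rel(x, y)
        else:
            raise PanelError(f"unknown test_kind {test_kind!r}")
        if not np.isfinite(t) and np.mean(x) == np.mean(y):
            t, p = 0.0, 1.0  # equal-mean degenerate groups (zero variance)
        out.append(
            BurdenComparison(
                element_class=cls,
                n_cnv_genes=len(x),
                n_other_genes=len(y),
                t_statistic=float(t),
                p_value=float(p),
                test_kind=test_kind,
            )
        )
    return out
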