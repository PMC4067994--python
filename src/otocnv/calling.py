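"""Per-target copy-state classification and segmentation into CNV calls.

Ratios near 0, 0.5, 1, 1.5+ correspond to diploid copy numbers 0, 1, 2, 3+.
Thresholds sit midway between the ideal levels and are configurable; exact
boundary values resolve to the lower-copy state.  Maximal runs of targets in
the same non-normal state within one gene become calls.  Because the panels
resolve single exons, there is no minimum-size requirement — single-target
calls instead carry a ``single_exon`` QC flag standing in for manual
curation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .panel import PanelDefinition, PanelError
from .ratios import RatioMatrix

STATES = ("hom_del", "het_del", "normal", "dup")


@dataclass(frozen=True)
class Thresholds:
    """Ratio cut-points separating copy states (0 < hom < het < 1 < dup)."""

    hom: float = 0.2
    het: float = 0.7
    dup: float = 1.3

    def __post_init__(self) -> None:
        if not (0 < self.hom < self.het < 1 < self.dup):
            raise PanelError("need 0 < hom < het < 1 < dup")


DEFAULT_THRESHOLDS = Thresholds()


def classify_target(ratio: float, thresholds: Thresholds = DEFAULT_THRESHOLDS) -> str:
    """Map one ratio to a copy state; boundaries go to the lower-copy state."""
    if ratio < 0:
        raise PanelError("ratio must be >= 0")
    if ratio <= thresholds.hom:
        return "hom_del"
    if ratio <= thresholds.het:
        return "het_del"
    if ratio >= thresholds.dup:
        return "dup"
    return "normal"


@dataclass(frozen=True)
class CnvCall:
    """A contiguous copy-state event over >= 1 targets of one gene.

    ``zygosity`` may be None for calls on chrX without sample sex metadata.
    Flags: single_exon, segdup_overlap, low_coverage_neighbor,
    multi_gene_contiguous, x_unknown_sex, ad_review.
    """

    sample_id: str
    gene: str
    chrom: str
    start: int
    end: int
    exon_first: int
    exon_last: int
    cnv_class: str  # deletion | duplication | conversion
    zygosity: str | None  # het | hom | biallelic | None
    mean_ratio: float
    n_targets: int
    flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.n_targets < 1:
            raise PanelError("call must cover >= 1 target")
        if self.cnv_class not in ("deletion", "duplication", "conversion"):
            raise PanelError(f"unknown cnv_class {self.cnv_class!r}")

    @property
    def copy_number(self) -> float:
        return estimate_copy_number(self)

    @property
    def exon_span(self) -> tuple[int, int]:
        return (self.exon_first, self.exon_last)

    def with_flags(self, *new: str) -> "CnvCall":
        return replace(self, flags=self.flags | frozenset(new))


def estimate_copy_number(call: CnvCall) -> float:
    """Continuous copy-number estimate: cn = 2 * mean ratio."""
    return 2.0 * call.mean_ratio


_X_CHROMS = {"chrX", "X"}


def _make_call(
    sample: str,
    gene: str,
    targets,
    ratios_vals,
    state: str,
    extra_flags=(),
) -> CnvCall:
    mean_ratio = float(np.mean(ratios_vals))
    if state in ("hom_del", "het_del"):
        cls = "deletion"
        zyg = "hom" if state == "hom_del" else "het"
    else:
        cls = "duplication"
        # >= 2 extra copies on average -> both alleles carry the gain
        zyg = "hom" if mean_ratio >= 1.75 else "het"
    flags = set(extra_flags)
    if len(targets) == 1:
        flags.add("single_exon")
    if any(t.segdup_flag for t in targets):
        flags.add("segdup_overlap")
    if targets[0].chrom in _X_CHROMS:
        flags.add("x_unknown_sex")
        zyg = None
    return CnvCall(
        sample_id=sample,
        gene=gene,
        chrom=targets[0].chrom,
        start=min(t.start for t in targets),
        end=max(t.end for t in targets),
        exon_first=min(t.exon_index for t in targets),
        exon_last=max(t.exon_index for t in targets),
        cnv_class=cls,
        zygosity=zyg,
        mean_ratio=mean_ratio,
        n_targets=len(targets),
        flags=frozenset(flags),
    )


def segment_calls(
    ratios: RatioMatrix,
    panel: PanelDefinition,
    sample: str,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> list[CnvCall]:
    """Segment one sample's ratio track into CNV calls.

    Per gene, unmasked targets are classified and maximal same-state runs
    of non-normal states become calls.  Masked targets inside a run do not
    break it but add a ``low_coverage_neighbor`` flag.  Adjacent hom/het
    deletion runs are merged into a single call when the het-looking segment
    lies entirely in a segmental duplication (paralog reads inflate its
    apparent depth — the classic artifact at gene-pseudogene loci).
    """
    if sample not in ratios.samples:
        raise PanelError(f"unknown sample {sample!r}")
    i = ratios.sample_index(sample)
    col = {tid: j for j, tid in enumerate(ratios.target_ids)}
    calls: list[CnvCall] = []
    for gene in panel.gene_symbols():
        gts = [t for t in panel.targets_for_gene(gene) if t.target_id in col]
        if not gts:
            continue
        runs = []  # (state, [targets], [ratios], saw_masked_gap)
        cur_state, cur_t, cur_r, cur_gap = None, [], [], False
        pending_gap = False
        for t in gts:
            j = col[t.target_id]
            if ratios.mask[j]:
                if cur_state is not None:
                    pending_gap = True  # masked target inside/next to a run
                continue
            s = classify_target(float(ratios.ratio[i, j]), thresholds)
            if s == cur_state:
                cur_t.append(t)
                cur_r.append(float(ratios.ratio[i, j]))
                cur_gap = cur_gap or pending_gap
            else:
                if cur_state is not None:
                    runs.append((cur_state, cur_t, cur_r, cur_gap))
                cur_state, cur_t = s, [t]
                cur_r = [float(ratios.ratio[i, j])]
                cur_gap = pending_gap
            pending_gap = False
        if cur_state is not None:
            runs.append((cur_state, cur_t, cur_r, cur_gap))

        runs = _merge_segdup_shadow(runs)
        for state, ts, rs, gap in runs:
            if state == "normal":
                continue
            flags = {"low_coverage_neighbor"} if gap else set()
            calls.append(_make_call(sample, gene, ts, rs, state, flags))
    return _annotate_multi_gene(calls, panel)


def _merge_segdup_shadow(runs):
    """Merge an adjacent (hom_del, het_del) run pair when the het-looking
    side lies wholly in a segdup: one deletion, zygosity from the clean side.
    """
    out = []
    k = 0
    while k < len(runs):
        if k + 1 < len(runs):
            (s1, t1, r1, g1), (s2, t2, r2, g2) = runs[k], runs[k + 1]
            pair = {s1, s2}
            if pair == {"hom_del", "het_del"}:
                hom_first = s1 == "hom_del"
                shadow_t = t2 if hom_first else t1
                if all(t.segdup_flag for t in shadow_t):
                    out.append(("hom_del", t1 + t2, r1 + r2, g1 or g2))
                    k += 2
                    continue
        out.append(runs[k])
        k += 1
    return out


def _annotate_multi_gene(calls: list[CnvCall], panel: PanelDefinition):
    """Flag calls in adjacent same-chromosome genes with compatible state.

    Breakpoints outside targeted exons cannot be mapped, so a deletion
    spanning neighbouring panel genes surfaces as per-gene calls; compatible
    calls in chromosomally adjacent genes get a ``multi_gene_contiguous``
    annotation (the large contiguous-deletion case).
    """
    gene_order: dict[str, list[str]] = {}
    for g in panel.gene_symbols():
        chrom, s, _ = panel.gene_span(g)
        gene_order.setdefault(chrom, []).append(g)
    for chrom in gene_order:
        gene_order[chrom].sort(key=lambda g: panel.gene_span(g)[1])

    out = list(calls)
    by_key = {(c.sample_id, c.gene): n for n, c in enumerate(out)}
    for n, c in enumerate(out):
        order = gene_order.get(c.chrom, [])
        if c.gene not in order:
            continue
        gi = order.index(c.gene)
        for neighbor in order[max(0, gi - 1) : gi + 2]:
            if neighbor == c.gene:
                continue
            m = by_key.get((c.sample_id, neighbor))
            if m is None:
                continue
            o = out[m]
            if o.cnv_class == c.cnv_class and o.zygosity == c.zygosity:
                out[n] = out[n].with_flags("multi_gene_contiguous")
                out[m] = out[m].with_flags("multi_gene_contiguous")
    return out


def call_cohort(
    ratios: RatioMatrix,
    panel: PanelDefinition,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> list[CnvCall]:
    """Segment every sample in the ratio matrix."""
    calls: list[CnvCall] = []
    for s in ratios.samples:
        calls.extend(segment_calls(ratios, panel, s, thresholds))
    return calls
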