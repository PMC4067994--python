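"""Batch-normalized median read-depth ratios with sliding-window smoothing.

This is the quantitative core of the CNV method.  Normalization is a fixed
two-step median contract:

1. library-size scaling: each sample's depths are divided by that sample's
   median depth over all targets, removing per-sample library size;
2. batch ratio: each scaled depth is divided by the per-target median of the
   scaled depths over the sample's batch, removing per-target capture
   efficiency.

The resulting ratio is ~copy_number/2 for a diploid locus.  Targets whose raw
batch-median depth falls below ``min_depth`` are masked as uncallable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .panel import PanelDefinition, PanelError

DEFAULT_MIN_DEPTH = 20.0


@dataclass
class DepthMatrix:
    """Samples x targets mean-depth matrix with per-sample batch labels."""

    samples: list[str]
    batches: list[str]
    target_ids: list[str]
    depth: np.ndarray  # shape (n_samples, n_targets)

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        if self.depth.shape != (len(self.samples), len(self.target_ids)):
            raise PanelError("depth matrix shape mismatch")
        if len(self.batches) != len(self.samples):
            raise PanelError("every sample needs a batch label")
        if not np.isfinite(self.depth).all() or (self.depth < 0).any():
            raise PanelError("depths must be finite and >= 0")

    def sample_index(self, sample: str) -> int:
        return self.samples.index(sample)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.depth, index=self.samples, columns=self.target_ids)
        df.insert(0, "batch", self.batches)
        df.index.name = "sample"
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "DepthMatrix":
        df = pd.read_csv(path, sep="\t", index_col="sample")
        batches = df.pop("batch").astype(str).tolist()
        return cls(
            samples=[str(s) for s in df.index],
            batches=batches,
            target_ids=list(df.columns),
            depth=df.to_numpy(dtype=float),
        )


@dataclass
class RatioMatrix:
    """Normalized read-depth ratios; ratio ~ copy number / 2."""

    samples: list[str]
    batches: list[str]
    target_ids: list[str]
    ratio: np.ndarray
    mask: np.ndarray  # True = excluded (low coverage)
    window_w: int = 1

    def __post_init__(self) -> None:
        self.ratio = np.asarray(self.ratio, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.ratio.shape != (len(self.samples), len(self.target_ids)):
            raise PanelError("ratio matrix shape mismatch")
        if self.mask.shape != (len(self.target_ids),):
            raise PanelError("mask must be per-target")

    def sample_index(self, sample: str) -> int:
        return self.samples.index(sample)

    def sample_ratios(self, sample: str) -> np.ndarray:
        return self.ratio[self.sample_index(sample)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.ratio, index=self.samples, columns=self.target_ids)
        df.insert(0, "batch", self.batches)
        df.index.name = "sample"
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")


def normalize_by_batch(
    depths: DepthMatrix, min_depth: float = DEFAULT_MIN_DEPTH
) -> RatioMatrix:
    """Two-step median normalization of a depth matrix (see module docstring).

    Requires >= 2 samples per batch (the per-target ratio denominator is a
    batch median).  Raises on an all-zero sample, whose library size is
    undefined.
    """
    D = depths.depth
    batches = np.asarray(depths.batches)
    for b in np.unique(batches):
        if (batches == b).sum() < 2:
            raise PanelError(f"batch {b!r} has fewer than 2 samples")

    lib = np.median(D, axis=1, keepdims=True)
    if (lib <= 0).any():
        bad = [depths.samples[i] for i in np.where(lib.ravel() <= 0)[0]]
        raise PanelError(f"sample(s) with zero median depth: {bad}")
    Dp = D / lib

    R = np.empty_like(Dp)
    mask = np.zeros(D.shape[1], dtype=bool)
    for b in np.unique(batches):
        rows = batches == b
        med = np.median(Dp[rows], axis=0)
        raw_med = np.median(D[rows], axis=0)
        mask |= raw_med < min_depth
        with np.errstate(divide="ignore", invalid="ignore"):
            R[rows] = np.where(med > 0, Dp[rows] / med, 0.0)
    return RatioMatrix(
        samples=list(depths.samples),
        batches=list(depths.batches),
        target_ids=list(depths.target_ids),
        ratio=R,
        mask=mask,
        window_w=1,
    )


def sliding_window_smooth(
    ratios: RatioMatrix, w: int, panel: PanelDefinition
) -> RatioMatrix:
    """Windowed median over ``w`` same-gene targets (w odd, in exon units).

    Windows never cross gene boundaries and skip masked targets; ``w=1`` is
    the identity.  Smoothing suppresses single-target outliers, so the
    default calling track stays at w=1 (single-exon CNVs are real events on
    these panels) and the smoothed track serves as QC annotation.
    """
    if w < 1 or w % 2 == 0:
        raise PanelError(f"window must be odd and >= 1, got {w}")
    if w == 1:
        return replace(ratios, ratio=ratios.ratio.copy(), window_w=1)
    half = w // 2
    col = {tid: j for j, tid in enumerate(ratios.target_ids)}
    out = ratios.ratio.copy()
    for gene in panel.gene_symbols():
        gts = [t.target_id for t in panel.targets_for_gene(gene) if t.target_id in col]
        idx = np.array([col[tid] for tid in gts], dtype=int)
        if idx.size == 0:
            continue
        unmasked = ~ratios.mask[idx]
        for k in range(len(idx)):
            if not unmasked[k]:
                continue
            lo, hi = max(0, k - half), min(len(idx), k + half + 1)
            wsel = idx[lo:hi][unmasked[lo:hi]]
            out[:, idx[k]] = np.median(ratios.ratio[:, wsel], axis=1)
    return replace(ratios, ratio=out, window_w=w)


def ratio_plot_data(
    ratios: RatioMatrix, panel: PanelDefinition, sample: str, gene: str
) -> pd.DataFrame:
    """Per-gene (target midpoint, ratio) table for ratio-track plots."""
    i = ratios.sample_index(sample)
    col = {tid: j for j, tid in enumerate(ratios.target_ids)}
    rows = []
    for t in panel.targets_for_gene(gene):
        j = col[t.target_id]
        rows.append(
            {
                "target_id": t.target_id,
                "exon_index": t.exon_index,
                "midpoint": t.midpoint,
                "ratio": ratios.ratio[i, j],
                "masked": bool(ratios.mask[j]),
            }
        )
    return pd.DataFrame(rows)
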