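"""Panel definitions, depth tables, small variants, repeats and call IO.

A targeted deafness panel is modelled as an ordered list of exon-level capture
targets.  Each target knows its gene, its ordinal exon within that gene
(transcription order, as supplied by the panel designer), and — where the gene
sits in a segmental duplication with a pseudogene that is also tiled with
probes — the id of its homologous pseudogene target.  All internal coordinates
are 0-based half-open; BED input is taken as-is, 1-based formats (depth
tables, VCF) are converted on read.
"""

from __future__ import annotations

import csv
import io
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

REPEAT_FAMILIES = ("Alu", "L1", "segdup", "simple_repeat", "other")

CNV_CLASSES = ("deletion", "duplication", "conversion")


class PanelError(ValueError):
    """Malformed panel, depth or annotation input."""


@dataclass(frozen=True)
class TargetInterval:
    """One captured exon-level target.

    ``pseudo_partner`` links a gene exon to the homologous exon of its
    pseudogene when the panel tiles both sides of a segmental duplication
    (e.g. STRC exon k <-> pseudo-STRC exon k).  ``segdup_flag`` marks targets
    whose sequence lies inside a segmental duplication, where read-depth
    signal is shared with the paralog.
    """

    chrom: str
    start: int
    end: int
    gene: str
    exon_index: int
    target_id: str
    pseudo_partner: str | None = None
    segdup_flag: bool = False

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise PanelError(
                f"target {self.target_id}: start {self.start} >= end {self.end}"
            )
        if self.exon_index < 1:
            raise PanelError(f"target {self.target_id}: exon_index must be >= 1")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


@dataclass(frozen=True)
class GeneInfo:
    symbol: str
    inheritance: str = "AR"  # one of AR, AD, XL, both
    is_nshl_mimic: bool = False

    def __post_init__(self) -> None:
        if self.inheritance not in ("AR", "AD", "XL", "both"):
            raise PanelError(f"unknown inheritance mode {self.inheritance!r}")


@dataclass
class PanelDefinition:
    """An ordered panel: targets sorted by (chrom, start) plus gene metadata."""

    name: str
    targets: list[TargetInterval]
    genes: list[GeneInfo] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.targets = sorted(self.targets, key=lambda t: (t.chrom, t.start))
        self._validate()
        self._by_id = {t.target_id: t for t in self.targets}
        known = {g.symbol for g in self.genes}
        for sym in self.gene_symbols():
            if sym not in known:
                self.genes.append(GeneInfo(sym))
        self._gene_info = {g.symbol: g for g in self.genes}

    def _validate(self) -> None:
        seen: set[str] = set()
        for t in self.targets:
            if t.target_id in seen:
                raise PanelError(f"duplicate target_id {t.target_id}")
            seen.add(t.target_id)
        by_id = {t.target_id: t for t in self.targets}
        for t in self.targets:
            if t.pseudo_partner is not None:
                p = by_id.get(t.pseudo_partner)
                if p is None:
                    raise PanelError(
                        f"target {t.target_id}: dangling pseudo_partner "
                        f"{t.pseudo_partner!r}"
                    )
                if p.gene == t.gene:
                    raise PanelError(
                        f"target {t.target_id}: pseudo_partner must be in a "
                        f"different gene"
                    )
        # same-gene targets must not overlap
        per_gene: dict[str, list[TargetInterval]] = {}
        for t in self.targets:
            per_gene.setdefault(t.gene, []).append(t)
        for gene, ts in per_gene.items():
            ts = sorted(ts, key=lambda t: (t.chrom, t.start))
            for a, b in zip(ts, ts[1:]):
                if a.chrom == b.chrom and b.start < a.end:
                    raise PanelError(f"overlapping targets within gene {gene}")

    # -- lookups -----------------------------------------------------------
    def target(self, target_id: str) -> TargetInterval:
        return self._by_id[target_id]

    def __contains__(self, target_id: str) -> bool:
        return target_id in self._by_id

    def gene_symbols(self) -> list[str]:
        out: list[str] = []
        for t in self.targets:
            if t.gene not in out:
                out.append(t.gene)
        return out

    def gene_info(self, symbol: str) -> GeneInfo:
        return self._gene_info[symbol]

    def targets_for_gene(self, gene: str) -> list[TargetInterval]:
        """Targets of one gene in exon order."""
        ts = [t for t in self.targets if t.gene == gene]
        return sorted(ts, key=lambda t: t.exon_index)

    def gene_span(self, gene: str) -> tuple[str, int, int]:
        ts = self.targets_for_gene(gene)
        if not ts:
            raise PanelError(f"gene {gene} not on panel")
        return ts[0].chrom, min(t.start for t in ts), max(t.end for t in ts)

    def target_ids(self) -> list[str]:
        return [t.target_id for t in self.targets]

    def interval_trees(self) -> dict[str, IntervalTree]:
        trees: dict[str, IntervalTree] = {}
        for t in self.targets:
            trees.setdefault(t.chrom, IntervalTree()).addi(t.start, t.end, t.target_id)
        return trees


@dataclass(frozen=True)
class SmallVariant:
    """A small sequence variant used for trans-phasing against het CNVs."""

    sample_id: str
    gene: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    zygosity: str  # het | hom
    pathogenic: bool = False

    def __post_init__(self) -> None:
        if self.zygosity not in ("het", "hom"):
            raise PanelError(f"zygosity must be het/hom, got {self.zygosity!r}")
        if self.pos < 1:
            raise PanelError("pos is 1-based and must be >= 1")


@dataclass(frozen=True)
class RepeatAnnotation:
    """One repetitive-element annotation (0-based half-open)."""

    chrom: str
    start: int
    end: int
    family: str
    identity_pct: float | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise PanelError("repeat annotation with start >= end")
        if self.family not in REPEAT_FAMILIES:
            raise PanelError(f"unknown repeat family {self.family!r}")


# ---------------------------------------------------------------------------
# panel BED reader


def read_panel_bed(
    path: str | os.PathLike,
    gene_metadata: dict[str, GeneInfo] | list[GeneInfo] | None = None,
    name: str = "panel",
) -> PanelDefinition:
    """Read a panel from a BED file.

    The 4th (name) column encodes ``gene|exon_index[|pseudo_partner[|segdup]]``.
    Target ids are ``GENE_EXONINDEX``.  Malformed lines are reported with
    their 1-based line number.
    """
    if isinstance(gene_metadata, dict):
        genes = list(gene_metadata.values())
    else:
        genes = list(gene_metadata or [])
    targets: list[TargetInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise PanelError(f"{path}:{lineno}: expected >=4 BED columns")
            chrom, s, e, namefield = fields[:4]
            try:
                start, end = int(s), int(e)
            except ValueError as exc:
                raise PanelError(f"{path}:{lineno}: non-integer coordinates") from exc
            parts = namefield.split("|")
            if len(parts) < 2:
                raise PanelError(
                    f"{path}:{lineno}: name must be gene|exon_index[|partner[|segdup]]"
                )
            gene = parts[0]
            try:
                exon_index = int(parts[1])
            except ValueError as exc:
                raise PanelError(f"{path}:{lineno}: bad exon_index {parts[1]!r}") from exc
            partner = parts[2] if len(parts) > 2 and parts[2] not in ("", ".") else None
            segdup = len(parts) > 3 and parts[3] == "segdup"
            try:
                targets.append(
                    TargetInterval(
                        chrom=chrom,
                        start=start,
                        end=end,
                        gene=gene,
                        exon_index=exon_index,
                        target_id=f"{gene}_{exon_index}",
                        pseudo_partner=partner,
                        segdup_flag=segdup,
                    )
                )
            except PanelError as exc:
                raise PanelError(f"{path}:{lineno}: {exc}") from exc
    return PanelDefinition(name=name, targets=targets, genes=genes)


def write_panel_bed(panel: PanelDefinition, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for t in panel.targets:
            name = f"{t.gene}|{t.exon_index}|{t.pseudo_partner or '.'}"
            if t.segdup_flag:
                name += "|segdup"
            fh.write(f"{t.chrom}\t{t.start}\t{t.end}\t{name}\n")


# ---------------------------------------------------------------------------
# depth tables


def mean_target_depth(
    positions: np.ndarray, depths: np.ndarray, target: TargetInterval
) -> float:
    """Mean per-base depth over [start, end); absent positions count 0."""
    pos0 = positions - 1  # 1-based -> 0-based
    sel = (pos0 >= target.start) & (pos0 < target.end)
    return float(depths[sel].sum()) / target.length


def read_depth_table(
    path: str | os.PathLike,
    panel: PanelDefinition,
    sample_id: str | None = None,
    batch_map: dict[str, str] | None = None,
):
    """Read a depth table into a :class:`~otocnv.ratios.DepthMatrix`.

    Two layouts are accepted:

    * per-position TSV with columns ``chrom pos depth`` (one sample;
      ``sample_id`` required) or ``sample chrom pos depth``;  ``pos`` is
      1-based.  Positions outside panel targets are dropped; per-target mean
      depth is computed over the full target length.
    * samples x targets matrix TSV with a ``sample`` (and optional ``batch``)
      column and one column per target_id.
    """
    from .ratios import DepthMatrix  # local import to avoid a cycle

    with open(path) as fh:
        header = fh.readline()
    cols = header.rstrip("\n").split("\t")
    if "sample" in cols and any(c in panel for c in cols):
        df = pd.read_csv(path, sep="\t", dtype={"sample": str})
        tids = [c for c in cols if c in panel]
        batches = (
            df["batch"].astype(str).tolist()
            if "batch" in df.columns
            else ["batch0"] * len(df)
        )
        if batch_map:
            batches = [batch_map[s] for s in df["sample"]]
        D = df[tids].to_numpy(dtype=float)
        if (D < 0).any():
            raise PanelError("negative depth in depth matrix")
        return DepthMatrix(
            samples=df["sample"].tolist(), batches=batches, target_ids=tids, depth=D
        )

    # per-position layout
    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    if df.shape[1] == 3:
        if sample_id is None:
            raise PanelError("per-position depth without sample column needs sample_id")
        df.columns = ["chrom", "pos", "depth"]
        df["sample"] = sample_id
    elif df.shape[1] >= 4:
        df = df.iloc[:, :4]
        df.columns = ["sample", "chrom", "pos", "depth"]
    else:
        raise PanelError("depth table needs 3 or 4 columns")
    if (df["depth"] < 0).any():
        raise PanelError("negative depth in depth table")

    trees = panel.interval_trees()
    known_chroms = set(trees)
    samples = list(dict.fromkeys(df["sample"].astype(str)))
    tids = panel.target_ids()
    tindex = {tid: j for j, tid in enumerate(tids)}
    D = np.zeros((len(samples), len(tids)))
    for i, s in enumerate(samples):
        sub = df[df["sample"].astype(str) == s]
        for chrom, grp in sub.groupby("chrom"):
            if chrom not in known_chroms:
                continue  # coordinate outside any panel chromosome: skip
            pos0 = grp["pos"].to_numpy(dtype=int) - 1
            dep = grp["depth"].to_numpy(dtype=float)
            tree = trees[chrom]
            for p, d in zip(pos0, dep):
                for iv in tree.at(p):
                    D[i, tindex[iv.data]] += d
    for j, tid in enumerate(tids):
        D[:, j] /= panel.target(tid).length
    batches = [batch_map[s] if batch_map else "batch0" for s in samples]
    return DepthMatrix(samples=samples, batches=batches, target_ids=tids, depth=D)


# ---------------------------------------------------------------------------
# small variants


def read_small_variants_vcf(
    path: str | os.PathLike,
    panel: PanelDefinition,
    pathogenic_all: bool = True,
) -> list[SmallVariant]:
    """Read per-sample small variants from a VCF (CHROM POS REF ALT GT).

    The gene is assigned from the panel target or gene span overlapping the
    variant position; variants outside panel genes are dropped.  Pathogenicity
    is an upstream assertion: by default every record is taken as asserted
    pathogenic, or supply INFO/PATHOGENIC=0/1.
    """
    from cyvcf2 import VCF

    spans = {g: panel.gene_span(g) for g in panel.gene_symbols()}
    out: list[SmallVariant] = []
    vcf = VCF(str(path))
    samples = vcf.samples
    for rec in vcf:
        gene = None
        for g, (chrom, s, e) in spans.items():
            if rec.CHROM == chrom and s <= rec.POS - 1 < e:
                gene = g
                break
        if gene is None:
            continue
        patho = pathogenic_all
        if "PATHOGENIC" in dict(rec.INFO):
            patho = bool(int(rec.INFO["PATHOGENIC"]))
        for sid, gt in zip(samples, rec.genotypes):
            alleles = [a for a in gt[:-1] if a >= 0]
            nalt = sum(1 for a in alleles if a > 0)
            if nalt == 0:
                continue
            zyg = "hom" if nalt >= 2 else "het"
            out.append(
                SmallVariant(
                    sample_id=sid,
                    gene=gene,
                    chrom=rec.CHROM,
                    pos=rec.POS,
                    ref=rec.REF,
                    alt=rec.ALT[0] if rec.ALT else ".",
                    zygosity=zyg,
                    pathogenic=patho,
                )
            )
    return out


# ---------------------------------------------------------------------------
# repeat annotations


def read_repeats_bed(path: str | os.PathLike) -> list[RepeatAnnotation]:
    """BED with name column = family[|identity_pct]."""
    out: list[RepeatAnnotation] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 4:
                raise PanelError(f"{path}:{lineno}: repeats BED needs 4 columns")
            parts = f[3].split("|")
            ident = float(parts[1]) if len(parts) > 1 else None
            out.append(
                RepeatAnnotation(
                    chrom=f[0],
                    start=int(f[1]),
                    end=int(f[2]),
                    family=parts[0],
                    identity_pct=ident,
                )
            )
    return out


_RM_FAMILY = {"SINE/Alu": "Alu", "LINE/L1": "L1", "Simple_repeat": "simple_repeat"}


def read_repeatmasker_out(path: str | os.PathLike) -> list[RepeatAnnotation]:
    """Read a RepeatMasker .out table (1-based inclusive query coordinates)."""
    out: list[RepeatAnnotation] = []
    with open(path) as fh:
        for raw in fh:
            f = raw.split()
            if len(f) < 11 or not f[0].replace(".", "").isdigit():
                continue  # header / blank lines
            chrom, qbegin, qend = f[4], int(f[5]), int(f[6])
            family = _RM_FAMILY.get(f[10], "other")
            div = float(f[1])  # % divergence -> identity
            out.append(
                RepeatAnnotation(
                    chrom=chrom,
                    start=qbegin - 1,
                    end=qend,
                    family=family,
                    identity_pct=100.0 - div,
                )
            )
    return out


# ---------------------------------------------------------------------------
# CNV call IO (the CnvCall type lives in otocnv.calling)

_CALL_COLUMNS = [
    "sample_id",
    "gene",
    "chrom",
    "start",
    "end",
    "exon_first",
    "exon_last",
    "cnv_class",
    "zygosity",
    "mean_ratio",
    "copy_number",
    "n_targets",
    "flags",
]


def write_cnv_calls(calls, path: str | os.PathLike, format: str = "tsv") -> None:
    """Write CNV calls as TSV (round-trippable) or a minimal symbolic-ALT VCF."""
    if format == "tsv":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(_CALL_COLUMNS)
            for c in calls:
                w.writerow(
                    [
                        c.sample_id,
                        c.gene,
                        c.chrom,
                        c.start,
                        c.end,
                        c.exon_first,
                        c.exon_last,
                        c.cnv_class,
                        c.zygosity if c.zygosity is not None else ".",
                        f"{c.mean_ratio:.6g}",
                        f"{c.copy_number:.6g}",
                        c.n_targets,
                        ",".join(sorted(c.flags)) or ".",
                    ]
                )
    elif format == "vcf":
        _write_calls_vcf(calls, path)
    else:
        raise PanelError(f"unknown call format {format!r}")


def _write_calls_vcf(calls, path: str | os.PathLike) -> None:
    buf = io.StringIO()
    buf.write("##fileformat=VCFv4.2\n")
    buf.write('##ALT=<ID=DEL,Description="Deletion">\n')
    buf.write('##ALT=<ID=DUP,Description="Duplication">\n')
    buf.write('##INFO=<ID=END,Number=1,Type=Integer,Description="End of variant">\n')
    buf.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
    buf.write('##INFO=<ID=CN,Number=1,Type=Float,Description="Estimated copy number">\n')
    buf.write('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">\n')
    buf.write(
        '##INFO=<ID=CNVCLASS,Number=1,Type=String,'
        'Description="deletion/duplication/conversion">\n'
    )
    buf.write('##INFO=<ID=EXONS,Number=2,Type=Integer,Description="First,last exon">\n')
    buf.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
    for i, c in enumerate(calls, start=1):
        svtype = "DUP" if c.cnv_class == "duplication" else "DEL"
        info = (
            f"END={c.end};SVTYPE={svtype};CN={c.copy_number:.3g};GENE={c.gene};"
            f"CNVCLASS={c.cnv_class};EXONS={c.exon_first},{c.exon_last}"
        )
        buf.write(
            f"{c.chrom}\t{c.start + 1}\t{c.sample_id}_cnv{i}\tN\t<{svtype}>\t.\t"
            f"PASS\t{info}\n"
        )
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_cnv_calls(path: str | os.PathLike):
    """Read back a TSV written by :func:`write_cnv_calls`."""
    from .calling import CnvCall

    calls = []
    with open(path) as fh:
        r = csv.DictReader(fh, delimiter="\t")
        for row in r:
            calls.append(
                CnvCall(
                    sample_id=row["sample_id"],
                    gene=row["gene"],
                    chrom=row["chrom"],
                    start=int(row["start"]),
                    end=int(row["end"]),
                    exon_first=int(row["exon_first"]),
                    exon_last=int(row["exon_last"]),
                    cnv_class=row["cnv_class"],
                    zygosity=None if row["zygosity"] == "." else row["zygosity"],
                    mean_ratio=float(row["mean_ratio"]),
                    n_targets=int(row["n_targets"]),
                    flags=frozenset(
                        row["flags"].split(",") if row["flags"] != "." else []
                    ),
                )
            )
    return calls
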