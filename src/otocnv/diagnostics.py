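"""Per-patient causative assignment and cohort summarization.

A CNV alone rarely makes a diagnosis in a recessive gene: the machinery here
combines residual CNV calls, conversion events and trans-phased small
variants into one causative category per (sample, gene), then tallies
allele-level records into the cohort summary table (per-gene totals by class
with column percentages) and the headline cohort statistics.

Counting unit: one record = one CNV allele.  A homozygous deletion is two
alleles; a biallelic deletion/conversion pair is one allele of each class.
Percentages are rounded half-away-from-zero at the printed precision
(integers in the summary table, one decimal for cohort scalars).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .calling import CnvCall
from .conversions import ConversionEvent
from .panel import PanelDefinition, PanelError, SmallVariant

CATEGORIES = (
    "hom_cnv",
    "biallelic_cnv",
    "hemizygous_cnv_plus_snv",
    "contiguous_multi_gene",
    "carrier_only",
    "none",
)


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (what printed clinical tables use)."""
    factor = 10.0**ndigits
    r = math.floor(abs(x) * factor + 0.5) / factor
    return math.copysign(r, x)


def pct(num: float, den: float, ndigits: int = 0) -> float:
    if den == 0:
        return 0.0
    return round_half_away(100.0 * num / den, ndigits)


@dataclass(frozen=True)
class CausativeAssignment:
    sample_id: str
    gene: str
    category: str
    inheritance_consistent: bool = True
    flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise PanelError(f"unknown category {self.category!r}")


def _deletion_frame_flag(call: CnvCall, panel: PanelDefinition) -> str:
    """out_of_frame / in_frame annotation from summed deleted exon lengths."""
    length = sum(
        t.length
        for t in panel.targets_for_gene(call.gene)
        if call.exon_first <= t.exon_index <= call.exon_last
    )
    return "in_frame" if length % 3 == 0 else "out_of_frame"


def classify_causative(
    cnv_calls: list[CnvCall],
    conversions: list[ConversionEvent],
    small_variants: list[SmallVariant],
    panel: PanelDefinition,
) -> list[CausativeAssignment]:
    """Assign one causative category per (sample, gene) with lesions.

    Precedence: hom_cnv > biallelic_cnv > hemizygous_cnv_plus_snv >
    contiguous_multi_gene > carrier_only.  Recessive genes need two hit
    alleles; a lone heterozygous CNV in a dominant gene is never
    auto-causative — it is returned as carrier_only with an ``ad_review``
    flag plus a reading-frame annotation, mirroring expert adjudication.
    """
    genes = set(panel.gene_symbols())
    for v in small_variants:
        if v.gene not in genes:
            raise PanelError(f"small variant in gene {v.gene!r} absent from panel")

    lesions: dict[tuple[str, str], dict] = {}

    def slot(sample, gene):
        return lesions.setdefault(
            (sample, gene), {"calls": [], "conv": [], "snv": []}
        )

    for c in cnv_calls:
        slot(c.sample_id, c.gene)["calls"].append(c)
    for ev in conversions:
        slot(ev.sample_id, ev.gene)["conv"].append(ev)
    for v in small_variants:
        if v.pathogenic:
            slot(v.sample_id, v.gene).setdefault("snv", []).append(v)

    out: list[CausativeAssignment] = []
    for (sample, gene), L in sorted(lesions.items()):
        calls, convs, snvs = L["calls"], L["conv"], L["snv"]
        if not calls and not convs:
            continue
        info = panel.gene_info(gene)
        recessive = info.inheritance in ("AR", "XL", "both")
        flags: set[str] = set()

        hom_del = any(
            c.cnv_class == "deletion" and c.zygosity == "hom" for c in calls
        )
        cnv_alleles = sum(
            2 if c.zygosity == "hom" else 1 for c in calls if c.zygosity
        ) + sum(ev.alleles for ev in convs)
        classes = {c.cnv_class for c in calls} | {"conversion" for _ in convs}
        het_snv = any(v.zygosity == "het" for v in snvs)
        contiguous = any("multi_gene_contiguous" in c.flags for c in calls)

        hom_conv = any(ev.alleles == 2 for ev in convs) or any(
            c.cnv_class == "conversion" and c.zygosity == "hom" for c in calls
        )
        if hom_del:
            category = "hom_cnv"
        elif cnv_alleles >= 2 and (len(classes) >= 2 or hom_conv):
            category = "biallelic_cnv"
        elif cnv_alleles >= 1 and het_snv and recessive:
            category = "hemizygous_cnv_plus_snv"
        elif contiguous:
            category = "contiguous_multi_gene"
        else:
            category = "carrier_only"
            if info.inheritance in ("AD", "both") and calls:
                flags.add("ad_review")
                for c in calls:
                    if c.cnv_class == "deletion":
                        flags.add(_deletion_frame_flag(c, panel))
        consistent = category != "carrier_only" if recessive else category in (
            "hom_cnv",
            "contiguous_multi_gene",
        )
        out.append(
            CausativeAssignment(
                sample_id=sample,
                gene=gene,
                category=category,
                inheritance_consistent=consistent,
                flags=frozenset(flags),
            )
        )
    return out


# ---------------------------------------------------------------------------
# cohort summary


@dataclass
class CohortSummary:
    """Per-gene class tallies plus headline cohort statistics."""

    table: pd.DataFrame
    scalars: dict[str, float]


_CLS = ("deletion", "conversion", "duplication")


def summarize_cohort(
    records: pd.DataFrame, n_tested: int, n_diagnosed: int
) -> CohortSummary:
    """Tally allele-level CNV records into the cohort summary.

    ``records`` needs columns patient_id, gene, cnv_class, causative,
    category (see :func:`otocnv.fixture.cohort_records` for the layout; the
    same frame can be produced from pipeline output with
    :func:`records_from_calls`).
    """
    if n_diagnosed > n_tested:
        raise PanelError("n_diagnosed cannot exceed n_tested")
    totals = {
        "total": len(records),
        "carrier": int((~records["causative"]).sum()),
        "causative": int(records["causative"].sum()),
        **{c: int((records["cnv_class"] == c).sum()) for c in _CLS},
    }
    rows = []
    order = (
        records.groupby("gene")
        .size()
        .sort_values(ascending=False, kind="stable")
        .index
    )
    for gene in order:
        g = records[records["gene"] == gene]
        row = {"gene": gene}
        for key, sel in [
            ("total", g),
            ("carrier", g[~g["causative"]]),
            ("causative", g[g["causative"]]),
            ("deletion", g[g["cnv_class"] == "deletion"]),
            ("conversion", g[g["cnv_class"] == "conversion"]),
            ("duplication", g[g["cnv_class"] == "duplication"]),
        ]:
            row[key] = len(sel)
            row[f"{key}_pct"] = pct(len(sel), totals[key])
        rows.append(row)
    cols = ["gene"] + [
        f"{k}{suffix}"
        for k in ("total", "carrier", "causative", "deletion", "conversion", "duplication")
        for suffix in ("", "_pct")
    ]
    table = pd.DataFrame(rows, columns=cols).set_index("gene")

    caus = records[records["causative"]]
    caus_patients = caus.groupby("patient_id")["category"].first()
    n_caus_patients = caus_patients.size
    cat_counts = caus_patients.value_counts()
    strc = records[records["gene"] == "STRC"]

    scalars = {
        "n_tested": n_tested,
        "n_diagnosed": n_diagnosed,
        "n_cnvs": totals["total"],
        "n_patients_with_cnv": int(records["patient_id"].nunique()),
        "n_cnv_diagnosed": int(n_caus_patients),
        "overall_cnv_carrier_pct": pct(totals["total"], n_tested, 1),
        "patients_with_cnv_pct": pct(records["patient_id"].nunique(), n_tested, 1),
        "cnv_diagnosed_pct": pct(n_caus_patients, n_diagnosed, 1),
        "deletions_pct": pct(totals["deletion"], totals["total"], 1),
        "conversions_pct": pct(totals["conversion"], totals["total"], 1),
        "duplications_pct": pct(totals["duplication"], totals["total"], 1),
        "strc_share_pct": pct(len(strc), totals["total"]),
        "otoa_share_pct": pct(
            len(records[records["gene"] == "OTOA"]), totals["total"]
        ),
        "strc_causative_rate_pct": pct(
            strc[strc["causative"]]["patient_id"].nunique(), n_tested, 1
        ),
        "hom_cnv_pct": pct(cat_counts.get("hom_cnv", 0), n_caus_patients),
        "hemizygous_pct": pct(
            cat_counts.get("hemizygous_cnv_plus_snv", 0), n_caus_patients
        ),
        "biallelic_pct": pct(cat_counts.get("biallelic_cnv", 0), n_caus_patients),
        # the contiguous category is tallied per CNV, not per patient: one
        # patient carrying a two-gene deletion contributes both CNVs here
        "contiguous_pct": pct(
            int((caus["category"] == "contiguous_multi_gene").sum()),
            n_caus_patients,
        ),
        "strc_deletion_allele_freq_pct": pct(
            (strc["cnv_class"] == "deletion").sum(), 2 * n_tested, 1
        ),
        "strc_conversion_allele_freq_pct": pct(
            (strc["cnv_class"] == "conversion").sum(), 2 * n_tested, 1
        ),
        "strc_duplication_allele_freq_pct": pct(
            (strc["cnv_class"] == "duplication").sum(), 2 * n_tested, 1
        ),
    }
    return CohortSummary(table=table, scalars=scalars)


def records_from_calls(
    calls: list[CnvCall],
    conversions: list[ConversionEvent],
    assignments: list[CausativeAssignment],
) -> pd.DataFrame:
    """Expand pipeline output into allele-level records for summarization."""
    causative_keys = {
        (a.sample_id, a.gene)
        for a in assignments
        if a.category not in ("carrier_only", "none")
    }
    categories = {(a.sample_id, a.gene): a.category for a in assignments}
    rows = []
    for c in calls:
        n = 2 if c.zygosity == "hom" else 1
        key = (c.sample_id, c.gene)
        for _ in range(n):
            rows.append(
                (
                    c.sample_id,
                    c.gene,
                    c.cnv_class,
                    key in causative_keys,
                    categories.get(key, "carrier_only"),
                    c.zygosity or "het",
                    False,
                )
            )
    for ev in conversions:
        key = (ev.sample_id, ev.gene)
        for _ in range(ev.alleles):
            rows.append(
                (
                    ev.sample_id,
                    ev.gene,
                    "conversion",
                    key in causative_keys,
                    categories.get(key, "carrier_only"),
                    "het",
                    False,
                )
            )
    from .fixture import _COLUMNS

    return pd.DataFrame(rows, columns=_COLUMNS)


def carrier_frequency(
    records, n_samples: int, locus: str, cnv_class: str
) -> float:
    """Abnormal-allele frequency: carrier alleles / (2 * n_samples).

    ``records`` is either the allele-level DataFrame (one row = one allele)
    or a list of calls/ConversionEvents (hom events count 2 alleles, het 1;
    conversions count their ``alleles``).
    """
    if n_samples <= 0:
        raise PanelError("n_samples must be > 0")
    if isinstance(records, pd.DataFrame):
        n = int(
            ((records["gene"] == locus) & (records["cnv_class"] == cnv_class)).sum()
        )
    else:
        n = 0
        for r in records:
            if isinstance(r, ConversionEvent):
                if r.gene == locus and cnv_class == "conversion":
                    n += r.alleles
            elif r.gene == locus and r.cnv_class == cnv_class:
                n += 2 if r.zygosity == "hom" else 1
    return n / (2.0 * n_samples)
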