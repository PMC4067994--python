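"""Gene-pseudogene conversion detection and STRC-locus diagnosis.

In read-depth space a non-allelic gene conversion looks like a deletion of
gene exons with a reciprocal duplication of the homologous pseudogene exons:
copies are moved, not lost, so gene cn + pseudogene cn stays 4 over each
converted exon pair.  This module pairs gene-side deletion calls with
pseudogene-side duplication calls through the panel's explicit
``pseudo_partner`` links and re-emits matched pairs as conversion events.

The STRC locus gets dedicated logic because its clinical reading depends on
which neighbours are lost: biallelic loss of STRC alone causes recessive
hearing loss, while homozygous deletion of the whole region including
CATSPER2 causes deafness-infertility syndrome (DIS).
"""

from __future__ import annotations

from dataclasses import dataclass

from .calling import CnvCall
from .panel import PanelDefinition, PanelError

DEFAULT_OVERLAP_FRAC = 0.8
DEFAULT_RECIPROCITY_TOL = 0.6  # copies


@dataclass(frozen=True)
class ConversionEvent:
    """A mono- or biallelic gene->pseudogene conversion with its evidence."""

    sample_id: str
    gene: str
    pseudogene: str
    exon_span: tuple[int, int]
    alleles: int  # 1 monoallelic, 2 biallelic
    evidence: tuple[CnvCall, CnvCall]  # (gene deletion, pseudogene duplication)

    def __post_init__(self) -> None:
        if self.alleles not in (1, 2):
            raise PanelError("conversion alleles must be 1 or 2")


def _member_targets(call: CnvCall, panel: PanelDefinition):
    return [
        t
        for t in panel.targets_for_gene(call.gene)
        if call.exon_first <= t.exon_index <= call.exon_last
    ]


def detect_conversions(
    calls: list[CnvCall],
    panel: PanelDefinition,
    overlap_frac: float = DEFAULT_OVERLAP_FRAC,
    reciprocity_tol: float = DEFAULT_RECIPROCITY_TOL,
) -> tuple[list[ConversionEvent], list[CnvCall]]:
    """Pair deletion calls with partner-target duplication calls.

    For each gene-side deletion whose member targets carry pseudo_partner
    links, a duplication call on the partner gene matches when it covers at
    least ``overlap_frac`` of the partner images and the copies lost on the
    gene side equal the copies gained on the pseudogene side within
    ``reciprocity_tol``.  Matched pairs become ConversionEvents with
    alleles = 2 for a homozygous gene-side deletion, 1 for heterozygous;
    both member calls leave the residual pool.  No match is a valid outcome:
    plain deletions are never promoted.
    """
    events: list[ConversionEvent] = []
    consumed: set[int] = set()
    dups = [
        (n, c) for n, c in enumerate(calls) if c.cnv_class == "duplication"
    ]
    for n, c in enumerate(calls):
        if c.cnv_class != "deletion" or c.zygosity not in ("het", "hom"):
            continue
        members = _member_targets(c, panel)
        images = [t.pseudo_partner for t in members if t.pseudo_partner]
        if not images or len(images) < len(members):
            continue  # conversion requires every exon in range to be paired
        pseudogene = panel.target(images[0]).gene
        image_exons = {panel.target(i).exon_index for i in images}
        for m, d in dups:
            if m in consumed or d.sample_id != c.sample_id or d.gene != pseudogene:
                continue
            covered = sum(
                1 for e in image_exons if d.exon_first <= e <= d.exon_last
            )
            if covered / len(image_exons) < overlap_frac:
                continue
            gene_loss = 2.0 - 2.0 * c.mean_ratio
            pseudo_gain = 2.0 * d.mean_ratio - 2.0
            if abs(gene_loss - pseudo_gain) > reciprocity_tol:
                continue
            events.append(
                ConversionEvent(
                    sample_id=c.sample_id,
                    gene=c.gene,
                    pseudogene=pseudogene,
                    exon_span=(c.exon_first, c.exon_last),
                    alleles=2 if c.zygosity == "hom" else 1,
                    evidence=(c, d),
                )
            )
            consumed.update((n, m))
            break
    residual = [c for n, c in enumerate(calls) if n not in consumed]
    return events, residual


# ---------------------------------------------------------------------------
# STRC locus / DIS logic


@dataclass(frozen=True)
class StrcLocusDiagnosis:
    """Per-allele STRC status plus deafness-infertility-syndrome call.

    ``dis`` is true iff both alleles delete STRC *and* CATSPER2 (homozygous
    deletion of the whole region).  A deletion touching only CATSPER2 and the
    pseudogene leaves STRC intact and is not DIS.
    """

    sample_id: str
    strc_status: tuple[str, str]  # each: intact|deleted|converted|duplicated
    catsper2_involved: bool
    dis: bool


_STATUS_FOR_CLASS = {"deletion": "deleted", "duplication": "duplicated"}


def diagnose_strc_locus(
    calls: list[CnvCall],
    conversions: list[ConversionEvent],
    sample: str,
    panel: PanelDefinition,
    gene: str = "STRC",
    catsper2: str = "CATSPER2",
) -> StrcLocusDiagnosis:
    """Combine residual calls and conversions into a per-allele STRC verdict."""
    if gene not in panel.gene_symbols():
        raise PanelError(f"{gene} absent from panel")
    alleles = ["intact", "intact"]
    slot = 0

    def fill(status: str, n: int) -> None:
        nonlocal slot
        for _ in range(n):
            if slot < 2:
                alleles[slot] = status
                slot += 1

    for ev in conversions:
        if ev.sample_id == sample and ev.gene == gene:
            fill("converted", ev.alleles)
    for c in calls:
        if c.sample_id != sample or c.gene != gene:
            continue
        status = _STATUS_FOR_CLASS.get(c.cnv_class)
        if status is None:
            continue
        fill(status, 2 if c.zygosity == "hom" else 1)

    catsper2_calls = [
        c
        for c in calls
        if c.sample_id == sample and c.gene == catsper2 and c.cnv_class == "deletion"
    ]
    catsper2_involved = bool(catsper2_calls)
    catsper2_hom = any(c.zygosity == "hom" for c in catsper2_calls)
    dis = alleles[0] == "deleted" and alleles[1] == "deleted" and catsper2_hom
    return StrcLocusDiagnosis(
        sample_id=sample,
        strc_status=(alleles[0], alleles[1]),
        catsper2_involved=catsper2_involved,
        dis=dis,
    )
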