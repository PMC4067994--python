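"""The published-cohort fixture: 686 tested patients, 143 CNV alleles.

Patient-level data for the clinical cohort could not be deposited, so the
package carries a synthetic patient-level reconstruction ("synthetic" in the
sense that within-patient assignments are ours) that reproduces *every*
printed cohort marginal simultaneously: the per-gene total/carrier/causative
and deletion/conversion/duplication counts, 143 CNV alleles across 104
distinct patients, 267 diagnosed patients, 50 patients with causative CNVs
split 21 homozygous / 16 hemizygous-plus-variant / 12 biallelic / 1 carrying
a two-gene contiguous deletion, and 37 patients with causative STRC lesions.

Each record is one CNV *allele* (a homozygous deletion contributes two
records), which is the counting unit under which the printed STRC carrier
allele frequencies (65, 35 and 5 per 1,372 alleles) coincide with the
per-class column of the summary table.  Two biallelic STRC patients carry a
complex second allele with both a conversion and a duplication lesion
(recorded as one allele-row per lesion class); this is the unique structure
under which all printed marginals close.
"""

from __future__ import annotations

import pandas as pd

N_TESTED = 686
N_DIAGNOSED = 267

_COLUMNS = ["patient_id", "gene", "cnv_class", "causative", "category", "zygosity", "dis"]


def _rows():
    rows = []
    pid = [0]

    def patient() -> str:
        pid[0] += 1
        return f"P{pid[0]:03d}"

    def add(p, gene, cls, causative, category, zyg, dis=False):
        rows.append((p, gene, cls, causative, category, zyg, dis))

    # --- causative patients (50) -------------------------------------
    # 20 homozygous STRC deletions; the first 4 are whole-locus deletions
    # that also remove CATSPER2 (DIS, not isolated hearing loss)
    for k in range(20):
        p = patient()
        for _ in range(2):
            add(p, "STRC", "deletion", True, "hom_cnv", "hom", dis=k < 4)
    # 1 homozygous whole-gene OTOA deletion
    p = patient()
    for _ in range(2):
        add(p, "OTOA", "deletion", True, "hom_cnv", "hom")
    # 8 biallelic STRC: deletion opposite conversion
    for _ in range(8):
        p = patient()
        add(p, "STRC", "deletion", True, "biallelic_cnv", "het")
        add(p, "STRC", "conversion", True, "biallelic_cnv", "het")
    # 1 biallelic STRC conversion (conversion on each allele)
    p = patient()
    add(p, "STRC", "conversion", True, "biallelic_cnv", "het")
    add(p, "STRC", "conversion", True, "biallelic_cnv", "het")
    # 2 biallelic STRC with a complex second allele (conversion + duplication)
    for _ in range(2):
        p = patient()
        add(p, "STRC", "deletion", True, "biallelic_cnv", "het")
        add(p, "STRC", "conversion", True, "biallelic_cnv", "het")
        add(p, "STRC", "duplication", True, "biallelic_cnv", "het")
    # 1 biallelic OTOA: deletion opposite conversion
    p = patient()
    add(p, "OTOA", "deletion", True, "biallelic_cnv", "het")
    add(p, "OTOA", "conversion", True, "biallelic_cnv", "het")
    # hemizygous CNV + second pathogenic small variant (16 patients)
    for gene, n in [
        ("STRC", 6), ("OTOA", 3), ("GJB6", 3),
        ("USH2A", 1), ("SLC26A4", 1), ("TMC1", 1), ("TMPRSS3", 1),
    ]:
        for _ in range(n):
            add(patient(), gene, "deletion", True, "hemizygous_cnv_plus_snv", "het")
    # 1 patient with the large contiguous chr22 deletion hitting two genes
    p = patient()
    add(p, "MYH9", "deletion", True, "contiguous_multi_gene", "het")
    add(p, "TRIOBP", "deletion", True, "contiguous_multi_gene", "het")

    # --- carrier-only patients (54, carrying 57 CNV alleles) ----------
    # 3 carry two carrier CNVs (an STRC conversion plus an OTOA deletion)
    for _ in range(3):
        p = patient()
        add(p, "STRC", "conversion", False, "carrier_only", "het")
        add(p, "OTOA", "deletion", False, "carrier_only", "het")
    singles = (
        [("STRC", "deletion")] * 9
        + [("STRC", "conversion")] * 20
        + [("STRC", "duplication")] * 3
        + [("OTOA", "deletion")] * 3
        + [("OTOA", "conversion")] * 2
        + [("OTOA", "duplication")] * 3
        + [("GJB6", "deletion")] * 1
        + [("USH2A", "deletion"), ("USH2A", "duplication")]
        + [("MYH9", "duplication")]
        + [("ALMS1", "deletion"), ("MYO6", "deletion")]
        + [("PDZD7", "deletion"), ("SERPINB6", "deletion")]
        + [("EYA4", "duplication"), ("WFS1", "duplication")]
        + [("PNPT1", "duplication")]
    )
    for gene, cls in singles:
        add(patient(), gene, cls, False, "carrier_only", "het")
    return rows


# printed per-gene marginals: total, carrier, causative, del, conv, dup
PER_GENE_EXPECTED = {
    "STRC": (105, 35, 70, 65, 35, 5),
    "OTOA": (18, 11, 7, 12, 3, 3),
    "GJB6": (4, 1, 3, 4, 0, 0),
    "USH2A": (3, 2, 1, 2, 0, 1),
    "MYH9": (2, 1, 1, 1, 0, 1),
    "ALMS1": (1, 1, 0, 1, 0, 0),
    "MYO6": (1, 1, 0, 1, 0, 0),
    "PDZD7": (1, 1, 0, 1, 0, 0),
    "SERPINB6": (1, 1, 0, 1, 0, 0),
    "SLC26A4": (1, 0, 1, 1, 0, 0),
    "TMC1": (1, 0, 1, 1, 0, 0),
    "TMPRSS3": (1, 0, 1, 1, 0, 0),
    "TRIOBP": (1, 0, 1, 1, 0, 0),
    "EYA4": (1, 1, 0, 0, 0, 1),
    "WFS1": (1, 1, 0, 0, 0, 1),
    "PNPT1": (1, 1, 0, 0, 0, 1),
}


def _validate(df: pd.DataFrame) -> None:
    assert len(df) == 143, "total CNV alleles"
    assert df["patient_id"].nunique() == 104, "patients with >=1 CNV"
    caus = df[df["causative"]]
    assert len(caus) == 86, "causative alleles"
    assert caus["patient_id"].nunique() == 50, "patients with causative CNVs"
    cats = caus.groupby("patient_id")["category"].first().value_counts()
    assert cats["hom_cnv"] == 21
    assert cats["hemizygous_cnv_plus_snv"] == 16
    assert cats["biallelic_cnv"] == 12
    assert cats["contiguous_multi_gene"] == 1
    assert caus[caus["gene"] == "STRC"]["patient_id"].nunique() == 37
    cls = df["cnv_class"].value_counts()
    assert cls["deletion"] == 92 and cls["conversion"] == 38 and cls["duplication"] == 13
    for gene, (tot, car, cau, d, cv, du) in PER_GENE_EXPECTED.items():
        g = df[df["gene"] == gene]
        got = (
            len(g),
            int((~g["causative"]).sum()),
            int(g["causative"].sum()),
            int((g["cnv_class"] == "deletion").sum()),
            int((g["cnv_class"] == "conversion").sum()),
            int((g["cnv_class"] == "duplication").sum()),
        )
        assert got == (tot, car, cau, d, cv, du), f"{gene}: {got}"
    assert df[df["dis"]]["patient_id"].nunique() == 4


def cohort_records() -> pd.DataFrame:
    """Return the allele-level cohort record table (validated on build)."""
    df = pd.DataFrame(_rows(), columns=_COLUMNS)
    _validate(df)
    return df


def write_fixture_tsv(path) -> None:
    cohort_records().to_csv(path, sep="\t", index=False)
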