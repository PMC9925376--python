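"""CYP2C19 star-allele calling and metabolic-phenotype classification.

Two phased SNPs define the common functional CYP2C19 star alleles:
rs4244285 G>A marks the non-functional *2 allele and rs12248560 C>T the
increased-function *17 allele; haplotypes carrying neither variant are wild
type (*1).  A haplotype carrying both variant alleles does not occur as a
star allele and, in phased input, indicates data corruption — it is rejected,
never silently dropped.

The diplotype (unordered pair of star alleles) maps onto six metabolic
phenotypes, ordered from fastest to slowest metabolism:

    UM (*17/*17)  EM+ (*1/*17)  EM (*1/*1)  IM+ (*2/*17)  IM (*1/*2)  PM (*2/*2)

with an inverted activity score 1 (UM) ... 6 (PM), so that a higher score
means slower metabolism and higher expected drug exposure.

Two further phased SNPs (rs2860840 C>T, rs11188059 G>A) identify the rapid
CYP2C:TG haplotype on a *1 background, supporting an expanded 10-level
CYP2C diplotype scheme ranked from fastest (1, CYP2C:TG/CYP2C19*17) to
slowest (10, CYP2C19null/CYP2C19null) expected metabolism, with the
CG-or-TA homozygote as reference.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from . import resources

__all__ = [
    "ClassificationError",
    "star_allele",
    "metabolic_phenotype",
    "cyp2c_haplotype_label",
    "cyp2c_diplotype",
    "allele_frequency",
    "classify_cohort",
    "phenotype_table",
    "PHENOTYPE_LEVELS",
    "ACTIVITY_SCORE",
    "COLLAPSE3",
]


class ClassificationError(ValueError):
    """A haplotype or diplotype cannot be mapped to the published scheme."""


#: the six levels in slow-to-fast listing order used for tabulation
PHENOTYPE_LEVELS = ("PM", "IM", "IM+", "EM", "EM+", "UM")

#: inverted activity score: UM=1 ... PM=6 (higher = slower metabolism)
ACTIVITY_SCORE = {"UM": 1, "EM+": 2, "EM": 3, "IM+": 4, "IM": 5, "PM": 6}

#: three-group collapse used when events are sparse
COLLAPSE3 = {
    "PM": "PM/IM/IM+", "IM": "PM/IM/IM+", "IM+": "PM/IM/IM+",
    "EM": "EM",
    "EM+": "EM+/UM", "UM": "EM+/UM",
}

_PHENOTYPE_BY_PAIR = {
    ("*2", "*2"): "PM",
    ("*1", "*2"): "IM",
    ("*17", "*2"): "IM+",
    ("*1", "*1"): "EM",
    ("*1", "*17"): "EM+",
    ("*17", "*17"): "UM",
}


def star_allele(rs4244285: str, rs12248560: str) -> str:
    """Call the star allele of one haplotype from its two core SNP alleles."""
    if rs4244285 not in ("G", "A") or rs12248560 not in ("C", "T"):
        raise ClassificationError(
            f"unrecognised alleles rs4244285={rs4244285!r}, rs12248560={rs12248560!r}"
        )
    if rs4244285 == "A" and rs12248560 == "T":
        raise ClassificationError(
            "recombinant haplotype carrying both rs4244285-A (*2) and "
            "rs12248560-T (*17); phased input is corrupt"
        )
    if rs4244285 == "A":
        return "*2"
    if rs12248560 == "T":
        return "*17"
    return "*1"


def metabolic_phenotype(allele1: str, allele2: str) -> tuple[str, int]:
    """Map an unordered star-allele pair to (phenotype level, activity score)."""
    key = tuple(sorted((allele1, allele2)))
    try:
        level = _PHENOTYPE_BY_PAIR[key]
    except KeyError:
        raise ClassificationError(f"unknown star-allele pair {allele1}/{allele2}") from None
    return level, ACTIVITY_SCORE[level]


def cyp2c_haplotype_label(rs4244285: str, rs12248560: str,
                          rs2860840: str, rs11188059: str) -> str:
    """Label one 4-SNP haplotype for the expanded CYP2C scheme.

    *2 haplotypes are CYP2C19null; *17 haplotypes keep their label; a *1
    background carrying rs2860840-T with rs11188059-G is the rapid CYP2C:TG
    haplotype; every other *1 background is CYP2C:CG-or-TA.
    """
    star = star_allele(rs4244285, rs12248560)
    if star == "*2":
        return "CYP2C19null"
    if star == "*17":
        return "CYP2C19*17"
    if rs2860840 == "T" and rs11188059 == "G":
        return "CYP2C:TG"
    return "CYP2C:CG-or-TA"


def cyp2c_diplotype(h1_labels: tuple[str, str, str, str],
                    h2_labels: tuple[str, str, str, str],
                    rank_table: dict | None = None) -> tuple[int, str]:
    """Rank a 4-SNP diplotype on the 10-level CYP2C scheme.

    Parameters
    ----------
    h1_labels, h2_labels
        Per-haplotype alleles (rs4244285, rs12248560, rs2860840, rs11188059).
    rank_table
        Optional override of the shipped rank table, keyed on the sorted pair
        of haplotype labels.

    Returns
    -------
    (rank, collapse3) where collapse3 is "lower-exposure", "reference" or
    "higher-exposure" relative to the CG-or-TA homozygote reference.
    """
    table = rank_table if rank_table is not None else resources.cyp2c_rank_table()
    lab1 = cyp2c_haplotype_label(*h1_labels)
    lab2 = cyp2c_haplotype_label(*h2_labels)
    key = tuple(sorted((lab1, lab2)))
    try:
        rank = table[key]
    except KeyError:
        raise ClassificationError(f"diplotype {lab1}/{lab2} absent from rank table") from None
    ref_rank = table[resources.reference_diplotype()]
    if rank < ref_rank:
        collapse = "lower-exposure"
    elif rank > ref_rank:
        collapse = "higher-exposure"
    else:
        collapse = "reference"
    return rank, collapse


def allele_frequency(hom_ref: int, het: int, hom_alt: int) -> float:
    """Alternate-allele frequency from genotype counts (2·hom_alt + het)/(2·n)."""
    for c in (hom_ref, het, hom_alt):
        if c < 0:
            raise ValueError("genotype counts must be non-negative")
    total = hom_ref + het + hom_alt
    if total == 0:
        raise ValueError("cannot compute an allele frequency from zero genotypes")
    return (2 * hom_alt + het) / (2 * total)


def classify_cohort(genotypes: pd.DataFrame) -> pd.DataFrame:
    """Classify a phased-genotype table into phenotypes and activity scores.

    Expects columns person_id, h1_rs4244285, h1_rs12248560, h2_rs4244285,
    h2_rs12248560 and, optionally, h{1,2}_rs2860840 / h{1,2}_rs11188059 for
    the expanded CYP2C scheme.  Raises :class:`ClassificationError` naming
    the offending persons if any haplotype is recombinant.
    """
    g = genotypes
    stars = {}
    for h in ("h1", "h2"):
        a = g[f"{h}_rs4244285"].to_numpy()
        t = g[f"{h}_rs12248560"].to_numpy()
        bad = (a == "A") & (t == "T")
        if bad.any():
            who = g.loc[bad, "person_id"].tolist()
            raise ClassificationError(
                f"recombinant *2+*17 haplotype ({h}) for persons {who[:10]}"
            )
        stars[h] = np.where(a == "A", "*2", np.where(t == "T", "*17", "*1"))

    pair = [tuple(sorted(p)) for p in zip(stars["h1"], stars["h2"])]
    level = pd.Series([_PHENOTYPE_BY_PAIR[k] for k in pair], index=g.index)
    out = pd.DataFrame({
        "person_id": g["person_id"].to_numpy(),
        "star1": stars["h1"],
        "star2": stars["h2"],
        "phenotype": level.to_numpy(),
        "activity_score": level.map(ACTIVITY_SCORE).astype(int).to_numpy(),
    }, index=g.index)
    out["phenotype3"] = out["phenotype"].map(COLLAPSE3)

    four_snp = all(
        f"{h}_{snp}" in g.columns
        for h in ("h1", "h2") for snp in ("rs2860840", "rs11188059")
    )
    if four_snp:
        ranks, collapses = [], []
        for _, row in g.iterrows():
            rank, coll = cyp2c_diplotype(
                (row["h1_rs4244285"], row["h1_rs12248560"],
                 row["h1_rs2860840"], row["h1_rs11188059"]),
                (row["h2_rs4244285"], row["h2_rs12248560"],
                 row["h2_rs2860840"], row["h2_rs11188059"]),
            )
            ranks.append(rank)
            collapses.append(coll)
        out["cyp2c_rank"] = ranks
        out["cyp2c_collapse3"] = collapses
    return out


def phenotype_table(genotypes_or_phenotypes: pd.DataFrame) -> pd.DataFrame:
    """Count the six metabolic phenotypes in a cohort.

    Accepts either a phased-genotype table (classified on the fly) or an
    already-classified table with a ``phenotype`` column.  Returns one row
    per level in PM..UM listing order with columns n and percent (one
    decimal); counts sum to the cohort size.
    """
    df = genotypes_or_phenotypes
    if "phenotype" not in df.columns:
        df = classify_cohort(df)
    counts = df["phenotype"].value_counts()
    n = len(df)
    rows = []
    for level in PHENOTYPE_LEVELS:
        c = int(counts.get(level, 0))
        rows.append({
            "phenotype": level,
            "n": c,
            "percent": round(100.0 * c / n, 1) if n else 0.0,
        })
    return pd.DataFrame(rows)


def read_phased_vcf(path) -> pd.DataFrame:
    """Read the two core CYP2C19 SNPs from a phased VCF into the genotype schema.

    Looks for records whose ID is rs4244285 or rs12248560 and splits each
    sample's phased GT ("0|1") onto the two haplotype columns.
    """
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover - cyvcf2 is an optional reader
        raise ImportError("reading VCF input requires cyvcf2") from exc

    wanted = {"rs4244285": ("G", "A"), "rs12248560": ("C", "T")}
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    columns: dict[str, list[str]] = {}
    for var in vcf:
        if var.ID not in wanted:
            continue
        ref, alt = wanted[var.ID]
        for i, gt in enumerate(var.genotypes):
            a1, a2, phased = gt[0], gt[1], gt[2]
            if not phased:
                raise ClassificationError(f"unphased genotype for {samples[i]} at {var.ID}")
            columns.setdefault(f"h1_{var.ID}", [None] * len(samples))[i] = alt if a1 else ref
            columns.setdefault(f"h2_{var.ID}", [None] * len(samples))[i] = alt if a2 else ref
    out = pd.DataFrame({"person_id": samples, **columns})
    missing = [f"{h}_{s}" for h in ("h1", "h2") for s in wanted if f"{h}_{s}" not in out]
    if missing:
        raise ClassificationError(f"VCF lacked phased records for {sorted(set(missing))}")
    return out
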