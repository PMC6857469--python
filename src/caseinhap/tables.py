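"""Built-in reference tables for the bovine casein gene cluster.

The casein cluster on BTA6 holds four genes in chromosomal order
CSN1S1 - CSN2 - CSN1S2 - CSN3 (encoding alpha-S1, beta, alpha-S2 and
kappa casein).  This module bundles the published constants the rest of
the package needs:

* the seven missense SNPs whose alleles define the common protein
  variants, with UMD3.1 positions, rs identifiers and amino-acid changes;
* per-breed frequencies of the named protein variants and of the
  comprehensive four-gene protein haplotypes in 14 B. taurus breeds;
* default cohort sizes and default variant-category counts used by the
  synthetic fixture generator.

Frequencies are stored exactly as published; absent entries are zero.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass

import pandas as pd

#: Genes in chromosomal order on BTA6.
GENE_ORDER = ("CSN1S1", "CSN2", "CSN1S2", "CSN3")

#: Coding strand of each gene (CSN2 is transcribed on the reverse strand).
GENE_STRAND = {"CSN1S1": "+", "CSN2": "-", "CSN1S2": "+", "CSN3": "+"}

#: Signal peptide length (precursor position - mature position).
SIGNAL_PEPTIDE = {"CSN1S1": 15, "CSN2": 15, "CSN1S2": 15, "CSN3": 21}


@dataclass(frozen=True)
class CoreSnp:
    """One of the seven protein-variant defining missense SNPs."""

    gene: str
    pos: int          # 1-based UMD3.1 position on BTA6
    ref: str          # reference allele (genomic / forward strand)
    alt: str          # alternative allele
    ref_aa: str       # amino acid encoded with the reference allele
    alt_aa: str       # amino acid encoded with the alternative allele
    precursor_pos: int  # amino-acid position in the precursor protein
    snp_id: str


CORE_SNPS = (
    CoreSnp("CSN1S1", 87157262, "A", "G", "Glu", "Gly", 207, "rs43703010"),
    CoreSnp("CSN2", 87181542, "T", "G", "Met", "Leu", 108, "rs109299401"),
    CoreSnp("CSN2", 87181619, "T", "G", "His", "Pro", 82, "rs43703011"),
    CoreSnp("CSN1S2", 87266177, "C", "T", "Ser", "Phe", 23, "rs441966828"),
    CoreSnp("CSN3", 87390576, "T", "C", "Ile", "Thr", 157, "rs43703015"),
    CoreSnp("CSN3", 87390612, "C", "A", "Ala", "Asp", 169, "rs43703016"),
    CoreSnp("CSN3", 87390632, "A", "G", "Ser", "Gly", 176, "rs43703017"),
)


def core_snps_of(gene: str) -> tuple[CoreSnp, ...]:
    return tuple(s for s in CORE_SNPS if s.gene == gene)


def core_positions(gene: str | None = None) -> tuple[int, ...]:
    """Positions of the defining SNPs, genomically sorted."""
    snps = CORE_SNPS if gene is None else core_snps_of(gene)
    return tuple(sorted(s.pos for s in snps))


# ---------------------------------------------------------------------------
# Protein-variant rule signatures: variant name -> {pos: allele}.
# A haplotype matches a variant iff it carries the listed allele at every
# listed position.  Signatures within a gene are mutually exclusive.
# ---------------------------------------------------------------------------

VARIANT_SIGNATURES: dict[str, dict[str, dict[int, str]]] = {
    "CSN1S1": {
        "B": {87157262: "A"},
    },
    "CSN2": {
        "A1": {87181619: "T"},
        "A2": {87181619: "G", 87181542: "T"},
        "I": {87181619: "G", 87181542: "G"},
    },
    "CSN1S2": {
        "A": {87266177: "C"},
    },
    "CSN3": {
        "A": {87390576: "C", 87390612: "C", 87390632: "A"},
        "B": {87390576: "T", 87390612: "A"},
        "E": {87390576: "C", 87390612: "C", 87390632: "G"},
    },
}

# ---------------------------------------------------------------------------
# Allele expansion used by the synthetic generator: per-gene variant label ->
# alleles at that gene's core SNPs.  Variants whose defining SNPs are outside
# the seven simulated sites are expanded to the closest representable allele
# pattern (CSN1S1*C via the Gly allele; CSN2*B and *F on an A1-like
# background; CSN1S2*C/*D via the Phe allele, which no rule names).
# "Residual" is a stand-in for unprinted low-frequency haplotypes and maps
# to an allele pattern matching no named variant.
# ---------------------------------------------------------------------------

SIM_VARIANT_ALLELES: dict[str, dict[str, dict[int, str]]] = {
    "CSN1S1": {
        "B": {87157262: "A"},
        "C": {87157262: "G"},
    },
    "CSN2": {
        "A1": {87181619: "T", 87181542: "T"},
        "A2": {87181619: "G", 87181542: "T"},
        "I": {87181619: "G", 87181542: "G"},
        "B": {87181619: "T", 87181542: "T"},
        "F": {87181619: "T", 87181542: "T"},
    },
    "CSN1S2": {
        "A": {87266177: "C"},
        "C": {87266177: "T"},
        "D": {87266177: "T"},
    },
    "CSN3": {
        "A": {87390576: "C", 87390612: "C", 87390632: "A"},
        "B": {87390576: "T", 87390612: "A", 87390632: "A"},
        "E": {87390576: "C", 87390612: "C", 87390632: "G"},
        # matches no named kappa-casein signature
        "residual": {87390576: "T", 87390612: "C", 87390632: "A"},
    },
}

# ---------------------------------------------------------------------------
# Cohort composition: 14 B. taurus breeds with published sample sizes.
# ---------------------------------------------------------------------------

BREED_SIZES: "OrderedDict[str, int]" = OrderedDict(
    [
        ("Limousin", 82),
        ("Angus", 276),
        ("Hereford", 75),
        ("Charolais", 127),
        ("Simmental", 217),
        ("Fleckvieh", 53),
        ("Normande", 44),
        ("Montbeliarde", 54),
        ("BrownSwiss", 148),
        ("Gelbvieh", 52),
        ("Jersey", 66),
        ("DanishRed", 56),
        ("Holstein", 541),
        ("DSN", 30),
    ]
)

BREEDS = tuple(BREED_SIZES)

# ---------------------------------------------------------------------------
# Published per-breed frequencies of the named protein variants
# (columns: DSN, Holstein, pooled over all 14 breeds).
# ---------------------------------------------------------------------------

_MISSENSE_ROWS = [
    ("CSN1S1", "B", 1.0, 0.995, 0.944),
    ("CSN2", "A1", 0.827, 0.340, 0.295),
    ("CSN2", "A2", 0.156, 0.562, 0.592),
    ("CSN2", "I", 0.017, 0.059, 0.036),
    ("CSN1S2", "A", 1.0, 1.0, 0.994),
    ("CSN3", "A", 0.833, 0.752, 0.628),
    ("CSN3", "B", 0.133, 0.203, 0.341),
    ("CSN3", "E", 0.034, 0.045, 0.030),
]


def builtin_variant_frequencies() -> pd.DataFrame:
    """Published protein-variant frequencies (index: gene, variant)."""
    df = pd.DataFrame(
        _MISSENSE_ROWS, columns=["gene", "variant", "DSN", "Holstein", "All"]
    )
    return df.set_index(["gene", "variant"])


# ---------------------------------------------------------------------------
# Published comprehensive-haplotype frequencies (13 named haplotypes plus a
# residual mass) per breed.  Labels follow the CSN1S1-CSN2-CSN1S2-CSN3 gene
# order.  Empty cells in the source are zeros.
# ---------------------------------------------------------------------------

_HAP_COLUMNS = [
    "Total", "Limousin", "Angus", "Hereford", "Charolais", "Simmental",
    "Fleckvieh", "Normande", "Montbeliarde", "BrownSwiss", "Gelbvieh",
    "Jersey", "DanishRed", "Holstein", "DSN",
]

_HAP_ROWS: list[tuple] = [
    ("B-A2-A-A", 0.424, 0.419, 0.644, 0.359, 0.331, 0.446, 0.415, 0.100,
     0.072, 0.115, 0.490, 0.045, 0.136, 0.531, 0.116),
    ("B-A1-A-A", 0.147, 0.071, 0.032, 0.313, 0.041, 0.145, 0.270, 0.046,
     0.055, 0.078, 0.091, 0.0, 0.439, 0.196, 0.717),
    ("B-A2-A-B", 0.141, 0.196, 0.075, 0.026, 0.286, 0.178, 0.147, 0.081,
     0.304, 0.500, 0.133, 0.047, 0.132, 0.056, 0.024),
    ("B-A1-A-B", 0.057, 0.105, 0.006, 0.028, 0.163, 0.081, 0.0, 0.062,
     0.014, 0.020, 0.114, 0.124, 0.031, 0.063, 0.093),
    ("B-B-A-B", 0.051, 0.038, 0.002, 0.238, 0.013, 0.009, 0.0, 0.221,
     0.0, 0.079, 0.0, 0.226, 0.017, 0.027, 0.0),
    ("C-A2-A-B", 0.048, 0.094, 0.026, 0.007, 0.033, 0.032, 0.0, 0.284,
     0.0, 0.069, 0.0, 0.506, 0.002, 0.001, 0.0),
    ("B-I-A-B", 0.035, 0.029, 0.007, 0.007, 0.0, 0.020, 0.0, 0.162,
     0.151, 0.0, 0.0, 0.052, 0.0, 0.061, 0.017),
    ("B-A2-A-E", 0.020, 0.0, 0.105, 0.0, 0.0, 0.003, 0.0, 0.0,
     0.0, 0.0, 0.0, 0.0, 0.028, 0.002, 0.013),
    ("C-A2-A-A", 0.019, 0.018, 0.020, 0.023, 0.028, 0.049, 0.117, 0.020,
     0.034, 0.051, 0.0, 0.0, 0.0, 0.002, 0.0),
    ("B-B-A-A", 0.017, 0.0, 0.0, 0.0, 0.065, 0.030, 0.022, 0.0,
     0.359, 0.083, 0.0, 0.0, 0.0, 0.001, 0.0),
    ("B-A2-D-B", 0.004, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0,
     0.0, 0.0, 0.132, 0.0, 0.054, 0.0, 0.0),
    ("B-F-A-A", 0.005, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0,
     0.0, 0.0, 0.0, 0.0, 0.136, 0.003, 0.0),
    ("B-A2-C-A", 0.011, 0.0, 0.075, 0.0, 0.0, 0.0, 0.0, 0.0,
     0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0),
    ("Residual", 0.021, 0.030, 0.007, 0.0, 0.040, 0.006, 0.030, 0.023,
     0.011, 0.005, 0.040, 0.0, 0.022, 0.057, 0.021),
]


def builtin_haplotype_frequencies(include_residual: bool = True) -> pd.DataFrame:
    """Published comprehensive-haplotype frequency matrix.

    Rows are haplotype labels (plus ``Residual`` unless excluded), columns
    ``Total`` plus the 14 breeds.  Values are frequencies as published;
    columns sum to ~1 including the residual row.
    """
    df = pd.DataFrame(
        [r[1:] for r in _HAP_ROWS],
        index=[r[0] for r in _HAP_ROWS],
        columns=_HAP_COLUMNS,
    )
    if not include_residual:
        df = df.drop(index="Residual")
    return df


def breed_haplotype_distribution(
    breed: str, keep_residual: bool = True
) -> "OrderedDict[str, float]":
    """Normalized haplotype distribution for one breed.

    With ``keep_residual`` the published residual mass is retained under the
    label ``Residual`` (simulated as an unnamed haplotype); otherwise it is
    dropped and the named rows renormalized.
    """
    col = builtin_haplotype_frequencies(include_residual=keep_residual)[breed]
    col = col[col > 0]
    total = col.sum()
    return OrderedDict((label, f / total) for label, f in col.items())


# ---------------------------------------------------------------------------
# Default variant-category composition of the synthetic 892-SNP fixture.
# Chosen so counts sum to 892 and each category share reproduces the
# published percentage after rounding to one decimal (intron 87.3 %,
# upstream 5.8 %, missense 2.2 %, 3'-UTR 2.2 %, synonymous 1.2 %,
# splice region 0.7 %, 5'-UTR 0.4 %).  The seven core missense SNPs count
# toward the missense category.
# ---------------------------------------------------------------------------

DEFAULT_CATEGORY_COUNTS: dict[str, int] = {
    "intron": 779,
    "upstream": 52,
    "missense": 20,
    "utr3": 20,
    "synonymous": 11,
    "splice_region": 6,
    "utr5": 4,
}
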