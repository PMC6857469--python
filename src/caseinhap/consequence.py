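"""SNP consequence classification against single-transcript gene models.

Each SNP inside a gene's upstream window or transcript span receives
exactly one category out of {upstream, utr5, intron, splice_region,
synonymous, missense, utr3}, with precedence

    splice_region > (missense | synonymous) > utr5/utr3 > intron > upstream.

Coding calls are codon-aware on the coding strand (reverse-complemented
for minus-strand genes, standard genetic code).  The splice region covers
1-3 bases into an exon and 1-8 bases into an intron from every
exon-intron junction; the two canonical donor/acceptor bases are folded
into the same category.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .models import CaseinhapError, GeneModel, ReferenceSequence, VariantRecord

CATEGORIES = ("upstream", "utr5", "intron", "splice_region",
              "synonymous", "missense", "utr3")


class OutOfScopeError(CaseinhapError):
    """Variant lies outside every gene's upstream window and transcript."""


class ReferenceMismatchError(CaseinhapError):
    """VCF ref allele disagrees with the reference sequence."""


def _check_reference(variant: VariantRecord, reference: ReferenceSequence) -> None:
    base = reference.base(variant.pos)
    if base != variant.ref:
        raise ReferenceMismatchError(
            f"{variant.chrom}:{variant.pos}: reference base {base} != "
            f"VCF ref allele {variant.ref}")


def splice_region_test(pos: int, gene_model: GeneModel) -> bool:
    """True iff ``pos`` lies within 1-3 exonic or 1-8 intronic bases of an
    exon-intron junction."""
    for a, b in gene_model.introns:
        if a <= pos <= b:  # intronic side
            if pos - a < 8 or b - pos < 8:
                return True
        else:  # exonic side
            if a - 3 <= pos <= a - 1 or b + 1 <= pos <= b + 3:
                return True
    return False


def amino_acid_change(variant: VariantRecord, gene_model: GeneModel,
                      reference: ReferenceSequence
                      ) -> tuple[str, str, int, int]:
    """(ref_aa, alt_aa, precursor_pos, mature_pos) for a CDS SNP.

    Amino acids are 1-letter codes; the mature position subtracts the
    gene's signal-peptide length and may be <= 0 for signal-peptide
    residues.
    """
    if not gene_model.in_cds(variant.pos):
        raise CaseinhapError(
            f"{variant.pos} is not in the CDS of {gene_model.gene_id}")
    _check_reference(variant, reference)
    codon_no, codon_pos = gene_model.codon_number(variant.pos)
    codon = "".join(
        reference.base(gene_model.genomic_position((codon_no - 1) * 3 + k))
        for k in (1, 2, 3)
    )
    ref_allele, alt_allele = variant.ref, variant.alt
    if gene_model.strand == "-":
        codon = str(Seq(codon).complement())
        ref_allele = str(Seq(ref_allele).complement())
        alt_allele = str(Seq(alt_allele).complement())
    assert codon[codon_pos - 1] == ref_allele
    mutated = codon[:codon_pos - 1] + alt_allele + codon[codon_pos:]
    ref_aa = str(Seq(codon).translate())
    alt_aa = str(Seq(mutated).translate())
    return ref_aa, alt_aa, codon_no, codon_no - gene_model.signal_peptide


@dataclass(frozen=True)
class Consequence:
    gene: str
    category: str
    ref_aa: str | None = None
    alt_aa: str | None = None
    precursor_pos: int | None = None
    mature_pos: int | None = None


def classify(variant: VariantRecord, gene_model: GeneModel,
             reference: ReferenceSequence) -> Consequence:
    """Classify one SNP against one gene model (precedence order above)."""
    pos = variant.pos
    if not gene_model.in_scope(pos):
        raise OutOfScopeError(
            f"{variant.chrom}:{pos} outside scope of {gene_model.gene_id}")
    _check_reference(variant, reference)
    gid = gene_model.gene_id
    if gene_model.in_transcript(pos):
        if splice_region_test(pos, gene_model):
            return Consequence(gid, "splice_region")
        if gene_model.in_cds(pos):
            ref_aa, alt_aa, ppos, mpos = amino_acid_change(
                variant, gene_model, reference)
            cat = "synonymous" if ref_aa == alt_aa else "missense"
            return Consequence(gid, cat, ref_aa, alt_aa, ppos, mpos)
        if gene_model.in_utr5(pos):
            return Consequence(gid, "utr5")
        if gene_model.in_utr3(pos):
            return Consequence(gid, "utr3")
        if gene_model.in_intron(pos):
            return Consequence(gid, "intron")
        raise CaseinhapError(
            f"{pos} in transcript of {gid} but in no annotated region")
    return Consequence(gid, "upstream")


def pick_gene_model(pos: int, gene_models: list[GeneModel]) -> GeneModel | None:
    """Owning model for a position: a gene body wins over another gene's
    upstream window."""
    body = [gm for gm in gene_models if gm.in_transcript(pos)]
    if body:
        return body[0]
    up = [gm for gm in gene_models if gm.in_upstream(pos)]
    return up[0] if up else None


def classify_all(variants: list[VariantRecord], gene_models: list[GeneModel],
                 reference: ReferenceSequence) -> pd.DataFrame:
    """Classify every SNP; returns a tidy frame (one row per SNP)."""
    rows = []
    for v in variants:
        gm = pick_gene_model(v.pos, gene_models)
        if gm is None:
            raise OutOfScopeError(f"{v.chrom}:{v.pos} outside every gene scope")
        c = classify(v, gm, reference)
        rows.append((v.chrom, v.pos, v.id, v.ref, v.alt, c.gene, c.category,
                     c.ref_aa, c.alt_aa, c.precursor_pos, c.mature_pos))
    return pd.DataFrame(rows, columns=[
        "chrom", "pos", "id", "ref", "alt", "gene", "category",
        "ref_aa", "alt_aa", "precursor_pos", "mature_pos"])


def category_counts(classified: pd.DataFrame) -> pd.Series:
    counts = classified.category.value_counts()
    return counts.reindex(CATEGORIES, fill_value=0)


# ---------------------------------------------------------------------------
# SNP density (per 10 kb)
# ---------------------------------------------------------------------------

DENSITY_REGIONS = ("upstream", "intron", "exon", "missense", "synonymous")


def snp_density(counts: dict[str, dict[str, int]],
                lengths: dict[str, dict[str, int]]) -> pd.DataFrame:
    """counts/lengths per gene x region -> SNPs per 10 kb (1 decimal)."""
    genes = list(counts)
    data = {}
    for region in DENSITY_REGIONS:
        col = []
        for g in genes:
            n = counts[g].get(region, 0)
            length = lengths[g][region]
            if length <= 0:
                raise CaseinhapError(f"non-positive length for {g}/{region}")
            col.append(round(n / length * 10_000, 1))
        data[region] = col
    return pd.DataFrame(data, index=genes)


def region_lengths(gene_models: list[GeneModel]) -> dict[str, dict[str, int]]:
    """Denominators for the density table.  The exon/missense/synonymous
    columns all use the coding (CDS) length."""
    out = {}
    for gm in gene_models:
        intron_len = sum(b - a + 1 for a, b in gm.introns)
        out[gm.gene_id] = {
            "upstream": gm.upstream_length,
            "intron": intron_len,
            "exon": gm.cds_length,
            "missense": gm.cds_length,
            "synonymous": gm.cds_length,
        }
    return out


def density_table(classified: pd.DataFrame,
                  gene_models: list[GeneModel]) -> pd.DataFrame:
    """Per-gene density table plus a pooled ``Total`` row."""
    lengths = region_lengths(gene_models)
    counts: dict[str, dict[str, int]] = {}
    for gm in gene_models:
        sub = classified[classified.gene == gm.gene_id]
        cc = sub.category.value_counts()
        counts[gm.gene_id] = {
            "upstream": int(cc.get("upstream", 0)),
            "intron": int(cc.get("intron", 0)),
            "missense": int(cc.get("missense", 0)),
            "synonymous": int(cc.get("synonymous", 0)),
            "exon": int(cc.get("missense", 0) + cc.get("synonymous", 0)),
        }
    totals_n = {r: sum(c[r] for c in counts.values()) for r in DENSITY_REGIONS}
    totals_l = {r: sum(lengths[g][r] for g in counts) for r in DENSITY_REGIONS}
    df = snp_density(counts, lengths)
    df.loc["Total"] = [round(totals_n[r] / totals_l[r] * 10_000, 1)
                       for r in DENSITY_REGIONS]
    return df
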