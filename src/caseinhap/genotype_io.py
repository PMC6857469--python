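"""Reading and writing of the standard formats.

VCF parsing is delegated to :mod:`cyvcf2`; GFF3 parsing to
:mod:`gffutils`; FASTA to Biopython.  The in-memory genotype
representation is :class:`~caseinhap.models.GenotypeMatrix`.
"""

from __future__ import annotations

import logging
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from cyvcf2 import VCF

from .models import (
    CaseinhapError,
    GeneModel,
    GenotypeMatrix,
    ReferenceSequence,
    VariantRecord,
)

logger = logging.getLogger(__name__)

_BASES = frozenset("ACGT")


class VcfError(CaseinhapError):
    pass


class BreedMapError(CaseinhapError):
    pass


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path,
             region: tuple[str, int, int] | None = None) -> GenotypeMatrix:
    """Load biallelic SNPs from a VCF into a genotype matrix.

    GT is decoded to alternative-allele dosage (phase separators are
    accepted but phase is discarded); AD to (ref_reads, alt_reads) pairs,
    with -1 where AD is absent.  Multiallelic records, indels and records
    outside ``region`` are skipped; the skip count is logged.
    """
    path = Path(path)
    try:
        vcf = VCF(str(path), gts012=True)
    except Exception as exc:  # htslib raises bare OSError on bad input
        raise VcfError(f"cannot parse VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    if not samples:
        raise VcfError(f"VCF {path} contains no samples")

    variants: list[VariantRecord] = []
    dosage_cols: list[np.ndarray] = []
    depth_cols: list[np.ndarray] = []
    skipped = 0
    n_records = 0
    try:
        for rec in vcf:
            n_records += 1
            if region is not None:
                chrom, start, end = region
                if rec.CHROM != chrom or not (start <= rec.POS <= end):
                    skipped += 1
                    continue
            if (len(rec.ALT) != 1 or rec.REF not in _BASES
                    or rec.ALT[0] not in _BASES):
                skipped += 1
                continue
            variants.append(VariantRecord(rec.CHROM, rec.POS, rec.REF,
                                          rec.ALT[0], rec.ID or "."))
            gt = rec.gt_types.astype(np.int16)  # 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
            gt[gt == 3] = -1
            dosage_cols.append(gt)
            ad = rec.format("AD")
            if ad is None:
                depth_cols.append(np.full((len(samples), 2), -1, dtype=np.int32))
            else:
                ad = ad[:, :2].astype(np.int32)
                ad[ad < 0] = -1
                depth_cols.append(ad)
    except VcfError:
        raise
    except Exception as exc:
        raise VcfError(
            f"malformed VCF {path} near record {n_records}: {exc}") from exc
    if skipped:
        logger.info("read_vcf: skipped %d non-biallelic/out-of-region records",
                    skipped)
    n, m = len(samples), len(variants)
    dosage = (np.stack(dosage_cols, axis=1) if m
              else np.zeros((n, 0), dtype=np.int16))
    depths = (np.stack(depth_cols, axis=1) if m
              else np.zeros((n, 0, 2), dtype=np.int32))
    matrix = GenotypeMatrix(samples, variants, dosage, depths)
    matrix.n_skipped_records = skipped  # type: ignore[attr-defined]
    return matrix


def write_vcf(matrix: GenotypeMatrix, path: str | Path,
              contig_length: int | None = None) -> None:
    """Write a VCF 4.2 with GT and AD fields (deterministic formatting)."""
    path = Path(path)
    contigs: dict[str, None] = {}
    for v in matrix.variants:
        contigs.setdefault(v.chrom, None)
    lines = [
        "##fileformat=VCFv4.2",
        "##source=caseinhap",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description='
        '"Allelic depths for the ref and alt alleles">',
    ]
    for c in contigs:
        if contig_length is not None:
            lines.append(f"##contig=<ID={c},length={contig_length}>")
        else:
            lines.append(f"##contig=<ID={c}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(matrix.samples))
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
    for j, v in enumerate(matrix.variants):
        fields = [v.chrom, str(v.pos), v.id, v.ref, v.alt, ".", "PASS", ".",
                  "GT:AD"]
        dose = matrix.dosage[:, j]
        dep = matrix.depths[:, j]
        for i in range(matrix.n_samples):
            if dep[i, 0] < 0 or dep[i, 1] < 0:
                ad = "."
            else:
                ad = f"{dep[i, 0]},{dep[i, 1]}"
            fields.append(f"{gt_str[int(dose[i])]}:{ad}")
        lines.append("\t".join(fields))
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Breed map
# ---------------------------------------------------------------------------

def read_breed_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV (sample_id, breed) -> mapping; strict on duplicates."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise BreedMapError(f"breed map {path} is empty") from exc
    if df.shape[1] < 2:
        raise BreedMapError(f"breed map {path} needs two columns")
    df = df.iloc[:, :2]
    df.columns = ["sample_id", "breed"]
    if df.empty:
        raise BreedMapError(f"breed map {path} has no rows")
    dupes = df.sample_id[df.sample_id.duplicated()].tolist()
    if dupes:
        raise BreedMapError(f"duplicate sample ids in breed map: {dupes[:5]}")
    if df.isna().any().any():
        raise BreedMapError(f"breed map {path} has missing fields")
    return dict(zip(df.sample_id, df.breed))


def attach_breeds(matrix: GenotypeMatrix, breed_of: dict[str, str]) -> GenotypeMatrix:
    unmapped = [s for s in matrix.samples if s not in breed_of]
    if unmapped:
        raise BreedMapError(f"samples missing from breed map: {unmapped[:5]}")
    matrix.breed_of = {s: breed_of[s] for s in matrix.samples}
    return matrix


# ---------------------------------------------------------------------------
# FASTA (with coordinate-offset header)
# ---------------------------------------------------------------------------

def write_fasta(reference: ReferenceSequence, path: str | Path) -> None:
    rec = SeqRecord(Seq(reference.seq), id=reference.name,
                    description=f"offset={reference.offset}")
    SeqIO.write([rec], str(path), "fasta")


def read_fasta(path: str | Path) -> ReferenceSequence:
    rec = next(SeqIO.parse(str(path), "fasta"))
    offset = 0
    for token in rec.description.split():
        if token.startswith("offset="):
            offset = int(token.split("=", 1)[1])
    return ReferenceSequence(rec.id, offset, str(rec.seq).upper())


# ---------------------------------------------------------------------------
# GFF3 gene models
# ---------------------------------------------------------------------------

_GFF_COLS = "seqid source type start end score strand phase attributes".split()


def write_gff3(gene_models: list[GeneModel], path: str | Path) -> None:
    """Emit gene/mRNA/exon/CDS/five_prime_UTR/three_prime_UTR features."""
    rows = ["##gff-version 3"]

    def feat(gm, ftype, start, end, phase=".", suffix=""):
        attrs = (f"ID={gm.gene_id}{suffix};Parent={gm.gene_id}.t1"
                 if suffix else f"ID={gm.gene_id}")
        rows.append("\t".join([gm.chrom, "caseinhap", ftype, str(start),
                               str(end), ".", gm.strand, str(phase), attrs]))

    for gm in gene_models:
        rows.append("\t".join([gm.chrom, "caseinhap", "gene", str(gm.tx_start),
                               str(gm.tx_end), ".", gm.strand, ".",
                               f"ID={gm.gene_id};signal_peptide={gm.signal_peptide}"]))
        rows.append("\t".join([gm.chrom, "caseinhap", "mRNA", str(gm.tx_start),
                               str(gm.tx_end), ".", gm.strand, ".",
                               f"ID={gm.gene_id}.t1;Parent={gm.gene_id}"]))
        for k, (a, b) in enumerate(gm.exons, 1):
            feat(gm, "exon", a, b, suffix=f".exon{k}")
        # phase: number of bases to skip before the first complete codon
        cds = gm.cds if gm.strand == "+" else list(reversed(gm.cds))
        done = 0
        phases = {}
        for a, b in cds:
            phases[(a, b)] = (3 - done % 3) % 3
            done += b - a + 1
        for k, (a, b) in enumerate(gm.cds, 1):
            feat(gm, "CDS", a, b, phase=phases[(a, b)], suffix=f".cds{k}")
        for k, (a, b) in enumerate(gm.utr5, 1):
            feat(gm, "five_prime_UTR", a, b, suffix=f".utr5.{k}")
        for k, (a, b) in enumerate(gm.utr3, 1):
            feat(gm, "three_prime_UTR", a, b, suffix=f".utr3.{k}")
    Path(path).write_text("\n".join(rows) + "\n")


def read_gff3(path: str | Path, upstream_length: int = 1000) -> list[GeneModel]:
    """Reconstruct gene models from a GFF3 file (one transcript per gene)."""
    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            merge_strategy="create_unique", keep_order=True)
    models = []
    for gene in db.features_of_type("gene"):
        def ivs(ftype):
            out = [
                (f.start, f.end)
                for f in db.region(region=(gene.seqid, gene.start, gene.end),
                                   featuretype=ftype)
                if f.id.startswith(gene.id + ".") or
                (f.attributes.get("Parent", [""])[0].startswith(gene.id))
            ]
            return sorted(out)
        sp = int(gene.attributes.get("signal_peptide", [15])[0])
        models.append(GeneModel(
            gene_id=gene.id,
            chrom=gene.seqid,
            strand=gene.strand,
            exons=ivs("exon"),
            cds=ivs("CDS"),
            utr5=ivs("five_prime_UTR"),
            utr3=ivs("three_prime_UTR"),
            upstream_length=upstream_length,
            signal_peptide=sp,
        ))
    models.sort(key=lambda gm: gm.tx_start)
    return models


# ---------------------------------------------------------------------------
# Frequency tables / Newick
# ---------------------------------------------------------------------------

def write_frequency_table(table: pd.DataFrame, path: str | Path,
                          float_format: str = "%.6f") -> None:
    table.to_csv(path, sep="\t", float_format=float_format)


def read_frequency_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_newick(newick: str, path: str | Path) -> None:
    Path(path).write_text(newick.rstrip("\n") + "\n")


def read_newick(path: str | Path) -> str:
    return Path(path).read_text().strip()
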