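"""Synthetic casein-cluster fixtures with known generating truth.

Builds a miniature but internally consistent BTA6 casein region: four
strand-annotated gene models anchored so that the seven protein-variant
defining SNPs fall at their published genomic positions and codon
contexts, a reference window whose codons translate to the published
amino acids, and multi-breed diploid cohorts drawn from configurable
haplotype distributions.  Everything is written as plain-text VCF / GFF3 /
FASTA / TSV so downstream modules can be exercised end to end without any
restricted data.

Only a ~237 kb window of the chromosome is materialized; the FASTA header
carries an explicit coordinate offset so published positions remain valid.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqUtils import seq1

from . import genotype_io, tables
from .models import (
    CaseinhapError,
    GeneModel,
    GenotypeMatrix,
    ReferenceSequence,
    VariantRecord,
)

CONTIG = "6"
REFERENCE_OFFSET = 87_154_000
REFERENCE_END = 87_391_000

CATEGORIES = ("upstream", "utr5", "intron", "splice_region",
              "synonymous", "missense", "utr3")

_STOP_CODONS = {"TAA", "TAG", "TGA"}
_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]
_SENSE_CODONS = [c for c in _CODONS if c not in _STOP_CODONS]


class SimulationError(CaseinhapError):
    pass


# ---------------------------------------------------------------------------
# Gene architecture.  Coordinates were chosen so each defining SNP sits at
# its published position with the correct codon number and within-codon
# offset, given the signal-peptide-inclusive amino-acid numbering.
# ---------------------------------------------------------------------------

_GENE_LAYOUT: dict[str, dict] = {
    "CSN1S1": dict(
        strand="+",
        exons=[(87_155_093, 87_155_442), (87_156_943, 87_157_487)],
        cds=[(87_155_143, 87_155_442), (87_156_943, 87_157_287)],
        utr5=[(87_155_093, 87_155_142)],
        utr3=[(87_157_288, 87_157_487)],
    ),
    "CSN2": dict(
        strand="-",
        exons=[(87_180_989, 87_181_863), (87_183_514, 87_183_563),
               (87_183_764, 87_183_813)],
        cds=[(87_181_189, 87_181_863)],
        utr5=[(87_183_514, 87_183_563), (87_183_764, 87_183_813)],
        utr3=[(87_180_989, 87_181_188)],
    ),
    "CSN1S2": dict(
        strand="+",
        exons=[(87_265_860, 87_265_909), (87_266_110, 87_266_978)],
        cds=[(87_266_110, 87_266_778)],
        utr5=[(87_265_860, 87_265_909)],
        utr3=[(87_266_779, 87_266_978)],
    ),
    "CSN3": dict(
        strand="+",
        exons=[(87_389_857, 87_389_906), (87_390_107, 87_390_879)],
        cds=[(87_390_107, 87_390_679)],
        utr5=[(87_389_857, 87_389_906)],
        utr3=[(87_390_680, 87_390_879)],
    ),
}


def build_gene_models(upstream_length: int = 1000) -> list[GeneModel]:
    """Four non-overlapping strand-annotated casein gene models on contig 6."""
    models = []
    for gene in tables.GENE_ORDER:
        layout = _GENE_LAYOUT[gene]
        gm = GeneModel(
            gene_id=gene,
            chrom=CONTIG,
            strand=layout["strand"],
            exons=list(layout["exons"]),
            cds=list(layout["cds"]),
            utr5=list(layout["utr5"]),
            utr3=list(layout["utr3"]),
            upstream_length=upstream_length,
            signal_peptide=tables.SIGNAL_PEPTIDE[gene],
        )
        models.append(gm)
    spans = sorted(gm.span for gm in models)
    for (_, b), (c, _) in zip(spans, spans[1:]):
        if c <= b:
            raise SimulationError("gene scopes overlap")
    return models


# ---------------------------------------------------------------------------
# Reference construction
# ---------------------------------------------------------------------------

def solve_codon(ref_aa: str, alt_aa: str, codon_pos: int,
                ref_base: str, alt_base: str) -> str:
    """Find a codon carrying ``ref_base`` at ``codon_pos`` (1-based) that
    translates to ``ref_aa`` and, with ``alt_base`` substituted, to
    ``alt_aa``.  Amino acids are 3-letter codes.

    Raises :class:`SimulationError` if no codon satisfies the constraint.
    """
    want_ref, want_alt = seq1(ref_aa), seq1(alt_aa)
    i = codon_pos - 1
    for codon in _CODONS:
        if codon[i] != ref_base:
            continue
        mutated = codon[:i] + alt_base + codon[i + 1:]
        if (str(Seq(codon).translate()) == want_ref
                and str(Seq(mutated).translate()) == want_alt):
            return codon
    raise SimulationError(
        f"infeasible codon constraint: {ref_aa}->{alt_aa} with "
        f"{ref_base}->{alt_base} at codon position {codon_pos}"
    )


def _coding_base_to_genomic(base: str, strand: str) -> str:
    return base if strand == "+" else str(Seq(base).complement())


def build_reference(gene_models: list[GeneModel],
                    seed: int | np.random.Generator = 0) -> ReferenceSequence:
    """Reference window satisfying every defining-SNP codon constraint.

    Unconstrained bases are pseudorandom under ``seed``; CDS regions are
    filled with sense codons (ATG start, TAA stop), splice dinucleotides
    are canonical GT/AG on each gene's coding strand, and the codons
    containing the seven defining SNPs are solved so the reference allele
    translates to the published reference amino acid and the alternative
    allele to the alternative amino acid.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    length = REFERENCE_END - REFERENCE_OFFSET
    buf = list("".join(rng.choice(list("ACGT"), size=length)))

    def put(pos: int, base: str) -> None:
        buf[pos - REFERENCE_OFFSET - 1] = base

    for gm in gene_models:
        # CDS: start codon, sense codons, stop codon (coding orientation)
        n_codons = gm.cds_length // 3
        codons = ["ATG"]
        idx = rng.integers(0, len(_SENSE_CODONS), size=n_codons - 2)
        codons += [_SENSE_CODONS[i] for i in idx]
        codons.append("TAA")
        coding = "".join(codons)
        # constrained codons
        for snp in tables.core_snps_of(gm.gene_id):
            codon_no, codon_pos = gm.codon_number(snp.pos)
            ref_b = _coding_base_to_genomic(snp.ref, gm.strand)
            alt_b = _coding_base_to_genomic(snp.alt, gm.strand)
            codon = solve_codon(snp.ref_aa, snp.alt_aa, codon_pos, ref_b, alt_b)
            start = (codon_no - 1) * 3
            coding = coding[:start] + codon + coding[start + 3:]
        for off, base in enumerate(coding, start=1):
            put(gm.genomic_position(off), _coding_base_to_genomic(base, gm.strand))
        # canonical splice dinucleotides on the coding strand
        for a, b in gm.introns:
            if gm.strand == "+":
                put(a, "G"), put(a + 1, "T"), put(b - 1, "A"), put(b, "G")
            else:
                put(b, "C"), put(b - 1, "A"), put(a + 1, "T"), put(a, "C")

    return ReferenceSequence(CONTIG, REFERENCE_OFFSET, "".join(buf))


# ---------------------------------------------------------------------------
# Simulation configuration
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Configuration of one synthetic cohort.

    ``haplotype_freqs`` maps breed -> {haplotype label -> frequency}; the
    per-breed distributions are renormalized at validation.  The label
    ``Residual`` denotes an unnamed haplotype carrying an allele pattern
    matching no named kappa-casein variant.
    """

    breeds: list[tuple[str, int]] = field(
        default_factory=lambda: list(tables.BREED_SIZES.items()))
    haplotype_freqs: dict[str, dict[str, float]] | None = None
    mean_depth: float = 10.0
    missing_rate: float = 0.0
    category_counts: dict[str, int] = field(
        default_factory=lambda: dict(tables.DEFAULT_CATEGORY_COUNTS))
    seed: int = 0
    keep_residual: bool = True
    upstream_length: int = 1000

    def __post_init__(self):
        if not self.breeds:
            raise SimulationError("at least one breed required")
        for name, n in self.breeds:
            if n < 1:
                raise SimulationError(f"breed {name}: n_animals must be >= 1")
        if self.mean_depth <= 0:
            raise SimulationError("mean_depth must be > 0")
        if not 0 <= self.missing_rate < 1:
            raise SimulationError("missing_rate must be in [0, 1)")
        for cat, count in self.category_counts.items():
            if cat not in CATEGORIES:
                raise SimulationError(f"unknown category {cat!r}")
            if count < 0:
                raise SimulationError(f"negative count for category {cat!r}")
        n_core = len(tables.CORE_SNPS)
        if self.category_counts.get("missense", 0) < n_core:
            raise SimulationError(
                f"missense count must be >= {n_core} (the defining SNPs)")
        if self.haplotype_freqs is None:
            self.haplotype_freqs = {
                name: dict(tables.breed_haplotype_distribution(
                    name, keep_residual=self.keep_residual))
                for name, _ in self.breeds
            }
        normalized = {}
        for name, _ in self.breeds:
            if name not in self.haplotype_freqs:
                raise SimulationError(f"no haplotype frequencies for breed {name}")
            dist = self.haplotype_freqs[name]
            total = float(sum(dist.values()))
            if total <= 0:
                raise SimulationError(f"breed {name}: frequencies sum to {total}")
            normalized[name] = {h: f / total for h, f in dist.items()}
            assert abs(sum(normalized[name].values()) - 1.0) < 1e-9
        self.haplotype_freqs = normalized


def expand_haplotype(label: str) -> dict[int, str]:
    """Deterministic expansion of a 4-gene haplotype label to alleles at
    the seven defining SNP positions."""
    if label == "Residual":
        parts = dict(zip(tables.GENE_ORDER, ("B", "A1", "A", "residual")))
    else:
        fields = label.split("-")
        if len(fields) != len(tables.GENE_ORDER):
            raise SimulationError(f"unknown haplotype label {label!r}")
        parts = dict(zip(tables.GENE_ORDER, fields))
    alleles: dict[int, str] = {}
    for gene, variant in parts.items():
        try:
            alleles.update(tables.SIM_VARIANT_ALLELES[gene][variant])
        except KeyError:
            raise SimulationError(
                f"unknown variant {variant!r} for {gene} in label {label!r}"
            ) from None
    return alleles


# ---------------------------------------------------------------------------
# Fixture bundle
# ---------------------------------------------------------------------------

@dataclass
class FixtureBundle:
    reference: ReferenceSequence
    gene_models: list[GeneModel]
    vcf_path: Path
    breed_map_path: Path
    fasta_path: Path
    gff3_path: Path
    truth_path: Path
    truth: pd.DataFrame          # sample_id, breed, hap1, hap2
    placements: pd.DataFrame     # chrom, pos, id, ref, alt, gene, category
    generating_freqs: dict[str, dict[str, float]]
    config: SimConfig
    matrix: GenotypeMatrix | None = None  # generator's in-memory genotypes

    def gene_model(self, gene: str) -> GeneModel:
        for gm in self.gene_models:
            if gm.gene_id == gene:
                return gm
        raise KeyError(gene)

    def truth_haplotype_counts(self, breed: str | None = None) -> pd.Series:
        t = self.truth if breed is None else self.truth[self.truth.breed == breed]
        return pd.concat([t.hap1, t.hap2]).value_counts()


# ---------------------------------------------------------------------------
# Filler placement
# ---------------------------------------------------------------------------

def _splice_zone(gm: GeneModel) -> set[int]:
    """Positions 1-8 into an intron or 1-3 into an exon from any junction."""
    zone: set[int] = set()
    for a, b in gm.introns:
        zone.update(range(a, min(a + 8, b) + 1))
        zone.update(range(max(b - 7, a), b + 1))
        zone.update(range(a - 3, a))      # exon bases left of intron
        zone.update(range(b + 1, b + 4))  # exon bases right of intron
    return zone


def _category_pools(gene_models: list[GeneModel]) -> dict[str, list]:
    """Candidate positions per category, as (pos, gene) pairs, core SNPs
    excluded and pools pairwise disjoint."""
    core = set(tables.core_positions())
    pools: dict[str, list] = {c: [] for c in CATEGORIES}
    for gm in gene_models:
        zone = _splice_zone(gm)
        a, b = gm.upstream_window
        pools["upstream"] += [(p, gm.gene_id) for p in range(a, b + 1)]
        pools["splice_region"] += [(p, gm.gene_id) for p in sorted(zone)]
        for ivs, cat in ((gm.utr5, "utr5"), (gm.utr3, "utr3")):
            for s, e in ivs:
                pools[cat] += [(p, gm.gene_id) for p in range(s, e + 1)
                               if p not in zone]
        for s, e in gm.introns:
            pools["intron"] += [(p, gm.gene_id) for p in range(s, e + 1)
                                if p not in zone]
        # coding candidates exclude start/stop codons, defining-SNP codons
        # and splice-adjacent bases; missense vs synonymous is decided per
        # position when the alt allele is chosen.
        anchor_codons = {gm.codon_number(s.pos)[0]
                         for s in tables.core_snps_of(gm.gene_id)}
        for off in range(4, gm.cds_length - 3 + 1):
            codon_no = (off - 1) // 3 + 1
            if codon_no in anchor_codons:
                continue
            p = gm.genomic_position(off)
            if p in zone or p in core:
                continue
            pools["missense"].append((p, gm.gene_id))
    pools["synonymous"] = pools["missense"]
    return pools


def _coding_alts(reference: ReferenceSequence, gm: GeneModel,
                 pos: int) -> dict[str, list[str]]:
    """Possible alt alleles at a CDS position, keyed by consequence."""
    codon_no, codon_pos = gm.codon_number(pos)
    coding_codon = "".join(
        _coding_base_to_genomic(reference.base(gm.genomic_position((codon_no - 1) * 3 + k)),
                                gm.strand)
        for k in (1, 2, 3)
    )
    ref_aa = str(Seq(coding_codon).translate())
    out: dict[str, list[str]] = {"missense": [], "synonymous": []}
    ref_base = reference.base(pos)
    for alt in "ACGT":
        if alt == ref_base:
            continue
        coding_alt = _coding_base_to_genomic(alt, gm.strand)
        i = codon_pos - 1
        mutated = coding_codon[:i] + coding_alt + coding_codon[i + 1:]
        alt_aa = str(Seq(mutated).translate())
        if alt_aa == ref_aa:
            out["synonymous"].append(alt)
        elif alt_aa != "*" and ref_aa != "*":
            out["missense"].append(alt)
    return out


def _place_fillers(config: SimConfig, gene_models: list[GeneModel],
                   reference: ReferenceSequence,
                   rng: np.random.Generator) -> list[tuple[int, str, str, str, str]]:
    """Choose filler SNP sites; returns (pos, gene, category, ref, alt)."""
    pools = _category_pools(gene_models)
    counts = dict(config.category_counts)
    counts["missense"] = counts.get("missense", 0) - len(tables.CORE_SNPS)
    taken: set[int] = set(tables.core_positions())
    records = []
    bases = np.array(list("ACGT"))
    for cat in CATEGORIES:
        want = counts.get(cat, 0)
        if want == 0:
            continue
        pool = [pg for pg in pools[cat] if pg[0] not in taken]
        order = rng.permutation(len(pool))
        placed = 0
        for k in order:
            if placed == want:
                break
            pos, gene = pool[k]
            if pos in taken:
                continue
            ref = reference.base(pos)
            if cat in ("missense", "synonymous"):
                gm = next(g for g in gene_models if g.gene_id == gene)
                choices = _coding_alts(reference, gm, pos)[cat]
                if not choices:
                    continue
                alt = choices[rng.integers(0, len(choices))]
            else:
                alts = [b for b in bases if b != ref]
                alt = alts[rng.integers(0, 3)]
            taken.add(pos)
            records.append((pos, gene, cat, ref, alt))
            placed += 1
        if placed < want:
            raise SimulationError(
                f"category {cat!r}: requested {want} SNPs but only "
                f"{placed} sites available"
            )
    return records


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

def simulate_cohort(config: SimConfig, outdir: str | Path) -> FixtureBundle:
    """Simulate a multi-breed cohort and write VCF/GFF3/FASTA/TSV fixtures.

    Per animal, two haplotypes are drawn i.i.d. from its breed's haplotype
    distribution and expanded to alleles at the seven defining SNPs; filler
    SNPs get independent per-breed allele frequencies.  Allele depths are
    Poisson per allele copy and genotypes are masked at ``missing_rate``.
    Identical config and seed give byte-identical output files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    root = np.random.default_rng(config.seed)
    ref_rng, place_rng, hap_rng, filler_rng, noise_rng = root.spawn(5)

    gene_models = build_gene_models(config.upstream_length)
    reference = build_reference(gene_models, ref_rng)
    fillers = _place_fillers(config, gene_models, reference, place_rng)

    core_records = [
        (s.pos, s.gene, "missense", s.ref, s.alt, s.snp_id) for s in tables.CORE_SNPS
    ]
    all_records = sorted(
        [(p, g, c, r, a, ".") for (p, g, c, r, a) in fillers] + core_records
    )
    placements = pd.DataFrame(
        all_records, columns=["pos", "gene", "category", "ref", "alt", "id"]
    ).assign(chrom=CONTIG)[["chrom", "pos", "id", "ref", "alt", "gene", "category"]]

    variants = [
        VariantRecord(CONTIG, int(r.pos), r.ref, r.alt, r.id)
        for r in placements.itertuples()
    ]
    pos_to_col = {v.pos: j for j, v in enumerate(variants)}
    core_cols = {p: pos_to_col[p] for p in tables.core_positions()}
    filler_cols = [j for j, v in enumerate(variants) if v.pos not in core_cols]

    samples: list[str] = []
    breed_of: dict[str, str] = {}
    truth_rows = []
    n_total = sum(n for _, n in config.breeds)
    n_var = len(variants)
    dosage = np.zeros((n_total, n_var), dtype=np.int16)

    row = 0
    for breed, n in config.breeds:
        dist = config.haplotype_freqs[breed]
        labels = list(dist)
        probs = np.array([dist[h] for h in labels])
        expansions = {h: expand_haplotype(h) for h in labels}
        draws = hap_rng.choice(len(labels), size=(n, 2), p=probs)
        # per-breed allele frequencies for filler SNPs
        filler_af = filler_rng.beta(0.5, 0.5, size=len(filler_cols))
        filler_dose = filler_rng.binomial(2, filler_af, size=(n, len(filler_cols)))
        dosage[row:row + n, filler_cols] = filler_dose
        for i in range(n):
            sample = f"{breed}_{i + 1:04d}"
            samples.append(sample)
            breed_of[sample] = breed
            h1, h2 = labels[draws[i, 0]], labels[draws[i, 1]]
            truth_rows.append((sample, breed, h1, h2))
            for pos, col in core_cols.items():
                alt = variants[col].alt
                d = int(expansions[h1][pos] == alt) + int(expansions[h2][pos] == alt)
                dosage[row + i, col] = d
        row += n

    # depths: each allele copy contributes Poisson(mean_depth) reads
    depths = np.stack(
        [
            noise_rng.poisson(config.mean_depth * (2 - np.maximum(dosage, 0))),
            noise_rng.poisson(config.mean_depth * np.maximum(dosage, 0)),
        ],
        axis=-1,
    ).astype(np.int32)
    if config.missing_rate > 0:
        mask = noise_rng.random(dosage.shape) < config.missing_rate
        dosage[mask] = -1
        depths[mask] = -1

    truth = pd.DataFrame(truth_rows, columns=["sample_id", "breed", "hap1", "hap2"])

    fasta_path = outdir / "reference.fa"
    gff3_path = outdir / "genes.gff3"
    vcf_path = outdir / "cohort.vcf"
    breed_map_path = outdir / "breeds.tsv"
    truth_path = outdir / "truth.tsv"

    genotype_io.write_fasta(reference, fasta_path)
    genotype_io.write_gff3(gene_models, gff3_path)
    matrix = GenotypeMatrix(samples, variants, dosage, depths, dict(breed_of))
    genotype_io.write_vcf(matrix, vcf_path, contig_length=reference.end)
    breed_map = pd.DataFrame(
        {"sample_id": samples, "breed": [breed_of[s] for s in samples]}
    )
    breed_map.to_csv(breed_map_path, sep="\t", index=False)
    truth.to_csv(truth_path, sep="\t", index=False)
    placements.to_csv(outdir / "variants_truth.tsv", sep="\t", index=False)

    return FixtureBundle(
        reference=reference,
        gene_models=gene_models,
        vcf_path=vcf_path,
        breed_map_path=breed_map_path,
        fasta_path=fasta_path,
        gff3_path=gff3_path,
        truth_path=truth_path,
        truth=truth,
        placements=placements,
        generating_freqs={b: dict(d) for b, d in config.haplotype_freqs.items()},
        config=dataclasses.replace(config),
        matrix=matrix,
    )
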