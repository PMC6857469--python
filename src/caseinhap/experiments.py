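"""Parameter-recovery experiments: simulate cohorts from the built-in
frequency tables and measure what the EM / protein-variant pipeline
recovers.  Used by the acceptance checks and reproducible from the CLI.

Replicate loops draw haplotypes with the same label-to-allele expansion
as the fixture generator but keep genotypes in memory (no VCF round trip
per replicate; the round trip itself is covered by the pipeline tests).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import haplotype_em as hem
from . import protein_variants as pv
from . import synthetic_data as sd
from . import tables


def _haplotype_dosage_vectors(labels, positions):
    alt = {s.pos: s.alt for s in tables.CORE_SNPS}
    out = {}
    for lab in labels:
        alleles = sd.expand_haplotype(lab)
        out[lab] = np.array([int(alleles[p] == alt[p]) for p in positions])
    return out


def draw_genotypes(distribution: dict[str, float], n_animals: int,
                   rng: np.random.Generator,
                   positions=None) -> np.ndarray:
    """Unphased dosages for ``n_animals`` diploids drawing haplotype pairs
    i.i.d. from ``distribution`` (labels as in the haplotype table)."""
    positions = positions or tables.core_positions()
    labels = list(distribution)
    probs = np.array([distribution[lab] for lab in labels], dtype=float)
    probs /= probs.sum()
    vec = _haplotype_dosage_vectors(labels, positions)
    draws = rng.choice(len(labels), size=(n_animals, 2), p=probs)
    return np.array([vec[labels[a]] + vec[labels[b]] for a, b in draws])


def modal_haplotype_recovery(breed: str, n_animals: int, n_reps: int,
                             seed: int, keep_residual: bool = True,
                             tol: float = 1e-8) -> dict:
    """Average EM estimate of the modal haplotype frequency over seeded
    replicate cohorts generated from a breed's built-in distribution."""
    dist = tables.breed_haplotype_distribution(breed,
                                               keep_residual=keep_residual)
    positions = tables.core_positions()
    rng = np.random.default_rng(seed)
    estimates = []
    for _ in range(n_reps):
        G = draw_genotypes(dist, n_animals, rng, positions)
        res = hem.em_fit(G, tol=tol, positions=positions)
        estimates.append(res.modal()[1])
    return {
        "breed": breed,
        "n_animals": n_animals,
        "n_reps": n_reps,
        "mean_pct": 100.0 * float(np.mean(estimates)),
        "sd_pct": 100.0 * float(np.std(estimates)),
        "generating_modal": max(dist.values()),
    }


def _gene_dosage(gene: str, variant_dist: dict[str, float], n_animals: int,
                 rng: np.random.Generator):
    positions = tables.core_positions(gene)
    alt = {s.pos: s.alt for s in tables.CORE_SNPS}
    labels = list(variant_dist)
    probs = np.array([variant_dist[v] for v in labels], dtype=float)
    probs /= probs.sum()
    vec = {
        v: np.array([int(tables.SIM_VARIANT_ALLELES[gene][v][p] == alt[p])
                     for p in positions])
        for v in labels}
    draws = rng.choice(len(labels), size=(n_animals, 2), p=probs)
    G = np.array([vec[labels[a]] + vec[labels[b]] for a, b in draws])
    return G, positions


def variant_recovery(gene: str, variant_dist: dict[str, float],
                     n_animals: int, n_reps: int, seed: int,
                     tol: float = 1e-8) -> pd.Series:
    """Mean recovered protein-variant frequencies (per variant, as
    fractions) over seeded replicates generated at the given per-gene
    variant distribution."""
    rules = pv.builtin_rules()
    snps = {s.pos: s for s in tables.CORE_SNPS}
    rng = np.random.default_rng(seed)
    acc: dict[str, float] = {}
    for _ in range(n_reps):
        G, positions = _gene_dosage(gene, variant_dist, n_animals, rng)
        alleles = [(snps[p].ref, snps[p].alt) for p in positions]
        res = hem.em_fit(G, tol=tol, positions=positions, alleles=alleles)
        table = pv.variant_frequencies({gene: {"sim": res}}, rules)
        for (g, variant), row in table.iterrows():
            acc[variant] = acc.get(variant, 0.0) + float(row["sim"])
    return pd.Series({v: s / n_reps for v, s in acc.items()}).sort_index()


def minimum_detectable_frequency(n_animals: int = 30) -> float:
    """Alt-allele frequency produced by a single heterozygote among
    ``n_animals`` diploids, computed through the genotype matrix."""
    from .models import GenotypeMatrix, VariantRecord

    dosage = np.zeros((n_animals, 1), dtype=np.int16)
    dosage[0, 0] = 1
    depths = np.full((n_animals, 1, 2), 10, dtype=np.int32)
    matrix = GenotypeMatrix([f"S{i}" for i in range(n_animals)],
                            [VariantRecord("6", 87390576, "T", "C")],
                            dosage, depths)
    return round(float(matrix.allele_frequencies()[0]), 3)


def common_haplotype_count(threshold: float = 0.05) -> int:
    """Named haplotypes in the built-in table exceeding ``threshold`` in
    at least one breed column."""
    named = tables.builtin_haplotype_frequencies(
        include_residual=False).drop(columns="Total")
    return int(named.gt(threshold).any(axis=1).sum())


def intron_share_pct(seed: int = 0) -> tuple[float, int]:
    """Classify the default 892-SNP fixture and return the intron share
    (percent, 1 decimal) plus the SNP count."""
    import tempfile

    from . import consequence as cq
    from . import genotype_io as gio

    with tempfile.TemporaryDirectory() as tmp:
        cfg = sd.SimConfig(
            breeds=[(b, 3) for b in tables.BREEDS], seed=seed)
        bundle = sd.simulate_cohort(cfg, tmp)
        matrix = gio.read_vcf(bundle.vcf_path)
        classified = cq.classify_all(matrix.variants, bundle.gene_models,
                                     bundle.reference)
    counts = cq.category_counts(classified)
    total = int(counts.sum())
    return round(100.0 * counts["intron"] / total, 1), total
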