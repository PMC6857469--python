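"""Haplotype frequency estimation from unphased genotypes by EM.

Implements the classic gene-counting EM (Excoffier-Slatkin): the E-step
weights every haplotype pair compatible with an individual's multilocus
dosages by ``c * p_h * p_k`` (c = 2 for heterozygous pairs), the M-step
re-estimates frequencies from expected haplotype counts.  The
log-likelihood is non-decreasing and the frequency simplex is preserved
every iteration.  Initialization is uniform over compatible haplotypes
and haplotype ordering is lexicographic, so runs are bit-reproducible.

Also assembles comprehensive 4-gene protein haplotype tables with the
5 % variant-inclusion rule and a residual row.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from . import tables
from .models import CaseinhapError, GenotypeMatrix

logger = logging.getLogger(__name__)

Hap = tuple[int, ...]  # 0 = ref allele, 1 = alt allele per locus


class EMError(CaseinhapError):
    pass


class AmbiguityCapExceeded(CaseinhapError):
    pass


def enumerate_pairs(dosages, max_ambiguity: int = 12) -> list[tuple[Hap, Hap]]:
    """All unordered haplotype pairs consistent with one individual's
    per-locus dosages (0/1/2; -1 = missing, expanded over both alleles).

    Raises :class:`AmbiguityCapExceeded` when the number of unresolved
    (heterozygous or missing) loci exceeds ``max_ambiguity``.
    """
    dosages = list(dosages)
    unresolved = sum(1 for d in dosages if d == 1 or d < 0)
    if unresolved > max_ambiguity:
        raise AmbiguityCapExceeded(
            f"{unresolved} unresolved loci exceed cap {max_ambiguity}")
    per_locus: list[list[tuple[int, int]]] = []
    for d in dosages:
        if d == 0:
            per_locus.append([(0, 0)])
        elif d == 2:
            per_locus.append([(1, 1)])
        elif d == 1:
            per_locus.append([(0, 1), (1, 0)])
        elif d < 0:
            per_locus.append([(0, 0), (0, 1), (1, 0), (1, 1)])
        else:
            raise EMError(f"invalid dosage {d}")
    seen: set[tuple[Hap, Hap]] = set()
    for combo in product(*per_locus):
        h1 = tuple(a for a, _ in combo)
        h2 = tuple(b for _, b in combo)
        pair = (h1, h2) if h1 <= h2 else (h2, h1)
        seen.add(pair)
    return sorted(seen)


@dataclass
class EMResult:
    """Fitted haplotype frequencies for one locus block."""

    positions: tuple[int, ...]
    haplotypes: list[Hap]                # lexicographic order
    frequencies: np.ndarray              # sums to 1
    loglik_trace: list[float]
    n_iter: int
    converged: bool
    n_individuals: int
    excluded: list[int] = field(default_factory=list)  # input row indices
    alleles: list[tuple[str, str]] | None = None       # (ref, alt) per locus

    @property
    def loglik(self) -> float:
        return self.loglik_trace[-1]

    def hap_string(self, hap: Hap) -> str:
        if self.alleles is None:
            return "".join(str(a) for a in hap)
        return "".join(self.alleles[i][a] for i, a in enumerate(hap))

    def hap_alleles(self, hap: Hap) -> dict[int, str]:
        if self.alleles is None:
            raise EMError("allele labels not attached")
        return {p: self.alleles[i][a]
                for i, (p, a) in enumerate(zip(self.positions, hap))}

    def as_series(self) -> pd.Series:
        return pd.Series(self.frequencies,
                         index=[self.hap_string(h) for h in self.haplotypes])

    def implied_allele_frequencies(self) -> np.ndarray:
        """Marginal alt-allele frequency per locus implied by the fit."""
        H = np.array(self.haplotypes, dtype=float)
        return self.frequencies @ H

    def modal(self) -> tuple[Hap, float]:
        """Highest-frequency haplotype (ties: lexicographically first)."""
        best = int(np.argmax(self.frequencies))
        # argmax returns the first maximum; haplotypes are sorted, so the
        # tie-break is already lexicographic.
        return self.haplotypes[best], float(self.frequencies[best])


def em_fit(genotypes, tol: float = 1e-8, max_iter: int = 1000,
           max_ambiguity: int = 12, max_missing_frac: float = 0.5,
           positions: tuple[int, ...] = (),
           alleles: list[tuple[str, str]] | None = None,
           n_restarts: int = 1, restart_seed: int = 0) -> EMResult:
    """Fit haplotype frequencies to unphased multilocus genotypes.

    ``genotypes`` is an (n_individuals x n_loci) array of dosages in
    {0, 1, 2, -1}.  Individuals exceeding the ambiguity cap or missing
    more than ``max_missing_frac`` of loci are excluded (logged).
    Convergence: change in log-likelihood below ``tol``.

    The first run starts from the uniform distribution over compatible
    haplotypes (a deterministic, bit-reproducible default).  On perfectly
    symmetric data that start can be a stationary point below the global
    maximum; ``n_restarts > 1`` adds seeded Dirichlet restarts and returns
    the best fit.
    """
    G = np.asarray(genotypes, dtype=np.int64)
    if G.ndim != 2:
        raise EMError("genotypes must be 2-D (individuals x loci)")
    n_ind, n_loci = G.shape
    if n_loci == 0:
        raise EMError("no loci")

    excluded: list[int] = []
    keep_rows = []
    for i in range(n_ind):
        row = G[i]
        n_missing = int((row < 0).sum())
        unresolved = n_missing + int((row == 1).sum())
        if n_missing > max_missing_frac * n_loci or unresolved > max_ambiguity:
            excluded.append(i)
        else:
            keep_rows.append(i)
    if excluded:
        logger.info("em_fit: excluded %d/%d individuals (ambiguity cap or "
                    "missingness)", len(excluded), n_ind)
    if not keep_rows:
        raise EMError("no individuals left after ambiguity/missingness cap")
    G = G[keep_rows]

    # collapse identical genotype rows
    uniq, counts = np.unique(G, axis=0, return_counts=True)
    pairs_per_genotype = [enumerate_pairs(row, max_ambiguity) for row in uniq]

    hap_index: dict[Hap, int] = {}
    for pairs in pairs_per_genotype:
        for h, k in pairs:
            hap_index.setdefault(h, None)
            hap_index.setdefault(k, None)
    haplotypes = sorted(hap_index)
    hap_index = {h: i for i, h in enumerate(haplotypes)}
    n_hap = len(haplotypes)

    # flat pair arrays
    pa, pb, coef, group = [], [], [], []
    for g, pairs in enumerate(pairs_per_genotype):
        for h, k in pairs:
            pa.append(hap_index[h])
            pb.append(hap_index[k])
            coef.append(1.0 if h == k else 2.0)
            group.append(g)
    pa = np.array(pa)
    pb = np.array(pb)
    coef = np.array(coef)
    group = np.array(group)
    n_groups = len(uniq)
    w_count = counts.astype(float)
    n_chrom = 2.0 * w_count.sum()

    def run_em(p0):
        p = p0.copy()
        trace: list[float] = []
        converged = False
        n_iter = 0
        for n_iter in range(1, max_iter + 1):
            pair_prob = coef * p[pa] * p[pb]
            group_tot = np.bincount(group, weights=pair_prob,
                                    minlength=n_groups)
            if np.any(group_tot <= 0):
                raise EMError("an individual has zero likelihood under the "
                              "current frequencies (contradictory data)")
            ll = float(np.dot(w_count, np.log(group_tot)))
            trace.append(ll)
            w = w_count[group] * pair_prob / group_tot[group]
            new_p = (np.bincount(pa, weights=w, minlength=n_hap)
                     + np.bincount(pb, weights=w, minlength=n_hap)) / n_chrom
            new_p /= new_p.sum()
            if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol:
                converged = True
                p = new_p
                break
            p = new_p
        return p, trace, n_iter, converged

    p, trace, n_iter, converged = run_em(np.full(n_hap, 1.0 / n_hap))
    if n_restarts > 1:
        rng = np.random.default_rng(restart_seed)
        for _ in range(n_restarts - 1):
            cand = run_em(rng.dirichlet(np.ones(n_hap)))
            if cand[1][-1] > trace[-1] + 1e-12:
                p, trace, n_iter, converged = cand

    return EMResult(
        positions=tuple(positions) or tuple(range(n_loci)),
        haplotypes=haplotypes,
        frequencies=p,
        loglik_trace=trace,
        n_iter=n_iter,
        converged=converged,
        n_individuals=len(keep_rows),
        excluded=[keep for keep in excluded],
        alleles=alleles,
    )


def block_loglik(genotypes, haplotypes: list[Hap], freqs) -> float:
    """Direct log-likelihood of unphased genotypes under given haplotype
    frequencies (independent oracle for the EM objective)."""
    freqs = np.asarray(freqs, dtype=float)
    idx = {h: i for i, h in enumerate(haplotypes)}
    ll = 0.0
    for row in np.asarray(genotypes):
        tot = 0.0
        for h, k in enumerate_pairs(row, max_ambiguity=64):
            if h in idx and k in idx:
                c = 1.0 if h == k else 2.0
                tot += c * freqs[idx[h]] * freqs[idx[k]]
        if tot <= 0:
            return -np.inf
        ll += np.log(tot)
    return ll


# ---------------------------------------------------------------------------
# Per-breed fits
# ---------------------------------------------------------------------------

POOLED = "Total"


def per_breed_frequencies(matrix: GenotypeMatrix, block_positions,
                          tol: float = 1e-8, max_iter: int = 1000,
                          max_ambiguity: int = 12) -> dict[str, EMResult]:
    """Independent EM fit within each breed plus a pooled fit (``Total``)."""
    if not matrix.breed_of:
        raise EMError("breed map not attached")
    cols = matrix.variant_index(block_positions)
    alleles = [(matrix.variants[j].ref, matrix.variants[j].alt) for j in cols]
    out: dict[str, EMResult] = {}
    for breed in matrix.breeds():
        rows = matrix.breed_rows(breed)
        if rows.size == 0:
            raise EMError(f"breed {breed} has no individuals")
        out[breed] = em_fit(matrix.dosage[np.ix_(rows, cols)], tol=tol,
                            max_iter=max_iter, max_ambiguity=max_ambiguity,
                            positions=tuple(block_positions), alleles=alleles)
    out[POOLED] = em_fit(matrix.dosage[:, cols], tol=tol, max_iter=max_iter,
                         max_ambiguity=max_ambiguity,
                         positions=tuple(block_positions), alleles=alleles)
    return out


# ---------------------------------------------------------------------------
# Comprehensive 4-gene protein haplotypes
# ---------------------------------------------------------------------------

RESIDUAL = "Residual"
UNASSIGNED = "unassigned"


def _label_haplotype(hap_alleles: dict[int, str], rules_by_gene) -> str | None:
    """Map a 7-SNP haplotype to a 4-gene label, or None if any gene's
    sub-haplotype matches no named variant."""
    from .protein_variants import call_variant  # local import, no cycle at load

    parts = []
    for gene in tables.GENE_ORDER:
        sub = {p: hap_alleles[p] for p in tables.core_positions(gene)}
        name = call_variant(sub, rules_by_gene[gene])
        if name == UNASSIGNED:
            return None
        parts.append(name.split("*", 1)[1])
    return "-".join(parts)


def comprehensive_haplotypes(em_per_breed: dict[str, EMResult], rules,
                             min_variant_freq: float = 0.05,
                             residual_threshold: float = 0.05,
                             n_animals: dict[str, int] | None = None
                             ) -> pd.DataFrame:
    """Assemble the haplotype-frequency table (labels x breeds).

    Protein variants below ``min_variant_freq`` in every breed are
    excluded and their haplotypes pooled into ``Residual``; likewise
    named haplotypes below ``residual_threshold`` in every breed.
    Columns each sum to 1 (including the residual row).
    """
    from .protein_variants import rules_by_gene as _group

    rules_by_gene = _group(rules)
    breeds = [b for b in em_per_breed if b != POOLED]
    columns = ([POOLED] if POOLED in em_per_breed else []) + breeds

    # label each haplotype per fit
    label_freqs: dict[str, dict[str, float]] = {}
    variant_freqs: dict[str, dict[tuple[str, str], float]] = {}
    for col in columns:
        res = em_per_breed[col]
        lf: dict[str, float] = {}
        vf: dict[tuple[str, str], float] = {}
        for hap, freq in zip(res.haplotypes, res.frequencies):
            alleles = res.hap_alleles(hap)
            label = _label_haplotype(alleles, rules_by_gene)
            lf[label or RESIDUAL] = lf.get(label or RESIDUAL, 0.0) + freq
            if label is not None:
                for gene, part in zip(tables.GENE_ORDER, label.split("-")):
                    key = (gene, part)
                    vf[key] = vf.get(key, 0.0) + freq
        label_freqs[col] = lf
        variant_freqs[col] = vf

    # 5 % variant-inclusion rule, assessed over breed columns only
    all_variants = {k for col in breeds for k in variant_freqs[col]}
    kept_variants = {
        k for k in all_variants
        if any(variant_freqs[b].get(k, 0.0) >= min_variant_freq for b in breeds)
    }

    def uses_only_kept(label: str) -> bool:
        return all((g, p) in kept_variants
                   for g, p in zip(tables.GENE_ORDER, label.split("-")))

    named = sorted({lab for col in breeds for lab in label_freqs[col]
                    if lab != RESIDUAL})
    kept_labels = [lab for lab in named if uses_only_kept(lab)]
    # drop labels below the residual threshold everywhere
    kept_labels = [
        lab for lab in kept_labels
        if any(label_freqs[b].get(lab, 0.0) >= residual_threshold
               for b in breeds)
    ]

    data = {}
    for col in columns:
        lf = label_freqs[col]
        vals = {lab: lf.get(lab, 0.0) for lab in kept_labels}
        vals[RESIDUAL] = sum(f for lab, f in lf.items()
                             if lab not in kept_labels)
        data[col] = vals
    df = pd.DataFrame(data).fillna(0.0)
    order = (df.drop(index=RESIDUAL)
             .sort_values(POOLED if POOLED in df else df.columns[0],
                          ascending=False).index.tolist())
    df = df.loc[order + [RESIDUAL]]
    if n_animals:
        df.attrs["n_animals"] = dict(n_animals)
    return df


def theoretical_haplotype_count(variant_freq_table: pd.DataFrame,
                                breed: str) -> int:
    """Product over genes of the number of protein variants detected
    (nonzero frequency) in ``breed``.

    ``variant_freq_table`` is indexed by (gene, variant) with breeds as
    columns; ``unassigned`` rows are ignored.
    """
    count = 1
    for gene in tables.GENE_ORDER:
        sub = variant_freq_table.loc[gene]
        named = sub[(sub.index != UNASSIGNED) & (sub[breed] > 0)]
        count *= max(len(named), 1)
    return count
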