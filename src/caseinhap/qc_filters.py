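"""Cohort cleaning rules.

Order is fixed: depth-based genotype trust, similarity-based animal
exclusion, breed-size floor, then the polymorphic-in-at-least-one-breed
variant filter.  The full pass is idempotent.

Assumptions (the underlying rules are stated loosely in the literature):
the read-depth rule is applied to ref+alt total depth; similarity is
1 minus the Manhattan distance between dosage vectors normalized by twice
the number of co-called sites; when a similar pair is broken up, the
member with more missing genotypes is removed (ties: lexicographically
larger id).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .models import CaseinhapError, GenotypeMatrix

logger = logging.getLogger(__name__)


class FilterError(CaseinhapError):
    pass


@dataclass
class FilterReport:
    genotypes_masked: int = 0
    genotypes_unknown_depth: int = 0
    animals_removed: list[tuple[str, str]] = field(default_factory=list)
    variants_removed: int = 0
    breeds_dropped: list[str] = field(default_factory=list)
    breeds_kept: list[str] = field(default_factory=list)

    def merge(self, other: "FilterReport") -> "FilterReport":
        return FilterReport(
            genotypes_masked=self.genotypes_masked + other.genotypes_masked,
            genotypes_unknown_depth=(self.genotypes_unknown_depth
                                     + other.genotypes_unknown_depth),
            animals_removed=self.animals_removed + other.animals_removed,
            variants_removed=self.variants_removed + other.variants_removed,
            breeds_dropped=self.breeds_dropped + other.breeds_dropped,
            breeds_kept=other.breeds_kept or self.breeds_kept,
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("genotypes_masked", str(self.genotypes_masked)),
            ("genotypes_unknown_depth", str(self.genotypes_unknown_depth)),
            ("variants_removed", str(self.variants_removed)),
            ("breeds_dropped", ",".join(self.breeds_dropped)),
            ("breeds_kept", ",".join(self.breeds_kept)),
        ] + [("animal_removed", f"{sid}:{reason}")
             for sid, reason in self.animals_removed]
        return pd.DataFrame(rows, columns=["field", "value"])

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------

def depth_trust_filter(matrix: GenotypeMatrix, min_reads: int = 3
                       ) -> tuple[GenotypeMatrix, FilterReport]:
    """Mask genotypes whose total allele depth is below ``min_reads``.

    Genotypes with unknown depth are kept (and counted in the report).
    """
    if min_reads < 1:
        raise FilterError("min_reads must be >= 1")
    out = matrix.copy()
    known = (out.depths[:, :, 0] >= 0) & (out.depths[:, :, 1] >= 0)
    total = out.depths[:, :, 0] + out.depths[:, :, 1]
    called = out.dosage >= 0
    to_mask = known & (total < min_reads) & called
    out.dosage[to_mask] = -1
    n_unknown = int((~known & called).sum())
    if n_unknown:
        logger.info("depth_trust_filter: %d called genotypes lack depth; kept",
                    n_unknown)
    report = FilterReport(genotypes_masked=int(to_mask.sum()),
                          genotypes_unknown_depth=n_unknown)
    return out, report


def relative_manhattan_similarity(matrix: GenotypeMatrix) -> np.ndarray:
    """Pairwise similarity s(i,j) = 1 - sum_v |d_iv - d_jv| / (2 L_ij).

    The sum runs over variants called in both samples; ``L_ij`` counts
    them.  Pairs with no co-called variants are NaN.  The diagonal is 1.
    """
    if matrix.n_samples < 2:
        raise FilterError("need at least two samples")
    D = matrix.dosage
    called = (D >= 0).astype(np.float64)
    # decompose |a-b| over dosage levels via indicator matrices
    ind = [((D == k) & (D >= 0)).astype(np.float64) for k in (0, 1, 2)]
    L = called @ called.T
    manhattan = np.zeros_like(L)
    for a in range(3):
        for b in range(3):
            if a == b:
                continue
            manhattan += abs(a - b) * (ind[a] @ ind[b].T)
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = 1.0 - manhattan / (2.0 * L)
    sim[L == 0] = np.nan
    np.fill_diagonal(sim, 1.0)
    return sim


def drop_similar_animals(matrix: GenotypeMatrix, threshold: float = 0.99
                         ) -> tuple[GenotypeMatrix, FilterReport]:
    """Iteratively remove one member of every pair more similar than
    ``threshold`` (the member with more missing genotypes; ties broken
    toward the lexicographically larger id)."""
    out = matrix.copy()
    report = FilterReport()
    while out.n_samples >= 2:
        sim = relative_manhattan_similarity(out)
        iu, ju = np.triu_indices(out.n_samples, k=1)
        vals = sim[iu, ju]
        over = ~np.isnan(vals) & (vals > threshold)
        if not over.any():
            break
        order = np.argsort(-vals[over], kind="stable")
        i, j = iu[over][order[0]], ju[over][order[0]]
        miss = out.missing_counts()
        si, sj = out.samples[i], out.samples[j]
        if miss[i] > miss[j]:
            drop = i
        elif miss[j] > miss[i]:
            drop = j
        else:
            drop = i if si > sj else j
        dropped_id = out.samples[drop]
        other = sj if drop == i else si
        report.animals_removed.append(
            (dropped_id, f"similarity {sim[i, j]:.4f} with {other}"))
        keep = [k for k in range(out.n_samples) if k != drop]
        out = out.subset(rows=keep)
    return out, report


def breed_and_polymorphism_filter(matrix: GenotypeMatrix,
                                  min_breed_size: int = 30
                                  ) -> tuple[GenotypeMatrix, FilterReport]:
    """Drop breeds below the size floor, then variants that are
    monomorphic in every remaining breed."""
    if not matrix.breed_of:
        raise FilterError("breed map not attached")
    report = FilterReport()
    sizes: dict[str, int] = {}
    for s in matrix.samples:
        sizes[matrix.breed_of[s]] = sizes.get(matrix.breed_of[s], 0) + 1
    kept_breeds = [b for b, n in sizes.items() if n >= min_breed_size]
    report.breeds_dropped = [b for b in sizes if b not in kept_breeds]
    report.breeds_kept = kept_breeds
    if not kept_breeds:
        raise FilterError(
            f"no breed reaches the floor of {min_breed_size} animals")
    rows = [i for i, s in enumerate(matrix.samples)
            if matrix.breed_of[s] in kept_breeds]
    for i, s in enumerate(matrix.samples):
        if i not in set(rows):
            report.animals_removed.append((s, "breed below size floor"))
    out = matrix.subset(rows=rows)

    poly = np.zeros(out.n_variants, dtype=bool)
    for b in kept_breeds:
        rows_b = out.breed_rows(b)
        d = out.dosage[rows_b]
        called = d >= 0
        n_called = called.sum(axis=0)
        alt = np.where(called, d, 0).sum(axis=0)
        poly |= (alt > 0) & (alt < 2 * n_called)
    report.variants_removed = int((~poly).sum())
    out = out.subset(cols=np.flatnonzero(poly))
    return out, report


def apply_all(matrix: GenotypeMatrix, min_reads: int = 3,
              similarity_threshold: float = 0.99, min_breed_size: int = 30
              ) -> tuple[GenotypeMatrix, FilterReport]:
    """Run the full filter cascade in the fixed order."""
    out, r1 = depth_trust_filter(matrix, min_reads)
    out, r2 = drop_similar_animals(out, similarity_threshold)
    out, r3 = breed_and_polymorphism_filter(out, min_breed_size)
    return out, r1.merge(r2).merge(r3)
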