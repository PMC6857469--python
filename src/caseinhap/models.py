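"""Shared domain types: variants, genotype matrices, gene models, reference.

Coordinates are 1-based throughout and intervals are closed on both ends,
matching VCF and GFF3 conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

VALID_BASES = frozenset("ACGT")

#: dosage / depth sentinel for missing values
MISSING = -1


class CaseinhapError(Exception):
    """Base class for package errors."""


@dataclass(frozen=True)
class VariantRecord:
    """A biallelic SNP."""

    chrom: str
    pos: int
    ref: str
    alt: str
    id: str = "."

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref not in VALID_BASES or self.alt not in VALID_BASES:
            raise ValueError(f"alleles must be single bases in ACGT: {self.ref}/{self.alt}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt alleles are identical at {self.chrom}:{self.pos}")


@dataclass
class GenotypeMatrix:
    """Samples x variants dosage matrix with per-genotype allele depths.

    ``dosage`` holds alternative-allele counts in {0, 1, 2} with -1 for
    missing calls.  ``depths[s, v]`` is ``(ref_reads, alt_reads)`` with -1
    for unknown depth (AD absent in the source VCF).
    """

    samples: list[str]
    variants: list[VariantRecord]
    dosage: np.ndarray                  # (n_samples, n_variants) int16
    depths: np.ndarray                  # (n_samples, n_variants, 2) int32
    breed_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        n, m = len(self.samples), len(self.variants)
        if self.dosage.shape != (n, m):
            raise ValueError(f"dosage shape {self.dosage.shape} != ({n}, {m})")
        if self.depths.shape != (n, m, 2):
            raise ValueError(f"depths shape {self.depths.shape} != ({n}, {m}, 2)")
        if self.breed_of:
            unmapped = [s for s in self.samples if s not in self.breed_of]
            if unmapped:
                raise ValueError(f"samples without a breed: {unmapped[:5]}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def breeds(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(self.breed_of[s], None)
        return list(seen)

    def sample_index(self, sample_ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        return np.array([lookup[s] for s in sample_ids], dtype=int)

    def breed_rows(self, breed: str) -> np.ndarray:
        return np.array(
            [i for i, s in enumerate(self.samples) if self.breed_of.get(s) == breed],
            dtype=int,
        )

    def variant_index(self, positions) -> np.ndarray:
        lookup = {v.pos: j for j, v in enumerate(self.variants)}
        try:
            return np.array([lookup[p] for p in positions], dtype=int)
        except KeyError as exc:
            raise KeyError(f"position {exc.args[0]} not in matrix") from exc

    def subset(self, rows=None, cols=None) -> "GenotypeMatrix":
        rows = np.arange(self.n_samples) if rows is None else np.asarray(rows)
        cols = np.arange(self.n_variants) if cols is None else np.asarray(cols)
        samples = [self.samples[i] for i in rows]
        return GenotypeMatrix(
            samples=samples,
            variants=[self.variants[j] for j in cols],
            dosage=self.dosage[np.ix_(rows, cols)].copy(),
            depths=self.depths[np.ix_(rows, cols)].copy(),
            breed_of={s: self.breed_of[s] for s in samples} if self.breed_of else {},
        )

    def copy(self) -> "GenotypeMatrix":
        return self.subset()

    def allele_frequencies(self, rows=None) -> np.ndarray:
        """Alternative allele frequency per variant (NaN where no calls)."""
        d = self.dosage if rows is None else self.dosage[np.asarray(rows)]
        called = d >= 0
        n_called = called.sum(axis=0)
        alt = np.where(called, d, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_called > 0, alt / (2.0 * n_called), np.nan)

    def missing_counts(self) -> np.ndarray:
        return (self.dosage < 0).sum(axis=1)


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

Interval = tuple[int, int]  # 1-based closed


def _length(iv: Interval) -> int:
    return iv[1] - iv[0] + 1


def _contains(ivs, pos: int) -> bool:
    return any(a <= pos <= b for a, b in ivs)


@dataclass
class GeneModel:
    """Strand-aware single-transcript gene model plus its upstream window."""

    gene_id: str
    chrom: str
    strand: str                       # "+" or "-"
    exons: list[Interval]             # genomic ascending, non-overlapping
    cds: list[Interval]               # genomic ascending
    utr5: list[Interval] = field(default_factory=list)
    utr3: list[Interval] = field(default_factory=list)
    upstream_length: int = 1000
    signal_peptide: int = 15

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        for ivs in (self.exons, self.cds):
            for (a, b) in ivs:
                if a > b:
                    raise ValueError(f"inverted interval ({a}, {b}) in {self.gene_id}")
            for (a, b), (c, d) in zip(ivs, ivs[1:]):
                if c <= b:
                    raise ValueError(f"overlapping/unsorted intervals in {self.gene_id}")
        if self.cds_length % 3 != 0:
            raise ValueError(
                f"{self.gene_id}: CDS length {self.cds_length} not divisible by 3"
            )

    # -- spans ------------------------------------------------------------

    @property
    def tx_start(self) -> int:
        return self.exons[0][0]

    @property
    def tx_end(self) -> int:
        return self.exons[-1][1]

    @property
    def upstream_window(self) -> Interval:
        if self.strand == "+":
            return (self.tx_start - self.upstream_length, self.tx_start - 1)
        return (self.tx_end + 1, self.tx_end + self.upstream_length)

    @property
    def span(self) -> Interval:
        """Transcript plus upstream window."""
        up = self.upstream_window
        return (min(up[0], self.tx_start), max(up[1], self.tx_end))

    @property
    def introns(self) -> list[Interval]:
        return [
            (a[1] + 1, b[0] - 1) for a, b in zip(self.exons, self.exons[1:])
        ]

    @property
    def cds_length(self) -> int:
        return sum(_length(iv) for iv in self.cds)

    @property
    def n_amino_acids(self) -> int:
        """Precursor protein length (CDS minus the stop codon)."""
        return self.cds_length // 3 - 1

    # -- membership -------------------------------------------------------

    def in_transcript(self, pos: int) -> bool:
        return self.tx_start <= pos <= self.tx_end

    def in_scope(self, pos: int) -> bool:
        a, b = self.span
        return a <= pos <= b

    def in_upstream(self, pos: int) -> bool:
        a, b = self.upstream_window
        return a <= pos <= b

    def in_exon(self, pos: int) -> bool:
        return _contains(self.exons, pos)

    def in_cds(self, pos: int) -> bool:
        return _contains(self.cds, pos)

    def in_intron(self, pos: int) -> bool:
        return self.in_transcript(pos) and not self.in_exon(pos)

    def in_utr5(self, pos: int) -> bool:
        return _contains(self.utr5, pos)

    def in_utr3(self, pos: int) -> bool:
        return _contains(self.utr3, pos)

    # -- coding coordinates ----------------------------------------------

    def coding_offset(self, pos: int) -> int:
        """1-based offset of a genomic position within the spliced CDS,
        counted along the coding strand."""
        if not self.in_cds(pos):
            raise ValueError(f"{self.gene_id}: position {pos} is not in the CDS")
        if self.strand == "+":
            off = 0
            for a, b in self.cds:
                if pos > b:
                    off += b - a + 1
                else:
                    return off + pos - a + 1
        off = 0
        for a, b in reversed(self.cds):
            if pos < a:
                off += b - a + 1
            else:
                return off + b - pos + 1
        raise AssertionError("unreachable")

    def genomic_position(self, coding_offset: int) -> int:
        """Inverse of :meth:`coding_offset`."""
        if not 1 <= coding_offset <= self.cds_length:
            raise ValueError(f"coding offset {coding_offset} out of range")
        remaining = coding_offset
        cds = self.cds if self.strand == "+" else list(reversed(self.cds))
        for a, b in cds:
            n = b - a + 1
            if remaining <= n:
                return a + remaining - 1 if self.strand == "+" else b - remaining + 1
            remaining -= n
        raise AssertionError("unreachable")

    def codon_number(self, pos: int) -> tuple[int, int]:
        """(1-based codon number, 1-based position within codon)."""
        off = self.coding_offset(pos)
        return (off - 1) // 3 + 1, (off - 1) % 3 + 1


# ---------------------------------------------------------------------------
# Reference sequence window
# ---------------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ReferenceSequence:
    """A contiguous window of a contig, stored with a coordinate offset.

    Genomic position ``p`` (1-based) maps to ``seq[p - offset - 1]``; the
    window covers positions ``offset + 1 .. offset + len(seq)``.
    """

    name: str
    offset: int
    seq: str

    def __post_init__(self):
        if self.offset < 0:
            raise ValueError("offset must be non-negative")

    @property
    def start(self) -> int:
        return self.offset + 1

    @property
    def end(self) -> int:
        return self.offset + len(self.seq)

    def base(self, pos: int) -> str:
        if not self.start <= pos <= self.end:
            raise IndexError(f"position {pos} outside reference window "
                             f"[{self.start}, {self.end}]")
        return self.seq[pos - self.offset - 1]

    def fetch(self, start: int, end: int) -> str:
        """Closed-interval slice [start, end]."""
        if start > end:
            raise ValueError("start > end")
        if not (self.start <= start and end <= self.end):
            raise IndexError(f"interval [{start}, {end}] outside reference window")
        return self.seq[start - self.offset - 1 : end - self.offset]

    def with_base(self, pos: int, base: str) -> "ReferenceSequence":
        i = pos - self.offset - 1
        return ReferenceSequence(self.name, self.offset,
                                 self.seq[:i] + base + self.seq[i + 1:])
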