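"""Named casein protein variants: rule table, haplotype calling, and
per-breed protein-variant frequency tables.

A rule is a signature of (position, allele) pairs within one gene; a
phased gene haplotype matches a variant iff it carries every signature
allele.  Haplotypes matching no rule are reported as ``unassigned``,
never silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import tables
from .haplotype_em import EMResult, UNASSIGNED
from .models import CaseinhapError


class RuleError(CaseinhapError):
    pass


@dataclass(frozen=True)
class ProteinVariantRule:
    """Signature defining one named protein variant of one casein gene."""

    gene: str
    name: str                          # e.g. "CSN3*A"
    signature: tuple[tuple[int, str], ...]  # ((pos, allele), ...)

    @property
    def short_name(self) -> str:
        return self.name.split("*", 1)[1]

    def matches(self, haplotype: dict[int, str]) -> bool:
        return all(haplotype[pos] == allele for pos, allele in self.signature)


def builtin_rules() -> list[ProteinVariantRule]:
    """Rules for CSN1S1*B; CSN2*A1, *A2, *I; CSN1S2*A; CSN3*A, *B, *E."""
    rules = []
    for gene, variants in tables.VARIANT_SIGNATURES.items():
        for short, sig in variants.items():
            rules.append(ProteinVariantRule(
                gene=gene,
                name=f"{gene}*{short}",
                signature=tuple(sorted(sig.items())),
            ))
    return rules


def load_rules_tsv(path: str | Path) -> list[ProteinVariantRule]:
    """Load extension rules from a TSV (gene, variant, pos, allele; one
    row per signature element)."""
    df = pd.read_csv(path, sep="\t", dtype={"pos": int})
    required = {"gene", "variant", "pos", "allele"}
    if not required.issubset(df.columns):
        raise RuleError(f"rule TSV must have columns {sorted(required)}")
    rules = []
    for (gene, variant), grp in df.groupby(["gene", "variant"], sort=True):
        name = variant if "*" in str(variant) else f"{gene}*{variant}"
        rules.append(ProteinVariantRule(
            gene=str(gene),
            name=str(name),
            signature=tuple(sorted(zip(grp.pos.astype(int), grp.allele))),
        ))
    return rules


def merge_rules(base: list[ProteinVariantRule],
                extra: list[ProteinVariantRule]) -> list[ProteinVariantRule]:
    """Extend the builtin table; reject rules that conflict with it."""
    by_name = {r.name: r for r in base}
    out = list(base)
    for rule in extra:
        existing = by_name.get(rule.name)
        if existing is not None:
            if existing.signature != rule.signature:
                raise RuleError(
                    f"extension rule {rule.name} conflicts with builtin "
                    f"signature")
            continue
        for other in out:
            if other.gene == rule.gene and other.signature == rule.signature:
                raise RuleError(
                    f"extension rule {rule.name} duplicates signature of "
                    f"{other.name}")
        out.append(rule)
        by_name[rule.name] = rule
    return out


def rules_by_gene(rules: list[ProteinVariantRule]
                  ) -> dict[str, list[ProteinVariantRule]]:
    out: dict[str, list[ProteinVariantRule]] = {g: [] for g in tables.GENE_ORDER}
    for r in rules:
        out.setdefault(r.gene, []).append(r)
    return out


def call_variant(gene_haplotype: dict[int, str],
                 rules: list[ProteinVariantRule]) -> str:
    """Name of the unique matching variant, or ``unassigned``.

    ``gene_haplotype`` maps position -> allele and must cover every
    position used by the gene's rules.
    """
    for rule in rules:
        for pos, _ in rule.signature:
            if pos not in gene_haplotype:
                raise RuleError(
                    f"haplotype does not cover position {pos} required by "
                    f"{rule.name}")
    matches = [r for r in rules if r.matches(gene_haplotype)]
    if len(matches) > 1:
        raise RuleError(
            "ambiguous match: " + ", ".join(r.name for r in matches))
    return matches[0].name if matches else UNASSIGNED


def variant_frequencies(em_results: dict[str, dict[str, EMResult]],
                        rules: list[ProteinVariantRule]) -> pd.DataFrame:
    """Per-breed protein-variant frequencies from per-gene EM fits.

    ``em_results`` maps gene -> (breed -> EMResult for that gene's SNP
    block).  A variant's frequency is the summed EM frequency of the SNP
    haplotypes mapping to it; unmatched mass is reported per gene under
    ``unassigned``.  Index: (gene, variant); columns: breeds.
    """
    grouped = rules_by_gene(rules)
    rows: dict[tuple[str, str], dict[str, float]] = {}
    for gene, per_breed in em_results.items():
        gene_rules = grouped[gene]
        for breed, res in per_breed.items():
            for hap, freq in zip(res.haplotypes, res.frequencies):
                name = call_variant(res.hap_alleles(hap), gene_rules)
                short = name.split("*", 1)[1] if name != UNASSIGNED else name
                key = (gene, short)
                rows.setdefault(key, {})
                rows[key][breed] = rows[key].get(breed, 0.0) + float(freq)
    df = pd.DataFrame.from_dict(rows, orient="index").fillna(0.0)
    df.index = pd.MultiIndex.from_tuples(df.index, names=["gene", "variant"])
    return df.sort_index()
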