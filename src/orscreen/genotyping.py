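"""Haplotype assignment from per-site variant calls.

Sanger sequencing of the OR10A6 and OR2W1 amplicons yields unphased diploid
genotype calls at a handful of coding SNPs (rs numbers). This module turns
those calls into a diplotype — an unordered pair of named haplotypes — by
enumerating every pair of defined haplotypes consistent with all per-site
genotypes. When several pairs are consistent (phase ambiguity), the pair with
the largest product of population haplotype frequencies is returned and an
ambiguity flag is set: a Sanger workflow cannot phase heterozygous sites
either, and the population frequencies are the only available prior.

The haplotype definition table (labels, rs sites, population frequencies,
functional status) ships with the package as a versioned CSV.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from itertools import combinations_with_replacement
from typing import Iterable, Mapping

import pandas as pd

from .errors import (
    InconsistentCallsError,
    MalformedRecordError,
    UnknownVariantError,
)

# Nominal ref/alt allele codes per site. The published record identifies the
# sites by rs number only; the single-letter codes below are synthetic
# placeholders — haplotype assignment depends only on the ref/alt identity of
# each call, never on the actual base.
SITE_ALLELES: dict[str, tuple[str, str]] = {
    "rs7928451": ("C", "T"),  # OR10A6 A117V
    "rs7933807": ("T", "G"),  # OR10A6 V140G
    "rs4758258": ("T", "C"),  # OR10A6 L287P
    "rs34892006": ("A", "G"),  # OR2W1 M81V
    "rs35771565": ("G", "A"),  # OR2W1 D296N
}


@dataclass(frozen=True)
class HaplotypeDef:
    """One named haplotype: the set of alternate-allele sites it carries."""

    gene: str
    label: str
    sites: frozenset[str]
    maf_pct: float | None
    freq_pct: float | None
    functional: bool

    def allele(self, site: str) -> str:
        ref, alt = SITE_ALLELES[site]
        return alt if site in self.sites else ref


@dataclass(frozen=True)
class DiplotypeCall:
    """Result of haplotype assignment for one gene in one individual."""

    gene: str
    hap1: str
    hap2: str
    ambiguous: bool

    @property
    def labels(self) -> tuple[str, str]:
        return (self.hap1, self.hap2)


@lru_cache(maxsize=1)
def load_haplotype_defs() -> pd.DataFrame:
    """The packaged haplotype definition table as a DataFrame."""
    path = resources.files("orscreen.data").joinpath("haplotype_defs.csv")
    with resources.as_file(path) as p:
        df = pd.read_csv(p, dtype={"sites": "string"})
    df["sites"] = df["sites"].fillna("")
    df["functional"] = df["functional"].astype(bool)
    return df


@lru_cache(maxsize=None)
def defs_for_gene(gene: str) -> tuple[HaplotypeDef, ...]:
    """Defined haplotypes of ``gene``, in table order."""
    df = load_haplotype_defs()
    sub = df[df["gene"] == gene]
    if sub.empty:
        raise UnknownVariantError(f"no haplotype definitions for gene {gene!r}")
    out = []
    for row in sub.itertuples(index=False):
        sites = frozenset(s for s in str(row.sites).split(";") if s)
        out.append(
            HaplotypeDef(
                gene=gene,
                label=row.haplotype,
                sites=sites,
                maf_pct=None if pd.isna(row.maf_pct) else float(row.maf_pct),
                freq_pct=None if pd.isna(row.freq_pct) else float(row.freq_pct),
                functional=bool(row.functional),
            )
        )
    return tuple(out)


def haplotype_frequencies(gene: str) -> dict[str, float]:
    """Population haplotype frequencies (percent); missing entries are 0."""
    return {d.label: (d.freq_pct or 0.0) for d in defs_for_gene(gene)}


def _def_by_label(gene: str, label: str) -> HaplotypeDef:
    for d in defs_for_gene(gene):
        if d.label == label:
            return d
    raise UnknownVariantError(f"unknown haplotype {label!r} for gene {gene}")


def gene_sites(gene: str) -> frozenset[str]:
    sites: set[str] = set()
    for d in defs_for_gene(gene):
        sites |= d.sites
    return frozenset(sites)


def assign_diplotype(
    calls: Mapping[str, tuple[str, str]], gene: str
) -> DiplotypeCall:
    """Assign the diplotype consistent with unphased per-site genotype calls.

    ``calls`` maps rs identifiers to the two (unordered) allele calls and must
    cover every site appearing in the gene's haplotype definitions.
    """
    sites = sorted(gene_sites(gene))
    missing = [s for s in sites if s not in calls]
    if missing:
        raise MalformedRecordError(f"{gene}: calls missing sites {missing}")
    observed = {}
    for s in sites:
        pair = calls[s]
        if len(pair) != 2:
            raise MalformedRecordError(f"{s}: expected exactly two allele calls")
        observed[s] = tuple(sorted(pair))

    defs = defs_for_gene(gene)
    consistent = []
    for h1, h2 in combinations_with_replacement(defs, 2):
        if all(tuple(sorted((h1.allele(s), h2.allele(s)))) == observed[s] for s in sites):
            consistent.append((h1, h2))
    if not consistent:
        alt_sites = [s for s in sites if observed[s] != tuple(sorted(SITE_ALLELES[s][0] * 2))]
        raise InconsistentCallsError(
            f"{gene}: no defined haplotype pair matches calls at sites {alt_sites or sites}"
        )

    ambiguous = len(consistent) > 1
    # Frequency-product prior; deterministic label sort breaks exact ties.
    best = max(
        consistent,
        key=lambda p: (
            (p[0].freq_pct or 0.0) * (p[1].freq_pct or 0.0),
            tuple(sorted((p[0].label, p[1].label), reverse=True)),
        ),
    )
    h1, h2 = sorted(best, key=lambda d: (d.label != "ref", d.label))
    return DiplotypeCall(gene=gene, hap1=h1.label, hap2=h2.label, ambiguous=ambiguous)


def genotypes_from_diplotype(
    gene: str, hap1: str, hap2: str
) -> dict[str, tuple[str, str]]:
    """Regenerate unphased per-site genotype calls from a diplotype."""
    d1, d2 = _def_by_label(gene, hap1), _def_by_label(gene, hap2)
    return {
        s: tuple(sorted((d1.allele(s), d2.allele(s)))) for s in sorted(gene_sites(gene))
    }


def _parse_variant(variant: str, gene: str | None) -> tuple[str, str]:
    if " " in variant:
        g, label = variant.split(" ", 1)
        return g, label
    if gene is None:
        raise UnknownVariantError(
            f"variant {variant!r} has no gene prefix and no gene was given"
        )
    return gene, variant


def is_carrier(
    diplotype: Iterable[str], variant: str, gene: str | None = None
) -> bool:
    """Whether either haplotype of ``diplotype`` carries the named variant.

    ``variant`` is a single-substitution label, optionally gene-prefixed
    (e.g. ``"OR10A6 L287P"``); carriage means the variant's site belongs to
    the haplotype's alternate-allele sites, so composite haplotypes such as
    A117V/V140G/L287P carry L287P.
    """
    g, label = _parse_variant(variant, gene)
    vdef = _def_by_label(g, label)
    if len(vdef.sites) != 1:
        raise UnknownVariantError(
            f"{variant!r} is not a single-site variant; carrier status undefined"
        )
    (site,) = vdef.sites
    hap_defs = [_def_by_label(g, h) for h in diplotype]
    return any(site in h.sites for h in hap_defs)


def carrier_labels(
    gene: str, variant: str, functional_only: bool = False
) -> frozenset[str]:
    """All haplotype labels of ``gene`` that carry ``variant``'s site.

    With ``functional_only`` the set is restricted to functional haplotypes:
    the non-functional triple mutant A117V/V140G/L287P carries the L287P site
    but confers no receptor function, so phenotype models condition on
    functional carriage.
    """
    g, label = _parse_variant(variant, gene)
    (site,) = _def_by_label(g, label).sites
    return frozenset(
        d.label
        for d in defs_for_gene(g)
        if site in d.sites and (d.functional or not functional_only)
    )


def is_functional_carrier(
    diplotype: Iterable[str], variant: str, gene: str | None = None
) -> bool:
    """Whether either haplotype is a functional haplotype bearing the variant."""
    g, label = _parse_variant(variant, gene)
    return any(h in carrier_labels(g, label, functional_only=True) for h in diplotype)


def assign_calls_table(calls: pd.DataFrame, gene: str) -> pd.DataFrame:
    """Assign diplotypes for a long-format calls table.

    ``calls`` columns: panelist_id, site, allele1, allele2. Returns one row
    per panelist: panelist_id, gene, hap1, hap2, ambiguous.
    """
    rows = []
    for pid, sub in calls.groupby("panelist_id", sort=True):
        mapping = {
            r.site: (str(r.allele1), str(r.allele2)) for r in sub.itertuples(index=False)
        }
        call = assign_diplotype(mapping, gene)
        rows.append(
            {
                "panelist_id": pid,
                "gene": gene,
                "hap1": call.hap1,
                "hap2": call.hap2,
                "ambiguous": call.ambiguous,
            }
        )
    return pd.DataFrame(rows)
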