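"""Post-genotyping SNP handling on a VCF-backed genotype table.

Mirrors a typical RAD-seq filtering sequence: completeness (loci present
in all populations and, optionally, in every individual), exclusion of
loci deviating from Hardy-Weinberg equilibrium in one or more species
(exact test, per-locus alpha = 0.05, no multiple-testing correction),
optional reduction to the first SNP per locus, then transition/
transversion and diagnostic (fixed inter-species difference)
classification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import GenotypeTable

__all__ = ["completeness_filter", "hwe_exact_pvalue", "hwe_filter",
           "first_snp_per_locus", "classify_snps", "SnpClassSummary",
           "filter_report"]

_TRANSITIONS = frozenset({frozenset("AG"), frozenset("CT")})


def completeness_filter(table: GenotypeTable, min_pops: int | None = None,
                        require_all_individuals: bool = True) -> GenotypeTable:
    """Keep loci genotyped in >= ``min_pops`` populations (default: all),
    and — when ``require_all_individuals`` — with no missing call in any
    retained population.  A locus is dropped as a whole, all its SNPs with it.
    """
    pops = table.populations
    if min_pops is None:
        min_pops = len(pops)
    per_pop_complete = np.ones((table.n_snps, len(pops)), dtype=bool)
    per_pop_present = np.ones((table.n_snps, len(pops)), dtype=bool)
    for j, pop in enumerate(pops):
        g = table.geno[:, table.pop_mask(pop)]
        n_missing = (g == -1).sum(axis=1)
        per_pop_complete[:, j] = n_missing == 0
        per_pop_present[:, j] = n_missing < g.shape[1]
    snp_ok = per_pop_present.sum(axis=1) >= min_pops
    if require_all_individuals:
        snp_ok &= per_pop_complete.all(axis=1)
    # propagate to whole loci: every SNP of the locus must pass
    ok = pd.Series(snp_ok).groupby(table.snps["locus"].values).transform("all")
    return table.subset_snps(ok.to_numpy())


def hwe_exact_pvalue(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided exact Hardy-Weinberg p-value on heterozygote counts.

    Conditional on the observed allele counts, sums the probabilities of
    all heterozygote configurations whose probability does not exceed that
    of the observed configuration (Wigginton-style exact test; no mid-p).
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        return 1.0
    n_a = 2 * n_hom_ref + n_het          # copies of one allele
    n_b = 2 * n_hom_alt + n_het
    n_minor = min(n_a, n_b)
    # possible het counts share the parity of the minor allele count
    hets = range(n_minor % 2, n_minor + 1, 2)
    lgamma = math.lgamma

    def logprob(h: int) -> float:
        ha = (n_a - h) // 2   # homozygotes of allele a
        hb = (n_b - h) // 2
        return (lgamma(n + 1) - lgamma(ha + 1) - lgamma(h + 1)
                - lgamma(hb + 1) + h * math.log(2.0)
                + lgamma(n_a + 1) + lgamma(n_b + 1) - lgamma(2 * n + 1))

    lp_obs = logprob(n_het)
    p = 0.0
    for h in hets:
        lp = logprob(h)
        if lp <= lp_obs + 1e-12:
            p += math.exp(lp)
    return min(p, 1.0)


def hwe_pvalues(table: GenotypeTable, pop: str) -> np.ndarray:
    """Per-SNP exact HWE p-values within one population (missing calls
    are simply not counted)."""
    counts = table.genotype_counts(pop)
    return np.array([hwe_exact_pvalue(int(a), int(b), int(c))
                     for a, b, c, _ in counts])


def hwe_filter(table: GenotypeTable, alpha: float = 0.05) -> GenotypeTable:
    """Drop every locus with an HWE-deviating SNP (p < alpha) in >= 1 population."""
    if not 0.0 <= alpha < 1.0:
        raise ValueError(f"alpha must be in [0, 1), got {alpha}")
    if alpha == 0.0 or table.n_snps == 0:
        return table.subset_snps(np.ones(table.n_snps, dtype=bool))
    deviates = np.zeros(table.n_snps, dtype=bool)
    for pop in table.populations:
        deviates |= hwe_pvalues(table, pop) < alpha
    locus_bad = pd.Series(deviates).groupby(table.snps["locus"].values).transform("any")
    return table.subset_snps(~locus_bad.to_numpy())


def first_snp_per_locus(table: GenotypeTable) -> GenotypeTable:
    """Keep only the lowest-position SNP of each locus (idempotent)."""
    if table.n_snps == 0:
        return table.subset_snps(np.ones(0, dtype=bool))
    pos = table.snps[["locus", "pos"]].reset_index()
    keep_idx = pos.sort_values(["locus", "pos"]).groupby("locus")["index"].first()
    mask = np.zeros(table.n_snps, dtype=bool)
    mask[keep_idx.to_numpy()] = True
    return table.subset_snps(mask)


@dataclass
class SnpClassSummary:
    """Per-SNP substitution classes and the study-style totals."""

    per_snp: pd.DataFrame        # columns: locus, pos, klass, diagnostic
    n_transitions: int
    n_transversions: int
    n_diagnostic: int


def classify_snps(table: GenotypeTable, pops: tuple[str, str]) -> SnpClassSummary:
    """Transition/transversion class per SNP plus the diagnostic flag
    (both populations fixed, for different alleles)."""
    klass = []
    for ref, alt in zip(table.snps["ref"], table.snps["alt"]):
        pair = frozenset((str(ref).upper(), str(alt).upper()))
        if not pair <= set("ACGT") or len(pair) != 2:
            raise ValueError(f"not a biallelic nucleotide SNP: {ref}/{alt}")
        klass.append("transition" if pair in _TRANSITIONS else "transversion")
    alt1, n1 = table.alt_counts(pops[0])
    alt2, n2 = table.alt_counts(pops[1])
    fixed1_ref = (alt1 == 0) & (n1 > 0)
    fixed1_alt = (alt1 == n1) & (n1 > 0)
    fixed2_ref = (alt2 == 0) & (n2 > 0)
    fixed2_alt = (alt2 == n2) & (n2 > 0)
    diagnostic = (fixed1_ref & fixed2_alt) | (fixed1_alt & fixed2_ref)
    per_snp = pd.DataFrame({
        "locus": table.snps["locus"],
        "pos": table.snps["pos"],
        "klass": klass,
        "diagnostic": diagnostic,
    })
    n_ts = int(sum(k == "transition" for k in klass))
    return SnpClassSummary(per_snp=per_snp,
                           n_transitions=n_ts,
                           n_transversions=table.n_snps - n_ts,
                           n_diagnostic=int(diagnostic.sum()))


def filter_report(stages: dict[str, GenotypeTable],
                  classify_pops: tuple[str, str] | None = None) -> pd.DataFrame:
    """Summary counts per filter stage (SNPs, loci; ts/tv/diagnostic for
    the final stage if ``classify_pops`` is given)."""
    rows = []
    names = list(stages)
    for i, name in enumerate(names):
        t = stages[name]
        row = {"stage": name, "n_snps": t.n_snps,
               "n_loci": t.snps["locus"].nunique()}
        if classify_pops and i == len(names) - 1 and t.n_snps:
            s = classify_snps(t, classify_pops)
            row.update(n_transitions=s.n_transitions,
                       n_transversions=s.n_transversions,
                       n_diagnostic=s.n_diagnostic)
        rows.append(row)
    return pd.DataFrame(rows)
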