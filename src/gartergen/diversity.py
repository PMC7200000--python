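"""Per-population genetic-diversity summaries.

Four SNP-wise statistics per population/period: mean observed
heterozygosity (Ho), mean expected heterozygosity (He, plug-in),
mean nucleotide diversity at variant sites (pi, the sample-size
corrected expected heterozygosity), and rarefied allelic richness
(Ar, hypergeometric rarefaction to a common number of gene copies).
He is the plug-in estimator 1 - sum(p^2) while pi carries the
2n/(2n-1) correction, so pi >= He on the same sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .genotype_io import MISSING, GenotypeMatrix, GenotypeValidationError


@dataclass
class DiversityRow:
    """One row of a diversity summary table."""

    population: str
    period: str
    n_mean: float  # mean non-missing individuals per locus
    ar: float
    ho: float
    he: float
    pi: float


def _pop_dosages(g: GenotypeMatrix, population: str, period: str | None = None):
    sub = g.subset(population, period)
    if sub.n_individuals == 0:
        raise GenotypeValidationError(f"population {population!r} is empty")
    return sub.dosages


def observed_heterozygosity(
    g: GenotypeMatrix, population: str, period: str | None = None
) -> tuple[np.ndarray, float]:
    """Per-locus Ho (heterozygote fraction among called genotypes) and its mean.

    Loci with no calls in the population are NaN and excluded from the mean.
    """
    d = _pop_dosages(g, population, period)
    called = d != MISSING
    n = called.sum(axis=0)
    het = (d == 1).sum(axis=0)
    with np.errstate(invalid="ignore"):
        ho = np.where(n > 0, het / np.maximum(n, 1), np.nan)
    return ho, float(np.nanmean(ho))


def expected_heterozygosity(
    g: GenotypeMatrix, population: str, period: str | None = None
) -> tuple[np.ndarray, float]:
    """Per-locus He = 1 - p^2 - q^2 (plug-in) and its mean."""
    d = _pop_dosages(g, population, period)
    called = d != MISSING
    copies = 2 * called.sum(axis=0)
    alt = np.where(called, d, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(copies > 0, alt / np.maximum(copies, 1), np.nan)
    he = 2 * p * (1 - p)
    return he, float(np.nanmean(he))


def nucleotide_diversity(
    g: GenotypeMatrix, population: str, period: str | None = None
) -> tuple[np.ndarray, float]:
    """Per-locus pi = (2n/(2n-1)) * He_plugin and its mean.

    pi is the mean pairwise difference per variant site — the unbiased
    expected-heterozygosity estimator. Loci with fewer than two gene
    copies are skipped (NaN) with a warning.
    """
    d = _pop_dosages(g, population, period)
    called = d != MISSING
    copies = 2 * called.sum(axis=0)
    alt = np.where(called, d, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(copies >= 2, alt / np.maximum(copies, 1), np.nan)
        pi = copies / np.maximum(copies - 1, 1) * 2 * p * (1 - p)
    if (copies < 2).any():
        import warnings

        warnings.warn(
            f"{int((copies < 2).sum())} loci with <2 gene copies skipped",
            stacklevel=2,
        )
    return pi, float(np.nanmean(pi))


def _log_comb(n: np.ndarray, k: float) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def rarefied_allelic_richness(
    g: GenotypeMatrix,
    population: str,
    g_copies: int,
    period: str | None = None,
) -> tuple[np.ndarray, float]:
    """Per-locus rarefied allele count at ``g_copies`` gene copies, and mean.

    Hypergeometric rarefaction: the expected number of distinct alleles
    in a random draw of ``g_copies`` gene copies,

        Ar = sum_a [ 1 - C(2n - n_a, g) / C(2n, g) ],

    where ``n_a`` counts copies of allele ``a`` among the ``2n``
    non-missing copies at the locus. ``g_copies`` may not exceed the
    smallest per-locus copy count in the population.
    """
    if g_copies < 2:
        raise GenotypeValidationError("g_copies must be >= 2")
    d = _pop_dosages(g, population, period)
    called = d != MISSING
    copies = 2 * called.sum(axis=0)
    if (copies < g_copies).any():
        raise GenotypeValidationError(
            f"g_copies={g_copies} exceeds the minimum per-locus gene-copy "
            f"count ({int(copies.min())}) in {population!r}"
        )
    alt = np.where(called, d, 0).sum(axis=0)
    ref = copies - alt
    ar = np.zeros(d.shape[1])
    for counts in (ref, alt):
        with np.errstate(invalid="ignore"):
            # P(allele absent from the subsample) via log-combinatorics
            log_p_absent = _log_comb(copies - counts, g_copies) - _log_comb(
                copies, g_copies
            )
        p_absent = np.where(copies - counts >= g_copies, np.exp(log_p_absent), 0.0)
        ar += np.where(counts > 0, 1.0 - p_absent, 0.0)
    return ar, float(np.mean(ar))


def diversity_table(
    g: GenotypeMatrix,
    g_copies: int | None = None,
    by_period: bool = True,
) -> pd.DataFrame:
    """Diversity summary with one row per population (and period).

    ``g_copies`` defaults to the smallest per-locus gene-copy count over
    all groups, so allelic richness is rarefied to a common baseline.
    """
    groups: list[tuple[str, str | None]] = []
    for pop in g.populations():
        if by_period:
            for per in pd.unique(g.period[g.pop_mask(pop)]):
                groups.append((pop, per))
        else:
            groups.append((pop, None))

    if g_copies is None:
        mins = []
        for pop, per in groups:
            d = _pop_dosages(g, pop, per)
            mins.append(int(2 * (d != MISSING).sum(axis=0).min()))
        g_copies = min(mins)

    rows = []
    for pop, per in groups:
        d = _pop_dosages(g, pop, per)
        n_mean = float((d != MISSING).sum(axis=0).mean())
        _, ho = observed_heterozygosity(g, pop, per)
        _, he = expected_heterozygosity(g, pop, per)
        _, pi = nucleotide_diversity(g, pop, per)
        _, ar = rarefied_allelic_richness(g, pop, g_copies, per)
        rows.append(
            DiversityRow(pop, per if per is not None else "", n_mean, ar, ho, he, pi)
        )
    return pd.DataFrame(
        {
            "population": [r.population for r in rows],
            "period": [r.period for r in rows],
            "N": [r.n_mean for r in rows],
            "Ar": [r.ar for r in rows],
            "Ho": [r.ho for r in rows],
            "He": [r.he for r in rows],
            "pi": [r.pi for r in rows],
        }
    )
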