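"""Population differentiation: Weir-Cockerham theta, permutation
significance, Bonferroni correction, and Mantel isolation-by-distance.

Theta is the variance-components estimator of FST for diploid data.
Per locus, three components are computed: a (among populations),
b (among individuals within populations) and c (within individuals);
the multi-locus estimate is the ratio of sums, sum(a) / sum(a+b+c).
Negative estimates are reported as computed, not truncated at zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix, GenotypeValidationError
from .geo import great_circle_km


@dataclass
class ThetaMatrix:
    """Pairwise theta with permutation p-values and a global estimate."""

    populations: list[str]
    theta: pd.DataFrame
    p_values: pd.DataFrame | None
    global_theta: float
    bonferroni_alpha: float | None = None


@dataclass
class IbdResult:
    """Mantel isolation-by-distance summary."""

    r: float
    r_squared: float
    p_value: float
    n_permutations: int
    geo_dist_km: pd.DataFrame | None = None


def _components(g: GenotypeMatrix, pops: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus (a, a+b+c) Weir-Cockerham variance components.

    Loci with fewer than two populations containing data, or monomorphic
    over the chosen populations, contribute NaN.
    """
    r_arrays = []
    for pop in pops:
        d = g.dosages[g.pop_mask(pop)]
        r_arrays.append(d)

    L = g.n_loci
    n_i = np.zeros((len(pops), L))
    p_i = np.zeros((len(pops), L))
    h_i = np.zeros((len(pops), L))
    for k, d in enumerate(r_arrays):
        called = d != MISSING
        n = called.sum(axis=0)
        n_i[k] = n
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i[k] = np.where(n > 0, np.where(called, d, 0).sum(axis=0) / (2 * np.maximum(n, 1)), np.nan)
            h_i[k] = np.where(n > 0, (d == 1).sum(axis=0) / np.maximum(n, 1), np.nan)

    valid = (n_i > 0).all(axis=0)
    r = len(pops)
    with np.errstate(invalid="ignore", divide="ignore"):
        n_bar = n_i.mean(axis=0)
        n_tot = n_i.sum(axis=0)
        n_c = (n_tot - (n_i**2).sum(axis=0) / n_tot) / (r - 1)
        p_bar = (n_i * p_i).sum(axis=0) / n_tot
        s2 = (n_i * (p_i - p_bar) ** 2).sum(axis=0) / ((r - 1) * n_bar)
        h_bar = (n_i * h_i).sum(axis=0) / n_tot

        inner = p_bar * (1 - p_bar) - (r - 1) / r * s2
        a = n_bar / n_c * (s2 - (inner - h_bar / 4) / (n_bar - 1))
        b = n_bar / (n_bar - 1) * (inner - (2 * n_bar - 1) / (4 * n_bar) * h_bar)
        c = h_bar / 2

    poly = valid & (p_bar > 0) & (p_bar < 1) & (n_bar > 1)
    a = np.where(poly, a, np.nan)
    total = np.where(poly, a + b + c, np.nan)
    return a, total


def wc_theta(
    g: GenotypeMatrix,
    pops: list[str] | None = None,
    n_perm: int = 0,
    alpha: float = 0.05,
    seed: int | None = None,
) -> ThetaMatrix:
    """Pairwise (and global) multi-locus theta over the given populations.

    With ``n_perm > 0`` each pair also gets a permutation p-value
    (individual site labels shuffled), and the Bonferroni-corrected
    alpha for the number of pairs is recorded.
    """
    pops = pops if pops is not None else g.populations()
    if len(pops) < 2:
        raise GenotypeValidationError("need at least two populations")
    for pop in pops:
        if int(g.pop_mask(pop).sum()) < 2:
            raise GenotypeValidationError(f"population {pop!r} has <2 individuals")

    k = len(pops)
    theta = np.full((k, k), np.nan)
    pvals = np.full((k, k), np.nan)
    rng = np.random.default_rng(seed)
    for i in range(k):
        for j in range(i + 1, k):
            pair = [pops[i], pops[j]]
            t = _pair_theta(g, pair)
            theta[i, j] = theta[j, i] = t
            if n_perm:
                pvals[i, j] = pvals[j, i] = theta_permutation_test(
                    g, pair, n_perm, rng=rng
                )
    np.fill_diagonal(theta, 0.0)

    a, total = _components(g, pops)
    global_theta = float(np.nansum(a) / np.nansum(total))
    n_tests = k * (k - 1) // 2
    return ThetaMatrix(
        populations=pops,
        theta=pd.DataFrame(theta, index=pops, columns=pops),
        p_values=pd.DataFrame(pvals, index=pops, columns=pops) if n_perm else None,
        global_theta=global_theta,
        bonferroni_alpha=bonferroni_alpha(n_tests, alpha) if n_perm else None,
    )


def _pair_theta(g: GenotypeMatrix, pair: list[str]) -> float:
    a, total = _components(g, pair)
    denom = np.nansum(total)
    if not np.isfinite(denom) or denom == 0 or np.all(np.isnan(total)):
        raise GenotypeValidationError(
            f"no shared polymorphic loci between {pair[0]!r} and {pair[1]!r}"
        )
    return float(np.nansum(a) / denom)


def theta_permutation_test(
    g: GenotypeMatrix,
    pair: list[str],
    n_perm: int = 999,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> float:
    """Permutation p-value for pairwise theta.

    Individual population labels are shuffled between the two sites;
    p = (1 + #{theta_perm >= theta_obs}) / (n_perm + 1).
    """
    if n_perm < 99:
        raise GenotypeValidationError("n_perm must be >= 99")
    rng = rng if rng is not None else np.random.default_rng(seed)
    obs = _pair_theta(g, pair)
    mask = g.pop_mask(pair[0]) | g.pop_mask(pair[1])
    sub = g.take_individuals(np.flatnonzero(mask))
    labels = sub.population.copy()
    hits = 0
    for _ in range(n_perm):
        sub.population = rng.permutation(labels)
        try:
            if _pair_theta(sub, pair) >= obs - 1e-15:
                hits += 1
        except GenotypeValidationError:
            # a permutation can leave no polymorphic information; count as
            # not exceeding the observed value
            continue
    sub.population = labels
    return (1 + hits) / (n_perm + 1)


def bonferroni_alpha(n_tests: int, alpha: float = 0.05) -> float:
    """Bonferroni-corrected per-test significance level."""
    if n_tests < 1:
        raise GenotypeValidationError("n_tests must be >= 1")
    return alpha / n_tests


def geographic_distance_matrix(sites) -> pd.DataFrame:
    """Great-circle distance matrix (km) from a list of SiteMetadata."""
    names = [s.site for s in sites]
    k = len(sites)
    d = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            d[i, j] = d[j, i] = great_circle_km(
                sites[i].latitude, sites[i].longitude,
                sites[j].latitude, sites[j].longitude,
            )
    return pd.DataFrame(d, index=names, columns=names)


def mantel_test(
    gen_dist: np.ndarray | pd.DataFrame,
    geo_dist: np.ndarray | pd.DataFrame,
    n_perm: int = 1000,
    seed: int | None = None,
) -> IbdResult:
    """Mantel correlation between two distance matrices.

    r is the Pearson correlation of the off-diagonal elements; the
    p-value permutes population labels jointly on rows and columns of
    the genetic matrix; two-sided by magnitude of r.
    """
    gd = np.asarray(gen_dist, dtype=float)
    hd = np.asarray(geo_dist, dtype=float)
    if gd.shape != hd.shape or gd.ndim != 2 or gd.shape[0] != gd.shape[1]:
        raise GenotypeValidationError("distance matrices must share a square shape")
    n = gd.shape[0]
    if n < 3:
        raise GenotypeValidationError("need at least 3 populations")
    if not (np.allclose(gd, gd.T) and np.allclose(hd, hd.T)):
        raise GenotypeValidationError("distance matrices must be symmetric")

    iu = np.triu_indices(n, k=1)

    def corr(mat: np.ndarray) -> float:
        x, y = mat[iu], hd[iu]
        sx, sy = x.std(), y.std()
        if sx == 0 or sy == 0:
            return np.nan
        return float(np.corrcoef(x, y)[0, 1])

    r_obs = corr(gd)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if abs(corr(gd[np.ix_(perm, perm)])) >= abs(r_obs) - 1e-15:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    geo_df = geo_dist if isinstance(geo_dist, pd.DataFrame) else None
    return IbdResult(r=r_obs, r_squared=r_obs**2, p_value=p,
                     n_permutations=n_perm, geo_dist_km=geo_df)
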