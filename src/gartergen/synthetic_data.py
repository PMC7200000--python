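"""Synthetic genotype and capture-history generators.

These generators produce data with the statistical structure the
analysis modules assume, so the whole pipeline is testable without
field or sequence data.

Wright-Fisher simulator
-----------------------
Two modes:

* ``"individual"`` (default): the deme is a set of N diploid
  genotypes; each offspring draws two parents uniformly at random
  (an ideal monoecious population, selfing allowed) and inherits one
  allele per locus from each, with loci transmitted independently
  (free recombination). Finite parent numbers generate the composite
  linkage disequilibrium among unlinked loci that the LD-based Ne
  estimator measures, in addition to allele-frequency drift.
* ``"frequency"``: only allele frequencies are tracked (binomial
  resampling of 2N gene copies per generation); sampled genotypes are
  assembled under Hardy-Weinberg. Much faster, carries the correct
  drift signal for temporal-method work, but by construction has no
  inter-locus associations.

Migration follows a symmetric island model: each gene copy (frequency
mode) or parent draw (individual mode) originates from a random other
deme with probability m.

Capture-history simulator
-------------------------
Individuals get sex, snout-vent length (SVL) and per-occasion capture
probabilities from the same logit-linear model fitted by the CMR
module (intercept, air-temperature, sex, SVL and previous-capture
effects; optional date/individual random effects). Individuals never
captured are absent from the returned dataset but present in the truth
record.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cmr import CaptureDataset
from .genotype_io import MISSING, GenotypeMatrix


@dataclass
class WrightFisherConfig:
    """Forward-in-time simulation settings for an island model."""

    deme_sizes: list[int]
    n_loci: int
    generations: int
    migration: float = 0.0
    #: (generation, deme index, diploid sample size) triples
    sampling: list[tuple[int, int, int]] = field(default_factory=list)
    init_freq_range: tuple[float, float] = (0.05, 0.95)
    missing_rate: float = 0.0
    inbreeding_f: float = 0.0  # excess homozygosity at sampling (frequency mode)
    mode: str = "individual"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.migration < 1):
            raise ValueError("migration must be in [0, 1)")
        if self.mode not in ("individual", "frequency"):
            raise ValueError(f"unknown mode {self.mode!r}")
        for gen, deme, size in self.sampling:
            if not (0 <= deme < len(self.deme_sizes)):
                raise ValueError(f"sample references unknown deme {deme}")
            if size > self.deme_sizes[deme]:
                raise ValueError("sample size exceeds deme size")
            if not (0 <= gen <= self.generations):
                raise ValueError("sample generation outside the simulated range")


def _assemble_hw(
    rng: np.random.Generator, freqs: np.ndarray, n: int, f_is: float
) -> np.ndarray:
    """Diploid dosages for n individuals under HW (optionally with
    excess homozygosity f_is)."""
    if f_is == 0.0:
        a1 = rng.random((n, freqs.size)) < freqs
        a2 = rng.random((n, freqs.size)) < freqs
        return (a1.astype(np.int16) + a2.astype(np.int16))
    p = freqs
    p_hom_alt = p**2 + f_is * p * (1 - p)
    p_het = 2 * p * (1 - p) * (1 - f_is)
    u = rng.random((n, freqs.size))
    return np.where(u < p_hom_alt, 2, np.where(u < p_hom_alt + p_het, 1, 0)).astype(
        np.int16
    )


def _apply_missing(
    rng: np.random.Generator, dosages: np.ndarray, rate: float
) -> np.ndarray:
    if rate <= 0:
        return dosages
    mask = rng.random(dosages.shape) < rate
    out = dosages.copy()
    out[mask] = MISSING
    return out


def simulate_wright_fisher(cfg: WrightFisherConfig) -> dict[tuple[int, int], GenotypeMatrix]:
    """Run the simulation and return one GenotypeMatrix per scheduled sample.

    Keys are ``(generation, deme)``. Samples taken at the same
    generation from the same deme state are drawn without replacement.
    """
    rng = np.random.default_rng(cfg.seed)
    D = len(cfg.deme_sizes)
    L = cfg.n_loci
    lo, hi = cfg.init_freq_range
    init = rng.uniform(lo, hi, size=L)
    schedule: dict[int, list[tuple[int, int]]] = {}
    for gen, deme, size in cfg.sampling:
        schedule.setdefault(gen, []).append((deme, size))

    out: dict[tuple[int, int], GenotypeMatrix] = {}
    counter = 0

    def take_sample(gen: int, deme: int, dosages: np.ndarray) -> None:
        nonlocal counter
        dosages = _apply_missing(rng, dosages, cfg.missing_rate)
        n = dosages.shape[0]
        ids = [f"d{deme}_g{gen}_i{k}_{counter + k}" for k in range(n)]
        counter += n
        out[(gen, deme)] = GenotypeMatrix(
            sample_ids=ids,
            locus_ids=[f"L{j}" for j in range(L)],
            dosages=dosages,
            population=np.array([f"deme{deme}"] * n, dtype=object),
            period=np.array([f"gen{gen}"] * n, dtype=object),
        )

    if cfg.mode == "frequency":
        freqs = np.tile(init, (D, 1))
        for gen in range(cfg.generations + 1):
            for deme, size in schedule.get(gen, []):
                take_sample(
                    gen, deme, _assemble_hw(rng, freqs[deme], size, cfg.inbreeding_f)
                )
            if gen == cfg.generations:
                break
            if D > 1 and cfg.migration > 0:
                others = (freqs.sum(axis=0) - freqs) / (D - 1)
                freqs = (1 - cfg.migration) * freqs + cfg.migration * others
            for d in range(D):
                n2 = 2 * cfg.deme_sizes[d]
                freqs[d] = rng.binomial(n2, freqs[d]) / n2
        return out

    # individual mode: genotype matrices per deme
    demes = [
        _assemble_hw(rng, init, n, 0.0) for n in cfg.deme_sizes
    ]
    for gen in range(cfg.generations + 1):
        for deme, size in schedule.get(gen, []):
            idx = rng.choice(cfg.deme_sizes[deme], size=size, replace=False)
            take_sample(gen, deme, demes[deme][idx])
        if gen == cfg.generations:
            break
        new_demes = []
        for d in range(D):
            n = cfg.deme_sizes[d]
            # parental deme per parent draw (island migration)
            child = np.zeros((n, L), dtype=np.int16)
            for _parent in range(2):
                if D > 1 and cfg.migration > 0:
                    src = np.where(
                        rng.random(n) < cfg.migration,
                        (d + rng.integers(1, D, size=n)) % D,
                        d,
                    )
                else:
                    src = np.full(n, d)
                picks = np.empty(n, dtype=np.int64)
                for s in range(D):
                    m = src == s
                    picks[m] = rng.integers(0, cfg.deme_sizes[s], size=int(m.sum()))
                # gamete: one allele per locus from the chosen parent
                gam = np.empty((n, L), dtype=np.int16)
                for s in range(D):
                    m = src == s
                    if m.any():
                        pg = demes[s][picks[m]]
                        gam[m] = (rng.random(pg.shape) < pg / 2.0).astype(np.int16)
                child += gam
            new_demes.append(child)
        demes = new_demes
    return out


# ---------------------------------------------------------------------
# Capture histories
# ---------------------------------------------------------------------

@dataclass
class CaptureSimConfig:
    """Closed-population capture-history simulation settings."""

    n_true: int
    n_occasions: int
    site: str = "site1"
    p_intercept: float = 0.2  # mean capture probability (probability scale)
    beta_temp: float = 0.0
    beta_sex: float = 0.0  # effect of being male (logit scale)
    beta_svl: float = 0.0
    beta_behavior: float = 0.0
    sd_date: float = 0.0
    sd_individual: float = 0.0
    sex_ratio: float = 0.5  # P(male)
    svl_mean: float = 450.0  # mm
    svl_sd: float = 80.0
    temperature: np.ndarray | None = None  # per-occasion air temp (deg C)
    start_date: str = "2018-04-05"
    seed: int = 0


def simulate_capture_histories(
    cfg: CaptureSimConfig,
) -> tuple[CaptureDataset, pd.DataFrame]:
    """Simulate daily captures of a closed population.

    Returns the observed dataset (individuals captured at least once)
    and a truth record with one row per *true* individual, including
    those never captured.
    """
    rng = np.random.default_rng(cfg.seed)
    N, D = cfg.n_true, cfg.n_occasions
    male = rng.random(N) < cfg.sex_ratio
    svl = rng.normal(cfg.svl_mean, cfg.svl_sd, size=N)
    temp = (
        np.asarray(cfg.temperature, dtype=float)
        if cfg.temperature is not None
        else rng.normal(16.0, 3.0, size=D)
    )
    if temp.size != D:
        raise ValueError("temperature series length must equal n_occasions")
    temp_z = (temp - temp.mean()) / (temp.std() if temp.std() > 0 else 1.0)
    svl_z = (svl - svl.mean()) / (svl.std() if svl.std() > 0 else 1.0)

    e_ind = rng.normal(0.0, cfg.sd_individual, size=N) if cfg.sd_individual else np.zeros(N)
    b_date = rng.normal(0.0, cfg.sd_date, size=D) if cfg.sd_date else np.zeros(D)

    mu = np.log(cfg.p_intercept / (1 - cfg.p_intercept))
    y = np.zeros((N, D), dtype=np.int8)
    prev = np.zeros(N)
    for d in range(D):
        eta = (
            mu
            + b_date[d]
            + e_ind
            + cfg.beta_temp * temp_z[d]
            + cfg.beta_sex * male
            + cfg.beta_svl * svl_z
            + cfg.beta_behavior * prev
        )
        p = 1.0 / (1.0 + np.exp(-eta))
        y[:, d] = rng.random(N) < p
        prev = y[:, d].astype(float)

    dates = pd.date_range(cfg.start_date, periods=D, freq="D")
    truth = pd.DataFrame(
        {
            "individual_id": [f"{cfg.site}_t{i}" for i in range(N)],
            "sex": np.where(male, "M", "F"),
            "svl_mm": svl,
            "captured": y.sum(axis=1) > 0,
            "n_captures": y.sum(axis=1),
        }
    )
    seen = np.flatnonzero(y.sum(axis=1) > 0)
    individuals = pd.DataFrame(
        {
            "individual_id": [f"{cfg.site}_t{i}" for i in seen],
            "sex": np.where(male[seen], "M", "F"),
            "svl_mm": svl[seen],
        }
    )
    dataset = CaptureDataset(
        site=cfg.site,
        occasions=list(dates.strftime("%Y-%m-%d")),
        air_temp=temp,
        individuals=individuals,
        captures=y[seen].astype(np.int8),
    )
    return dataset, truth
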