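"""Bayesian closed-population abundance estimation from capture histories.

The core model is a closed-population multinomial mixture fitted by
parameter-expanded data augmentation: the observed capture histories
are padded with all-zero pseudo-histories to a fixed pool of M rows,
each row carries a latent inclusion indicator z_i ~ Bernoulli(psi),
and site abundance is N_s = sum_i z_i * 1[g_i = s] where g_i is the
(latent, for pseudo rows) site membership with a flat Dirichlet prior.
Capture probability follows a logit-linear model

    logit p_id = logit(p_mean) + a_site + b_site,date + e_ind
                 + bT * temp + bSex * male + bSVL * svl + bBeh * c_id

with Uniform(0,1) prior on the mean capture probability, Normal(0,
3.16) priors on fixed effects, half-Cauchy(1) priors on random-effect
SDs, and c_id = 1 iff the individual was observed captured on the
previous day. Unknown sexes are imputed from a per-site Bernoulli with
uniform prior; missing (pseudo) standardized SVL from a standard
normal.

Two sampler paths share one interface: a fully conjugate Gibbs sampler
when capture probability is constant (no covariates, no random
effects), and Metropolis-within-Gibbs for the covariate/random-effects
model. Posterior summaries follow the reporting conventions of
closed-population monitoring studies: the posterior mode of integer
abundance and the shortest 95% highest-posterior-density interval.

A Huggins-type conditional-likelihood estimator (likelihood of each
observed history divided by its probability of being captured at
least once, abundance by Horvitz-Thompson summation) is provided as a
separately testable alternative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special

_SEXES = ("F", "M", "U")


class CmrError(ValueError):
    """Raised on invalid capture data or model configuration."""


class MSaturationError(CmrError):
    """Posterior abundance piles up at the augmentation pool capacity."""


# ---------------------------------------------------------------------
# Data containers
# ---------------------------------------------------------------------

@dataclass
class CaptureDataset:
    """Daily capture records for one site.

    ``captures`` is an (n_observed x n_occasions) 0/1 matrix; every
    observed individual must be captured at least once.
    """

    site: str
    occasions: list[str]  # ISO dates
    air_temp: np.ndarray  # per-occasion air temperature (deg C)
    individuals: pd.DataFrame  # individual_id, sex in {F,M,U}, svl_mm
    captures: np.ndarray

    def __post_init__(self) -> None:
        self.captures = np.asarray(self.captures, dtype=np.int8)
        self.air_temp = np.asarray(self.air_temp, dtype=float)
        n, d = self.captures.shape if self.captures.size else (0, len(self.occasions))
        if self.captures.size == 0:
            self.captures = self.captures.reshape(0, len(self.occasions))
        if d != len(self.occasions) or self.air_temp.size != len(self.occasions):
            raise CmrError("occasions, temperatures and capture columns disagree")
        if len(self.individuals) != self.captures.shape[0]:
            raise CmrError("individual table and capture matrix disagree")
        if self.captures.shape[0] and (self.captures.sum(axis=1) == 0).any():
            raise CmrError("observed individuals must have >= 1 capture")
        bad_sex = ~self.individuals["sex"].isin(_SEXES)
        if bad_sex.any():
            raise CmrError(f"invalid sex codes: {set(self.individuals['sex'][bad_sex])}")
        svl = self.individuals["svl_mm"]
        if ((svl.notna()) & (svl <= 0)).any():
            raise CmrError("SVL must be positive where present")

    @property
    def n_observed(self) -> int:
        return self.captures.shape[0]

    @property
    def n_occasions(self) -> int:
        return len(self.occasions)


def read_capture_csvs(captures_path, occasions_path) -> list[CaptureDataset]:
    """Read long-format capture records plus an occasions table.

    ``captures_path``: individual_id, site, date (ISO-8601), sex, svl_mm
    (one row per capture event). ``occasions_path``: site, date,
    air_temp_C — defines the full occasion set per site.
    """
    caps = pd.read_csv(captures_path, dtype={"individual_id": str}, comment="#")
    occ = pd.read_csv(occasions_path, comment="#")
    datasets = []
    for site, occ_site in occ.groupby("site"):
        occ_site = occ_site.sort_values("date")
        dates = list(occ_site["date"].astype(str))
        date_index = {d: j for j, d in enumerate(dates)}
        sub = caps[caps["site"] == site]
        ids = list(pd.unique(sub["individual_id"]))
        y = np.zeros((len(ids), len(dates)), dtype=np.int8)
        meta = []
        for i, ind in enumerate(ids):
            rows = sub[sub["individual_id"] == ind]
            for d in rows["date"].astype(str):
                if d not in date_index:
                    raise CmrError(f"capture of {ind} on {d} outside occasions of {site}")
                y[i, date_index[d]] = 1
            meta.append(
                {
                    "individual_id": ind,
                    "sex": rows["sex"].iloc[0],
                    "svl_mm": rows["svl_mm"].iloc[0],
                }
            )
        datasets.append(
            CaptureDataset(
                site=str(site),
                occasions=dates,
                air_temp=occ_site["air_temp_C"].to_numpy(dtype=float),
                individuals=pd.DataFrame(meta, columns=["individual_id", "sex", "svl_mm"]),
                captures=y,
            )
        )
    return datasets


@dataclass
class AugmentedData:
    """Observed histories plus all-zero pseudo-histories, pooled over sites.

    Occasions of all sites are concatenated on one axis; each row's
    capture opportunities are the occasion block of its (fixed or
    latent) site.
    """

    sites: list[str]
    occasion_site: np.ndarray  # site index per occasion column
    temp_z: np.ndarray  # standardized air temperature per occasion
    y: np.ndarray  # M x D_total (pseudo rows all zero)
    observed: np.ndarray  # bool per row
    site_index: np.ndarray  # fixed site per observed row, -1 for pseudo
    male: np.ndarray  # 1/0/nan per row (nan = unknown / pseudo)
    svl_z: np.ndarray  # standardized SVL, nan where missing
    behavior: np.ndarray  # M x D_total previous-day observed capture

    @property
    def m_total(self) -> int:
        return self.y.shape[0]

    @property
    def n_observed(self) -> int:
        return int(self.observed.sum())


def build_augmented_data(
    data: list[CaptureDataset] | CaptureDataset, m_total: int
) -> AugmentedData:
    """Pad observed capture histories to a pool of exactly ``m_total`` rows.

    Covariate standardization (temperature, SVL) uses observed-data
    means and SDs. The behavioral covariate marks occasions directly
    following an *observed* capture; it is zero on each site's first
    occasion and for all pseudo rows.
    """
    if isinstance(data, CaptureDataset):
        data = [data]
    if not data:
        raise CmrError("need at least one capture dataset")
    n_obs = sum(d.n_observed for d in data)
    if m_total < n_obs:
        raise CmrError(
            f"m_total={m_total} smaller than the {n_obs} observed individuals"
        )
    sites = [d.site for d in data]
    if len(set(sites)) != len(sites):
        raise CmrError("duplicate site in capture datasets")

    occasion_site = np.concatenate(
        [np.full(d.n_occasions, k) for k, d in enumerate(data)]
    )
    temps = np.concatenate([d.air_temp for d in data])
    temp_z = (temps - temps.mean()) / (temps.std() if temps.std() > 0 else 1.0)

    d_total = occasion_site.size
    y = np.zeros((m_total, d_total), dtype=np.int8)
    site_index = np.full(m_total, -1, dtype=np.int64)
    male = np.full(m_total, np.nan)
    svl_raw = np.full(m_total, np.nan)
    row = 0
    col = 0
    for k, d in enumerate(data):
        n, dd = d.captures.shape
        y[row : row + n, col : col + dd] = d.captures
        site_index[row : row + n] = k
        sex = d.individuals["sex"].to_numpy()
        male[row : row + n] = np.where(sex == "M", 1.0, np.where(sex == "F", 0.0, np.nan))
        svl_raw[row : row + n] = d.individuals["svl_mm"].to_numpy(dtype=float)
        row += n
        col += dd
    observed = np.zeros(m_total, dtype=bool)
    observed[:n_obs] = True

    obs_svl = svl_raw[np.isfinite(svl_raw)]
    mu = obs_svl.mean() if obs_svl.size else 0.0
    sd = obs_svl.std() if obs_svl.size > 1 and obs_svl.std() > 0 else 1.0
    svl_z = (svl_raw - mu) / sd

    behavior = np.zeros_like(y)
    for k in range(len(data)):
        cols = np.flatnonzero(occasion_site == k)
        behavior[:, cols[1:]] = y[:, cols[:-1]]
    return AugmentedData(
        sites=sites,
        occasion_site=occasion_site,
        temp_z=temp_z,
        y=y,
        observed=observed,
        site_index=site_index,
        male=male,
        svl_z=svl_z,
        behavior=behavior,
    )


# ---------------------------------------------------------------------
# Posterior container and summaries
# ---------------------------------------------------------------------

@dataclass
class CmrConfig:
    """Sampler settings. Defaults follow the monitoring protocol the
    model reproduces (5 chains, 200k iterations, 10k burn-in, thin 10);
    tests and examples use far smaller runs."""

    chains: int = 5
    iterations: int = 200_000
    burn_in: int = 10_000
    thin: int = 10
    seed: int = 0
    # model structure
    use_temperature: bool = True
    use_sex: bool = True
    use_svl: bool = True
    use_behavior: bool = True
    re_site: bool = True
    re_date: bool = True
    re_individual: bool = True
    proposal_scale: float = 0.15
    rhat_warn: float = 1.1

    @property
    def constant_p(self) -> bool:
        return not (
            self.use_temperature
            or self.use_sex
            or self.use_svl
            or self.use_behavior
            or self.re_site
            or self.re_date
            or self.re_individual
        )


def constant_p_config(**kwargs) -> CmrConfig:
    """Config for the intercept-only model (conjugate Gibbs path)."""
    return CmrConfig(
        use_temperature=False,
        use_sex=False,
        use_svl=False,
        use_behavior=False,
        re_site=False,
        re_date=False,
        re_individual=False,
        **kwargs,
    )


@dataclass
class CmrPosterior:
    """Thinned posterior draws with chain metadata and diagnostics."""

    sites: list[str]
    n_draws: np.ndarray  # (chains, draws, n_sites) integer abundance
    males: np.ndarray  # (chains, draws, n_sites)
    females: np.ndarray  # (chains, draws, n_sites)
    scalars: dict[str, np.ndarray]  # name -> (chains, draws)
    config: CmrConfig
    diagnostics: pd.DataFrame | None = None

    def site_draws(self, site: str) -> np.ndarray:
        s = self.sites.index(site)
        return self.n_draws[:, :, s].reshape(-1)

    def scalar_draws(self, name: str) -> np.ndarray:
        return self.scalars[name].reshape(-1)


def posterior_mode(draws: np.ndarray) -> int:
    """Most frequent integer value; ties break toward the smaller value."""
    draws = np.asarray(draws, dtype=np.int64)
    if draws.size == 0:
        raise CmrError("no draws")
    offset = draws.min()
    counts = np.bincount(draws - offset)
    return int(np.argmax(counts) + offset)


def hpdi(draws: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval of sorted draws holding ``level`` mass."""
    draws = np.sort(np.asarray(draws, dtype=float))
    n = draws.size
    if n < 20:
        raise CmrError("need at least 20 draws for an HPDI")
    m = int(np.ceil(level * n))
    widths = draws[m - 1 :] - draws[: n - m + 1]
    start = int(np.argmin(widths))
    return float(draws[start]), float(draws[start + m - 1])


def covariate_evidence(draws: np.ndarray, threshold: float = 0.9) -> tuple[float, bool]:
    """Posterior probability that a coefficient shares its median's sign."""
    draws = np.asarray(draws, dtype=float)
    med = np.median(draws)
    if med == 0:
        return 0.5, False
    frac = float(np.mean(np.sign(draws) == np.sign(med)))
    return frac, frac >= threshold


def sex_ratio_posterior(
    post: CmrPosterior, site: str, level: float = 0.95
) -> dict[str, object]:
    """Per-draw male/female ratio at a site and a bias assessment.

    Draws with zero females are recorded as missing; the returned
    ``biased`` flag is True when the HPDI of the defined ratios
    excludes 1.
    """
    s = post.sites.index(site)
    males = post.males[:, :, s].reshape(-1).astype(float)
    females = post.females[:, :, s].reshape(-1).astype(float)
    ok = females > 0
    ratio = np.full(males.size, np.nan)
    ratio[ok] = males[ok] / females[ok]
    frac_undefined = float(1 - ok.mean())
    defined = ratio[ok]
    if defined.size < 20:
        return {
            "ratio_draws": ratio,
            "fraction_undefined": frac_undefined,
            "hpdi": (np.nan, np.nan),
            "biased": bool(frac_undefined > 0.5),
        }
    lo, hi = hpdi(defined, level)
    return {
        "ratio_draws": ratio,
        "fraction_undefined": frac_undefined,
        "hpdi": (lo, hi),
        "biased": bool(lo > 1.0 or hi < 1.0),
    }


def _compute_diagnostics(post: CmrPosterior) -> pd.DataFrame:
    import arviz as az

    data = {name: post.scalars[name] for name in post.scalars}
    for s, site in enumerate(post.sites):
        data[f"N_{site}"] = post.n_draws[:, :, s].astype(float)
    idata = az.from_dict(posterior=data)
    rhat = az.rhat(idata)
    ess = az.ess(idata)
    rows = []
    for name in data:
        rows.append(
            {
                "parameter": name,
                "rhat": float(rhat[name].values),
                "ess": float(ess[name].values),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------
# Conjugate Gibbs sampler (constant capture probability)
# ---------------------------------------------------------------------

def _fit_constant_p(aug: AugmentedData, cfg: CmrConfig) -> CmrPosterior:
    rng = np.random.default_rng(cfg.seed)
    m_total = aug.m_total
    n_sites = len(aug.sites)
    d_site = np.array([(aug.occasion_site == k).sum() for k in range(n_sites)])
    obs = aug.observed
    n_obs = int(obs.sum())
    c_obs = aug.y[obs].sum()  # total successes among observed rows
    c_i = aug.y.sum(axis=1)
    obs_site = aug.site_index[obs]
    obs_trials = d_site[obs_site].sum()
    n_obs_site = np.bincount(obs_site, minlength=n_sites) if n_obs else np.zeros(
        n_sites, dtype=np.int64
    )
    known_male = np.where(np.isfinite(aug.male), aug.male, np.nan)

    n_pseudo = m_total - n_obs
    n_keep = max(cfg.iterations // cfg.thin, 1)

    n_out = np.zeros((cfg.chains, n_keep, n_sites), dtype=np.int64)
    male_out = np.zeros((cfg.chains, n_keep, n_sites), dtype=np.int64)
    female_out = np.zeros((cfg.chains, n_keep, n_sites), dtype=np.int64)
    p_out = np.zeros((cfg.chains, n_keep))
    psi_out = np.zeros((cfg.chains, n_keep))

    for chain in range(cfg.chains):
        p = rng.uniform(0.05, 0.5)
        psi = rng.uniform(0.1, 0.9)
        pi = np.full(n_sites, 1.0 / n_sites)
        z_pseudo = rng.random(n_pseudo) < psi
        g_pseudo = rng.integers(0, n_sites, size=n_pseudo)
        sex_male = np.where(np.isfinite(known_male), known_male, rng.random(m_total) < 0.5)
        rho = np.full(n_sites, 0.5)
        keep_idx = 0
        total_iters = cfg.burn_in + cfg.iterations
        for it in range(total_iters):
            # (z, g) joint update for pseudo rows
            q_site = (1 - p) ** d_site  # P(all-zero history | included at site)
            w_incl = psi * pi * q_site  # per-site inclusion weight
            w0 = 1 - psi
            w = np.concatenate(([w0], w_incl))
            w /= w.sum()
            draw = rng.choice(n_sites + 1, size=n_pseudo, p=w)
            z_pseudo = draw > 0
            # rows with z=0 keep a site draw from pi for bookkeeping
            g_pseudo = np.where(z_pseudo, draw - 1, rng.choice(n_sites, size=n_pseudo, p=pi))

            n_incl_pseudo = int(z_pseudo.sum())
            n_incl = n_obs + n_incl_pseudo
            psi = rng.beta(1 + n_incl, 1 + m_total - n_incl)

            pseudo_site_counts = (
                np.bincount(g_pseudo[z_pseudo], minlength=n_sites)
                if n_incl_pseudo
                else np.zeros(n_sites, dtype=np.int64)
            )
            site_counts = n_obs_site + pseudo_site_counts
            if n_sites > 1:
                pi = rng.dirichlet(1 + site_counts)

            trials = obs_trials + d_site[g_pseudo[z_pseudo]].sum()
            p = rng.beta(1 + c_obs, 1 + trials - c_obs)

            # sex imputation for unknown-sex included rows
            unknown = ~np.isfinite(known_male)
            row_site = aug.site_index.copy()
            row_site[~obs] = g_pseudo
            if unknown.any():
                sex_male[unknown] = rng.random(int(unknown.sum())) < rho[row_site[unknown]]
            z_all = np.ones(m_total, dtype=bool)
            z_all[~obs] = z_pseudo
            males_site = np.zeros(n_sites, dtype=np.int64)
            females_site = np.zeros(n_sites, dtype=np.int64)
            for s in range(n_sites):
                in_s = z_all & (row_site == s)
                males_site[s] = int(sex_male[in_s].sum())
                females_site[s] = int(in_s.sum() - males_site[s])
                rho[s] = rng.beta(1 + males_site[s], 1 + females_site[s])

            if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0 and keep_idx < n_keep:
                n_out[chain, keep_idx] = site_counts
                male_out[chain, keep_idx] = males_site
                female_out[chain, keep_idx] = females_site
                p_out[chain, keep_idx] = p
                psi_out[chain, keep_idx] = psi
                keep_idx += 1

    post = CmrPosterior(
        sites=list(aug.sites),
        n_draws=n_out,
        males=male_out,
        females=female_out,
        scalars={"p_mean": p_out, "psi": psi_out},
        config=cfg,
    )
    return post


# ---------------------------------------------------------------------
# Metropolis-within-Gibbs sampler (covariates + random effects)
# ---------------------------------------------------------------------

def _log_half_cauchy(sigma: np.ndarray | float, scale: float = 1.0) -> float:
    return float(np.sum(-np.log1p((np.asarray(sigma) / scale) ** 2)))


class _FullModelState:
    """Mutable sampler state for the covariate/random-effects model."""

    def __init__(self, aug: AugmentedData, cfg: CmrConfig, rng: np.random.Generator):
        self.aug, self.cfg, self.rng = aug, cfg, rng
        m, d_total = aug.y.shape
        self.n_sites = len(aug.sites)
        self.mu = special.logit(np.clip(rng.uniform(0.1, 0.4), 1e-3, 1 - 1e-3))
        self.betas = {
            name: 0.0
            for name, used in (
                ("beta_temp", cfg.use_temperature),
                ("beta_sex", cfg.use_sex),
                ("beta_svl", cfg.use_svl),
                ("beta_behavior", cfg.use_behavior),
            )
            if used
        }
        self.a_site = np.zeros(self.n_sites)
        self.b_date = np.zeros(d_total)
        self.e_ind = np.zeros(m)
        self.sigma = {
            name: 0.5
            for name, used in (
                ("sigma_site", cfg.re_site and self.n_sites > 1),
                ("sigma_date", cfg.re_date),
                ("sigma_ind", cfg.re_individual),
            )
            if used
        }
        self.psi = rng.uniform(0.2, 0.8)
        self.pi = np.full(self.n_sites, 1.0 / self.n_sites)
        self.rho = np.full(self.n_sites, 0.5)
        self.z = aug.observed.copy()
        self.g = aug.site_index.copy()
        pseudo = ~aug.observed
        self.g[pseudo] = rng.integers(0, self.n_sites, size=int(pseudo.sum()))
        self.male = np.where(
            np.isfinite(aug.male), aug.male, (rng.random(m) < 0.5).astype(float)
        )
        self.svl = np.where(np.isfinite(aug.svl_z), aug.svl_z, rng.normal(size=m))
        self.occ_cols = [np.flatnonzero(aug.occasion_site == k) for k in range(self.n_sites)]

    # -- likelihood helpers -------------------------------------------
    def eta_block(self, rows: np.ndarray, s: int) -> np.ndarray:
        """(len(rows) x occasions-of-site-s) linear predictor matrix."""
        aug = self.aug
        cols = self.occ_cols[s]
        row_part = self.e_ind[rows]
        if "beta_sex" in self.betas:
            row_part = row_part + self.betas["beta_sex"] * self.male[rows]
        if "beta_svl" in self.betas:
            row_part = row_part + self.betas["beta_svl"] * self.svl[rows]
        occ_part = self.mu + self.a_site[s] + self.b_date[cols]
        if "beta_temp" in self.betas:
            occ_part = occ_part + self.betas["beta_temp"] * aug.temp_z[cols]
        eta = row_part[:, None] + occ_part[None, :]
        if "beta_behavior" in self.betas:
            eta = eta + self.betas["beta_behavior"] * aug.behavior[np.ix_(rows, cols)]
        return eta

    def loglik_block(self, rows: np.ndarray, s: int) -> np.ndarray:
        """Per-row Bernoulli log-likelihood of rows evaluated at site s."""
        if rows.size == 0:
            return np.zeros(0)
        cols = self.occ_cols[s]
        eta = self.eta_block(rows, s)
        yv = self.aug.y[np.ix_(rows, cols)]
        return (yv * eta - np.logaddexp(0.0, eta)).sum(axis=1)

    def loglik_rows(self, rows: np.ndarray, g_rows: np.ndarray | None = None) -> np.ndarray:
        """Bernoulli log-likelihood of each row's history at its site."""
        if g_rows is None:
            g_rows = self.g[rows]
        lls = np.zeros(rows.size)
        for s in range(self.n_sites):
            m = g_rows == s
            if m.any():
                lls[m] = self.loglik_block(rows[m], s)
        return lls

    def total_loglik(self) -> float:
        rows = np.flatnonzero(self.z)
        return float(self.loglik_rows(rows).sum())


def _fit_full_model(aug: AugmentedData, cfg: CmrConfig) -> CmrPosterior:
    rng = np.random.default_rng(cfg.seed + 1)
    m, d_total = aug.y.shape
    n_sites = len(aug.sites)
    n_keep = max(cfg.iterations // cfg.thin, 1)

    n_out = np.zeros((cfg.chains, n_keep, n_sites), dtype=np.int64)
    male_out = np.zeros((cfg.chains, n_keep, n_sites), dtype=np.int64)
    female_out = np.zeros((cfg.chains, n_keep, n_sites), dtype=np.int64)
    scalar_names = ["p_mean", "psi"]

    probe = _FullModelState(aug, cfg, np.random.default_rng(0))
    scalar_names += list(probe.betas) + list(probe.sigma)
    scalars = {name: np.zeros((cfg.chains, n_keep)) for name in scalar_names}

    pseudo_rows = np.flatnonzero(~aug.observed)
    obs_rows = np.flatnonzero(aug.observed)
    unknown_sex = np.flatnonzero(~np.isfinite(aug.male))
    missing_svl = np.flatnonzero(~np.isfinite(aug.svl_z))
    scale = cfg.proposal_scale

    for chain in range(cfg.chains):
        st = _FullModelState(aug, cfg, np.random.default_rng(cfg.seed + 101 * chain))
        keep_idx = 0
        total_iters = cfg.burn_in + cfg.iterations
        for it in range(total_iters):
            _update_latents(st, pseudo_rows, unknown_sex, missing_svl)
            _update_location_params(st, scale)
            _update_random_effects(st, scale)
            if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0 and keep_idx < n_keep:
                site_counts = np.bincount(st.g[st.z], minlength=n_sites)
                n_out[chain, keep_idx] = site_counts
                males = np.zeros(n_sites, dtype=np.int64)
                for s in range(n_sites):
                    in_s = st.z & (st.g == s)
                    males[s] = int(st.male[in_s].sum())
                male_out[chain, keep_idx] = males
                female_out[chain, keep_idx] = site_counts - males
                scalars["p_mean"][chain, keep_idx] = special.expit(st.mu)
                scalars["psi"][chain, keep_idx] = st.psi
                for name in st.betas:
                    scalars[name][chain, keep_idx] = st.betas[name]
                for name in st.sigma:
                    scalars[name][chain, keep_idx] = st.sigma[name]
                keep_idx += 1

    return CmrPosterior(
        sites=list(aug.sites),
        n_draws=n_out,
        males=male_out,
        females=female_out,
        scalars=scalars,
        config=cfg,
    )


def _update_latents(st, pseudo_rows, unknown_sex, missing_svl) -> None:
    rng, aug = st.rng, st.aug
    n_sites = st.n_sites
    # site membership + inclusion for pseudo rows (joint Gibbs)
    if pseudo_rows.size:
        # log P(all-zero | included at site s) per pseudo row
        ll_site = np.zeros((pseudo_rows.size, n_sites))
        for s in range(n_sites):
            ll_site[:, s] = st.loglik_block(pseudo_rows, s)
        w_incl = np.log(np.maximum(st.psi * st.pi, 1e-300))[None, :] + ll_site
        w0 = np.log(max(1 - st.psi, 1e-300))
        wmax = np.maximum(w_incl.max(axis=1), w0)
        probs = np.exp(np.column_stack([np.full(pseudo_rows.size, w0), w_incl]) - wmax[:, None])
        probs /= probs.sum(axis=1, keepdims=True)
        u = rng.random(pseudo_rows.size)
        choice = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)
        st.z[pseudo_rows] = choice > 0
        new_g = np.where(
            choice > 0, choice - 1, rng.choice(n_sites, size=pseudo_rows.size, p=st.pi)
        )
        st.g[pseudo_rows] = new_g
    n_incl = int(st.z.sum())
    st.psi = rng.beta(1 + n_incl, 1 + st.z.size - n_incl)
    if n_sites > 1:
        counts = np.bincount(st.g[st.z], minlength=n_sites)
        st.pi = rng.dirichlet(1 + counts)

    # sex imputation (affects likelihood through beta_sex)
    if unknown_sex.size:
        logit_rho = np.log(st.rho[st.g[unknown_sex]]) - np.log1p(-st.rho[st.g[unknown_sex]])
        logit_pm = logit_rho
        if "beta_sex" in st.betas:
            delta_ll = np.zeros(unknown_sex.size)
            saved = st.male[unknown_sex].copy()
            for s in range(st.n_sites):
                m = st.z[unknown_sex] & (st.g[unknown_sex] == s)
                rows = unknown_sex[m]
                if rows.size == 0:
                    continue
                st.male[rows] = 1.0
                ll1 = st.loglik_block(rows, s)
                st.male[rows] = 0.0
                ll0 = st.loglik_block(rows, s)
                delta_ll[m] = ll1 - ll0
            st.male[unknown_sex] = saved
            logit_pm = logit_rho + delta_ll
        pm = special.expit(logit_pm)
        st.male[unknown_sex] = (rng.random(unknown_sex.size) < pm).astype(float)
    for s in range(st.n_sites):
        in_s = st.z & (st.g == s)
        males = int(st.male[in_s].sum())
        st.rho[s] = rng.beta(1 + males, 1 + int(in_s.sum()) - males)

    # SVL imputation for pseudo rows (standard-normal prior)
    if missing_svl.size and "beta_svl" in st.betas:
        for s in range(st.n_sites):
            rows = missing_svl[st.z[missing_svl] & (st.g[missing_svl] == s)]
            if rows.size == 0:
                continue
            old = st.svl[rows].copy()
            cur_ll = st.loglik_block(rows, s)
            prop = old + rng.normal(0, 0.5, size=rows.size)
            st.svl[rows] = prop
            new_ll = st.loglik_block(rows, s)
            log_acc = new_ll - cur_ll + 0.5 * (old**2 - prop**2)
            reject = np.log(rng.random(rows.size)) >= log_acc
            st.svl[rows[reject]] = old[reject]
        not_incl = missing_svl[~st.z[missing_svl]]
        st.svl[not_incl] = rng.normal(size=not_incl.size)


def _update_location_params(st, scale) -> None:
    rng = st.rng
    # mean capture probability (uniform prior on the probability scale)
    cur_ll = st.total_loglik()
    prop = st.mu + rng.normal(0, scale)

    def logistic_logpdf(x):
        return x - 2 * np.logaddexp(0.0, x)

    old = st.mu
    st.mu = prop
    new_ll = st.total_loglik()
    log_acc = new_ll - cur_ll + logistic_logpdf(prop) - logistic_logpdf(old)
    if np.log(rng.random()) < log_acc:
        cur_ll = new_ll
    else:
        st.mu = old

    for name in st.betas:
        old = st.betas[name]
        prop = old + rng.normal(0, scale)
        st.betas[name] = prop
        new_ll = st.total_loglik()
        log_acc = new_ll - cur_ll + (old**2 - prop**2) / (2 * 3.16**2)
        if np.log(rng.random()) < log_acc:
            cur_ll = new_ll
        else:
            st.betas[name] = old


def _update_random_effects(st, scale) -> None:
    rng = st.rng
    included = np.flatnonzero(st.z)

    if "sigma_site" in st.sigma:
        sig = st.sigma["sigma_site"]
        for s in range(st.n_sites):
            rows = included[st.g[included] == s]
            old = st.a_site[s]
            prop = old + rng.normal(0, scale)
            cur = st.loglik_rows(rows).sum() if rows.size else 0.0
            st.a_site[s] = prop
            new = st.loglik_rows(rows).sum() if rows.size else 0.0
            log_acc = new - cur + (old**2 - prop**2) / (2 * sig**2)
            if np.log(rng.random()) >= log_acc:
                st.a_site[s] = old
        st.sigma["sigma_site"] = _update_sigma(rng, st.a_site, st.sigma["sigma_site"], scale)

    if "sigma_date" in st.sigma:
        sig = st.sigma["sigma_date"]
        # occasion effects: likelihood contribution is separable by column
        for s in range(st.n_sites):
            rows = included[st.g[included] == s]
            if rows.size == 0:
                cols = st.occ_cols[s]
                st.b_date[cols] = rng.normal(0, sig, size=cols.size)
                continue
            cols = st.occ_cols[s]
            etas = st.eta_block(rows, s)
            yv = st.aug.y[np.ix_(rows, cols)]
            prop = st.b_date[cols] + rng.normal(0, scale, size=cols.size)
            delta = prop - st.b_date[cols]
            cur_col = (yv * etas - np.logaddexp(0.0, etas)).sum(axis=0)
            etas_new = etas + delta[None, :]
            new_col = (yv * etas_new - np.logaddexp(0.0, etas_new)).sum(axis=0)
            log_acc = new_col - cur_col + (st.b_date[cols] ** 2 - prop**2) / (2 * sig**2)
            accept = np.log(rng.random(cols.size)) < log_acc
            st.b_date[cols[accept]] = prop[accept]
        st.sigma["sigma_date"] = _update_sigma(rng, st.b_date, st.sigma["sigma_date"], scale)

    if "sigma_ind" in st.sigma:
        sig = st.sigma["sigma_ind"]
        for s in range(st.n_sites):
            rows = included[st.g[included] == s]
            if rows.size == 0:
                continue
            cols = st.occ_cols[s]
            etas = st.eta_block(rows, s)
            yv = st.aug.y[np.ix_(rows, cols)]
            old = st.e_ind[rows].copy()
            prop = old + rng.normal(0, scale, size=rows.size)
            delta = prop - old
            cur = (yv * etas - np.logaddexp(0.0, etas)).sum(axis=1)
            etas_new = etas + delta[:, None]
            new = (yv * etas_new - np.logaddexp(0.0, etas_new)).sum(axis=1)
            log_acc = new - cur + (old**2 - prop**2) / (2 * sig**2)
            accept = np.log(rng.random(rows.size)) < log_acc
            st.e_ind[rows[accept]] = prop[accept]
        excluded = np.flatnonzero(~st.z)
        st.e_ind[excluded] = rng.normal(0, sig, size=excluded.size)
        st.sigma["sigma_ind"] = _update_sigma(rng, st.e_ind, st.sigma["sigma_ind"], scale)


def _update_sigma(rng, effects: np.ndarray, sigma: float, scale: float) -> float:
    """Random-walk update of a random-effect SD (half-Cauchy(1) prior)."""
    log_prop = np.log(sigma) + rng.normal(0, scale)
    prop = float(np.exp(log_prop))
    n = effects.size

    def logpost(s):
        return (
            -n * np.log(s)
            - np.sum(effects**2) / (2 * s**2)
            + _log_half_cauchy(s)
            + np.log(s)  # Jacobian of the log transform
        )

    if np.log(rng.random()) < logpost(prop) - logpost(sigma):
        return prop
    return sigma


# ---------------------------------------------------------------------
# Public fitting interface
# ---------------------------------------------------------------------

def fit_cmr(
    aug: AugmentedData,
    config: CmrConfig | None = None,
    diagnostics: bool = True,
    saturation_tol: float = 0.01,
) -> CmrPosterior:
    """Sample the posterior of the data-augmentation CMR model.

    Uses the conjugate Gibbs path when ``config`` disables every
    covariate and random effect (constant capture probability), and
    Metropolis-within-Gibbs otherwise. Raises
    :class:`MSaturationError` when more than ``saturation_tol`` of the
    posterior mass sits at the pool capacity (the prior is truncating
    the abundance posterior — rebuild with a larger M). Warns when any
    monitored potential-scale-reduction factor exceeds the configured
    threshold.
    """
    cfg = config if config is not None else CmrConfig()
    for k, count in enumerate(np.bincount(aug.occasion_site, minlength=len(aug.sites))):
        if count < 2:
            raise CmrError(f"site {aug.sites[k]!r} has fewer than 2 occasions")
    post = _fit_constant_p(aug, cfg) if cfg.constant_p else _fit_full_model(aug, cfg)

    total_n = post.n_draws.sum(axis=2).reshape(-1)
    sat = float(np.mean(total_n >= aug.m_total))
    if sat > saturation_tol:
        raise MSaturationError(
            f"{sat:.1%} of draws reach the pool capacity M={aug.m_total}; "
            "increase the augmentation pool"
        )
    if diagnostics and cfg.chains >= 2 and post.n_draws.shape[1] >= 4:
        post.diagnostics = _compute_diagnostics(post)
        bad = post.diagnostics[post.diagnostics["rhat"] > cfg.rhat_warn]
        if len(bad):
            warnings.warn(
                "potential scale reduction above "
                f"{cfg.rhat_warn} for: {', '.join(bad['parameter'])}",
                stacklevel=2,
            )
    return post


def summarize_abundance(post: CmrPosterior, level: float = 0.95) -> pd.DataFrame:
    """Posterior mode and HPDI of abundance per site."""
    rows = []
    for site in post.sites:
        draws = post.site_draws(site)
        lo, hi = hpdi(draws, level)
        rows.append(
            {
                "site": site,
                "mode": posterior_mode(draws),
                "hpdi_lower": int(lo),
                "hpdi_upper": int(hi),
                "mean": float(draws.mean()),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------
# Huggins conditional-likelihood estimator
# ---------------------------------------------------------------------

def huggins_fit(
    data: CaptureDataset, effects: tuple[str, ...] = ("sex", "occasion")
) -> dict[str, object]:
    """Closed-population abundance by conditional likelihood.

    logit p_id = b0 + b_sex * male_i + d_t (occasion fixed effects);
    each observed history's likelihood is divided by its inclusion
    probability p*_i = 1 - prod_d (1 - p_id), and abundance is the
    Horvitz-Thompson sum N = sum_i 1 / p*_i. Occasions with zero
    captures get no free effect (their effect is tied to the baseline)
    to avoid separation.
    """
    y = data.captures.astype(float)
    n, d = y.shape
    if n == 0:
        raise CmrError("no observed individuals")
    if d < 2:
        raise CmrError("need at least 2 occasions")
    if y.sum() <= n:
        raise CmrError("need at least one recapture")
    sex = data.individuals["sex"].to_numpy()
    male = np.where(sex == "M", 1.0, np.where(sex == "F", 0.0, 0.5))
    use_sex = "sex" in effects
    use_occ = "occasion" in effects

    occ_caps = y.sum(axis=0)
    free_occ = np.flatnonzero(occ_caps > 0)[1:] if use_occ else np.array([], dtype=int)
    if use_occ and (occ_caps == 0).any():
        warnings.warn(
            f"{int((occ_caps == 0).sum())} occasions without captures share "
            "the baseline capture effect",
            stacklevel=2,
        )

    k_sex = 1 if use_sex else 0

    def unpack(theta):
        b0 = theta[0]
        b_sex = theta[1] if use_sex else 0.0
        d_occ = np.zeros(d)
        d_occ[free_occ] = theta[1 + k_sex :]
        return b0, b_sex, d_occ

    def neg_loglik(theta):
        b0, b_sex, d_occ = unpack(theta)
        eta = b0 + b_sex * male[:, None] + d_occ[None, :]
        logp = -np.logaddexp(0.0, -eta)
        log1mp = -np.logaddexp(0.0, eta)
        ll_hist = (y * logp + (1 - y) * log1mp).sum(axis=1)
        log_pstar = np.log1p(-np.exp(np.clip(log1mp.sum(axis=1), -700, -1e-12)))
        return -(ll_hist - log_pstar).sum()

    theta0 = np.zeros(1 + k_sex + free_occ.size)
    theta0[0] = special.logit(np.clip(y.mean(), 1e-3, 1 - 1e-3))
    res = optimize.minimize(neg_loglik, theta0, method="L-BFGS-B")
    if not res.success:
        warnings.warn(f"Huggins optimizer: {res.message}", stacklevel=2)
    b0, b_sex, d_occ = unpack(res.x)
    eta = b0 + b_sex * male[:, None] + d_occ[None, :]
    p = special.expit(eta)
    pstar = 1 - np.prod(1 - p, axis=1)
    n_hat = float(np.sum(1.0 / pstar))
    return {
        "n_hat": n_hat,
        "pstar": pstar,
        "coefficients": {
            "intercept": float(b0),
            "sex_male": float(b_sex) if use_sex else None,
        },
        "converged": bool(res.success),
    }


def na_sexratio_regression(
    modal_na: dict[str, float],
    sex_ratio: dict[str, float],
    exclude: list[str] | None = None,
) -> dict[str, float]:
    """OLS of sex ratio on modal abundance across sites.

    Returns the slope, its two-sided p-value, and the adjusted R^2
    (which may be negative for uninformative fits). ``exclude`` drops
    outlier sites before fitting.
    """
    import statsmodels.api as sm

    exclude = set(exclude or [])
    sites = [s for s in modal_na if s in sex_ratio and s not in exclude]
    if len(sites) < 3:
        raise CmrError("need at least 3 sites after exclusions")
    x = np.array([modal_na[s] for s in sites], dtype=float)
    yv = np.array([sex_ratio[s] for s in sites], dtype=float)
    model = sm.OLS(yv, sm.add_constant(x)).fit()
    return {
        "slope": float(model.params[1]),
        "p_value": float(model.pvalues[1]),
        "adj_r_squared": float(model.rsquared_adj),
        "n_sites": len(sites),
    }
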