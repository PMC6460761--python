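"""Bayesian hierarchical trait model and the P_ST posterior.

The model for individual i on island j is

    y_ij = mu + a_j + s_[j],sex(i) + sum_k beta_k x_ik + eps_ij
    a_j   ~ Normal(0, sigma_B^2)       (island random effect)
    eps   ~ Normal(0, sigma_W^2)       (residual, within-island)

with half-Cauchy priors on both standard deviations sigma_B and sigma_W and
vague Normal(0, 1000^2) priors on the grand mean, sex effects and covariate
coefficients.  Sex may enter as no effect, a single sample-wide (shared) male
effect, or island-specific male effects, optionally with a correlated
bivariate prior on the (island intercept, island sex effect) pairs whose
correlation rho gets a uniform(-1, 1) prior.

Phenotypic differentiation is derived per retained draw as

    P_ST = (c/h^2 * sigma_B^2) / (c/h^2 * sigma_B^2 + 2 * sigma_W^2)

reported at the best case c = h^2 (ratio 1); other ratios can be evaluated
from the stored variance draws with :func:`pst_from_variances`.

Sampling is a seeded, pure-numpy component-wise Gibbs sweep.  The half-Cauchy
priors are represented exactly through the inverse-gamma scale-mixture
(sigma^2 ~ IG(1/2, 1/a), a ~ IG(1/2, 1/A^2) gives sigma ~ half-Cauchy(A)),
which keeps every variance update conjugate; only the correlated-sex-effect
covariance needs a random-walk Metropolis step on
(log sigma_B, log sigma_S, atanh rho).

With only two islands the posterior of sigma_B^2 is weakly identified and
prior-sensitive; this is inherent to two-population P_ST and is surfaced, not
hidden, by the wide posteriors.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .im_convert import PosteriorDraws

log = logging.getLogger(__name__)

SEXES = ("female", "male", "unknown")
_FLAT_SD = 1000.0  # vague normal prior sd for location parameters

__all__ = [
    "TraitTable",
    "ModelSpec",
    "McmcConfig",
    "TraitFit",
    "pst_from_variances",
    "fit_trait_model",
    "psrf",
    "effective_sample_size",
    "posterior_predictive_check",
]


@dataclass
class TraitTable:
    """Per-individual trait records: population, sex, numeric traits.

    Backed by a DataFrame with columns ``individual_id``, ``population``,
    ``sex`` and one numeric column per trait/covariate.  ``metadata`` may
    carry ground-truth parameters when the table came from the synthetic
    generator.
    """

    df: pd.DataFrame
    units: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"individual_id", "population", "sex"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"trait table missing columns: {sorted(missing)}")
        bad_sex = set(self.df["sex"].unique()) - set(SEXES)
        if bad_sex:
            raise ValueError(f"unknown sex codes: {sorted(bad_sex)}")
        if self.df["population"].nunique() < 2:
            raise ValueError("trait table needs >= 2 populations")

    @property
    def trait_names(self) -> list:
        return [
            c
            for c in self.df.columns
            if c not in ("individual_id", "population", "sex")
        ]

    @classmethod
    def from_csv(cls, path, units: "dict | None" = None) -> "TraitTable":
        return cls(pd.read_csv(path), units=units or {})

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)


@dataclass(frozen=True)
class ModelSpec:
    """Which trait to model and how sex and covariates enter."""

    trait: str
    sex_effect: str = "shared"  # none | shared | island_specific
    covariates: tuple = ()
    correlation_between_effects: bool = False

    def __post_init__(self) -> None:
        if self.sex_effect not in ("none", "shared", "island_specific"):
            raise ValueError(f"unknown sex_effect {self.sex_effect!r}")
        if self.correlation_between_effects and self.sex_effect != "island_specific":
            raise ValueError(
                "correlation_between_effects requires island_specific sex "
                "effects"
            )
        object.__setattr__(self, "covariates", tuple(self.covariates))


@dataclass(frozen=True)
class McmcConfig:
    """Chain lengths and priors.

    Defaults follow common practice for this model class: 4 chains, 25,000
    burn-in then 25,000 further iterations thinned by 25 (1,000 retained per
    chain), half-Cauchy scale 100 on both standard deviations.
    """

    n_chains: int = 4
    burn_in: int = 25_000
    n_iter: int = 25_000
    thin: int = 25
    seed: int = 0
    prior_scale_sd: float = 100.0

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise ValueError("need >= 2 chains (for convergence diagnostics)")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_iter // self.thin < 200:
            raise ValueError("retained draws per chain (n_iter/thin) must be >= 200")
        if self.burn_in < 0:
            raise ValueError("burn_in must be non-negative")
        if self.prior_scale_sd <= 0:
            raise ValueError("prior_scale_sd must be positive")

    @property
    def n_saved(self) -> int:
        return self.n_iter // self.thin


def pst_from_variances(sigma_b2, sigma_w2, c_over_h2: float = 1.0):
    """P_ST from between/within variances at a given c/h^2 ratio.

    Accepts scalars or arrays (applied elementwise).  Monotone increasing in
    ``sigma_b2`` and in the ratio; 0 when ``sigma_b2`` is 0.
    """
    sb = np.asarray(sigma_b2, dtype=float)
    sw = np.asarray(sigma_w2, dtype=float)
    if c_over_h2 <= 0:
        raise ValueError("c/h^2 ratio must be positive")
    if np.any(sb < 0) or np.any(sw < 0):
        raise ValueError("variances must be non-negative")
    denom = c_over_h2 * sb + 2.0 * sw
    if np.any(denom == 0):
        raise ValueError("both variances zero: P_ST undefined")
    out = c_over_h2 * sb / denom
    return float(out) if out.ndim == 0 else out


# --------------------------------------------------------------------------
# MCMC internals


def _inv_gamma(rng: np.random.Generator, shape: float, rate) -> np.ndarray:
    """Draw from InverseGamma(shape, rate): rate / Gamma(shape, 1)."""
    return rate / rng.gamma(shape, 1.0, size=np.shape(rate) or None)


class _Design:
    """Prepared numeric design shared by the sampler and predictive checks."""

    def __init__(self, data: TraitTable, spec: ModelSpec):
        df = data.df
        cols = [spec.trait, *spec.covariates]
        for c in cols:
            if c not in df.columns:
                raise ValueError(f"column {c!r} not in trait table")
        keep = df[cols].notna().all(axis=1)
        dropped = int((~keep).sum())
        if dropped:
            log.info("dropping %d record(s) with missing trait/covariates", dropped)
        df = df[keep]
        if spec.sex_effect != "none":
            unk = df["sex"] == "unknown"
            if unk.any():
                log.info("dropping %d record(s) with unknown sex", int(unk.sum()))
                df = df[~unk]
        df = df.reset_index(drop=True)

        self.populations = sorted(df["population"].unique())
        if len(self.populations) < 2:
            raise ValueError("need >= 2 populations after filtering")
        counts = df["population"].value_counts()
        thin_pops = [p for p in self.populations if counts[p] < 2]
        if thin_pops:
            raise ValueError(
                f"population(s) {thin_pops} have < 2 usable individuals"
            )

        self.y = df[spec.trait].to_numpy(dtype=float)
        pop_idx = {p: i for i, p in enumerate(self.populations)}
        self.island = df["population"].map(pop_idx).to_numpy(dtype=int)
        self.male = (df["sex"] == "male").to_numpy()
        self.sex = df["sex"].to_numpy()
        if spec.covariates:
            X = df[list(spec.covariates)].to_numpy(dtype=float)
            self.x_center = X.mean(axis=0)
            self.X = X - self.x_center  # centered, documented convention
        else:
            self.x_center = np.zeros(0)
            self.X = np.zeros((len(df), 0))
        self.n = len(df)
        self.J = len(self.populations)
        self.df = df


def _run_chain(design: _Design, spec: ModelSpec, cfg: McmcConfig,
               rng: np.random.Generator) -> dict:
    y, island, male, X = design.y, design.island, design.male, design.X
    n, J, p = design.n, design.J, X.shape[1]
    A = cfg.prior_scale_sd
    tau0_prec = 1.0 / _FLAT_SD**2

    n_j = np.bincount(island, minlength=J).astype(float)
    nmale_j = np.bincount(island[male], minlength=J).astype(float)

    island_spec = spec.sex_effect == "island_specific"
    shared = spec.sex_effect == "shared"
    corr = spec.correlation_between_effects

    # initial values: data-driven, overdispersed a little by the rng
    mu = float(y.mean()) + rng.normal(0, max(y.std(), 1e-3))
    eta = np.array([y[island == j].mean() for j in range(J)])
    eta += rng.normal(0, max(y.std(), 1e-3) / 2, J)
    s_shared = 0.0
    s_island = np.zeros(J)
    beta = np.zeros(p)
    sw2 = max(float(y.var()), 1e-6)
    sb2 = max(float(np.var(eta)), 1e-3)
    ss2 = 1.0  # sex-effect variance (correlated model)
    rho = 0.0
    a_b = a_w = 1.0

    n_saved = cfg.n_saved
    out = {
        "mu": np.empty(n_saved),
        "sigma_b2": np.empty(n_saved),
        "sigma_w2": np.empty(n_saved),
    }
    for pop in design.populations:
        out[f"effect_{pop}"] = np.empty(n_saved)
    if shared:
        out["sex_male"] = np.empty(n_saved)
    elif island_spec:
        for pop in design.populations:
            out[f"sex_male_{pop}"] = np.empty(n_saved)
        if corr:
            out["sigma_s2"] = np.empty(n_saved)
            out["rho"] = np.empty(n_saved)
    for c in spec.covariates:
        out[f"beta_{c}"] = np.empty(n_saved)

    def sex_term():
        if shared:
            return np.where(male, s_shared, 0.0)
        if island_spec:
            return np.where(male, s_island[island], 0.0)
        return 0.0

    def log_halfcauchy(s):  # unnormalized
        return -math.log(1.0 + (s / A) ** 2)

    total = cfg.burn_in + cfg.n_iter
    save_at = cfg.burn_in - 1  # save when (it - burn_in + 1) % thin == 0
    k_saved = 0
    xb = X @ beta if p else 0.0

    for it in range(total):
        st = sex_term()

        if not corr:
            # island means (centered parameterization eta_j = mu + a_j)
            r = y - st - xb
            sum_r = np.bincount(island, weights=r, minlength=J)
            prec = n_j / sw2 + 1.0 / sb2
            mean = (sum_r / sw2 + mu / sb2) / prec
            eta = mean + rng.standard_normal(J) / np.sqrt(prec)

            # grand mean
            prec_mu = J / sb2 + tau0_prec
            mu = float(
                rng.normal(np.sum(eta) / sb2 / prec_mu, 1.0 / math.sqrt(prec_mu))
            )

            # between-island variance (half-Cauchy via IG mixture)
            ssq = float(np.sum((eta - mu) ** 2))
            sb2 = float(_inv_gamma(rng, 0.5 + J / 2.0, 1.0 / a_b + ssq / 2.0))
            a_b = float(_inv_gamma(rng, 1.0, 1.0 / A**2 + 1.0 / sb2))

            # sex effects
            if shared or island_spec:
                r = y - eta[island] - xb
                if shared:
                    prec_s = nmale_j.sum() / sw2 + tau0_prec
                    mean_s = float(r[male].sum()) / sw2 / prec_s
                    s_shared = float(rng.normal(mean_s, 1.0 / math.sqrt(prec_s)))
                else:
                    sum_rm = np.bincount(
                        island[male], weights=r[male], minlength=J
                    )
                    prec_s = nmale_j / sw2 + tau0_prec
                    mean_s = sum_rm / sw2 / prec_s
                    s_island = mean_s + rng.standard_normal(J) / np.sqrt(prec_s)
        else:
            # correlated (intercept, sex effect) pairs per island
            r = y - xb
            Sig = np.array(
                [
                    [sb2, rho * math.sqrt(sb2 * ss2)],
                    [rho * math.sqrt(sb2 * ss2), ss2],
                ]
            )
            P_prior = np.linalg.inv(Sig)
            for j in range(J):
                mask = island == j
                rj = r[mask]
                mj = male[mask]
                P_lik = (
                    np.array(
                        [
                            [n_j[j], nmale_j[j]],
                            [nmale_j[j], nmale_j[j]],
                        ]
                    )
                    / sw2
                )
                b = np.array([rj.sum(), rj[mj].sum()]) / sw2
                b_prior = P_prior @ np.array([mu, 0.0])
                P_post = P_lik + P_prior
                C = np.linalg.inv(P_post)
                mpost = C @ (b + b_prior)
                L = np.linalg.cholesky(C)
                draw = mpost + L @ rng.standard_normal(2)
                eta[j], s_island[j] = draw

            # grand mean given the bivariate prior: eta_j | s_j
            slope = rho * math.sqrt(sb2 / ss2)
            var_c = sb2 * (1.0 - rho**2) + 1e-12
            pseudo = eta - slope * s_island
            prec_mu = J / var_c + tau0_prec
            mu = float(
                rng.normal(
                    pseudo.sum() / var_c / prec_mu, 1.0 / math.sqrt(prec_mu)
                )
            )

            # covariance of the pairs: RW Metropolis on transformed scale
            U = np.column_stack([eta - mu, s_island])

            def logpost(lsb, lss, z):
                sb_, ss_, rho_ = math.exp(lsb), math.exp(lss), math.tanh(z)
                S = np.array(
                    [
                        [sb_**2, rho_ * sb_ * ss_],
                        [rho_ * sb_ * ss_, ss_**2],
                    ]
                )
                det = S[0, 0] * S[1, 1] - S[0, 1] ** 2
                if det <= 0:
                    return -np.inf
                Sinv = np.array(
                    [[S[1, 1], -S[0, 1]], [-S[0, 1], S[0, 0]]]
                ) / det
                ll = -0.5 * J * math.log(det) - 0.5 * float(
                    np.sum((U @ Sinv) * U)
                )
                lp = log_halfcauchy(sb_) + log_halfcauchy(ss_)
                # Jacobian of (log sb, log ss, atanh rho)
                jac = lsb + lss + math.log(1.0 - rho_**2)
                return ll + lp + jac

            state = np.array([0.5 * math.log(sb2), 0.5 * math.log(ss2),
                              math.atanh(min(max(rho, -0.999), 0.999))])
            lp0 = logpost(*state)
            for _ in range(3):
                prop = state + 0.4 * rng.standard_normal(3)
                lp1 = logpost(*prop)
                if math.log(rng.uniform()) < lp1 - lp0:
                    state, lp0 = prop, lp1
            sb2 = math.exp(2.0 * state[0])
            ss2 = math.exp(2.0 * state[1])
            rho = math.tanh(state[2])
            st = np.where(male, s_island[island], 0.0)

        st = sex_term()

        # covariate coefficients (joint conjugate update)
        if p:
            r = y - eta[island] - st
            V = np.linalg.inv(X.T @ X / sw2 + np.eye(p) * tau0_prec)
            mcoef = V @ (X.T @ r) / sw2
            beta = rng.multivariate_normal(mcoef, V, method="cholesky")
            xb = X @ beta

        # residual variance (half-Cauchy via IG mixture)
        resid = y - eta[island] - st - xb
        ssr = float(resid @ resid)
        sw2 = float(_inv_gamma(rng, 0.5 + n / 2.0, 1.0 / a_w + ssr / 2.0))
        a_w = float(_inv_gamma(rng, 1.0, 1.0 / A**2 + 1.0 / sw2))

        if it >= cfg.burn_in and (it - cfg.burn_in + 1) % cfg.thin == 0:
            k = k_saved
            out["mu"][k] = mu
            out["sigma_b2"][k] = sb2
            out["sigma_w2"][k] = sw2
            for j, pop in enumerate(design.populations):
                out[f"effect_{pop}"][k] = eta[j] - mu
            if shared:
                out["sex_male"][k] = s_shared
            elif island_spec:
                for j, pop in enumerate(design.populations):
                    out[f"sex_male_{pop}"][k] = s_island[j]
                if corr:
                    out["sigma_s2"][k] = ss2
                    out["rho"][k] = rho
            for i, c in enumerate(spec.covariates):
                out[f"beta_{c}"][k] = beta[i]
            k_saved += 1

    return out


@dataclass
class TraitFit:
    """Posterior draws, derived P_ST and convergence diagnostics."""

    spec: ModelSpec
    cfg: McmcConfig
    populations: list
    draws: dict  # name -> (n_chains, n_saved) arrays; includes "pst"
    psrf: dict
    ess: dict
    design: "_Design" = field(repr=False, default=None)

    @property
    def parameter_names(self) -> list:
        return sorted(self.draws)

    def flat(self, name: str) -> np.ndarray:
        return self.draws[name].reshape(-1)

    def pst_draws(self) -> PosteriorDraws:
        return PosteriorDraws(
            parameter="Pst",
            draws=np.clip(self.flat("pst"), np.nextafter(0.0, 1.0), 1.0),
            population="NA",
            units="proportion",
        )

    def write_draws_tsv(self, path) -> None:
        pd.DataFrame({k: self.flat(k) for k in self.parameter_names}).to_csv(
            path, sep="\t", index=False
        )

    def diagnostics_dict(self) -> dict:
        return {
            "psrf": dict(sorted(self.psrf.items())),
            "ess": dict(sorted(self.ess.items())),
            "spec": {
                "trait": self.spec.trait,
                "sex_effect": self.spec.sex_effect,
                "covariates": list(self.spec.covariates),
                "correlation_between_effects": self.spec.correlation_between_effects,
            },
            "config": {
                "n_chains": self.cfg.n_chains,
                "burn_in": self.cfg.burn_in,
                "n_iter": self.cfg.n_iter,
                "thin": self.cfg.thin,
                "seed": self.cfg.seed,
                "prior_scale_sd": self.cfg.prior_scale_sd,
            },
            "populations": list(self.populations),
        }


def fit_trait_model(
    data: TraitTable, spec: ModelSpec, cfg: McmcConfig
) -> TraitFit:
    """Sample the posterior of the hierarchical trait model.

    Runs ``cfg.n_chains`` independent chains (seeds spawned deterministically
    from ``cfg.seed``), derives P_ST at c = h^2 for every retained draw, and
    computes the potential scale reduction factor and effective sample size
    for every saved parameter.  Non-convergence is reported through the
    diagnostics, never raised.
    """
    design = _Design(data, spec)
    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.n_chains)
    chains = [
        _run_chain(design, spec, cfg, np.random.default_rng(s)) for s in seeds
    ]
    draws = {
        name: np.stack([c[name] for c in chains]) for name in chains[0]
    }
    draws["pst"] = pst_from_variances(draws["sigma_b2"], draws["sigma_w2"], 1.0)

    psrf_d, ess_d = {}, {}
    for name, arr in draws.items():
        psrf_d[name] = psrf(arr)
        ess_d[name] = float(
            sum(effective_sample_size(chain) for chain in arr)
        )
    return TraitFit(
        spec=spec,
        cfg=cfg,
        populations=list(design.populations),
        draws=draws,
        psrf=psrf_d,
        ess=ess_d,
        design=design,
    )


def psrf(chains) -> float:
    """Gelman-Rubin potential scale reduction factor.

    ``sqrt(((n-1)/n * W + B/n) / W)`` with W the mean within-chain variance
    and B/n the sample variance of the chain means (i.e. B is n/(m-1) times
    the summed squared deviation of chain means from the grand mean).
    """
    arr = np.asarray(chains, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("need >= 2 chains as a 2-d (chains x draws) array")
    m, n = arr.shape
    if n < 10:
        raise ValueError("need chains of length >= 10")
    W = float(np.mean(np.var(arr, axis=1, ddof=1)))
    means = arr.mean(axis=1)
    B_over_n = float(np.var(means, ddof=1))
    if W == 0.0:
        return 1.0 if np.allclose(arr, arr[0]) else math.inf
    return math.sqrt(((n - 1) / n * W + B_over_n) / W)


def effective_sample_size(draws) -> float:
    """ESS with Geyer's initial-positive-sequence truncation.

    ``n / (1 + 2 * sum(rho_t))`` summing autocorrelations in consecutive
    pairs (rho_1+rho_2), (rho_3+rho_4), ... until the first non-positive
    pair.  A constant sequence reports ESS = n (no autocorrelation signal to
    penalize) with a logged flag.
    """
    x = np.asarray(draws, dtype=float)
    if x.size < 100:
        raise ValueError("need >= 100 draws for ESS")
    n = x.size
    x = x - x.mean()
    var0 = float(x @ x) / n
    if var0 == 0.0:
        log.warning("constant draw sequence: ESS reported as n")
        return float(n)
    # autocovariance via FFT
    m = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(x, m)
    acov = np.fft.irfft(f * np.conjugate(f), m)[:n] / n
    rho = acov / acov[0]
    tau = 1.0
    t = 1
    while t + 1 < n:
        pair = rho[t] + rho[t + 1]
        if pair <= 0:
            break
        tau += 2.0 * pair
        t += 2
    return float(n / tau)


def posterior_predictive_check(
    fit: TraitFit, data: TraitTable, n_rep: int, seed: int = 0
) -> dict:
    """Simulate replicate datasets from the fitted model and locate the
    observed per-(population x sex) mean and sd within them.

    Returns ``{"population/sex": {"mean": {...}, "sd": {...}}}`` where each
    statistic entry carries the observed value and the two-sided tail
    probability of the observed statistic under the replicate distribution.
    """
    total = fit.cfg.n_chains * fit.cfg.n_saved
    if n_rep <= 0:
        raise ValueError("n_rep must be positive")
    if n_rep > total:
        raise ValueError(f"n_rep={n_rep} exceeds retained draws ({total})")
    design = fit.design
    if design is None:
        raise ValueError("fit carries no design; refit before checking")

    rng = np.random.default_rng(seed)
    idx = np.linspace(0, total - 1, n_rep).astype(int)
    flat = {k: fit.flat(k) for k in fit.draws}

    island = design.island
    male = design.male
    X = design.X
    spec = fit.spec

    cells = []
    for pop in design.populations:
        for sex in sorted(set(design.sex)):
            mask = (design.df["population"] == pop).to_numpy() & (
                design.sex == sex
            )
            if mask.sum() >= 2:
                cells.append((pop, sex, mask))

    obs = {
        (pop, sex): (float(design.y[mask].mean()), float(design.y[mask].std(ddof=1)))
        for pop, sex, mask in cells
    }
    rep_stats = {key: ([], []) for key in obs}

    for r in idx:
        eta = np.array(
            [flat["mu"][r] + flat[f"effect_{p}"][r] for p in design.populations]
        )
        yhat = eta[island].copy()
        if spec.sex_effect == "shared":
            yhat += np.where(male, flat["sex_male"][r], 0.0)
        elif spec.sex_effect == "island_specific":
            s = np.array(
                [flat[f"sex_male_{p}"][r] for p in design.populations]
            )
            yhat += np.where(male, s[island], 0.0)
        for c in spec.covariates:
            yhat += X[:, list(spec.covariates).index(c)] * flat[f"beta_{c}"][r]
        y_rep = yhat + rng.normal(0.0, math.sqrt(flat["sigma_w2"][r]), design.n)
        for pop, sex, mask in cells:
            rep_stats[(pop, sex)][0].append(float(y_rep[mask].mean()))
            rep_stats[(pop, sex)][1].append(float(y_rep[mask].std(ddof=1)))

    result = {}
    for (pop, sex), (means, sds) in rep_stats.items():
        entry = {}
        for stat_name, reps, observed in (
            ("mean", np.asarray(means), obs[(pop, sex)][0]),
            ("sd", np.asarray(sds), obs[(pop, sex)][1]),
        ):
            p_le = float(np.mean(reps <= observed))
            p_ge = float(np.mean(reps >= observed))
            entry[stat_name] = {
                "observed": observed,
                "tail_prob": min(1.0, 2.0 * min(p_le, p_ge)),
            }
        result[f"{pop}/{sex}"] = entry
    return result
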