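"""Conversion of coalescent-scaled isolation-with-migration posteriors.

Isolation-with-migration samplers (e.g. IMa2) report parameters scaled by the
mutation rate: ``theta = 4*Ne*mu`` per population, directional migration
``m = M/mu`` and the splitting time ``tau = t*mu``.  This module converts those
draws to natural units (individuals, years) given per-locus substitution rates
and a generation time, and transforms posterior draws of the effective number
of migrants ``Nm`` into a posterior distribution of ``F_ST`` under Wright's
island model with Takahata's correction for a finite number of demes ``d``::

    F_ST = 1 / (1 + 4*Nm * d**2 / (d - 1)**2)

Because the transform is applied draw-by-draw, the resulting ``F_ST``
distribution carries over all the uncertainty in the migration posterior,
including asymmetry between directions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import gaussian_kde

__all__ = [
    "PosteriorDraws",
    "RateSet",
    "DemeCount",
    "PosteriorSummary",
    "fst_from_nm",
    "fst_distribution",
    "nm_from_theta_m",
    "ne_from_theta",
    "split_time_from_tau",
    "geometric_mean_rate",
    "per_generation_rate",
    "summarize_posterior",
    "round_to_nearest_thousand",
    "years_to_ma",
]


@dataclass(frozen=True)
class DemeCount:
    """Number of demes ``d`` in the finite-island correction ``d**2/(d-1)**2``.

    The correction is undefined at ``d = 1`` (a single deme cannot
    differentiate), hence ``d >= 2``.
    """

    d: int = 2

    def __post_init__(self) -> None:
        if int(self.d) != self.d or self.d < 2:
            raise ValueError(f"deme count d must be an integer >= 2, got {self.d}")

    @property
    def correction(self) -> float:
        return self.d**2 / (self.d - 1) ** 2


@dataclass(frozen=True)
class PosteriorDraws:
    """A labeled vector of MCMC draws for one scalar parameter.

    ``parameter`` is a free name token (``theta``, ``m``, ``tau``, ``Nm``,
    ``Fst``, ``Pst`` ...); ``population`` labels the deme or migration
    direction the parameter refers to (``"NA"`` when not applicable).
    """

    parameter: str
    draws: np.ndarray
    population: str = "NA"
    units: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.draws, dtype=float)
        object.__setattr__(self, "draws", arr)
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError("draws must be a non-empty 1-d sequence")
        if not np.all(np.isfinite(arr)):
            bad = int(np.flatnonzero(~np.isfinite(arr))[0])
            raise ValueError(f"non-finite draw at index {bad}")
        name = self.parameter.lower()
        if name in {"theta", "m", "tau", "nm"} and np.any(arr < 0):
            bad = int(np.flatnonzero(arr < 0)[0])
            raise ValueError(f"{self.parameter} draw negative at index {bad}")
        if name in {"fst", "pst"} and (np.any(arr <= 0) or np.any(arr > 1)):
            bad = int(np.flatnonzero((arr <= 0) | (arr > 1))[0])
            raise ValueError(
                f"{self.parameter} draw outside (0, 1] at index {bad}"
            )

    def __len__(self) -> int:
        return int(self.draws.size)


@dataclass(frozen=True)
class RateSet:
    """Per-locus substitution rates plus the multilocus summaries used for
    natural-parameter conversion.

    The multilocus rate is the geometric mean of the locus rates (per year);
    the per-generation rate multiplies by the generation time in years.
    """

    locus_rates_per_year: tuple
    generation_time_years: float
    multilocus_rate_per_year: float
    multilocus_rate_per_generation: float

    @classmethod
    def from_locus_rates(
        cls, locus_rates_per_year: Sequence[float], generation_time_years: float
    ) -> "RateSet":
        per_year = geometric_mean_rate(locus_rates_per_year)
        return cls(
            locus_rates_per_year=tuple(float(r) for r in locus_rates_per_year),
            generation_time_years=float(generation_time_years),
            multilocus_rate_per_year=per_year,
            multilocus_rate_per_generation=per_generation_rate(
                per_year, generation_time_years
            ),
        )

    def __post_init__(self) -> None:
        if self.generation_time_years <= 0:
            raise ValueError("generation time must be positive")
        if self.multilocus_rate_per_year <= 0:
            raise ValueError("multilocus rate must be positive")
        if self.locus_rates_per_year:
            gm = geometric_mean_rate(self.locus_rates_per_year)
            if not math.isclose(gm, self.multilocus_rate_per_year, rel_tol=1e-9):
                raise ValueError(
                    "multilocus_rate_per_year is not the geometric mean of the "
                    "locus rates"
                )
        expected = self.multilocus_rate_per_year * self.generation_time_years
        if not math.isclose(
            expected, self.multilocus_rate_per_generation, rel_tol=1e-9
        ):
            raise ValueError(
                "multilocus_rate_per_generation must equal rate/year x "
                "generation time"
            )


@dataclass(frozen=True)
class PosteriorSummary:
    """Mode, HPD interval and quantiles of one posterior sample."""

    mode: float
    hpd_low: float
    hpd_high: float
    hpd_mass: float
    quantiles: Mapping[float, float]
    n_draws: int
    mode_outside_hpd: bool = False

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "hpd_low": self.hpd_low,
            "hpd_high": self.hpd_high,
            "hpd_mass": self.hpd_mass,
            "quantiles": {str(p): v for p, v in self.quantiles.items()},
            "n_draws": self.n_draws,
            "mode_outside_hpd": self.mode_outside_hpd,
        }


def _deme(d: "DemeCount | int") -> DemeCount:
    return d if isinstance(d, DemeCount) else DemeCount(d)


def fst_from_nm(nm: float, d: "DemeCount | int" = 2) -> float:
    """F_ST expected under the island model for ``nm`` effective migrants.

    Applies the finite-deme correction ``d**2/(d-1)**2``; strictly decreasing
    in ``nm`` and equal to 1 at ``nm = 0`` (no migration, complete
    differentiation).
    """
    if nm < 0 or not math.isfinite(nm):
        raise ValueError(f"Nm must be a finite non-negative real, got {nm}")
    return 1.0 / (1.0 + 4.0 * nm * _deme(d).correction)


def fst_distribution(
    nm_draws: PosteriorDraws, d: "DemeCount | int" = 2
) -> PosteriorDraws:
    """Transform a posterior of Nm into a posterior of F_ST, draw by draw."""
    if nm_draws.parameter.lower() != "nm":
        raise ValueError(
            f"expected Nm draws, got parameter {nm_draws.parameter!r}"
        )
    corr = _deme(d).correction
    fst = 1.0 / (1.0 + 4.0 * nm_draws.draws * corr)
    return PosteriorDraws(
        parameter="Fst",
        draws=fst,
        population=nm_draws.population,
        units="proportion",
    )


def nm_from_theta_m(
    theta_draws: PosteriorDraws, m_draws: PosteriorDraws
) -> PosteriorDraws:
    """Effective migrants per generation from paired theta and m draws.

    ``theta = 4*Ne*mu`` and ``m = M/mu``, so ``theta*m/4 = Ne*M = Nm``; the
    mutation rate cancels.  Draws must be paired by MCMC iteration (same
    genealogy sample), so unequal lengths are an error, never recycled.
    """
    if len(theta_draws) != len(m_draws):
        raise ValueError(
            f"theta ({len(theta_draws)}) and m ({len(m_draws)}) draw counts "
            "differ; draws must be paired by iteration"
        )
    return PosteriorDraws(
        parameter="Nm",
        draws=theta_draws.draws * m_draws.draws / 4.0,
        population=m_draws.population,
        units="migrants/generation",
    )


def ne_from_theta(theta: float, mu_per_generation: float) -> float:
    """Effective population size (individuals) from ``theta = 4*Ne*mu``."""
    if mu_per_generation <= 0:
        raise ValueError("per-generation mutation rate must be positive")
    if theta < 0:
        raise ValueError("theta must be non-negative")
    return theta / (4.0 * mu_per_generation)


def split_time_from_tau(tau: float, mu_per_year: float) -> float:
    """Splitting time in years from ``tau = t*mu``."""
    if mu_per_year <= 0:
        raise ValueError("per-year mutation rate must be positive")
    if tau < 0:
        raise ValueError("tau must be non-negative")
    return tau / mu_per_year


def geometric_mean_rate(locus_rates: Sequence[float]) -> float:
    """Geometric mean of per-locus substitution rates."""
    rates = np.asarray(locus_rates, dtype=float)
    if rates.size == 0:
        raise ValueError("need at least one locus rate")
    if np.any(rates <= 0) or not np.all(np.isfinite(rates)):
        raise ValueError("all locus rates must be finite and positive")
    return float(np.exp(np.mean(np.log(rates))))


def per_generation_rate(
    rate_per_year: float, generation_time_years: float
) -> float:
    """Per-generation substitution rate from a per-year rate."""
    if rate_per_year <= 0 or generation_time_years <= 0:
        raise ValueError("rate and generation time must both be positive")
    return rate_per_year * generation_time_years


def round_to_nearest_thousand(x: float) -> int:
    """Human-readable rounding used for effective population sizes."""
    return int(round(x / 1000.0)) * 1000


def years_to_ma(years: float, decimals: int = 2) -> float:
    """Years expressed in millions of years, rounded for presentation."""
    return round(years / 1e6, decimals)


def summarize_posterior(
    draws: "PosteriorDraws | Sequence[float]",
    hpd_mass: float = 0.95,
    quantile_probs: Sequence[float] = (0.025, 0.05, 0.5, 0.95, 0.975),
) -> PosteriorSummary:
    """Mode, shortest HPD interval and empirical quantiles of a sample.

    The mode is the argmax of a Gaussian kernel density (Silverman bandwidth)
    on a 512-point grid spanning the draw range.  The HPD is the shortest
    window of ``ceil(mass*n)`` consecutive order statistics.  Quantiles use
    linear interpolation of order statistics (numpy's default, "type 7"), so
    tail quantiles are reproducible bit for bit.
    """
    x = draws.draws if isinstance(draws, PosteriorDraws) else np.asarray(
        draws, dtype=float
    )
    if x.size < 100:
        raise ValueError(f"need >= 100 draws for mode estimation, got {x.size}")
    if not 0.0 < hpd_mass < 1.0:
        raise ValueError("hpd_mass must lie in (0, 1)")

    s = np.sort(x)
    if s[0] == s[-1]:  # degenerate: constant draws
        c = float(s[0])
        return PosteriorSummary(
            mode=c,
            hpd_low=c,
            hpd_high=c,
            hpd_mass=hpd_mass,
            quantiles={float(p): c for p in quantile_probs},
            n_draws=int(x.size),
        )

    kde = gaussian_kde(x, bw_method="silverman")
    grid = np.linspace(s[0], s[-1], 512)
    mode = float(grid[int(np.argmax(kde(grid)))])

    n = x.size
    k = int(math.ceil(hpd_mass * n))
    k = min(max(k, 1), n)
    widths = s[k - 1 :] - s[: n - k + 1]
    i = int(np.argmin(widths))
    lo, hi = float(s[i]), float(s[i + k - 1])

    quantiles = {
        float(p): float(np.quantile(x, p, method="linear"))
        for p in quantile_probs
    }
    return PosteriorSummary(
        mode=mode,
        hpd_low=lo,
        hpd_high=hi,
        hpd_mass=hpd_mass,
        quantiles=quantiles,
        n_draws=int(n),
        mode_outside_hpd=not (lo <= mode <= hi),
    )
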