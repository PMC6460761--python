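"""Compare P_ST and F_ST posterior distributions.

Two complementary summaries decide whether phenotypic divergence exceeds the
neutral expectation:

* the overlap between the two posterior densities on [0, 1] (integral of the
  pointwise minimum of boundary-corrected Gaussian kernel density estimates);
* the critical additive-genetic ratio

      c/h^2_critical = (1 - P_ST[0.05]) * F_ST[0.95]
                       / (P_ST[0.05] * (1 - F_ST[0.95]))

  evaluated at the lower 5% tail of P_ST and the upper 5% tail of F_ST.  A
  small critical ratio means P_ST exceeds F_ST over a wide range of unknown
  c/h^2, so the rejection of drift is robust.

The verdict reported by :func:`compare` is a convention, not an inference
rule: drift is "rejected" when the overlap falls below a threshold (default
0.05) and the 5% P_ST tail clears the 95% F_ST tail.  Both ingredients are
always reported.  Overlaps are always proportions in [0, 1], never percent.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
from scipy.integrate import simpson

from .im_convert import PosteriorDraws
from .pst_model import TraitFit

__all__ = [
    "DriftComparison",
    "critical_c_over_h2",
    "kde_overlap",
    "compare",
    "drift_report",
]

GRID_SIZE = 512


@dataclass(frozen=True)
class DriftComparison:
    """One trait x one F_ST direction: overlap, tails, critical ratio."""

    trait: str
    focal_population: str
    overlap: float
    fst_q95: float
    pst_q05: float
    c_over_h2_critical: float
    verdict: str  # drift_rejected | drift_not_rejected
    overlap_threshold: float

    def to_dict(self) -> dict:
        d = asdict(self)
        if math.isinf(d["c_over_h2_critical"]):
            d["c_over_h2_critical"] = "inf"
        return d


def _as_array(x) -> np.ndarray:
    return x.draws if isinstance(x, PosteriorDraws) else np.asarray(x, float)


def critical_c_over_h2(pst_draws, fst_draws) -> float:
    """Critical c/h^2 ratio from the 5% P_ST and 95% F_ST tail quantiles.

    Empirical quantiles (linear interpolation) are used, matching the tails
    the definition names.  Returns ``inf`` when the tails degenerate
    (P_ST 5% quantile at 0 or F_ST 95% quantile at 1).
    """
    pst = _as_array(pst_draws)
    fst = _as_array(fst_draws)
    for name, arr in (("Pst", pst), ("Fst", fst)):
        if np.any(arr < 0) or np.any(arr > 1):
            raise ValueError(f"{name} draws must lie in [0, 1]")
    p05 = float(np.quantile(pst, 0.05))
    f95 = float(np.quantile(fst, 0.95))
    if p05 <= 0.0 or f95 >= 1.0:
        return math.inf
    return (1.0 - p05) * f95 / (p05 * (1.0 - f95))


def _silverman_bw(x: np.ndarray) -> float:
    """Silverman's rule of thumb, robust version: 0.9 min(sd, IQR/1.34) n^-1/5."""
    n = x.size
    sd = float(np.std(x, ddof=1)) if n > 1 else 0.0
    iqr = float(np.subtract(*np.percentile(x, [75, 25])))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    if spread <= 0:
        return 1e-4  # degenerate sample: effectively a point mass
    return 0.9 * spread * n ** (-0.2)


def _reflected_kde(x: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Gaussian KDE on [0, 1] with reflection at both boundaries.

    Reflection keeps the density mass of draws near 0 or 1 inside the unit
    interval, so each estimate integrates to ~1 on the grid.
    """
    h = _silverman_bw(x)
    dens = np.zeros_like(grid)
    norm = 1.0 / (x.size * h * math.sqrt(2.0 * math.pi))
    for source in (x, -x, 2.0 - x):  # data, reflection at 0, reflection at 1
        for chunk in np.array_split(source, max(1, source.size // 8192)):
            z = (grid[:, None] - chunk[None, :]) / h
            dens += np.exp(-0.5 * z * z).sum(axis=1)
    return dens * norm


def kde_overlap(a, b) -> float:
    """Overlap (in [0, 1]) of two differentiation-index posteriors.

    Both samples get a reflected Gaussian KDE (Silverman bandwidth) on a
    shared 512-point grid over [0, 1]; the overlap is the Simpson integral of
    the pointwise minimum.  Symmetric in its arguments and invariant to draw
    order.
    """
    xa, xb = _as_array(a), _as_array(b)
    for name, arr in (("a", xa), ("b", xb)):
        if arr.size < 100:
            raise ValueError(f"sample {name}: need >= 100 draws")
        if np.any(arr < 0) or np.any(arr > 1):
            raise ValueError(
                f"sample {name}: differentiation indices must lie in [0, 1]"
            )
    grid = np.linspace(0.0, 1.0, GRID_SIZE)
    da = _reflected_kde(xa, grid)
    db = _reflected_kde(xb, grid)
    ov = float(simpson(np.minimum(da, db), x=grid))
    return min(max(ov, 0.0), 1.0)


def compare(
    pst,
    fst: PosteriorDraws,
    overlap_threshold: float = 0.05,
    trait: "str | None" = None,
) -> DriftComparison:
    """Assemble the drift-vs-selection comparison for one trait/direction.

    ``pst`` may be a :class:`TraitFit` (its derived P_ST draws are used) or a
    draw container.  Drift is reported rejected iff the overlap is below the
    threshold AND the 5% P_ST quantile exceeds the 95% F_ST quantile.
    """
    if not 0.0 < overlap_threshold < 0.5:
        raise ValueError("overlap_threshold must lie in (0, 0.5)")
    if isinstance(pst, TraitFit):
        trait = trait or pst.spec.trait
        pst = pst.pst_draws()
    pst_arr = _as_array(pst)
    fst_arr = _as_array(fst)
    if pst_arr.size == 0 or fst_arr.size == 0:
        raise ValueError("empty draw sets")

    overlap = kde_overlap(pst_arr, fst_arr)
    pst_q05 = float(np.quantile(pst_arr, 0.05))
    fst_q95 = float(np.quantile(fst_arr, 0.95))
    crit = critical_c_over_h2(pst_arr, fst_arr)
    rejected = overlap < overlap_threshold and pst_q05 > fst_q95
    return DriftComparison(
        trait=trait or "trait",
        focal_population=getattr(fst, "population", "NA"),
        overlap=overlap,
        fst_q95=fst_q95,
        pst_q05=pst_q05,
        c_over_h2_critical=crit,
        verdict="drift_rejected" if rejected else "drift_not_rejected",
        overlap_threshold=overlap_threshold,
    )


def drift_report(
    comparisons: Sequence[DriftComparison],
    densities: "dict | None" = None,
) -> str:
    """Machine-readable JSON report keyed by trait x focal population.

    Deterministic: sorted keys, fixed float formatting via ``json.dumps``.
    ``densities`` may carry exported density curves (grid + values) to plot
    elsewhere.
    """
    if not comparisons:
        raise ValueError("need at least one comparison")
    entries = {}
    for c in comparisons:
        key = f"{c.trait}|{c.focal_population}"
        if key in entries:
            raise ValueError(f"duplicate comparison key {key}")
        entries[key] = c.to_dict()
    doc = {"comparisons": entries, "overlap_scale": "proportion"}
    if densities:
        doc["densities"] = densities
    return json.dumps(doc, sort_keys=True, indent=2)


def density_curves(samples: dict) -> dict:
    """Reflected-KDE curves on the shared grid, for CSV/plot export."""
    grid = np.linspace(0.0, 1.0, GRID_SIZE)
    out = {"grid": grid.tolist()}
    for name, draws in samples.items():
        out[name] = _reflected_kde(_as_array(draws), grid).tolist()
    return out
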