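"""Multi-locus sequence differentiation: Hedrick's G'_ST from haplotypes.

Workflow: filter alignment columns that violate the infinite-sites model
(more than two nucleotide states), call whole haplotypes as alleles, compute
Nei & Chesser (1983) small-sample-corrected heterozygosities H_S and H_T,
apply Hedrick's (2005) standardization with the finite-subpopulation
correction, pool across loci, and bootstrap a confidence interval.

Haploid sequence data are treated throughout: the observed-heterozygosity
correction term of the diploid Nei-Chesser estimators is identically zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from Bio import SeqIO

log = logging.getLogger(__name__)

MISSING = frozenset("-N")
ALPHABET = frozenset("ACGT-N")

__all__ = [
    "HaplotypeAlignment",
    "PopulationMap",
    "LocusDiversity",
    "GstResult",
    "filter_infinite_sites",
    "locus_heterozygosities",
    "gprime_st",
    "multilocus_gprime_st",
    "bootstrap_gprime",
]


@dataclass
class HaplotypeAlignment:
    """Equal-length haplotype sequences for one locus.

    Nucleotides are case-folded to upper case on construction; ``-`` and
    ``N`` are treated as missing data by downstream operations.
    """

    locus_name: str
    sequences: list
    sample_ids: list
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sequences = [str(s).upper() for s in self.sequences]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.sequences) < 2:
            raise ValueError(f"{self.locus_name}: need at least 2 sequences")
        if len(self.sequences) != len(self.sample_ids):
            raise ValueError(f"{self.locus_name}: one sample id per sequence")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError(f"{self.locus_name}: sample ids must be unique")
        L = len(self.sequences[0])
        for sid, seq in zip(self.sample_ids, self.sequences):
            if len(seq) != L:
                raise ValueError(
                    f"{self.locus_name}: sequence {sid} has length {len(seq)}"
                    f" != {L}"
                )
            bad = set(seq) - ALPHABET
            if bad:
                raise ValueError(
                    f"{self.locus_name}: sequence {sid} contains characters "
                    f"{sorted(bad)} outside ACGT-N"
                )

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    @classmethod
    def from_fasta(cls, path, locus_name: "str | None" = None) -> "HaplotypeAlignment":
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise ValueError(f"no sequences in {path}")
        name = locus_name or str(path).rsplit("/", 1)[-1].rsplit(".", 1)[0]
        return cls(
            locus_name=name,
            sequences=[str(r.seq) for r in records],
            sample_ids=[r.id for r in records],
        )

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for sid, seq in zip(self.sample_ids, self.sequences):
                fh.write(f">{sid}\n{seq}\n")


@dataclass
class PopulationMap:
    """sample_id -> population assignments."""

    assignments: dict

    def __post_init__(self) -> None:
        self.assignments = {str(k): str(v) for k, v in self.assignments.items()}

    @classmethod
    def from_tsv(cls, path) -> "PopulationMap":
        assignments = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise ValueError(
                        f"{path}: expected two tab-separated columns, got "
                        f"{line!r}"
                    )
                assignments[parts[0]] = parts[1]
        if not assignments:
            raise ValueError(f"{path}: empty population map")
        return cls(assignments)

    @property
    def populations(self) -> list:
        return sorted(set(self.assignments.values()))

    def require_covers(self, sample_ids: Sequence[str], locus: str = "") -> None:
        missing = [s for s in sample_ids if s not in self.assignments]
        if missing:
            where = f" in locus {locus}" if locus else ""
            raise ValueError(
                f"samples{where} absent from population map: {missing}"
            )


@dataclass(frozen=True)
class LocusDiversity:
    """Per-locus heterozygosity components for the G'_ST estimator."""

    locus_name: str
    hs: float
    ht: float
    k: int
    n_harmonic: float
    ht_adjusted: bool = False
    n_dropped_missing: int = 0


@dataclass(frozen=True)
class GstResult:
    """Multi-locus G_ST / G'_ST with a stratified-bootstrap interval."""

    gst: float
    gprime_st: float
    per_locus: tuple
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "gst": self.gst,
            "gprime_st": self.gprime_st,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_boot": self.n_boot,
            "seed": self.seed,
            "per_locus": [
                {
                    "locus": ld.locus_name,
                    "hs": ld.hs,
                    "ht": ld.ht,
                    "k": ld.k,
                    "n_harmonic": ld.n_harmonic,
                    "ht_adjusted": ld.ht_adjusted,
                    "n_dropped_missing": ld.n_dropped_missing,
                }
                for ld in self.per_locus
            ],
        }


def filter_infinite_sites(aln: HaplotypeAlignment) -> HaplotypeAlignment:
    """Drop alignment columns with more than two nucleotide states.

    ``-`` and ``N`` do not count as states.  Column order is preserved and the
    removed column indices are recorded in the result's
    ``metadata["removed_sites"]``.  Idempotent.
    """
    mat = np.array([list(s) for s in aln.sequences])
    keep, removed = [], []
    for j in range(mat.shape[1]):
        states = set(mat[:, j]) - MISSING
        (keep if len(states) <= 2 else removed).append(j)
    filtered = ["".join(row[keep]) for row in mat]
    out = HaplotypeAlignment(
        locus_name=aln.locus_name,
        sequences=filtered,
        sample_ids=list(aln.sample_ids),
        metadata=dict(aln.metadata),
    )
    out.metadata["removed_sites"] = removed
    return out


def _locus_arrays(aln: HaplotypeAlignment, pops: PopulationMap):
    """Haplotype labels and population indices for complete sequences.

    Sequences still containing missing data after filtering are dropped
    (haplotype identity is undefined with gaps) with a logged warning.
    """
    pops.require_covers(aln.sample_ids, aln.locus_name)
    pop_names = pops.populations
    pop_index = {p: i for i, p in enumerate(pop_names)}
    hap_index: dict = {}
    labels, pop_of = [], []
    n_dropped = 0
    for sid, seq in zip(aln.sample_ids, aln.sequences):
        if set(seq) & MISSING:
            n_dropped += 1
            continue
        labels.append(hap_index.setdefault(seq, len(hap_index)))
        pop_of.append(pop_index[pops.assignments[sid]])
    if n_dropped:
        log.warning(
            "%s: dropped %d sequence(s) with missing data from haplotype "
            "calling",
            aln.locus_name,
            n_dropped,
        )
    labels = np.asarray(labels, dtype=int)
    pop_of = np.asarray(pop_of, dtype=int)
    present = sorted(set(pop_of.tolist()))
    missing_pops = [p for p in pop_names if pop_index[p] not in present]
    if missing_pops:
        raise ValueError(
            f"{aln.locus_name}: population(s) {missing_pops} have zero "
            "complete sequences"
        )
    return labels, pop_of, pop_names, max(len(hap_index), 1), n_dropped


def _heterozygosities_from_counts(counts: np.ndarray):
    """Nei-Chesser corrected H_S / H_T from a (pops x haplotypes) count table.

    For haploid data the observed-heterozygosity terms vanish:
      H_S = n~/(n~-1) * (1 - mean_i sum_a p_ia^2)
      H_T = 1 - sum_a pbar_a^2 + H_S/(n~ * k)
    with n~ the harmonic mean sample size and pbar the unweighted mean of the
    per-population frequencies.
    """
    n_i = counts.sum(axis=1).astype(float)
    if np.any(n_i == 0):
        raise ValueError("population with zero sequences")
    k = counts.shape[0]
    n_harm = k / np.sum(1.0 / n_i)
    freqs = counts / n_i[:, None]
    hs = (n_harm / (n_harm - 1.0)) * (1.0 - np.mean(np.sum(freqs**2, axis=1)))
    pbar = freqs.mean(axis=0)
    ht = 1.0 - float(np.sum(pbar**2)) + hs / (n_harm * k)
    return float(hs), float(ht), int(k), float(n_harm)


def locus_heterozygosities(
    aln: HaplotypeAlignment, pops: PopulationMap
) -> LocusDiversity:
    """H_S, H_T and sample-size summaries treating haplotypes as alleles."""
    labels, pop_of, pop_names, n_hap, n_dropped = _locus_arrays(aln, pops)
    k = len(pop_names)
    if k < 2:
        raise ValueError("need >= 2 populations for differentiation")
    counts = np.zeros((k, n_hap), dtype=float)
    np.add.at(counts, (pop_of, labels), 1.0)
    hs, ht, k, n_harm = _heterozygosities_from_counts(counts)
    adjusted = False
    if ht < hs:  # estimator correction can invert the order by sampling noise
        ht, adjusted = hs, True
        log.warning("%s: H_T < H_S after correction; clamped", aln.locus_name)
    return LocusDiversity(
        locus_name=aln.locus_name,
        hs=hs,
        ht=ht,
        k=k,
        n_harmonic=n_harm,
        ht_adjusted=adjusted,
        n_dropped_missing=n_dropped,
    )


def _hedrick(hs: float, ht: float, k: int) -> float:
    gst = (ht - hs) / ht
    gprime = gst * (k - 1.0 + hs) / ((k - 1.0) * (1.0 - hs))
    return min(max(gprime, 0.0), 1.0)


def gprime_st(ld: LocusDiversity) -> float:
    """Hedrick's standardized G'_ST for one locus; NaN when monomorphic."""
    if ld.ht <= 0 or ld.hs >= 1.0:
        log.info("%s: monomorphic or degenerate locus; G'_ST undefined",
                 ld.locus_name)
        return math.nan
    return _hedrick(ld.hs, ld.ht, ld.k)


def _pooled(loci: Sequence[LocusDiversity]):
    informative = [ld for ld in loci if ld.ht > 0 and ld.hs < 1.0]
    if not informative:
        raise ValueError("all loci monomorphic; G'_ST undefined")
    skipped = len(loci) - len(informative)
    if skipped:
        log.info("excluded %d monomorphic locus/loci from pooling", skipped)
    ks = {ld.k for ld in informative}
    if len(ks) > 1:
        raise ValueError(f"inconsistent population counts across loci: {ks}")
    hs = float(np.mean([ld.hs for ld in informative]))
    ht = float(np.mean([ld.ht for ld in informative]))
    k = informative[0].k
    return hs, ht, k


def multilocus_gprime_st(loci: Sequence[LocusDiversity]) -> float:
    """Global G'_ST from arithmetic-mean pooled H_S and H_T across loci."""
    hs, ht, k = _pooled(loci)
    return _hedrick(hs, ht, k)


def multilocus_gst(loci: Sequence[LocusDiversity]) -> float:
    """Plain (unstandardized) global G_ST from pooled H_S / H_T."""
    hs, ht, _ = _pooled(loci)
    return (ht - hs) / ht


def bootstrap_gprime(
    alns: Sequence[HaplotypeAlignment],
    pops: PopulationMap,
    n_boot: int = 1000,
    seed: int = 0,
) -> GstResult:
    """Multi-locus G'_ST with a stratified bootstrap confidence interval.

    Each replicate resamples sequences with replacement within every
    (locus, population) stratum, preserving the per-population sample sizes
    the small-sample estimators correct for, then recomputes the pooled
    G'_ST.  The interval is the 2.5/97.5 empirical percentile of the
    replicates.  Deterministic given ``seed``.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100 for stable percentiles")
    filtered = [filter_infinite_sites(a) for a in alns]
    per_locus = []
    locus_data = []
    for aln in filtered:
        labels, pop_of, pop_names, n_hap, _ = _locus_arrays(aln, pops)
        locus_data.append((labels, pop_of, len(pop_names), n_hap))
        per_locus.append(locus_heterozygosities(aln, pops))
    point_gst = multilocus_gst(per_locus)
    point = multilocus_gprime_st(per_locus)

    rng = np.random.default_rng(seed)
    reps = np.empty(n_boot)
    for b in range(n_boot):
        lds = []
        for (labels, pop_of, k, n_hap), ld0 in zip(locus_data, per_locus):
            counts = np.zeros((k, n_hap))
            for p in range(k):
                idx = np.flatnonzero(pop_of == p)
                resampled = labels[idx[rng.integers(0, idx.size, idx.size)]]
                np.add.at(counts[p], resampled, 1.0)
            hs, ht, _, n_harm = _heterozygosities_from_counts(counts)
            ht = max(ht, hs)
            lds.append(
                LocusDiversity(ld0.locus_name, hs, ht, k, n_harm)
            )
        try:
            reps[b] = multilocus_gprime_st(lds)
        except ValueError:  # every locus monomorphic in this replicate
            reps[b] = math.nan
    reps = reps[np.isfinite(reps)]
    if reps.size == 0:
        raise ValueError("all bootstrap replicates undefined")
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return GstResult(
        gst=point_gst,
        gprime_st=point,
        per_locus=tuple(per_locus),
        ci_low=float(lo),
        ci_high=float(hi),
        n_boot=n_boot,
        seed=seed,
    )
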