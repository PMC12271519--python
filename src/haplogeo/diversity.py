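"""Diversity indices and neutrality tests for haplotype samples.

Implements the classical mitochondrial diversity statistics -- pairwise
difference matrices under three gap conventions, haplotype diversity
(Nei 1987), mean pairwise differences k with its total variance
(Tajima 1983), nucleotide diversity pi = k/L -- plus the two standard
neutrality tests:

* Tajima's D, computed from the segregating-site count S and the
  substitutions-only mean pairwise difference (gap columns excluded, as is
  conventional when an indel segregates in the sample);
* Fu's Fs, the log-odds of observing at least the sampled number of
  alleles under the Ewens sampling distribution at theta estimated by k.

Significance for both tests is obtained by simulation under the standard
neutral coalescent (see :mod:`haplogeo.synthetic_data`), mirroring the
approach of the standard population-genetics packages.

All Ewens/Stirling arithmetic is carried out in log space; there is no
intermediate overflow for sample sizes up to at least n = 1000.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Callable, Sequence

import numpy as np

from .seqdata import HaplotypeTable

__all__ = [
    "DistanceMode",
    "DistanceMatrix",
    "DiversityStats",
    "TajimaConstants",
    "EwensModel",
    "NeutralityResult",
    "sequence_distance",
    "pairwise_distances",
    "haplotype_diversity",
    "mean_pairwise_differences",
    "nucleotide_diversity",
    "segregating_sites",
    "tajima_constants",
    "tajimas_d",
    "ewens_log_pmf",
    "fus_fs",
    "neutrality_pvalue",
    "diversity_summary",
]


class DistanceMode(str, Enum):
    """Gap convention for pairwise sequence distances.

    ``PER_COLUMN_GAP`` counts every differing column, gap-versus-base
    columns included (ARLEQUIN's "including sites with gaps").
    ``INDEL_AS_EVENT`` counts each maximal contiguous gap-versus-base run
    as a single mutational event. ``SUBSTITUTIONS_ONLY`` ignores gap
    columns entirely. ``N`` never contributes in any mode.
    """

    PER_COLUMN_GAP = "PER_COLUMN_GAP"
    INDEL_AS_EVENT = "INDEL_AS_EVENT"
    SUBSTITUTIONS_ONLY = "SUBSTITUTIONS_ONLY"


def sequence_distance(a: str, b: str, mode: DistanceMode) -> int:
    """Distance between two equal-length aligned sequences under `mode`.

    This two-sequence view deletes gap (``SUBSTITUTIONS_ONLY``) and ``N``
    columns pairwise; masked columns can hide differences, so this
    function is not guaranteed metric under those deletions. Matrices
    built by :func:`pairwise_distances` exclude gap columns alignment-wide
    instead.
    """
    if len(a) != len(b):
        raise ValueError("sequences must be aligned to equal length")
    mode = DistanceMode(mode)
    subs = 0
    gap_cols = 0
    runs = 0
    in_run = False
    for x, y in zip(a, b):
        if x == "N" or y == "N":
            in_run = False
            continue
        xg, yg = x == "-", y == "-"
        if xg != yg:
            gap_cols += 1
            if not in_run:
                runs += 1
            in_run = True
        else:
            in_run = False
            if not xg and x != y:
                subs += 1
    if mode is DistanceMode.SUBSTITUTIONS_ONLY:
        return subs
    if mode is DistanceMode.INDEL_AS_EVENT:
        return subs + runs
    return subs + gap_cols


@dataclass(frozen=True)
class DistanceMatrix:
    haplotype_ids: tuple[str, ...]
    d: np.ndarray  # symmetric, zero diagonal
    mode: DistanceMode

    def value(self, a: str, b: str) -> float:
        i = self.haplotype_ids.index(a)
        j = self.haplotype_ids.index(b)
        return float(self.d[i, j])

    def offdiagonal(self) -> np.ndarray:
        iu = np.triu_indices(len(self.haplotype_ids), k=1)
        return self.d[iu]


def pairwise_distances(table: HaplotypeTable, mode: DistanceMode) -> DistanceMatrix:
    """Distance matrix between a table's canonical haplotype sequences.

    Under ``SUBSTITUTIONS_ONLY`` every column holding a gap in any
    haplotype is removed alignment-wide before comparison (the DnaSP
    convention, and the only reading under which the triangle inequality
    is guaranteed); the other two modes need no global column view.
    """
    mode = DistanceMode(mode)
    seqs = [e.sequence for e in table.entries]
    if mode is DistanceMode.SUBSTITUTIONS_ONLY:
        keep = [
            c for c in range(len(seqs[0])) if all(s[c] != "-" for s in seqs)
        ]
        seqs = ["".join(s[c] for c in keep) for s in seqs]
    h = len(seqs)
    d = np.zeros((h, h))
    for i in range(h):
        for j in range(i + 1, h):
            d[i, j] = d[j, i] = sequence_distance(seqs[i], seqs[j], mode)
    return DistanceMatrix(table.ids, d, mode)


def haplotype_diversity(counts: Sequence[int], n: int | None = None) -> tuple[float, float]:
    """Unbiased haplotype (gene) diversity and its standard deviation.

    Hd = n/(n-1) * (1 - sum p_i^2); the sd comes from Nei's (1987)
    sampling-variance formula, the convention used by ARLEQUIN.
    """
    counts = np.asarray(counts, dtype=float)
    if n is None:
        n = int(counts.sum())
    if n < 2:
        raise ValueError("haplotype diversity requires n >= 2")
    if counts.sum() != n:
        raise ValueError("counts must sum to n")
    p = counts / n
    s2 = float(np.sum(p**2))
    s3 = float(np.sum(p**3))
    hd = n / (n - 1) * (1.0 - s2)
    var = (2.0 / (n * (n - 1))) * (
        2.0 * (n - 2) * (s3 - s2**2) + s2 - s2**2
    )
    return hd, math.sqrt(max(var, 0.0))


def mean_pairwise_differences(
    table: HaplotypeTable, mode: DistanceMode
) -> tuple[float, float]:
    """Mean pairwise differences k over all individual pairs, with sd.

    k is the frequency-weighted mean of the haplotype distance matrix
    over the n(n-1)/2 pairs of sampled individuals. The sd is the square
    root of Tajima's (1983) total variance (stochastic + sampling, no
    recombination), V(k) = (3n(n+1)k + 2(n^2+n+3)k^2) / (11(n^2-7n+6)).
    """
    n = table.n_total
    if n < 2:
        raise ValueError("k requires n >= 2")
    dm = pairwise_distances(table, mode)
    c = np.asarray(table.counts, dtype=float)
    total = float(c @ dm.d @ c) / 2.0  # within-class distance is 0
    npairs = n * (n - 1) / 2.0
    k = total / npairs
    var = (3.0 * n * (n + 1) * k + 2.0 * (n**2 + n + 3) * k**2) / (
        11.0 * (n**2 - 7 * n + 6)
    )
    return k, math.sqrt(max(var, 0.0))


def nucleotide_diversity(k: float, L: int) -> float:
    """pi = k / L for an alignment of L sites."""
    if L <= 0:
        raise ValueError("L must be positive")
    return k / L


def segregating_sites(table: HaplotypeTable, exclude_gaps: bool = True) -> int:
    """Number of polymorphic columns among the canonical sequences.

    With ``exclude_gaps`` (the Tajima's-D convention here), columns where
    any haplotype carries a gap are skipped; ``N`` never counts as a state.
    """
    seqs = [e.sequence for e in table.entries]
    S = 0
    for col in range(len(seqs[0])):
        states = {s[col] for s in seqs} - {"N"}
        if exclude_gaps and "-" in states:
            continue
        if len(states) >= 2:
            S += 1
    return S


@dataclass(frozen=True)
class TajimaConstants:
    """Tajima's (1989) normalising constants, functions of n only."""

    n: int
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float


def tajima_constants(n: int) -> TajimaConstants:
    if n < 4:
        raise ValueError("Tajima's constants require n >= 4")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return TajimaConstants(n, a1, a2, b1, b2, c1, c2, e1, e2)


def tajimas_d(n: int, S: int, k_subst: float) -> float:
    """Tajima's D from n, segregating sites S, and substitutions-only k.

    Returns ``nan`` (undefined, no division attempted) when S = 0.
    """
    if S < 0:
        raise ValueError("S must be non-negative")
    if S == 0:
        return float("nan")
    c = tajima_constants(n)
    return (k_subst - S / c.a1) / math.sqrt(c.e1 * S + c.e2 * S * (S - 1))


# --- Ewens sampling distribution / Fu's Fs --------------------------------

_log_stirling_cache: dict[int, np.ndarray] = {}


def _log_stirling_row(n: int) -> np.ndarray:
    """log |s(n, k)| for k = 0..n (unsigned Stirling, first kind).

    Triangle recursion |s(m+1,k)| = m|s(m,k)| + |s(m,k-1)|, kept in log
    space row by row.
    """
    if n in _log_stirling_cache:
        return _log_stirling_cache[n]
    row = np.full(n + 1, -np.inf)
    row[0] = 0.0  # |s(0,0)| = 1
    for m in range(1, n + 1):
        new = np.full(n + 1, -np.inf)
        new[1 : m + 1] = row[0:m]  # |s(m, k-1)| term
        if m > 1:
            new[1:m] = np.logaddexp(new[1:m], math.log(m - 1) + row[1:m])
        row = new
    _log_stirling_cache[n] = row
    return row


def ewens_log_pmf(n: int, theta: float) -> np.ndarray:
    """log Pr(K = k | theta, n) for k = 1..n under the Ewens distribution.

    Pr(K = k) = |s(n,k)| theta^k / (theta)_n with (theta)_n the rising
    factorial; evaluated entirely in log space.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if theta <= 0:
        raise ValueError("theta must be positive")
    log_s = _log_stirling_row(n)[1:]
    log_rise = float(np.sum(np.log(theta + np.arange(n))))
    k = np.arange(1, n + 1)
    return log_s + k * math.log(theta) - log_rise


@dataclass(frozen=True)
class EwensModel:
    theta: float
    n: int
    K_obs: int
    S_prime: float  # Pr(K >= K_obs)
    Fs: float


def fus_fs(n: int, K_obs: int, theta: float) -> tuple[float, EwensModel]:
    """Fu's Fs = ln(S' / (1 - S')) with S' = Pr(K >= K_obs | theta, n).

    Computed as log S' minus the log of the explicit lower-tail sum, which
    keeps the statistic exact at the symmetric point and stable when one
    tail is tiny. A tail that underflows to probability 0 yields a signed
    infinity (flagged through the returned model, never raised).
    """
    if not 1 <= K_obs <= n:
        raise ValueError("K_obs must be in 1..n")
    logp = ewens_log_pmf(n, theta)
    from scipy.special import logsumexp

    log_upper = logsumexp(logp[K_obs - 1 :])
    if K_obs == 1:
        fs = float("inf")
        s_prime = 1.0
    else:
        log_lower = logsumexp(logp[: K_obs - 1])
        fs = float(log_upper - log_lower)
        s_prime = float(np.exp(log_upper))
    return fs, EwensModel(theta, n, K_obs, s_prime, fs)


# --- simulation p-values ---------------------------------------------------


@dataclass(frozen=True)
class NeutralityResult:
    statistic: str
    observed: float
    p: float
    tail: str  # "lower" or "upper"
    n_reps: int
    seed: int
    null_mean: float
    null_median: float


def _stats_from_patterns(patterns: np.ndarray) -> tuple[int, float, int]:
    """(S, mean pairwise differences, distinct haplotypes) from a 0/1
    site-by-sample pattern matrix of shape (n, S)."""
    n = patterns.shape[0]
    S = patterns.shape[1]
    if S == 0:
        return 0, 0.0, 1
    counts = patterns.sum(axis=0)
    k = float(np.sum(counts * (n - counts))) / (n * (n - 1) / 2.0)
    K = len({tuple(row) for row in patterns})
    return S, k, K


def neutrality_pvalue(
    statistic: str,
    observed: float,
    n: int,
    conditioning: str = "FIXED_S",
    value: float = 5,
    n_reps: int = 1000,
    seed: int = 0,
    sampler: Callable[..., "object"] | None = None,
) -> NeutralityResult:
    """One-tailed simulation p-value for Tajima's D or Fu's Fs.

    Replicates are drawn under the standard neutral coalescent,
    conditioned either on the segregating-site count (``FIXED_S``,
    default, the convention matching a D computed from a fixed S) or on
    ``THETA``. The tail is chosen toward the observed direction: p is the
    proportion of replicate statistics <= observed when the observed value
    falls below the null median, and >= observed otherwise.

    ``statistic`` is ``"tajimas_d"`` or ``"fus_fs"``; ``sampler`` defaults
    to :func:`haplogeo.synthetic_data.coalescent_sample`.
    """
    if statistic not in ("tajimas_d", "fus_fs"):
        raise ValueError(f"unknown statistic: {statistic}")
    if n_reps < 100:
        raise ValueError("n_reps must be >= 100")
    if sampler is None:
        from .synthetic_data import coalescent_sample as sampler  # type: ignore

    rng = np.random.default_rng(seed)
    null = np.empty(n_reps)
    for r in range(n_reps):
        sample = sampler(n, conditioning=conditioning, value=value, rng=rng)
        S, k, K = _stats_from_patterns(sample.patterns)
        if statistic == "tajimas_d":
            null[r] = tajimas_d(n, S, k) if S > 0 else 0.0
        else:
            if K == 1 or k <= 0:
                # monomorphic replicate: no allele spread, treat as the
                # most expansion-like extreme (Fs -> +inf direction is
                # K_obs = 1 certain), conventionally +inf
                null[r] = float("inf")
            else:
                null[r] = fus_fs(n, K, k)[0]
    null_median = float(np.median(null))
    if observed < null_median:
        p = float(np.mean(null <= observed))
        tail = "lower"
    else:
        p = float(np.mean(null >= observed))
        tail = "upper"
    return NeutralityResult(
        statistic, observed, p, tail, n_reps, seed,
        float(np.mean(null[np.isfinite(null)])), null_median,
    )


@dataclass(frozen=True)
class DiversityStats:
    """One row of a diversity summary (the usual Table-of-indices shape)."""

    n: int
    h: int
    S: int
    pi: float
    pi_sd: float
    Hd: float
    Hd_sd: float
    k: float
    k_sd: float
    L: int


def diversity_summary(
    table: HaplotypeTable,
    headline_mode: DistanceMode = DistanceMode.PER_COLUMN_GAP,
) -> DiversityStats:
    """Aggregate diversity indices for one haplotype table.

    ``S`` counts all polymorphic columns (gap columns included, matching
    the headline per-column convention); k and pi use ``headline_mode``.
    """
    L = len(table.entries[0].sequence)
    hd, hd_sd = haplotype_diversity(table.counts, table.n_total)
    k, k_sd = mean_pairwise_differences(table, headline_mode)
    return DiversityStats(
        n=table.n_total,
        h=len(table.entries),
        S=segregating_sites(table, exclude_gaps=False),
        pi=nucleotide_diversity(k, L),
        pi_sd=k_sd / L,
        Hd=hd,
        Hd_sd=hd_sd,
        k=k,
        k_sd=k_sd,
        L=L,
    )
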