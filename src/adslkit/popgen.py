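"""Selection-signature statistics on phased haplotype panels.

Implements the classical site-frequency-spectrum summaries (segregating
sites S, nucleotide diversity pi, Tajima's D) on binary haplotype
matrices, sliding-window scans over a genomic region, Hardy-Weinberg
carrier frequencies, population-scaled selection coefficients, a diploid
Wright-Fisher allele-frequency simulator under genic selection, and
empirical p-values against frequency-matched control variants.

Tajima's D contrasts two estimators of the scaled mutation rate theta:
mean pairwise diversity pi and Watterson's S/a1. An excess of rare
alleles -- the footprint left by a recent selective sweep -- drives pi
below S/a1 and D below zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "HaplotypeMatrix",
    "WindowStat",
    "WFTrajectory",
    "EmpiricalNull",
    "diversity_stats",
    "tajimas_d",
    "tajima_constants",
    "sliding_window_scan",
    "carrier_frequency",
    "scaled_selection_coefficient",
    "wright_fisher_trajectory",
    "wf_fixation_probability",
    "diffusion_fixation_probability",
    "empirical_null_pvalue",
]

NEARLY_NEUTRAL_THRESHOLD = 1.0  # |2*Ne*s| below this: drift dominates


@dataclass
class HaplotypeMatrix:
    """Phased biallelic haplotypes: n haplotypes x m sites, entries 0/1.

    Positions are 1-based base-pair coordinates, strictly increasing.
    Convention: 1 is the derived (ALT) allele unless an ancestral-allele
    annotation said otherwise at construction time.
    """

    matrix: np.ndarray
    positions: np.ndarray
    contig: str = "chr"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.matrix.ndim != 2:
            raise ValueError("haplotype matrix must be 2-dimensional")
        if self.matrix.shape[1] != self.positions.shape[0]:
            raise ValueError(
                f"{self.matrix.shape[1]} matrix columns but "
                f"{self.positions.shape[0]} positions"
            )
        if self.positions.size and np.any(np.diff(self.positions) <= 0):
            raise ValueError("site positions must be strictly increasing")
        bad = ~np.isin(self.matrix, (0, 1))
        if bad.any():
            raise ValueError("haplotype entries must be 0 or 1")

    @property
    def n_haplotypes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    def segregating(self) -> "HaplotypeMatrix":
        """Drop monomorphic columns (derived count 0 or n)."""
        counts = self.matrix.sum(axis=0)
        keep = (counts > 0) & (counts < self.n_haplotypes)
        return HaplotypeMatrix(
            self.matrix[:, keep], self.positions[keep], self.contig, dict(self.metadata)
        )


@dataclass
class WindowStat:
    """Per-window diversity summary; D is None when undefined."""

    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    n_haplotypes: int
    S: int
    pi: float
    D: float | None


@dataclass
class WFTrajectory:
    """A diploid Wright-Fisher allele-frequency path.

    ``freqs`` has length T+1 with freqs[0] == p0; once the frequency
    hits 0 or 1 it stays there.
    """

    N: int
    s: float
    p0: float
    freqs: np.ndarray

    @property
    def outcome(self) -> str:
        last = self.freqs[-1]
        if last == 0.0:
            return "lost"
        if last == 1.0:
            return "fixed"
        return "segregating"


@dataclass
class EmpiricalNull:
    """Empirical p-value of a focal statistic against frequency-matched controls."""

    focal_freq: float
    focal_stat: float
    control_freqs: np.ndarray
    control_stats: np.ndarray
    delta: float
    direction: str
    n_matched: int
    p_value: float


def diversity_stats(hap: HaplotypeMatrix) -> tuple[int, float]:
    """Segregating sites S and nucleotide diversity pi.

    pi is the average number of pairwise differences over all
    n*(n-1)/2 haplotype pairs, computed from per-site derived-allele
    counts c as sum over sites of 2*c*(n-c) / (n*(n-1)).
    """
    n = hap.n_haplotypes
    if n < 2:
        raise ValueError("need at least 2 haplotypes")
    counts = hap.matrix.sum(axis=0, dtype=np.int64)
    seg = (counts > 0) & (counts < n)
    S = int(seg.sum())
    c = counts[seg].astype(np.float64)
    pi = float(np.sum(2.0 * c * (n - c)) / (n * (n - 1)))
    return S, pi


def tajima_constants(n: int) -> dict[str, float]:
    """The a1, a2, b1, b2, c1, c2, e1, e2 constants of Tajima's D for n haplotypes."""
    if n < 2:
        raise ValueError("constants need n >= 2")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d(hap: HaplotypeMatrix) -> float | None:
    """Tajima's D, or None when undefined (S = 0 or n < 4).

    D = (pi - S/a1) / sqrt(e1*S + e2*S*(S-1)).

    The n < 4 policy is deliberate: the variance constants are
    ill-behaved at tiny sample sizes, so such panels are reported as
    undefined rather than returning an unstable number.
    """
    n = hap.n_haplotypes
    if n < 4:
        return None
    S, pi = diversity_stats(hap)
    if S == 0:
        return None
    k = tajima_constants(n)
    var = k["e1"] * S + k["e2"] * S * (S - 1)
    return float((pi - S / k["a1"]) / math.sqrt(var))


def sliding_window_scan(
    hap: HaplotypeMatrix, window_bp: int, step_bp: int
) -> list[WindowStat]:
    """Tile [first position, last position] with windows and summarize each.

    Windows are reported 1-based inclusive; internally the arithmetic is
    half-open [start, start + window_bp). Empty windows get S = 0 and an
    undefined D. Returns an empty list when the matrix has no sites.
    """
    if step_bp < 1 or window_bp < step_bp:
        raise ValueError("require window_bp >= step_bp >= 1")
    if hap.n_sites == 0:
        return []
    pos = hap.positions
    first, last = int(pos[0]), int(pos[-1])
    out: list[WindowStat] = []
    start = first
    while True:
        stop = start + window_bp  # half-open
        in_win = (pos >= start) & (pos < stop)
        sub = HaplotypeMatrix(hap.matrix[:, in_win], pos[in_win], hap.contig)
        S, pi = diversity_stats(sub) if hap.n_haplotypes >= 2 else (0, 0.0)
        out.append(
            WindowStat(
                start=start,
                end=stop - 1,
                n_haplotypes=hap.n_haplotypes,
                S=S,
                pi=pi,
                D=tajimas_d(sub),
            )
        )
        if stop > last:
            break
        start += step_bp
    return out


def window_stats_frame(windows: Sequence[WindowStat], contig: str = "chr") -> pd.DataFrame:
    """Tabular form of a scan (contig, start, end, n, S, pi, D)."""
    return pd.DataFrame(
        {
            "contig": contig,
            "start": [w.start for w in windows],
            "end": [w.end for w in windows],
            "n": [w.n_haplotypes for w in windows],
            "S": [w.S for w in windows],
            "pi": [w.pi for w in windows],
            "D": [np.nan if w.D is None else w.D for w in windows],
        }
    )


def carrier_frequency(p: float) -> float:
    """Fraction of individuals carrying >= 1 copy of an allele at frequency p.

    Under Hardy-Weinberg equilibrium: 1 - (1 - p)^2.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"allele frequency must lie in [0, 1], got {p}")
    return 1.0 - (1.0 - p) ** 2


def scaled_selection_coefficient(s: float, Ne: int | float) -> tuple[float, bool]:
    """Population-scaled selection coefficient alpha = 2*Ne*s.

    Returns (alpha, above_nearly_neutral) where the flag marks
    |alpha| > 1, the conventional threshold separating selection from
    nearly neutral evolution. Note the 2*Ne*s convention (not 4*Ne*s).
    """
    if Ne <= 0:
        raise ValueError("Ne must be positive")
    alpha = 2.0 * Ne * s
    return alpha, abs(alpha) > NEARLY_NEUTRAL_THRESHOLD


def _wf_update(p: np.ndarray | float, s: float) -> np.ndarray | float:
    """Deterministic post-selection frequency under genic selection.

    Genotype fitnesses 1, 1+s, 1+2s give marginal allele fitness
    1 + s(1+p) and mean fitness 1 + 2sp, hence

        p' = p * (1 + s*(1 + p)) / (1 + 2*s*p).
    """
    return p * (1.0 + s * (1.0 + p)) / (1.0 + 2.0 * s * p)


def wright_fisher_trajectory(
    N: int, s: float, p0: float, T: int, seed: int | np.random.Generator
) -> WFTrajectory:
    """Simulate one diploid Wright-Fisher allele-frequency path.

    Each generation the next allele count is Binomial(2N, p') with p'
    the genic-selection update; 0 and 1 are absorbing.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if not 0.0 <= p0 <= 1.0:
        raise ValueError("p0 must lie in [0, 1]")
    if T < 1:
        raise ValueError("T must be >= 1")
    rng = np.random.default_rng(seed)
    freqs = np.empty(T + 1, dtype=np.float64)
    freqs[0] = p = p0
    two_n = 2 * N
    for t in range(1, T + 1):
        if p == 0.0 or p == 1.0:
            freqs[t:] = p
            break
        p = rng.binomial(two_n, _wf_update(p, s)) / two_n
        freqs[t] = p
    return WFTrajectory(N=N, s=s, p0=p0, freqs=freqs)


def wf_fixation_probability(
    N: int,
    s: float,
    p0: float,
    replicates: int,
    seed: int | np.random.Generator,
    max_generations: int | None = None,
) -> float:
    """Monte-Carlo fixation probability over vectorized WF replicates.

    Runs all replicates in lockstep until every path is absorbed or
    ``max_generations`` (default 40N) elapses; unabsorbed paths count as
    not fixed.
    """
    rng = np.random.default_rng(seed)
    if max_generations is None:
        max_generations = 40 * N
    two_n = 2 * N
    p = np.full(replicates, p0, dtype=np.float64)
    active = np.ones(replicates, dtype=bool)
    for _ in range(max_generations):
        if not active.any():
            break
        pa = p[active]
        p[active] = rng.binomial(two_n, _wf_update(pa, s)) / two_n
        active &= (p > 0.0) & (p < 1.0)
    return float(np.mean(p == 1.0))


def diffusion_fixation_probability(N: int, s: float, p0: float) -> float:
    """Kimura's diffusion fixation probability for genic selection.

    u(p0) = (1 - exp(-4*N*s*p0)) / (1 - exp(-4*N*s)); the neutral limit
    is p0.
    """
    if s == 0.0:
        return p0
    return float(np.expm1(-4.0 * N * s * p0) / np.expm1(-4.0 * N * s))


def empirical_null_pvalue(
    focal: tuple[float, float],
    controls: Sequence[tuple[float, float]],
    delta: float,
    direction: Literal["greater", "less"] = "greater",
) -> EmpiricalNull:
    """Empirical p of a focal statistic against frequency-matched controls.

    Controls within ``delta`` of the focal allele frequency are
    retained; for direction "greater" the p-value is
    (1 + #{matched controls with stat >= focal stat}) / (M + 1),
    mirrored for "less". This is the add-one empirical rank rule, so
    p >= 1/(M+1) always.
    """
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    f_freq, f_stat = focal
    arr = np.asarray(controls, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("controls must be (frequency, statistic) pairs")
    matched = np.abs(arr[:, 0] - f_freq) <= delta
    m = int(matched.sum())
    if m == 0:
        raise ValueError(
            f"no control variants within delta={delta} of focal frequency "
            f"{f_freq}; increase delta"
        )
    stats = arr[matched, 1]
    if direction == "greater":
        extreme = int(np.sum(stats >= f_stat))
    else:
        extreme = int(np.sum(stats <= f_stat))
    p = (1 + extreme) / (m + 1)
    return EmpiricalNull(
        focal_freq=f_freq,
        focal_stat=f_stat,
        control_freqs=arr[matched, 0],
        control_stats=stats,
        delta=delta,
        direction=direction,
        n_matched=m,
        p_value=p,
    )
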