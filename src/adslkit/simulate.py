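"""Synthetic data generators matching the structure each analysis assumes.

Three generators, all pure functions of (parameters, seed):

* **Visit streams** -- an exponential latency race at water onset. Each
  animal's first visit after onset arrives after an Exp(rate) latency
  with rate lambda*theta for hAdsl animals and lambda for WT; later
  visits follow a homogeneous Poisson process at the same rate until
  the session ends. theta = 1 is the exchangeable null; theta > 1
  makes humanized animals faster. The race has closed-form checks: in
  a 1-vs-1 race with multiplier theta, the hAdsl animal arrives first
  with probability theta/(theta+1).

* **Metabolite tables** -- log-normal peak areas with a per-tissue
  genotype fold effect on target metabolites, multiplicative per-sample
  scale factors (what upper-quartile normalization must remove) and
  unaffected background metabolites.

* **Haplotype panels** -- a forward-time diploid Wright-Fisher
  population with infinite-sites mutation and no recombination,
  optionally with a single selected mutant (fitnesses 1, 1+s, 1+2s)
  injected and conditioned on survival by rejection sampling. A fast
  neutral-spectrum alternative draws site frequencies directly from
  the standard neutral SFS (P(count=i) proportional to 1/i).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .behavior import HADSL, WT
from .metabolomics import MetaboliteTable
from .popgen import HaplotypeMatrix

__all__ = [
    "VisitSimParams",
    "MetaboliteSimParams",
    "simulate_visit_stream",
    "simulate_metabolite_table",
    "simulate_haplotypes_wf",
    "simulate_neutral_panel_sfs",
    "make_roster",
]

#: default corner-choice weights: uniform over the four corners
UNIFORM_CORNERS = (0.25, 0.25, 0.25, 0.25)


def make_roster(
    n_hadsl: int = 5,
    n_wt: int = 5,
    n_cages: int = 1,
    sex: str = "F",
    prefix: str = "m",
) -> pd.DataFrame:
    """A roster of ``n_cages`` cages, each with n_hadsl + n_wt animals of one sex.

    Mirrors the housing design of five to eight animals per genotype
    per cage, same sex throughout a cage.
    """
    rows = []
    for c in range(1, n_cages + 1):
        for i in range(n_hadsl):
            rows.append((f"{prefix}{c}h{i+1}", HADSL, sex, f"cage{c}"))
        for i in range(n_wt):
            rows.append((f"{prefix}{c}w{i+1}", WT, sex, f"cage{c}"))
    return pd.DataFrame(rows, columns=["animal", "genotype", "sex", "cage"])


@dataclass
class VisitSimParams:
    """Parameters of the water-competition visit simulator.

    ``lam`` is the base visit rate in visits per animal per hour;
    ``theta`` multiplies the rate for hAdsl animals (1 = null);
    ``onset`` is the water-onset time in seconds from day start and
    ``session_s`` how long the session lasts after onset.
    """

    roster: pd.DataFrame
    n_days: int = 9
    onset: float = 0.0
    session_s: float = 3 * 3600.0
    theta: float = 1.0
    lam: float = 6.0
    corner_weights: Sequence[float] = UNIFORM_CORNERS
    seed: int | np.random.Generator = 0

    def validate(self) -> None:
        if self.theta <= 0:
            raise ValueError("theta must be > 0")
        if self.lam <= 0:
            raise ValueError("lam must be > 0")
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        w = np.asarray(self.corner_weights, dtype=np.float64)
        if w.shape != (4,) or (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("corner_weights must be 4 nonnegative numbers summing to 1")


def simulate_visit_stream(params: VisitSimParams) -> pd.DataFrame:
    """Simulate a visit-event stream for every animal on every day.

    Per animal per day, the first visit latency after onset is
    exponential with rate lambda*theta (hAdsl) or lambda (WT); later
    visits arrive as a homogeneous Poisson process at the same rate
    until the session ends. Corners are drawn independently from the
    choice weights; lick counts are Poisson(20) per visit. Events are
    sorted by (cage, day, timestamp, animal).
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    lam_s = params.lam / 3600.0  # per second
    w = np.asarray(params.corner_weights, dtype=np.float64)
    end = params.onset + params.session_s
    rows: list[tuple] = []
    roster = params.roster.sort_values(["cage", "animal"])
    for day in range(1, params.n_days + 1):
        for animal, genotype, _sex, cage in roster[
            ["animal", "genotype", "sex", "cage"]
        ].itertuples(index=False):
            rate = lam_s * (params.theta if genotype == HADSL else 1.0)
            t1 = params.onset + rng.exponential(1.0 / rate)
            if t1 >= end:
                continue
            # homogeneous process after the first arrival: Poisson count,
            # order statistics of uniforms
            n_later = rng.poisson(rate * (end - t1))
            times = np.concatenate(([t1], np.sort(rng.uniform(t1, end, n_later))))
            corners = rng.choice(4, size=times.size, p=w) + 1
            licks = rng.poisson(20, size=times.size)
            rows.extend(
                (cage, day, float(t), animal, int(c), int(lk))
                for t, c, lk in zip(times, corners, licks)
            )
    events = pd.DataFrame(
        rows, columns=["cage", "day", "timestamp", "animal", "corner", "licks"]
    )
    return events.sort_values(
        ["cage", "day", "timestamp", "animal"], kind="mergesort"
    ).reset_index(drop=True)


@dataclass
class MetaboliteSimParams:
    """Parameters of the peak-area table simulator.

    The design is tissues x sexes x genotypes x replicates. Target
    metabolites get a per-tissue genotype fold effect (> 0; 1 = null)
    applied to hAdsl samples; background metabolites are unaffected and
    make the per-sample upper quartile robust. Values are
    baseline * fold^(genotype==hAdsl) * scale * exp(N(0, sigma^2)),
    with the per-sample scale drawn log-uniformly from scale_range and
    recorded in the metadata (column ``true_scale``) for tests.
    """

    tissues: Sequence[str] = ("forebrain", "liver", "muscle")
    sexes: Sequence[str] = ("F", "M")
    n_replicates: int = 6
    metabolites: Sequence[str] = ("SAICAr", "S-Ado")
    n_background: int = 18
    baseline: float | Mapping = 1000.0
    fold: float | Mapping = 2.0
    sigma: float = 0.1
    scale_range: tuple[float, float] = (0.5, 2.0)
    seed: int | np.random.Generator = 0

    def _lookup(self, table, metabolite: str, tissue: str, default: float) -> float:
        if not isinstance(table, Mapping):
            return float(table)
        if (metabolite, tissue) in table:
            return float(table[(metabolite, tissue)])
        if metabolite in table:
            return float(table[metabolite])
        if tissue in table:
            return float(table[tissue])
        return default

    def baseline_of(self, metabolite: str, tissue: str) -> float:
        return self._lookup(self.baseline, metabolite, tissue, 1000.0)

    def fold_of(self, metabolite: str, tissue: str) -> float:
        return self._lookup(self.fold, metabolite, tissue, 1.0)

    def validate(self) -> None:
        if self.n_replicates < 2:
            raise ValueError("need >= 2 replicates per design cell")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        lo, hi = self.scale_range
        if not 0 < lo <= hi:
            raise ValueError("scale_range must be 0 < lo <= hi")
        for m in self.metabolites:
            for t in self.tissues:
                if self.baseline_of(m, t) <= 0:
                    raise ValueError(f"nonpositive baseline for ({m}, {t})")
                if self.fold_of(m, t) <= 0:
                    raise ValueError(f"nonpositive fold for ({m}, {t})")


def simulate_metabolite_table(params: MetaboliteSimParams) -> MetaboliteTable:
    """Simulate an unnormalized peak-area table with known ground truth."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    metab_names = list(params.metabolites) + [
        f"bg{i:02d}" for i in range(1, params.n_background + 1)
    ]
    # background baselines spread over an order of magnitude, fixed by design
    bg_base = np.exp(np.linspace(np.log(200.0), np.log(5000.0), params.n_background))
    sample_rows, value_rows, index = [], [], []
    k = 0
    lo, hi = params.scale_range
    for tissue in params.tissues:
        for sex in params.sexes:
            for genotype in (HADSL, WT):
                for _rep in range(params.n_replicates):
                    k += 1
                    sid = f"s{k:03d}"
                    scale = math.exp(rng.uniform(math.log(lo), math.log(hi)))
                    vals = []
                    for m in params.metabolites:
                        base = params.baseline_of(m, tissue)
                        fold = params.fold_of(m, tissue) if genotype == HADSL else 1.0
                        vals.append(base * fold)
                    vals.extend(bg_base)
                    noise = np.exp(rng.normal(0.0, params.sigma, len(vals)))
                    value_rows.append(np.asarray(vals) * scale * noise)
                    sample_rows.append((tissue, sex, genotype, scale))
                    index.append(sid)
    values = pd.DataFrame(value_rows, index=index, columns=metab_names)
    samples = pd.DataFrame(
        sample_rows, index=index, columns=["tissue", "sex", "genotype", "true_scale"]
    )
    return MetaboliteTable(values=values, samples=samples, normalized=False)


# ---------------------------------------------------------------------------
# Wright-Fisher haplotype panels


class _Population:
    """2N haplotypes as nodes in a mutation tree (structural sharing).

    Each node represents "parent haplotype plus one new mutation"; a
    haplotype's mutation set is recovered by walking to the root. The
    selected allele is carried separately as a boolean flag.
    """

    def __init__(self, two_n: int) -> None:
        self.nodes = np.zeros(two_n, dtype=np.int64)  # node 0 = mutation-free root
        self.sel = np.zeros(two_n, dtype=bool)
        self.parent: list[int] = [-1]

    def snapshot(self) -> tuple[np.ndarray, np.ndarray, int]:
        return self.nodes.copy(), self.sel.copy(), len(self.parent)

    def restore(self, snap: tuple[np.ndarray, np.ndarray, int]) -> None:
        nodes, sel, n_nodes = snap
        self.nodes = nodes.copy()
        self.sel = sel.copy()
        del self.parent[n_nodes:]

    def step(self, rng: np.random.Generator, s: float, mu_total: float) -> None:
        """One non-overlapping generation: selection, drift, mutation."""
        two_n = self.nodes.size
        if s != 0.0 and self.sel.any():
            w = 1.0 + s * (self.sel[0::2].astype(np.float64) + self.sel[1::2])
            dip = rng.choice(two_n // 2, size=two_n, p=w / w.sum())
            k = 2 * dip + rng.integers(0, 2, size=two_n)
        else:
            k = rng.integers(0, two_n, size=two_n)
        self.nodes = self.nodes[k]
        self.sel = self.sel[k]
        n_mut = rng.poisson(mu_total * two_n)
        if n_mut:
            for child in rng.integers(0, two_n, size=n_mut):
                self.parent.append(int(self.nodes[child]))
                self.nodes[child] = len(self.parent) - 1

    def mutation_sets(self, indices: np.ndarray) -> list[set[int]]:
        cache: dict[int, frozenset[int]] = {0: frozenset()}

        def resolve(node: int) -> frozenset[int]:
            chain = []
            while node not in cache:
                chain.append(node)
                node = self.parent[node]
            acc = cache[node]
            for nd in reversed(chain):
                acc = acc | {nd}
                cache[nd] = acc
            return acc

        return [set(resolve(int(self.nodes[i]))) for i in indices]


def simulate_haplotypes_wf(
    N: int,
    n_sample: int,
    L: int,
    mu: float,
    s: float = 0.0,
    sweep_site: int | None = None,
    T: int = 1000,
    seed: int | np.random.Generator = 0,
    sweep_generation: int | None = None,
    min_final_freq: float | None = None,
    max_attempts: int = 10_000,
) -> HaplotypeMatrix:
    """Forward-time diploid Wright-Fisher panel without recombination.

    Runs T non-overlapping generations from a mutation-free population
    of 2N haplotypes with infinite-sites mutation at total rate mu*L
    per haplotype per generation. When ``sweep_site`` is set, a single
    selected mutant (genotype fitnesses 1, 1+s, 1+2s) is injected into
    one haplotype at ``sweep_generation`` (default: late enough that a
    successful sweep is near fixation at sampling, T - ceil((2/s)*
    ln(2N)) - 4/s) and the run is conditioned, by rejection sampling of
    the post-injection phase, on the selected allele surviving to the
    sampling time (and reaching ``min_final_freq`` if given).

    Returns ``n_sample`` haplotypes at the sites segregating in the
    sample, with uniform random site positions in [1, L]; the selected
    site, when segregating, sits exactly at ``sweep_site``. Metadata
    records the population frequency of the selected allele at
    sampling and the number of rejection attempts.
    """
    if n_sample > 2 * N:
        raise ValueError("n_sample cannot exceed 2N haplotypes")
    if n_sample < 2 or N < 2:
        raise ValueError("need N >= 2 and n_sample >= 2")
    if mu < 0 or L < 1 or T < 1:
        raise ValueError("require mu >= 0, L >= 1, T >= 1")
    if sweep_site is not None and not 1 <= sweep_site <= L:
        raise ValueError("sweep_site must lie in [1, L]")
    rng = np.random.default_rng(seed)
    mu_total = mu * L
    pop = _Population(2 * N)

    if sweep_site is None:
        for _ in range(T):
            pop.step(rng, 0.0, mu_total)
        sel_freq = 0.0
        attempts = 0
    else:
        if sweep_generation is None:
            # time for a successful additive sweep to complete, plus margin
            dur = math.ceil((2.0 / s) * math.log(2 * N) + 4.0 / s) if s > 0 else T
            sweep_generation = max(0, T - dur)
        if not 0 <= sweep_generation < T:
            raise ValueError("sweep_generation must lie in [0, T)")
        for _ in range(sweep_generation):
            pop.step(rng, 0.0, mu_total)
        snap = pop.snapshot()
        for attempts in range(1, max_attempts + 1):
            pop.restore(snap)
            pop.sel[rng.integers(0, 2 * N)] = True
            for _ in range(T - sweep_generation):
                pop.step(rng, s, mu_total)
                if not pop.sel.any():
                    break
            sel_freq = pop.sel.mean()
            if sel_freq > 0 and (min_final_freq is None or sel_freq >= min_final_freq):
                break
        else:
            raise RuntimeError(
                f"selected allele never met the sampling condition in "
                f"{max_attempts} attempts"
            )

    sample_idx = rng.choice(2 * N, size=n_sample, replace=False)
    mut_sets = pop.mutation_sets(sample_idx)
    all_muts = sorted(set().union(*mut_sets)) if mut_sets else []
    columns = []
    for m in all_muts:
        col = np.fromiter((m in ms for ms in mut_sets), dtype=np.int8, count=n_sample)
        c = int(col.sum())
        if 0 < c < n_sample:
            columns.append(col)
    sel_col = None
    if sweep_site is not None:
        sc = pop.sel[sample_idx].astype(np.int8)
        if 0 < sc.sum() < n_sample:
            sel_col = sc
    n_neutral = len(columns)
    avail = [p for p in range(1, L + 1) if p != sweep_site]
    pos = np.sort(rng.choice(len(avail), size=n_neutral, replace=False))
    positions = [avail[i] for i in pos]
    if sel_col is not None:
        positions.append(sweep_site)
        columns.append(sel_col)
        order = np.argsort(positions, kind="stable")
        positions = [positions[i] for i in order]
        columns = [columns[i] for i in order]
    matrix = (
        np.column_stack(columns) if columns else np.zeros((n_sample, 0), dtype=np.int8)
    )
    return HaplotypeMatrix(
        matrix=matrix,
        positions=np.asarray(positions, dtype=np.int64),
        contig="sim",
        metadata={
            "selected_freq": float(sel_freq),
            "sweep_site": sweep_site,
            "attempts": attempts if sweep_site is not None else 0,
            "N": N,
            "s": s,
            "T": T,
        },
    )


def simulate_neutral_panel_sfs(
    n_sample: int,
    S: int,
    L: int,
    seed: int | np.random.Generator = 0,
) -> HaplotypeMatrix:
    """Fast neutral panel: site frequencies drawn from the standard neutral SFS.

    Each of the S sites gets an independent derived-allele count i in
    1..n_sample-1 with probability proportional to 1/i, placed on a
    uniformly chosen subset of haplotypes, at distinct uniform
    positions. This matches the expected neutral site-frequency
    spectrum but ignores the shared genealogy, so it is a labeled fast
    fixture, not a replacement for the Wright-Fisher generator.
    """
    if n_sample < 2 or S < 0 or L < S:
        raise ValueError("require n_sample >= 2, 0 <= S <= L")
    rng = np.random.default_rng(seed)
    i = np.arange(1, n_sample)
    probs = (1.0 / i) / np.sum(1.0 / i)
    counts = rng.choice(i, size=S, p=probs)
    matrix = np.zeros((n_sample, S), dtype=np.int8)
    for j, c in enumerate(counts):
        matrix[rng.choice(n_sample, size=int(c), replace=False), j] = 1
    positions = np.sort(rng.choice(L, size=S, replace=False)) + 1
    return HaplotypeMatrix(matrix=matrix, positions=positions, contig="sim")
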