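"""Competitive water-access scoring from home-cage visit streams.

The experimental design: RFID-tagged mice of two genotypes (humanized
``hAdsl`` and wild-type ``WT``) share a cage in which water becomes
available at a fixed onset time each day at rewarded corners. Who gets
there early is a readout of competition for a desirable resource.

Statistics are tested against a shuffled-label null: genotype labels
are permuted among the animals within each cage (label counts per cage
preserved, visit streams untouched), which preserves all temporal and
individual structure under the null hypothesis that genotype is
exchangeable. P-values are two-tailed by distance from the null mean,
with the add-one correction so p >= 1/(B+1).

Events and rosters are plain pandas DataFrames; see
:mod:`adslkit.io` for the on-disk schemas.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "HADSL",
    "WT",
    "first_n_proportion",
    "shuffle_null_test",
    "visit_ratio",
    "first_visitor_fraction",
    "corner_visit_balance",
    "tube_test_summary",
    "VisitRatio",
    "CornerBalance",
    "TubeTestSummary",
    "usable_cages",
]

HADSL = "hAdsl"
WT = "WT"
GENOTYPES = (HADSL, WT)
ALL_CORNERS = frozenset({1, 2, 3, 4})


@dataclass
class VisitRatio:
    """Pooled hAdsl/WT visit-count ratio among first-K visits."""

    ratio: float
    n_hadsl: int
    n_wt: int
    infinite: bool


@dataclass
class CornerBalance:
    """Unrewarded-corner visit comparison between genotypes."""

    per_animal: pd.DataFrame  # animal, cage, genotype, count
    mean_hadsl: float
    mean_wt: float
    observed_diff: float
    null_mean: float
    null_sd: float
    p_two_tailed: float
    B: int


@dataclass
class TubeTestSummary:
    """Win fractions in dyadic tube-test matches and exact binomial test."""

    n_matches: int
    wins_hadsl: int
    wins_wt: int
    fraction_hadsl: float
    p_two_sided: float


def usable_cages(roster: pd.DataFrame) -> list:
    """Cages containing at least one animal of each genotype.

    Cages failing this (no competition possible) are reported with a
    warning and excluded from competition statistics.
    """
    good = []
    for cage, sub in roster.groupby("cage", sort=True):
        present = set(sub["genotype"])
        if set(GENOTYPES) <= present:
            good.append(cage)
        else:
            warnings.warn(
                f"cage {cage!r} has genotypes {sorted(present)} only; "
                "excluded from competition statistics",
                stacklevel=2,
            )
    return good


def _check_animals(events: pd.DataFrame, roster: pd.DataFrame) -> None:
    unknown = set(events["animal"]) - set(roster["animal"])
    if unknown:
        raise KeyError(
            f"animals present in events but missing from roster: {sorted(unknown)}"
        )


def _eligible(
    events: pd.DataFrame, onset: float, rewarded_corners: Iterable[int]
) -> pd.DataFrame:
    corners = set(rewarded_corners)
    mask = (events["timestamp"] >= onset) & events["corner"].isin(corners)
    # deterministic order: timestamp ties broken by animal id
    return events.loc[mask].sort_values(
        ["cage", "day", "timestamp", "animal"], kind="mergesort"
    )


def _first_k_counts(
    events: pd.DataFrame,
    roster: pd.DataFrame,
    K: int,
    onset: float,
    rewarded_corners: Iterable[int],
) -> dict[tuple, pd.Series]:
    """Per (cage, day): visit counts per animal among the K earliest eligible visits."""
    _check_animals(events, roster)
    if K < 1:
        raise ValueError("K must be >= 1")
    cages = usable_cages(roster)
    elig = _eligible(events, onset, rewarded_corners)
    elig = elig[elig["cage"].isin(cages)]
    out: dict[tuple, pd.Series] = {}
    for (cage, day), sub in elig.groupby(["cage", "day"], sort=True):
        out[(cage, day)] = sub.head(K)["animal"].value_counts()
    return out


def first_n_proportion(
    events: pd.DataFrame,
    roster: pd.DataFrame,
    K: int,
    onset: float = 0.0,
    rewarded_corners: Iterable[int] = ALL_CORNERS,
) -> pd.DataFrame:
    """Proportion of the first K eligible visits made by hAdsl animals.

    Eligible visits have timestamp >= onset and a rewarded corner. Days
    providing fewer than K eligible visits are retained with the actual
    number in ``n_counted``; days with none are flagged undefined
    (``proportion_hadsl`` is NaN).

    Returns one row per (cage, day): cage, day, K, n_counted, n_hadsl,
    proportion_hadsl, undefined.
    """
    counts = _first_k_counts(events, roster, K, onset, rewarded_corners)
    geno = roster.set_index("animal")["genotype"]
    rows = []
    for (cage, day), cnt in counts.items():
        n_counted = int(cnt.sum())
        n_h = int(cnt[geno.reindex(cnt.index) == HADSL].sum())
        rows.append(
            {
                "cage": cage,
                "day": day,
                "K": K,
                "n_counted": n_counted,
                "n_hadsl": n_h,
                "proportion_hadsl": (n_h / n_counted) if n_counted else np.nan,
                "undefined": n_counted == 0,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "cage",
            "day",
            "K",
            "n_counted",
            "n_hadsl",
            "proportion_hadsl",
            "undefined",
        ],
    )


def _cage_label_matrix(
    rng: np.random.Generator, labels: np.ndarray, B: int
) -> np.ndarray:
    """B random within-cage permutations of a boolean label vector (B x n)."""
    order = np.argsort(rng.random((B, labels.size)), axis=1)
    return labels[order]


def shuffle_null_test(
    events: pd.DataFrame,
    roster: pd.DataFrame,
    K: int,
    onset: float = 0.0,
    rewarded_corners: Iterable[int] = ALL_CORNERS,
    B: int = 1000,
    seed: int | np.random.Generator = 0,
    family_m: int | None = None,
) -> pd.DataFrame:
    """Two-tailed permutation test of the first-K hAdsl proportion, per day.

    The observed statistic for a day is the mean over cages of
    ``proportion_hadsl``. Each null replicate independently permutes
    genotype labels among animals within each cage and recomputes the
    same statistic. The two-tailed p-value counts null replicates at
    least as far from the null mean as the observation:

        p = (1 + #{b : |T_b - mu0| >= |T_obs - mu0|}) / (B + 1)

    where mu0 is the exact permutation-null mean, computed in closed
    form as the mean over contributing cages of each cage's hAdsl
    label fraction (a random k-subset of a cage's visits has expected
    hAdsl share k/n regardless of how visits distribute over animals).
    Using the exact center rather than the Monte-Carlo estimate keeps
    the tie classes of the discrete null stable. The
    Bonferroni-adjusted p is min(1, m * p) with family size m
    defaulting to the number of days tested.

    Returns one row per day: day, K, observed, null_mean, null_sd, p,
    p_adj, B, m, n_cages.
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    rng = np.random.default_rng(seed)
    counts = _first_k_counts(events, roster, K, onset, rewarded_corners)
    if not counts:
        raise ValueError("no usable cages with eligible visits")
    geno = roster.set_index("animal")["genotype"]
    roster_by_cage = {
        cage: sub["animal"].to_numpy() for cage, sub in roster.groupby("cage")
    }

    days = sorted({day for (_, day) in counts})
    m = len(days) if family_m is None else int(family_m)
    rows = []
    for day in days:
        obs_props, null_props, label_fracs = [], [], []
        for cage, animals in roster_by_cage.items():
            cnt = counts.get((cage, day))
            if cnt is None or cnt.sum() == 0:
                continue
            n_counted = int(cnt.sum())
            c_vec = cnt.reindex(animals).fillna(0).to_numpy(dtype=np.float64)
            labels = (geno.reindex(animals) == HADSL).to_numpy()
            obs_props.append(float(c_vec[labels].sum()) / n_counted)
            label_fracs.append(labels.mean())
            perm = _cage_label_matrix(rng, labels, B)  # B x n
            null_props.append(perm.astype(np.float64) @ c_vec / n_counted)
        if not obs_props:
            continue
        observed = float(np.mean(obs_props))
        null = np.mean(np.column_stack(null_props), axis=1)
        mu0 = float(np.mean(label_fracs))  # exact permutation-null mean
        null_sd = float(null.std(ddof=1))
        # tolerance keeps mathematically tied distances tied in floats
        extreme = int(
            np.sum(np.abs(null - mu0) >= abs(observed - mu0) - 1e-9)
        )
        p = (1 + extreme) / (B + 1)
        rows.append(
            {
                "day": day,
                "K": K,
                "observed": observed,
                "null_mean": mu0,
                "null_sd": null_sd,
                "p": p,
                "p_adj": min(1.0, m * p),
                "B": B,
                "m": m,
                "n_cages": len(obs_props),
            }
        )
    if not rows:
        raise ValueError("no day had eligible visits in any usable cage")
    return pd.DataFrame(rows)


def visit_ratio(
    events: pd.DataFrame,
    roster: pd.DataFrame,
    K: int,
    onset: float = 0.0,
    rewarded_corners: Iterable[int] = ALL_CORNERS,
    mode: str = "pooled",
) -> VisitRatio | pd.DataFrame:
    """Ratio of hAdsl to WT visit counts among the first K visits.

    ``mode="pooled"`` (default) sums counts over all cages and days
    before dividing; ``mode="per_day"`` returns a per-day frame of
    ratios pooled over cages. A zero WT count yields an infinite ratio
    with the ``infinite`` flag set.
    """
    counts = _first_k_counts(events, roster, K, onset, rewarded_corners)
    geno = roster.set_index("animal")["genotype"]

    def _pool(keys) -> VisitRatio:
        n_h = n_w = 0
        for key in keys:
            cnt = counts[key]
            g = geno.reindex(cnt.index)
            n_h += int(cnt[g == HADSL].sum())
            n_w += int(cnt[g == WT].sum())
        inf = n_w == 0
        return VisitRatio(
            ratio=np.inf if inf else n_h / n_w, n_hadsl=n_h, n_wt=n_w, infinite=inf
        )

    if mode == "pooled":
        return _pool(counts.keys())
    if mode == "per_day":
        days = sorted({day for (_, day) in counts})
        rows = []
        for day in days:
            r = _pool([k for k in counts if k[1] == day])
            rows.append(
                {
                    "day": day,
                    "ratio": r.ratio,
                    "n_hadsl": r.n_hadsl,
                    "n_wt": r.n_wt,
                    "infinite": r.infinite,
                }
            )
        return pd.DataFrame(rows)
    raise ValueError("mode must be 'pooled' or 'per_day'")


def first_visitor_fraction(
    events: pd.DataFrame,
    roster: pd.DataFrame,
    onset: float = 0.0,
    rewarded_corners: Iterable[int] = ALL_CORNERS,
) -> pd.DataFrame:
    """Per cage: fraction of days whose first eligible visit is by hAdsl.

    Days without any eligible visit are excluded from the denominator
    and counted in ``n_excluded_days``. Returns cage, n_days,
    n_first_hadsl, fraction_hadsl, n_excluded_days.
    """
    _check_animals(events, roster)
    geno = roster.set_index("animal")["genotype"]
    cages = usable_cages(roster)
    elig = _eligible(events, onset, rewarded_corners)
    all_days = sorted(events["day"].unique())
    rows = []
    for cage in cages:
        sub = elig[elig["cage"] == cage]
        firsts = sub.groupby("day", sort=True).first()
        n_days = len(firsts)
        n_h = int((geno.reindex(firsts["animal"]) == HADSL).sum())
        rows.append(
            {
                "cage": cage,
                "n_days": n_days,
                "n_first_hadsl": n_h,
                "fraction_hadsl": n_h / n_days if n_days else np.nan,
                "n_excluded_days": len(all_days) - n_days,
            }
        )
    return pd.DataFrame(rows)


def corner_visit_balance(
    events: pd.DataFrame,
    roster: pd.DataFrame,
    unrewarded_corners: Iterable[int],
    B: int = 1000,
    seed: int | np.random.Generator = 0,
) -> CornerBalance:
    """Do genotypes differ in visits to unrewarded corners?

    Statistic: difference of per-animal mean visit counts (hAdsl minus
    WT), tested against the within-cage label-shuffle null with the
    same two-tailed distance-from-mean rule as the competition test.
    A null result indicates both genotypes move around the cage
    equally -- the control for generic hyperactivity.
    """
    corners = set(unrewarded_corners)
    if not corners:
        raise ValueError("unrewarded_corners must be nonempty")
    _check_animals(events, roster)
    rng = np.random.default_rng(seed)
    cages = usable_cages(roster)
    ros = roster[roster["cage"].isin(cages)]
    sub = events[events["corner"].isin(corners) & events["cage"].isin(cages)]
    per_animal = (
        sub.groupby("animal").size().reindex(ros["animal"]).fillna(0).astype(int)
    )
    frame = ros[["animal", "cage", "genotype"]].copy()
    frame["count"] = per_animal.to_numpy()

    labels = (frame["genotype"] == HADSL).to_numpy()
    counts = frame["count"].to_numpy(dtype=np.float64)
    n_h, n_w = int(labels.sum()), int((~labels).sum())

    def _diff(lab: np.ndarray) -> np.ndarray:
        # lab: (..., n) boolean; returns mean(hAdsl) - mean(WT)
        return counts @ lab.T / n_h - counts @ (~lab).T / n_w

    observed = float(_diff(labels[None, :])[0])
    # permute within cage, preserving each cage's label counts
    cage_codes = frame["cage"].to_numpy()
    perm_labels = np.empty((B, labels.size), dtype=bool)
    mu0 = 0.0  # exact permutation-null mean of the difference statistic
    for cage in cages:
        idx = np.flatnonzero(cage_codes == cage)
        perm_labels[:, idx] = _cage_label_matrix(rng, labels[idx], B)
        cage_mean = counts[idx].mean()
        mu0 += cage_mean * (labels[idx].sum() / n_h - (~labels[idx]).sum() / n_w)
    null = _diff(perm_labels)
    extreme = int(np.sum(np.abs(null - mu0) >= abs(observed - mu0) - 1e-9))
    return CornerBalance(
        per_animal=frame,
        mean_hadsl=float(counts[labels].mean()),
        mean_wt=float(counts[~labels].mean()),
        observed_diff=observed,
        null_mean=mu0,
        null_sd=float(null.std(ddof=1)),
        p_two_tailed=(1 + extreme) / (B + 1),
        B=B,
    )


def tube_test_summary(winners: Sequence[str]) -> TubeTestSummary:
    """Win fractions from dyadic dominance matches and exact binomial test.

    Each match pits one hAdsl against one WT mouse in a tube; the mouse
    that pushes the other out wins. Under the null of no dominance
    difference each genotype wins with probability 1/2; the two-sided
    p sums the point masses <= that of the observed count.
    """
    winners = list(winners)
    if not winners:
        raise ValueError("at least one match is required")
    bad = set(winners) - set(GENOTYPES)
    if bad:
        raise ValueError(f"unknown winner labels {sorted(bad)}; expected {GENOTYPES}")
    n = len(winners)
    wins_h = sum(w == HADSL for w in winners)
    p = stats.binomtest(wins_h, n, 0.5, alternative="two-sided").pvalue
    return TubeTestSummary(
        n_matches=n,
        wins_hadsl=wins_h,
        wins_wt=n - wins_h,
        fraction_hadsl=wins_h / n,
        p_two_sided=float(p),
    )
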