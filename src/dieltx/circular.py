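"""Time-of-day binning and circular homogeneity tests for peak times.

Peak expression times live on the 24-h circle (theta = 2 pi t / 24).
This module bins them into four 6-h day-phase bins, computes (optionally
expression-weighted) circular means, and tests groups of peak times for
homogeneity with two classical procedures:

* Watson-Wheeler — nonparametric uniform-scores test; pooled angles are
  circularly ranked, each rank r mapped to the score 2 pi r / N, and the
  statistic W = 2 * sum_j |resultant_j|^2 / n_j is referred to a
  chi-square with 2(k-1) df. Exact ties are broken by adding seeded
  jitter far below the data resolution and averaging the statistic and p
  over many jitter draws; an exact permutation p is available for small
  two-group designs.
* Watson-Williams — parametric F-type test of equal mean directions,
  with the standard concentration correction factor; it assumes
  von-Mises-like samples with a reasonably high shared concentration
  (a warning flag is set when the pooled mean resultant length is low).

``cascade_test`` applies Watson-Wheeler per functional category against
the pooled remaining categories, BH-adjusted, to locate categories whose
peak timing departs from the overall schedule (e.g. the morning cascade
of photosynthesis components).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

HOURS_PER_DAY = 24.0
TIE_JITTER_H = 0.001  # uniform jitter half-width (hours), far below data resolution


class PhaseBin(enum.Enum):
    """Four 6-h day-phase bins, half-open on the left endpoint."""

    EARLY_DAY = "early_day"  # [6, 12)
    LATE_DAY = "late_day"  # [12, 18)
    EARLY_NIGHT = "early_night"  # [18, 24)
    LATE_NIGHT = "late_night"  # [0, 6)


def bin_peak_time(peak_time: float) -> PhaseBin:
    """Assign a clock-time peak (hours in [0, 24)) to its day-phase bin."""
    if not (0.0 <= peak_time < HOURS_PER_DAY):
        raise ValueError(f"peak_time must be in [0, 24), got {peak_time}")
    if peak_time < 6.0:
        return PhaseBin.LATE_NIGHT
    if peak_time < 12.0:
        return PhaseBin.EARLY_DAY
    if peak_time < 18.0:
        return PhaseBin.LATE_DAY
    return PhaseBin.EARLY_NIGHT


def hours_to_radians(hours) -> np.ndarray:
    return (np.asarray(hours, dtype=float) % HOURS_PER_DAY) * 2.0 * np.pi / HOURS_PER_DAY


def radians_to_hours(theta) -> np.ndarray:
    h = (np.asarray(theta, dtype=float) * HOURS_PER_DAY / (2.0 * np.pi)) % HOURS_PER_DAY
    # a tiny negative angle can round the modulus to exactly 24.0
    return np.where(h >= HOURS_PER_DAY, 0.0, h)


@dataclass
class CircularSample:
    """A labelled set of angles on the circle, with optional weights."""

    group_label: str
    angles: np.ndarray  # radians in [0, 2 pi)
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.angles, dtype=float) % (2.0 * np.pi)
        object.__setattr__(self, "angles", a)
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if w.shape != a.shape:
                raise ValueError("weights must match angles in shape")
            if (w < 0).any():
                raise ValueError("weights must be non-negative")
            object.__setattr__(self, "weights", w)

    @classmethod
    def from_hours(cls, label: str, hours, weights=None) -> "CircularSample":
        return cls(label, hours_to_radians(hours), None if weights is None else np.asarray(weights, float))

    @property
    def n(self) -> int:
        return int(self.angles.size)


@dataclass
class CircularTestResult:
    test_name: str
    groups: tuple[str, ...]
    statistic: float
    p_value: float
    q_value: float | None = None
    n_tiebreak_iterations: int = 1
    warnings: list = field(default_factory=list)


def circular_mean(sample: CircularSample) -> tuple[float, float]:
    """Mean direction in hours and mean resultant length Rbar in [0, 1].

    Weights, when present, scale each unit vector. A (numerically) zero
    resultant has no defined mean direction: hours is returned as NaN.
    """
    if sample.n == 0:
        raise ValueError("need at least one angle")
    w = sample.weights if sample.weights is not None else np.ones(sample.n)
    if w.sum() == 0:
        raise ValueError("weights sum to zero")
    C = float(np.sum(w * np.cos(sample.angles))) / w.sum()
    S = float(np.sum(w * np.sin(sample.angles))) / w.sum()
    rbar = math.hypot(C, S)
    if rbar < 1e-12:
        return float("nan"), rbar
    return float(radians_to_hours(math.atan2(S, C))), rbar


def pooled_circular_mean(samples: list[CircularSample]) -> tuple[float, float]:
    """Circular mean of all angles pooled across samples."""
    allang = np.concatenate([s.angles for s in samples])
    allw = None
    if any(s.weights is not None for s in samples):
        allw = np.concatenate(
            [s.weights if s.weights is not None else np.ones(s.n) for s in samples]
        )
    return circular_mean(CircularSample("pooled", allang, allw))


def _uniform_scores_statistic(angles: np.ndarray, sizes: list[int]) -> float:
    """W = 2 sum_j |R_j|^2 / n_j on circular ranks of the pooled sample."""
    N = angles.size
    ranks = np.empty(N, dtype=float)
    ranks[np.argsort(angles, kind="stable")] = np.arange(1, N + 1)
    beta = 2.0 * np.pi * ranks / N
    W = 0.0
    start = 0
    for n_j in sizes:
        b = beta[start : start + n_j]
        W += (np.sum(np.cos(b)) ** 2 + np.sum(np.sin(b)) ** 2) / n_j
        start += n_j
    return 2.0 * W


def watson_wheeler(
    groups: list[CircularSample],
    tiebreak_iterations: int = 1000,
    seed: int | None = None,
    exact: bool = False,
) -> CircularTestResult:
    """Watson-Wheeler (uniform-scores) homogeneity test for k >= 2 groups.

    With exact ties in the pooled sample the statistic and p-value are
    averaged over `tiebreak_iterations` seeded jitter draws (uniform on
    +/- 0.001 h). `exact=True` (two groups only) replaces the chi-square
    p by full enumeration of the group-label permutations.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g in groups:
        if g.n < 2:
            raise ValueError(f"group {g.group_label!r} has n={g.n} < 2")
    sizes = [g.n for g in groups]
    pooled = np.concatenate([g.angles for g in groups])
    N = pooled.size
    k = len(groups)
    df = 2 * (k - 1)
    warns: list[str] = []
    if N < 8 and not exact:
        warns.append("total n < 8: chi-square approximation unreliable; consider exact=True")
    labels = tuple(g.group_label for g in groups)

    if np.unique(pooled).size == 1:
        return CircularTestResult("watson_wheeler", labels, 0.0, 1.0, warnings=warns)

    has_ties = np.unique(pooled).size < N
    jitter_rad = TIE_JITTER_H * 2.0 * np.pi / HOURS_PER_DAY

    def one_pass(angles: np.ndarray) -> tuple[float, float]:
        if exact:
            if k != 2:
                raise ValueError("exact enumeration implemented for two groups only")
            W_obs = _uniform_scores_statistic(angles, sizes)
            n1 = sizes[0]
            idx = np.arange(N)
            count = total = 0
            for comb in combinations(idx, n1):
                perm = np.concatenate([angles[list(comb)], np.delete(angles, list(comb))])
                W = _uniform_scores_statistic(perm, sizes)
                total += 1
                if W >= W_obs - 1e-12:
                    count += 1
            return W_obs, count / total
        W_obs = _uniform_scores_statistic(angles, sizes)
        return W_obs, float(stats.chi2.sf(W_obs, df))

    if not has_ties:
        W, p = one_pass(pooled)
        return CircularTestResult("watson_wheeler", labels, float(W), float(p), warnings=warns)

    rng = np.random.default_rng(seed)
    Ws = np.empty(tiebreak_iterations)
    ps = np.empty(tiebreak_iterations)
    for i in range(tiebreak_iterations):
        jit = rng.uniform(-jitter_rad, jitter_rad, size=N)
        Ws[i], ps[i] = one_pass((pooled + jit) % (2 * np.pi))
    return CircularTestResult(
        "watson_wheeler",
        labels,
        float(Ws.mean()),
        float(ps.mean()),
        n_tiebreak_iterations=tiebreak_iterations,
        warnings=warns,
    )


def _a1inv(rbar: float) -> float:
    """Invert the mean-resultant-length / concentration relation for the
    von Mises distribution (standard piecewise approximation)."""
    if rbar < 0.53:
        return 2 * rbar + rbar**3 + 5 * rbar**5 / 6
    if rbar < 0.85:
        return -0.4 + 1.39 * rbar + 0.43 / (1 - rbar)
    return 1.0 / (rbar**3 - 4 * rbar**2 + 3 * rbar)


LOW_CONCENTRATION_RBAR = 0.45


def watson_williams(groups: list[CircularSample]) -> CircularTestResult:
    """Watson-Williams F test of equal mean directions for k >= 2 groups.

    Assumes each group is von-Mises with a common, reasonably large
    concentration; a warning flag is attached when the within-group mean
    resultant length falls below 0.45, where the F approximation
    degrades.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g in groups:
        if g.n < 2:
            raise ValueError(f"group {g.group_label!r} has n={g.n} < 2")
    labels = tuple(g.group_label for g in groups)
    k = len(groups)
    N = sum(g.n for g in groups)
    Rj = []
    for g in groups:
        C, S = np.sum(np.cos(g.angles)), np.sum(np.sin(g.angles))
        Rj.append(math.hypot(C, S))
    pooled = np.concatenate([g.angles for g in groups])
    R = math.hypot(float(np.sum(np.cos(pooled))), float(np.sum(np.sin(pooled))))
    sumRj = float(np.sum(Rj))
    rw = sumRj / N
    warns: list[str] = []
    if rw < LOW_CONCENTRATION_RBAR:
        warns.append(
            f"within-group mean resultant length {rw:.3f} < {LOW_CONCENTRATION_RBAR}: "
            "F approximation unreliable"
        )
    kappa = _a1inv(rw)
    K = 1.0 + 3.0 / (8.0 * kappa) if kappa > 0 else 1.0
    denom = N - sumRj
    if denom <= 0 or sumRj - R <= 0:
        F = 0.0 if sumRj - R <= 0 else float("inf")
    else:
        F = K * ((N - k) * (sumRj - R)) / ((k - 1) * denom)
    F = max(F, 0.0)
    p = float(stats.f.sf(F, k - 1, N - k)) if np.isfinite(F) else 0.0
    return CircularTestResult("watson_williams", labels, float(F), p, warnings=warns)


def cascade_test(
    peak_times: pd.Series,
    categories: pd.Series,
    alpha: float = 0.05,
    tiebreak_iterations: int = 1000,
    seed: int | None = None,
    include_self: bool = False,
    weights: pd.Series | None = None,
) -> pd.DataFrame:
    """Locate functional categories whose peak timing departs from the rest.

    For each category with n >= 2, runs Watson-Wheeler of that
    category's peak times against the pooled *other* categories
    (``include_self=True`` pools everything instead, which biases toward
    the null and is provided only for comparison), then BH-adjusts
    across tested categories and flags q < alpha. Singleton categories
    are reported untested (NaN statistic and p).

    Returns a frame with category, n, circular_mean_h, rbar, W, p, q,
    flagged.
    """
    peak_times = pd.Series(peak_times)
    categories = pd.Series(categories, index=peak_times.index)
    ok = peak_times.notna()
    peak_times, categories = peak_times[ok], categories[ok]
    cats = categories.unique().tolist()
    if len(cats) < 2:
        raise ValueError("need at least two categories")
    rows = []
    rng = np.random.default_rng(seed)
    for cat in cats:
        mask = categories == cat
        hrs = peak_times[mask].to_numpy()
        w = None if weights is None else weights.loc[peak_times.index[mask]].to_numpy()
        samp = CircularSample.from_hours(str(cat), hrs, w)
        mean_h, rbar = circular_mean(samp)
        row = {"category": cat, "n": int(mask.sum()), "circular_mean_h": mean_h, "rbar": rbar}
        others = peak_times[~mask] if not include_self else peak_times
        if mask.sum() >= 2 and len(others) >= 2:
            res = watson_wheeler(
                [samp, CircularSample.from_hours("rest", others.to_numpy())],
                tiebreak_iterations=tiebreak_iterations,
                seed=int(rng.integers(2**31 - 1)),
            )
            row["W"] = res.statistic
            row["p"] = res.p_value
        else:
            row["W"] = np.nan
            row["p"] = np.nan
        rows.append(row)
    out = pd.DataFrame(rows).set_index("category")
    tested = out["p"].notna()
    out["q"] = np.nan
    if tested.any():
        out.loc[tested, "q"] = multipletests(out.loc[tested, "p"], method="fdr_bh")[1]
    out["flagged"] = out["q"] < alpha
    return out


def category_taxon_homogeneity(
    peak_times: pd.Series,
    categories: pd.Series,
    taxa: pd.Series,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Within each functional category, Watson-Williams across taxa.

    Asks whether a category's peak time is conserved across lineages;
    categories with fewer than two taxa of n >= 2 are reported untested.
    BH adjustment across tested categories.
    """
    peak_times = pd.Series(peak_times)
    categories = pd.Series(categories, index=peak_times.index)
    taxa = pd.Series(taxa, index=peak_times.index)
    ok = peak_times.notna()
    rows = []
    for cat in categories[ok].unique():
        mask = ok & (categories == cat)
        samples = []
        for tx in taxa[mask].unique():
            hrs = peak_times[mask & (taxa == tx)]
            if len(hrs) >= 2:
                samples.append(CircularSample.from_hours(str(tx), hrs.to_numpy()))
        row = {"category": cat, "n_taxa_tested": len(samples)}
        if len(samples) >= 2:
            res = watson_williams(samples)
            row["F"] = res.statistic
            row["p"] = res.p_value
            row["low_concentration"] = bool(res.warnings)
        else:
            row["F"] = np.nan
            row["p"] = np.nan
            row["low_concentration"] = False
        rows.append(row)
    out = pd.DataFrame(rows).set_index("category")
    tested = out["p"].notna()
    out["q"] = np.nan
    if tested.any():
        out.loc[tested, "q"] = multipletests(out.loc[tested, "p"], method="fdr_bh")[1]
    out["flagged"] = out["q"] < alpha
    return out
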