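"""Harmonic regression analysis (HRA) for 24-h transcriptional periodicity.

Each ORF's series y(t) is fit by ordinary least squares to the single
diel harmonic

    y = m + a cos(2 pi t / T) + b sin(2 pi t / T),        T = 24 h,

on the *actual* sample clock times (the ~4-h drift design is unequally
distributed over the day; no interpolation onto a grid is done).
Amplitude = sqrt(a^2 + b^2); peak time (acrophase) =
(T / 2 pi) atan2(b, a) mod T; significance is the F test of the two
harmonic degrees of freedom against the intercept-only model, with an
optional label-permutation alternative. Benjamini-Hochberg FDR is
applied within each taxon group by default (callable globally), and ORFs
with q <= 0.1 are called periodic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from dieltx.matrix import NormalizedMatrix, aggregate_group_expression
from dieltx.timeline import Timeline

DEFAULT_PERIOD = 24.0
DEFAULT_Q = 0.1
MIN_OBS = 5  # 3 fitted parameters need residual degrees of freedom


@dataclass(frozen=True)
class HarmonicFit:
    """A single cosinor fit: mesor, amplitude, acrophase and inference."""

    orf_id: str
    mesor: float
    amplitude: float
    relative_amplitude: float
    peak_time: float  # hours in [0, 24); NaN when amplitude is 0
    r_squared: float
    p_value: float
    q_value: float | None
    n_obs: int


def _design(t: np.ndarray, period: float) -> np.ndarray:
    w = 2.0 * np.pi / period
    return np.column_stack([np.ones_like(t), np.cos(w * t), np.sin(w * t)])


def _fit_many(Y: np.ndarray, t: np.ndarray, period: float):
    """Vectorized OLS of the diel harmonic over rows of Y.

    Returns (mesor, amplitude, peak_time, r2, p) arrays. Constant rows
    get amplitude 0, peak NaN, p = 1 by convention.
    """
    X = _design(t, period)
    if np.linalg.matrix_rank(X) < 3:
        raise ValueError("degenerate phase coverage: harmonic design matrix is rank-deficient")
    n = len(t)
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)  # 3 x n_series
    resid = Y.T - X @ beta
    rss1 = np.einsum("ij,ij->j", resid, resid)
    mean = Y.mean(axis=1)
    rss0 = np.einsum("ij,ij->i", Y - mean[:, None], Y - mean[:, None])
    mesor, a, b = beta
    amplitude = np.hypot(a, b)
    peak = (period / (2.0 * np.pi)) * np.arctan2(b, a) % period
    peak = np.where(peak >= period, 0.0, peak)  # guard the modulus rounding to `period`
    constant = rss0 <= 1e-300
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(constant, 0.0, 1.0 - rss1 / rss0)
        F = ((rss0 - rss1) / 2.0) / (rss1 / (n - 3))
    p = np.where(
        constant | (rss1 <= 0),
        np.where(constant, 1.0, np.nextafter(0.0, 1.0)),
        stats.f.sf(np.where(rss1 > 0, F, 0.0), 2, n - 3),
    )
    amplitude = np.where(constant, 0.0, amplitude)
    peak = np.where(constant | (amplitude == 0), np.nan, peak)
    r2 = np.clip(r2, 0.0, 1.0)
    return mesor, amplitude, peak, r2, p


def fit_harmonic(
    y,
    t,
    period: float = DEFAULT_PERIOD,
    orf_id: str = "",
    test: str = "ftest",
    n_permutations: int = 10000,
    seed: int | None = None,
) -> HarmonicFit:
    """Least-squares single-harmonic (cosinor) fit of one time series.

    `t` are clock times in hours (any continuous axis; only t mod period
    matters for the phase). `test="permutation"` replaces the parametric
    F-test p with the proportion of timepoint-label shuffles achieving an
    equal or larger F statistic.
    """
    y = np.asarray(y, dtype=float)
    t = np.asarray(t, dtype=float)
    if y.shape != t.shape or y.ndim != 1:
        raise ValueError("y and t must be 1-D arrays of equal length")
    if len(y) < MIN_OBS:
        raise ValueError(f"need at least {MIN_OBS} observations, got {len(y)}")
    mesor, amp, peak, r2, p = (v[0] for v in _fit_many(y[None, :], t, period))
    if test == "permutation" and amp > 0:
        rng = np.random.default_rng(seed)
        n = len(y)
        perms = np.array([rng.permutation(n) for _ in range(n_permutations)])
        _, _, _, r2p, _ = _fit_many(y[perms], t, period)
        p = (1 + int(np.sum(r2p >= r2 - 1e-12))) / (1 + n_permutations)
    elif test not in ("ftest", "permutation"):
        raise ValueError(f"unknown test {test!r}")
    rel = amp / mesor if mesor > 0 else float("nan")
    return HarmonicFit(
        orf_id=orf_id,
        mesor=float(mesor),
        amplitude=float(amp),
        relative_amplitude=float(rel),
        peak_time=float(peak),
        r_squared=float(r2),
        p_value=float(p),
        q_value=None,
        n_obs=len(y),
    )


@dataclass
class PeriodicCallSet:
    """All per-ORF fits plus the q <= threshold periodic call."""

    fits: pd.DataFrame  # orf_id-indexed: taxon_group, mesor, amplitude, ..., p, q, called
    q_threshold: float
    ineligible: pd.Index  # ORFs excluded before fitting (too sparse / constant)

    @property
    def called(self) -> pd.Index:
        return self.fits.index[self.fits["called"]]

    def taxon_summary(self, matrix: NormalizedMatrix | None = None) -> pd.DataFrame:
        """Per-taxon percentage of ORFs — and of total expression — that
        is significantly periodic. Expression percentages need the
        matrix the fits were computed from."""
        rows = []
        for group, block in self.fits.groupby("taxon_group", sort=True):
            called = block["called"]
            row = {
                "taxon_group": group,
                "n_orfs_tested": len(block),
                "n_called": int(called.sum()),
                "pct_orfs_periodic": 100.0 * called.mean() if len(block) else 0.0,
            }
            if matrix is not None:
                gmask = matrix.taxon_group == group
                totals = matrix.counts.loc[gmask].sum(axis=1)
                denom = totals.sum()
                num = totals.loc[totals.index.intersection(block.index[called])].sum()
                row["pct_expression_periodic"] = 100.0 * num / denom if denom > 0 else 0.0
            rows.append(row)
        return pd.DataFrame(rows)


def call_periodic(
    matrix: NormalizedMatrix,
    timeline: Timeline,
    q_threshold: float = DEFAULT_Q,
    fdr_scope: str = "taxon",
    test: str = "ftest",
    period: float = DEFAULT_PERIOD,
    seed: int | None = None,
    n_permutations: int = 1000,
) -> PeriodicCallSet:
    """Fit every eligible ORF and call the q <= threshold periodic set.

    Eligibility: at least `MIN_OBS` nonzero observations and nonzero
    variance. FDR adjustment is Benjamini-Hochberg within each taxon
    group (``fdr_scope="taxon"``, matching per-taxon periodic-fraction
    summaries) or over all tested ORFs (``"global"``).
    """
    if fdr_scope not in ("taxon", "global"):
        raise ValueError(f"fdr_scope must be 'taxon' or 'global', got {fdr_scope!r}")
    t = timeline.start_clock + timeline.sample_times
    Y = matrix.counts.to_numpy(dtype=float)
    nonzero = (Y != 0).sum(axis=1)
    varying = Y.std(axis=1) > 0
    eligible = (nonzero >= MIN_OBS) & varying
    idx_el = matrix.orf_ids[eligible]
    fits = pd.DataFrame(index=idx_el)
    fits["taxon_group"] = matrix.taxon_group.loc[idx_el]
    if eligible.any():
        if test == "permutation":
            recs = [
                fit_harmonic(
                    Y[i], t, period=period, test="permutation",
                    n_permutations=n_permutations,
                    seed=None if seed is None else seed + i,
                )
                for i in np.flatnonzero(eligible)
            ]
            mesor = np.array([r.mesor for r in recs])
            amp = np.array([r.amplitude for r in recs])
            peak = np.array([r.peak_time for r in recs])
            r2 = np.array([r.r_squared for r in recs])
            p = np.array([r.p_value for r in recs])
        else:
            mesor, amp, peak, r2, p = _fit_many(Y[eligible], t, period)
        fits["mesor"] = mesor
        fits["amplitude"] = amp
        with np.errstate(divide="ignore", invalid="ignore"):
            fits["relative_amplitude"] = np.where(mesor > 0, amp / mesor, np.nan)
        fits["peak_time"] = peak
        fits["r2"] = r2
        fits["p"] = p
        if fdr_scope == "global":
            fits["q"] = multipletests(fits["p"], method="fdr_bh")[1]
        else:
            fits["q"] = np.nan
            for _, block in fits.groupby("taxon_group", sort=False):
                fits.loc[block.index, "q"] = multipletests(block["p"], method="fdr_bh")[1]
    else:
        for col in ("mesor", "amplitude", "relative_amplitude", "peak_time", "r2", "p", "q"):
            fits[col] = np.nan
    fits["called"] = fits["q"] <= q_threshold
    return PeriodicCallSet(
        fits=fits, q_threshold=q_threshold, ineligible=matrix.orf_ids[~eligible]
    )


def taxon_total_periodicity(
    matrix: NormalizedMatrix,
    timeline: Timeline,
    groups=None,
    q_threshold: float = DEFAULT_Q,
    period: float = DEFAULT_PERIOD,
) -> pd.DataFrame:
    """HRA on each taxon's aggregate (summed) expression series.

    Detects taxa whose *total* activity follows a smooth day/night
    oscillation. BH adjustment is across taxa.
    """
    if groups is None:
        groups = matrix.taxon_group.unique().tolist()
    t = timeline.start_clock + timeline.sample_times
    rows = []
    for g in groups:
        series = aggregate_group_expression(matrix, g).to_numpy()
        fit = fit_harmonic(series, t, period=period, orf_id=str(g))
        rows.append(
            {
                "taxon_group": g,
                "mesor": fit.mesor,
                "amplitude": fit.amplitude,
                "peak_time": fit.peak_time,
                "r2": fit.r_squared,
                "p": fit.p_value,
            }
        )
    out = pd.DataFrame(rows).set_index("taxon_group")
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    out["called"] = out["q"] <= q_threshold
    return out


def write_fits(callset: PeriodicCallSet, path) -> None:
    out = callset.fits.reset_index().rename(columns={"index": "orf_id"})
    if "orf_id" not in out.columns:
        out = out.rename(columns={out.columns[0]: "orf_id"})
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")
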