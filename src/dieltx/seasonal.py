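"""Dawn-relative phases, the seasonal-adaptation window, and marker ratios.

Translational coincidence: protein synthesis in phototrophs runs 3-5x
faster in daylight, so a transcript under dawn-tracking clock control
whose peak falls in the late day of a long photoperiod falls *after*
dusk in a short photoperiod — its protein pool therefore tracks season.
The "seasonal adaptation window" is the span of dawn-relative peak
times with that property (default 9.9-14.4 h after local dawn).
Transcripts peaking there are candidates for photoperiod-coupled
regulation; iron-stress markers are of particular interest because iron
limitation intensifies with day length over the upwelling season.

Also here: expression ratios of paired marker genes, e.g. flavodoxin
(iron-free electron carrier) to ferredoxin (its iron-sulfur
counterpart) — an elevated ratio is a classic iron-stress signature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from dieltx.matrix import ExpressionMatrix

HOURS_PER_DAY = 24.0


@dataclass(frozen=True)
class SeasonalWindow:
    """Dawn-relative window (hours after dawn), half-open [start, end)."""

    start_after_dawn: float = 9.9
    end_after_dawn: float = 14.4

    def __post_init__(self) -> None:
        if not (0.0 <= self.start_after_dawn < self.end_after_dawn < HOURS_PER_DAY):
            raise ValueError(
                f"window must satisfy 0 <= start < end < 24, got "
                f"[{self.start_after_dawn}, {self.end_after_dawn})"
            )

    def contains(self, dawn_relative: float) -> bool:
        return self.start_after_dawn <= dawn_relative < self.end_after_dawn


@dataclass(frozen=True)
class WindowClassification:
    orf_id: str
    dawn_relative_peak: float
    in_window: bool


def dawn_relative_phase(peak_time: float, dawn: float) -> float:
    """Hours elapsed from local dawn to a clock-time peak, in [0, 24)."""
    if not (0.0 <= peak_time < HOURS_PER_DAY):
        raise ValueError(f"peak_time must be in [0, 24), got {peak_time}")
    if not (0.0 <= dawn < HOURS_PER_DAY):
        raise ValueError(f"dawn must be in [0, 24), got {dawn}")
    return (peak_time - dawn) % HOURS_PER_DAY


def classify_window(
    fits: pd.DataFrame,
    dawn: float,
    window: SeasonalWindow = SeasonalWindow(),
    matrix: ExpressionMatrix | None = None,
    top_n_functions: int = 10,
):
    """Flag called periodic (nuclear) ORFs peaking in the seasonal window.

    `fits` is a frame indexed by orf_id with at least ``peak_time``; the
    caller restricts it to the significantly periodic, nuclear set. The
    return is (classifications frame, per-taxon counts, top functions):
    the frame adds ``dawn_relative_peak`` and ``in_window``; per-taxon
    counts summarize window membership when a ``taxon_group`` column is
    present; the top in-window function labels ranked by total
    expression are included when `matrix` is given and a
    ``function_label`` column is present.
    """
    out = fits.copy()
    out["dawn_relative_peak"] = [
        dawn_relative_phase(pt, dawn) if np.isfinite(pt) else np.nan for pt in out["peak_time"]
    ]
    out["in_window"] = [
        window.contains(dr) if np.isfinite(dr) else False for dr in out["dawn_relative_peak"]
    ]
    per_taxon = None
    if "taxon_group" in out.columns:
        per_taxon = (
            out.groupby("taxon_group")["in_window"]
            .agg(n_orfs="size", n_in_window="sum")
            .reset_index()
        )
    top_functions = None
    if matrix is not None and "function_label" in out.columns:
        inw = out.index[out["in_window"]]
        totals = matrix.counts.loc[matrix.counts.index.intersection(inw)].sum(axis=1)
        tf = (
            pd.DataFrame(
                {"function_label": out.loc[totals.index, "function_label"], "expression": totals}
            )
            .groupby("function_label")["expression"]
            .sum()
            .sort_values(ascending=False)
            .head(top_n_functions)
        )
        top_functions = tf.reset_index()
    return out, per_taxon, top_functions


@dataclass
class MarkerRatio:
    numerator_label: str
    denominator_label: str
    per_timepoint: pd.Series  # NaN where the denominator is zero
    pooled: float  # NaN when the pooled denominator is zero
    zero_denominator_timepoints: list


def marker_ratio(
    matrix: ExpressionMatrix,
    numerator_labels,
    denominator_labels,
) -> MarkerRatio:
    """Per-timepoint and pooled expression ratio of two marker gene sets.

    ORFs are matched by ``function_label``. Timepoints where the
    denominator sums to zero are flagged and carry a NaN ratio; the
    pooled ratio (sum of numerator counts over sum of denominator
    counts, across all timepoints) remains defined as long as the
    pooled denominator is positive.
    """
    if isinstance(numerator_labels, str):
        numerator_labels = [numerator_labels]
    if isinstance(denominator_labels, str):
        denominator_labels = [denominator_labels]
    num_mask = matrix.function_label.isin(numerator_labels)
    den_mask = matrix.function_label.isin(denominator_labels)
    if not num_mask.any():
        raise ValueError(f"no ORFs match numerator labels {list(numerator_labels)}")
    if not den_mask.any():
        raise ValueError(f"no ORFs match denominator labels {list(denominator_labels)}")
    num = matrix.counts.loc[num_mask].sum(axis=0)
    den = matrix.counts.loc[den_mask].sum(axis=0)
    zero_tp = den.index[den == 0].tolist()
    with np.errstate(divide="ignore", invalid="ignore"):
        per_tp = num / den.replace(0, np.nan)
    pooled = float(num.sum() / den.sum()) if den.sum() > 0 else float("nan")
    return MarkerRatio(
        numerator_label="|".join(map(str, numerator_labels)),
        denominator_label="|".join(map(str, denominator_labels)),
        per_timepoint=per_tp,
        pooled=pooled,
        zero_denominator_timepoints=zero_tp,
    )
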