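"""Expression matrices and the two normalizations every stage consumes.

An :class:`ExpressionMatrix` holds non-negative ORF x timepoint counts with
per-ORF taxon-group, functional and genome-compartment labels. Two
normalizations produce relative abundances:

* ``library`` — each timepoint (column) sums to 1 over the included ORFs,
  i.e. classical total-count (compositional) normalization per library;
* ``taxon_group`` — each column sums to 1 *within* each taxon group, which
  removes whole-group abundance swings before per-ORF periodicity calling.
"""

from __future__ import annotations

import itertools
import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from dieltx.timeline import Timeline

VALID_COMPARTMENTS = ("nuclear", "organellar", "none")

META_COLUMNS = ["orf_id", "taxon_group", "function_label", "compartment"]


@dataclass
class ExpressionMatrix:
    """ORF x timepoint counts with per-ORF annotation.

    Attributes
    ----------
    counts
        DataFrame, index = orf_id (unique), one column per sample.
    meta
        DataFrame aligned to ``counts.index`` with columns
        ``taxon_group``, ``function_label``, ``compartment``.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.counts.index.is_unique:
            dupes = self.counts.index[self.counts.index.duplicated()].tolist()
            raise ValueError(f"orf_ids must be unique; duplicated: {dupes[:5]}")
        if (self.counts.values < 0).any():
            bad = self.counts.index[(self.counts.values < 0).any(axis=1)][0]
            raise ValueError(f"negative count in row {bad!r}")
        if not self.counts.index.equals(self.meta.index):
            raise ValueError("counts and meta must share the same orf_id index")

    @property
    def orf_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def taxon_group(self) -> pd.Series:
        return self.meta["taxon_group"]

    @property
    def function_label(self) -> pd.Series:
        return self.meta["function_label"]

    @property
    def compartment(self) -> pd.Series:
        return self.meta["compartment"]

    @property
    def n_orfs(self) -> int:
        return len(self.counts)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def subset_compartments(self, compartments) -> "ExpressionMatrix":
        """Restrict to ORFs whose compartment is in `compartments`."""
        keep = self.meta["compartment"].isin(list(compartments))
        return ExpressionMatrix(self.counts.loc[keep], self.meta.loc[keep])


@dataclass
class NormalizedMatrix(ExpressionMatrix):
    """Relative-abundance matrix; ``mode`` records which normalization."""

    mode: str = "library"
    warnings: list = field(default_factory=list)

    @property
    def values(self) -> pd.DataFrame:
        return self.counts


def read_expression(path, timeline: Timeline) -> ExpressionMatrix:
    """Read an expression TSV against a timeline.

    The file has columns orf_id, taxon_group, function_label, compartment,
    then one column per sample. The number of sample columns must equal
    the timeline's sample count; rows that are all zero are retained.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"orf_id": str})
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"expression TSV missing required columns: {missing}")
    sample_cols = [c for c in df.columns if c not in META_COLUMNS]
    if len(sample_cols) != timeline.n_samples:
        raise ValueError(
            f"expression file has {len(sample_cols)} sample columns but the "
            f"timeline has {timeline.n_samples} samples"
        )
    counts = df[sample_cols].astype(float)
    counts.index = pd.Index(df["orf_id"], name="orf_id")
    if (counts.values < 0).any():
        bad = counts.index[(counts.values < 0).any(axis=1)][0]
        raise ValueError(f"negative count in row {bad!r}")
    meta = df[["taxon_group", "function_label", "compartment"]].copy()
    meta["function_label"] = meta["function_label"].fillna("")
    meta.index = counts.index
    return ExpressionMatrix(counts=counts, meta=meta)


def write_expression(matrix: ExpressionMatrix, path, header_comment: str | None = None) -> None:
    """Write the expression TSV dialect read by :func:`read_expression`."""
    out = pd.concat([matrix.meta, matrix.counts], axis=1)
    out.insert(0, "orf_id", matrix.orf_ids)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        if isinstance(matrix, NormalizedMatrix):
            fh.write(f"# normalization_mode: {matrix.mode}\n")
        out.to_csv(fh, sep="\t", index=False)


def normalize(
    matrix: ExpressionMatrix,
    mode: str = "library",
    compartments=None,
) -> NormalizedMatrix:
    """Convert counts to relative abundances.

    Parameters
    ----------
    mode
        ``"library"`` — each column sums to 1 over included ORFs;
        ``"taxon_group"`` — each column sums to 1 within each taxon group.
    compartments
        Optional sequence of compartment labels to retain before
        normalizing (e.g. ``("nuclear", "none")`` to drop organellar
        ORFs). ``None`` keeps everything.

    Zero rows stay zero. In library mode an all-zero column is an error;
    in taxon_group mode an all-zero group is emitted as zeros with a
    warning record on the result.
    """
    if mode not in ("library", "taxon_group"):
        raise ValueError(f"unknown normalization mode {mode!r}")
    if compartments is not None:
        matrix = matrix.subset_compartments(compartments)
    counts = matrix.counts
    warn_records: list[str] = []
    if mode == "library":
        colsums = counts.sum(axis=0)
        zero_cols = colsums.index[colsums == 0].tolist()
        if zero_cols:
            raise ValueError(f"all-zero column(s) in library normalization: {zero_cols}")
        values = counts / colsums
    else:
        parts = []
        for group, block in counts.groupby(matrix.taxon_group, sort=False):
            gsums = block.sum(axis=0)
            zero = gsums == 0
            if zero.any():
                warn_records.append(
                    f"taxon group {group!r}: zero total at {int(zero.sum())} timepoint(s); emitted as zeros"
                )
            safe = gsums.where(~zero, 1.0)
            parts.append(block / safe)
        values = pd.concat(parts).loc[counts.index]
    return NormalizedMatrix(counts=values, meta=matrix.meta, mode=mode, warnings=warn_records)


def ingroup_synchrony(matrix: ExpressionMatrix, group: str) -> float:
    """Mean pairwise Pearson correlation of a taxon group's time series.

    Averages Pearson's r over all unordered pairs of the group's ORFs,
    using only ORFs with nonzero variance across timepoints. Returns NaN
    (an undefined-result signal, not an exception) when fewer than two
    eligible ORFs exist.
    """
    _check_group(matrix, group)
    block = matrix.counts.loc[matrix.taxon_group == group]
    eligible = block.loc[block.std(axis=1, ddof=0) > 0]
    n = len(eligible)
    if n < 2:
        return float("nan")
    x = eligible.values
    # row-standardize, then the mean pairwise r is the off-diagonal mean of X X^T / T
    z = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, ddof=0, keepdims=True)
    corr = (z @ z.T) / x.shape[1]
    iu = np.triu_indices(n, k=1)
    return float(corr[iu].mean())


def aggregate_group_expression(matrix: ExpressionMatrix, group: str) -> pd.Series:
    """Per-timepoint sum of a taxon group's (normalized) values."""
    _check_group(matrix, group)
    return matrix.counts.loc[matrix.taxon_group == group].sum(axis=0)


def _check_group(matrix: ExpressionMatrix, group: str) -> None:
    known = matrix.taxon_group.unique().tolist()
    if group not in known:
        raise KeyError(f"unknown taxon group {group!r}; known groups: {sorted(known)}")
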