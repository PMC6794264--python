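"""Lineage assignment from homology hit tables via a Lineage Probability Index.

Best-BLAST taxonomy is fragile when reference databases contain
contaminated sequences (common for transcriptomes assembled from
non-axenic cultures). Instead of trusting the single best hit, each query
is assigned the lineage shared by its *top-scoring window* of hits — all
hits with bit score within a fraction (default 0.95) of the query's
maximum — and the LPI score in [0, 1] measures how unanimous that window
is, rank by rank, from domain down to the deepest rank retained.

Aggregation rule (the precise formula is this package's documented
choice; only the [0,1] "lineage commonality among top hits" semantics is
fixed by the method's definition): at each rank r from the root, let
``f_r`` be the fraction of window hits whose rank-r lineage prefix equals
the modal prefix. The assignment follows the modal prefix while
``f_r >= consensus_floor`` (default 0.5); LPI is the mean of the ``f_r``
over the ranks traversed. A unanimous window gives LPI = 1.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd

UNRESOLVED = "unresolved"
NO_MATCH = "no_match"

HIT_COLUMNS = ["query_id", "subject_id", "percent_identity", "bit_score"]


@dataclass
class HitTable:
    """Per-query homology hits plus a subject -> ranked-lineage map.

    ``hits`` has columns query_id, subject_id, percent_identity,
    bit_score (> 0). ``lineage_map`` maps subject_id to a tuple of ranked
    labels, root first (e.g. domain, phylum, ..., genus). Subjects absent
    from the map are tolerated and flagged at assignment time.
    """

    hits: pd.DataFrame
    lineage_map: dict[str, tuple[str, ...]]
    n_skipped_rows: int = 0

    def __post_init__(self) -> None:
        missing = [c for c in HIT_COLUMNS if c not in self.hits.columns]
        if missing:
            raise ValueError(f"hit table missing columns: {missing}")
        if len(self.hits) and (self.hits["bit_score"] <= 0).any():
            raise ValueError("bit scores must be positive")


@dataclass(frozen=True)
class LineageAssignment:
    query_id: str
    assigned_lineage: tuple[str, ...]
    lpi: float
    n_hits_considered: int

    @property
    def lineage_str(self) -> str:
        return ";".join(self.assigned_lineage)


def read_hit_table(hits_path, lineage_path) -> HitTable:
    """Read BLAST-tabular-style hits and a subject -> lineage TSV.

    The hits file is headerless. With >= 12 columns it is treated as
    standard tabular output (pident in column 3, bitscore in column 12);
    otherwise columns are qseqid, sseqid, pident, bitscore. Extra columns
    are ignored; malformed rows are skipped and counted.
    """
    raw = pd.read_csv(hits_path, sep="\t", header=None, comment="#", dtype=str)
    if raw.shape[1] >= 12:
        cols = {0: "query_id", 1: "subject_id", 2: "percent_identity", 11: "bit_score"}
    else:
        cols = {0: "query_id", 1: "subject_id", 2: "percent_identity", 3: "bit_score"}
    hits = raw[list(cols)].rename(columns=cols)
    for c in ("percent_identity", "bit_score"):
        hits[c] = pd.to_numeric(hits[c], errors="coerce")
    ok = hits["bit_score"].notna() & (hits["bit_score"] > 0) & hits["percent_identity"].notna()
    n_skipped = int((~ok).sum())
    hits = hits.loc[ok].reset_index(drop=True)

    lin = pd.read_csv(lineage_path, sep="\t", header=None, comment="#", dtype=str)
    lineage_map = {
        str(s): tuple(str(l).split(";")) for s, l in zip(lin.iloc[:, 0], lin.iloc[:, 1])
    }
    return HitTable(hits=hits, lineage_map=lineage_map, n_skipped_rows=n_skipped)


def top_percentile_hits(query_hits: pd.DataFrame, fraction: float = 0.95) -> pd.DataFrame:
    """Hits with bit score >= `fraction` x the query's maximum bit score.

    This is the best-hit-window reading of a "top percentile by bit
    score"; `fraction` is exposed so the top-5%-of-hits reading is one
    argument away.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if len(query_hits) == 0:
        raise ValueError("no hits supplied")
    threshold = fraction * query_hits["bit_score"].max()
    return query_hits.loc[query_hits["bit_score"] >= threshold]


def compute_lpi(
    query_hits: pd.DataFrame,
    lineage_map: dict[str, tuple[str, ...]],
    consensus_floor: float = 0.5,
) -> LineageAssignment:
    """Assign a lineage and LPI score from a (pre-windowed) hit subset.

    Hits whose subject is not in `lineage_map` are dropped first; with no
    mapped hit the query is reported unclassified (``no_match``, LPI NaN).
    A modal-prefix count tie at the first rank yields ``unresolved`` with
    LPI 0.0 by convention; count ties at deeper ranks are broken by
    higher summed bit score within the window, then lexicographically,
    for determinism.
    """
    qid = str(query_hits["query_id"].iloc[0]) if len(query_hits) else ""
    mapped = query_hits.loc[query_hits["subject_id"].map(lambda s: s in lineage_map)]
    if len(mapped) == 0:
        return LineageAssignment(qid, (NO_MATCH,), float("nan"), 0)
    lineages = [lineage_map[s] for s in mapped["subject_id"]]
    scores = mapped["bit_score"].to_numpy()
    n = len(lineages)
    max_depth = max(len(l) for l in lineages)

    assigned: list[str] = []
    fs: list[float] = []
    for r in range(1, max_depth + 1):
        # candidates: hits extending the currently assigned prefix with depth >= r
        idx = [
            i
            for i, lin in enumerate(lineages)
            if len(lin) >= r and list(lin[: r - 1]) == assigned
        ]
        if not idx:
            break
        counts = Counter(lineages[i][r - 1] for i in idx)
        top_count = max(counts.values())
        modal = [lab for lab, c in counts.items() if c == top_count]
        if len(modal) > 1:
            if r == 1:
                return LineageAssignment(qid, (UNRESOLVED,), 0.0, n)
            # deeper-rank tie: summed bit score, then lexicographic
            score_of = {
                lab: sum(scores[i] for i in idx if lineages[i][r - 1] == lab) for lab in modal
            }
            best = max(score_of.values())
            modal = sorted(lab for lab, s in score_of.items() if s == best)
        label = modal[0]
        f_r = top_count / n
        if f_r < consensus_floor:
            break
        assigned.append(label)
        fs.append(f_r)
    if not assigned:
        return LineageAssignment(qid, (UNRESOLVED,), 0.0, n)
    return LineageAssignment(qid, tuple(assigned), float(sum(fs) / len(fs)), n)


def assign_all(
    table: HitTable,
    fraction: float = 0.95,
    consensus_floor: float = 0.5,
    query_ids=None,
) -> list[LineageAssignment]:
    """One :class:`LineageAssignment` per distinct query.

    `query_ids`, when given, enumerates the full query universe so that
    queries with no hits at all appear as ``no_match`` records (a large
    no-match fraction is the norm for environmental ORF catalogs).
    """
    out: dict[str, LineageAssignment] = {}
    for qid, block in table.hits.groupby("query_id", sort=False):
        window = top_percentile_hits(block, fraction=fraction)
        out[str(qid)] = compute_lpi(window, table.lineage_map, consensus_floor=consensus_floor)
    if query_ids is not None:
        for qid in query_ids:
            if str(qid) not in out:
                out[str(qid)] = LineageAssignment(str(qid), (NO_MATCH,), float("nan"), 0)
        return [out[str(q)] for q in query_ids]
    return list(out.values())


def write_assignments(assignments: list[LineageAssignment], path) -> None:
    df = pd.DataFrame(
        {
            "query_id": [a.query_id for a in assignments],
            "lineage": [a.lineage_str for a in assignments],
            "lpi": [a.lpi for a in assignments],
            "n_hits": [a.n_hits_considered for a in assignments],
        }
    )
    df.to_csv(path, sep="\t", index=False)
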