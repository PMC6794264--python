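"""Synthetic drift community: expression matrices, hit tables, phase sets.

The generator emulates the statistical structure of a multi-day,
~4-h-resolution drift metatranscriptome so that every downstream stage
(taxonomy, normalization, periodicity calling, circular tests, the
seasonal window) can be exercised against known ground truth:

* a mixed-taxon community in which each taxon has its own fraction of
  24-h-cyclic genes (phototrophs high, dinoflagellates near zero);
* cyclic genes peak preferentially in the early day and early night —
  the two modes observed for periodic transcripts in situ;
* multiplicative (lognormal) or count (negative binomial) noise;
* compositional coupling: column means are rescaled so each library's
  expected total is fixed, reproducing the closure artifact of
  sequencing depth (a strongly oscillating taxon induces apparent
  anti-phase oscillation in truly constant taxa after library
  normalization — a hazard the test suite demonstrates rather than
  hides).

Cyclic-gene means follow baseline * (1 + A cos(2 pi (t - phi) / 24))
with relative amplitude A in [0, 1] so means stay non-negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from dieltx.lpi import HitTable
from dieltx.matrix import ExpressionMatrix
from dieltx.timeline import Timeline

HOURS_PER_DAY = 24.0

# Early-day / early-night phase mixture: weights mirror the observed
# in-situ split of periodic transcripts (~55% early day, ~31% early
# night, remainder spread around the clock).
DEFAULT_PHASE_MIXTURE = ((0.55, 11.0, 8.0), (0.31, 23.0, 8.0))

DEFAULT_FUNCTION_POOL = (
    "chlorophyll a-b binding protein",
    "photosystem II D1/D2",
    "photosystem I",
    "cytochrome b6f",
    "phycobilisome",
    "ribulose bisphosphate carboxylase",
    "flavodoxin",
    "ferredoxin",
    "histone",
    "tubulin",
    "proteorhodopsin",
    "glycoside hydrolase",
)


@dataclass(frozen=True)
class TaxonSpec:
    """One taxon's generative parameters.

    phase_mixture is a tuple of (weight, mean_hour, kappa) von Mises
    components on the 24-h circle; leftover weight is uniform.
    amplitude_range bounds the relative amplitude A (must stay within
    [0, 1] or cyclic means would go negative).
    """

    name: str
    n_orfs: int
    frac_cyclic: float
    phase_mixture: tuple = DEFAULT_PHASE_MIXTURE
    amplitude_range: tuple[float, float] = (0.2, 0.8)
    dispersion: float = 0.09  # NB: var = mu + dispersion * mu^2  (CV ~ 0.3 at high mu)
    organellar_fraction: float = 0.0
    function_fraction: float = 0.5  # fraction of ORFs given a function label

    def __post_init__(self) -> None:
        if not 0.0 <= self.frac_cyclic <= 1.0:
            raise ValueError(f"frac_cyclic must be in [0,1], got {self.frac_cyclic}")
        lo, hi = self.amplitude_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError(
                f"amplitude_range must lie within [0,1] (negative means otherwise), got {self.amplitude_range}"
            )
        if sum(w for w, _, _ in self.phase_mixture) > 1.0 + 1e-9:
            raise ValueError("phase mixture weights exceed 1")


@dataclass
class SimulationConfig:
    """Study-design-shaped defaults: 16 samples at 4-h spacing (~2.6
    days, so days are unequally covered), fixed library size, lognormal
    noise with CV 0.3."""

    taxa: list = field(default_factory=lambda: default_community())
    n_timepoints: int = 16
    spacing_h: float = 4.0
    start_clock: float = 10.0
    dawn: float = 6.9
    dusk: float = 19.0
    library_size: float | None = 1_000_000.0
    noise_model: str = "lognormal"  # lognormal | negative_binomial | none
    cv: float = 0.3  # lognormal coefficient of variation
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spacing_h <= 0:
            raise ValueError("spacing_h must be positive")
        if self.noise_model not in ("lognormal", "negative_binomial", "none"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")

    def timeline(self) -> Timeline:
        return Timeline(
            sample_times=np.arange(self.n_timepoints) * self.spacing_h,
            start_clock=self.start_clock,
            dawn=self.dawn,
            dusk=self.dusk,
        )


def default_community() -> list[TaxonSpec]:
    """A drift-like mixed community: dinoflagellate-dominated, with
    phototroph transcriptomes far more rhythmic than heterotrophs
    (prasinophytes highest, dinoflagellates lowest)."""
    return [
        TaxonSpec("dinophyta", 400, 0.01, organellar_fraction=0.1),
        TaxonSpec("ciliophora", 150, 0.05),
        TaxonSpec("haptophyta", 150, 0.10, organellar_fraction=0.15),
        TaxonSpec("bacillariophyta", 150, 0.12, organellar_fraction=0.15),
        TaxonSpec("pelagophyceae", 100, 0.10, organellar_fraction=0.15),
        TaxonSpec("synechococcus", 100, 0.15),
        TaxonSpec("ostreococcus", 100, 0.25, organellar_fraction=0.1),
        TaxonSpec("flavobacteria", 100, 0.05),
        TaxonSpec("euryarchaeota", 50, 0.0),
        TaxonSpec("fungi", 50, 0.0),
    ]


def _sample_phases(rng: np.random.Generator, n: int, mixture) -> np.ndarray:
    """Draw peak times (hours) from a von Mises mixture plus uniform rest."""
    weights = [w for w, _, _ in mixture]
    p_uniform = max(0.0, 1.0 - sum(weights))
    choices = rng.choice(len(mixture) + 1, size=n, p=list(weights) + [p_uniform])
    out = np.empty(n)
    for i, c in enumerate(choices):
        if c == len(mixture):
            out[i] = rng.uniform(0.0, HOURS_PER_DAY)
        else:
            _, mean_h, kappa = mixture[c]
            mu = 2.0 * np.pi * mean_h / HOURS_PER_DAY
            theta = rng.vonmises(mu, kappa) if kappa > 0 else rng.uniform(-np.pi, np.pi)
            out[i] = (theta * HOURS_PER_DAY / (2.0 * np.pi)) % HOURS_PER_DAY
    return out


@dataclass
class SyntheticTruth:
    """Ground truth per simulated ORF; non-cyclic ORFs carry NaN phase."""

    table: pd.DataFrame  # orf_id-indexed: taxon_group, is_cyclic, true_peak_time, true_relative_amplitude, baseline

    def write(self, path) -> None:
        self.table.reset_index().to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def read(cls, path) -> "SyntheticTruth":
        df = pd.read_csv(path, sep="\t", dtype={"orf_id": str}).set_index("orf_id")
        df["is_cyclic"] = df["is_cyclic"].astype(bool)
        return cls(df)


def simulate_expression(config: SimulationConfig) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Generate a community count matrix and its ground truth.

    Fully reproducible from ``config.seed``. With ``library_size`` set,
    each column's expected total equals the library size (compositional
    coupling); with ``library_size=None`` raw per-ORF means are kept,
    which is the right mode for noise-free phase-recovery checks.
    """
    rng = np.random.default_rng(config.seed)
    timeline = config.timeline()
    t_clock = config.start_clock + timeline.sample_times  # continuous; cos is 24h-periodic

    orf_ids, taxa_labels, compartments, functions = [], [], [], []
    is_cyclic_all, phase_all, amp_all, baseline_all = [], [], [], []
    mean_rows = []
    for spec in config.taxa:
        n = spec.n_orfs
        ids = [f"{spec.name}_orf{i:05d}" for i in range(n)]
        cyc = rng.random(n) < spec.frac_cyclic
        phases = np.where(cyc, _sample_phases(rng, n, spec.phase_mixture), np.nan)
        lo, hi = spec.amplitude_range
        amps = np.where(cyc, rng.uniform(lo, hi, size=n), 0.0)
        # heavy-tailed baselines: a few ORFs dominate, as in real libraries
        baselines = rng.lognormal(mean=2.0, sigma=1.2, size=n)
        phase_term = np.cos(2.0 * np.pi * (t_clock[None, :] - phases[:, None]) / HOURS_PER_DAY)
        means = baselines[:, None] * (1.0 + np.where(cyc[:, None], amps[:, None] * phase_term, 0.0))
        comp = np.where(
            rng.random(n) < spec.organellar_fraction, "organellar", "nuclear"
        )
        has_fn = rng.random(n) < spec.function_fraction
        pool = DEFAULT_FUNCTION_POOL
        fn = np.where(has_fn, [pool[i % len(pool)] for i in range(n)], "")

        orf_ids.extend(ids)
        taxa_labels.extend([spec.name] * n)
        compartments.extend(comp.tolist())
        functions.extend(fn.tolist())
        is_cyclic_all.append(cyc)
        phase_all.append(phases)
        amp_all.append(amps)
        baseline_all.append(baselines)
        mean_rows.append(means)

    means = np.vstack(mean_rows)
    if config.library_size is not None:
        colsums = means.sum(axis=0)
        means = means * (config.library_size / colsums)[None, :]

    if config.noise_model == "none":
        counts = means
    elif config.noise_model == "lognormal":
        sigma = np.sqrt(np.log1p(config.cv**2))
        counts = means * rng.lognormal(mean=-(sigma**2) / 2.0, sigma=sigma, size=means.shape)
    else:  # negative binomial, var = mu + d mu^2
        d = max(s.dispersion for s in config.taxa) if config.taxa else 0.09
        disp = np.concatenate(
            [np.full(s.n_orfs, s.dispersion) for s in config.taxa]
        )[:, None]
        mu = means
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(disp > 0, 1.0 / disp, np.inf)
            p = np.where(np.isfinite(r), r / (r + mu), 1.0)
        counts = np.where(
            np.isfinite(r) & (mu > 0),
            rng.negative_binomial(np.where(np.isfinite(r), r, 1.0), np.clip(p, 1e-12, 1.0)),
            rng.poisson(mu),
        ).astype(float)

    index = pd.Index(orf_ids, name="orf_id")
    counts_df = pd.DataFrame(counts, index=index, columns=timeline.sample_labels)
    meta = pd.DataFrame(
        {
            "taxon_group": taxa_labels,
            "function_label": functions,
            "compartment": compartments,
        },
        index=index,
    )
    truth = pd.DataFrame(
        {
            "taxon_group": taxa_labels,
            "is_cyclic": np.concatenate(is_cyclic_all),
            "true_peak_time": np.concatenate(phase_all),
            "true_relative_amplitude": np.where(
                np.concatenate(is_cyclic_all), np.concatenate(amp_all), np.nan
            ),
            "baseline": np.concatenate(baseline_all),
        },
        index=index,
    )
    return ExpressionMatrix(counts=counts_df, meta=meta), SyntheticTruth(truth)


def simulate_hit_table(
    n_queries: int,
    lineage_pool,
    purity: float,
    seed: int = 0,
    min_hits: int = 5,
    max_hits: int = 50,
) -> tuple[HitTable, dict[str, tuple[str, ...]]]:
    """Homology hit tables with controllable lineage purity.

    Each query gets 5-50 hits with bit scores decaying from a maximum;
    each hit carries the query's true lineage with probability `purity`
    and a different pool lineage otherwise. Returns the table and the
    map of true lineages.
    """
    if not 0.0 <= purity <= 1.0:
        raise ValueError(f"purity must be in [0,1], got {purity}")
    pool = [tuple(l.split(";")) if isinstance(l, str) else tuple(l) for l in lineage_pool]
    if not pool:
        raise ValueError("lineage_pool must be non-empty")
    rng = np.random.default_rng(seed)
    rows = []
    lineage_map: dict[str, tuple[str, ...]] = {}
    truth: dict[str, tuple[str, ...]] = {}
    for q in range(n_queries):
        qid = f"query{q:05d}"
        true_idx = int(rng.integers(len(pool)))
        truth[qid] = pool[true_idx]
        n_hits = int(rng.integers(min_hits, max_hits + 1))
        max_score = rng.uniform(80.0, 500.0)
        decays = np.sort(rng.uniform(0.0, 0.3, size=n_hits))
        scores = max_score * (1.0 - decays)
        for j, score in enumerate(scores):
            sid = f"s{q:05d}_{j:03d}"
            if len(pool) > 1 and rng.random() >= purity:
                other = int(rng.integers(len(pool) - 1))
                lin = pool[other if other < true_idx else other + 1]
            else:
                lin = pool[true_idx]
            lineage_map[sid] = lin
            pident = float(np.clip(rng.normal(70.0, 15.0), 20.0, 100.0))
            rows.append((qid, sid, pident, float(score)))
    hits = pd.DataFrame(rows, columns=["query_id", "subject_id", "percent_identity", "bit_score"])
    return HitTable(hits=hits, lineage_map=lineage_map), truth


def simulate_phase_cascade(groups, seed: int = 0) -> pd.DataFrame:
    """Peak-time samples for circular-test fixtures.

    `groups` is a sequence of (label, n, circular_mean_hours,
    concentration); each group is von Mises on the 24-h circle
    (concentration 0 means uniform). Groups with n = 0 yield no rows.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for label, n, mean_h, kappa in groups:
        if kappa < 0:
            raise ValueError(f"concentration must be >= 0, got {kappa} for {label!r}")
        if n == 0:
            continue
        mu = 2.0 * np.pi * float(mean_h) / HOURS_PER_DAY
        theta = rng.vonmises(mu, kappa, size=n) if kappa > 0 else rng.uniform(-np.pi, np.pi, size=n)
        hours = (theta * HOURS_PER_DAY / (2.0 * np.pi)) % HOURS_PER_DAY
        rows.extend((str(label), h) for h in hours)
    return pd.DataFrame(rows, columns=["group", "peak_time"])
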