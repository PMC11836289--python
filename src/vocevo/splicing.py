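"""Percent-spliced-in quantification, differential calls and enrichment.

PSI (percent spliced in) for an alternative-splicing event is estimated
from junction reads supporting the inclusion and skipping isoforms.
Because isoforms are supported by different numbers of junctions (a
cassette exon has two inclusion junctions and one skipping junction),
inclusion reads are normalized by junction multiplicity first:

    PSI = (inc / n_inc) / (inc / n_inc + skip / n_skip)

Events pass the coverage filter when both groups have at least 20 raw
junction reads; an event is called differential when it passes coverage,
the between-group exact test gives p < 0.05, and |dPSI| > 0.05.

The module also provides the resampling gene-set enrichment test: the
observed overlap between a query gene set (e.g. differentially spliced
transcripts) and a category (e.g. vocal-behavior genes) is compared with
overlaps of uniformly resampled gene sets of the same size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import chi2_contingency, fisher_exact

__all__ = [
    "AS_TYPES",
    "EnrichmentResult",
    "compute_psi",
    "coverage_filter",
    "test_event",
    "analyze_events",
    "resample_enrichment",
    "peak_overlap",
    "read_gene_list",
    "read_bed",
]

AS_TYPES = ("cass", "alt5", "alt3", "taca", "mutx")

JUNCTION_COLUMNS = ["event_id", "gene", "as_type", "group", "inc_reads",
                    "skip_reads", "n_inc_junctions", "n_skip_junctions"]


def compute_psi(inc_reads: float, skip_reads: float,
                n_inc_junctions: int = 1, n_skip_junctions: int = 1) -> float:
    """Junction-multiplicity-normalized percent spliced in.

    Returns NaN (undefined) when no junction read supports either isoform.
    """
    if n_inc_junctions < 1 or n_skip_junctions < 1:
        raise ValueError("junction multiplicities must be >= 1")
    if inc_reads < 0 or skip_reads < 0:
        raise ValueError("read counts must be non-negative")
    inc_n = inc_reads / n_inc_junctions
    skip_n = skip_reads / n_skip_junctions
    total = inc_n + skip_n
    if total == 0:
        return float("nan")
    return inc_n / total


def coverage_filter(inc_a: float, skip_a: float, inc_b: float, skip_b: float,
                    min_reads: int = 20) -> bool:
    """True when both groups have >= ``min_reads`` raw junction reads."""
    return (inc_a + skip_a) >= min_reads and (inc_b + skip_b) >= min_reads


def _normalized_table(inc_a, skip_a, inc_b, skip_b, n_inc, n_skip):
    """2x2 integer table of inclusion-normalized vs skipping counts."""
    return np.array([
        [round(inc_a / n_inc), round(skip_a / n_skip)],
        [round(inc_b / n_inc), round(skip_b / n_skip)],
    ], dtype=int)


def test_event(inc_a: float, skip_a: float, inc_b: float, skip_b: float,
               n_inc_junctions: int = 1, n_skip_junctions: int = 1,
               strategy: str = "fisher") -> float:
    """Between-group p-value for one event on normalized pooled counts.

    ``strategy="fisher"`` (default) runs the two-sided 2x2 exact test;
    ``"chi2"`` the chi-square test with continuity correction.  Degenerate
    tables (an empty margin) return p = 1.
    """
    table = _normalized_table(inc_a, skip_a, inc_b, skip_b,
                              n_inc_junctions, n_skip_junctions)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return 1.0
    if strategy == "fisher":
        return float(fisher_exact(table, alternative="two-sided")[1])
    if strategy == "chi2":
        return float(chi2_contingency(table, correction=True)[1])
    raise ValueError(f"unknown test strategy: {strategy!r}")


def analyze_events(junctions: pd.DataFrame, group_a: str, group_b: str,
                   min_reads: int = 20, p_threshold: float = 0.05,
                   di_threshold: float = 0.05,
                   strategy: str = "fisher") -> pd.DataFrame:
    """Per-event PSI, dPSI, p-value and differential call for a long table.

    ``junctions`` holds one row per event and group with columns
    ``event_id, gene, as_type, group, inc_reads, skip_reads,
    n_inc_junctions, n_skip_junctions``; counts are assumed already summed
    over each group's samples.
    """
    missing = [c for c in JUNCTION_COLUMNS if c not in junctions.columns]
    if missing:
        raise ValueError(f"junction table missing columns: {missing}")
    bad = set(junctions["as_type"]) - set(AS_TYPES)
    if bad:
        raise ValueError(f"unknown as_type values: {sorted(bad)}")
    rows = []
    for event_id, sub in junctions.groupby("event_id", sort=False):
        a = sub[sub["group"] == group_a]
        b = sub[sub["group"] == group_b]
        if len(a) != 1 or len(b) != 1:
            raise ValueError(
                f"event {event_id!r} must have exactly one row per group")
        a, b = a.iloc[0], b.iloc[0]
        n_inc = int(a["n_inc_junctions"])
        n_skip = int(a["n_skip_junctions"])
        psi_a = compute_psi(a["inc_reads"], a["skip_reads"], n_inc, n_skip)
        psi_b = compute_psi(b["inc_reads"], b["skip_reads"], n_inc, n_skip)
        passes = coverage_filter(a["inc_reads"], a["skip_reads"],
                                 b["inc_reads"], b["skip_reads"], min_reads)
        di = psi_b - psi_a
        if passes:
            p = test_event(a["inc_reads"], a["skip_reads"],
                           b["inc_reads"], b["skip_reads"],
                           n_inc, n_skip, strategy=strategy)
        else:
            p = float("nan")
        rows.append({
            "event_id": event_id, "gene": a["gene"], "as_type": a["as_type"],
            "psi_a": psi_a, "psi_b": psi_b, "dI": di,
            "p_value": p, "passes_coverage": passes,
            "is_differential": bool(passes and np.isfinite(di)
                                    and p < p_threshold
                                    and abs(di) > di_threshold),
        })
    return pd.DataFrame(rows)


@dataclass
class EnrichmentResult:
    """Observed vs resampled gene-set overlap."""

    observed_overlap: int
    resample_mean: float
    resample_median: float
    q95: float
    empirical_p: float
    n_resamples: int
    seed: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def resample_enrichment(universe, category, query, n_resamples: int = 1000,
                        seed: int = 0) -> EnrichmentResult:
    """Resampling test for over-representation of a category in a query set.

    Each resample draws ``len(query)`` genes uniformly without replacement
    from the universe and counts the overlap with the category.  The
    empirical p-value is ``(1 + #{resample >= observed}) / (n + 1)``.
    """
    universe = list(dict.fromkeys(universe))
    category = set(category)
    query = set(query)
    uni_set = set(universe)
    if not query <= uni_set:
        raise ValueError("query must be a subset of the universe")
    if not category <= uni_set:
        raise ValueError("category must be a subset of the universe")
    if len(query) > len(universe):
        raise ValueError("query larger than universe")
    observed = len(query & category)
    rng = np.random.default_rng(seed)
    cat_mask = np.fromiter((g in category for g in universe), dtype=bool,
                           count=len(universe))
    n_uni, n_query = len(universe), len(query)
    overlaps = np.empty(n_resamples, dtype=np.int64)
    for r in range(n_resamples):
        idx = rng.choice(n_uni, size=n_query, replace=False)
        overlaps[r] = cat_mask[idx].sum()
    emp_p = (1 + int(np.sum(overlaps >= observed))) / (n_resamples + 1)
    return EnrichmentResult(
        observed_overlap=observed,
        resample_mean=float(overlaps.mean()),
        resample_median=float(np.median(overlaps)),
        q95=float(np.quantile(overlaps, 0.95)),
        empirical_p=emp_p, n_resamples=n_resamples, seed=seed,
    )


def peak_overlap(events: pd.DataFrame, peaks: pd.DataFrame,
                 one_based_peaks: bool = False) -> pd.DataFrame:
    """Mark events whose transcript span overlaps any binding peak.

    ``events`` needs ``chrom, tx_start, tx_end`` (0-based half-open);
    ``peaks`` needs ``chrom, start, end``.  ``one_based_peaks`` converts
    1-based inclusive peak coordinates on input.  Overlap requires at
    least one shared base (adjacent half-open intervals do not overlap).
    """
    peaks = peaks.copy()
    if one_based_peaks:
        peaks["start"] = peaks["start"] - 1
    if (peaks["start"] >= peaks["end"]).any():
        raise ValueError("malformed peak interval (start >= end)")
    if (events["tx_start"] >= events["tx_end"]).any():
        raise ValueError("malformed transcript interval (start >= end)")
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in peaks.groupby("chrom"):
        trees[chrom] = IntervalTree.from_tuples(
            zip(sub["start"].astype(int), sub["end"].astype(int)))
    out = events.copy()
    out["has_peak"] = [
        bool(trees.get(c) and trees[c].overlap(int(s), int(e)))
        for c, s, e in zip(events["chrom"], events["tx_start"],
                           events["tx_end"])
    ]
    return out


def read_gene_list(path) -> list[str]:
    """Newline-delimited gene list (blank lines ignored)."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def read_bed(path) -> pd.DataFrame:
    """Minimal BED reader: chrom, start, end (0-based half-open)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2], names=["chrom", "start", "end"])
    return df
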