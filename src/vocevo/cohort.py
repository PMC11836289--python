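"""Per-animal aggregation and genotype comparisons of syllable features.

The unit of inference is the animal, not the syllable: feature values are
averaged per session, session means are averaged per animal (pups have a
single session and pass through), and genotype groups of per-animal means
are compared with two-sided Wilcoxon rank-sum tests.  Bonferroni
correction is applied over the genotype pairs for independent parameters;
within-syllable "call structure" parameters conventionally skip the
correction because they are strongly inter-correlated and correcting them
inflates type-II error.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

__all__ = [
    "per_animal_aggregate",
    "wilcoxon_pairwise",
    "syllable_composition",
]

GENOTYPES = ("wt/wt", "hu/wt", "hu/hu")

#: combined sample size at or below which the exact rank-sum null is used
EXACT_N_MAX = 20


def per_animal_aggregate(syllables: pd.DataFrame, meta: pd.DataFrame,
                         features: list[str]) -> pd.DataFrame:
    """Per-animal feature means (session means averaged across sessions).

    ``syllables`` must carry ``animal_id`` and ``session`` columns;
    ``meta`` maps ``animal_id`` to ``genotype``.  Animals present in the
    metadata but without any syllables are excluded with a warning.
    """
    for col in ("animal_id", "session"):
        if col not in syllables.columns:
            raise ValueError(f"syllable table missing {col!r}")
    session_means = (syllables
                     .groupby(["animal_id", "session"], observed=True)[features]
                     .mean())
    animal_means = (session_means
                    .groupby("animal_id", observed=True)
                    .mean()
                    .reset_index())
    out = meta.merge(animal_means, on="animal_id", how="left")
    missing = out[features[0]].isna()
    if missing.any():
        warnings.warn(
            f"excluding {int(missing.sum())} animal(s) with no syllables: "
            f"{sorted(out.loc[missing, 'animal_id'])}")
        out = out[~missing]
    return out.reset_index(drop=True)


def _exact_or_asymptotic(x: np.ndarray, y: np.ndarray) -> str:
    pooled = np.concatenate([x, y])
    ties = len(np.unique(pooled)) < len(pooled)
    return "exact" if (len(pooled) <= EXACT_N_MAX and not ties) else "asymptotic"


def wilcoxon_pairwise(groups: dict[str, np.ndarray] | pd.DataFrame,
                      correct: bool = True,
                      feature: str | None = None,
                      group_col: str = "genotype") -> pd.DataFrame:
    """Two-sided rank-sum test for every group pair.

    ``groups`` is either ``{group: values}`` or a per-animal table with a
    group column and a ``feature`` column.  The exact null distribution is
    used when the combined sample size is at most 20 and there are no
    ties; otherwise the normal approximation with tie correction.  With
    ``correct=True`` p-values are Bonferroni-adjusted over the number of
    pairs tested.
    """
    if isinstance(groups, pd.DataFrame):
        if feature is None:
            raise ValueError("feature column name required with a DataFrame")
        groups = {g: sub[feature].to_numpy(dtype=float)
                  for g, sub in groups.groupby(group_col, observed=True)}
    names = list(groups)
    pairs = list(itertools.combinations(names, 2))
    rows = []
    for a, b in pairs:
        x = np.asarray(groups[a], dtype=float)
        y = np.asarray(groups[b], dtype=float)
        if len(x) < 2 or len(y) < 2:
            warnings.warn(f"skipping pair ({a}, {b}): group with < 2 animals")
            continue
        method = _exact_or_asymptotic(x, y)
        stat, p = mannwhitneyu(x, y, alternative="two-sided", method=method)
        rows.append({"feature": feature, "pair": f"{a} vs {b}",
                     "statistic": float(stat), "p_raw": float(p)})
    out = pd.DataFrame(rows,
                       columns=["feature", "pair", "statistic", "p_raw"])
    m = len(out)
    out["p_adjusted"] = (np.minimum(1.0, out["p_raw"] * m) if correct
                         else out["p_raw"])
    out["correction_applied"] = bool(correct)
    return out


def syllable_composition(syllables: pd.DataFrame, meta: pd.DataFrame,
                         classes: tuple[str, ...] = ("s", "u", "d", "m",
                                                     "notIDd")
                         ) -> pd.DataFrame:
    """Per-animal fraction of each syllable type (fractions sum to 1)."""
    if "animal_id" not in syllables.columns:
        raise ValueError("syllable table missing 'animal_id'")
    counts = (syllables.groupby("animal_id", observed=True)["class"]
              .value_counts()
              .unstack(fill_value=0)
              .reindex(columns=list(classes), fill_value=0))
    fractions = counts.div(counts.sum(axis=1), axis=0)
    fractions.columns = [f"frac_{c}" for c in fractions.columns]
    return meta.merge(fractions.reset_index(), on="animal_id", how="inner")
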