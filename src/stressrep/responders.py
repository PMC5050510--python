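"""Low/high responder (LR/HR) classification from repeated cortisol measures.

Cortisol is standardized within each sampling occasion to Z-scores, the
per-fish Z-scores are summed across occasions, and fish in the lower /
upper quartile of the summed-Z distribution are labelled LR / HR.  The
summed Z captures both the intensity and the consistency of the response:
a fish must sit below (above) the cohort mean repeatedly to accumulate a
strongly negative (positive) sum.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "validate_phenotypes",
    "zscore_by_occasion",
    "classify_responders",
    "mean_rank_consistency",
]

REQUIRED_COLUMNS = ("fish_id", "family_id", "occasion", "cortisol")


def validate_phenotypes(data: pd.DataFrame) -> pd.DataFrame:
    """Check the phenotype-table contract and return the validated frame.

    Requires the long-format columns (fish_id, family_id, occasion,
    cortisol), uniqueness of (fish_id, occasion), a single family per fish,
    and non-negative cortisol.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in data.columns]
    if missing:
        raise ValueError(f"phenotype table missing columns: {missing}")
    dup = data.duplicated(subset=["fish_id", "occasion"])
    if dup.any():
        rows = data.loc[dup, ["fish_id", "occasion"]].head(5).to_dict("records")
        raise ValueError(f"duplicate (fish_id, occasion) records: {rows}")
    fam_per_fish = data.groupby("fish_id")["family_id"].nunique()
    bad = fam_per_fish[fam_per_fish > 1]
    if len(bad):
        raise ValueError(f"fish mapped to multiple families: {list(bad.index)}")
    if not np.issubdtype(np.asarray(data["cortisol"]).dtype, np.number):
        raise ValueError("cortisol column must be numeric")
    if (data["cortisol"] < 0).any():
        raise ValueError("cortisol values must be non-negative")
    return data


def zscore_by_occasion(data: pd.DataFrame) -> pd.Series:
    """Per-record Z-score of cortisol within each sampling occasion.

    z = (x - mean_occasion) / sd_occasion, with mean and sample SD
    (denominator N-1) computed over the fish observed at that occasion.
    """
    validate_phenotypes(data)
    grouped = data.groupby("occasion")["cortisol"]
    counts = grouped.transform("count")
    if (counts < 2).any():
        occ = sorted(data.loc[counts < 2, "occasion"].unique())
        raise ValueError(f"occasions with < 2 observed fish: {occ}")
    sd = grouped.transform("std")  # ddof=1
    zero_sd = sd <= 0
    if zero_sd.any():
        occ = sorted(data.loc[zero_sd, "occasion"].unique())
        raise ValueError(f"zero cortisol SD at occasion(s) {occ}: "
                         "Z-scores undefined")
    z = (data["cortisol"] - grouped.transform("mean")) / sd
    z.name = "z"
    return z


def classify_responders(
    data: pd.DataFrame,
    quartile: float = 0.25,
    method: str = "sum",
) -> pd.DataFrame:
    """Classify fish as LR / HR / INTERMEDIATE by summed-Z quartiles.

    Parameters
    ----------
    data : long-format phenotype table.
    quartile : fraction of fish labelled at each tail; the default 0.25
        takes the classical lower and upper quartiles.
    method : "sum" sums Z over the occasions a fish was observed at;
        "mean" divides by the number of observed occasions, which removes
        the advantage/penalty of being observed more often when the table
        is unbalanced.

    Returns a DataFrame (one row per fish) with columns fish_id, family_id,
    sum_z, n_occasions_observed, rank (1 = lowest score) and label.  Ties
    in the score are broken by fish_id for determinism and logged when they
    straddle a quartile boundary.
    """
    if not 0 < quartile <= 0.5:
        raise ValueError("quartile must be in (0, 0.5]")
    if method not in ("sum", "mean"):
        raise ValueError("method must be 'sum' or 'mean'")
    z = zscore_by_occasion(data)
    per_fish = (
        data.assign(z=z)
        .groupby(["fish_id", "family_id"], as_index=False)
        .agg(sum_z=("z", "sum"), n_occasions_observed=("z", "count"))
    )
    if method == "mean":
        per_fish["sum_z"] = per_fish["sum_z"] / per_fish["n_occasions_observed"]

    n = len(per_fish)
    if per_fish["sum_z"].nunique() == 1:
        raise ValueError("all fish have identical scores; "
                         "quartile classification is undefined")
    per_fish = per_fish.sort_values(["sum_z", "fish_id"]).reset_index(drop=True)
    per_fish["rank"] = np.arange(1, n + 1)

    k = math.floor(quartile * n)
    labels = np.array(["INTERMEDIATE"] * n, dtype=object)
    labels[:k] = "LR"
    labels[n - k:] = "HR"
    per_fish["label"] = labels

    scores = per_fish["sum_z"].to_numpy()
    for boundary in (k, n - k):
        if 0 < boundary < n and scores[boundary - 1] == scores[boundary]:
            logger.warning(
                "tie at quartile boundary (score %.6g); broken by fish_id",
                scores[boundary])
    return per_fish


def mean_rank_consistency(data: pd.DataFrame) -> pd.DataFrame:
    """Per-fish mean cortisol rank across occasions, with standard error.

    Within each occasion fish are ranked by cortisol (average ranks on
    ties); each fish's ranks are then averaged over the occasions it was
    observed at.  Plotted against the fish's overall rank order, perfectly
    repeatable data fall on the identity line with zero SE.  Fish observed
    once have an undefined SE (NaN).
    """
    validate_phenotypes(data)
    ranks = data.groupby("occasion")["cortisol"].rank(method="average")
    per_fish = (
        data.assign(rank=ranks)
        .groupby(["fish_id", "family_id"], as_index=False)
        .agg(mean_rank=("rank", "mean"),
             sd_rank=("rank", "std"),
             n_occasions_observed=("rank", "count"))
    )
    per_fish["se_rank"] = per_fish["sd_rank"] / np.sqrt(
        per_fish["n_occasions_observed"])
    per_fish = per_fish.drop(columns="sd_rank")
    per_fish = per_fish.sort_values(
        ["mean_rank", "fish_id"]).reset_index(drop=True)
    per_fish["order"] = np.arange(1, len(per_fish) + 1)
    return per_fish
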