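"""Repeatability, variance components, and group-comparison statistics.

The core estimator is the ANOVA-based intraclass correlation
(Lessells & Boag):

    r = s²_among / (s²_among + s²_within)

with s²_among = (MS_ind - MS_within) / n0 and s²_within = MS_within, taken
from a two-level nested ANOVA (individuals nested within full-sib
families).  n0 is the effective number of replicates per individual for
unbalanced data,

    n0 = [Σn_i - Σn_i² / Σn_i] / (a - 1)

over the individuals' replicate counts n_i (a individuals).  Family is
treated as a blocking stratum excluded from the denominator by default;
``include_family`` adds the family component for a cohort-wide intraclass
correlation.  Measurement error is defined as sqrt(MS_within) in trait
units.

Variance components for the unbalanced nested design are solved by the
expected-mean-squares method of moments (Searle-type coefficients), which
is closed-form and exactly testable against brute-force sums of squares.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .responders import validate_phenotypes, zscore_by_occasion

logger = logging.getLogger(__name__)

__all__ = [
    "NestedAnovaTable",
    "RepeatabilityEstimate",
    "VarianceComponents",
    "GroupSummary",
    "nested_anova",
    "repeatability_estimate",
    "variance_components",
    "pooled_t_from_summary",
    "pooled_t_from_raw",
    "two_way_rm_anova",
    "assumption_checks",
    "free_cortisol_metrics",
]


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass
class NestedAnovaTable:
    """Sums of squares / mean squares for the two-level nested design."""

    ss_family: float
    ss_individual: float
    ss_within: float
    df_family: int
    df_individual: int
    df_within: int
    n_obs: int
    replicate_counts: pd.Series  # per-individual n_i, (family_id, fish_id) index
    family_sizes: pd.Series      # per-family total observations N_f
    grand_mean: float

    @property
    def ms_family(self) -> float:
        return self.ss_family / self.df_family

    @property
    def ms_individual(self) -> float:
        return self.ss_individual / self.df_individual

    @property
    def ms_within(self) -> float:
        return self.ss_within / self.df_within

    @property
    def f_individual(self) -> float:
        """F for consistent among-individual differences (MS_ind/MS_within)."""
        if self.ss_within == 0:
            return math.inf
        return self.ms_individual / self.ms_within

    @property
    def p_individual(self) -> float:
        f = self.f_individual
        if math.isinf(f):
            return 0.0
        return float(stats.f.sf(f, self.df_individual, self.df_within))

    def to_frame(self) -> pd.DataFrame:
        rows = {
            "family": (self.ss_family, self.df_family, self.ms_family),
            "individual(family)": (self.ss_individual, self.df_individual,
                                   self.ms_individual),
            "within": (self.ss_within, self.df_within, self.ms_within),
        }
        df = pd.DataFrame(rows, index=["SS", "df", "MS"]).T
        df["df"] = df["df"].astype(int)
        return df


@dataclass
class RepeatabilityEstimate:
    r: float
    s2_among: float
    s2_within: float
    n0: float
    measurement_error: float
    f_statistic: float
    df: tuple[int, int]
    p_value: float
    negative_s2_among: bool = False
    include_family: bool = False


@dataclass
class VarianceComponents:
    var_family: float
    var_individual: float
    var_residual: float
    raw_family: float
    raw_individual: float
    truncated: bool

    @property
    def pct_family(self) -> float:
        total = self.var_family + self.var_individual + self.var_residual
        return 100.0 * self.var_family / total if total > 0 else float("nan")

    @property
    def pct_individual(self) -> float:
        total = self.var_family + self.var_individual + self.var_residual
        return 100.0 * self.var_individual / total if total > 0 else float("nan")


@dataclass
class GroupSummary:
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group summary needs n >= 2")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")

    @classmethod
    def from_values(cls, values) -> "GroupSummary":
        values = np.asarray(values, dtype=float)
        return cls(mean=float(values.mean()),
                   sd=float(values.std(ddof=1)),
                   n=len(values))


# ---------------------------------------------------------------------------
# nested ANOVA (method of moments, unbalanced)
# ---------------------------------------------------------------------------

def nested_anova(data: pd.DataFrame, response: str = "raw") -> NestedAnovaTable:
    """Two-level nested ANOVA: individuals nested within families.

    SS_within = ΣΣ (x_it - x̄_i)²
    SS_ind    = Σ_f Σ_{i in f} n_i (x̄_i - x̄_f)²
    SS_family = Σ_f N_f (x̄_f - x̄)²

    ``response`` selects the raw cortisol scale or per-occasion Z-scores.
    """
    validate_phenotypes(data)
    if response == "z":
        y = zscore_by_occasion(data)
    elif response == "raw":
        y = data["cortisol"].astype(float)
    else:
        raise ValueError("response must be 'raw' or 'z'")

    df = data[["fish_id", "family_id"]].copy()
    df["y"] = np.asarray(y, dtype=float)

    n_obs = len(df)
    if df["family_id"].nunique() < 2:
        raise ValueError("nested ANOVA needs >= 2 families")
    per_ind = df.groupby(["family_id", "fish_id"])["y"].agg(["mean", "count"])
    if (per_ind["count"] >= 2).sum() == 0:
        raise ValueError("within-individual stratum has zero df "
                         "(all individuals observed once)")
    n_ind = len(per_ind)
    n_fam = df["family_id"].nunique()
    if n_ind == n_fam:
        raise ValueError("individual stratum has zero df "
                         "(one individual per family)")

    grand = df["y"].mean()
    per_fam = df.groupby("family_id")["y"].agg(["mean", "count"])

    ind_means = df.groupby("fish_id")["y"].transform("mean")
    ss_within = float(((df["y"] - ind_means) ** 2).sum())

    fam_mean_of_ind = per_ind.index.get_level_values("family_id").map(
        per_fam["mean"])
    ss_ind = float((per_ind["count"]
                    * (per_ind["mean"] - fam_mean_of_ind) ** 2).sum())
    ss_fam = float((per_fam["count"] * (per_fam["mean"] - grand) ** 2).sum())

    return NestedAnovaTable(
        ss_family=ss_fam,
        ss_individual=ss_ind,
        ss_within=ss_within,
        df_family=n_fam - 1,
        df_individual=n_ind - n_fam,
        df_within=n_obs - n_ind,
        n_obs=n_obs,
        replicate_counts=per_ind["count"],
        family_sizes=per_fam["count"],
        grand_mean=float(grand),
    )


def _lessells_boag_n0(replicate_counts: pd.Series) -> float:
    n_i = np.asarray(replicate_counts, dtype=float)
    total = n_i.sum()
    return float((total - (n_i ** 2).sum() / total) / (len(n_i) - 1))


def repeatability_estimate(
    anova: NestedAnovaTable,
    include_family: bool = False,
) -> RepeatabilityEstimate:
    """ANOVA repeatability from the individual vs within-individual strata.

    With ``include_family=True`` the family variance component (EMS
    solution) is added to the denominator, giving the fraction of total
    phenotypic variance due to consistent individual differences rather
    than the within-family repeatability.
    """
    if anova.df_within < 1:
        raise ValueError("within stratum has no degrees of freedom")
    n0 = _lessells_boag_n0(anova.replicate_counts)
    ms_ind, ms_within = anova.ms_individual, anova.ms_within
    s2_among = (ms_ind - ms_within) / n0
    s2_within = ms_within
    negative = s2_among < 0
    if negative:
        logger.warning("MS_ind < MS_within: s2_among = %.4g < 0 "
                       "(r reported negative, not clamped)", s2_among)
    denom = s2_among + s2_within
    if include_family:
        coef = _nested_ems_coefficients(anova)
        var_fam = (anova.ms_family - ms_within
                   - coef["c2"] * max(s2_among, 0.0)) / coef["c3"]
        denom += max(var_fam, 0.0)
    r = s2_among / denom if denom > 0 else float("nan")
    return RepeatabilityEstimate(
        r=float(r),
        s2_among=float(s2_among),
        s2_within=float(s2_within),
        n0=n0,
        measurement_error=float(np.sqrt(ms_within)),
        f_statistic=anova.f_individual,
        df=(anova.df_individual, anova.df_within),
        p_value=anova.p_individual,
        negative_s2_among=bool(negative),
        include_family=include_family,
    )


def _nested_ems_coefficients(anova: NestedAnovaTable) -> dict[str, float]:
    """Expected-mean-squares coefficients for the unbalanced nested design.

    E[MS_within] = σ²_e
    E[MS_ind]    = σ²_e + c1 σ²_I
    E[MS_family] = σ²_e + c2 σ²_I + c3 σ²_F

    For a balanced design with n replicates and m individuals per family
    these reduce to c1 = c2 = n and c3 = n·m.
    """
    n_i = anova.replicate_counts  # index: fish_id
    fam_sizes = anova.family_sizes
    n = float(anova.n_obs)
    a = len(fam_sizes)
    b = len(n_i)

    sum_ni2_by_fam = (n_i ** 2).groupby(level="family_id").sum()
    term_fam = float((sum_ni2_by_fam / fam_sizes).sum())
    sum_ni2 = float((n_i ** 2).sum())
    sum_nf2 = float((fam_sizes ** 2).sum())

    c1 = (n - term_fam) / (b - a)
    c2 = (term_fam - sum_ni2 / n) / (a - 1)
    c3 = (n - sum_nf2 / n) / (a - 1)
    return {"c1": c1, "c2": c2, "c3": c3}


def variance_components(data: pd.DataFrame, response: str = "raw") -> VarianceComponents:
    """Family / individual / residual variance components (EMS method).

    Solves the three expected-mean-squares equations of the nested ANOVA
    bottom-up; negative solutions are reported raw and truncated to zero
    for the percentage decomposition, with a flag.
    """
    anova = nested_anova(data, response=response)
    coef = _nested_ems_coefficients(anova)
    s2_e = anova.ms_within
    raw_ind = (anova.ms_individual - s2_e) / coef["c1"]
    var_ind = max(raw_ind, 0.0)
    raw_fam = (anova.ms_family - s2_e - coef["c2"] * var_ind) / coef["c3"]
    var_fam = max(raw_fam, 0.0)
    truncated = (raw_ind < 0) or (raw_fam < 0)
    if truncated:
        logger.warning("negative variance component estimate truncated to 0 "
                       "(raw individual=%.4g, family=%.4g)", raw_ind, raw_fam)
    return VarianceComponents(
        var_family=float(var_fam),
        var_individual=float(var_ind),
        var_residual=float(s2_e),
        raw_family=float(raw_fam),
        raw_individual=float(raw_ind),
        truncated=bool(truncated),
    )


# ---------------------------------------------------------------------------
# t-tests and assumption checks
# ---------------------------------------------------------------------------

def pooled_t_from_summary(g1: GroupSummary, g2: GroupSummary):
    """Classical pooled-variance two-sample t-test from summary statistics.

    Returns (t, df, two-sided p).  Both groups constant and equal gives
    t = 0 by convention; constant but different means gives infinite t.
    """
    df = g1.n + g2.n - 2
    sp2 = ((g1.n - 1) * g1.sd ** 2 + (g2.n - 1) * g2.sd ** 2) / df
    diff = g1.mean - g2.mean
    if sp2 == 0:
        if diff == 0:
            return 0.0, df, 1.0
        logger.warning("zero pooled variance with unequal means: t infinite")
        return math.copysign(math.inf, diff), df, 0.0
    se = math.sqrt(sp2 * (1.0 / g1.n + 1.0 / g2.n))
    t = diff / se
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return float(t), int(df), p


def pooled_t_from_raw(values1, values2):
    """Pooled two-sample t-test on raw values (see pooled_t_from_summary)."""
    return pooled_t_from_summary(GroupSummary.from_values(values1),
                                 GroupSummary.from_values(values2))


def two_way_rm_anova(data: pd.DataFrame, labels: pd.DataFrame) -> pd.DataFrame:
    """Split-plot ANOVA: responder group (between) × occasion (within).

    ``labels`` is a classification table with fish_id and label columns;
    only LR and HR fish enter.  Fish not observed at every occasion are
    dropped (logged); requires >= 2 complete fish per group.  Returns the
    ANOVA table with F and p per term (group, occasion, interaction).
    """
    import pingouin as pg

    validate_phenotypes(data)
    keep = labels.loc[labels["label"].isin(["LR", "HR"]), ["fish_id", "label"]]
    df = data.merge(keep, on="fish_id")
    n_occ = df["occasion"].nunique()
    complete = df.groupby("fish_id")["occasion"].nunique()
    complete_fish = complete[complete == n_occ].index
    dropped = sorted(set(df["fish_id"]) - set(complete_fish))
    if dropped:
        logger.info("dropping %d fish without complete occasion data", len(dropped))
    df = df[df["fish_id"].isin(complete_fish)]
    group_n = df.groupby("label")["fish_id"].nunique()
    if len(group_n) < 2 or (group_n < 2).any():
        raise ValueError("need >= 2 complete fish in each of LR and HR")

    table = pg.mixed_anova(data=df, dv="cortisol", within="occasion",
                           subject="fish_id", between="label")
    table = table.rename(columns={"Source": "term", "p-unc": "p",
                                  "p_unc": "p"})
    table["term"] = table["term"].replace({"label": "group",
                                           "Interaction": "group x occasion"})
    return table[["term", "SS", "DF1", "DF2", "F", "p"]]


def assumption_checks(values_by_group: dict) -> pd.DataFrame:
    """Report-only normality (Lilliefors/KS vs fitted normal) and Levene.

    Returns one row per group for the normality check plus one row for the
    homogeneity-of-variance check across groups (Levene, center=mean).
    Never gates any analysis.
    """
    from statsmodels.stats.diagnostic import lilliefors

    rows = []
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_group.items()}
    for name, vals in groups.items():
        if len(vals) < 3:
            raise ValueError(f"group {name!r} needs n >= 3")
        if np.ptp(vals) == 0:
            rows.append({"check": "ks_normality", "group": name,
                         "statistic": np.nan, "p": np.nan,
                         "note": "constant values; undefined"})
            continue
        stat, p = lilliefors(vals, dist="norm")
        rows.append({"check": "ks_normality", "group": name,
                     "statistic": float(stat), "p": float(p), "note": ""})
    if len(groups) >= 2:
        if all(np.ptp(v) == 0 for v in groups.values()):
            rows.append({"check": "levene", "group": "all",
                         "statistic": np.nan, "p": np.nan,
                         "note": "all groups constant; undefined"})
        else:
            stat, p = stats.levene(*groups.values(), center="mean")
            rows.append({"check": "levene", "group": "all",
                         "statistic": float(stat), "p": float(p), "note": ""})
    return pd.DataFrame(rows)


def free_cortisol_metrics(total, free, tolerance: float = 0.05) -> pd.DataFrame:
    """Percentage of free over total cortisol per fish.

    pct_free = 100 * free / total.  Zero totals yield NaN with a flag;
    free > total*(1+tolerance) is flagged as exceeding assay plausibility
    but still reported.
    """
    total = np.asarray(total, dtype=float)
    free = np.asarray(free, dtype=float)
    if total.shape != free.shape:
        raise ValueError("total and free must have the same length")
    if (free < 0).any() or (total < 0).any():
        raise ValueError("cortisol concentrations must be non-negative")
    undefined = total == 0
    exceeds = free > total * (1 + tolerance)
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(undefined, np.nan, 100.0 * free / total)
    if undefined.any():
        logger.warning("%d zero-total records: %%free undefined", undefined.sum())
    if exceeds.any():
        logger.warning("%d records with free > total beyond tolerance",
                       int(exceeds.sum()))
    return pd.DataFrame({"total": total, "free": free, "pct_free": pct,
                         "flag_zero_total": undefined,
                         "flag_free_exceeds_total": exceeds})
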