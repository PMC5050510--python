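"""Synthetic data generators for the cortisol-repeatability pipeline.

Three generators with known ground truth:

* :func:`simulate_cortisol` — repeated post-stress plasma cortisol for a
  full-sib family design, as an additive random-effects model with
  occasion-specific location/scale shifts and record-wise MCAR missingness.
* :func:`simulate_counts` — a transcript × sample negative-binomial count
  matrix with planted group-exclusive transcripts.
* :func:`simulate_annotation` — a gene → GO-term map with planted enriched
  terms over-representing a designated study set.

All generators draw from a single ``numpy.random.default_rng`` (PCG64)
engine seeded per call, so identical configs give identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CortisolSimConfig",
    "CountSimConfig",
    "AnnotationSimConfig",
    "simulate_cortisol",
    "simulate_counts",
    "simulate_annotation",
]


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------

@dataclass
class CortisolSimConfig:
    """Generative model for repeated cortisol measurements.

    cortisol(f, i, t) = occasion_means[t]
                        + occasion_sd_scale[t] * (F_f + I_i + e_fit)

    with F_f ~ N(0, var_family) per family, I_i ~ N(0, var_individual) per
    individual (drawn once), and e_fit ~ N(0, var_residual) per record.
    Records are deleted independently with probability ``missing_rate``
    (MCAR); negative values are floored at 0 and counted.

    Defaults mirror the study design this package models: 6 full-sib
    families of 12 fish sampled at 4 monthly occasions, post-stress plasma
    cortisol on the ~300 ng/ml scale, with variance split
    (family, individual, residual) = (2500, 3000, 4500) ng²/ml², i.e. a
    true within-family repeatability of 3000/7500 = 0.4.
    """

    n_families: int = 6
    n_per_family: int = 12
    n_occasions: int = 4
    var_family: float = 2500.0
    var_individual: float = 3000.0
    var_residual: float = 4500.0
    occasion_means: list[float] = field(
        default_factory=lambda: [300.0, 320.0, 280.0, 310.0])
    occasion_sd_scale: list[float] = field(
        default_factory=lambda: [1.0, 1.0, 1.0, 1.0])
    missing_rate: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_families, self.n_per_family, self.n_occasions) < 1:
            raise ValueError("design dimensions must be positive")
        for name in ("var_family", "var_individual", "var_residual"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if len(self.occasion_means) != self.n_occasions:
            raise ValueError("occasion_means length must equal n_occasions")
        if len(self.occasion_sd_scale) != self.n_occasions:
            raise ValueError("occasion_sd_scale length must equal n_occasions")
        if any(s <= 0 for s in self.occasion_sd_scale):
            raise ValueError("occasion_sd_scale entries must be > 0")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.missing_rate > 0 and self.n_occasions * (1 - self.missing_rate) < 1:
            logger.warning(
                "missing_rate %.2f leaves < 1 expected occasion per fish",
                self.missing_rate)


@dataclass
class CountSimConfig:
    """Two-group NB count matrix with planted exclusive transcripts.

    Non-exclusive transcripts are NB(mean = baseline_mean * size_factor_j,
    dispersion) in every sample, with Var = mu + dispersion * mu².  A
    transcript planted as exclusive to one group is zero in every sample of
    the other group and has at least one count in every sample of its own
    group.  Three replicates per group matches the liver RNA-seq design
    (3 LR vs 3 HR fish).
    """

    n_transcripts: int = 2000
    n_per_group: int = 3
    baseline_mean: float = 100.0
    dispersion: float = 0.1
    n_exclusive_g1: int = 169
    n_exclusive_g2: int = 161
    library_size_factors: list[float] | None = None
    group_names: tuple[str, str] = ("LR", "HR")
    seed: int = 0

    def validate(self) -> None:
        if self.n_transcripts < 1 or self.n_per_group < 1:
            raise ValueError("n_transcripts and n_per_group must be positive")
        if self.baseline_mean <= 0 or self.dispersion < 0:
            raise ValueError("baseline_mean must be > 0 and dispersion >= 0")
        if self.n_exclusive_g1 < 0 or self.n_exclusive_g2 < 0:
            raise ValueError("exclusive counts must be >= 0")
        if self.n_exclusive_g1 + self.n_exclusive_g2 > self.n_transcripts:
            raise ValueError("more exclusive transcripts than transcripts")
        if self.library_size_factors is not None:
            if len(self.library_size_factors) != 2 * self.n_per_group:
                raise ValueError(
                    "library_size_factors must have one entry per sample")
            if any(s <= 0 for s in self.library_size_factors):
                raise ValueError("library size factors must be > 0")


@dataclass
class AnnotationSimConfig:
    """Gene → GO-term map with planted enriched terms."""

    n_terms: int = 100
    genes_per_term_mean: float = 20.0
    n_enriched_terms: int = 5
    enrichment_fold: float = 8.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_terms < 1 or self.genes_per_term_mean <= 0:
            raise ValueError("n_terms and genes_per_term_mean must be positive")
        if not 0 <= self.n_enriched_terms <= self.n_terms:
            raise ValueError("n_enriched_terms must be in [0, n_terms]")
        if self.enrichment_fold < 1:
            raise ValueError("enrichment_fold must be >= 1")


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def simulate_cortisol(
    config: CortisolSimConfig,
    return_effects: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a long-format phenotype table of repeated cortisol values.

    Returns a DataFrame with columns ``fish_id``, ``family_id``,
    ``occasion`` (1-based), ``cortisol``, ``floored`` (True where a
    negative draw was clipped to 0).  With ``return_effects=True`` also
    returns the per-fish latent truth (family effect ``F``, individual
    effect ``I``) for parameter-recovery tests.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_fam, n_ind, n_occ = config.n_families, config.n_per_family, config.n_occasions
    n_fish = n_fam * n_ind

    fam_eff = rng.normal(0.0, np.sqrt(config.var_family), n_fam)
    ind_eff = rng.normal(0.0, np.sqrt(config.var_individual), n_fish)
    resid = rng.normal(0.0, np.sqrt(config.var_residual), (n_fish, n_occ))

    family_of_fish = np.repeat(np.arange(n_fam), n_ind)
    base = fam_eff[family_of_fish][:, None] + ind_eff[:, None] + resid
    means = np.asarray(config.occasion_means, dtype=float)
    scales = np.asarray(config.occasion_sd_scale, dtype=float)
    values = means[None, :] + scales[None, :] * base

    fam_width = len(str(n_fam))
    fish_width = len(str(n_fish))
    fish_ids = np.array([f"fish{i + 1:0{fish_width}d}" for i in range(n_fish)])
    family_ids = np.array([f"fam{f + 1:0{fam_width}d}" for f in range(n_fam)])

    table = pd.DataFrame({
        "fish_id": np.repeat(fish_ids, n_occ),
        "family_id": np.repeat(family_ids[family_of_fish], n_occ),
        "occasion": np.tile(np.arange(1, n_occ + 1), n_fish),
        "cortisol": values.ravel(),
    })

    keep = rng.random(len(table)) >= config.missing_rate
    table = table.loc[keep].reset_index(drop=True)

    floored = table["cortisol"] < 0
    n_floored = int(floored.sum())
    if n_floored:
        logger.info("floored %d negative cortisol values at 0", n_floored)
    table["cortisol"] = table["cortisol"].clip(lower=0.0)
    table["floored"] = floored.to_numpy()

    if not return_effects:
        return table
    effects = pd.DataFrame({
        "fish_id": fish_ids,
        "family_id": family_ids[family_of_fish],
        "family_effect": fam_eff[family_of_fish],
        "individual_effect": ind_eff,
    })
    return table, effects


def _nb_draws(rng: np.random.Generator, mean, dispersion: float, size):
    """NB draws under the mean/dispersion convention Var = mu + a*mu²."""
    mean = np.broadcast_to(np.asarray(mean, dtype=float), size)
    if dispersion == 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_counts(config: CountSimConfig) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Simulate a transcript × sample count matrix with planted exclusives.

    Returns ``(counts, groups, truth)``:

    * ``counts`` — DataFrame indexed by transcript id, one column per sample;
    * ``groups`` — Series mapping sample id to group name;
    * ``truth`` — Series per transcript in {"none", "<g1>_only", "<g2>_only"}.

    Planted exclusive transcripts draw their present-group counts from the
    same NB model clipped to at least 1 (so they are detected in every
    replicate) and are exactly 0 in the other group.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    g1, g2 = config.group_names
    n = config.n_per_group
    samples = [f"{g1}_{i + 1}" for i in range(n)] + [f"{g2}_{i + 1}" for i in range(n)]
    groups = pd.Series([g1] * n + [g2] * n, index=samples, name="group")

    sf = (np.ones(2 * n) if config.library_size_factors is None
          else np.asarray(config.library_size_factors, dtype=float))
    mu = config.baseline_mean * sf

    counts = _nb_draws(rng, mu, config.dispersion,
                       (config.n_transcripts, 2 * n)).astype(np.int64)

    truth = np.array(["none"] * config.n_transcripts, dtype=object)
    k1, k2 = config.n_exclusive_g1, config.n_exclusive_g2
    idx1 = np.arange(k1)
    idx2 = np.arange(k1, k1 + k2)
    g1_cols = np.arange(n)
    g2_cols = np.arange(n, 2 * n)
    if k1:
        counts[np.ix_(idx1, g1_cols)] = np.maximum(counts[np.ix_(idx1, g1_cols)], 1)
        counts[np.ix_(idx1, g2_cols)] = 0
        truth[idx1] = f"{g1}_only"
    if k2:
        counts[np.ix_(idx2, g2_cols)] = np.maximum(counts[np.ix_(idx2, g2_cols)], 1)
        counts[np.ix_(idx2, g1_cols)] = 0
        truth[idx2] = f"{g2}_only"

    width = len(str(config.n_transcripts))
    tids = [f"transcript{i + 1:0{width}d}" for i in range(config.n_transcripts)]
    counts_df = pd.DataFrame(counts, index=pd.Index(tids, name="transcript_id"),
                             columns=samples)
    truth_s = pd.Series(truth, index=counts_df.index, name="truth")
    return counts_df, groups, truth_s


def simulate_annotation(
    config: AnnotationSimConfig,
    gene_ids,
    study_genes=None,
) -> tuple[pd.DataFrame, list[str]]:
    """Simulate a gene → GO-term annotation table.

    Each term draws ~Poisson(genes_per_term_mean) member genes (at least 1).
    The first ``n_enriched_terms`` terms sample members with the genes in
    ``study_genes`` up-weighted by ``enrichment_fold``, planting true
    over-representation.  Returns the long-format annotation table and the
    list of planted enriched term ids.
    """
    config.validate()
    gene_ids = list(gene_ids)
    if not gene_ids:
        raise ValueError("gene_ids must be non-empty")
    study = set(study_genes) if study_genes is not None else set()
    rng = np.random.default_rng(config.seed)

    genes = np.asarray(gene_ids, dtype=object)
    in_study = np.array([g in study for g in genes])
    base_w = np.ones(len(genes))
    enr_w = np.where(in_study, config.enrichment_fold, 1.0)

    rows_gene: list[str] = []
    rows_term: list[str] = []
    enriched_terms: list[str] = []
    for t in range(config.n_terms):
        term = f"GO:{t + 1:07d}"
        size = min(len(genes), max(1, rng.poisson(config.genes_per_term_mean)))
        w = enr_w if t < config.n_enriched_terms else base_w
        members = rng.choice(genes, size=size, replace=False, p=w / w.sum())
        if t < config.n_enriched_terms:
            enriched_terms.append(term)
        rows_gene.extend(members)
        rows_term.extend([term] * size)

    annotation = pd.DataFrame({"gene_id": rows_gene, "go_id": rows_term})
    return annotation, enriched_terms
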