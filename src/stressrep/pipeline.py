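"""End-to-end pipeline driver.

Chains the analysis stages — responder classification, repeatability and
variance components, then (when count data are supplied) the exclusive-
transcript screen and GO enrichment — and writes all stage outputs plus a
JSON run report with the seed, thresholds and row counts at every stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from . import io as srio
from .repeatability import nested_anova, repeatability_estimate, variance_components
from .responders import classify_responders, mean_rank_consistency
from .screen import (
    exclusive_transcripts,
    expression_heatmap_cluster,
    fisher_go_enrichment,
    low_support_filter,
    nb_pairwise_test,
    size_factors_median_of_ratios,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    phenotypes: str
    out_dir: str
    counts: str | None = None
    groups: str | None = None
    annotation: str | None = None
    quartile: float = 0.25
    response: str = "z"
    min_total: int = 10
    detection_min: int = 1
    absence_max: int = 0
    alpha: float = 0.05
    fdr: float = 0.05
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def validate(self) -> None:
        if not 0 < self.quartile <= 0.5:
            raise ValueError("quartile must be in (0, 0.5]")
        if self.response not in ("raw", "z"):
            raise ValueError("response must be 'raw' or 'z'")
        for name in ("min_total", "detection_min", "absence_max"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("alpha", "fdr"):
            if not 0 < getattr(self, name) < 1:
                raise ValueError(f"{name} must be in (0, 1)")
        if (self.counts is None) != (self.groups is None):
            raise ValueError("counts and groups must be given together")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns the run report (also written to out_dir)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": {k: v for k, v in asdict(config).items() if k != "extra"},
        "stages": {},
    }

    # --- phenotype stages -------------------------------------------------
    pheno = srio.read_phenotypes(config.phenotypes)
    report["stages"]["phenotypes"] = {
        "rows": len(pheno),
        "fish": int(pheno["fish_id"].nunique()),
        "families": int(pheno["family_id"].nunique()),
    }

    classification = classify_responders(pheno, quartile=config.quartile)
    classification.to_csv(out / "classification.tsv", sep="\t", index=False)
    n_lr = int((classification["label"] == "LR").sum())
    n_hr = int((classification["label"] == "HR").sum())
    report["stages"]["classification"] = {
        "n_fish": len(classification), "n_LR": n_lr, "n_HR": n_hr,
    }

    ranks = mean_rank_consistency(pheno)
    ranks.to_csv(out / "mean_ranks.tsv", sep="\t", index=False)

    anova = nested_anova(pheno, response=config.response)
    anova.to_frame().to_csv(out / "nested_anova.tsv", sep="\t",
                            index_label="stratum")
    est = repeatability_estimate(anova)
    me = repeatability_estimate(nested_anova(pheno, response="raw"))
    comps = variance_components(pheno, response=config.response)
    report["stages"]["repeatability"] = {
        "response": config.response,
        "r": est.r,
        "F": est.f_statistic,
        "df": list(est.df),
        "p": est.p_value,
        "measurement_error_raw": me.measurement_error,
        "pct_family_variance": comps.pct_family,
    }

    # --- transcriptome stages ---------------------------------------------
    if config.counts is None:
        report["stages"]["transcriptome"] = "skipped (no count data supplied)"
    else:
        counts = srio.read_counts(config.counts)
        groups = srio.read_groups(config.groups)
        n_in = len(counts)
        counts, _ = low_support_filter(counts, min_total=config.min_total)
        sf = size_factors_median_of_ratios(counts)
        sf.rename_axis("sample_id").reset_index().to_csv(
            out / "size_factors.tsv", sep="\t", index=False)
        p = nb_pairwise_test(counts, groups, size_factors=sf)
        calls = exclusive_transcripts(
            counts, groups, p,
            detection_min=config.detection_min,
            absence_max=config.absence_max,
            alpha=config.alpha, fdr=config.fdr)
        calls.to_csv(out / "exclusive_calls.tsv", sep="\t",
                     index_label="transcript_id")
        call_counts = calls["call"].value_counts().to_dict()
        report["stages"]["screen"] = {
            "transcripts_in": n_in,
            "transcripts_retained": len(counts),
            "transcripts_dropped": n_in - len(counts),
            "calls": {k: int(v) for k, v in call_counts.items()},
        }

        called = calls.index[calls["call"] != "none"]
        if len(called) >= 2:
            clust = expression_heatmap_cluster(counts, groups, called)
            srio.write_json_report(
                {"row_order": list(map(str, clust.row_order)),
                 "col_order": list(map(str, clust.col_order)),
                 "top_split": {str(k): int(v)
                               for k, v in clust.top_split.items()},
                 "purity": clust.purity},
                out / "clustering.json")
            report["stages"]["clustering"] = {"column_split_purity": clust.purity}

        if config.annotation is not None:
            ann = srio.read_annotation(config.annotation)
            background = list(counts.index)
            enrichment = {}
            for group in pd.unique(groups[counts.columns]):
                study = list(calls.index[calls["call"] == f"{group}_only"])
                if not study:
                    continue
                res = fisher_go_enrichment(study, background, ann)
                res.to_csv(out / f"enrichment_{group}.tsv", sep="\t",
                           index=False)
                enrichment[group] = {
                    "terms_tested": len(res),
                    "significant": int((res["p"] < config.alpha).sum()),
                }
            report["stages"]["enrichment"] = enrichment

    srio.write_json_report(report, out / "run_report.json")
    return report
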