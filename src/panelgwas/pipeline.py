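"""End-to-end analysis pipeline.

Stages run in the study's order: sample/SNP QC, per-cohort and pooled
additive association, two-cohort meta-analysis with heterogeneity, and
the weighted genetic risk score with quintile-gradient, correlation and
AUC evaluation. All outputs are tab-delimited tables; runs are
deterministic for a fixed configuration and input.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import grs as grs_mod
from .assoc import bonferroni_threshold, run_panel
from .meta import meta_analyze_table
from .qc import QcReport, apply_qc
from .types import GenotypeMatrix, SnpPanel, StudyConfig

log = logging.getLogger("panelgwas")


class ConfigurationError(ValueError):
    """The requested analysis is inconsistent with the supplied data."""


@dataclass
class ReportBundle:
    """All tables produced by one pipeline run."""

    qc: QcReport
    assoc: pd.DataFrame
    meta: Optional[pd.DataFrame]
    grs_weights: pd.DataFrame
    grs_scores: pd.DataFrame
    grs_summary: pd.DataFrame
    summary: dict = field(default_factory=dict)

    def write(self, out_dir: str) -> None:
        os.makedirs(out_dir, exist_ok=True)
        self.qc.snps.to_csv(os.path.join(out_dir, "qc_snps.tsv"), sep="\t", index=False)
        self.qc.individuals.to_csv(os.path.join(out_dir, "qc_individuals.tsv"),
                                   sep="\t", index=False)
        self.assoc.to_csv(os.path.join(out_dir, "association.tsv"), sep="\t",
                          index=False, float_format="%.6g")
        if self.meta is not None:
            self.meta.to_csv(os.path.join(out_dir, "meta_analysis.tsv"), sep="\t",
                             index=False, float_format="%.6g")
        self.grs_weights.to_csv(os.path.join(out_dir, "grs_weights.tsv"), sep="\t",
                                index=False, float_format="%.6g")
        self.grs_scores.to_csv(os.path.join(out_dir, "grs_scores.tsv"), sep="\t",
                               index=False, float_format="%.6g")
        self.grs_summary.to_csv(os.path.join(out_dir, "grs_quintiles.tsv"), sep="\t",
                                index=False, float_format="%.6g")
        with open(os.path.join(out_dir, "summary.txt"), "w") as fh:
            for k, v in self.summary.items():
                fh.write(f"{k}\t{v}\n")


def run_pipeline(
    config: StudyConfig,
    gm: GenotypeMatrix,
    phenotypes: pd.DataFrame,
    panel: Optional[SnpPanel] = None,
    meta: bool = True,
) -> ReportBundle:
    """Run QC, association, meta-analysis and the risk score.

    Requires every genotyped individual to appear in ``phenotypes``.
    Meta-analysis needs exactly two cohorts; requesting it with fewer is
    a :class:`ConfigurationError`.
    """
    cohorts = sorted(set(gm.cohort))
    if meta and len(cohorts) < 2:
        raise ConfigurationError(
            f"meta-analysis requested but only {len(cohorts)} cohort present"
        )

    filtered, qc_report = apply_qc(gm, phenotypes, config, panel)
    log.info("QC: excluded %d individuals, %d SNPs",
             qc_report.n_excluded_individuals, qc_report.n_excluded_snps)
    for r in qc_report.snps.itertuples():
        if not r.kept:
            log.info("QC exclusion: %s (%s)", r.snp_id, r.exclusion_reason)

    assoc = run_panel(filtered, phenotypes, config, panel)
    threshold = bonferroni_threshold(config.alpha, config.n_independent_tests)

    meta_table = None
    if meta:
        if panel is None:
            raise ConfigurationError("meta-analysis requires a SNP panel for allele pairs")
        meta_table = meta_analyze_table(assoc, panel, cohorts=cohorts)

    weights = grs_mod.select_grs_snps(
        assoc, panel, cohorts=cohorts, pooled="pooled",
    ) if len(cohorts) > 1 else grs_mod.GrsWeights(
        table=pd.DataFrame(columns=["snp_id", "risk_allele", "weight"]))

    pheno_idx = phenotypes.set_index("individual_id")
    if len(weights):
        scores = grs_mod.compute_wgrs(filtered.subset(snps=weights.snp_ids),
                                      weights, missing=config.grs_missing)
        ph = pheno_idx.reindex(scores["individual_id"])
        grad = grs_mod.quintile_gradient(scores["integer_score"], ph["bmi"],
                                         ph["age"], ph["sex"].to_numpy())
        r, r_p = grs_mod.score_bmi_correlation(scores["integer_score"], ph["bmi"])
        auc = grs_mod.auc_obesity(scores["integer_score"],
                                  ph["obesity"].to_numpy(dtype=bool))
        summary_grs = {
            "grs_n_snps": len(weights),
            "grs_q5_minus_q1": grad["q5_minus_q1"],
            "grs_bmi_pearson_r": r,
            "grs_bmi_pearson_p": r_p,
            "grs_auc_obesity": auc,
        }
        grs_summary = grad["table"]
    else:
        scores = pd.DataFrame(columns=["individual_id", "cohort", "raw_score",
                                       "integer_score"])
        grs_summary = pd.DataFrame()
        summary_grs = {"grs_n_snps": 0}

    summary = {
        "n_individuals_input": gm.n_individuals,
        "n_individuals_kept": filtered.n_individuals,
        "n_snps_input": gm.n_snps,
        "n_snps_kept": filtered.n_snps,
        "bonferroni_threshold": float(f"{threshold:.3g}"),
        **summary_grs,
    }
    return ReportBundle(
        qc=qc_report,
        assoc=assoc,
        meta=meta_table,
        grs_weights=weights.table,
        grs_scores=scores,
        grs_summary=grs_summary,
        summary=summary,
    )
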