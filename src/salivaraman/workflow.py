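"""End-to-end analysis: preprocessing -> PCA-LDA -> biomarker statistics.

:func:`analyze_cohort` runs the complete study workflow on an assembled
cohort and returns an :class:`AnalysisResult` whose pieces the CLI writes to
disk. Stages degrade gracefully: when the assay concentration columns are
absent the correlation and linear-model stages are skipped with a warning
and everything upstream still completes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import biomarker_stats as bstats
from .biomarker_stats import LACTIC_ACID_WINDOW
from .chemometrics import RamanPCALDA, RamanPCALDAResults
from .exceptions import DegenerateDataError, SalivaRamanError
from .preprocess import (
    PreprocessConfig,
    PreprocessResult,
    group_summary,
    preprocess_cohort,
    subtraction_spectrum,
)
from .spectra_io import Cohort, clinical_frame

logger = logging.getLogger(__name__)


@dataclass
class AnalysisResult:
    """Everything the analysis computes, stage by stage."""

    preprocess: PreprocessResult
    group_summaries: dict                    # group -> GroupSpectrumSummary
    subtraction: Optional[np.ndarray]        # OSAS mean - CTR mean
    classification: RamanPCALDAResults
    peak_table: pd.DataFrame                 # subject_id, group, auc_920
    stats: dict = field(default_factory=dict)          # named GroupComparison
    stratifications: dict = field(default_factory=dict)
    correlations: dict = field(default_factory=dict)   # named CorrelationResult
    lm_quadratic: Optional[object] = None
    lm_joint: Optional[object] = None
    skipped: list = field(default_factory=list)

    def cv_frame(self) -> pd.DataFrame:
        return self.classification.crossval.frame()


def _safe(stats_dict, skipped, name, fn, *args, **kwargs):
    try:
        stats_dict[name] = fn(*args, **kwargs)
    except (DegenerateDataError, SalivaRamanError) as exc:
        logger.warning("stage %s skipped: %s", name, exc)
        skipped.append(name)


def analyze_cohort(
    cohort: Cohort,
    preprocess_config: Optional[PreprocessConfig] = None,
    n_components: Optional[int] = None,
    k_max: int = 10,
    peak_window: tuple = LACTIC_ACID_WINDOW,
    welch: bool = False,
    local_chord: bool = False,
) -> AnalysisResult:
    """Run the full pipeline on `cohort`.

    ``n_components=None`` (default) selects the PC count by minimizing the
    balanced LOOCV error over ``1..k_max``; a fixed integer skips selection.
    """
    pre = preprocess_cohort(cohort, preprocess_config)

    summaries = {}
    for grp in ("OSAS", "CTR"):
        try:
            summaries[grp] = group_summary(cohort, grp)
        except DegenerateDataError:
            logger.warning("group %s absent from the preprocessed cohort", grp)
    subtraction = None
    if len(summaries) == 2:
        subtraction = subtraction_spectrum(summaries["OSAS"], summaries["CTR"])

    model = RamanPCALDA(
        pre.matrix, pre.labels.to_numpy(), n_components=n_components, k_max=k_max
    )
    classification = model.fit()

    peak_table = bstats.peak_auc_table(cohort, peak_window, local_chord)
    clin = clinical_frame(cohort).loc[peak_table.index]

    stats_out: dict = {}
    skipped: list = []
    osas_auc = peak_table.loc[peak_table["group"] == "OSAS", "auc_920"].to_numpy()
    ctr_auc = peak_table.loc[peak_table["group"] == "CTR", "auc_920"].to_numpy()

    _safe(stats_out, skipped, "auc920_shapiro_osas", bstats.shapiro_wilk, osas_auc)
    _safe(stats_out, skipped, "auc920_shapiro_ctr", bstats.shapiro_wilk, ctr_auc)
    _safe(stats_out, skipped, "auc920_ttest", bstats.two_sample_t,
          osas_auc, ctr_auc, welch)

    # severity / obesity stratification of the OSAS peak areas
    records = [c.clinical for c in cohort.subjects if c.subject_id in peak_table.index]
    osas_records = [r for r in records if r.group == "OSAS"]
    strat: dict = {}
    for by in ("ahi_class", "bmi_class"):
        strat[by] = bstats.stratify(osas_records, by)
    auc_by_id = peak_table["auc_920"]
    ahi_groups = [
        auc_by_id.loc[ids].to_numpy()
        for ids in strat["ahi_class"].groups.values()
        if len(ids) >= 2
    ]
    if len(ahi_groups) >= 2:
        _safe(stats_out, skipped, "auc920_anova_ahi", bstats.anova_oneway, ahi_groups)
    else:
        skipped.append("auc920_anova_ahi")
    bmi_groups = [
        auc_by_id.loc[ids].to_numpy()
        for ids in strat["bmi_class"].groups.values()
        if len(ids) >= 2
    ]
    if len(bmi_groups) == 2:
        _safe(stats_out, skipped, "auc920_ttest_bmi", bstats.two_sample_t,
              bmi_groups[0], bmi_groups[1], welch)
    else:
        skipped.append("auc920_ttest_bmi")

    # assay concentration group contrasts (Mann-Whitney)
    for column in ("lactate_uM", "cortisol_ng_ml", "sod3_pg_ml"):
        sub = clin.dropna(subset=[column]) if column in clin else pd.DataFrame()
        if len(sub) == 0:
            skipped.append(f"{column}_mannwhitney")
            continue
        a = sub.loc[sub["group"] == "OSAS", column].to_numpy(dtype=float)
        b = sub.loc[sub["group"] == "CTR", column].to_numpy(dtype=float)
        if a.size and b.size:
            _safe(stats_out, skipped, f"{column}_mannwhitney", bstats.mann_whitney, a, b)
        else:
            skipped.append(f"{column}_mannwhitney")

    # correlations and linear models (within the OSAS group, as the study's
    # canonical-variable correlates were examined in patients)
    correlations: dict = {}
    lm_quadratic = lm_joint = None
    cvf = classification.crossval.frame().set_index("subject_id")
    osas_ids = [r.subject_id for r in osas_records]
    cv_osas = cvf.loc[osas_ids, "cv_score"].to_numpy(dtype=float)
    auc_osas = auc_by_id.loc[osas_ids].to_numpy(dtype=float)

    def _corr(name, xs, ys):
        try:
            correlations[name] = bstats.spearman(xs, ys)
        except (DegenerateDataError, SalivaRamanError) as exc:
            logger.warning("correlation %s skipped: %s", name, exc)
            skipped.append(name)

    clin_osas = clin.loc[osas_ids]
    has_lactate = "lactate_uM" in clin_osas and clin_osas["lactate_uM"].notna().all()
    if has_lactate:
        lact = clin_osas["lactate_uM"].to_numpy(dtype=float)
        _corr("cv_vs_lactate", cv_osas, lact)
    else:
        skipped.append("cv_vs_lactate")
    _corr("cv_vs_auc920", cv_osas, auc_osas)
    for cov in ("ahi", "ess", "bmi"):
        vals = clin_osas[cov]
        if vals.notna().all():
            _corr(f"cv_vs_{cov}", cv_osas, vals.to_numpy(dtype=float))
    if clin_osas["bmi"].notna().all():
        _corr("auc920_vs_bmi", auc_osas, clin_osas["bmi"].to_numpy(dtype=float))

    if has_lactate and len(osas_ids) >= 10:
        lact = clin_osas["lactate_uM"].to_numpy(dtype=float)
        try:
            lm_quadratic = bstats.fit_lm_quadratic(cv_osas, lact, osas_ids)
            lm_joint = bstats.fit_lm_joint(
                cv_osas, lact, auc_osas, osas_ids,
                exclude=lm_quadratic.removed_points,
            )
        except (SalivaRamanError, np.linalg.LinAlgError) as exc:
            logger.warning("linear-model stage skipped: %s", exc)
            skipped.append("linear_models")
    else:
        skipped.append("linear_models")

    return AnalysisResult(
        preprocess=pre,
        group_summaries=summaries,
        subtraction=subtraction,
        classification=classification,
        peak_table=peak_table,
        stats=stats_out,
        stratifications=strat,
        correlations=correlations,
        lm_quadratic=lm_quadratic,
        lm_joint=lm_joint,
        skipped=skipped,
    )
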