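"""Lactic-acid peak-area biomarker and downstream univariate statistics.

The spectroscopic biomarker is the trapezoidal area of the preprocessed
subject spectrum over the lactic-acid window 910.75-930.13 cm^-1 (the
920 cm^-1 band). Around it sit the study's univariate battery (Shapiro-Wilk,
pooled two-sample t, Mann-Whitney, one-way ANOVA), severity/obesity
stratification, Spearman correlations, and two ordinary least squares
models of the canonical variable: a quadratic-lactate screen used to flag
and drop outliers/influential points, then a joint model
``CV ~ lactate + auc_920``.

All hypothesis tests are two-sided and report nominal p-values without
multiplicity correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.diagnostic import het_breuschpagan

from .exceptions import CoverageError, DegenerateDataError, FitError
from .spectra_io import ClinicalRecord, RamanSpectrum

#: Integration window of the lactic-acid band (cm^-1).
LACTIC_ACID_WINDOW = (910.75, 930.13)


# ---------------------------------------------------------------------------
# peak area
# ---------------------------------------------------------------------------

@dataclass
class PeakAUCResult:
    subject_id: str
    auc: float
    window: tuple                 # requested window (cm^-1)
    snapped_window: tuple         # window after snapping inward to the grid


def peak_auc(
    spectrum: RamanSpectrum,
    window: tuple = LACTIC_ACID_WINDOW,
    local_chord: bool = False,
) -> PeakAUCResult:
    """Trapezoidal integral of intensity over `window`.

    Window endpoints are snapped inward to the nearest grid points so the
    integration bounds are bit-reproducible on a fixed grid. With
    ``local_chord=True`` the straight line joining the window's endpoint
    intensities is subtracted first (local-baseline convention).
    """
    lo, hi = window
    w, y = spectrum.wavenumbers, spectrum.intensities
    if lo < w[0] or hi > w[-1]:
        raise CoverageError(
            f"window {window} outside grid ({w[0]:.2f}..{w[-1]:.2f})"
        )
    idx = np.flatnonzero((w >= lo) & (w <= hi))
    if idx.size < 2:
        raise CoverageError(f"window {window} contains fewer than 2 grid points")
    ww, yy = w[idx], y[idx]
    if local_chord:
        chord = yy[0] + (yy[-1] - yy[0]) * (ww - ww[0]) / (ww[-1] - ww[0])
        yy = yy - chord
    return PeakAUCResult(
        subject_id=spectrum.subject_id,
        auc=float(np.trapezoid(yy, ww)),
        window=(lo, hi),
        snapped_window=(float(ww[0]), float(ww[-1])),
    )


# ---------------------------------------------------------------------------
# univariate tests
# ---------------------------------------------------------------------------

def _summary(values: np.ndarray) -> dict:
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return {
        "n": int(values.size),
        "mean": float(values.mean()),
        "sd": float(values.std(ddof=1)) if values.size > 1 else 0.0,
        "median": float(med),
        "iqr": float(q3 - q1),
    }


@dataclass
class GroupComparison:
    test: str
    statistic: float
    p_value: float
    group_summaries: list = field(default_factory=list)


def shapiro_wilk(values: Sequence[float]) -> GroupComparison:
    """Shapiro-Wilk normality test (3 <= n <= 5000)."""
    values = np.asarray(values, dtype=float)
    if not 3 <= values.size <= 5000:
        raise DegenerateDataError(
            f"Shapiro-Wilk needs 3 <= n <= 5000, got n = {values.size}"
        )
    if np.all(values == values[0]):
        raise DegenerateDataError("constant sample: normality test undefined")
    res = stats.shapiro(values)
    return GroupComparison(
        test="shapiro_wilk",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        group_summaries=[_summary(values)],
    )


def two_sample_t(
    values_a: Sequence[float],
    values_b: Sequence[float],
    welch: bool = False,
) -> GroupComparison:
    """Two-sided two-sample t-test, pooled variance by default."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DegenerateDataError("t-test needs n >= 2 per group")
    if np.all(a == a[0]) and np.all(b == b[0]):
        raise DegenerateDataError("zero pooled variance: t-test undefined")
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return GroupComparison(
        test="t_welch" if welch else "t_two_sample",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        group_summaries=[_summary(a), _summary(b)],
    )


def mann_whitney(values_a: Sequence[float], values_b: Sequence[float]) -> GroupComparison:
    """Two-sided Mann-Whitney U test (tie-corrected normal approximation)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise DegenerateDataError("Mann-Whitney needs n >= 1 per group")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        stat, p = a.size * b.size / 2.0, 1.0
    else:
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic",
            use_continuity=False,
        )
        stat, p = float(res.statistic), float(res.pvalue)
    return GroupComparison(
        test="mann_whitney",
        statistic=stat,
        p_value=p,
        group_summaries=[_summary(a), _summary(b)],
    )


def anova_oneway(groups: Sequence[Sequence[float]]) -> GroupComparison:
    """One-way ANOVA across >= 2 groups."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(g.size < 2 for g in arrays):
        raise DegenerateDataError("ANOVA needs >= 2 groups of n >= 2")
    within = sum(float(np.sum((g - g.mean()) ** 2)) for g in arrays)
    if within == 0:
        grand = np.concatenate(arrays)
        if np.all(grand == grand[0]):
            return GroupComparison(
                test="anova_oneway", statistic=0.0, p_value=1.0,
                group_summaries=[_summary(g) for g in arrays],
            )
        raise DegenerateDataError("zero within-group variance: F undefined")
    res = stats.f_oneway(*arrays)
    return GroupComparison(
        test="anova_oneway",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        group_summaries=[_summary(g) for g in arrays],
    )


# ---------------------------------------------------------------------------
# stratification
# ---------------------------------------------------------------------------

#: AHI severity bins (events/h): both boundary values 15 and 30 are moderate.
AHI_CLASSES = ("mild", "moderate", "severe")
BMI_CLASSES = ("overweight", "obese")


def ahi_class(ahi: float) -> Optional[str]:
    if 5 <= ahi < 15:
        return "mild"
    if 15 <= ahi <= 30:
        return "moderate"
    if ahi > 30:
        return "severe"
    return None


def bmi_class(bmi: float) -> Optional[str]:
    if 25 <= bmi < 30:
        return "overweight"
    if bmi >= 30:
        return "obese"
    return None


@dataclass
class StratificationResult:
    by: str
    groups: dict                  # class label -> list of subject ids
    excluded: list                # subject ids outside every bin


def stratify(records: Sequence[ClinicalRecord], by: str) -> StratificationResult:
    """Partition subjects into AHI severity or BMI obesity classes.

    Subjects missing the covariate or falling outside every bin (e.g.
    BMI < 25) are reported in ``excluded`` rather than dropped silently.
    """
    if by == "ahi_class":
        classes, fn, attr = AHI_CLASSES, ahi_class, "ahi"
    elif by == "bmi_class":
        classes, fn, attr = BMI_CLASSES, bmi_class, "bmi"
    else:
        raise ValueError(f"unknown stratification {by!r}")
    groups = {c: [] for c in classes}
    excluded = []
    for r in records:
        value = getattr(r, attr)
        label = fn(value) if value is not None else None
        if label is None:
            excluded.append(r.subject_id)
        else:
            groups[label].append(r.subject_id)
    return StratificationResult(by=by, groups=groups, excluded=excluded)


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------

@dataclass
class CorrelationResult:
    variables: tuple
    rho: float
    p_value: float
    n: int
    method: str = "spearman"


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p for Spearman's rho (small n)."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    perms = np.array(list(permutations(range(x.size))))
    permuted = ry[perms]                      # (n!, n)
    rx_c = rx - rx.mean()
    p_c = permuted - permuted.mean(axis=1, keepdims=True)
    denom = np.sqrt((rx_c**2).sum() * (p_c**2).sum(axis=1))
    rhos = (p_c @ rx_c) / denom
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def spearman(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman rank correlation; exact permutation p for n <= 9, the
    t-distribution approximation otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise DegenerateDataError("Spearman needs paired data with n >= 4")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise DegenerateDataError("constant vector: rank correlation undefined")
    res = stats.spearmanr(x, y)
    rho = float(res.statistic)
    if x.size <= 9:
        p = _spearman_exact_p(x, y, rho)
    else:
        p = float(res.pvalue)
    return CorrelationResult(variables=("x", "y"), rho=rho, p_value=p, n=x.size)


# ---------------------------------------------------------------------------
# linear models
# ---------------------------------------------------------------------------

@dataclass
class LinearModelFit:
    formula: str
    coefficients: dict
    p_values: dict
    removed_points: list
    diagnostics: dict
    n_used: int
    results: object = field(repr=False, default=None)  # statsmodels results


def _diagnostics(results) -> dict:
    resid = np.asarray(results.resid)
    out = {"resid_shapiro_p": np.nan, "breusch_pagan_p": np.nan}
    if resid.size >= 3 and np.ptp(resid) > 1e-12 * max(1.0, np.abs(resid).max()):
        out["resid_shapiro_p"] = float(stats.shapiro(resid).pvalue)
        try:
            out["breusch_pagan_p"] = float(
                het_breuschpagan(resid, results.model.exog)[1]
            )
        except (ValueError, np.linalg.LinAlgError):
            pass
    return out


def _influence_flags(results, n: int) -> np.ndarray:
    """Cook's distance > 4/n or |externally studentized residual| > 3."""
    scale = max(float(np.abs(results.model.endog).max()), 1.0)
    if results.ssr < 1e-16 * scale**2:        # interpolating fit: nothing to flag
        return np.zeros(n, dtype=bool)
    infl = results.get_influence()
    cooks = infl.cooks_distance[0]
    student = infl.resid_studentized_external
    with np.errstate(invalid="ignore"):
        return (cooks > 4.0 / n) | (np.abs(student) > 3.0)


def fit_lm_quadratic(
    cv_scores: Sequence[float],
    lactate: Sequence[float],
    subject_ids: Optional[Sequence[str]] = None,
) -> LinearModelFit:
    """OLS of the canonical variable on lactate and lactate squared.

    The quadratic term uses centered lactate to limit collinearity; reported
    coefficients are mapped back to the raw ``(1, lactate, lactate^2)``
    basis. Points with Cook's distance above 4/n or an externally
    studentized residual beyond +/-3 are flagged, removed and the model
    refit; the final fit's residual normality (Shapiro-Wilk) and
    homoscedasticity (Breusch-Pagan) p-values are reported.
    """
    cv = np.asarray(cv_scores, dtype=float)
    lac = np.asarray(lactate, dtype=float)
    if cv.size != lac.size or cv.size < 10:
        raise FitError("quadratic LM needs paired data with n >= 10")
    ids = list(subject_ids) if subject_ids is not None else [f"s{i}" for i in range(cv.size)]

    def _fit(cv_v, lac_v):
        mu = lac_v.mean()
        lc = lac_v - mu
        X = sm.add_constant(np.column_stack([lc, lc**2]))
        res = sm.OLS(cv_v, X).fit()
        b0, b1c, b2 = res.params
        # back-transform: cv = b0' + b1*lac + b2*lac^2 in the raw basis
        coefs = {
            "intercept": float(b0 - b1c * mu + b2 * mu**2),
            "lactate": float(b1c - 2 * b2 * mu),
            "lactate_sq": float(b2),
        }
        pvals = {
            "intercept": float(res.pvalues[0]),
            "lactate": float(res.pvalues[1]),
            "lactate_sq": float(res.pvalues[2]),
        }
        return res, coefs, pvals

    res, _, _ = _fit(cv, lac)
    flags = _influence_flags(res, cv.size)
    removed = [ids[i] for i in np.flatnonzero(flags)]
    keep = ~flags
    if keep.sum() < 4:
        raise FitError("outlier removal left too few points to refit")
    res, coefs, pvals = _fit(cv[keep], lac[keep])
    return LinearModelFit(
        formula="cv ~ lactate + lactate^2",
        coefficients=coefs,
        p_values=pvals,
        removed_points=removed,
        diagnostics=_diagnostics(res),
        n_used=int(keep.sum()),
        results=res,
    )


def fit_lm_joint(
    cv_scores: Sequence[float],
    lactate: Sequence[float],
    auc_920: Sequence[float],
    subject_ids: Optional[Sequence[str]] = None,
    exclude: Sequence[str] = (),
) -> LinearModelFit:
    """OLS of the canonical variable on lactate (beta1) and auc_920 (beta2).

    `exclude` holds subject ids flagged by the quadratic screen; they are
    dropped before fitting. A rank-deficient or near-collinear design
    raises :class:`FitError`.
    """
    cv = np.asarray(cv_scores, dtype=float)
    lac = np.asarray(lactate, dtype=float)
    auc = np.asarray(auc_920, dtype=float)
    if not (cv.size == lac.size == auc.size):
        raise FitError("joint LM needs three columns of equal length")
    ids = list(subject_ids) if subject_ids is not None else [f"s{i}" for i in range(cv.size)]
    keep = np.array([sid not in set(exclude) for sid in ids])
    cv, lac, auc = cv[keep], lac[keep], auc[keep]
    kept_ids = [sid for sid in ids if sid not in set(exclude)]
    if cv.size < 4:
        raise FitError("joint LM needs n >= 4 after exclusions")
    X = sm.add_constant(np.column_stack([lac, auc]))
    if np.linalg.matrix_rank(X) < 3 or np.linalg.cond(X) > 1e10:
        raise FitError("rank-deficient/collinear design (lactate vs auc_920)")
    res = sm.OLS(cv, X).fit()
    return LinearModelFit(
        formula="cv ~ lactate + auc_920",
        coefficients={
            "intercept": float(res.params[0]),
            "beta1_lactate": float(res.params[1]),
            "beta2_auc_920": float(res.params[2]),
        },
        p_values={
            "intercept": float(res.pvalues[0]),
            "beta1_lactate": float(res.pvalues[1]),
            "beta2_auc_920": float(res.pvalues[2]),
        },
        removed_points=list(exclude),
        diagnostics=_diagnostics(res),
        n_used=int(cv.size),
        results=res,
    )


def peak_auc_table(cohort, window: tuple = LACTIC_ACID_WINDOW, local_chord: bool = False) -> pd.DataFrame:
    """Per-subject lactic-acid peak areas from the averaged spectra."""
    rows = []
    for s in cohort.subjects:
        if s.averaged is None:
            continue
        res = peak_auc(s.averaged, window, local_chord)
        rows.append(
            {"subject_id": s.subject_id, "group": s.group, "auc_920": res.auc}
        )
    return pd.DataFrame(rows).set_index("subject_id")
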