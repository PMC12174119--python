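"""Cohort-level statistics for the biomarker screening pipeline.

Implements the classical two-group screening workflow on a cohort feature
table: demographic comparisons, a per-marker differential battery with
normality-based test routing (Shapiro–Wilk per group; independent-samples t
when both groups look normal, Mann–Whitney U otherwise; chi-square for
categorical columns), stepwise binary logistic selection of markers, ROC
analysis with DeLong confidence intervals, and an a priori two-sample
t-test sample-size computation via the noncentral-t power function.

The Mann–Whitney test uses exact enumeration for small untied samples and
the tie- and continuity-corrected normal approximation otherwise. The AUC
is the pairwise concordance probability (ties count 1/2) with the MCI group
as the positive class; DeLong's structural-component variance gives the
95% interval.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .session import BIOMARKER_COLUMNS

__all__ = [
    "GroupComparison",
    "StepwiseModel",
    "RocResult",
    "PowerSpec",
    "ScreeningReport",
    "PipelineConfig",
    "compare_groups",
    "stepwise_logistic",
    "roc_auc",
    "sample_size_ttest",
    "run_screening_pipeline",
]

log = logging.getLogger(__name__)

POSITIVE_CLASS = "MCI"


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------

@dataclass
class GroupComparison:
    """One marker's two-group test: the test actually used, the matching
    descriptive style (mean±SD for t, median(IQR) for Mann–Whitney,
    counts for chi-square), the statistic and the two-sided p."""

    marker: str
    test: str  # t_independent | mann_whitney | chi_square
    desc_mci: str
    desc_hc: str
    statistic: float
    p: float

    @property
    def significant(self) -> bool:
        return self.p < 0.05


def _mean_sd(x: np.ndarray) -> str:
    return f"{np.mean(x):.2f} ± {np.std(x, ddof=1):.2f}"


def _median_iqr(x: np.ndarray) -> str:
    q1, q2, q3 = np.percentile(x, [25, 50, 75])
    return f"{q2:.2f} ({q3 - q1:.2f})"


def _mann_whitney_exact(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact two-sided Mann–Whitney p by full enumeration of the
    ``C(nx+ny, nx)`` group assignments (tie-aware: ties add 1/2 to U).

    The two-sided p counts assignments whose U deviates from the null mean
    ``nx*ny/2`` at least as much as the observed U.
    """
    from itertools import combinations

    pooled = np.concatenate([x, y])
    n, nx = len(pooled), len(x)
    mu = nx * (n - nx) / 2.0

    def u_of(idx: tuple) -> float:
        mask = np.zeros(n, bool)
        mask[list(idx)] = True
        a, b = pooled[mask], pooled[~mask]
        diff = a[:, None] - b[None, :]
        return float((diff > 0).sum() + 0.5 * (diff == 0).sum())

    u_obs = u_of(tuple(range(nx)))
    dev = abs(u_obs - mu) - 1e-12
    total = hits = 0
    for idx in combinations(range(n), nx):
        total += 1
        if abs(u_of(idx) - mu) >= dev:
            hits += 1
    return u_obs, hits / total


def _mann_whitney(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann–Whitney U: exact enumeration for small samples,
    otherwise the tie-corrected normal approximation with continuity
    correction."""
    nx, ny = len(x), len(y)
    if nx <= 7 and ny <= 7:
        return _mann_whitney_exact(x, y)
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                           use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def compare_groups(cohort: pd.DataFrame, markers: Sequence[str],
                   normality_alpha: float = 0.05) -> list:
    """Differential battery over ``markers`` between the MCI and HC rows.

    Numeric markers are routed by per-group Shapiro–Wilk at
    ``normality_alpha``: only when *both* groups pass is the independent t
    test used (descriptives mean±SD); otherwise Mann–Whitney (median(IQR)).
    Categorical markers (e.g. sex) always use the Pearson chi-square without
    continuity correction. Missing values are dropped per marker; a marker
    with fewer than 3 usable values in either group is skipped with a
    warning.
    """
    groups = cohort["group"]
    if not {"MCI", "HC"} <= set(groups):
        raise ValueError("cohort must contain both MCI and HC rows")
    out: list[GroupComparison] = []
    for marker in markers:
        if marker not in cohort.columns:
            raise KeyError(f"marker {marker!r} not in cohort table")
        col = cohort[marker]
        if not pd.api.types.is_numeric_dtype(col):
            tab = pd.crosstab(groups, col)
            chi2, p, _, _ = sps.chi2_contingency(tab.to_numpy(),
                                                 correction=False)
            def fmt(g):
                return "/".join(str(v) for v in tab.loc[g])
            out.append(GroupComparison(marker, "chi_square",
                                       fmt("MCI"), fmt("HC"),
                                       float(chi2), float(p)))
            continue
        x = col[groups == "MCI"].dropna().to_numpy(float)
        y = col[groups == "HC"].dropna().to_numpy(float)
        if len(x) < 3 or len(y) < 3:
            warnings.warn(f"marker {marker}: fewer than 3 usable values in a "
                          "group; skipped")
            continue
        normal = all(
            len(np.unique(v)) > 1 and sps.shapiro(v).pvalue > normality_alpha
            for v in (x, y))
        if normal:
            res = sps.ttest_ind(x, y, equal_var=True)
            out.append(GroupComparison(marker, "t_independent",
                                       _mean_sd(x), _mean_sd(y),
                                       float(res.statistic), float(res.pvalue)))
        else:
            u, p = _mann_whitney(x, y)
            out.append(GroupComparison(marker, "mann_whitney",
                                       _median_iqr(x), _median_iqr(y), u, p))
    return out


# ---------------------------------------------------------------------------
# stepwise logistic selection
# ---------------------------------------------------------------------------

@dataclass
class StepwiseModel:
    """Bidirectional stepwise binary logistic model (MCI = 1)."""

    selected: list
    coef: dict  # original-scale coefficients
    intercept: float
    probabilities: np.ndarray  # per-subject P(MCI)
    separation_fallback: bool = False
    trace: list = field(default_factory=list)


def _logit_loglik(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))


def _fit_logit(y: np.ndarray, X: np.ndarray):
    """Maximum-likelihood logistic fit; returns (params, probs, ll, ok)."""
    import statsmodels.api as sm

    Xc = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
        except Exception:
            return None, None, -np.inf, False
    params = np.asarray(res.params, float)
    ok = bool(res.mle_retvals.get("converged", True)) and \
        bool(np.all(np.abs(params) < 1e3))
    probs = np.asarray(res.predict(Xc), float)
    return params, probs, _logit_loglik(y, probs), ok


def _fit_ridge(y: np.ndarray, X: np.ndarray):
    """L2-stabilized fallback for (quasi-)separated data."""
    from sklearn.linear_model import LogisticRegression

    clf = LogisticRegression(C=1.0, max_iter=1000)
    clf.fit(X, y)
    params = np.concatenate([clf.intercept_, clf.coef_[0]])
    probs = clf.predict_proba(X)[:, 1]
    return params, probs, _logit_loglik(y, probs)


def stepwise_logistic(cohort: pd.DataFrame, candidates: Sequence[str],
                      p_enter: float = 0.05,
                      p_remove: float = 0.10) -> StepwiseModel:
    """Bidirectional stepwise selection with likelihood-ratio p-values.

    Candidates are z-standardized internally (selection is therefore
    invariant to affine rescaling of the columns); the final model is refit
    on the original scale. Rows with any missing candidate value are
    dropped. Perfect separation triggers a flagged ridge-stabilized
    refit instead of unbounded coefficients.
    """
    y_all = (cohort["group"] == POSITIVE_CLASS).to_numpy(int)
    candidates = list(candidates)
    sub = cohort[candidates].apply(pd.to_numeric) if candidates \
        else pd.DataFrame(index=cohort.index)
    keep = ~sub.isna().any(axis=1) if candidates else pd.Series(
        True, index=cohort.index)
    y = y_all[keep.to_numpy()]
    Z = sub[keep].to_numpy(float)
    if candidates:
        mu, sd = Z.mean(axis=0), Z.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        Z = (Z - mu) / sd

    selected: list[int] = []
    trace: list[str] = []

    def ll_of(idx: list[int]) -> float:
        if not idx:
            p0 = np.full_like(y, y.mean(), dtype=float)
            return _logit_loglik(y, p0)
        _, _, ll, ok = _fit_logit(y, Z[:, idx])
        if not ok:
            _, probs, ll = _fit_ridge(y, Z[:, idx])
        return ll

    changed = True
    while changed:
        changed = False
        # forward step
        ll_cur = ll_of(selected)
        best_p, best_j = 1.0, None
        for j in range(len(candidates)):
            if j in selected:
                continue
            ll_new = ll_of(selected + [j])
            lr = max(0.0, 2.0 * (ll_new - ll_cur))
            p = sps.chi2.sf(lr, df=1)
            if p < best_p:
                best_p, best_j = p, j
        if best_j is not None and best_p < p_enter:
            selected.append(best_j)
            trace.append(f"+{candidates[best_j]} (LR p={best_p:.3g})")
            changed = True
        # backward step
        if len(selected) > 1:
            ll_cur = ll_of(selected)
            worst_p, worst_j = 0.0, None
            for j in selected[:-1] if changed else selected:
                rest = [k for k in selected if k != j]
                lr = max(0.0, 2.0 * (ll_cur - ll_of(rest)))
                p = sps.chi2.sf(lr, df=1)
                if p > worst_p:
                    worst_p, worst_j = p, j
            if worst_j is not None and worst_p > p_remove:
                selected.remove(worst_j)
                trace.append(f"-{candidates[worst_j]} (LR p={worst_p:.3g})")
                changed = True

    # final refit on the original scale
    names = [candidates[j] for j in selected]
    fallback = False
    if names:
        X = sub[keep][names].to_numpy(float)
        params, probs, _, ok = _fit_logit(y, X)
        if not ok:
            params, probs, _ = _fit_ridge(y, X)
            fallback = True
            log.warning("separation detected; ridge-stabilized fit reported")
        coef = dict(zip(names, params[1:]))
        intercept = float(params[0])
    else:
        coef, probs = {}, np.full_like(y, y.mean(), dtype=float)
        pbar = float(np.clip(y.mean(), 1e-9, 1 - 1e-9))
        intercept = math.log(pbar / (1 - pbar))
    return StepwiseModel(selected=names, coef=coef, intercept=intercept,
                         probabilities=np.asarray(probs, float),
                         separation_fallback=fallback, trace=trace)


# ---------------------------------------------------------------------------
# ROC / AUC with DeLong interval
# ---------------------------------------------------------------------------

@dataclass
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    fpr: np.ndarray
    tpr: np.ndarray
    positive_class: str = POSITIVE_CLASS
    flipped: bool = False  # scores negated for orientation (AUC >= 0.5)


def _midranks(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def roc_auc(scores: np.ndarray, labels: Sequence[str],
            positive: str = POSITIVE_CLASS, alpha: float = 0.05,
            orient: bool = False) -> RocResult:
    """Concordance AUC (ties = 1/2) with a DeLong confidence interval.

    The AUC equals the probability that a random positive-class score
    exceeds a random negative-class score; the variance uses DeLong's
    per-subject structural components. ``orient=True`` negates the scores
    when the raw AUC is below 1/2, recording the flip (used for
    single-marker ROCs where either direction of difference is of
    interest).
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    pos = scores[labels == positive]
    neg = scores[labels != positive]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present for a ROC")

    flipped = False
    m, n = len(pos), len(neg)
    rank_all = _midranks(np.concatenate([pos, neg]))
    auc = (rank_all[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    if orient and auc < 0.5:
        flipped = True
        scores = -scores
        pos, neg = -pos, -neg
        rank_all = _midranks(np.concatenate([pos, neg]))
        auc = (rank_all[:m].sum() - m * (m + 1) / 2.0) / (m * n)

    # DeLong structural components
    v10 = (rank_all[:m] - _midranks(pos)) / n
    v01 = 1.0 - (rank_all[m:] - _midranks(neg)) / m
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    se = math.sqrt(s10 / m + s01 / n)
    z = sps.norm.ppf(1 - alpha / 2)
    lo, hi = max(0.0, auc - z * se), min(1.0, auc + z * se)

    from sklearn.metrics import roc_curve

    y = np.concatenate([np.ones(m, int), np.zeros(n, int)])
    fpr, tpr, _ = roc_curve(y, np.concatenate([pos, neg]))
    return RocResult(auc=float(auc), ci_low=float(min(lo, auc)),
                     ci_high=float(max(hi, auc)), fpr=fpr, tpr=tpr,
                     positive_class=positive, flipped=flipped)


# ---------------------------------------------------------------------------
# a priori sample size (two-sample t)
# ---------------------------------------------------------------------------

@dataclass
class PowerSpec:
    """A priori power-analysis inputs for a two-independent-means t test."""

    effect_size_d: float
    alpha: float = 0.05
    power: float = 0.8
    allocation_ratio: float = 1.0  # n2 / n1
    tails: int = 2

    def __post_init__(self):
        if self.effect_size_d <= 0:
            raise ValueError("effect size d must be > 0")
        if not (0 < self.alpha < 1 and 0 < self.power < 1):
            raise ValueError("alpha and power must lie in (0, 1)")
        if self.tails not in (1, 2):
            raise ValueError("tails must be 1 or 2")


def _t_power(n1: int, n2: int, d: float, alpha: float, tails: int) -> float:
    df = n1 + n2 - 2
    if df < 1:
        return 0.0
    nc = d * math.sqrt(n1 * n2 / (n1 + n2))
    if tails == 2:
        tc = sps.t.ppf(1 - alpha / 2, df)
        return float(sps.nct.sf(tc, df, nc) + sps.nct.cdf(-tc, df, nc))
    tc = sps.t.ppf(1 - alpha, df)
    return float(sps.nct.sf(tc, df, nc))


def sample_size_ttest(spec: PowerSpec, n_max: int = 100000
                      ) -> tuple[int, int, int]:
    """Smallest per-group n reaching the target power under the
    noncentral-t distribution of the two-sample t statistic.

    Returns ``(n1, n2, total)`` with ``n2 = ceil(ratio * n1)``.
    """
    for n1 in range(2, n_max + 1):
        n2 = max(2, math.ceil(spec.allocation_ratio * n1))
        if _t_power(n1, n2, spec.effect_size_d, spec.alpha,
                    spec.tails) >= spec.power:
            return n1, n2, n1 + n2
    raise ValueError("target power unreachable within n_max")


# ---------------------------------------------------------------------------
# end-to-end screening pipeline
# ---------------------------------------------------------------------------

class PipelineConfig:
    """Thresholds of the screening pipeline (defaults mirror the published
    protocol: raw p < 0.05, stepwise 0.05/0.10, DeLong intervals)."""

    def __init__(self, alpha: float = 0.05, normality_alpha: float = 0.05,
                 p_enter: float = 0.05, p_remove: float = 0.10,
                 ci_method: str = "delong"):
        if ci_method not in ("delong",):
            raise ValueError(f"unsupported ci_method {ci_method!r}")
        self.alpha = alpha
        self.normality_alpha = normality_alpha
        self.p_enter = p_enter
        self.p_remove = p_remove
        self.ci_method = ci_method


@dataclass
class ScreeningReport:
    demographics: list  # GroupComparison
    battery: list  # GroupComparison, one per biomarker
    significant: list  # marker names with p < alpha
    bh_qvalues: dict  # Benjamini-Hochberg q per marker (informational only)
    model: StepwiseModel
    marker_rocs: dict  # marker -> RocResult (auto-oriented)
    joint_roc: RocResult | None
    log: list

    def battery_table(self) -> pd.DataFrame:
        return pd.DataFrame([vars(c) for c in self.battery])

    def demographics_table(self) -> pd.DataFrame:
        return pd.DataFrame([vars(c) for c in self.demographics])


def _bh_adjust(pvals: np.ndarray) -> np.ndarray:
    from statsmodels.stats.multitest import multipletests

    return multipletests(pvals, method="fdr_bh")[1]


def run_screening_pipeline(cohort: pd.DataFrame,
                           config: PipelineConfig | None = None
                           ) -> ScreeningReport:
    """Demographics → differential battery → stepwise model → ROC bundle.

    Raises with the failing stage's name in the message; the battery uses
    all 21 biomarker columns present, and stepwise candidates are the
    markers significant at ``config.alpha`` (no multiplicity correction is
    applied for selection; BH q-values are reported for information only).
    """
    cfg = config or PipelineConfig()
    runlog: list[str] = []
    if len(cohort) < 2 or cohort["group"].nunique() < 2:
        raise ValueError("compare_groups: need at least two subjects and "
                         "both group levels")

    demo_cols = [c for c in ("age", "sex", "education", "mmse", "moca")
                 if c in cohort.columns]
    try:
        demographics = compare_groups(cohort, demo_cols, cfg.normality_alpha)
    except Exception as exc:
        raise RuntimeError(f"stage demographics (compare_groups): {exc}") from exc
    runlog.append(f"demographics compared: {demo_cols}")

    markers = [c for c in BIOMARKER_COLUMNS if c in cohort.columns]
    if not markers:
        raise ValueError("compare_groups: no biomarker columns in cohort")
    try:
        battery = compare_groups(cohort, markers, cfg.normality_alpha)
    except Exception as exc:
        raise RuntimeError(f"stage battery (compare_groups): {exc}") from exc
    significant = [c.marker for c in battery if c.p < cfg.alpha]
    runlog.append(f"{len(significant)}/{len(battery)} markers significant at "
                  f"p<{cfg.alpha}")
    bh = dict(zip([c.marker for c in battery],
                  _bh_adjust(np.array([c.p for c in battery]))))

    try:
        model = stepwise_logistic(cohort, significant, cfg.p_enter,
                                  cfg.p_remove)
    except Exception as exc:
        raise RuntimeError(f"stage selection (stepwise_logistic): {exc}") from exc
    runlog.append(f"stepwise retained {model.selected}")

    labels = cohort["group"].to_numpy()
    marker_rocs = {}
    for mk in model.selected:
        vals = pd.to_numeric(cohort[mk])
        ok = vals.notna().to_numpy()
        marker_rocs[mk] = roc_auc(vals[ok].to_numpy(float), labels[ok],
                                  orient=True)
    joint = None
    if model.selected:
        sub = cohort[model.selected].apply(pd.to_numeric)
        ok = (~sub.isna().any(axis=1)).to_numpy()
        joint = roc_auc(model.probabilities, labels[ok])
        runlog.append(f"joint model AUC {joint.auc:.3f} "
                      f"[{joint.ci_low:.3f}, {joint.ci_high:.3f}]")
    return ScreeningReport(demographics=demographics, battery=battery,
                           significant=significant, bh_qvalues=bh,
                           model=model, marker_rocs=marker_rocs,
                           joint_roc=joint, log=runlog)
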