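"""Multi-reader agreement and diagnostic-performance statistics.

Implements, from their definitions, the battery used to evaluate a paired
crossover reader study with binary (benign/malignant) calls against a
pathology reference:

* two-way random-effects intraclass correlation with absolute agreement,
  ICC(A,1) and ICC(A,k), with F-based confidence intervals
  (McGraw & Wong 1996);
* Fleiss' kappa for multi-rater categorical agreement, with the
  Fleiss-Nee-Landis large-sample standard error;
* McNemar's paired test on discordant pairs (asymptotic, continuity
  corrected, and exact-binomial variants);
* the Cochran-Armitage test for a trend in a binary outcome across ordered
  categories;
* single-operating-point diagnostic metrics (Se, Sp, PPV, NPV, accuracy)
  with exact Clopper-Pearson (or Wilson) intervals, Youden's J, and the
  Mann-Whitney AUC with DeLong variance — for binary calls the AUC reduces
  exactly to (Se + Sp)/2;
* DeLong's test for comparing paired AUCs.

All estimators are pure functions of their inputs; degenerate inputs return
flagged results rather than raising mid-analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

__all__ = [
    "RatingsTable",
    "TrendTable",
    "DiagnosticMetrics",
    "icc_absolute",
    "fleiss_kappa",
    "cohen_kappa",
    "mcnemar",
    "cochran_armitage",
    "diagnostic_metrics",
    "auc_delong",
    "delong_compare",
    "reader_study_report",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class RatingsTable:
    """Complete cases x raters binary ratings with pathology ground truth."""

    case_ids: list[str]
    truth: np.ndarray        # (n,) binary, 1 = malignant by pathology
    ratings: np.ndarray      # (n, k) binary calls
    session_label: str = ""

    def __post_init__(self) -> None:
        self.truth = np.asarray(self.truth, dtype=np.int8).ravel()
        self.ratings = np.atleast_2d(np.asarray(self.ratings, dtype=np.int8))
        n, k = self.ratings.shape
        if len(self.case_ids) != n or self.truth.shape[0] != n:
            raise ValidationError("case_ids, truth and ratings disagree on the case count")
        if not np.isin(self.truth, (0, 1)).all() or not np.isin(self.ratings, (0, 1)).all():
            raise ValidationError("truth and ratings must be binary (0/1)")

    @property
    def n_cases(self) -> int:
        return self.ratings.shape[0]

    @property
    def n_raters(self) -> int:
        return self.ratings.shape[1]

    def pooled_calls(self) -> tuple[np.ndarray, np.ndarray]:
        """Flatten to (calls, truth) treating each rater x case as one
        observation (column-major over raters, matching a per-rater stack)."""
        calls = self.ratings.T.ravel()
        truth = np.tile(self.truth, self.n_raters)
        return calls, truth

    def majority_calls(self) -> np.ndarray:
        """Per-case majority vote (ties broken toward malignant)."""
        return (self.ratings.mean(axis=1) >= 0.5).astype(np.int8)

    # -- CSV round trip ----------------------------------------------------
    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        df = pd.DataFrame({"case_id": self.case_ids, "truth": self.truth})
        for j in range(self.n_raters):
            df[f"rater_{j + 1}"] = self.ratings[:, j]
        df.to_csv(path, index=False)
        return path

    @classmethod
    def from_csv(cls, path: str | Path, session_label: str = "") -> "RatingsTable":
        df = pd.read_csv(path)
        rater_cols = [c for c in df.columns if c.startswith("rater_")]
        if not rater_cols:
            raise ValidationError(f"{path}: no rater_* columns found")
        return cls(
            case_ids=[str(c) for c in df["case_id"]],
            truth=df["truth"].to_numpy(),
            ratings=df[rater_cols].to_numpy(),
            session_label=session_label or Path(path).stem,
        )


@dataclass
class TrendTable:
    """2 x K contingency table: rows (benign, malignant) x ordinal grades."""

    counts: np.ndarray
    scores: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != 2:
            raise ValidationError("counts must be a 2 x K table")
        if np.any(self.counts < 0):
            raise ValidationError("counts must be non-negative")
        if self.counts.sum() < 2:
            raise ValidationError("need at least 2 observations")
        if self.scores is None:
            self.scores = np.arange(1, self.counts.shape[1] + 1, dtype=np.float64)
        else:
            self.scores = np.asarray(self.scores, dtype=np.float64)
            if self.scores.shape != (self.counts.shape[1],):
                raise ValidationError("scores length must match the number of columns")


@dataclass(frozen=True)
class Estimate:
    """A point estimate with a two-sided 95% interval."""

    value: float
    lo: float
    hi: float

    def __iter__(self):
        return iter((self.value, self.lo, self.hi))


@dataclass
class DiagnosticMetrics:
    sensitivity: Estimate
    specificity: Estimate
    ppv: Estimate
    npv: Estimate
    accuracy: Estimate
    auc: Estimate
    youden: float
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0


# ---------------------------------------------------------------------------
# ICC — two-way random effects, absolute agreement
# ---------------------------------------------------------------------------

@dataclass
class IccResult:
    icc: float
    ci95: tuple[float, float]
    p: float
    form: str
    msr: float = math.nan
    msc: float = math.nan
    mse: float = math.nan
    degenerate: bool = False


def _anova_mean_squares(x: np.ndarray) -> tuple[float, float, float]:
    """Row (cases), column (raters) and residual mean squares of a complete
    two-way layout with one observation per cell."""
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sse = np.sum((x - row_means[:, None] - col_means[None, :] + grand) ** 2)
    return ssr / (n - 1), ssc / (k - 1), sse / ((n - 1) * (k - 1))


def icc_absolute(ratings: np.ndarray, form: str = "single", alpha: float = 0.05) -> IccResult:
    """ICC for absolute agreement under the two-way random-effects model.

    ``form='single'`` gives ICC(A,1) — the reliability of one rater's score;
    ``form='average'`` gives ICC(A,k) for the mean of the k raters.  The
    confidence interval uses the F-distribution method of McGraw & Wong
    (1996); the p-value tests H0: ICC = 0 via F = MSR/MSE.
    """
    x = np.asarray(ratings, dtype=np.float64)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValidationError("ratings must be a complete n>=2 x k>=2 matrix")
    if form not in ("single", "average"):
        raise ValidationError("form must be 'single' or 'average'")
    n, k = x.shape
    msr, msc, mse = _anova_mean_squares(x)

    scale = max(np.var(x), 1.0)
    if msr <= 1e-12 * scale:  # no between-case variance: agreement undefined
        return IccResult(0.0, (0.0, 0.0), 1.0, form, msr, msc, mse, degenerate=True)

    icc1 = (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))

    # McGraw & Wong case-2 CI for ICC(A,1)
    fc = msc / mse if mse > 0 else np.inf
    a_ = (k * icc1) / (n * (1.0 - icc1)) if icc1 < 1 else np.inf
    b_ = 1.0 + (k * icc1 * (n - 1)) / (n * (1.0 - icc1)) if icc1 < 1 else np.inf
    if np.isfinite(a_) and mse > 0:
        v = (a_ * msc + b_ * mse) ** 2 / (
            (a_ * msc) ** 2 / (k - 1) + (b_ * mse) ** 2 / ((n - 1) * (k - 1))
        )
        f_u = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f_l = stats.f.ppf(1 - alpha / 2, v, n - 1)
        lo = n * (msr - f_u * mse) / (f_u * (k * msc + (k * n - k - n) * mse) + n * msr)
        hi = n * (f_l * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_l * msr)
    else:  # perfect agreement or zero residual
        lo = hi = icc1 if mse == 0 else 1.0

    if mse > 0:
        fstat = msr / mse
        p = float(stats.f.sf(fstat, n - 1, (n - 1) * (k - 1)))
    else:
        p = 0.0

    if form == "average":
        def to_avg(r: float) -> float:
            return k * r / (1.0 + (k - 1) * r) if np.isfinite(r) else r
        return IccResult(to_avg(icc1), (to_avg(lo), to_avg(hi)), p, form, msr, msc, mse)
    return IccResult(float(icc1), (float(lo), float(hi)), p, form, msr, msc, mse)


# ---------------------------------------------------------------------------
# Fleiss / Cohen kappa
# ---------------------------------------------------------------------------

@dataclass
class KappaResult:
    kappa: float
    se: float
    ci95: tuple[float, float]
    p: float
    degenerate: bool = False


def fleiss_kappa(ratings: np.ndarray) -> KappaResult:
    """Fleiss' kappa for n cases rated by k raters into categorical levels.

    Agreement per case P_i, overall mean agreement, and chance agreement
    P_e = sum_j p_j^2 follow the 1971 definition; the standard error is the
    Fleiss-Nee-Landis large-sample null SE, used for both the test and the
    normal-approximation interval.
    """
    x = np.asarray(ratings)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValidationError("ratings must be a complete n>=2 x k>=2 matrix")
    n, k = x.shape
    cats = np.unique(x)
    counts = np.stack([(x == c).sum(axis=1) for c in cats], axis=1).astype(np.float64)

    p_j = counts.sum(axis=0) / (n * k)
    p_e = float(np.sum(p_j**2))
    if 1.0 - p_e < 1e-12:  # a single category used: chance agreement is 1
        return KappaResult(math.nan, math.nan, (math.nan, math.nan), math.nan, degenerate=True)
    p_i = (np.sum(counts**2, axis=1) - k) / (k * (k - 1))
    p_bar = float(p_i.mean())
    kappa = (p_bar - p_e) / (1.0 - p_e)

    se = (
        math.sqrt(2.0 / (n * k * (k - 1)))
        * math.sqrt(max(p_e - (2 * k - 3) * p_e**2 + 2 * (k - 2) * float(np.sum(p_j**3)), 0.0))
        / (1.0 - p_e)
    )
    z = kappa / se if se > 0 else math.inf
    p = float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else 0.0
    half = 1.959963984540054 * se
    return KappaResult(float(kappa), se, (kappa - half, kappa + half), p)


def cohen_kappa(a: np.ndarray, b: np.ndarray) -> KappaResult:
    """Cohen's kappa between two raters' categorical calls."""
    a = np.asarray(a).ravel()
    b = np.asarray(b).ravel()
    if a.shape != b.shape or a.size < 2:
        raise ValidationError("need two equal-length call vectors with n >= 2")
    n = a.size
    cats = np.unique(np.concatenate([a, b]))
    po = float(np.mean(a == b))
    pa = np.array([np.mean(a == c) for c in cats])
    pb = np.array([np.mean(b == c) for c in cats])
    pe = float(np.sum(pa * pb))
    if 1.0 - pe < 1e-12:
        return KappaResult(math.nan, math.nan, (math.nan, math.nan), math.nan, degenerate=True)
    kappa = (po - pe) / (1.0 - pe)
    se0 = math.sqrt(pe / (n * (1.0 - pe)))  # null SE for the test
    se = math.sqrt(po * (1.0 - po) / n) / (1.0 - pe)
    z = kappa / se0 if se0 > 0 else math.inf
    half = 1.959963984540054 * se
    return KappaResult(kappa, se, (kappa - half, kappa + half), float(2 * stats.norm.sf(abs(z))))


# ---------------------------------------------------------------------------
# McNemar
# ---------------------------------------------------------------------------

@dataclass
class McNemarResult:
    statistic: float
    p: float
    b: int
    c: int
    method: str
    degenerate: bool = False


def mcnemar(
    first: np.ndarray,
    second: np.ndarray,
    method: str = "auto",
) -> McNemarResult:
    """McNemar's paired test on two binary outcome vectors over the same cases.

    ``b`` counts (first=1, second=0) pairs, ``c`` the reverse.  Methods:
    ``asymptotic`` (b-c)^2/(b+c) uncorrected, ``corrected`` (|b-c|-1)^2/(b+c),
    ``exact`` two-sided binomial on min(b, c) out of b+c, ``auto`` (default)
    exact when b + c < 25, otherwise asymptotic.
    """
    a1 = np.asarray(first).ravel().astype(int)
    a2 = np.asarray(second).ravel().astype(int)
    if a1.shape != a2.shape:
        raise ValidationError("paired outcome vectors must have equal length")
    b = int(np.sum((a1 == 1) & (a2 == 0)))
    c = int(np.sum((a1 == 0) & (a2 == 1)))
    nd = b + c
    if nd == 0:
        return McNemarResult(0.0, 1.0, b, c, "zero-discordance", degenerate=True)
    if method == "auto":
        method = "exact" if nd < 25 else "asymptotic"
    if method == "exact":
        p = float(min(1.0, 2.0 * stats.binom.cdf(min(b, c), nd, 0.5)))
        return McNemarResult(float(min(b, c)), p, b, c, "exact")
    if method == "corrected":
        statistic = (abs(b - c) - 1) ** 2 / nd if abs(b - c) > 1 else 0.0
    elif method == "asymptotic":
        statistic = (b - c) ** 2 / nd
    else:
        raise ValidationError(f"unknown McNemar method {method!r}")
    p = float(stats.chi2.sf(statistic, 1))
    return McNemarResult(float(statistic), p, b, c, method)


# ---------------------------------------------------------------------------
# Cochran-Armitage trend test
# ---------------------------------------------------------------------------

@dataclass
class TrendResult:
    z: float
    p: float
    t_stat: float
    variance: float
    degenerate: bool = False


def cochran_armitage(table: TrendTable) -> TrendResult:
    """Cochran-Armitage test for a linear trend in the proportion of the
    second row's outcome (malignant) across ordered grade columns.

    T = sum_k s_k (n_1k - n_k pbar), Var T = pbar (1-pbar)
    (sum n_k s_k^2 - (sum n_k s_k)^2 / N), z = T / sqrt(Var T).
    """
    counts = table.counts
    s = table.scores
    n_k = counts.sum(axis=0).astype(np.float64)
    n1k = counts[1].astype(np.float64)  # event row: malignant
    n_total = float(counts.sum())
    p_bar = float(counts[1].sum()) / n_total
    if p_bar in (0.0, 1.0):
        return TrendResult(math.nan, math.nan, 0.0, 0.0, degenerate=True)
    t_stat = float(np.sum(s * (n1k - n_k * p_bar)))
    var = p_bar * (1 - p_bar) * (float(np.sum(n_k * s**2)) - float(np.sum(n_k * s)) ** 2 / n_total)
    if var <= 0:
        return TrendResult(math.nan, math.nan, t_stat, var, degenerate=True)
    z = t_stat / math.sqrt(var)
    return TrendResult(float(z), float(2 * stats.norm.sf(abs(z))), t_stat, var)


# ---------------------------------------------------------------------------
# proportions, ROC, DeLong
# ---------------------------------------------------------------------------

def _proportion_ci(x: int, n: int, method: str = "clopper-pearson", alpha: float = 0.05) -> Estimate:
    if n == 0:
        return Estimate(math.nan, math.nan, math.nan)
    p = x / n
    if method == "clopper-pearson":
        lo = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2, x, n - x + 1))
        hi = 1.0 if x == n else float(stats.beta.ppf(1 - alpha / 2, x + 1, n - x))
    elif method == "wilson":
        z = stats.norm.ppf(1 - alpha / 2)
        den = 1 + z**2 / n
        center = (p + z**2 / (2 * n)) / den
        half = z * math.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / den
        lo, hi = center - half, center + half
    else:
        raise ValidationError(f"unknown CI method {method!r}")
    return Estimate(p, lo, hi)


def _placements(scores: np.ndarray, truth: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Mann-Whitney AUC (ties half-weighted) and DeLong placement values."""
    pos = scores[truth == 1]
    neg = scores[truth == 0]
    m, n = pos.size, neg.size
    combined = np.concatenate([pos, neg])
    rk_all = stats.rankdata(combined, method="average")
    rk_pos = stats.rankdata(pos, method="average")
    rk_neg = stats.rankdata(neg, method="average")
    v10 = (rk_all[:m] - rk_pos) / n          # per-positive placement
    v01 = 1.0 - (rk_all[m:] - rk_neg) / m    # per-negative placement
    auc = (rk_all[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    return float(auc), v10, v01


def auc_delong(scores: np.ndarray, truth: np.ndarray, alpha: float = 0.05) -> Estimate:
    """AUC with the DeLong large-sample confidence interval."""
    scores = np.asarray(scores, dtype=np.float64).ravel()
    truth = np.asarray(truth).ravel()
    if set(np.unique(truth)) - {0, 1} or len({0, 1} - set(np.unique(truth))):
        raise ValidationError("truth must contain both classes, coded 0/1")
    auc, v10, v01 = _placements(scores, truth)
    var = np.var(v10, ddof=1) / v10.size + np.var(v01, ddof=1) / v01.size
    half = stats.norm.ppf(1 - alpha / 2) * math.sqrt(max(var, 0.0))
    return Estimate(auc, max(0.0, auc - half), min(1.0, auc + half))


@dataclass
class DeLongResult:
    auc_a: float
    auc_b: float
    z: float
    p: float
    var_diff: float
    degenerate: bool = False


def delong_compare(scores_a: np.ndarray, scores_b: np.ndarray, truth: np.ndarray) -> DeLongResult:
    """DeLong's test for the difference of two paired AUCs.

    Both score vectors are evaluated on the same cases; the covariance of
    the AUC estimates is obtained from the placement values.
    """
    sa = np.asarray(scores_a, dtype=np.float64).ravel()
    sb = np.asarray(scores_b, dtype=np.float64).ravel()
    truth = np.asarray(truth).ravel()
    if sa.shape != sb.shape or sa.shape != truth.shape:
        raise ValidationError("scores_a, scores_b and truth must be paired (equal length)")
    if not (np.any(truth == 1) and np.any(truth == 0)):
        raise ValidationError("truth must contain both classes")
    auc_a, v10a, v01a = _placements(sa, truth)
    auc_b, v10b, v01b = _placements(sb, truth)
    m, n = v10a.size, v01a.size

    def cov(u: np.ndarray, v: np.ndarray) -> float:
        return float(np.sum((u - u.mean()) * (v - v.mean())) / (u.size - 1))

    var_diff = (
        (cov(v10a, v10a) + cov(v10b, v10b) - 2 * cov(v10a, v10b)) / m
        + (cov(v01a, v01a) + cov(v01b, v01b) - 2 * cov(v01a, v01b)) / n
    )
    if var_diff <= 0:
        return DeLongResult(auc_a, auc_b, 0.0, 1.0, var_diff, degenerate=True)
    z = (auc_a - auc_b) / math.sqrt(var_diff)
    return DeLongResult(auc_a, auc_b, float(z), float(2 * stats.norm.sf(abs(z))), var_diff)


def diagnostic_metrics(
    calls: np.ndarray,
    truth: np.ndarray,
    ci_method: str = "clopper-pearson",
) -> DiagnosticMetrics:
    """Operating-point metrics of binary calls against binary truth.

    For binary calls the Mann-Whitney AUC with half-weighted ties equals
    (Se + Sp)/2 exactly; its interval is the DeLong CI of that AUC.
    """
    calls = np.asarray(calls).ravel().astype(int)
    truth = np.asarray(truth).ravel().astype(int)
    if calls.shape != truth.shape:
        raise ValidationError("calls and truth must have equal length")
    if not (np.any(truth == 1) and np.any(truth == 0)):
        raise ValidationError("truth must contain both benign and malignant cases")
    tp = int(np.sum((calls == 1) & (truth == 1)))
    fp = int(np.sum((calls == 1) & (truth == 0)))
    fn = int(np.sum((calls == 0) & (truth == 1)))
    tn = int(np.sum((calls == 0) & (truth == 0)))
    se = _proportion_ci(tp, tp + fn, ci_method)
    sp = _proportion_ci(tn, tn + fp, ci_method)
    ppv = _proportion_ci(tp, tp + fp, ci_method)
    npv = _proportion_ci(tn, tn + fn, ci_method)
    acc = _proportion_ci(tp + tn, len(calls), ci_method)
    auc = auc_delong(calls.astype(float), truth)
    return DiagnosticMetrics(
        sensitivity=se, specificity=sp, ppv=ppv, npv=npv, accuracy=acc,
        auc=auc, youden=se.value + sp.value - 1.0, tp=tp, fp=fp, fn=fn, tn=tn,
    )


# ---------------------------------------------------------------------------
# reader-study report
# ---------------------------------------------------------------------------

def _metrics_dict(m: DiagnosticMetrics) -> dict:
    def e(x: Estimate) -> dict:
        return {"value": x.value, "ci95": [x.lo, x.hi]}

    return {
        "auc": e(m.auc),
        "sensitivity": e(m.sensitivity),
        "specificity": e(m.specificity),
        "ppv": e(m.ppv),
        "npv": e(m.npv),
        "accuracy": e(m.accuracy),
        "youden": m.youden,
        "confusion": {"tp": m.tp, "fp": m.fp, "fn": m.fn, "tn": m.tn},
    }


def reader_study_report(
    sessions: dict[str, dict[str, RatingsTable]],
    icc_form: str = "single",
    ci_method: str = "clopper-pearson",
) -> dict:
    """Full statistical report over reader groups and sessions.

    ``sessions`` maps group name -> {session name -> RatingsTable}; sessions
    of one group must share case ids and truth.  For every group x session
    the report carries pooled and per-rater-averaged diagnostic metrics plus
    the intra-group ICC; for session pairs within a group it adds Fleiss'
    kappa over the pooled panel, Cohen's kappa between majority calls, and
    McNemar's test on per-observation correctness; cross-group kappas at the
    same session complete the picture.  No multiplicity adjustment is
    applied.
    """
    report: dict = {"groups": {}, "comparisons": [], "meta": {
        "icc_form": icc_form, "ci_method": ci_method, "multiple_testing": "none",
    }}

    for group, tabs in sessions.items():
        ids0 = None
        for name, tab in tabs.items():
            if ids0 is None:
                ids0 = tab.case_ids
            elif tab.case_ids != ids0:
                bad = sorted(set(tab.case_ids) ^ set(ids0))
                raise ValidationError(
                    f"case-id mismatch between sessions of group {group!r}: {bad[:10]}"
                )
        gdict: dict = {}
        for name, tab in tabs.items():
            calls, truth = tab.pooled_calls()
            pooled = diagnostic_metrics(calls, truth, ci_method)
            per_rater = [
                diagnostic_metrics(tab.ratings[:, j], tab.truth, ci_method)
                for j in range(tab.n_raters)
            ]
            icc = icc_absolute(tab.ratings, form=icc_form)
            kap = fleiss_kappa(tab.ratings)
            gdict[name] = {
                "pooled": _metrics_dict(pooled),
                "per_rater_mean": {
                    "auc": float(np.mean([m.auc.value for m in per_rater])),
                    "sensitivity": float(np.mean([m.sensitivity.value for m in per_rater])),
                    "specificity": float(np.mean([m.specificity.value for m in per_rater])),
                },
                "icc": {"value": icc.icc, "ci95": list(icc.ci95), "p": icc.p,
                        "form": icc.form, "degenerate": icc.degenerate},
                "fleiss_kappa": {"value": kap.kappa, "se": kap.se, "p": kap.p,
                                 "degenerate": kap.degenerate},
            }
        report["groups"][group] = gdict

        names = list(tabs)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                ta, tb = tabs[names[i]], tabs[names[j]]
                panel = np.hstack([ta.ratings, tb.ratings])
                ka = fleiss_kappa(panel)
                km = cohen_kappa(ta.majority_calls(), tb.majority_calls())
                ca, tr = ta.pooled_calls()
                cb, _ = tb.pooled_calls()
                mc = mcnemar((ca == tr).astype(int), (cb == tr).astype(int))
                report["comparisons"].append({
                    "kind": "within-group",
                    "group": group,
                    "sessions": [names[i], names[j]],
                    "pooled_panel_fleiss_kappa": {"value": ka.kappa, "p": ka.p},
                    "majority_cohen_kappa": {"value": km.kappa, "p": km.p},
                    "mcnemar_correctness": {"statistic": mc.statistic, "p": mc.p,
                                            "b": mc.b, "c": mc.c, "method": mc.method},
                })

    groups = list(sessions)
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            ga, gb = sessions[groups[i]], sessions[groups[j]]
            for name in set(ga) & set(gb):
                panel = np.hstack([ga[name].ratings, gb[name].ratings])
                ka = fleiss_kappa(panel)
                km = cohen_kappa(ga[name].majority_calls(), gb[name].majority_calls())
                report["comparisons"].append({
                    "kind": "between-group",
                    "groups": [groups[i], groups[j]],
                    "session": name,
                    "pooled_panel_fleiss_kappa": {"value": ka.kappa, "p": ka.p},
                    "majority_cohen_kappa": {"value": km.kappa, "p": km.p},
                })
    return report
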