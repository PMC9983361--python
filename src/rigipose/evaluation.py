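"""Ordinal-agreement metrics, interpretation bands and cohort handling.

Model quality on a 0-3 ordinal clinical scale is summarised by three
statistics: absolute accuracy (ACC±0, exact agreement), acceptable accuracy
(ACC±1, within one point), and the weighted Cohen kappa, whose weights
penalise disagreements by their distance on the scale (linear weights by
default, the standard choice for ordinal clinical scores; quadratic
selectable). Spearman's rho quantifies monotone association between
predicted and true scores. Kappa and rho carry conventional interpretation
labels (Slight/Fair/Moderate/Substantial/Almost Perfect for kappa,
Negligible/Weak/Moderate/Strong/Very Strong for rho). Kappa uncertainty
is a percentile bootstrap over subjects.

Cohorts are split into train and test sets by stratified sampling on the
combined rigidity + postural-stability total score, and the two groups are
balance-tested: chi-square with continuity correction for sex, Welch t-test
for normally distributed numerics, Wilcoxon rank-sum otherwise (normality
screened by Shapiro-Wilk on the pooled values at alpha = 0.05).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import cohen_kappa_score

from .errors import RigiposeError, SchemaError

__all__ = [
    "acc_within",
    "weighted_kappa_ci",
    "spearman_with_p",
    "interpret_level",
    "EvaluationReport",
    "evaluate_predictions",
    "SplitResult",
    "stratified_split",
    "cohort_balance_tests",
    "describe_cohort",
]

CLASSES = (0, 1, 2, 3)


def _as_scores(a, name: str) -> np.ndarray:
    arr = np.asarray(a)
    if arr.ndim != 1:
        raise SchemaError(f"{name} must be 1-D")
    return arr.astype(int)


def acc_within(true, pred, tol: int = 0) -> float:
    """Fraction of subjects with |pred - true| <= tol (tol = 0 or 1).

    ACC±0 is exact agreement; ACC±1 counts predictions within one scale
    point (a one-point slip on a 0-3 ordinal scale is clinically
    acceptable).
    """
    t = _as_scores(true, "true")
    p = _as_scores(pred, "pred")
    if t.size == 0:
        raise SchemaError("empty score vectors")
    if t.size != p.size:
        raise SchemaError("true and pred must have equal length")
    if tol not in (0, 1):
        raise SchemaError("tol must be 0 or 1")
    return float(np.mean(np.abs(t - p) <= tol))


def weighted_kappa_ci(
    true,
    pred,
    weights: str = "linear",
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[float, tuple[float, float]]:
    """Weighted Cohen kappa with a percentile-bootstrap confidence interval.

    The kappa is computed from the 4x4 contingency table over the fixed
    class set {0,1,2,3}; resampling is over subjects. Bootstrap replicates
    whose truth collapses to a single class (kappa undefined) are dropped.
    """
    t = _as_scores(true, "true")
    p = _as_scores(pred, "pred")
    if t.size != p.size:
        raise SchemaError("true and pred must have equal length")
    if t.size < 2:
        raise SchemaError("kappa needs at least 2 subjects")
    if weights not in ("linear", "quadratic"):
        raise SchemaError("weights must be 'linear' or 'quadratic'")
    union = set(t) | set(p)
    if len(union) < 2:
        raise SchemaError("kappa needs at least 2 distinct classes overall")

    def _kappa(ti, pi) -> float:
        return float(
            cohen_kappa_score(ti, pi, labels=list(CLASSES), weights=weights)
        )

    point = _kappa(t, p)
    rng = np.random.default_rng(seed)
    n = t.size
    reps = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        tb, pb = t[idx], p[idx]
        if len(set(tb) | set(pb)) < 2:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            k = _kappa(tb, pb)
        if np.isfinite(k):
            reps.append(k)
    if len(reps) < max(10, n_boot // 10):
        raise RigiposeError("bootstrap produced too few valid replicates")
    lo, hi = np.percentile(reps, [2.5, 97.5])
    lo = min(float(lo), point)
    hi = max(float(hi), point)
    return point, (lo, hi)


def spearman_with_p(true, pred) -> tuple[float, float]:
    """Spearman rank correlation (average ranks on ties) with two-sided p."""
    t = np.asarray(true, dtype=float)
    p = np.asarray(pred, dtype=float)
    if t.size != p.size or t.size < 3:
        raise SchemaError("spearman needs equal-length vectors, n >= 3")
    if np.ptp(t) == 0 or np.ptp(p) == 0:
        raise RigiposeError("undefined correlation: a score vector is constant")
    res = sps.spearmanr(t, p)
    return float(res.statistic), float(res.pvalue)


# Upper-inclusive band edges (a kappa of exactly 0.60 is still "Moderate").
_KAPPA_BANDS = (
    (0.20, "Slight"),
    (0.40, "Fair"),
    (0.60, "Moderate"),
    (0.80, "Substantial"),
    (1.00, "Almost Perfect"),
)
_RHO_BANDS = (
    (0.10, "Negligible"),
    (0.39, "Weak"),
    (0.69, "Moderate"),
    (0.89, "Strong"),
    (1.00, "Very Strong"),
)


def interpret_level(metric: str, value: float) -> str:
    """Conventional interpretation label for a kappa or rho value.

    Band upper bounds are inclusive; rho uses the magnitude, kappa below
    zero is "Poor".
    """
    if not -1.0 - 1e-12 <= value <= 1.0 + 1e-12:
        raise SchemaError(f"{metric} value {value} outside [-1, 1]")
    if metric == "kappa":
        if value < 0.0:
            return "Poor"
        for upper, name in _KAPPA_BANDS:
            if value <= upper:
                return name
        return _KAPPA_BANDS[-1][1]
    if metric == "rho":
        v = abs(value)
        for upper, name in _RHO_BANDS:
            if v <= upper:
                return name
        return _RHO_BANDS[-1][1]
    raise SchemaError(f"unknown metric {metric!r}")


@dataclass
class EvaluationReport:
    """Agreement summary of one target item's predictions."""

    target: str
    n: int
    acc0: float
    acc1: float
    kappa: float
    kappa_ci: tuple[float, float]
    kappa_weights: str
    rho: float
    rho_p: float
    kappa_level: str = ""
    rho_level: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.acc0 <= self.acc1 <= 1.0:
            raise SchemaError("need 0 <= ACC±0 <= ACC±1 <= 1")
        lo, hi = self.kappa_ci
        if not lo - 1e-9 <= self.kappa <= hi + 1e-9:
            raise SchemaError("kappa must lie inside its CI")
        if not self.kappa_level:
            self.kappa_level = interpret_level("kappa", self.kappa)
        if not self.rho_level:
            self.rho_level = interpret_level("rho", self.rho)

    def to_row(self) -> dict:
        lo, hi = self.kappa_ci
        return {
            "target": self.target,
            "n": self.n,
            "rho": round(self.rho, 4),
            "rho_p": round(self.rho_p, 4),
            "rho_level": self.rho_level,
            "kappa": round(self.kappa, 4),
            "kappa_ci_low": round(lo, 4),
            "kappa_ci_high": round(hi, 4),
            "kappa_level": self.kappa_level,
            "kappa_weights": self.kappa_weights,
            "acc0": round(self.acc0, 4),
            "acc1": round(self.acc1, 4),
        }

    def to_text(self) -> str:
        lo, hi = self.kappa_ci
        return (
            f"{self.target} (n={self.n})\n"
            f"  rho            {self.rho:.2f} ({self.rho_level}), p = {self.rho_p:.4g}\n"
            f"  weighted kappa {self.kappa:.2f} ({lo:.2f}-{hi:.2f}) "
            f"[{self.kappa_level}; {self.kappa_weights} weights]\n"
            f"  ACC±0          {self.acc0:.2f}\n"
            f"  ACC±1          {self.acc1:.2f}"
        )


def evaluate_predictions(
    true,
    pred,
    target: str = "",
    kappa_weights: str = "linear",
    n_boot: int = 2000,
    seed: int = 0,
) -> EvaluationReport:
    """Full agreement suite for one prediction vector."""
    t = _as_scores(true, "true")
    kappa, ci = weighted_kappa_ci(t, pred, kappa_weights, n_boot=n_boot, seed=seed)
    rho, rho_p = spearman_with_p(t, pred)
    return EvaluationReport(
        target=target,
        n=int(t.size),
        acc0=acc_within(t, pred, 0),
        acc1=acc_within(t, pred, 1),
        kappa=kappa,
        kappa_ci=ci,
        kappa_weights=kappa_weights,
        rho=rho,
        rho_p=rho_p,
    )


@dataclass
class SplitResult:
    """A stratified train/test split plus its balance-test table."""

    train_ids: list[str]
    test_ids: list[str]
    strata: pd.Series
    balance: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise SchemaError("train and test sets overlap")


def stratified_split(
    totals: pd.Series,
    test_fraction: float,
    seed: int = 0,
    min_stratum: int = 2,
) -> SplitResult:
    """Stratified train/test split on a per-subject total-score series.

    Strata are the distinct total-score values, merged upward (toward the
    next higher score) until each stratum holds at least ``min_stratum``
    subjects. Test subjects are drawn without replacement within strata;
    largest-remainder allocation makes the overall test count equal
    ``round(test_fraction * n)`` exactly.
    """
    totals = pd.Series(totals)
    n = len(totals)
    if n < 10:
        raise SchemaError("need at least 10 subjects to split")
    if not 0 < test_fraction < 1:
        raise SchemaError("test_fraction must lie in (0, 1)")

    # Build strata: merge sparse score values upward.
    values = sorted(totals.unique())
    counts = totals.value_counts()
    stratum_of: dict[float, float] = {}
    bucket: list[float] = []
    bucket_n = 0
    for v in values:
        bucket.append(v)
        bucket_n += int(counts[v])
        if bucket_n >= min_stratum:
            for b in bucket:
                stratum_of[b] = bucket[-1]
            bucket, bucket_n = [], 0
    if bucket:  # leftover tail: merge into the previous stratum
        prev = max(stratum_of.values()) if stratum_of else bucket[-1]
        if not stratum_of:
            warnings.warn("single under-filled stratum; all subjects pooled")
        for b in bucket:
            stratum_of[b] = prev
    strata = totals.map(stratum_of)

    n_test_target = int(round(test_fraction * n))
    groups = {k: list(idx) for k, idx in strata.groupby(strata).groups.items()}
    # Largest-remainder allocation of the test quota across strata.
    quotas = {k: test_fraction * len(v) for k, v in groups.items()}
    alloc = {k: int(np.floor(q)) for k, q in quotas.items()}
    remainder = n_test_target - sum(alloc.values())
    order = sorted(groups, key=lambda k: (-(quotas[k] - alloc[k]), k))
    for k in order[:max(0, remainder)]:
        alloc[k] += 1
    for k in groups:  # never empty a stratum of size 1 into test
        if len(groups[k]) == 1 and alloc[k] > 0:
            warnings.warn(f"stratum {k} has a single subject; kept in train")
            alloc[k] = 0

    rng = np.random.default_rng(seed)
    test_ids: list[str] = []
    for k in sorted(groups):
        members = sorted(groups[k])
        take = min(alloc[k], len(members) - 1) if len(members) > 1 else 0
        if take > 0:
            test_ids.extend(rng.choice(members, size=take, replace=False))
    test_set = set(test_ids)
    train_ids = [s for s in totals.index if s not in test_set]
    test_ids = [s for s in totals.index if s in test_set]
    return SplitResult(train_ids=train_ids, test_ids=test_ids, strata=strata)


def _fmt_mean_sd(x: pd.Series) -> str:
    return f"{x.mean():.2f} ± {x.std(ddof=1):.2f}"


def _fmt_median_iqr(x: pd.Series) -> str:
    q25, q50, q75 = x.quantile([0.25, 0.5, 0.75])
    return f"{q50:g}[{q25:g},{q75:g}]"


def cohort_balance_tests(
    train: pd.DataFrame,
    test: pd.DataFrame,
    sex_column: str = "sex",
    female_value="F",
    alpha_normality: float = 0.05,
) -> pd.DataFrame:
    """Train/test balance table in clinical-report conventions.

    Sex: counts with percentage, 2x2 chi-square with continuity correction.
    Numeric variables: Shapiro-Wilk on the pooled values decides between a
    Welch t-test (reported as mean ± SD) and a Wilcoxon rank-sum test
    (reported as median[IQR]). Constant variables are flagged and skipped.
    """
    if train.empty or test.empty:
        raise SchemaError("both groups must be non-empty")
    rows = []
    if sex_column in train.columns:
        a_f = int((train[sex_column] == female_value).sum())
        b_f = int((test[sex_column] == female_value).sum())
        table = np.array(
            [[a_f, len(train) - a_f], [b_f, len(test) - b_f]], dtype=float
        )
        if table[:, 0].sum() in (0, table.sum()) or 0 in table.sum(axis=1):
            rows.append(("sex (female)", "-", "-", np.nan, "chi2", "constant"))
        else:
            chi2, p, _, _ = sps.chi2_contingency(table, correction=True)
            rows.append(
                (
                    "sex (female)",
                    f"{a_f}({a_f / len(train):.1%})",
                    f"{b_f}({b_f / len(test):.1%})",
                    float(p),
                    "chi2",
                    "",
                )
            )
    numeric = [
        c
        for c in train.columns
        if c != sex_column and pd.api.types.is_numeric_dtype(train[c])
    ]
    for c in numeric:
        a = train[c].dropna().astype(float)
        b = test[c].dropna().astype(float)
        pooled = pd.concat([a, b])
        if pooled.nunique() <= 1:
            rows.append((c, "-", "-", np.nan, "skipped", "constant"))
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            normal = sps.shapiro(pooled.to_numpy()).pvalue > alpha_normality
        if normal:
            p = float(sps.ttest_ind(a, b, equal_var=False).pvalue)
            stat_name = "t"
        else:
            p = float(sps.ranksums(a, b).pvalue)
            stat_name = "ranksum"
        desc_a = _fmt_mean_sd(a) if normal else _fmt_median_iqr(a)
        desc_b = _fmt_mean_sd(b) if normal else _fmt_median_iqr(b)
        rows.append((c, desc_a, desc_b, p, stat_name, ""))
    return pd.DataFrame(
        rows, columns=["variable", "train", "test", "p", "test_used", "flag"]
    )


def describe_cohort(demographics: pd.DataFrame, sex_column: str = "sex",
                    female_value="F") -> dict[str, str]:
    """Cohort summary strings (count(percent), mean ± SD) per variable."""
    out = {}
    if sex_column in demographics.columns:
        n_f = int((demographics[sex_column] == female_value).sum())
        out["sex_female"] = f"{n_f}({100 * n_f / len(demographics):.1f}%)"
    for c in demographics.columns:
        if c != sex_column and pd.api.types.is_numeric_dtype(demographics[c]):
            out[c] = _fmt_mean_sd(demographics[c].astype(float))
    return out
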