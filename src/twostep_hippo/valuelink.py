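"""Linking hippocampal band power to model-based valuations.

Two routes: (1) session-wise univariate OLS of mean normalized band power
(0.5 s pre-peck) on the session-mean model-based value of the matching
option/state, with the regression F test; (2) trial-wise decoding of the
step-1 choice from electrode x band power features with a linear
maximum-margin classifier over repeated stratified 70/30 splits.
A small gatekeeper routes follow-up comparisons to a paired/two-sample t
test or a Wilcoxon test depending on a Lilliefors normality check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from statsmodels.stats.diagnostic import lilliefors

__all__ = [
    "RegressionResult",
    "DecodeResult",
    "StatReport",
    "session_value_regression",
    "decode_choice",
    "stat_tests",
]


@dataclass
class RegressionResult:
    """OLS fit of session-mean power on session-mean value."""

    beta0: float
    beta1: float
    r_squared: float
    f_statistic: float
    p_value: float
    n_sessions: int
    condition: str
    band_group: str


@dataclass
class DecodeResult:
    """Choice-decoding accuracies over repeated stratified splits."""

    accuracies: np.ndarray
    mean: float
    sd: float
    band_group: str
    n_trials: int
    config: dict


@dataclass
class StatReport:
    test: str  # 'paired_t' | 't' | 'wilcoxon_signed' | 'ranksum'
    statistic: float
    p_value: float
    df: float | None
    normal: bool  # Lilliefors gate outcome


def session_value_regression(
    power_by_session: np.ndarray,
    value_by_session: np.ndarray,
    condition: str = "",
    band_group: str = "high",
) -> RegressionResult:
    """OLS of session-mean normalized power on session-mean Q value.

    Reports R^2 and the regression F statistic on (1, n-2) degrees of
    freedom with its p value.  Sessions with a missing value in either
    series are dropped pairwise.
    """
    y = np.asarray(power_by_session, float)
    x = np.asarray(value_by_session, float)
    if y.shape != x.shape:
        raise ValueError("power and value series must have equal length")
    keep = np.isfinite(y) & np.isfinite(x)
    y, x = y[keep], x[keep]
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 sessions with both quantities")
    if np.std(x) < 1e-12:
        raise ValueError("value series is degenerate (zero variance)")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionResult(
        beta0=float(model.params[0]),
        beta1=float(model.params[1]),
        r_squared=float(model.rsquared),
        f_statistic=float(model.fvalue),
        p_value=float(model.f_pvalue),
        n_sessions=n,
        condition=condition,
        band_group=band_group,
    )


def decode_choice(
    features: np.ndarray,
    labels: np.ndarray,
    band_group: str = "high",
    n_repeats: int = 10,
    test_size: float = 0.3,
    C: float = 1.0,
    rng: np.random.Generator | None = None,
) -> DecodeResult:
    """Decode the step-1 choice from per-trial power features.

    Linear-kernel SVM on standardized features; repeated stratified 70/30
    splits (``n_repeats`` rounds, extended until every trial has appeared
    in at least one test set).  Standardization is fit on the training
    split only.  Accuracy is balanced (mean per-class recall) and the SVM
    is class-weighted, so chance stays at 0.5 even when the choice mix
    drifts over learning.
    """
    x = np.asarray(features, float)
    y = np.asarray(labels)
    if x.ndim != 2 or len(x) != len(y):
        raise ValueError("features must be (trials, K) aligned with labels")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("decoding requires two classes")
    if counts.min() < 2:
        raise ValueError("each class needs at least 2 trials")
    rng = rng if rng is not None else np.random.default_rng(0)
    col_ok = np.isfinite(x).all(axis=0)
    x = np.where(np.isfinite(x), x, 0.0) if col_ok.all() else x[:, col_ok]
    x = np.nan_to_num(x)

    n = len(y)
    tested = np.zeros(n, dtype=bool)
    accuracies: list[float] = []
    max_rounds = n_repeats + 20 * int(np.ceil(1 / test_size))
    rounds = 0
    while rounds < n_repeats or (not tested.all() and rounds < max_rounds):
        train_idx, test_idx = _stratified_split(y, test_size, rng)
        scaler = StandardScaler().fit(x[train_idx])
        clf = SVC(
            kernel="linear", C=C, class_weight="balanced", random_state=int(rng.integers(2**31))
        )
        clf.fit(scaler.transform(x[train_idx]), y[train_idx])
        pred = clf.predict(scaler.transform(x[test_idx]))
        truth = y[test_idx]
        acc = float(np.mean([np.mean(pred[truth == c] == c) for c in np.unique(truth)]))
        accuracies.append(acc)
        tested[test_idx] = True
        rounds += 1
    accs = np.array(accuracies)
    return DecodeResult(
        accuracies=accs,
        mean=float(accs.mean()),
        sd=float(accs.std(ddof=1)) if len(accs) > 1 else 0.0,
        band_group=band_group,
        n_trials=n,
        config={"kernel": "linear", "C": C, "test_size": test_size, "n_rounds": len(accs)},
    )


def _stratified_split(y: np.ndarray, test_size: float, rng) -> tuple[np.ndarray, np.ndarray]:
    train, test = [], []
    for cls in np.unique(y):
        idx = np.nonzero(y == cls)[0]
        idx = rng.permutation(idx)
        n_test = max(1, int(round(test_size * len(idx))))
        test.extend(idx[:n_test])
        train.extend(idx[n_test:])
    return np.array(train), np.array(test)


def stat_tests(x: np.ndarray, y: np.ndarray, paired: bool = False, alpha: float = 0.05) -> StatReport:
    """Compare two samples, gated on a Lilliefors normality check.

    Normal data get a (paired) t test; otherwise a Wilcoxon signed-rank
    (paired) or rank-sum (independent) test is used.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if paired and x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    if min(len(x), len(y)) < 3:
        raise ValueError("sample sizes must be at least 3")

    def _normal(v: np.ndarray) -> bool:
        if np.std(v) < 1e-12:
            return True  # constant data: the parametric branch handles it
        return lilliefors(v, dist="norm")[1] > alpha

    if paired:
        d = x - y
        normal = _normal(d)
        if normal:
            if np.std(d) < 1e-12 and abs(d.mean()) < 1e-12:
                return StatReport("paired_t", 0.0, 1.0, float(len(d) - 1), True)
            t, p = stats.ttest_rel(x, y)
            return StatReport("paired_t", float(t), float(p), float(len(d) - 1), True)
        res = stats.wilcoxon(x, y, zero_method="wilcox")
        return StatReport("wilcoxon_signed", float(res.statistic), float(res.pvalue), None, False)
    normal = _normal(x) and _normal(y)
    if normal:
        t, p = stats.ttest_ind(x, y)
        return StatReport("t", float(t), float(p), float(len(x) + len(y) - 2), True)
    res = stats.ranksums(x, y)
    return StatReport("ranksum", float(res.statistic), float(res.pvalue), None, False)
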