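"""Univariate biomarker screening of image features against class status.

The screening chain mirrors a common radiomics workflow:

1. a pooled-variance two-sample Student t-test gates features at p < alpha
   (strict inequality, df = n1 + n2 - 2);
2. retained features are profiled with Spearman rank correlation against the
   binary label, -log10(p) ranking, and a k-nearest-neighbour mutual
   information estimate (k = 3, nats);
3. each feature is z-scored and fitted with an unregularized univariate
   logistic model; discrimination is summarized by the trapezoidal ROC AUC
   computed on the feature's ascending orientation WITHOUT sign-flipping
   (an anti-predictive feature therefore reports AUC < 0.5, unlike most
   library defaults), with a stratified-bootstrap percentile confidence
   interval (2,000 resamples preserving class proportions).

No multiple-testing correction is applied by default (a Benjamini-Hochberg
option exists but is off), matching the screening design this package
reproduces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

NEGLOG10_CAP = 300.0


def _check_two_groups(a: np.ndarray, b: np.ndarray) -> None:
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("values must be finite")


def two_sample_ttest(group_a, group_b) -> tuple[float, float, int]:
    """Pooled-variance (Student) two-sample t-test.

    Returns (t, two-sided p, df) with df = n1 + n2 - 2.  Zero pooled
    variance yields t = 0, p = 1 for equal means and +/-inf, p = 0
    otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    _check_two_groups(a, b)
    df = len(a) + len(b) - 2
    sp2 = (((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / df)
    if sp2 == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0, df
        return float(np.inf * np.sign(a.mean() - b.mean())), 0.0, df
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / len(a) + 1 / len(b)))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(p), df


def spearman_vs_label(values, labels) -> tuple[float, float]:
    """Spearman rank correlation (midrank ties) against a binary label.

    Constant values return rho = 0 with p = 1 (degenerate)."""
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels)
    if len(v) < 4:
        raise ValueError("need at least 4 observations")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    if np.all(v == v[0]):
        return 0.0, 1.0
    rho, p = stats.spearmanr(v, y)
    return float(rho), float(p)


def mutual_information_score(values, labels, n_neighbors: int = 3,
                             seed: int = 0) -> float:
    """k-NN mutual information (nats) between a continuous feature and the
    binary label; negative estimates are clipped to zero."""
    from sklearn.feature_selection import mutual_info_classif
    v = np.asarray(values, dtype=float).reshape(-1, 1)
    y = np.asarray(labels)
    if len(v) < 10:
        raise ValueError("need at least 10 observations")
    if np.all(v == v[0]):
        return 0.0
    mi = mutual_info_classif(v, y, n_neighbors=n_neighbors,
                             random_state=seed)[0]
    return float(max(mi, 0.0))


def neglog10(p: float) -> float:
    """-log10(p) ranking score; p = 0 is capped at 300."""
    if p < 0 or p > 1:
        raise ValueError("p must lie in [0, 1]")
    if p == 0:
        return NEGLOG10_CAP
    return min(float(-np.log10(p)), NEGLOG10_CAP)


def zscore(values) -> np.ndarray:
    """Standardize to mean 0, sd 1 (population sd); constant input returns
    zeros (degenerate)."""
    v = np.asarray(values, dtype=float)
    sd = v.std()
    if sd == 0:
        return np.zeros_like(v)
    return (v - v.mean()) / sd


def rank_auc(values, labels) -> float:
    """Tie-corrected Mann-Whitney AUC of the feature's ascending orientation:
    P(X_pos > X_neg) + 0.5 P(X_pos = X_neg).  Equals the trapezoidal ROC
    area with half-credit for ties; never sign-flipped."""
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels).astype(bool)
    n1, n0 = int(y.sum()), int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    r = stats.rankdata(v)
    u = r[y].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


@dataclass
class AUCResult:
    auc_point: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int
    coef: float = np.nan
    intercept: float = np.nan
    fit_flag: str = ""
    skipped_replicates: int = 0


def stratified_bootstrap_ci(values, labels, statistic, n_boot: int = 2000,
                            seed: int = 0,
                            percentiles=(2.5, 97.5)) -> tuple[float, float, int]:
    """Percentile bootstrap CI with resampling within each class at the
    original class sizes.  Replicates where ``statistic`` returns NaN are
    skipped and counted; returns (lo, hi, n_skipped)."""
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels).astype(bool)
    idx1, idx0 = np.nonzero(y)[0], np.nonzero(~y)[0]
    if len(idx1) < 3 or len(idx0) < 3:
        raise ValueError("each class needs at least 3 members")
    rng = np.random.default_rng(seed)
    out = np.empty(n_boot)
    skipped = 0
    for b in range(n_boot):
        take = np.concatenate([rng.choice(idx1, len(idx1)),
                               rng.choice(idx0, len(idx0))])
        s = statistic(v[take], y[take])
        if np.isnan(s):
            skipped += 1
            out[b] = np.nan
        else:
            out[b] = s
    good = out[~np.isnan(out)]
    lo, hi = np.percentile(good, percentiles)
    return float(lo), float(hi), skipped


def _bootstrap_auc_fast(values, labels, n_boot, seed,
                        percentiles=(2.5, 97.5)) -> tuple[float, float]:
    """Vectorized stratified bootstrap of the rank AUC."""
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels).astype(bool)
    pos, neg = v[y], v[~y]
    n1, n0 = len(pos), len(neg)
    rng = np.random.default_rng(seed)
    bp = pos[rng.integers(0, n1, size=(n_boot, n1))]
    bn = neg[rng.integers(0, n0, size=(n_boot, n0))]
    both = np.concatenate([bp, bn], axis=1)
    r = stats.rankdata(both, axis=1)
    u = r[:, :n1].sum(axis=1) - n1 * (n1 + 1) / 2.0
    aucs = u / (n1 * n0)
    lo, hi = np.percentile(aucs, percentiles)
    return float(lo), float(hi)


def univariate_logistic_auc(values, labels, n_boot: int = 2000, seed: int = 0,
                            fast_bootstrap: bool = True) -> AUCResult:
    """Unregularized single-predictor logistic fit on the z-scored feature,
    with the rank/trapezoidal AUC of the feature's ascending orientation and
    a stratified-bootstrap percentile CI.

    The per-replicate AUC is computed directly from ranks: a univariate
    logistic link is strictly monotone in the predictor, so refitting it on
    each resample cannot change the replicate AUC of the feature
    orientation.  Perfect separation flags the fit; the AUC remains defined
    from ranks.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels).astype(int)
    if len(v) < 10:
        raise ValueError("need at least 10 observations")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    z = zscore(v)
    coef = intercept = np.nan
    flag = ""
    if z.std() == 0:
        flag = "constant"
    else:
        from sklearn.exceptions import ConvergenceWarning
        from sklearn.linear_model import LogisticRegression
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            fit = LogisticRegression(penalty=None, solver="lbfgs",
                                     max_iter=1000).fit(z.reshape(-1, 1), y)
        coef = float(fit.coef_[0, 0])
        intercept = float(fit.intercept_[0])
        pos, neg = v[y == 1], v[y == 0]
        separated = pos.min() > neg.max() or pos.max() < neg.min()
        if separated or any(issubclass(w.category, ConvergenceWarning)
                            for w in caught):
            flag = "separation"
    point = rank_auc(v, y)
    skipped = 0
    if fast_bootstrap:
        lo, hi = _bootstrap_auc_fast(v, y, n_boot, seed)
    else:
        lo, hi, skipped = stratified_bootstrap_ci(
            v, y, lambda vv, yy: rank_auc(vv, yy), n_boot=n_boot, seed=seed)
    return AUCResult(auc_point=point, ci_low=lo, ci_high=hi, n_boot=n_boot,
                     seed=seed, coef=coef, intercept=intercept, fit_flag=flag,
                     skipped_replicates=skipped)


def roc_curve_points(values, labels) -> pd.DataFrame:
    """ROC points (fpr, tpr, threshold) of the ascending feature orientation."""
    from sklearn.metrics import roc_curve
    fpr, tpr, thr = roc_curve(np.asarray(labels).astype(int),
                              np.asarray(values, dtype=float))
    return pd.DataFrame(dict(fpr=fpr, tpr=tpr, threshold=thr))


def abs_mean_difference_ranking(feature_table: pd.DataFrame,
                                label_col: str = "label",
                                positive_label: str = "DM",
                                exclude: tuple = ()) -> pd.DataFrame:
    """Range-adjusted absolute mean difference per feature, partitioned by
    the sign of the raw class difference.

    Each feature's |mean_pos - mean_neg| is divided by the feature's
    observed range; zero-range features score 0 with a flag.  Features in
    ``exclude`` (e.g. a dominant area term) are dropped before ranking.
    """
    feats = [c for c in feature_table.columns
             if c != label_col and c not in exclude
             and pd.api.types.is_numeric_dtype(feature_table[c])]
    pos = feature_table[feature_table[label_col] == positive_label]
    neg = feature_table[feature_table[label_col] != positive_label]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    rows = []
    for f in feats:
        diff = pos[f].mean() - neg[f].mean()
        rng = feature_table[f].max() - feature_table[f].min()
        score = abs(diff) / rng if rng > 0 else 0.0
        rows.append(dict(feature=f, raw_difference=diff,
                         range_adjusted_abs_mean_diff=score,
                         higher_in=positive_label if diff > 0 else "other",
                         zero_range=rng == 0))
    out = pd.DataFrame(rows).sort_values(
        "range_adjusted_abs_mean_diff", ascending=False).reset_index(drop=True)
    return out


def benjamini_hochberg(pvals) -> np.ndarray:
    """BH-adjusted p-values (optional; off by default in screening)."""
    from statsmodels.stats.multitest import multipletests
    return multipletests(np.asarray(pvals), method="fdr_bh")[1]


def screen_features(feature_table: pd.DataFrame, alpha: float = 0.05,
                    label_col: str = "label", positive_label: str = "DM",
                    n_boot: int = 2000, seed: int = 0,
                    compute_auc: bool = True,
                    bh_correction: bool = False) -> pd.DataFrame:
    """Full per-feature screening table.

    One row per numeric feature column with t, p, df, class means,
    range-adjusted |mean difference|, Spearman rho/p, -log10(p), k-NN mutual
    information, retention flag (p < alpha strict), and (optionally) the
    univariate logistic AUC with stratified-bootstrap CI.
    """
    y = feature_table[label_col] == positive_label
    if y.all() or (~y).all():
        raise ValueError("feature table must contain both classes")
    feats = [c for c in feature_table.columns
             if c != label_col and pd.api.types.is_numeric_dtype(feature_table[c])]
    rows = []
    for k, f in enumerate(feats):
        v = feature_table[f].to_numpy(dtype=float)
        a, b = v[y.to_numpy()], v[~y.to_numpy()]
        t, p, df = two_sample_ttest(a, b)
        rho, rho_p = spearman_vs_label(v, y.to_numpy().astype(int))
        mi = mutual_information_score(v, y.to_numpy().astype(int), seed=seed)
        rng = v.max() - v.min()
        row = dict(feature=f, t_value=t, p_value=p, df=df,
                   mean_dm=float(a.mean()), mean_non_dm=float(b.mean()),
                   abs_mean_diff_range_adjusted=(
                       abs(a.mean() - b.mean()) / rng if rng > 0 else 0.0),
                   spearman_rho=rho, spearman_p=rho_p,
                   neglog10_p=neglog10(p), mi_score=mi,
                   retained=bool(p < alpha))
        if compute_auc:
            res = univariate_logistic_auc(v, y.to_numpy().astype(int),
                                          n_boot=n_boot, seed=seed + k)
            row.update(auc=res.auc_point, auc_ci_low=res.ci_low,
                       auc_ci_high=res.ci_high, fit_flag=res.fit_flag)
        rows.append(row)
    out = pd.DataFrame(rows)
    if bh_correction:
        out["p_adjusted"] = benjamini_hochberg(out["p_value"])
        out["retained"] = out["p_adjusted"] < alpha
    return out
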