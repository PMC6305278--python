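"""Per-feature association screening across Gleason-score groups.

Each of the 41 features is tested with the Kruskal-Wallis rank test across
groups and with Spearman rank correlation against the ordinal group index;
both families of 41 p-values are corrected with the step-down
Holm-Bonferroni procedure (separately by default, a single 82-test family
is available).  Being rank-based, every statistic here is invariant to any
strictly increasing transform of a feature — in particular to the cohort
min-max scaling step.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


def kruskal_wallis(values, groups) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p-value.

    Degenerate inputs (a single group, or all observations identical, which
    leaves zero rank variance) return the defined result H=0, p=1 with a
    logged warning instead of NaN.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if labels.size < 2:
        logger.warning("Kruskal-Wallis with a single group: H=0, p=1")
        return 0.0, 1.0
    samples = [values[groups == g] for g in labels]
    if np.all(values == values[0]):
        logger.warning("Kruskal-Wallis with zero rank variance: H=0, p=1")
        return 0.0, 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        h, p = stats.kruskal(*samples)
    if not np.isfinite(h):
        logger.warning("Kruskal-Wallis degenerate: H=0, p=1")
        return 0.0, 1.0
    return float(h), float(p)


def spearman_vs_group(values, groups) -> tuple[float, float]:
    """Spearman rho between a feature and the ordinal group index.

    Ties get average ranks (group labels are heavily tied by construction);
    the p-value tests the null of no correlation.  Zero variance in either
    variable yields rho=0, p=1 with a warning.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups, dtype=float)
    if values.size < 3:
        raise ValueError("Spearman correlation needs at least 3 observations")
    if np.all(values == values[0]) or np.all(groups == groups[0]):
        logger.warning("Spearman with zero variance: rho=0, p=1")
        return 0.0, 1.0
    res = stats.spearmanr(values, groups)
    rho, p = float(res.statistic), float(res.pvalue)
    if not np.isfinite(rho):
        logger.warning("Spearman degenerate: rho=0, p=1")
        return 0.0, 1.0
    return rho, p


def holm_bonferroni(p_values, alpha: float = 0.05
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Step-down Holm correction: (adjusted p-values, reject flags).

    Adjusted p for the k-th smallest raw p is
    max_{j<=k} min(1, (m-j+1) * p_(j)); rejection at level alpha follows
    the step-down rule.  Uniformly more powerful than plain Bonferroni.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="holm")
    return p_adj, reject


@dataclass
class GroupSummary:
    """Per-feature, per-group median and interquartile range (Q3 - Q1)."""

    median: pd.DataFrame  # features x groups
    iqr: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        out = {}
        for g in self.median.columns:
            out[f"median_g{g}"] = self.median[g]
            out[f"iqr_g{g}"] = self.iqr[g]
        return pd.DataFrame(out)


class UnivariateScreen(BaseEstimator):
    """Screen every feature for association with the group label.

    Parameters
    ----------
    alpha : float
        Family-wise significance level after Holm correction.
    family : {"separate", "joint"}
        Correct the Kruskal-Wallis and Spearman p-value families separately
        (two families of n_features tests each, the default) or as one
        joint family of 2 * n_features tests.

    Attributes
    ----------
    results_ : pd.DataFrame
        Per feature: H, p_kw, p_kw_adj, kw_significant, rho, p_rho,
        p_rho_adj, rho_significant, neglog10_p_kw.
    summary_ : GroupSummary
        Per-group median / IQR table.
    """

    def __init__(self, alpha: float = 0.05, family: str = "separate"):
        self.alpha = alpha
        self.family = family

    def fit(self, X: pd.DataFrame, y) -> "UnivariateScreen":
        X = pd.DataFrame(X)
        y = np.asarray(y)
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        rows = []
        for name in X.columns:
            v = X[name].to_numpy(dtype=float)
            h, p_kw = kruskal_wallis(v, y)
            rho, p_rho = spearman_vs_group(v, y)
            rows.append((name, h, p_kw, rho, p_rho))
        res = pd.DataFrame(
            rows, columns=["feature", "H", "p_kw", "rho", "p_rho"]
        ).set_index("feature")
        if self.family == "separate":
            res["p_kw_adj"], res["kw_significant"] = holm_bonferroni(
                res["p_kw"], self.alpha
            )
            res["p_rho_adj"], res["rho_significant"] = holm_bonferroni(
                res["p_rho"], self.alpha
            )
        elif self.family == "joint":
            pooled = np.concatenate([res["p_kw"], res["p_rho"]])
            adj, rej = holm_bonferroni(pooled, self.alpha)
            m = len(res)
            res["p_kw_adj"], res["kw_significant"] = adj[:m], rej[:m]
            res["p_rho_adj"], res["rho_significant"] = adj[m:], rej[m:]
        else:
            raise ValueError(f"unknown correction family: {self.family!r}")
        res["neglog10_p_kw"] = -np.log10(np.maximum(res["p_kw"], 1e-300))
        self.results_ = res[
            ["H", "p_kw", "p_kw_adj", "kw_significant",
             "rho", "p_rho", "p_rho_adj", "rho_significant", "neglog10_p_kw"]
        ]
        groups = np.unique(y)
        med = {g: X[y == g].median() for g in groups}
        iqr = {
            g: X[y == g].quantile(0.75) - X[y == g].quantile(0.25)
            for g in groups
        }
        self.summary_ = GroupSummary(
            median=pd.DataFrame(med), iqr=pd.DataFrame(iqr)
        )
        return self


def screen_features(table, alpha: float = 0.05, family: str = "separate"):
    """Functional wrapper: returns (results frame, GroupSummary).

    ``table`` is a CohortFeatureTable (or any object with ``data`` and
    ``groups``).
    """
    screen = UnivariateScreen(alpha=alpha, family=family)
    screen.fit(table.data, table.groups.to_numpy())
    return screen.results_, screen.summary_
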