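"""Feature importance and clinical-score correlation.

Importance is the random-forest out-of-bag mean decrease in accuracy (MDA):
for every tree, the prediction accuracy on its out-of-bag athletes is
measured before and after permuting one feature's out-of-bag values, and the
drop is averaged over trees and expressed in percentage points. Redundant
informative features dilute each other's MDA, which is why a handful of
features carry the ranking even when many separate the groups univariately.

The top features (MDA above a threshold, 15% by convention here) are then
rank-correlated with the LESS score via Spearman's rho, interpreted with the
usual bands (none <= 0.1 < mild/modest <= 0.3 < moderate <= 0.6 < strong
< 1 = perfect).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.tree import DecisionTreeClassifier

from .features import FEATURE_NAMES


@dataclass
class ImportanceResult:
    mda: dict[str, float]  # feature -> mean decrease accuracy, percent
    ranking: list[str]     # features sorted by decreasing MDA
    threshold: float       # percent cut used to call a feature important
    n_trees: int
    seed: int | None

    @property
    def top_features(self) -> list[str]:
        return [f for f in self.ranking if self.mda[f] >= self.threshold]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"feature": self.ranking, "mda_percent": [self.mda[f] for f in self.ranking]}
        ).set_index("feature")


def mda_importance(
    features: pd.DataFrame | np.ndarray,
    labels,
    n_trees: int = 500,
    seed: int | None = None,
    threshold: float = 15.0,
    feature_names: list[str] | None = None,
    repeats: int = 1,
) -> ImportanceResult:
    """Out-of-bag permutation importance of a bagged-tree (random forest)
    ensemble.

    The forest is grown by hand (bootstrap of size n, sqrt(p) features per
    split) so each tree's out-of-bag samples are available for the
    before/after-permutation accuracy difference; ``repeats`` > 1 averages
    several permutations per tree to cut Monte-Carlo variance.
    """
    if isinstance(features, pd.DataFrame):
        names = [c for c in features.columns if c != "athlete_id"]
        X = features[names].to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
        names = feature_names or [f"f{i}" for i in range(X.shape[1])]
    y = np.asarray(labels)
    n, p = X.shape
    if len(np.unique(y)) < 2:
        raise ValueError("need at least two classes")
    if n_trees < 50:
        raise ValueError("need at least 50 trees for a stable OOB estimate")

    constant = np.ptp(X, axis=0) == 0
    if constant.any():
        warnings.warn(
            f"zero-variance features {[names[i] for i in np.flatnonzero(constant)]}; "
            "their MDA is defined as 0"
        )

    rng = np.random.default_rng(seed)
    drops = np.zeros(p)
    used = np.zeros(p)
    for _ in range(n_trees):
        boot = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), boot)
        if oob.size == 0:
            continue
        tree = DecisionTreeClassifier(
            max_features="sqrt", random_state=int(rng.integers(2**31))
        )
        tree.fit(X[boot], y[boot])
        base = np.mean(tree.predict(X[oob]) == y[oob])
        for f in range(p):
            if constant[f]:
                continue
            drop = 0.0
            for _ in range(repeats):
                Xp = X[oob].copy()
                Xp[:, f] = Xp[rng.permutation(oob.size), f]
                drop += base - np.mean(tree.predict(Xp) == y[oob])
            drops[f] += drop / repeats
            used[f] += 1
    mda_vals = np.where(used > 0, drops / np.maximum(used, 1) * 100.0, 0.0)
    mda = dict(zip(names, mda_vals.astype(float)))
    ranking = sorted(names, key=lambda f: -mda[f])
    return ImportanceResult(mda, ranking, threshold, n_trees, seed)


#: Spearman interpretation bands, upper |r| bound -> label (boundaries fall
#: into the lower band)
_BANDS = [(0.1, "none"), (0.3, "mild/modest"), (0.6, "moderate")]


@dataclass
class CorrelationResult:
    r: float
    p: float
    band: str


def spearman_band(x, y) -> CorrelationResult:
    """Spearman rank correlation (mid-ranks for ties, large-sample p) with
    its interpretation band."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 5:
        raise ValueError("need at least 5 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: rank correlation undefined")
    res = stats.spearmanr(x, y)
    r = float(res.statistic)
    for bound, label in _BANDS:
        if abs(r) <= bound:
            return CorrelationResult(r, float(res.pvalue), label)
    band = "perfect" if np.isclose(abs(r), 1.0) else "strong"
    return CorrelationResult(r, float(res.pvalue), band)


def correlation_table(
    features: pd.DataFrame,
    less_scores,
    which: list[str],
) -> pd.DataFrame:
    """Spearman r / p / band of selected features against the LESS score."""
    rows = []
    for name in which:
        res = spearman_band(features[name].to_numpy(), less_scores)
        rows.append({"feature": name, "r": res.r, "p": res.p, "band": res.band})
    return pd.DataFrame(rows).set_index("feature")


def plot_importance(result: ImportanceResult, path) -> None:
    """Bar chart of the MDA ranking with the importance-threshold line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    vals = [result.mda[f] for f in result.ranking]
    ax.bar(range(len(vals)), vals, color="steelblue")
    ax.axhline(result.threshold, color="red", ls=":", label=f"{result.threshold}%")
    ax.set_xticks(range(len(vals)))
    ax.set_xticklabels(result.ranking, rotation=60, ha="right", fontsize=7)
    ax.set_ylabel("mean decrease accuracy (%)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
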