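"""Fuzzy c-means temporal clustering of signed z-score trajectories.

Differential-analysis results are summarized per feature as signed z-scores
over the post-exercise contrasts (columns ordered EE then RE by time), rows
are scaled by a zero-anchored standard deviation (two zero columns standing
in for the pre-exercise baseline are temporarily appended before the SD is
computed), and clustered with fuzzy c-means. The fuzzifier ``m`` follows the
published heuristic estimator for soft clustering of expression time
courses; the number of clusters is scanned over a range using the minimum
pairwise centroid distance as the validity index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ClusterModel",
    "build_zscore_matrix",
    "scale_rows_with_zero_anchor",
    "estimate_fuzzifier",
    "fuzzy_cmeans",
    "select_k",
    "hard_assign",
]

Z_CAP = 40.0  # |z| bound used when p underflows to 0


def signed_z(estimate: float, p: float) -> float:
    """Signed z-score ``sign(estimate) * Phi^-1(1 - p/2)``, capped at +/-40."""
    if p <= 0.0:
        z = Z_CAP
    else:
        z = min(stats.norm.isf(p / 2.0), Z_CAP)
    return float(np.sign(estimate) * z)


def build_zscore_matrix(
    results: pd.DataFrame,
    feature_to_gene: dict[str, str] | None = None,
    groups: tuple[str, ...] = ("EE", "RE"),
    exclude_timepoints: tuple[str, ...] = ("D20M", "D40M"),
) -> pd.DataFrame:
    """Features x contrasts signed z-score matrix from a DA results table.

    Columns are ``group|timepoint`` ordered EE then RE by time; during-
    exercise contrasts are excluded by default. When ``feature_to_gene`` is
    given, multi-feature genes collapse to the z-score of largest magnitude
    per column (sign preserved).
    """
    res = results[results["contrast"] == "diff_in_changes"].copy()
    res = res[~res["timepoint"].isin(exclude_timepoints)]
    res = res[res["group"].isin(groups)]
    if res.empty:
        raise ValueError("no difference-in-changes rows to build z-scores from")
    res["z"] = [signed_z(e, p) for e, p in zip(res["estimate"], res["p"])]
    key = res["feature"].astype(str)
    if feature_to_gene is not None:
        key = key.map(lambda f: feature_to_gene.get(f, f))
    res["row_id"] = key
    res["col"] = res["group"] + "|" + res["timepoint"]
    # column order: EE block then RE block, each by time order of appearance
    tps = list(dict.fromkeys(results["timepoint"]))
    cols = [f"{g}|{t}" for g in groups for t in tps if f"{g}|{t}" in set(res["col"])]
    # most extreme z per (row, col)
    picked = res.loc[
        res.groupby(["row_id", "col"], sort=False)["z"]
        .apply(lambda s: s.abs().idxmax())
        .to_numpy()
    ]
    mat = picked.pivot(index="row_id", columns="col", values="z")
    return mat.reindex(columns=cols)


def scale_rows_with_zero_anchor(Z: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Divide each row by the sample SD of its values plus two zero anchors.

    The two appended zeros represent the (identically zero) pre-exercise
    baseline of each modality block; they enter the SD only and are not
    retained as columns. All-zero rows are left unscaled and returned as
    flagged ids.
    """
    if Z.shape[1] < 1:
        raise ValueError("need at least one column")
    vals = Z.to_numpy(float)
    T = vals.shape[1]
    padded = np.concatenate([vals, np.zeros((vals.shape[0], 2))], axis=1)
    sd = padded.std(axis=1, ddof=1)
    flagged = list(Z.index[sd == 0])
    sd_safe = np.where(sd == 0, 1.0, sd)
    return pd.DataFrame(vals / sd_safe[:, None], index=Z.index, columns=Z.columns), flagged


def estimate_fuzzifier(n_features: int, n_columns: int) -> float:
    """Heuristic fuzzifier estimate for expression time-course FCM.

    ``m = 1 + (1418/N + 22.05) D^-2 + (12.33/N + 0.243) D^(-0.0406 ln N - 0.1134)``
    — always > 1, decreasing in both N and D.
    """
    if n_features < 3 or n_columns < 1:
        raise ValueError("need N >= 3 features and D >= 1 columns")
    N, D = float(n_features), float(n_columns)
    return (
        1.0
        + (1418.0 / N + 22.05) * D**-2
        + (12.33 / N + 0.243) * D ** (-0.0406 * np.log(N) - 0.1134)
    )


@dataclass
class ClusterModel:
    """Fitted fuzzy c-means model."""

    centroids: np.ndarray  # k x T
    membership: pd.DataFrame  # N x k
    fuzzifier: float
    objective: float
    n_iter: int
    converged: bool
    seed: int
    validity_trace: dict[int, float] = field(default_factory=dict)

    @property
    def k(self) -> int:
        return self.centroids.shape[0]

    def min_centroid_distance(self) -> float:
        d = np.inf
        for i in range(self.k):
            for j in range(i + 1, self.k):
                d = min(d, float(np.linalg.norm(self.centroids[i] - self.centroids[j])))
        return d


def _fcm_once(
    X: np.ndarray, k: int, m: float, rng: np.random.Generator, tol: float, max_iter: int
) -> tuple[np.ndarray, np.ndarray, float, int, bool]:
    n = X.shape[0]
    # init centroids by sampling k distinct rows
    centroids = X[rng.choice(n, size=k, replace=False)].copy()
    u = np.zeros((n, k))
    obj_prev = np.inf
    exponent = 2.0 / (m - 1.0)
    for it in range(1, max_iter + 1):
        d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        zero = d2 < 1e-300
        if zero.any():
            u = np.where(zero, 1.0, 0.0)
            rows = zero.any(axis=1)
            u[rows] /= u[rows].sum(axis=1, keepdims=True)
            inv = (1.0 / d2[~rows]) ** (1.0 / (m - 1.0))
            u[~rows] = inv / inv.sum(axis=1, keepdims=True)
        else:
            inv = (1.0 / d2) ** (1.0 / (m - 1.0))
            u = inv / inv.sum(axis=1, keepdims=True)
        um = u**m
        denom = um.sum(axis=0)
        empty = denom < 1e-12
        if empty.any():
            # duplicate-point collapse: re-seed dead centroids from data rows
            centroids[empty] = X[rng.choice(n, size=int(empty.sum()), replace=False)]
            continue
        centroids = (um.T @ X) / denom[:, None]
        obj = float((um * d2).sum())
        if abs(obj_prev - obj) < tol:
            return centroids, u, obj, it, True
        obj_prev = obj
    return centroids, u, obj_prev, max_iter, False


def fuzzy_cmeans(
    X: pd.DataFrame,
    k: int,
    m: float | None = None,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 1000,
    n_restarts: int = 10,
) -> ClusterModel:
    """Fuzzy c-means with Euclidean distance and seeded multi-restart.

    Standard alternating updates: memberships ``u_ij` proportional to
    ``(1/||x_i - c_j||^2)^(1/(m-1))`` normalized per row, centroids the
    ``u^m``-weighted means. Keeps the best objective over ``n_restarts``
    seeded initializations.
    """
    n = X.shape[0]
    if not 2 <= k < n:
        raise ValueError("need 2 <= k < N")
    if m is None:
        m = estimate_fuzzifier(n, X.shape[1])
    if m <= 1:
        raise ValueError("fuzzifier must be > 1")
    vals = X.to_numpy(float)
    best = None
    for r in range(n_restarts):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(k, r)))
        cent, u, obj, it, conv = _fcm_once(vals, k, m, rng, tol, max_iter)
        if best is None or obj < best[2]:
            best = (cent, u, obj, it, conv)
    cent, u, obj, it, conv = best
    membership = pd.DataFrame(
        u, index=X.index, columns=[f"cluster_{j + 1}" for j in range(k)]
    )
    return ClusterModel(cent, membership, float(m), obj, it, conv, seed)


def select_k(
    X: pd.DataFrame,
    m: float | None = None,
    k_range: range | list[int] = range(3, 15),
    seed: int = 0,
    **fcm_kwargs,
) -> tuple[int, dict[int, float], dict[int, ClusterModel]]:
    """Scan k over a range; validity index = minimum centroid distance.

    Returns (suggested k, {k: min centroid distance}, {k: model}). The
    validity index stays high while every centroid still tracks a distinct
    temporal shape and collapses once clusters start splitting, so the
    programmatic elbow suggestion is the k immediately before the largest
    drop of the trace; the caller may override it after inspecting the
    scree.
    """
    ks = list(k_range)
    models: dict[int, ClusterModel] = {}
    trace: dict[int, float] = {}
    for k in ks:
        mod = fuzzy_cmeans(X, k, m=m, seed=seed, **fcm_kwargs)
        models[k] = mod
        trace[k] = mod.min_centroid_distance()
    if len(ks) == 1:
        k_star = ks[0]
    else:
        d = np.array([trace[k] for k in ks])
        k_star = ks[int(np.argmax(d[:-1] - d[1:]))]
    models[k_star].validity_trace = trace
    return k_star, trace, models


def hard_assign(model: ClusterModel, threshold: float = 0.3) -> pd.Series:
    """Assign each feature to its argmax-membership cluster, or leave unassigned.

    Features whose maximum membership is below ``threshold`` (strict <) stay
    unassigned (label 0); ties break toward the lowest cluster index.
    Cluster labels are 1-based.
    """
    u = model.membership.to_numpy()
    best = u.argmax(axis=1)  # argmax takes the first (lowest) index on ties
    maxu = u[np.arange(len(u)), best]
    labels = np.where(maxu >= threshold, best + 1, 0)
    return pd.Series(labels, index=model.membership.index, name="cluster")
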