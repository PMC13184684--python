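"""Regulator-target network inference scaffolding and network-motif scores.

A bipartite regulator-to-target network is inferred per exercise modality
(control samples excluded) from two matrices sharing sample columns: per
target, a pluggable backend assigns non-negative importances over regulators
that sum to one (default: tree-ensemble feature importance; alternative:
absolute partial correlation). Edges are trimmed by a permutation test
(pooled null from shuffled matrices, BH-adjusted) plus a hard weight cutoff
(> 0.1). Modality networks are merged by edge union, and each node receives
a Network Motif Score (NMS): its total participation count in feed-forward
loop, diamond, and 3-chain motifs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

__all__ = [
    "prepare_regulators",
    "infer_edge_weights",
    "permutation_trim",
    "merge_union",
    "count_motifs",
    "MotifCounts",
]


# ---------------------------------------------------------------------------
# input preparation
# ---------------------------------------------------------------------------


def prepare_regulators(
    phospho: pd.DataFrame,
    tf_genes: list[str] | None = None,
    max_missing_fraction: float = 0.40,
    n_imputations: int = 15,
    seed: int = 0,
) -> pd.DataFrame:
    """Filter, impute and TF-restrict a regulator (e.g. phosphosite) matrix.

    Rows with more than ``max_missing_fraction`` missing values are dropped
    (the boundary, exactly 40%, is kept); remaining missing values are
    imputed by chained iterative regression run ``n_imputations`` times with
    different seeds and averaged; observed values are never altered. When
    ``tf_genes`` is given, rows are restricted to ids whose gene part
    (prefix before ``'_'``) is an annotated transcription factor.
    """
    from sklearn.experimental import enable_iterative_imputer  # noqa: F401
    from sklearn.impute import IterativeImputer

    miss = phospho.isna().mean(axis=1)
    kept = phospho.loc[miss <= max_missing_fraction]
    if tf_genes is not None:
        tf_set = set(tf_genes)
        kept = kept.loc[[i for i in kept.index if str(i).split("_")[0] in tf_set]]
    if kept.empty:
        raise ValueError("no regulators left after filtering")
    if not kept.isna().any(axis=None):
        return kept.copy()
    X = kept.to_numpy(float).T  # samples x features for column-wise imputation
    acc = np.zeros_like(X)
    for r in range(n_imputations):
        imp = IterativeImputer(
            random_state=int(
                np.random.SeedSequence(seed, spawn_key=(r,)).generate_state(1)[0]
                % (2**31)
            ),
            sample_posterior=True,
            max_iter=10,
        )
        acc += imp.fit_transform(X)
    filled = acc / n_imputations
    obs = ~np.isnan(X)
    filled[obs] = X[obs]
    return pd.DataFrame(filled.T, index=kept.index, columns=kept.columns)


# ---------------------------------------------------------------------------
# edge-weight inference
# ---------------------------------------------------------------------------


def _tree_importances(R: np.ndarray, y: np.ndarray, seed: int) -> np.ndarray:
    from sklearn.ensemble import ExtraTreesRegressor

    model = ExtraTreesRegressor(
        n_estimators=100, max_features="sqrt", random_state=seed, n_jobs=1
    )
    model.fit(R, y)
    return model.feature_importances_


def _partial_corr_importances(R: np.ndarray, y: np.ndarray, seed: int) -> np.ndarray:
    # absolute regression-based partial correlation of each regulator with y
    n, p = R.shape
    Rs = (R - R.mean(0)) / np.where(R.std(0) == 0, 1.0, R.std(0))
    ys = (y - y.mean()) / (y.std() or 1.0)
    if n > p + 1:
        beta, *_ = np.linalg.lstsq(Rs, ys, rcond=None)
        imp = np.abs(beta)
    else:  # fall back to marginal correlation when under-determined
        imp = np.abs(Rs.T @ ys) / n
    return imp


_BACKENDS = {"trees": _tree_importances, "partial_corr": _partial_corr_importances}


def infer_edge_weights(
    regulators: pd.DataFrame,
    targets: pd.DataFrame,
    backend: str = "trees",
    modality: str = "",
    seed: int = 0,
) -> pd.DataFrame:
    """Weighted bipartite edge table: per-target importances over regulators.

    Both matrices are features x samples and must share sample columns.
    Importances are non-negative and normalized to sum to one per target;
    constant regulators receive weight zero. Self-loops (a feature acting as
    both regulator and target) are excluded.
    """
    shared = [c for c in regulators.columns if c in set(targets.columns)]
    if not shared:
        raise ValueError("regulator and target matrices share no samples")
    R = regulators[shared].to_numpy(float).T  # samples x regulators
    const = R.std(axis=0) == 0
    fn = _BACKENDS[backend]
    rows = []
    reg_ids = list(regulators.index)
    for ti, (tid, y) in enumerate(zip(targets.index, targets[shared].to_numpy(float))):
        # a feature acting on both sides is excluded from its own regression,
        # not merely zeroed afterwards
        usable = ~const
        if tid in reg_ids:
            usable = usable.copy()
            usable[reg_ids.index(tid)] = False
        imp = fn(R[:, usable], y, seed + ti) if usable.any() else np.array([])
        w = np.zeros(len(reg_ids))
        w[usable] = np.maximum(imp, 0.0)
        s = w.sum()
        if s > 0:
            w = w / s
        for rid, wi in zip(reg_ids, w):
            if rid != tid:
                rows.append((rid, tid, float(wi), modality))
    return pd.DataFrame(rows, columns=["regulator", "target", "weight", "modality"])


def permutation_trim(
    edges: pd.DataFrame,
    regulators: pd.DataFrame,
    targets: pd.DataFrame,
    backend: str = "trees",
    n_perm: int = 100,
    weight_cut: float = 0.1,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation p-values (pooled null) + BH + hard weight cutoff.

    The null pools all edge weights from ``n_perm`` re-inferences on
    sample-shuffled copies of both matrices; each observed edge's p-value is
    its upper-tail rank in the pooled null. Retained edges satisfy BH-adjusted
    p < ``alpha`` and weight strictly greater than ``weight_cut``.
    """
    from statsmodels.stats.multitest import multipletests

    if n_perm < 20:
        raise ValueError("need at least 20 permutations")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(99,)))
    null: list[np.ndarray] = []
    shared = [c for c in regulators.columns if c in set(targets.columns)]
    for b in range(n_perm):
        perm_r = regulators[shared].to_numpy(float)[
            :, rng.permutation(len(shared))
        ]
        perm_t = targets[shared].to_numpy(float)[:, rng.permutation(len(shared))]
        pr = pd.DataFrame(perm_r, index=regulators.index, columns=shared)
        pt = pd.DataFrame(perm_t, index=targets.index, columns=shared)
        e = infer_edge_weights(pr, pt, backend=backend, seed=seed + 1000 + b)
        null.append(e["weight"].to_numpy())
    pooled = np.sort(np.concatenate(null))
    w = edges["weight"].to_numpy()
    # upper-tail rank p with add-one continuity
    exceed = len(pooled) - np.searchsorted(pooled, w, side="left")
    p = (exceed + 1.0) / (len(pooled) + 1.0)
    out = edges.copy()
    out["p"] = p
    out["adj_p"] = multipletests(p, method="fdr_bh")[1]
    return out[(out["adj_p"] < alpha) & (out["weight"] > weight_cut)].reset_index(
        drop=True
    )


def merge_union(net_a: pd.DataFrame, net_b: pd.DataFrame) -> pd.DataFrame:
    """Edge-set union of two modality networks, provenance retained.

    Edges present in both keep their per-modality weights side by side
    (one row per modality); the unique edge set is the union.
    """
    out = pd.concat([net_a, net_b], ignore_index=True)
    return out.drop_duplicates(subset=["regulator", "target", "modality"]).reset_index(
        drop=True
    )


# ---------------------------------------------------------------------------
# motif counting
# ---------------------------------------------------------------------------


@dataclass
class MotifCounts:
    """Per-node motif participation counts and the resulting NMS."""

    ffl: pd.Series
    diamond: pd.Series
    chain3: pd.Series
    nms: pd.Series = field(init=False)

    def __post_init__(self) -> None:
        self.nms = (self.ffl + self.diamond + self.chain3).rename("nms")


def count_motifs(edges: pd.DataFrame) -> MotifCounts:
    """Exhaustively count FFL, diamond and 3-chain participation per node.

    Motif shapes (all nodes distinct): FFL = A->B, A->C, B->C; diamond =
    A->B, A->C, B->D, C->D with the two mid nodes unordered; 3-chain =
    A->B->C. Each node's count is the number of distinct motif instances it
    participates in; the NMS is the unweighted sum over the three motif
    types. Self-loops are disallowed.
    """
    import networkx as nx

    G = nx.DiGraph()
    nodes = sorted(set(edges["regulator"]) | set(edges["target"]))
    G.add_nodes_from(nodes)
    for r, t in zip(edges["regulator"], edges["target"]):
        if r == t:
            raise ValueError("self-loops are not allowed")
        G.add_edge(r, t)
    ffl = pd.Series(0, index=nodes, dtype=int)
    diamond = pd.Series(0, index=nodes, dtype=int)
    chain3 = pd.Series(0, index=nodes, dtype=int)

    for a in G.nodes:
        succ_a = set(G.successors(a))
        # 3-chains a->b->c (c != a) and FFLs a->b, a->c, b->c
        for b in succ_a:
            for c in G.successors(b):
                if c != a:
                    chain3[a] += 1
                    chain3[b] += 1
                    chain3[c] += 1
                    if c in succ_a:
                        ffl[a] += 1
                        ffl[b] += 1
                        ffl[c] += 1
        # diamonds: a->b, a->c (b<c unordered), b->d, c->d, d not in {a,b,c}
        for b, c in combinations(sorted(succ_a), 2):
            shared = (set(G.successors(b)) & set(G.successors(c))) - {a, b, c}
            for d in shared:
                diamond[a] += 1
                diamond[b] += 1
                diamond[c] += 1
                diamond[d] += 1
    return MotifCounts(ffl.rename("ffl"), diamond.rename("diamond"), chain3.rename("chain3"))
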