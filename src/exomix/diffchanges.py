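"""Cell-means mixed-model differential analysis with difference-in-changes contrasts.

Each feature is modeled as ``value ~ 0 + group:timepoint + covariates +
(1 | participant)``: one fixed-effect column per observed (group, timepoint)
cell plus clinical covariates, a participant random intercept, and optional
per-observation precision weights. Hypotheses are linear contrasts over the
cell means; the primary estimand is the difference-in-changes ("delta-delta"):
the pre-to-post change in an exercise group minus the same change in the
non-exercise control group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .lmm import RandomInterceptFit, SingularDesignError, fit_random_intercept
from .synthetic import DURING_CODES, TIMEPOINTS

__all__ = [
    "ModelSpec",
    "ContrastSpec",
    "build_design",
    "check_eligibility",
    "fit_feature",
    "test_contrast",
    "run_da",
    "adjust_fdr",
    "classify_response",
    "variance_explained",
    "pc_covariate_association",
]

DA_COLUMNS = [
    "feature",
    "contrast",
    "group",
    "timepoint",
    "estimate",
    "se",
    "t",
    "df",
    "p",
    "adj_p",
    "n_eligible",
]


@dataclass(frozen=True)
class ModelSpec:
    """Fixed-effect layout: cell means for group x timepoint plus covariates."""

    covariates: tuple[str, ...] = ("site", "age", "sex", "bmi")
    use_weights: bool = False


@dataclass(frozen=True)
class ContrastSpec:
    """A hypothesis over cell means.

    ``kind='diff_in_changes'`` compares the pre-to-``timepoint`` change in
    ``group`` against the same change in CON; ``'group_specific'`` is the
    within-group change alone; ``'ee_vs_re'`` sets RE as the matched control
    for EE (during-exercise blood cells are inestimable for RE and therefore
    excluded by construction).
    """

    kind: str
    group: str
    timepoint: str

    def __post_init__(self) -> None:
        if self.kind not in ("diff_in_changes", "group_specific", "ee_vs_re"):
            raise ValueError(f"unknown contrast kind {self.kind!r}")
        if self.timepoint == "Pre":
            raise ValueError("contrasts compare a post-exercise timepoint to Pre")

    def cell_weights(self) -> dict[tuple[str, str], float]:
        g, t = self.group, self.timepoint
        if self.kind == "diff_in_changes":
            return {(g, t): 1.0, (g, "Pre"): -1.0, ("CON", t): -1.0, ("CON", "Pre"): 1.0}
        if self.kind == "group_specific":
            return {(g, t): 1.0, (g, "Pre"): -1.0}
        return {("EE", t): 1.0, ("EE", "Pre"): -1.0, ("RE", t): -1.0, ("RE", "Pre"): 1.0}

    def label(self) -> str:
        return f"{self.kind}:{self.group}:{self.timepoint}"


def default_contrasts(
    samples: pd.DataFrame, kinds: tuple[str, ...] = ("diff_in_changes",)
) -> list[ContrastSpec]:
    """All estimable contrasts of the requested kinds for one tissue's samples."""
    out = []
    tps = [t for t in TIMEPOINTS if t in set(samples["timepoint"]) and t != "Pre"]
    for kind in kinds:
        for tp in tps:
            if kind == "ee_vs_re":
                if tp in DURING_CODES:
                    continue  # no blood during resistance bouts
                out.append(ContrastSpec(kind, "EE", tp))
            else:
                for g in ("EE", "RE"):
                    if tp in DURING_CODES and g == "RE":
                        continue
                    out.append(ContrastSpec(kind, g, tp))
                if kind == "group_specific":
                    out.append(ContrastSpec(kind, "CON", tp))
    return out


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------


def build_design(
    samples: pd.DataFrame, spec: ModelSpec = ModelSpec()
) -> tuple[np.ndarray, list[str], dict[tuple[str, str], int], np.ndarray]:
    """Cell-means design matrix for one tissue's sample table.

    Returns (X, column names, cell -> column index map, participant codes).
    Continuous covariates are centered; categorical covariates enter as
    treatment-coded indicator blocks so the cell-mean columns stay
    interpretable as adjusted cell means.
    """
    cells = (
        samples[["group", "timepoint"]]
        .drop_duplicates()
        .sort_values(["group", "timepoint"])
    )
    cell_keys = [tuple(r) for r in cells.to_numpy()]
    cell_index = {key: j for j, key in enumerate(cell_keys)}
    n = len(samples)
    X_cells = np.zeros((n, len(cell_keys)))
    for i, (g, t) in enumerate(zip(samples["group"], samples["timepoint"])):
        X_cells[i, cell_index[(g, t)]] = 1.0
    names = [f"{g}:{t}" for g, t in cell_keys]

    cov_cols = []
    for cov in spec.covariates:
        if cov not in samples.columns:
            continue
        col = samples[cov]
        if col.dtype == object or str(col.dtype) == "category":
            levels = sorted(col.unique())
            for lev in levels[1:]:
                cov_cols.append((f"{cov}[{lev}]", (col == lev).to_numpy(float)))
        else:
            v = col.to_numpy(float)
            cov_cols.append((cov, v - v.mean()))
    if cov_cols:
        X = np.column_stack([X_cells] + [c for _, c in cov_cols])
        names = names + [n_ for n_, _ in cov_cols]
    else:
        X = X_cells
    codes, _ = pd.factorize(samples["participant"])
    return X, names, cell_index, codes


# ---------------------------------------------------------------------------
# eligibility
# ---------------------------------------------------------------------------


def check_eligibility(
    samples: pd.DataFrame,
    observed: pd.Series | None = None,
    contrasts: list[ContrastSpec] | None = None,
    min_paired: int = 3,
) -> dict[str, int]:
    """Eligible contrasts for one feature, by the paired-participant floor.

    A contrast is eligible iff every group it involves has at least
    ``min_paired`` participants with both the pre-exercise and the target
    timepoint observed for this feature. ``observed`` is a boolean Series over
    sample ids (``participant:timepoint``); None means fully observed. Returns
    ``{contrast label: min paired count over involved groups}`` for the
    eligible subset.
    """
    if contrasts is None:
        contrasts = default_contrasts(samples)
    tab = samples[["participant", "group", "timepoint"]].copy()
    if observed is not None:
        ids = tab["participant"] + ":" + tab["timepoint"]
        tab = tab[ids.map(observed).fillna(False).to_numpy(bool)]
    have = tab.groupby(["group", "participant"])["timepoint"].agg(set)
    out: dict[str, int] = {}
    for c in contrasts:
        groups = sorted({g for g, _ in c.cell_weights()})
        counts = []
        for g in groups:
            if g not in have.index.get_level_values(0):
                counts.append(0)
                continue
            sets = have.loc[g]
            counts.append(
                int(sum(1 for s in sets if "Pre" in s and c.timepoint in s))
            )
        if min(counts) >= min_paired:
            out[c.label()] = min(counts)
    return out


# ---------------------------------------------------------------------------
# fitting and testing
# ---------------------------------------------------------------------------


def fit_feature(
    y: np.ndarray,
    samples: pd.DataFrame,
    spec: ModelSpec = ModelSpec(),
    weights: np.ndarray | None = None,
) -> tuple[RandomInterceptFit, dict[tuple[str, str], int], list[str]]:
    """REML fit of the cell-means random-intercept model for one feature.

    NaNs in ``y`` drop the corresponding rows (and the design is rebuilt on
    the observed subset).
    """
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(y)
    sub = samples.loc[mask].reset_index(drop=True)
    X, names, cell_index, codes = build_design(sub, spec)
    w = None if weights is None else np.asarray(weights, float)[mask]
    fit = fit_random_intercept(y[mask], X, codes, weights=w, column_names=names)
    return fit, cell_index, names


def test_contrast(
    fit: RandomInterceptFit,
    cell_index: dict[tuple[str, str], int],
    contrast: ContrastSpec,
) -> dict:
    """Evaluate one cell-means contrast on a fitted model."""
    weights = contrast.cell_weights()
    missing = [cell for cell in weights if cell not in cell_index]
    if missing:
        raise ValueError(f"contrast {contrast.label()} inestimable; missing cells {missing}")
    c = np.zeros(len(fit.beta))
    for cell, wgt in weights.items():
        c[cell_index[cell]] = wgt
    return fit.contrast(c)


def run_da(
    matrix: pd.DataFrame,
    samples: pd.DataFrame,
    contrasts: list[ContrastSpec] | None = None,
    spec: ModelSpec = ModelSpec(),
    weights: pd.DataFrame | None = None,
    min_paired: int = 3,
    adjust: bool = True,
) -> pd.DataFrame:
    """Differential analysis of a features-by-samples matrix for one tissue-ome.

    ``matrix`` columns must be ``participant:timepoint`` sample ids matching
    ``samples``. Returns one row per feature x eligible contrast with BH
    adjustment within each (contrast kind, group, timepoint) stratum.
    """
    samples = samples.reset_index(drop=True)
    ids = (samples["participant"] + ":" + samples["timepoint"]).to_numpy()
    missing_cols = [c for c in matrix.columns if c not in set(ids)]
    if missing_cols:
        raise ValueError(f"matrix columns not in sample table: {missing_cols[:5]}")
    aligned = matrix.loc[:, ids]
    if contrasts is None:
        contrasts = default_contrasts(samples)

    rows = []
    for feat, y in aligned.iterrows():
        yv = y.to_numpy(float)
        obs = pd.Series(np.isfinite(yv), index=ids)
        eligible = check_eligibility(samples, obs, contrasts, min_paired)
        if not eligible:
            continue
        w = None if weights is None else weights.loc[feat, ids].to_numpy(float)
        try:
            fit, cell_index, _ = fit_feature(yv, samples, spec, w)
        except SingularDesignError:
            continue
        for c in contrasts:
            if c.label() not in eligible:
                continue
            try:
                res = test_contrast(fit, cell_index, c)
            except ValueError:
                continue
            rows.append(
                (
                    feat,
                    c.kind,
                    c.group,
                    c.timepoint,
                    res["estimate"],
                    res["se"],
                    res["t"],
                    res["df"],
                    res["p"],
                    np.nan,
                    eligible[c.label()],
                )
            )
    out = pd.DataFrame(rows, columns=DA_COLUMNS)
    if adjust and not out.empty:
        out = adjust_fdr(out)
    return out


def adjust_fdr(
    results: pd.DataFrame,
    stratum: tuple[str, ...] = ("contrast", "group", "timepoint"),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Benjamini-Hochberg adjustment within each stratum of the results table.

    The default stratum corresponds to one unique contrast-group-timepoint
    combination per tissue-ome table (tissue and ome being fixed within one
    table).
    """
    out = results.copy()
    cols = [c for c in stratum if c in out.columns]
    for _, idx in out.groupby(cols, dropna=False).groups.items():
        p = out.loc[idx, "p"].to_numpy(float)
        out.loc[idx, "adj_p"] = multipletests(p, alpha=alpha, method="fdr_bh")[1]
    return out


def classify_response(
    feature_results: pd.DataFrame, group: str, timepoint: str, alpha: float = 0.05
) -> str:
    """Classify one feature's response at one (group, timepoint).

    Declared rule: ``exercise_effect`` = significant difference-in-changes
    with a significant within-exercise-group change; ``control_driven`` =
    significant difference-in-changes without a within-exercise change (the
    signal is carried by the control arm); ``non_exercise_change`` = a
    within-group change (control and/or exercise) without a significant
    difference-in-changes; ``none`` otherwise. Returns ``unclassifiable``
    when a needed contrast is absent.
    """

    def _sig(kind: str, g: str) -> bool | None:
        m = feature_results[
            (feature_results["contrast"] == kind)
            & (feature_results["group"] == g)
            & (feature_results["timepoint"] == timepoint)
        ]
        if m.empty:
            return None
        return bool(m["adj_p"].iloc[0] < alpha)

    dd = _sig("diff_in_changes", group)
    wg = _sig("group_specific", group)
    con = _sig("group_specific", "CON")
    if dd is None or wg is None or con is None:
        return "unclassifiable"
    if dd and wg:
        return "exercise_effect"
    if dd and not wg:
        return "control_driven"
    if not dd and (wg or con):
        return "non_exercise_change"
    return "none"


# ---------------------------------------------------------------------------
# variance decomposition and PC-covariate association
# ---------------------------------------------------------------------------


def variance_explained(
    y: np.ndarray, covariates: pd.DataFrame, order: list[str] | None = None
) -> pd.Series:
    """Fraction of variance attributed to each covariate plus residual.

    Sequential (type-I) decomposition of the total sum of squares over the
    covariate blocks in ``order`` (categorical columns expand to indicator
    blocks); fractions are non-negative and sum to one with the residual.
    """
    y = np.asarray(y, float)
    yc = y - y.mean()
    ss_total = float(yc @ yc)
    if ss_total == 0:
        raise ValueError("response is constant")
    names = order or list(covariates.columns)
    n = len(y)
    Q_prev = np.ones((n, 1)) / np.sqrt(n)
    fractions = {}
    resid = yc.copy()
    for name in names:
        col = covariates[name]
        if col.dtype == object or str(col.dtype) == "category":
            block = pd.get_dummies(col, drop_first=True).to_numpy(float)
        else:
            block = col.to_numpy(float)[:, None]
        # residualize the block against everything already fitted
        block = block - Q_prev @ (Q_prev.T @ block)
        q, r = np.linalg.qr(block)
        keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(r).max())
        q = q[:, keep]
        if q.shape[1] == 0 and block.shape[1] > 0:
            raise ValueError(f"covariate {name!r} is collinear with earlier terms")
        proj = q @ (q.T @ resid)
        fractions[name] = float(proj @ proj) / ss_total
        resid = resid - proj
        Q_prev = np.column_stack([Q_prev, q])
    fractions["residual"] = float(resid @ resid) / ss_total
    return pd.Series(fractions)


def pc_covariate_association(
    matrix: pd.DataFrame, covariates: pd.DataFrame, n_pcs: int = 5
) -> pd.DataFrame:
    """Canonical correlation of the first principal components with covariates.

    PCs are computed over samples (columns of the features-by-samples
    matrix). For a single PC against a covariate block the canonical
    correlation equals the square root of the regression R^2. Constant
    covariates get correlation 0.
    """
    X = matrix.to_numpy(float).T  # samples x features
    X = X - X.mean(axis=0)
    rank = np.linalg.matrix_rank(X)
    if n_pcs > rank:
        raise ValueError(f"requested {n_pcs} PCs but matrix rank is {rank}")
    _, _, vt = np.linalg.svd(X, full_matrices=False)
    scores = X @ vt[:n_pcs].T
    out = np.zeros((n_pcs, covariates.shape[1]))
    for j, name in enumerate(covariates.columns):
        col = covariates[name]
        if col.dtype == object or str(col.dtype) == "category":
            block = pd.get_dummies(col, drop_first=True).to_numpy(float)
        else:
            block = col.to_numpy(float)[:, None]
        if block.size == 0 or np.allclose(block.std(axis=0), 0):
            continue
        B = np.column_stack([np.ones(len(col)), block])
        for i in range(n_pcs):
            pc = scores[:, i]
            coef, *_ = np.linalg.lstsq(B, pc, rcond=None)
            fitted = B @ coef
            sst = float(((pc - pc.mean()) ** 2).sum())
            ssr = float(((fitted - pc.mean()) ** 2).sum())
            out[i, j] = np.sqrt(max(min(ssr / sst, 1.0), 0.0)) if sst > 0 else 0.0
    return pd.DataFrame(
        out,
        index=[f"PC{i + 1}" for i in range(n_pcs)],
        columns=list(covariates.columns),
    )
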