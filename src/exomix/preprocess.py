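"""Per-ome normalization, filtering, imputation, outlier and batch rules.

Implements the preprocessing conventions of the analysis: CPM-based low-count
filtering and trimmed-mean-of-M-values (TMM) scaling for count omes with
voom-style precision weights; median centering and a quantification-rate
filter for proteomics; missingness filtering, kNN / half-minimum imputation,
log transform and (conditional) median-MAD scaling for metabolomics;
boxplot-rule PCA outlier flagging; and batch regression with a protected
design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.impute import KNNImputer
from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess

__all__ = [
    "NormalizedMatrix",
    "OutlierReport",
    "cpm",
    "filter_low_counts",
    "tmm_factors",
    "voom_weights",
    "proteomics_prepare",
    "metabolomics_prepare",
    "resolve_redundant_metabolites",
    "pca_outliers",
    "remove_batch_effects",
]

MAD_SCALE = 1.4826  # consistency factor for Gaussian data


@dataclass
class NormalizedMatrix:
    """Normalized values plus provenance of the steps that produced them."""

    values: pd.DataFrame
    scale_factors: pd.Series | None = None
    weights: pd.DataFrame | None = None
    log: list[dict] = field(default_factory=list)

    def record(self, step: str, **params) -> None:
        self.log.append({"step": step, **params})


@dataclass
class OutlierReport:
    flagged: list[str]
    pc_index: dict[str, int]
    multiplier: float


# ---------------------------------------------------------------------------
# count omes
# ---------------------------------------------------------------------------


def cpm(counts: pd.DataFrame, log: bool = False, prior: float = 0.5) -> pd.DataFrame:
    """Counts per million; ``log=True`` gives log2 CPM with a prior count."""
    lib = counts.sum(axis=0)
    bad = lib[lib == 0]
    if len(bad):
        raise ValueError(f"samples with zero total counts: {list(bad.index)}")
    if log:
        # edgeR-style prior scaled by relative library size
        pr = prior * lib / lib.mean()
        return np.log2((counts + pr) / (lib + 2 * pr) * 1e6)
    return counts / lib * 1e6


def filter_low_counts(
    counts: pd.DataFrame, cpm_threshold: float = 0.5, sample_fraction: float = 0.10
) -> pd.Index:
    """Features expressed above ``cpm_threshold`` CPM in >= ``sample_fraction`` of samples.

    Returns the retained feature index (keep-if-expressed direction).
    """
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    frac = (cpm(counts) > cpm_threshold).mean(axis=1)
    return counts.index[frac >= sample_fraction]


def tmm_factors(
    counts: pd.DataFrame,
    trim_M: float = 0.30,
    trim_A: float = 0.05,
    ref: str | None = None,
) -> pd.Series:
    """Trimmed mean of M-values scaling factors (geometric mean 1).

    The reference sample is the one whose 75th-percentile of CPM is closest
    to the mean across samples. For each sample, the factor is the
    precision-weighted mean of gene-wise log-ratios (M) against the
    reference after doubly trimming by M (``trim_M`` each tail) and by
    average abundance A (``trim_A`` each tail). All-zero features are
    ignored; effective library sizes are ``lib_size * factor``.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM requires at least two samples")
    y = counts.to_numpy(float)
    lib = y.sum(axis=0)
    if (lib == 0).any():
        bad = list(counts.columns[lib == 0])
        raise ValueError(f"samples with no positive counts: {bad}")
    y = y[y.sum(axis=1) > 0]  # drop all-zero rows
    if ref is None:
        f75 = np.array(
            [np.quantile(y[:, j] / lib[j], 0.75) for j in range(y.shape[1])]
        )
        ref_j = int(np.argmin(np.abs(f75 - f75.mean())))
    else:
        ref_j = list(counts.columns).index(ref)
    yr, lr = y[:, ref_j], lib[ref_j]

    factors = np.ones(y.shape[1])
    for j in range(y.shape[1]):
        if j == ref_j:
            factors[j] = 1.0
            continue
        ys, ls = y[:, j], lib[j]
        ok = (ys > 0) & (yr > 0)
        if not ok.any():
            factors[j] = 1.0
            continue
        M = np.log2((ys[ok] / ls) / (yr[ok] / lr))
        A = 0.5 * np.log2((ys[ok] / ls) * (yr[ok] / lr))
        w = 1.0 / ((ls - ys[ok]) / (ls * ys[ok]) + (lr - yr[ok]) / (lr * yr[ok]))
        n = len(M)
        loM = np.floor(n * trim_M) + 1
        hiM = n + 1 - loM
        loA = np.floor(n * trim_A) + 1
        hiA = n + 1 - loA
        rM = stats.rankdata(M)
        rA = stats.rankdata(A)
        keep = (rM >= loM) & (rM <= hiM) & (rA >= loA) & (rA <= hiA)
        if not keep.any() or np.max(np.abs(M)) < 1e-6:
            factors[j] = 1.0
            continue
        factors[j] = 2.0 ** (np.sum(w[keep] * M[keep]) / np.sum(w[keep]))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def voom_weights(
    logcpm: pd.DataFrame, design: np.ndarray, span: float = 0.5
) -> pd.DataFrame:
    """Precision weights from the empirical mean-variance trend of log-counts.

    Per-feature residual standard deviations from an OLS fit of ``design``
    are square-root transformed and smoothed (lowess) against mean
    log-abundance; each observation's weight is the predicted trend at its
    fitted value, raised to the power -4.
    """
    if logcpm.shape[0] < 10:
        raise ValueError("too few features to fit a mean-variance trend")
    X = np.atleast_2d(np.asarray(design, float))
    Y = logcpm.to_numpy(float)
    n, p = X.shape
    if n != Y.shape[1]:
        raise ValueError("design rows must match samples")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is not full rank")
    pinv = np.linalg.pinv(X)
    B = Y @ pinv.T  # features x p
    fitted = B @ X.T
    resid = Y - fitted
    sd = np.sqrt((resid**2).sum(axis=1) / (n - p))
    mean_y = Y.mean(axis=1)
    sqrt_sd = np.sqrt(sd)
    trend = sm_lowess(sqrt_sd, mean_y, frac=span, return_sorted=True)
    tx, ty = trend[:, 0], np.maximum(trend[:, 1], 1e-6)
    pred = np.interp(fitted, tx, ty)
    w = pred**-4.0
    return pd.DataFrame(w, index=logcpm.index, columns=logcpm.columns)


# ---------------------------------------------------------------------------
# proteomics
# ---------------------------------------------------------------------------


def proteomics_prepare(
    log_ratios: pd.DataFrame, min_quant_fraction: float = 0.30
) -> NormalizedMatrix:
    """Median-center each sample to zero; drop sparsely quantified features.

    Features quantified in fewer than ``min_quant_fraction`` of samples are
    removed (the boundary, exactly 30%, is retained). Missing values remain
    missing.
    """
    fully_missing = log_ratios.columns[log_ratios.isna().all(axis=0)]
    if len(fully_missing):
        raise ValueError(f"samples with no quantified features: {list(fully_missing)}")
    quant = log_ratios.notna().mean(axis=1)
    kept = log_ratios.loc[quant >= min_quant_fraction]
    centered = kept - kept.median(axis=0, skipna=True)
    nm = NormalizedMatrix(values=centered)
    nm.record(
        "proteomics_prepare",
        min_quant_fraction=min_quant_fraction,
        n_removed=int((quant < min_quant_fraction).sum()),
    )
    return nm


# ---------------------------------------------------------------------------
# metabolomics
# ---------------------------------------------------------------------------


def _kw_pvalue(values: np.ndarray, labels: pd.Series) -> float:
    groups = [values[np.asarray(labels) == lev] for lev in pd.unique(labels)]
    groups = [g for g in groups if len(g) > 0]
    if len(groups) < 2:
        return 1.0
    return float(stats.kruskal(*groups).pvalue)


def metabolomics_prepare(
    matrix: pd.DataFrame,
    max_missing_fraction: float = 0.20,
    knn_k: int = 10,
    knn_min_features: int = 12,
    sex: pd.Series | None = None,
    group: pd.Series | None = None,
    kw_alpha: float = 0.01,
) -> NormalizedMatrix:
    """Metabolomics filtering, imputation and log transform.

    Steps, in order: average duplicate metabolite ids; set values <= 0 to
    missing; drop features with more than ``max_missing_fraction`` missing
    (strict >); impute by kNN when more than ``knn_min_features`` features
    remain, otherwise by half the feature minimum; transform ``log2(x + 1)``;
    then apply median-MAD sample scaling only if neither sample medians nor
    upper quartiles associate with sex or sex-stratified group
    (Kruskal-Wallis p < ``kw_alpha``).
    """
    nm_log: list[dict] = []
    m = matrix.groupby(level=0).mean()
    if m.shape[0] != matrix.shape[0]:
        nm_log.append({"step": "average_duplicates", "n_merged": matrix.shape[0] - m.shape[0]})
    m = m.mask(m <= 0)
    if m.isna().all(axis=None):
        raise ValueError("all features missing after nonpositive-value masking")
    miss = m.isna().mean(axis=1)
    m = m.loc[miss <= max_missing_fraction]
    if m.empty:
        raise ValueError("all features removed by the missingness filter")
    nm_log.append({"step": "missingness_filter", "n_removed": int((miss > max_missing_fraction).sum())})

    if m.isna().any(axis=None):
        if m.shape[0] > knn_min_features:
            imputer = KNNImputer(n_neighbors=min(knn_k, m.shape[0] - 1))
            imputed = imputer.fit_transform(m.to_numpy(float).T).T  # impute over feature vectors
            m = pd.DataFrame(imputed, index=m.index, columns=m.columns)
            nm_log.append({"step": "knn_impute", "k": knn_k})
        else:
            half_min = m.min(axis=1, skipna=True) / 2.0
            m = m.apply(lambda row: row.fillna(half_min[row.name]), axis=1)
            nm_log.append({"step": "half_min_impute"})

    m = np.log2(m + 1.0)
    nm_log.append({"step": "log2_plus1"})

    do_scale = True
    if sex is not None:
        med = m.median(axis=0).to_numpy()
        uq = m.quantile(0.75, axis=0).to_numpy()
        checks = [_kw_pvalue(med, sex), _kw_pvalue(uq, sex)]
        if group is not None:
            strat = sex.astype(str) + ":" + group.astype(str)
            checks += [_kw_pvalue(med, strat), _kw_pvalue(uq, strat)]
        if min(checks) < kw_alpha:
            do_scale = False
            nm_log.append({"step": "median_mad_scaling_skipped", "min_kw_p": min(checks)})
    if do_scale:
        med = m.median(axis=0)
        mad = MAD_SCALE * (m - med).abs().median(axis=0)
        mad = mad.mask(mad == 0, 1.0)
        m = (m - med) / mad
        nm_log.append({"step": "median_mad_scaling", "mad_scale": MAD_SCALE})
    nm = NormalizedMatrix(values=m)
    nm.log = nm_log
    return nm


def resolve_redundant_metabolites(
    platform_matrices: dict[str, pd.DataFrame],
    reference_cv: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One platform per metabolite id: lowest reference-standard CV wins.

    ``reference_cv`` is platforms x metabolite ids (NaN where a platform has
    no reference-standard CV for that id). Ties break lexicographically by
    platform name; ids with no CV anywhere fall back to the platform with the
    most non-missing measurements. Returns (merged matrix, provenance table).
    """
    all_ids: list[str] = []
    for mat in platform_matrices.values():
        all_ids.extend(i for i in mat.index if i not in all_ids)
    chosen_rows, prov = [], []
    platforms = sorted(platform_matrices)
    for mid in all_ids:
        carrying = [p for p in platforms if mid in platform_matrices[p].index]
        if len(carrying) == 1:
            pick, why = carrying[0], "single_platform"
        else:
            cvs = {
                p: reference_cv.loc[p, mid]
                for p in carrying
                if p in reference_cv.index
                and mid in reference_cv.columns
                and np.isfinite(reference_cv.loc[p, mid])
            }
            if cvs:
                best = min(cvs.values())
                pick = min(p for p, v in cvs.items() if v == best)
                why = "lowest_cv"
            else:
                counts = {p: platform_matrices[p].loc[mid].notna().sum() for p in carrying}
                best = max(counts.values())
                pick = min(p for p, v in counts.items() if v == best)
                why = "most_observed_fallback"
        chosen_rows.append(platform_matrices[pick].loc[mid])
        prov.append((mid, pick, why, [p for p in carrying if p != pick]))
    merged = pd.DataFrame(chosen_rows, index=all_ids)
    provenance = pd.DataFrame(prov, columns=["metabolite", "platform", "rule", "excluded"])
    return merged, provenance


# ---------------------------------------------------------------------------
# outliers and batch
# ---------------------------------------------------------------------------


def pca_outliers(
    matrix: pd.DataFrame, multiplier: float = 5.0, n_pcs: int = 3
) -> OutlierReport:
    """Flag samples whose PC scores fall outside boxplot whiskers.

    A sample is flagged when any of its first ``n_pcs`` principal-component
    scores lies outside ``[Q1 - m*IQR, Q3 + m*IQR]`` of that component's
    score distribution.
    """
    X = matrix.to_numpy(float).T
    if np.isnan(X).any():
        raise ValueError("matrix must be complete (impute first)")
    Xc = X - X.mean(axis=0)
    rank = np.linalg.matrix_rank(Xc)
    if n_pcs > rank:
        raise ValueError(f"requested {n_pcs} PCs but matrix rank is {rank}")
    _, _, vt = np.linalg.svd(Xc, full_matrices=False)
    scores = Xc @ vt[:n_pcs].T
    flagged: list[str] = []
    pc_of: dict[str, int] = {}
    for k in range(n_pcs):
        q1, q3 = np.quantile(scores[:, k], [0.25, 0.75])
        iqr = q3 - q1
        lo, hi = q1 - multiplier * iqr, q3 + multiplier * iqr
        for j, sample in enumerate(matrix.columns):
            if (scores[j, k] < lo or scores[j, k] > hi) and sample not in pc_of:
                flagged.append(sample)
                pc_of[sample] = k + 1
    return OutlierReport(flagged=flagged, pc_index=pc_of, multiplier=multiplier)


def remove_batch_effects(
    matrix: pd.DataFrame,
    batch: pd.Series,
    protected: pd.DataFrame,
) -> pd.DataFrame:
    """Regress out batch from each feature while protecting the design.

    Fits the joint linear model ``[protected | batch indicators]`` per
    feature and subtracts only the batch component (batch indicators
    centered, so protected-effect estimates are unchanged). Refuses when
    batch is collinear with the protected design, mirroring the decision not
    to regress a batch variable confounded with group.
    """
    prot_cols = []
    for name in protected.columns:
        col = protected[name]
        if col.dtype == object or str(col.dtype) == "category":
            prot_cols.append(pd.get_dummies(col, drop_first=True).to_numpy(float))
        else:
            prot_cols.append(col.to_numpy(float)[:, None])
    P = np.column_stack([np.ones(len(batch))] + prot_cols)
    B = pd.get_dummies(batch.astype(str), drop_first=True).to_numpy(float)
    B = B - B.mean(axis=0)
    full = np.column_stack([P, B])
    if np.linalg.matrix_rank(full) < np.linalg.matrix_rank(P) + B.shape[1]:
        raise ValueError(
            "batch is confounded with the protected design; refusing to regress it out"
        )
    Y = matrix.to_numpy(float)
    coef, *_ = np.linalg.lstsq(full, Y.T, rcond=None)
    batch_part = B @ coef[P.shape[1] :]
    return pd.DataFrame(Y - batch_part.T, index=matrix.index, columns=matrix.columns)
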