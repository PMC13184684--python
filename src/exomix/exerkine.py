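"""Secreted-factor (exerkine) candidate funnel.

A candidate exerkine is a gene with differential evidence in a solid tissue
(transcript, protein, or phosphosite) and in circulating plasma protein, both
at BH-adjusted p < 0.1. Matched genes are annotated for directional
concordance (most significant tissue and plasma effects agree in sign),
temporal precedence (earliest significant tissue change at or before the
earliest significant plasma change on the aligned timepoint scale), and an
extracellular compartment score (max over extracellular region / space /
exosome / vesicle, 0-5). Primary candidates require score > 4 and an actual
plasma increase. Gene-program context around an anchor gene uses biweight
midcorrelation fed to the correlation-adjusted competitive set test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .enrichment import EnrichmentResult, camera_pr

__all__ = [
    "align_timepoints",
    "match_candidates",
    "assess_concordance_precedence",
    "extracellular_score",
    "flag_primary",
    "bicor",
    "correlate_gene_programs",
]

EXTRACELLULAR_COMPARTMENTS = (
    "extracellular_region",
    "extracellular_space",
    "extracellular_exosome",
    "extracellular_vesicle",
)

# Ordinal alignment of the normalized timepoint vocabulary across tissues:
# plasma during-exercise draws precede all post-exercise ranks; the early
# collections (15/30/45 min depending on tissue) share one rank, as do the
# intermediate (3.5/4 h) and late (24 h) collections.
_TIMEPOINT_RANK = {
    "Pre": 0,
    "D20M": 1,
    "D40M": 2,
    "P10M": 3,
    "PEarly": 4,
    "PMid": 5,
    "PLate": 6,
}


def align_timepoints(codes: list[str] | pd.Series) -> pd.Series:
    """Map normalized timepoint codes to their ordinal cross-tissue rank."""
    out = []
    for c in codes:
        if c not in _TIMEPOINT_RANK:
            raise ValueError(f"unknown timepoint code {c!r}")
        out.append(_TIMEPOINT_RANK[c])
    return pd.Series(out, index=list(codes), name="rank")


def match_candidates(
    tissue_da: pd.DataFrame,
    plasma_da: pd.DataFrame,
    feature_to_gene: dict[str, str],
    alpha: float = 0.1,
) -> pd.DataFrame:
    """Genes with tissue and plasma differential evidence at adj_p < alpha.

    ``tissue_da`` / ``plasma_da`` are DA tables (one or more concatenated)
    with feature, timepoint, estimate, adj_p columns. Features without a
    gene mapping are skipped (count recorded in ``.attrs['n_unmapped']``).
    Returns one row per (gene, side, timepoint) significant effect for
    matched genes.
    """
    frames = []
    n_unmapped = 0
    for side, da in (("tissue", tissue_da), ("plasma", plasma_da)):
        d = da.copy()
        genes = d["feature"].map(feature_to_gene)
        n_unmapped += int(genes.isna().sum())
        d["gene"] = genes
        d = d.dropna(subset=["gene"])
        d = d[d["adj_p"] < alpha]
        d["side"] = side
        frames.append(d[["gene", "side", "timepoint", "estimate", "adj_p"]])
    evidence = pd.concat(frames, ignore_index=True)
    t_genes = set(evidence.loc[evidence["side"] == "tissue", "gene"])
    p_genes = set(evidence.loc[evidence["side"] == "plasma", "gene"])
    matched = t_genes & p_genes
    out = evidence[evidence["gene"].isin(matched)].reset_index(drop=True)
    out.attrs["n_unmapped"] = n_unmapped
    return out


def assess_concordance_precedence(matched: pd.DataFrame) -> pd.DataFrame:
    """Per-gene concordance and precedence flags plus summary fractions.

    Concordance: the sign of the most significant tissue effect agrees with
    the sign of the most significant plasma effect. Precedence: the earliest
    significant tissue timepoint rank is <= the earliest significant plasma
    rank. Summary fractions over matched genes are stored in ``.attrs``.
    """
    rows = []
    for gene, sub in matched.groupby("gene", sort=True):
        t = sub[sub["side"] == "tissue"]
        p = sub[sub["side"] == "plasma"]
        t_best = t.loc[t["adj_p"].idxmin()]
        p_best = p.loc[p["adj_p"].idxmin()]
        concordant = bool(np.sign(t_best["estimate"]) == np.sign(p_best["estimate"]))
        t_rank = min(_TIMEPOINT_RANK[tp] for tp in t["timepoint"])
        p_rank = min(_TIMEPOINT_RANK[tp] for tp in p["timepoint"])
        plasma_up = bool((p["estimate"] > 0).any())
        rows.append(
            {
                "gene": gene,
                "concordant": concordant,
                "precedent": t_rank <= p_rank,
                "plasma_increase": plasma_up,
                "tissue_direction": float(np.sign(t_best["estimate"])),
                "plasma_direction": float(np.sign(p_best["estimate"])),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out.attrs["fraction_concordant"] = float(out["concordant"].mean())
        out.attrs["fraction_precedent"] = float(out["precedent"].mean())
    return out


def extracellular_score(gene: str, compartments: pd.DataFrame) -> float:
    """Max score over the four extracellular compartments; absent gene -> 0."""
    if gene not in compartments.index:
        return 0.0
    row = compartments.loc[gene]
    cols = [c for c in EXTRACELLULAR_COMPARTMENTS if c in row.index]
    return float(row[cols].max()) if cols else 0.0


def flag_primary(
    candidates: pd.DataFrame,
    compartments: pd.DataFrame,
    min_score: float = 4.0,
) -> pd.DataFrame:
    """Primary-candidate flag: extracellular score strictly > ``min_score`` and plasma increase."""
    out = candidates.copy()
    out["extracellular_score"] = [
        extracellular_score(g, compartments) for g in out["gene"]
    ]
    out["primary"] = (out["extracellular_score"] > min_score) & out["plasma_increase"]
    return out


def bicor(x: np.ndarray, y: np.ndarray) -> float:
    """Biweight midcorrelation (Tukey biweights around the median).

    ``u_i = (x_i - med x) / (9 MAD_x)``; weights ``(1 - u^2)^2`` inside
    ``|u| < 1`` and zero outside. Falls back to Pearson when either MAD is
    zero.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need at least 3 paired finite values")

    def _weights(v: np.ndarray) -> tuple[np.ndarray, np.ndarray] | None:
        med = np.median(v)
        mad = np.median(np.abs(v - med))
        if mad == 0:
            return None
        u = (v - med) / (9.0 * mad)
        w = (1 - u**2) ** 2 * (np.abs(u) < 1)
        return v - med, w

    wx, wy = _weights(x), _weights(y)
    if wx is None or wy is None:
        # zero MAD: fall back to Pearson
        sx, sy = x.std(), y.std()
        if sx == 0 or sy == 0:
            return 0.0
        return float(np.corrcoef(x, y)[0, 1])
    dx, ax = wx
    dy, ay = wy
    num = np.sum(dx * ax * dy * ay)
    den = np.sqrt(np.sum((dx * ax) ** 2)) * np.sqrt(np.sum((dy * ay) ** 2))
    if den == 0:
        return 0.0
    return float(num / den)


def correlate_gene_programs(
    expr: pd.DataFrame,
    anchor: str,
    collections: dict[str, list[str]],
    rho: float = 0.01,
) -> pd.DataFrame:
    """Set enrichment of z-scaled bicor against an anchor gene's expression.

    Computes the biweight midcorrelation of the anchor with every other gene
    (rows of ``expr``), standardizes the correlations across genes, and runs
    the parametric correlation-adjusted competitive test per set.
    """
    if anchor not in expr.index:
        raise ValueError(f"anchor {anchor!r} not in expression matrix")
    a = expr.loc[anchor].to_numpy(float)
    if np.nanstd(a) == 0:
        raise ValueError("anchor expression is constant")
    genes = [g for g in expr.index if g != anchor]
    cors = pd.Series(
        [bicor(a, expr.loc[g].to_numpy(float)) for g in genes], index=genes
    )
    z = (cors - cors.mean()) / cors.std(ddof=1)
    rows: list[EnrichmentResult] = []
    for name, members in collections.items():
        present = [m for m in members if m in z.index]
        if len(present) < 2 or len(z) < len(present) + 2:
            continue
        rows.append(camera_pr(z, present, rho=rho, set_name=name))
    return pd.DataFrame([r.as_dict() for r in rows])
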