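"""Synthetic acute-exercise cohorts and omic matrices with planted ground truth.

The generator emulates a three-arm (endurance / resistance / non-exercise
control) acute-exercise study sampled in three tissues at tissue-specific
timepoints, with participants randomized both to an intervention arm and to a
*temporal profile* that determines which post-exercise timepoints are
collected. Molecular values decompose into a participant random intercept, a
within-participant correlated non-normal residual (Fleishman third-order
polynomials combined through Vale-Maurelli intermediate correlations), and
planted fixed exercise effects expressed on the difference-in-changes scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "DesignConfig",
    "EffectSpec",
    "MomentTarget",
    "TruthBundle",
    "fleishman_coefficients",
    "intermediate_correlation",
    "simulate_cohort",
    "simulate_ome",
    "simulate_genesets",
    "simulate_exerkines",
    "child_rng",
]

# Normalized timepoint vocabulary. D* codes are during-exercise blood draws,
# P10M is the immediately-post blood draw, PEarly/PMid/PLate are the
# tissue-specific early (15/30/45 min), intermediate (3.5/4 h) and late (24 h)
# post-exercise collections.
TIMEPOINTS = ("Pre", "D20M", "D40M", "P10M", "PEarly", "PMid", "PLate")
PROFILE_RANKS = ("PEarly", "PMid", "PLate")
DURING_CODES = ("D20M", "D40M")

DEFAULT_TISSUE_TIMEPOINTS: dict[str, tuple[str, ...]] = {
    "muscle": ("Pre", "PEarly", "PMid", "PLate"),
    "adipose": ("Pre", "PEarly", "PMid", "PLate"),
    "blood": ("Pre", "D20M", "D40M", "P10M", "PEarly", "PMid", "PLate"),
}

DEFAULT_PROFILES: dict[str, tuple[str, ...]] = {
    "all": ("PEarly", "PMid", "PLate"),
    "early": ("PEarly",),
    "middle": ("PMid",),
    "late": ("PLate",),
}

# Minute mapping of the rank codes per tissue (documentation + plotting only).
TISSUE_MINUTES = {
    "muscle": {"PEarly": 15, "PMid": 210, "PLate": 1440},
    "blood": {"PEarly": 30, "PMid": 210, "PLate": 1440},
    "adipose": {"PEarly": 45, "PMid": 240, "PLate": 1440},
}

GROUPS = ("EE", "RE", "CON")


class InadmissibleMomentsError(ValueError):
    """Raised when a (skewness, excess kurtosis) pair admits no Fleishman solution."""


def child_rng(seed: int, *key: int) -> np.random.Generator:
    """Derive a child generator from a master seed and an integer counter key.

    The documented scheme: ``SeedSequence(seed, spawn_key=key)``; the same
    (seed, key) pair always yields the same stream.
    """
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


# ---------------------------------------------------------------------------
# design / effect / moment specifications
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DesignConfig:
    """Cohort design: arm sizes, tissue timepoints, temporal profiles, covariates.

    Defaults mirror the enrolled acute cohort: 65/73/37 participants in
    EE/RE/CON (an approximate 8:8:3 randomization), three tissues with
    tissue-specific timepoints, and equal randomization over the four
    temporal profiles.
    """

    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"EE": 65, "RE": 73, "CON": 37}
    )
    tissue_timepoints: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_TISSUE_TIMEPOINTS)
    )
    temporal_profiles: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_PROFILES)
    )
    profile_weights: dict[str, float] | None = None
    age_range: tuple[float, float] = (20.0, 65.0)
    female_fraction: float = 0.72
    bmi_mean_sd: tuple[float, float] = (26.9, 4.0)
    n_sites: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        for g, n in self.n_per_group.items():
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r}")
            if n < 1:
                raise ValueError(f"group {g!r} must have at least one participant")
        for tissue, tps in self.tissue_timepoints.items():
            if "Pre" not in tps:
                raise ValueError(f"tissue {tissue!r} lacks a pre-exercise timepoint")
            unknown = set(tps) - set(TIMEPOINTS)
            if unknown:
                raise ValueError(f"tissue {tissue!r}: unknown timepoints {unknown}")
        post = set().union(*(set(tp) for tp in self.tissue_timepoints.values()))
        for label, ranks in self.temporal_profiles.items():
            if not set(ranks) <= post:
                raise ValueError(f"profile {label!r} not a subset of design timepoints")


@dataclass
class EffectSpec:
    """Planted fixed effects on the difference-in-changes (log) scale.

    ``effects[feature][(group, timepoint)]`` is the population shift of that
    exercise group at that timepoint relative to the control-group change.
    Control-group and pre-exercise entries must be absent (identically zero).
    """

    effects: dict[str, dict[tuple[str, str], float]] = field(default_factory=dict)
    trajectory: dict[str, str] = field(default_factory=dict)
    modality: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for feat, cells in self.effects.items():
            for (group, tp), delta in cells.items():
                if group == "CON" and delta != 0:
                    raise ValueError(f"{feat}: control-group effects must be zero")
                if tp == "Pre" and delta != 0:
                    raise ValueError(f"{feat}: pre-exercise effects must be zero")

    def delta(self, feature: str, group: str, timepoint: str) -> float:
        return self.effects.get(feature, {}).get((group, timepoint), 0.0)

    @property
    def features(self) -> list[str]:
        return list(self.effects)


@dataclass(frozen=True)
class MomentTarget:
    """Target marginal moments and dependence for one ome's residual process."""

    mean: float = 0.0
    variance: float = 1.0
    skewness: float = 0.0
    excess_kurtosis: float = 0.0
    timepoint_corr: np.ndarray | None = None  # within-participant residual corr
    icc: float = 0.5

    def __post_init__(self) -> None:
        if self.variance <= 0:
            raise ValueError("variance must be positive")
        if not 0.0 <= self.icc <= 1.0:
            raise ValueError("ICC must lie in [0, 1]")
        if self.excess_kurtosis < self.skewness**2 - 2:
            raise InadmissibleMomentsError(
                "excess kurtosis must satisfy gamma2 >= gamma1^2 - 2"
            )
        if self.timepoint_corr is not None:
            r = np.asarray(self.timepoint_corr, dtype=float)
            if not np.allclose(r, r.T, atol=1e-10):
                raise ValueError("timepoint correlation must be symmetric")
            if np.min(np.linalg.eigvalsh(r)) < -1e-8:
                raise ValueError("timepoint correlation must be PSD")


@dataclass
class TruthBundle:
    """Ground-truth annotations accompanying one simulated matrix."""

    effects: EffectSpec
    planted_sets: list[str] = field(default_factory=list)
    exerkines: pd.DataFrame | None = None

    def to_json_dict(self) -> dict:
        out = {
            "effects": {
                f: {f"{g}|{t}": d for (g, t), d in cells.items()}
                for f, cells in self.effects.effects.items()
            },
            "planted_sets": list(self.planted_sets),
        }
        if self.exerkines is not None:
            out["exerkines"] = self.exerkines.to_dict(orient="records")
        return out


# ---------------------------------------------------------------------------
# Fleishman / Vale-Maurelli machinery
# ---------------------------------------------------------------------------


def _fleishman_system(x: np.ndarray, g1: float, g2: float) -> np.ndarray:
    b, c, d = x
    f1 = b**2 + 6 * b * d + 2 * c**2 + 15 * d**2 - 1.0
    f2 = 2 * c * (b**2 + 24 * b * d + 105 * d**2 + 2) - g1
    f3 = (
        24
        * (
            b * d
            + c**2 * (1 + b**2 + 28 * b * d)
            + d**2 * (12 + 48 * b * d + 141 * c**2 + 225 * d**2)
        )
        - g2
    )
    return np.array([f1, f2, f3])


def fleishman_coefficients(
    skewness: float, excess_kurtosis: float, tol: float = 1e-8
) -> tuple[float, float, float, float]:
    """Power-method polynomial coefficients (a, b, c, d) with ``a = -c``.

    ``Y = a + bZ + cZ^2 + dZ^3`` with standard-normal ``Z`` then has mean 0,
    variance 1, the requested skewness and excess kurtosis. Raises
    :class:`InadmissibleMomentsError` when the pair lies outside the
    admissible region (``gamma2 >= gamma1^2 - 2`` is necessary) or the moment
    system does not converge.
    """
    g1, g2 = float(skewness), float(excess_kurtosis)
    if g2 < g1**2 - 2:
        raise InadmissibleMomentsError(
            f"(skewness={g1}, excess kurtosis={g2}) violates gamma2 >= gamma1^2 - 2"
        )
    if g1 == 0.0 and g2 == 0.0:
        return (0.0, 1.0, 0.0, 0.0)
    starts = [
        (0.9, 0.0, 0.0),
        (1.0, g1 / 6.0, 0.0),
        (0.95, g1 / 5.0, g2 / 100.0),
        (0.8, g1 / 4.0, 0.05),
    ]
    for x0 in starts:
        sol = optimize.root(_fleishman_system, x0, args=(g1, g2), method="hybr")
        if sol.success and np.max(np.abs(sol.fun)) < tol:
            b, c, d = sol.x
            if b < 0:  # sign convention: keep the orientation-preserving root
                b, c, d = -b, c, -d
            return (-c, b, c, d)
    raise InadmissibleMomentsError(
        f"no Fleishman solution for skewness={g1}, excess kurtosis={g2}"
    )


def intermediate_correlation(
    target_rho: float, coef: tuple[float, float, float, float]
) -> float:
    """Vale-Maurelli intermediate (pre-transform) correlation for one pair.

    Solves ``rho_Y = rho_Z (b^2 + 6 b d + 9 d^2) + 2 c^2 rho_Z^2 + 6 d^2 rho_Z^3``
    for ``rho_Z`` when both margins share the same Fleishman coefficients.
    """
    _, b, c, d = coef
    if target_rho == 0.0:
        return 0.0

    def f(r: float) -> float:
        return (
            r * (b**2 + 6 * b * d + 9 * d**2)
            + 2 * c**2 * r**2
            + 6 * d**2 * r**3
            - target_rho
        )

    lo, hi = -1.0, 1.0
    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:
        raise ValueError(f"target correlation {target_rho} unattainable")
    return float(optimize.brentq(f, lo, hi, xtol=1e-12))


def _intermediate_matrix(
    target: np.ndarray, coef: tuple[float, float, float, float]
) -> np.ndarray:
    t = np.asarray(target, dtype=float)
    rz = np.eye(t.shape[0])
    for i in range(t.shape[0]):
        for j in range(i + 1, t.shape[0]):
            rz[i, j] = rz[j, i] = intermediate_correlation(t[i, j], coef)
    # clip to PSD (tiny negative eigenvalues can arise from the polynomial map)
    w, v = np.linalg.eigh(rz)
    if w.min() < 0:
        w = np.clip(w, 1e-10, None)
        rz = v @ np.diag(w) @ v.T
        s = np.sqrt(np.diag(rz))
        rz = rz / np.outer(s, s)
    return rz


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------


def _assign_profiles(
    n: int, labels: list[str], weights: np.ndarray, rng: np.random.Generator
) -> list[str]:
    """Deterministic largest-remainder allocation, then a seeded shuffle.

    Exact-count allocation keeps the realized profile mixture equal to the
    configured proportions (up to integer rounding), which in turn pins the
    missing-cell fractions of the design.
    """
    ideal = weights * n
    counts = np.floor(ideal).astype(int)
    rem = n - counts.sum()
    order = np.argsort(-(ideal - counts))
    for k in range(rem):
        counts[order[k]] += 1
    assigned = [lab for lab, c in zip(labels, counts) for _ in range(c)]
    rng.shuffle(assigned)
    return assigned


def simulate_cohort(config: DesignConfig) -> pd.DataFrame:
    """One row per collected biospecimen (participant x tissue x timepoint).

    Rules enforced: every participant has a pre-exercise row in every tissue;
    during-exercise blood draws exist only for EE and CON; the immediately-post
    blood draw (P10M) is collected in all groups; early/intermediate/late
    collections follow the participant's randomized temporal profile.
    """
    rng = child_rng(config.seed, 0)
    labels = list(config.temporal_profiles)
    if config.profile_weights is None:
        weights = np.full(len(labels), 1.0 / len(labels))
    else:
        weights = np.array([config.profile_weights[l] for l in labels], dtype=float)
        weights = weights / weights.sum()

    rows = []
    pid = 0
    for group in GROUPS:
        n = config.n_per_group.get(group, 0)
        if n == 0:
            continue
        profiles = _assign_profiles(n, labels, weights, rng)
        for i in range(n):
            pid += 1
            participant = f"P{pid:04d}"
            profile = profiles[i]
            age = rng.uniform(*config.age_range)
            sex = "F" if rng.random() < config.female_fraction else "M"
            bmi = rng.normal(*config.bmi_mean_sd)
            site = f"S{rng.integers(config.n_sites) + 1}"
            collected_ranks = set(config.temporal_profiles[profile])
            for tissue, tps in config.tissue_timepoints.items():
                for tp in tps:
                    if tp in DURING_CODES and group == "RE":
                        continue  # no samples during resistance exercise
                    if tp in PROFILE_RANKS and tp not in collected_ranks:
                        continue
                    rows.append(
                        (participant, group, profile, tissue, tp, age, sex, bmi, site)
                    )
    table = pd.DataFrame(
        rows,
        columns=[
            "participant",
            "group",
            "profile",
            "tissue",
            "timepoint",
            "age",
            "sex",
            "bmi",
            "site",
        ],
    )
    table["age"] = table["age"].round(1)
    table["bmi"] = table["bmi"].round(2)
    return table


# ---------------------------------------------------------------------------
# omic matrix simulation
# ---------------------------------------------------------------------------


def simulate_ome(
    samples: pd.DataFrame,
    moments: MomentTarget,
    effects: EffectSpec,
    *,
    tissue: str,
    n_features: int = 100,
    feature_ids: list[str] | None = None,
    ome_kind: str = "continuous",
    feature_prefix: str = "feat",
    seed: int = 0,
    mean_log_libsize: float = np.log(50.0),
    sd_log_libsize: float = 0.3,
    covariate_betas: dict[str, float] | None = None,
) -> tuple[pd.DataFrame, TruthBundle]:
    """Simulate one tissue-ome feature matrix over the collected samples.

    Values decompose as participant random intercept (variance ``icc * total``)
    plus a within-participant correlated Fleishman residual with the target
    marginal moments, plus planted fixed effects. ``ome_kind='counts'`` maps
    the continuous latent through an exponential link with per-sample
    log-normal size factors and Poisson sampling.

    Returns a features-by-samples DataFrame (columns are
    ``participant:timepoint`` sample ids) and the accompanying truth bundle.
    """
    if ome_kind not in ("continuous", "counts"):
        raise ValueError("ome_kind must be 'continuous' or 'counts'")
    sub = samples.loc[samples["tissue"] == tissue]
    if sub.empty:
        raise ValueError(f"no samples for tissue {tissue!r}")
    tps = [t for t in TIMEPOINTS if t in set(sub["timepoint"])]
    t_index = {t: k for k, t in enumerate(tps)}
    participants = sub[["participant", "group"]].drop_duplicates("participant")
    n_p = len(participants)
    T = len(tps)

    rng = child_rng(seed, 1)
    coef = fleishman_coefficients(moments.skewness, moments.excess_kurtosis)
    if moments.timepoint_corr is None:
        corr = np.eye(T)
    else:
        corr = np.asarray(moments.timepoint_corr, dtype=float)
        if corr.shape != (T, T):
            raise ValueError(
                f"timepoint_corr shape {corr.shape} does not match {T} timepoints"
            )
    rz = _intermediate_matrix(corr, coef)
    chol = np.linalg.cholesky(rz + 1e-12 * np.eye(T))

    resid_sd = np.sqrt(moments.variance * (1.0 - moments.icc))
    icpt_sd = np.sqrt(moments.variance * moments.icc)

    if feature_ids is None:
        feature_ids = [f"{feature_prefix}{i}" for i in range(n_features)]
    else:
        feature_ids = list(feature_ids)
        n_features = len(feature_ids)
    # latent array: participants x timepoints x features
    z = rng.standard_normal((n_p, T, n_features))
    z = np.einsum("st,ptf->psf", chol, z)
    a, b, c, d = coef
    resid = a + b * z + c * z**2 + d * z**3
    latent = moments.mean + resid_sd * resid
    latent += icpt_sd * rng.standard_normal((n_p, 1, n_features))

    group_of = dict(zip(participants["participant"], participants["group"]))
    p_index = {p: k for k, p in enumerate(participants["participant"])}

    # planted difference-in-changes effects
    for fi, feat in enumerate(feature_ids):
        cells = effects.effects.get(feat)
        if not cells:
            continue
        for (group, tp), delta in cells.items():
            if tp not in t_index or delta == 0.0:
                continue
            mask = [p_index[p] for p, g in group_of.items() if g == group]
            latent[mask, t_index[tp], fi] += delta

    if covariate_betas:
        cov = sub.drop_duplicates("participant").set_index("participant")
        for name, beta in covariate_betas.items():
            vals = cov[name]
            x = (
                (vals == "F").astype(float)
                if vals.dtype == object
                else (vals - vals.mean()) / vals.std()
            )
            latent += beta * x.reindex(participants["participant"]).to_numpy()[
                :, None, None
            ]

    sample_ids, cols = [], []
    for _, row in sub.iterrows():
        pi, ti = p_index[row["participant"]], t_index[row["timepoint"]]
        sample_ids.append(f"{row['participant']}:{row['timepoint']}")
        cols.append(latent[pi, ti, :])
    values = np.column_stack(cols)

    if ome_kind == "counts":
        size = rng.lognormal(mean_log_libsize, sd_log_libsize, size=values.shape[1])
        values = rng.poisson(size[None, :] * np.exp(values)).astype(float)

    matrix = pd.DataFrame(values, index=feature_ids, columns=sample_ids)
    return matrix, TruthBundle(effects=effects)


# ---------------------------------------------------------------------------
# gene sets and exerkine truth
# ---------------------------------------------------------------------------


def simulate_genesets(
    feature_ids: list[str],
    n_sets: int = 20,
    set_size: tuple[int, int] = (10, 40),
    n_planted: int = 0,
    planted_features: list[str] | None = None,
    coherence: float = 0.8,
    seed: int = 0,
) -> tuple[dict[str, list[str]], dict[str, bool]]:
    """Random gene-set collection with optionally planted coherent sets.

    Planted sets draw a fraction ``coherence`` of their members from
    ``planted_features`` (features carrying coordinated effects); null sets
    are uniform draws from the universe. Sizes below the downstream filter
    floor (5) are rejected.
    """
    lo, hi = set_size
    if lo < 5:
        raise ValueError("set sizes below 5 are removed by the downstream filter")
    if hi > len(feature_ids):
        raise ValueError("requested set size exceeds the feature universe")
    if n_planted > 0 and not planted_features:
        raise ValueError("planted sets require planted_features")
    rng = child_rng(seed, 2)
    universe = np.asarray(feature_ids)
    sets: dict[str, list[str]] = {}
    truth: dict[str, bool] = {}
    for k in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        name = f"SET_{k:03d}"
        if k < n_planted:
            pool = np.asarray(planted_features)
            n_coh = min(int(round(coherence * size)), len(pool))
            members = list(rng.choice(pool, size=n_coh, replace=False))
            rest = np.setdiff1d(universe, pool, assume_unique=False)
            members += list(rng.choice(rest, size=size - n_coh, replace=False))
            truth[name] = True
        else:
            members = list(rng.choice(universe, size=size, replace=False))
            truth[name] = False
        sets[name] = members
    return sets, truth


def simulate_exerkines(
    genes: list[str],
    *,
    n_exerkines: int = 20,
    n_tissue_only: int = 50,
    n_plasma_only: int = 50,
    tissue_timepoint: str = "PEarly",
    lag: int = 0,
    effect: float = 2.0,
    seed: int = 0,
) -> tuple[EffectSpec, EffectSpec, pd.DataFrame]:
    """Coordinated tissue + plasma effect injections with decoys.

    True exerkines receive a positive tissue-transcript effect at
    ``tissue_timepoint`` and a positive plasma-protein effect ``lag`` rank
    positions later; tissue-only and plasma-only decoys receive one-sided
    effects. Returns (tissue EffectSpec, plasma EffectSpec, truth table).
    """
    ranks = list(PROFILE_RANKS)
    if tissue_timepoint not in ranks:
        raise ValueError(f"unknown tissue timepoint {tissue_timepoint!r}")
    plasma_idx = ranks.index(tissue_timepoint) + lag
    if not 0 <= plasma_idx < len(ranks):
        raise ValueError("lag places the plasma effect outside the design")
    plasma_tp = ranks[plasma_idx]
    need = n_exerkines + n_tissue_only + n_plasma_only
    if need > len(genes):
        raise ValueError("not enough genes for the requested truth layout")
    rng = child_rng(seed, 3)
    chosen = rng.choice(np.asarray(genes), size=need, replace=False)
    exer = chosen[:n_exerkines]
    t_only = chosen[n_exerkines : n_exerkines + n_tissue_only]
    p_only = chosen[n_exerkines + n_tissue_only :]

    tissue_fx: dict[str, dict[tuple[str, str], float]] = {}
    plasma_fx: dict[str, dict[tuple[str, str], float]] = {}
    records = []
    for g in exer:
        tissue_fx[g] = {("EE", tissue_timepoint): effect, ("RE", tissue_timepoint): effect}
        plasma_fx[g] = {("EE", plasma_tp): effect, ("RE", plasma_tp): effect}
        records.append((g, "exerkine", tissue_timepoint, plasma_tp))
    for g in t_only:
        tissue_fx[g] = {("EE", tissue_timepoint): effect}
        records.append((g, "tissue_only", tissue_timepoint, None))
    for g in p_only:
        plasma_fx[g] = {("EE", plasma_tp): effect}
        records.append((g, "plasma_only", None, plasma_tp))
    truth = pd.DataFrame(
        records, columns=["gene", "label", "tissue_timepoint", "plasma_timepoint"]
    )
    return EffectSpec(effects=tissue_fx), EffectSpec(effects=plasma_fx), truth
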