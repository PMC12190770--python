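"""Group-level statistics for optogenetic activation experiments.

Covers dark-control subtraction, technical-replicate aggregation, the
wavelength-experiment random-intercept mixed model (REML, least-square
means), Monte-Carlo Dunnett/Tukey post-hoc comparisons, fold-change
reporting, and the phenotype-based mRNA-quality inclusion gate.

The random-intercept model is y_ij = mu + condition_i + rep_j + e_ij
with condition fixed and biological replicate random; it is fit by
direct profiled REML over the single variance ratio
lambda = sigma^2_rep / sigma^2_res.  On balanced data the least-square
means coincide exactly with the per-condition arithmetic means.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import minimize_scalar

__all__ = [
    "GroupObservation",
    "PhenotypeCounts",
    "MixedModelResult",
    "Comparison",
    "subtract_dark",
    "aggregate_technical",
    "fit_random_intercept",
    "posthoc",
    "anova_oneway",
    "fold_change",
    "phenotype_gate",
]


@dataclass(frozen=True)
class GroupObservation:
    """One aggregated observation: a GFP-normalized median (AU) for a
    condition level (wavelength / time / irradiance) and replicate."""

    value: float
    condition: str
    bio_replicate: str

    def __post_init__(self) -> None:
        if not self.condition or not self.bio_replicate:
            raise ValueError("condition and bio_replicate must be non-empty")


def _obs_frame(observations: Iterable[GroupObservation] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(observations, pd.DataFrame):
        return observations[["value", "condition", "bio_replicate"]].copy()
    return pd.DataFrame(
        [
            {"value": o.value, "condition": o.condition, "bio_replicate": o.bio_replicate}
            for o in observations
        ]
    )


def subtract_dark(
    treated: pd.DataFrame,
    dark: pd.DataFrame,
    keys: Sequence[str] = ("axis_value", "bio_replicate"),
    value_col: str = "value",
) -> pd.DataFrame:
    """Subtract matched dark controls key-by-key; negatives retained.

    ``treated`` and ``dark`` are tidy frames carrying ``keys`` and
    ``value_col``.  Every treated key must have exactly one dark match;
    a missing control raises with the offending key named.
    """
    keys = list(keys)
    dark_map = dark.set_index(keys)[value_col]
    if dark_map.index.has_duplicates:
        dupes = dark_map.index[dark_map.index.duplicated()].tolist()
        raise ValueError(f"multiple dark controls for key(s) {dupes}")
    out = treated.copy()
    subtracted = []
    for _, row in treated.iterrows():
        key = tuple(row[k] for k in keys) if len(keys) > 1 else row[keys[0]]
        try:
            ctrl = dark_map.loc[key]
        except KeyError:
            raise KeyError(f"no matched dark control for key {key!r}") from None
        subtracted.append(row[value_col] - ctrl)
    out[value_col] = subtracted
    return out


def aggregate_technical(
    records: pd.DataFrame,
    group_keys: Sequence[str] = ("tool", "condition", "axis_value", "bio_replicate"),
    value_col: str = "value",
    qc_col: str = "qc_passed",
) -> pd.DataFrame:
    """Average technical replicates within each group, excluding (and
    counting) QC failures.  Groups whose records all failed QC are kept
    with a NaN mean and ``missing=True`` rather than silently dropped.
    """
    group_keys = list(group_keys)
    rows = []
    for key, grp in records.groupby(group_keys, sort=True):
        passing = grp[grp[qc_col]] if qc_col in grp.columns else grp
        rows.append(
            dict(
                zip(group_keys, key if isinstance(key, tuple) else (key,)),
                value=float(passing[value_col].mean()) if len(passing) else float("nan"),
                n_technical=int(len(passing)),
                n_excluded=int(len(grp) - len(passing)),
                missing=len(passing) == 0,
            )
        )
    return pd.DataFrame(rows)


@dataclass
class MixedModelResult:
    """Profiled-REML fit of the one-way random-intercept model."""

    ls_means: dict[str, float]
    ls_se: dict[str, float]
    sigma2_rep: float
    sigma2_res: float
    f_stat: float
    f_pvalue: float
    df_num: int
    df_den: int
    conditions: tuple[str, ...]
    n_obs: int


def _reml_neg_loglik(log_lam, y, X, Z):
    lam = np.exp(log_lam)
    n, p = X.shape
    V = np.eye(n) + lam * (Z @ Z.T)
    try:
        Vinv = np.linalg.inv(V)
        XtVinvX = X.T @ Vinv @ X
        beta = np.linalg.solve(XtVinvX, X.T @ Vinv @ y)
    except np.linalg.LinAlgError:
        return np.inf
    r = y - X @ beta
    quad = float(r @ Vinv @ r)
    if quad <= 0:
        quad = 1e-300
    s2 = quad / (n - p)
    sign, logdetV = np.linalg.slogdet(V)
    sign2, logdetX = np.linalg.slogdet(XtVinvX)
    if sign <= 0 or sign2 <= 0:
        return np.inf
    return 0.5 * ((n - p) * np.log(s2) + logdetV + logdetX)


def fit_random_intercept(
    observations: Iterable[GroupObservation] | pd.DataFrame,
    fixed: str = "condition",
) -> MixedModelResult:
    """REML fit of value ~ condition (fixed) + bio_replicate (random).

    The REML criterion is profiled down to the variance ratio
    lambda = sigma^2_rep / sigma^2_res and optimized on a log grid plus
    bounded scalar refinement.  Least-square means per condition, their
    standard errors and a Wald F-test of the condition effect are
    reported; the denominator df is the balanced-design error df
    n - k - q + 1.
    """
    df = _obs_frame(observations)
    df = df.dropna(subset=["value"])
    conditions = tuple(sorted(df["condition"].unique()))
    reps = tuple(sorted(df["bio_replicate"].unique()))
    k, q, n = len(conditions), len(reps), len(df)
    if k < 2 or q < 2:
        raise ValueError("need >= 2 conditions and >= 2 replicates")
    y = df["value"].to_numpy(float)
    X = np.zeros((n, k))  # cell-means coding: one column per condition
    Z = np.zeros((n, q))
    for i, (_, row) in enumerate(df.iterrows()):
        X[i, conditions.index(row["condition"])] = 1.0
        Z[i, reps.index(row["bio_replicate"])] = 1.0
    if np.linalg.matrix_rank(X) < k:
        raise ValueError("singular design: some condition has no observations")

    # coarse deterministic grid then bounded refinement
    grid = np.linspace(-12.0, 12.0, 49)
    vals = [_reml_neg_loglik(g, y, X, Z) for g in grid]
    g0 = grid[int(np.argmin(vals))]
    res = minimize_scalar(
        _reml_neg_loglik,
        bounds=(g0 - 1.0, g0 + 1.0),
        args=(y, X, Z),
        method="bounded",
        options={"xatol": 1e-10},
    )
    log_lam = float(res.x) if res.fun <= min(vals) else float(g0)
    lam = float(np.exp(log_lam))
    if lam < 1e-10:
        lam = 0.0

    V = np.eye(n) + lam * (Z @ Z.T)
    Vinv = np.linalg.inv(V)
    XtVinvX = X.T @ Vinv @ X
    beta = np.linalg.solve(XtVinvX, X.T @ Vinv @ y)
    r = y - X @ beta
    sigma2_res = float(r @ Vinv @ r) / (n - k)
    sigma2_rep = lam * sigma2_res
    cov_beta = sigma2_res * np.linalg.inv(XtVinvX)

    ls_means = {c: float(beta[i]) for i, c in enumerate(conditions)}
    ls_se = {c: float(np.sqrt(cov_beta[i, i])) for i, c in enumerate(conditions)}

    # Wald F for equality of condition means
    L = np.zeros((k - 1, k))
    L[:, 0] = 1.0
    for i in range(k - 1):
        L[i, i + 1] = -1.0
    Lb = L @ beta
    M = L @ cov_beta @ L.T
    f_stat = float(Lb @ np.linalg.solve(M, Lb)) / (k - 1)
    df_den = max(n - k - q + 1, 1)
    f_pvalue = float(sps.f.sf(f_stat, k - 1, df_den))
    return MixedModelResult(
        ls_means=ls_means, ls_se=ls_se, sigma2_rep=sigma2_rep,
        sigma2_res=sigma2_res, f_stat=f_stat, f_pvalue=f_pvalue,
        df_num=k - 1, df_den=df_den, conditions=conditions, n_obs=n,
    )


@dataclass
class Comparison:
    """One post-hoc contrast with raw and family-adjusted p-values."""

    group_a: str
    group_b: str
    difference: float
    t_stat: float
    p_unadjusted: float
    p_adjusted: float
    significant: bool


def anova_oneway(
    observations: Iterable[GroupObservation] | pd.DataFrame,
) -> dict[str, float]:
    """Fixed-effect one-way ANOVA across condition levels."""
    df = _obs_frame(observations).dropna(subset=["value"])
    groups = [g["value"].to_numpy(float) for _, g in df.groupby("condition")]
    if len(groups) < 2:
        raise ValueError("need >= 2 condition levels")
    f, p = sps.f_oneway(*groups)
    return {"f_stat": float(f), "p_value": float(p)}


def posthoc(
    observations: Iterable[GroupObservation] | pd.DataFrame,
    style: Literal["tukey_all_pairs", "dunnett_vs_control"] = "dunnett_vs_control",
    control: str | None = None,
    alpha: float = 0.05,
    n_draws: int = 100_000,
    seed: int = 0,
) -> list[Comparison]:
    """Multiplicity-adjusted pairwise comparisons by seeded Monte Carlo.

    Adjusted p-values are tail probabilities of the null max-|t|
    distribution over the comparison family, simulated with ``n_draws``
    draws of group means and a pooled-variance chi-square.  To keep the
    family-adjustment monotone despite Monte-Carlo noise, each adjusted
    p is clamped to be at least its unadjusted two-sided t p-value.
    """
    df = _obs_frame(observations).dropna(subset=["value"])
    groups = {c: g["value"].to_numpy(float) for c, g in df.groupby("condition")}
    names = sorted(groups)
    if len(names) < 2:
        raise ValueError("need >= 2 groups")
    if style == "dunnett_vs_control":
        if control is None or control not in groups:
            raise ValueError(f"control {control!r} not among groups {names}")
        pairs = [(c, control) for c in names if c != control]
    elif style == "tukey_all_pairs":
        pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    else:
        raise ValueError("style must be 'tukey_all_pairs' or 'dunnett_vs_control'")

    ns = {c: len(v) for c, v in groups.items()}
    means = {c: float(np.mean(v)) for c, v in groups.items()}
    dof = sum(ns.values()) - len(names)
    if dof < 1:
        raise ValueError("no residual degrees of freedom for a pooled error")
    s2_pool = sum(np.sum((groups[c] - means[c]) ** 2) for c in names) / dof

    t_obs = {}
    for a, b in pairs:
        se = np.sqrt(s2_pool * (1 / ns[a] + 1 / ns[b]))
        t_obs[(a, b)] = (means[a] - means[b]) / se if se > 0 else 0.0

    # Monte-Carlo null: group means ~ N(0, s2/n_g), shared chi2 variance
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_draws, len(names)))
    scale = np.array([1.0 / np.sqrt(ns[c]) for c in names])
    sim_means = z * scale  # unit sigma
    sim_s = np.sqrt(rng.chisquare(dof, n_draws) / dof)
    t_sim = np.empty((n_draws, len(pairs)))
    for j, (a, b) in enumerate(pairs):
        ia, ib = names.index(a), names.index(b)
        se = np.sqrt(1.0 / ns[a] + 1.0 / ns[b])
        t_sim[:, j] = (sim_means[:, ia] - sim_means[:, ib]) / (sim_s * se)
    max_abs_t = np.abs(t_sim).max(axis=1)

    out = []
    for a, b in pairs:
        t = t_obs[(a, b)]
        p_unadj = float(2.0 * sps.t.sf(abs(t), dof))
        p_adj = float(np.mean(max_abs_t >= abs(t)))
        p_adj = min(max(p_adj, p_unadj), 1.0)
        out.append(
            Comparison(
                group_a=a, group_b=b, difference=means[a] - means[b],
                t_stat=float(t), p_unadjusted=p_unadj, p_adjusted=p_adj,
                significant=p_adj < alpha,
            )
        )
    return out


def dunnett_critical_value(
    k: int,
    n_per_group: int,
    alpha: float = 0.05,
    n_draws: int = 200_000,
    seed: int = 0,
) -> float:
    """Two-sided Dunnett critical value (k groups incl. control, equal n)
    from the same seeded Monte-Carlo null used by :func:`posthoc`."""
    dof = k * n_per_group - k
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_draws, k)) / np.sqrt(n_per_group)
    sim_s = np.sqrt(rng.chisquare(dof, n_draws) / dof)
    se = np.sqrt(2.0 / n_per_group)
    t_sim = (z[:, 1:] - z[:, [0]]) / (sim_s[:, None] * se)
    max_abs_t = np.abs(t_sim).max(axis=1)
    return float(np.quantile(max_abs_t, 1.0 - alpha))


def fold_change(mean_a: float, mean_b: float, digits: int = 1) -> float:
    """Ratio mean_a / mean_b, reported to one decimal by convention."""
    if mean_b <= 0:
        raise ValueError("fold change undefined for non-positive denominator")
    return round(mean_a / mean_b, digits)


@dataclass(frozen=True)
class PhenotypeCounts:
    """Phenotype tallies for one exposure condition of the quality gate."""

    normal: int = 0
    mild_deform: int = 0
    severe_deform: int = 0
    lysed: int = 0
    v1_v4: int = 0
    v2_plus_present: bool = False

    def __post_init__(self) -> None:
        for name in ("normal", "mild_deform", "severe_deform", "lysed", "v1_v4"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} count must be >= 0")

    @property
    def total(self) -> int:
        return self.normal + self.mild_deform + self.severe_deform + self.lysed + self.v1_v4

    @property
    def severe_or_lysed_fraction(self) -> float:
        return (self.severe_deform + self.lysed) / self.total

    @property
    def defect_fraction(self) -> float:
        return (self.total - self.normal) / self.total


def phenotype_gate(
    counts: Mapping[str, PhenotypeCounts],
    tool: str,
) -> tuple[bool, tuple[str, ...]]:
    """mRNA-quality inclusion gate based on 1 dpf phenotype controls.

    ``counts`` maps condition names (``light_injected``, ``dark_injected``
    and optionally ``uninjected_light`` / ``uninjected_dark``) to tallies.

    FGF/Nodal rule: proceed iff >= 60% of light-exposed injected embryos
    are severely deformed or lysed, and the dark injected condition shows
    at most 20% mild-to-severe deformity or lysis.  BMP rule: proceed iff
    >= 60% of light-exposed injected embryos show V1-V4 ventralization,
    V2-or-higher embryos are present, and the dark injected condition
    shows at most 20% disallowed phenotypes (V1-V4, deformity, lysis).
    Independently, the experiment is excluded when uninjected embryos
    exceed ~30% defects in both dark and light.
    """
    for required in ("light_injected", "dark_injected"):
        if required not in counts:
            raise ValueError(f"missing condition {required!r}")
        if counts[required].total == 0:
            raise ValueError(f"zero embryos in condition {required!r}")
    light = counts["light_injected"]
    dark = counts["dark_injected"]
    reasons: list[str] = []

    if tool in ("FGF", "Nodal"):
        if light.severe_or_lysed_fraction < 0.60:
            reasons.append("low_efficacy")
        dark_bad = (dark.mild_deform + dark.severe_deform + dark.lysed) / dark.total
        if dark_bad > 0.20:
            reasons.append("dark_leak")
    elif tool == "BMP":
        if light.v1_v4 / light.total < 0.60:
            reasons.append("low_efficacy")
        if not light.v2_plus_present:
            reasons.append("no_v2_or_higher")
        dark_bad = (dark.v1_v4 + dark.mild_deform + dark.severe_deform + dark.lysed) / dark.total
        if dark_bad > 0.20:
            reasons.append("dark_leak")
    else:
        raise ValueError(f"unknown tool {tool!r}")

    un_l = counts.get("uninjected_light")
    un_d = counts.get("uninjected_dark")
    if (
        un_l is not None and un_d is not None
        and un_l.total and un_d.total
        and un_l.defect_fraction > 0.30
        and un_d.defect_fraction > 0.30
    ):
        reasons.append("uninjected_defects")

    return (not reasons, tuple(reasons))
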