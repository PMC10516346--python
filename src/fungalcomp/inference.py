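"""Statistical layer: ANOVA/Tukey contrasts, the factorial interaction
model, crossed-random-effects mixed models, pseudo-R², and model comparison.

The central question the mixed models answer is whether a strain's
log effect-of-competition is better predicted by its phylogenetic
(patristic) distance to the opponent or by the difference in the two
strains' baseline growth rates.  Both models share crossed random
intercepts for focal species and plate::

    log(EoC) ~ growth_rate_distance + pH + (1 | focal) + (1 | plate)
    log(EoC) ~ patristic_distance * pH + (1 | focal) + (1 | plate)

The growth-rate-distance model carries no distance:pH interaction because
that distance is already pH-specific; the patristic distance is constant
across pH, so its model retains the interaction.  Models are compared on
AIC (and a likelihood-ratio-style chi-square that degenerates to 0 for
non-nested same-likelihood configurations).  Variance explained is
summarised with marginal/conditional pseudo-R² by variance partitioning:
marginal uses the fixed-effect linear predictor's variance alone,
conditional adds the random-intercept variances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.stats as st
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .phylo import DistanceMatrix

__all__ = [
    "AnovaResult",
    "TukeyResult",
    "LMMSpec",
    "LMMResult",
    "InteractionLMResult",
    "ModelComparison",
    "DistanceCorrelation",
    "anova_oneway",
    "tukey_hsd",
    "fit_interaction_lm",
    "fit_lmm",
    "pseudo_r2",
    "compare_models",
    "distance_correlation_check",
]


# ---------------------------------------------------------------------------
# ANOVA and Tukey HSD


@dataclass(frozen=True)
class AnovaResult:
    term: str
    df_num: int
    df_den: int
    f_stat: float
    p_value: float
    degenerate: bool = False


@dataclass(frozen=True)
class TukeyResult:
    group_a: str
    group_b: str
    mean_diff: float
    adjusted_p: float
    significant: bool


def _group_arrays(responses, groups):
    responses = np.asarray(responses, dtype=float)
    groups = np.asarray(groups)
    if responses.shape != groups.shape:
        raise ValueError("responses and groups must have equal length")
    levels = sorted(pd.unique(groups).tolist())
    samples = [responses[groups == g] for g in levels]
    empty = [g for g, s in zip(levels, samples) if s.size == 0]
    if empty or len(levels) < 2:
        raise ValueError(f"need >= 2 non-empty groups (empty: {empty})")
    return levels, samples


def anova_oneway(responses, groups) -> AnovaResult:
    """Classical one-way ANOVA F test.

    A zero within-group variance makes F undefined; the result is then
    flagged ``degenerate`` with NaN statistics instead of raising.
    """
    levels, samples = _group_arrays(responses, groups)
    k = len(levels)
    n = sum(s.size for s in samples)
    if n - k < 2:
        raise ValueError("need >= 2 residual degrees of freedom")
    grand = np.concatenate(samples).mean()
    ss_between = sum(s.size * (s.mean() - grand) ** 2 for s in samples)
    ss_within = sum(((s - s.mean()) ** 2).sum() for s in samples)
    df_num, df_den = k - 1, n - k
    if ss_within == 0:
        return AnovaResult("group", df_num, df_den, np.nan, np.nan, degenerate=True)
    f = (ss_between / df_num) / (ss_within / df_den)
    p = float(st.f.sf(f, df_num, df_den))
    return AnovaResult("group", df_num, df_den, float(f), p)


def tukey_hsd(responses, groups, alpha: float = 0.05) -> list[TukeyResult]:
    """All pairwise comparisons with studentized-range-adjusted p-values."""
    levels, samples = _group_arrays(responses, groups)
    if any(s.size < 2 for s in samples):
        raise ValueError("every group needs >= 2 observations for Tukey HSD")
    res = st.tukey_hsd(*samples)
    out = []
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            p = float(res.pvalue[i, j])
            out.append(
                TukeyResult(
                    group_a=str(levels[i]),
                    group_b=str(levels[j]),
                    mean_diff=float(samples[i].mean() - samples[j].mean()),
                    adjusted_p=p,
                    significant=bool(p < alpha),
                )
            )
    return out


# ---------------------------------------------------------------------------
# Factorial interaction model


@dataclass
class InteractionLMResult:
    """OLS fit of response ~ focal * opponent * pH with all interactions."""

    f_stat: float
    df_num: int
    df_den: int
    p_value: float
    adj_r_squared: float
    n_obs: int
    aliased: list = field(default_factory=list)
    params: pd.Series | None = None


def fit_interaction_lm(
    eoc_records: pd.DataFrame, response_col: str = "eoc"
) -> InteractionLMResult:
    """Fit ``response ~ focal * opponent * pH`` by OLS.

    The factorial crossing of focal and opponent species necessarily
    contains unobserved self-pairings, so the full-interaction design is
    rank deficient; aliased design columns are detected by pivoted QR and
    reported by name rather than silently dropped (estimation proceeds via
    the pseudoinverse, with degrees of freedom based on the design rank).
    """
    df = eoc_records.copy()
    df["_y"] = df[response_col]
    model = smf.ols("_y ~ C(focal) * C(opponent) * C(ph)", data=df)
    X = model.exog
    names = model.exog_names
    _, r, piv = sla.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    aliased = [names[piv[k]] for k in range(rank, X.shape[1])]
    if aliased:
        warnings.warn(f"rank-deficient factorial design; aliased: {len(aliased)} columns")
    fit = model.fit()
    return InteractionLMResult(
        f_stat=float(fit.fvalue),
        df_num=int(fit.df_model),
        df_den=int(fit.df_resid),
        p_value=float(fit.f_pvalue),
        adj_r_squared=float(fit.rsquared_adj),
        n_obs=int(fit.nobs),
        aliased=aliased,
        params=fit.params,
    )


# ---------------------------------------------------------------------------
# Mixed models


@dataclass
class LMMSpec:
    """Which distance predictor enters the mixed model, and how.

    ``distance_kind`` is ``"growth_rate"``, ``"colony_size"`` or
    ``"patristic"``.  ``interaction`` defaults by kind: pH-specific trait
    distances exclude the distance:pH interaction, the pH-constant
    patristic distance retains it.  ``estimation`` is REML (default, for
    reported coefficients) or ML (for cross-model likelihood comparison).
    """

    distance_kind: str = "growth_rate"
    interaction: bool | None = None
    estimation: str = "REML"

    def __post_init__(self) -> None:
        if self.distance_kind not in ("growth_rate", "colony_size", "patristic"):
            raise ValueError(f"unknown distance kind {self.distance_kind!r}")
        if self.estimation not in ("REML", "ML"):
            raise ValueError("estimation must be REML or ML")
        if self.interaction is None:
            self.interaction = self.distance_kind == "patristic"


@dataclass
class LMMResult:
    """Fitted crossed-random-intercept mixed model."""

    spec: LMMSpec
    coefficients: dict          # term -> {"estimate", "se", "p"}
    variance_components: dict   # {"fungal_id", "plate_id", "residual"} -> sigma^2
    log_lik: float
    aic: float
    bic: float
    r2_marginal: float
    r2_conditional: float
    n_obs: int
    n_params: int               # fixed + variance parameters
    converged: bool
    boundary: bool              # a variance component at (or near) zero
    fixed_names: list = field(default_factory=list)
    _design: np.ndarray | None = field(default=None, repr=False)
    _fe_params: np.ndarray | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "distance_kind": self.spec.distance_kind,
            "interaction": self.spec.interaction,
            "estimation": self.spec.estimation,
            "coefficients": self.coefficients,
            "variance_components": self.variance_components,
            "log_lik": self.log_lik,
            "aic": self.aic,
            "bic": self.bic,
            "r2_marginal": self.r2_marginal,
            "r2_conditional": self.r2_conditional,
            "n_obs": self.n_obs,
            "n_params": self.n_params,
            "converged": self.converged,
            "boundary": self.boundary,
        }


def _join_distance(eoc: pd.DataFrame, distances, spec: LMMSpec) -> pd.Series:
    """Attach the per-record distance value d(focal, opponent)."""
    if spec.distance_kind == "patristic":
        if not isinstance(distances, DistanceMatrix):
            raise TypeError("patristic spec needs a single DistanceMatrix")
        by_ph = {ph: distances for ph in eoc["ph"].unique()}
    else:
        mats = list(distances.values()) if isinstance(distances, dict) else list(distances)
        by_ph = {m.ph: m for m in mats}
        missing_ph = sorted(set(eoc["ph"]) - set(by_ph))
        if missing_ph:
            raise KeyError(f"no distance matrix for pH levels {missing_ph}")
    vals = np.empty(len(eoc))
    for k, (f, o, ph) in enumerate(zip(eoc["focal"], eoc["opponent"], eoc["ph"])):
        m = by_ph[ph]
        try:
            vals[k] = m[f, o]
        except KeyError:
            raise KeyError(f"record ({f}, {o}) not joinable to {spec.distance_kind} distances")
    return pd.Series(vals, index=eoc.index)


def fit_lmm(eoc_records: pd.DataFrame, distances, spec: LMMSpec | None = None) -> LMMResult:
    """Fit log(EoC) on a distance predictor with crossed random intercepts.

    Random intercepts for focal species and for plate are crossed (a plate
    hosts two species; a species appears on many plates), implemented as
    variance components over a single grouping.  pH enters as a two-level
    factor with the lower level as reference.  Fixed-effect p-values use a
    t reference with residual degrees of freedom ``n - p`` (a pragmatic
    stand-in for Satterthwaite denominators).  A variance component
    estimated at the boundary (zero) is flagged, not treated as an error.
    """
    spec = spec or LMMSpec()
    df = eoc_records.copy()
    if "log_eoc" not in df.columns:
        raise ValueError("eoc_records must carry a log_eoc column")
    df["distance"] = _join_distance(df, distances, spec)
    df["ph_level"] = pd.Categorical(df["ph"], categories=sorted(df["ph"].unique()))
    df["_group"] = 1
    fixed = "log_eoc ~ distance * C(ph_level)" if spec.interaction else "log_eoc ~ distance + C(ph_level)"
    vc = {"fungal_id": "0 + C(focal)", "plate_id": "0 + C(plate_id)"}
    model = smf.mixedlm(fixed, df, groups="_group", vc_formula=vc)
    reml = spec.estimation == "REML"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(reml=reml, method="lbfgs")
        # polish: L-BFGS-B alone stops at optimizer-dependent points when a
        # variance component sits near its zero boundary
        polished = model.fit(reml=reml, method="bfgs", start_params=fit.params_object)
        if polished.llf >= fit.llf:
            fit = polished
        if not getattr(fit, "converged", True):
            fit = model.fit(reml=reml, method="powell")
    converged = bool(getattr(fit, "converged", True))

    fe = fit.fe_params
    se = fit.bse_fe
    p_fixed = len(fe)
    n = int(fit.nobs)
    df_resid = max(n - p_fixed, 1)
    tvals = fe.to_numpy() / se.to_numpy()
    pvals = 2 * st.t.sf(np.abs(tvals), df_resid)
    coefficients = {
        name: {"estimate": float(est), "se": float(s), "p": float(p)}
        for name, est, s, p in zip(fe.index, fe.to_numpy(), se.to_numpy(), pvals)
    }
    vc_names = list(model.exog_vc.names)
    vcomp = dict(zip(vc_names, fit.vcomp))
    variance_components = {
        "fungal_id": float(vcomp.get("fungal_id", 0.0)),
        "plate_id": float(vcomp.get("plate_id", 0.0)),
        "residual": float(fit.scale),
    }
    boundary = any(v < 1e-6 for v in vcomp.values())

    llf = float(fit.llf)
    k = p_fixed + len(vc_names) + 1
    aic = -2 * llf + 2 * k
    bic = -2 * llf + k * np.log(n)

    X = model.exog
    result = LMMResult(
        spec=spec,
        coefficients=coefficients,
        variance_components=variance_components,
        log_lik=llf,
        aic=float(aic),
        bic=float(bic),
        r2_marginal=np.nan,
        r2_conditional=np.nan,
        n_obs=n,
        n_params=k,
        converged=converged,
        boundary=boundary,
        fixed_names=list(fe.index),
        _design=X,
        _fe_params=fe.to_numpy(),
    )
    result.r2_marginal, result.r2_conditional = pseudo_r2(result)
    return result


def pseudo_r2(lmm_result: LMMResult) -> tuple[float, float]:
    """Marginal and conditional pseudo-R² by variance partitioning.

    With ``var_f`` the sample variance of the fixed-effect linear predictor
    and ``s_u, s_w, s_e`` the species, plate and residual variance
    components::

        marginal    = var_f / (var_f + s_u + s_w + s_e)
        conditional = (var_f + s_u + s_w) / (var_f + s_u + s_w + s_e)
    """
    if lmm_result._design is None or lmm_result._fe_params is None:
        raise ValueError("LMMResult lacks the design needed for pseudo-R²")
    eta = lmm_result._design @ lmm_result._fe_params
    var_f = float(np.var(eta, ddof=1))
    vc = lmm_result.variance_components
    s_u, s_w, s_e = vc["fungal_id"], vc["plate_id"], vc["residual"]
    total = var_f + s_u + s_w + s_e
    if total <= 0:
        raise ValueError("zero total variance: pseudo-R² undefined")
    marginal = var_f / total
    conditional = (var_f + s_u + s_w) / total
    return float(marginal), float(conditional)


# ---------------------------------------------------------------------------
# Model comparison


@dataclass(frozen=True)
class ModelComparison:
    model_a: str
    model_b: str
    estimation: str
    aic_a: float
    aic_b: float
    delta_aic: float            # aic_b - aic_a
    delta_bic: float
    delta_df: int               # k_b - k_a, floored at 0
    chi_square: float           # 2 * (ll_b - ll_a), floored at 0
    p_value: float
    preferred_by_aic: str

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return asdict(self)


def compare_models(result_a: LMMResult, result_b: LMMResult) -> ModelComparison:
    """Compare two mixed models fitted to the same observations.

    Leads with AIC (defensible for non-nested models); also reports a
    likelihood-ratio-style chi-square on the parameter-count difference,
    floored at zero when model b has no likelihood advantage — the
    degenerate ``Chi-sq = 0, P = 1`` outcome for same-or-worse fits.
    """
    if result_a.n_obs != result_b.n_obs:
        raise ValueError(
            f"models fit to different observation sets: {result_a.n_obs} vs {result_b.n_obs}"
        )
    if result_a.spec.estimation != result_b.spec.estimation:
        raise ValueError("models use different estimation methods")
    if result_a.spec.estimation == "REML" and result_a.fixed_names != result_b.fixed_names:
        warnings.warn(
            "comparing REML likelihoods across different fixed-effect structures; "
            "refit with estimation='ML' for a cleaner comparison"
        )
    chi = max(0.0, 2.0 * (result_b.log_lik - result_a.log_lik))
    ddf = max(0, result_b.n_params - result_a.n_params)
    if chi == 0.0 or ddf == 0:
        p = 1.0 if chi == 0.0 else 0.0
    else:
        p = float(st.chi2.sf(chi, ddf))
    name_a = result_a.spec.distance_kind
    name_b = result_b.spec.distance_kind
    return ModelComparison(
        model_a=name_a,
        model_b=name_b,
        estimation=result_a.spec.estimation,
        aic_a=result_a.aic,
        aic_b=result_b.aic,
        delta_aic=result_b.aic - result_a.aic,
        delta_bic=result_b.bic - result_a.bic,
        delta_df=ddf,
        chi_square=chi,
        p_value=p,
        preferred_by_aic=name_a if result_a.aic <= result_b.aic else name_b,
    )


# ---------------------------------------------------------------------------
# Predictor-independence check


@dataclass(frozen=True)
class DistanceCorrelation:
    slope: float
    se: float
    p_value: float
    n_pairs: int
    n_obs: int
    collinear: bool


def distance_correlation_check(
    growth_dists,
    phylo_dist: DistanceMatrix,
    alpha: float = 0.05,
    n_permutations: int = 999,
    seed: int = 0,
) -> DistanceCorrelation:
    """Regress patristic on growth-rate distance with a pH random intercept.

    Certifies that the two candidate predictors can be treated as
    independent: a significant slope flags collinearity.  ``growth_dists``
    is an iterable (or pH-keyed dict) of per-pH growth-distance matrices.

    The slope and SE come from the mixed fit, but the p-value is a
    pair-permutation p: each species pair contributes the same patristic
    value at every pH, so its observations are not independent and a
    naive t reference is anti-conservative.  Permuting the patristic
    values across pairs preserves that duplication structure exactly.
    """
    mats = list(growth_dists.values()) if isinstance(growth_dists, dict) else list(growth_dists)
    rows = []
    for m in mats:
        pairs = m.pair_series()
        for _, r in pairs.iterrows():
            rows.append(
                {
                    "ph": m.ph,
                    "pair": (r["species_a"], r["species_b"]),
                    "growth": r["distance"],
                    "phylo": phylo_dist[r["species_a"], r["species_b"]],
                }
            )
    df = pd.DataFrame(rows)
    pair_labels = sorted(set(df["pair"]))
    n_pairs = len(pair_labels)
    if n_pairs < 3:
        raise ValueError(f"need >= 3 species pairs, got {n_pairs}")
    growth = df["growth"].to_numpy()
    phylo = df["phylo"].to_numpy()
    Xg = sm.add_constant(growth)

    def ols_slope(y):
        beta, *_ = np.linalg.lstsq(Xg, y, rcond=None)
        return beta[1]

    obs_slope_ols = ols_slope(phylo)
    ols = sm.OLS(phylo, Xg).fit()
    exact = ols.ssr <= 1e-12 * max(1.0, float((phylo**2).sum()))

    # permutation null: shuffle which pair carries which patristic value,
    # keeping the per-pair duplication across pH levels intact
    pair_values = {p: phylo_dist[p[0], p[1]] for p in pair_labels}
    pair_index = df["pair"].map({p: k for k, p in enumerate(pair_labels)}).to_numpy()
    vals = np.array([pair_values[p] for p in pair_labels])
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(len(vals))
        if abs(ols_slope(vals[perm][pair_index])) >= abs(obs_slope_ols) - 1e-15:
            hits += 1
    p = (1 + hits) / (1 + n_permutations)

    if exact:
        return DistanceCorrelation(
            slope=float(obs_slope_ols), se=0.0, p_value=float(p),
            n_pairs=n_pairs, n_obs=len(df), collinear=True,
        )
    # With only two pH groups the random intercept is weakly identified and
    # the mixed fit can be numerically singular; fall back to pooled OLS.
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm("phylo ~ growth", df, groups="ph")
            fit = model.fit(method="lbfgs")
        slope = float(fit.fe_params["growth"])
        se = float(fit.bse_fe["growth"])
    except (np.linalg.LinAlgError, ValueError):
        slope = float(ols.params[1])
        se = float(ols.bse[1])
    return DistanceCorrelation(
        slope=slope,
        se=se,
        p_value=float(p),
        n_pairs=n_pairs,
        n_obs=len(df),
        collinear=bool(p < alpha),
    )
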