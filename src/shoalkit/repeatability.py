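"""Variance partitioning and consistency repeatability for grouped behaviour.

The model is the Gaussian random-intercept linear mixed model of the animal
personality literature,

    y = X beta + u_group + u_individual + e,
    u_group ~ N(0, V_group),  u_individual ~ N(0, V_id),  e ~ N(0, V_res),

with categorical fixed effects (context or trial number), a group-identity
random intercept, and optionally an individual-identity intercept nested
within group. Estimation is by Gibbs sampling with conjugate full
conditionals: normal draws for the coefficients and random effects,
inverse-gamma draws for the variances. Consistency repeatability is the
intraclass correlation

    R_C = V_level / (V_group + V_id + V_res)

computed per posterior draw and summarised by its mean and equal-tailed 95%
credibility interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: diffuse prior variance for fixed-effect coefficients
DEFAULT_BETA_PRIOR_VAR = 1e8
#: inverse-gamma(shape, scale) prior for every variance component
DEFAULT_IG_SHAPE = 0.001
DEFAULT_IG_SCALE = 0.001

#: lower 95% bound of R above this counts as a CI that excludes zero
#: (variance draws are strictly positive, so a literal zero bound never occurs)
DEFAULT_ZERO_TOL = 0.01


class ModelError(ValueError):
    """Raised for malformed observation tables or model specifications."""


@dataclass(frozen=True)
class ModelSpec:
    """Names the response, fixed factors and random terms in a table."""

    response: str
    fixed: tuple[str, ...] = ()
    group: str = "group_id"
    individual: str | None = None


@dataclass
class PosteriorDraws:
    """Thinned post-burn-in draws from the Gibbs sampler, stacked by chain."""

    beta: np.ndarray                  # (chains, draws, p)
    beta_names: list[str]
    v_group: np.ndarray               # (chains, draws)
    v_res: np.ndarray                 # (chains, draws)
    v_id: np.ndarray | None = None    # (chains, draws) or None
    fixed_levels: dict[str, list] = field(default_factory=dict)
    rhat: dict[str, float] = field(default_factory=dict)

    def flat(self, name: str) -> np.ndarray:
        arr = getattr(self, name)
        if arr is None:
            raise ModelError(f"component {name} was not modelled")
        return arr.reshape(-1) if arr.ndim == 2 else arr.reshape(-1, arr.shape[-1])


@dataclass
class VarianceComponents:
    """Point variance components (posterior means or moment estimates)."""

    v_group: float
    v_res: float
    v_id: float | None = None
    confounded: bool = False


@dataclass
class RepeatabilityResult:
    """Posterior summary of the repeatability ratios."""

    r_group: float
    r_group_ci: tuple[float, float]
    r_id: float | None
    r_id_ci: tuple[float, float] | None
    r_group_point: float
    r_id_point: float | None
    significant_group: bool
    significant_id: bool | None
    draws_r_group: np.ndarray
    draws_r_id: np.ndarray | None


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------


def _design(table: pd.DataFrame, spec: ModelSpec):
    if spec.response not in table.columns:
        raise ModelError(f"response column {spec.response!r} not in table")
    y = table[spec.response].to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ModelError("missing responses are not allowed")

    cols = [np.ones(len(table))]
    names = ["(intercept)"]
    fixed_levels: dict[str, list] = {}
    for factor in spec.fixed:
        if factor not in table.columns:
            raise ModelError(f"fixed factor {factor!r} not in table")
        levels = sorted(pd.unique(table[factor]).tolist())
        fixed_levels[factor] = levels
        for lev in levels[1:]:  # treatment coding, first level is reference
            cols.append((table[factor] == lev).to_numpy(dtype=float))
            names.append(f"{factor}[{lev}]")
    X = np.column_stack(cols)

    if spec.group is None:
        # intercept-only reduction: no random terms at all
        if spec.individual is not None:
            raise ModelError("individual random term requires a group term")
        return y, X, names, fixed_levels, None, 0, None, 0

    groups, gi = np.unique(table[spec.group].astype(str), return_inverse=True)
    counts = np.bincount(gi)
    if counts.min() < 2:
        small = groups[counts < 2][0]
        raise ModelError(f"group {small!r} has fewer than 2 observations")

    ii = None
    inds = None
    if spec.individual is not None:
        key = table[spec.individual].astype(str)
        inds, ii = np.unique(key, return_inverse=True)
        owner = {}
        for g, ind in zip(table[spec.group].astype(str), key):
            if owner.setdefault(ind, g) != g:
                raise ModelError(
                    f"individual {ind!r} appears in more than one group"
                )
    return y, X, names, fixed_levels, gi, len(groups), ii, (len(inds) if inds is not None else 0)


# ---------------------------------------------------------------------------
# Gibbs sampler
# ---------------------------------------------------------------------------


def _inv_gamma(rng, shape: float, scale: float) -> float:
    return scale / rng.gamma(shape)


def fit_lmm_mcmc(
    table: pd.DataFrame,
    spec: ModelSpec,
    *,
    chains: int = 5,
    iters: int = 20_000,
    burnin: int = 2_000,
    thin: int = 10,
    seed: int | None = None,
    beta_prior_var: float = DEFAULT_BETA_PRIOR_VAR,
    ig_shape: float = DEFAULT_IG_SHAPE,
    ig_scale: float = DEFAULT_IG_SCALE,
) -> PosteriorDraws:
    """Gibbs-sample the Gaussian random-intercept mixed model.

    Full conditionals: multivariate normal for the fixed coefficients,
    independent normals for each random intercept, and inverse-gamma for
    every variance component. Draws after ``burnin`` are kept every
    ``thin`` iterations, separately per chain; the potential scale
    reduction factor (R-hat) across chains is reported for each variance
    component when more than one chain is run.
    """
    y, X, names, fixed_levels, gi, q, ii, m = _design(table, spec)
    n, p = X.shape
    XtX = X.T @ X
    n_keep = (iters - burnin) // thin
    if n_keep < 1:
        raise ModelError("no draws retained: increase iters or lower burnin/thin")

    has_group = gi is not None
    has_id = ii is not None
    beta_draws = np.empty((chains, n_keep, p))
    vg_draws = np.zeros((chains, n_keep))
    ve_draws = np.empty((chains, n_keep))
    vi_draws = np.empty((chains, n_keep)) if has_id else None

    seeds = np.random.SeedSequence(seed).spawn(chains)
    var_y = max(float(np.var(y)), 1e-12)
    for c in range(chains):
        rng = np.random.default_rng(seeds[c])
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        u_g = np.zeros(q)
        u_i = np.zeros(m) if has_id else None
        v_g = var_y / 2
        v_i = var_y / 4 if has_id else 0.0
        v_e = var_y / 2
        n_g = np.bincount(gi, minlength=q) if has_group else None
        n_i = np.bincount(ii, minlength=m) if has_id else None
        k = 0
        for it in range(iters):
            rand = (u_g[gi] if has_group else 0.0) + (u_i[ii] if has_id else 0.0)
            # beta | rest
            prec = XtX / v_e + np.eye(p) / beta_prior_var
            L = np.linalg.cholesky(prec)
            mean = np.linalg.solve(prec, X.T @ (y - rand) / v_e)
            z = rng.standard_normal(p)
            beta = mean + np.linalg.solve(L.T, z)
            fitted = X @ beta
            # group intercepts | rest
            if has_group:
                r = y - fitted - (u_i[ii] if has_id else 0.0)
                prec_g = n_g / v_e + 1.0 / v_g
                mean_g = np.bincount(gi, weights=r, minlength=q) / v_e / prec_g
                u_g = mean_g + rng.standard_normal(q) / np.sqrt(prec_g)
            # individual intercepts | rest
            if has_id:
                r = y - fitted - u_g[gi]
                prec_i = n_i / v_e + 1.0 / v_i
                mean_i = np.bincount(ii, weights=r, minlength=m) / v_e / prec_i
                u_i = mean_i + rng.standard_normal(m) / np.sqrt(prec_i)
            # variances | rest
            if has_group:
                v_g = _inv_gamma(rng, ig_shape + q / 2, ig_scale + 0.5 * u_g @ u_g)
            if has_id:
                v_i = _inv_gamma(rng, ig_shape + m / 2, ig_scale + 0.5 * u_i @ u_i)
            resid = y - fitted - (u_g[gi] if has_group else 0.0) - (
                u_i[ii] if has_id else 0.0
            )
            v_e = _inv_gamma(rng, ig_shape + n / 2, ig_scale + 0.5 * resid @ resid)
            if it >= burnin and (it - burnin) % thin == 0:
                beta_draws[c, k] = beta
                if has_group:
                    vg_draws[c, k] = v_g
                ve_draws[c, k] = v_e
                if has_id:
                    vi_draws[c, k] = v_i
                k += 1

    rhat: dict[str, float] = {}
    if chains > 1 and has_group:
        import arviz as az

        rhat["v_group"] = float(az.rhat(vg_draws))
        rhat["v_res"] = float(az.rhat(ve_draws))
        if has_id:
            rhat["v_id"] = float(az.rhat(vi_draws))
    return PosteriorDraws(
        beta=beta_draws,
        beta_names=names,
        v_group=vg_draws,
        v_res=ve_draws,
        v_id=vi_draws,
        fixed_levels=fixed_levels,
        rhat=rhat,
    )


# ---------------------------------------------------------------------------
# repeatability
# ---------------------------------------------------------------------------


def _ci(draws: np.ndarray, level: float) -> tuple[float, float]:
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(draws, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def compute_repeatability(
    draws: PosteriorDraws | None = None,
    *,
    v_group: float | None = None,
    v_id: float | None = None,
    v_res: float | None = None,
    ci_level: float = 0.95,
    zero_tol: float = DEFAULT_ZERO_TOL,
) -> RepeatabilityResult:
    """Consistency repeatability from posterior draws or point components.

    ``R_group = V_group / (V_group + V_id + V_res)`` (the ``V_id`` term is
    omitted when no individual component is modelled), and symmetrically for
    ``R_id``. With :class:`PosteriorDraws` the ratio is computed per draw and
    summarised by the posterior mean and equal-tailed CI; the
    ratio-of-posterior-means is also reported as a point estimate. With
    scalar components the result is the plain ratio.
    """
    if draws is not None:
        vg = draws.flat("v_group")
        ve = draws.flat("v_res")
        vi = draws.flat("v_id") if draws.v_id is not None else None
    else:
        if v_group is None or v_res is None:
            raise ModelError("need v_group and v_res (or posterior draws)")
        vg = np.atleast_1d(np.asarray(v_group, dtype=float))
        ve = np.atleast_1d(np.asarray(v_res, dtype=float))
        vi = (
            np.atleast_1d(np.asarray(v_id, dtype=float))
            if v_id is not None
            else None
        )
    if (vg < 0).any() or (ve < 0).any() or (vi is not None and (vi < 0).any()):
        raise RuntimeError("negative variance draw: sampler contract violated")

    total = vg + ve + (vi if vi is not None else 0.0)
    r_g = vg / total
    r_g_ci = _ci(r_g, ci_level)
    r_g_point = float(vg.mean() / total.mean())
    result = RepeatabilityResult(
        r_group=float(r_g.mean()),
        r_group_ci=r_g_ci,
        r_id=None,
        r_id_ci=None,
        r_group_point=r_g_point,
        r_id_point=None,
        significant_group=r_g_ci[0] > zero_tol,
        significant_id=None,
        draws_r_group=r_g,
        draws_r_id=None,
    )
    if vi is not None:
        r_i = vi / total
        r_i_ci = _ci(r_i, ci_level)
        result.r_id = float(r_i.mean())
        result.r_id_ci = r_i_ci
        result.r_id_point = float(vi.mean() / total.mean())
        result.significant_id = r_i_ci[0] > zero_tol
        result.draws_r_id = r_i
    return result


# ---------------------------------------------------------------------------
# method-of-moments oracle
# ---------------------------------------------------------------------------


def moment_estimator(table: pd.DataFrame, spec: ModelSpec) -> VarianceComponents:
    """ANOVA (expected-mean-squares) variance components for balanced designs.

    Fixed effects are removed by demeaning within fixed-factor cells; the
    nested expected-mean-squares identities are then solved for the group,
    individual-within-group and residual components, truncating negative
    solutions at zero. Intended as an independent oracle for the sampler,
    exact only for balanced designs (a warning is issued otherwise).
    """
    df = table.copy()
    y = df[spec.response].astype(float)
    if spec.fixed:
        y = y - y.groupby([df[f] for f in spec.fixed]).transform("mean")
    df["_y"] = y

    g_sizes = df.groupby(spec.group).size()
    if g_sizes.nunique() > 1:
        warnings.warn("unbalanced design: moment estimates are approximate")
    grand = df["_y"].mean()
    G = len(g_sizes)

    if spec.individual is None:
        r = g_sizes.mean()
        g_means = df.groupby(spec.group)["_y"].mean()
        ss_b = (r * (g_means - grand) ** 2).sum()
        ms_b = ss_b / (G - 1)
        ss_w = ((df["_y"] - df.groupby(spec.group)["_y"].transform("mean")) ** 2).sum()
        df_w = len(df) - G
        ms_w = ss_w / df_w if df_w > 0 else 0.0
        v_res = float(ms_w)
        v_group = float(max((ms_b - ms_w) / r, 0.0))
        return VarianceComponents(v_group=v_group, v_res=v_res)

    i_sizes = df.groupby(spec.individual).size()
    if i_sizes.nunique() > 1:
        warnings.warn("unbalanced design: moment estimates are approximate")
    R = i_sizes.mean()
    M = (df.groupby(spec.group)[spec.individual].nunique()).mean()
    g_means = df.groupby(spec.group)["_y"].mean()
    i_means = df.groupby(spec.individual)["_y"].mean()
    g_of_i = df.groupby(spec.individual)[spec.group].first()

    ms_g = (M * R * (g_means - grand) ** 2).sum() / (G - 1)
    n_ind = len(i_sizes)
    df_i = n_ind - G
    ss_i = (R * (i_means - g_means[g_of_i].to_numpy()) ** 2).sum()
    ms_i = ss_i / df_i if df_i > 0 else 0.0
    ss_e = ((df["_y"] - df.groupby(spec.individual)["_y"].transform("mean")) ** 2).sum()
    df_e = len(df) - n_ind
    if df_e <= 0:
        # one observation per individual: V_id and V_res are confounded
        return VarianceComponents(
            v_group=float(max((ms_g - ms_i) / (M * R), 0.0)),
            v_res=float(ms_i),
            v_id=float("nan"),
            confounded=True,
        )
    ms_e = ss_e / df_e
    return VarianceComponents(
        v_group=float(max((ms_g - ms_i) / (M * R), 0.0)),
        v_id=float(max((ms_i - ms_e) / R, 0.0)),
        v_res=float(ms_e),
    )


# ---------------------------------------------------------------------------
# fixed-effect comparison
# ---------------------------------------------------------------------------


def cis_overlap(ci_a: tuple[float, float], ci_b: tuple[float, float]) -> bool:
    """True when two intervals share at least one point."""
    return ci_a[0] <= ci_b[1] and ci_b[0] <= ci_a[1]


@dataclass
class LevelComparison:
    level_a: str
    level_b: str
    mean_a: float
    mean_b: float
    ci_a: tuple[float, float]
    ci_b: tuple[float, float]
    significantly_different: bool


def compare_levels(
    draws: PosteriorDraws,
    factor: str,
    level_a,
    level_b,
    *,
    ci_level: float = 0.95,
) -> LevelComparison:
    """Compare two fixed-factor cell means by 95% CI overlap.

    Non-overlapping credibility intervals are read as evidence that the
    levels differ; overlap as absence of such evidence.
    """
    if factor not in draws.fixed_levels:
        raise ModelError(f"unknown fixed factor {factor!r}")
    levels = draws.fixed_levels[factor]
    for lev in (level_a, level_b):
        if lev not in levels:
            raise ModelError(f"unknown level {lev!r} of factor {factor!r}")
    beta = draws.flat("beta")
    names = draws.beta_names

    def cell(lev):
        mean = beta[:, names.index("(intercept)")].copy()
        name = f"{factor}[{lev}]"
        if name in names:
            mean += beta[:, names.index(name)]
        return mean

    a, b = cell(level_a), cell(level_b)
    ci_a, ci_b = _ci(a, ci_level), _ci(b, ci_level)
    return LevelComparison(
        level_a=str(level_a),
        level_b=str(level_b),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        ci_a=ci_a,
        ci_b=ci_b,
        significantly_different=not cis_overlap(ci_a, ci_b),
    )
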