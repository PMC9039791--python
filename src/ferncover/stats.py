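"""Analysis stage: ratios, well filtering, and mixed-model inference.

The analysis follows the cover data from calibrated areas to inference:

1. per-well *theoretical* species areas (the species' proportional share of
   the well total under the no-interaction null),
2. real:theoretical ratios at week 5, standardized per species to mean 1
   over mixture wells,
3. removal of wells that lost spores at sowing,
4. gamma GLMMs (log link, plate random intercept) with sequential
   likelihood-ratio tests for the cover analyses, and
5. a per-species linear mixed model on the standardized week-5 ratios with
   Tukey-adjusted pairwise contrasts between spore-count groups.

The gamma GLMM is fitted in-package by maximum likelihood with adaptive
Gauss-Hermite quadrature over the one-dimensional plate intercept (the
marginal likelihood factorizes by plate, and the per-plate integrand is
strictly log-concave, so the quadrature is fast and reliable).  The linear
mixed model rides on :class:`statsmodels` ``MixedLM`` with ML refits, as
required for valid likelihood ratios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy import optimize, special, stats as sps

from .design import DEFAULT_SPECIES, SPORES_PER_WELL

# ---------------------------------------------------------------------------
# Ratio pre-processing
# ---------------------------------------------------------------------------


def theoretical_area(
    total_area: float, n_species: int, n_total: int = SPORES_PER_WELL
) -> float:
    """Proportional share of the well total expected for a species.

    ``total_area / n_total * n_species``: under the no-interaction null each
    sown spore contributes equally, so a species' expected cover is its
    spore share of the total.  Monocultures therefore have theoretical area
    equal to the measured total, and summing over a well's species returns
    the total exactly.
    """
    if not (0 < n_species <= n_total):
        raise ValueError(f"need 0 < n_species <= {n_total}, got {n_species}")
    return total_area * n_species / n_total


def build_ratio_records(
    week5: pd.DataFrame, method: str = "well-total"
) -> pd.DataFrame:
    """Attach theoretical areas and raw real:theoretical ratios at week 5.

    ``method='well-total'`` uses each well's own measured total (the primary
    definition); ``method='monoculture-mean'`` instead predicts each species'
    expected cover from the mean per-spore area of its monoculture wells, an
    alternative reading in which monocultures set the per-individual
    baseline.  Under the primary definition monoculture ratios equal 1
    exactly.
    """
    df = week5.copy()
    if method == "well-total":
        df["theoretical_area_mm2"] = [
            theoretical_area(t, n)
            for t, n in zip(df["total_area_mm2"], df["n_spores_of_species"])
        ]
    elif method == "monoculture-mean":
        mono = df[df["n_spores_of_species"] == SPORES_PER_WELL]
        per_spore = (
            mono.groupby("species")["area_species_mm2"].mean() / SPORES_PER_WELL
        )
        missing = set(df["species"]) - set(per_spore.index)
        if missing:
            raise ValueError(f"no monoculture wells for species: {sorted(missing)}")
        df["theoretical_area_mm2"] = [
            per_spore[s] * n
            for s, n in zip(df["species"], df["n_spores_of_species"])
        ]
    else:
        raise ValueError(f"unknown method: {method!r}")
    df["raw_ratio"] = df["area_species_mm2"] / df["theoretical_area_mm2"]
    return df


def standardize_ratios(records: pd.DataFrame) -> pd.DataFrame:
    """Scale each species' raw ratios so mixture wells average exactly 1.

    The divisor is the species' mean raw ratio over mixture wells only
    (monocultures are excluded from the mean: under the primary definition
    their ratio is identically 1 and carries no information), but every
    record of the species — monocultures included — is divided by it.
    """
    df = records.copy()
    out = np.empty(len(df))
    for species, sub in df.groupby("species"):
        mix = sub[sub["n_spores_of_species"] < SPORES_PER_WELL]
        if mix.empty:
            raise ValueError(f"species {species} has no mixture wells to standardize on")
        divisor = float(mix["raw_ratio"].mean())
        out[df["species"] == species] = df.loc[df["species"] == species, "raw_ratio"] / divisor
    df["standardized_ratio"] = out
    return df


def filter_wells(
    records: pd.DataFrame, required_spores: int = SPORES_PER_WELL
) -> tuple[pd.DataFrame, dict]:
    """Drop wells that lost spores at sowing; report what was excluded.

    A well that did not receive its full complement of spores is not a valid
    replicate of the replacement series, so all its rows are removed.  The
    report lists the excluded wells and their share of all wells, rounded to
    the nearest percent.
    """
    wells = records[["plate_id", "well", "n_spores_sown"]].drop_duplicates(
        subset=["plate_id", "well"]
    )
    bad = wells[wells["n_spores_sown"] != required_spores]
    keep = records.merge(
        bad[["plate_id", "well"]], on=["plate_id", "well"], how="left", indicator=True
    )
    filtered = (
        records[(keep["_merge"] == "left_only").to_numpy()].reset_index(drop=True)
    )
    pct = round(100.0 * len(bad) / len(wells)) if len(wells) else 0
    report = {
        "n_wells": int(len(wells)),
        "n_excluded": int(len(bad)),
        "percent_excluded": int(pct),
        "excluded_wells": [
            f"K{p}-{w}" for p, w in zip(bad["plate_id"], bad["well"])
        ],
    }
    if len(bad) == len(wells) and len(wells) > 0:
        warnings.warn("all wells were excluded by the sown-spore filter")
    return filtered, report


# ---------------------------------------------------------------------------
# Gamma GLMM (log link, single random intercept) by ML + adaptive quadrature
# ---------------------------------------------------------------------------


@dataclass
class GammaGLMMResult:
    """ML fit of a gamma GLMM with log link and one random intercept."""

    beta: np.ndarray
    nu: float  # gamma shape
    sigma: float  # random-intercept SD (log scale)
    loglik: float
    converged: bool
    n_obs: int
    colnames: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class ModelResult:
    """One sequential likelihood-ratio test in a model-building order."""

    term: str
    chi_square: float
    df: int
    p_value: float
    order: int
    converged: bool = True


def _glmm_negloglik(
    params: np.ndarray,
    y: np.ndarray,
    X: np.ndarray,
    group_idx: np.ndarray,
    n_groups: int,
    nodes: np.ndarray,
    weights: np.ndarray,
) -> float:
    k = X.shape[1]
    beta, log_nu, log_sigma = params[:k], params[k], params[k + 1]
    nu, sigma2 = np.exp(log_nu), np.exp(2.0 * log_sigma)
    eta0 = X @ beta
    w = y * np.exp(-eta0)  # y_i / exp(x_i beta)

    n_g = np.bincount(group_idx, minlength=n_groups).astype(float)
    # Newton for the per-group posterior mode of b (integrand is log-concave)
    b = np.zeros(n_groups)
    for _ in range(50):
        s1 = np.bincount(group_idx, weights=w * np.exp(-b[group_idx]), minlength=n_groups)
        grad = nu * (s1 - n_g) - b / sigma2
        hess = -nu * s1 - 1.0 / sigma2
        step = grad / hess
        b -= step
        if np.max(np.abs(step)) < 1e-10:
            break
    s1 = np.bincount(group_idx, weights=w * np.exp(-b[group_idx]), minlength=n_groups)
    h = nu * s1 + 1.0 / sigma2  # -f''(b_hat)

    # adaptive Gauss-Hermite around the mode
    scale = np.sqrt(2.0 / h)
    f_nodes = np.empty((len(nodes), n_groups))
    for q, z in enumerate(nodes):
        bq = b + scale * z
        s1q = np.bincount(group_idx, weights=w * np.exp(-bq[group_idx]), minlength=n_groups)
        # b-dependent part of the per-group joint log-density:
        # sum_i [-nu*b - nu*y_i*exp(-eta0_i - b)]  -  b^2 / (2 sigma^2)
        f_nodes[q] = -nu * bq * n_g - nu * s1q - bq**2 / (2.0 * sigma2)
    log_int = special.logsumexp(
        f_nodes + nodes[:, None] ** 2 + np.log(weights)[:, None], axis=0
    ) + np.log(scale)
    # b-independent pieces of the conditional log-likelihood and the normal prior
    const = (
        nu * log_nu - special.gammaln(nu) + (nu - 1.0) * np.log(y) - nu * eta0
    ).sum()
    prior_norm = -0.5 * n_groups * np.log(2.0 * np.pi * sigma2)
    return -(const + prior_norm + log_int.sum())


def fit_gamma_glmm(
    y: np.ndarray,
    X: np.ndarray,
    groups: np.ndarray,
    n_quad: int = 15,
    colnames: list[str] | None = None,
    start: np.ndarray | None = None,
    fix_sigma: float | None = None,
) -> GammaGLMMResult:
    """Fit ``y ~ Gamma(log link)`` with fixed effects ``X`` and a random
    intercept per level of ``groups``, by maximum marginal likelihood.

    The response must be strictly positive.  Starting values come from a
    plain gamma GLM; the shape and random-intercept SD are optimized on the
    log scale with box bounds that keep the quadrature well-conditioned.
    ``fix_sigma`` pins the random-intercept SD (a value of 0 collapses the
    model to a plain gamma GLM, useful as a degenerate reference).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if np.any(y <= 0):
        raise ValueError("gamma GLMM requires a strictly positive response")
    codes, _ = pd.factorize(np.asarray(groups))
    n_groups = int(codes.max()) + 1
    nodes, weights = hermgauss(n_quad)

    if start is None:
        import statsmodels.api as sm

        glm = sm.GLM(y, X, family=sm.families.Gamma(link=sm.families.links.Log())).fit()
        disp = max(float(glm.pearson_chi2 / glm.df_resid), 1e-3) if glm.df_resid > 0 else 0.1
        start = np.concatenate([glm.params, [np.log(1.0 / disp), np.log(0.2)]])

    k = X.shape[1]
    bounds = [(None, None)] * k + [(-3.0, 9.0), (-8.0, 3.0)]
    if fix_sigma is not None:
        log_fixed = np.log(fix_sigma) if fix_sigma > 0 else -8.0
        log_fixed = float(np.clip(log_fixed, -8.0, 3.0))
        bounds[-1] = (log_fixed, log_fixed)
        start = np.asarray(start, dtype=float).copy()
        start[-1] = log_fixed
    res = optimize.minimize(
        _glmm_negloglik,
        start,
        args=(y, X, codes, n_groups, nodes, weights),
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": 500, "ftol": 1e-11, "gtol": 1e-8},
    )
    return GammaGLMMResult(
        beta=res.x[:k],
        nu=float(np.exp(res.x[k])),
        sigma=float(np.exp(res.x[k + 1])),
        loglik=-float(res.fun),
        converged=bool(res.success),
        n_obs=len(y),
        colnames=colnames or [f"x{i}" for i in range(k)],
    )


# ---------------------------------------------------------------------------
# Term encoding and sequential likelihood-ratio testing
# ---------------------------------------------------------------------------


def _dummies(series: pd.Series, prefix: str) -> pd.DataFrame:
    d = pd.get_dummies(pd.Categorical(series), prefix=prefix, drop_first=True)
    return d.astype(float)


def encode_term(df: pd.DataFrame, spec: str) -> pd.DataFrame:
    """Columns for one model term.

    ``spec`` is a column name for a numeric covariate, ``C(col)`` for a
    categorical factor (reference level dropped), and ``a:b`` for the
    interaction of two such specs (elementwise products of their columns).
    """
    if ":" in spec:
        left, right = spec.split(":", 1)
        L, R = encode_term(df, left), encode_term(df, right)
        cols = {}
        for lc in L.columns:
            for rc in R.columns:
                cols[f"{lc}:{rc}"] = L[lc].to_numpy() * R[rc].to_numpy()
        return pd.DataFrame(cols, index=df.index)
    if spec.startswith("C(") and spec.endswith(")"):
        col = spec[2:-1]
        return _dummies(df[col], col)
    return pd.DataFrame({spec: df[spec].astype(float)}, index=df.index)


def fit_cover_glmm(
    data: pd.DataFrame,
    fixed_terms: list[str],
    response: str = "total_area_mm2",
    group: str = "plate_id",
    n_quad: int = 15,
) -> tuple[list[ModelResult], list[GammaGLMMResult]]:
    """Sequential (type-I) likelihood-ratio tests for a gamma GLMM.

    Terms are added one at a time in the declared order; each term's
    chi-square is twice the gain in maximized marginal log-likelihood over
    the previous model, with degrees of freedom equal to the parameters
    added.  Earlier terms therefore act as covariates for later ones.
    Returns the test table and the fitted model sequence (null model first).
    """
    y = data[response].to_numpy(dtype=float)
    groups = data[group].to_numpy()
    X = pd.DataFrame({"Intercept": np.ones(len(data))}, index=data.index)
    fits = [fit_gamma_glmm(y, X.to_numpy(), groups, n_quad, list(X.columns))]
    results: list[ModelResult] = []
    for order, term in enumerate(fixed_terms, start=1):
        cols = encode_term(data, term)
        X = pd.concat([X, cols], axis=1)
        prev = fits[-1]
        start = np.concatenate(
            [prev.beta, np.zeros(cols.shape[1]), [np.log(prev.nu), np.log(max(prev.sigma, 1e-3))]]
        )
        fit = fit_gamma_glmm(y, X.to_numpy(), groups, n_quad, list(X.columns), start=start)
        # a nested ML fit can only gain likelihood; retry from scratch if the
        # warm start stalled below the previous model
        if fit.loglik < prev.loglik - 1e-6:
            fit2 = fit_gamma_glmm(y, X.to_numpy(), groups, n_quad, list(X.columns))
            if fit2.loglik > fit.loglik:
                fit = fit2
        chi2 = max(0.0, 2.0 * (fit.loglik - prev.loglik))
        df = cols.shape[1]
        results.append(
            ModelResult(
                term=term,
                chi_square=float(chi2),
                df=df,
                p_value=float(sps.chi2.sf(chi2, df)),
                order=order,
                converged=fit.converged,
            )
        )
        fits.append(fit)
    return results, fits


# -- packaged model presets -------------------------------------------------

_TRAITS = {
    s.code: {"reproduction": s.reproduction, "ploidy": s.ploidy_sporophyte}
    for s in DEFAULT_SPECIES
}


def add_analysis_columns(cover: pd.DataFrame) -> pd.DataFrame:
    """Derived columns used by the model presets (combination label, traits)."""
    df = cover.copy()
    df["combination"] = [
        f"{s1}{n1}" + (f"{s2}{n2}" if s2 else "")
        for s1, n1, s2, n2 in zip(df["species_1"], df["n_1"], df["species_2"], df["n_2"])
    ]
    df["is_monoculture"] = (df["n_2"] == 0) | (df["species_2"] == "")
    df["reproduction"] = [
        _TRAITS.get(s, {}).get("reproduction", "unknown") for s in df["species_1"]
    ]
    df["ploidy"] = [float(_TRAITS.get(s, {}).get("ploidy", np.nan)) for s in df["species_1"]]
    return df


#: the three cover analyses plus the well-position check, in the order the
#: terms enter the sequential tests
PRESETS: dict[str, dict] = {
    "bordering": {
        "subset": "all",
        "terms": ["week", "C(bordering_sides)"],
    },
    "monoculture_species": {
        "subset": "monoculture",
        "terms": ["week", "C(species_1)", "week:C(species_1)"],
    },
    "monoculture_traits": {
        "subset": "monoculture",
        "terms": [
            "week",
            "C(reproduction)",
            "ploidy",
            "week:C(reproduction)",
            "week:ploidy",
        ],
    },
    "combinations": {
        "subset": "all",
        "terms": ["C(week)", "C(combination)", "C(week):C(combination)"],
    },
}


def run_preset(
    cover: pd.DataFrame, preset: str, n_quad: int = 15
) -> tuple[list[ModelResult], list[GammaGLMMResult]]:
    """Run one packaged cover analysis on a (filtered) cover table."""
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    spec = PRESETS[preset]
    df = add_analysis_columns(cover)
    if spec["subset"] == "monoculture":
        df = df[df["is_monoculture"]].reset_index(drop=True)
    return fit_cover_glmm(df, spec["terms"], n_quad=n_quad)


# ---------------------------------------------------------------------------
# Week-5 ratio LMM with Tukey-adjusted contrasts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Contrast:
    """One Tukey-adjusted pairwise difference between spore-count groups."""

    group_a: int
    group_b: int
    estimate: float
    se: float
    t_value: float
    p_tukey: float


@dataclass
class RatioLMMResult:
    """Per-species LMM of standardized ratio on spore-count group."""

    species: str
    chi_square: float
    df: int
    p_value: float
    group_means: dict[int, float]
    contrasts: list[Contrast]
    converged: bool
    n_obs: int


def fit_ratio_lmm(
    ratios: pd.DataFrame,
    species: str,
    response: str = "standardized_ratio",
) -> RatioLMMResult:
    """Does a species' week-5 performance depend on how rare it was sown?

    Mixture wells only (monocultures are excluded: their ratio is fixed at 1
    by construction); the predictor is the categorical number of spores of
    the species ({5, 10, 15}, pooling competitor identities within a count)
    and the plate enters as a random intercept.  The group term is tested by
    a likelihood ratio between ML fits; pairwise group contrasts on the
    estimated marginal means are adjusted with the studentized-range (Tukey)
    method, groups weighted equally.
    """
    import statsmodels.api as sm

    sub = ratios[
        (ratios["species"] == species)
        & (ratios["n_spores_of_species"] < SPORES_PER_WELL)
    ].reset_index(drop=True)
    levels = sorted(sub["n_spores_of_species"].unique())
    if len(levels) < 2 or any(
        (sub["n_spores_of_species"] == g).sum() < 2 for g in levels
    ):
        raise ValueError(
            f"species {species}: need >= 2 spore-count groups with >= 2 records each"
        )
    y = sub[response].to_numpy(dtype=float)
    groups = sub["plate_id"].to_numpy()
    dummies = _dummies(sub["n_spores_of_species"], "n")
    X_full = np.column_stack([np.ones(len(sub)), dummies.to_numpy()])
    X_null = np.ones((len(sub), 1))

    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        full = sm.MixedLM(y, X_full, groups=groups).fit(reml=False)
        null = sm.MixedLM(y, X_null, groups=groups).fit(reml=False)
    if not (full.converged and null.converged):
        converged = False
    chi2 = max(0.0, 2.0 * (full.llf - null.llf))
    df = dummies.shape[1]

    # estimated marginal means: reference level = intercept, others add dummies
    k = len(levels)
    fe = full.fe_params
    cov = full.cov_params()[: len(fe), : len(fe)]
    L = np.zeros((k, len(fe)))
    L[:, 0] = 1.0
    for i in range(1, k):
        L[i, i] = 1.0
    means = L @ fe
    ddf = max(len(sub) - len(fe) - 1, 1)
    contrasts = []
    for i in range(k):
        for j in range(i + 1, k):
            c = L[i] - L[j]
            est = float(c @ fe)
            se = float(np.sqrt(c @ cov @ c))
            t = est / se if se > 0 else np.inf
            p = float(sps.studentized_range.sf(abs(t) * np.sqrt(2.0), k, ddf))
            contrasts.append(Contrast(levels[i], levels[j], est, se, t, p))
    return RatioLMMResult(
        species=species,
        chi_square=float(chi2),
        df=df,
        p_value=float(sps.chi2.sf(chi2, df)),
        group_means={g: float(m) for g, m in zip(levels, means)},
        contrasts=contrasts,
        converged=converged,
        n_obs=len(sub),
    )


# ---------------------------------------------------------------------------
# Measurement-method comparison
# ---------------------------------------------------------------------------


def compare_measurers(
    estimates_a: np.ndarray, estimates_b: np.ndarray
) -> dict:
    """Ratio-of-estimates summary for two methods measured on the same wells.

    Returns the per-well ratios a/b and their min/max/mean, plus the mean
    percentage difference of method a relative to method b.
    """
    a = np.asarray(estimates_a, dtype=float)
    b = np.asarray(estimates_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired estimates must have the same length")
    if np.any(b == 0):
        raise ValueError("zero denominator in method-b estimates")
    ratios = a / b
    return {
        "ratios": ratios,
        "min_ratio": float(ratios.min()),
        "max_ratio": float(ratios.max()),
        "mean_ratio": float(ratios.mean()),
        "mean_pct_difference": float((ratios.mean() - 1.0) * 100.0),
        "mean_abs_pct_difference": float(np.abs(ratios - 1.0).mean() * 100.0),
    }


def model_results_to_frame(results: list[ModelResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "order": r.order,
                "term": r.term,
                "chisq": r.chi_square,
                "df": r.df,
                "p": r.p_value,
                "converged": r.converged,
            }
            for r in results
        ]
    )
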