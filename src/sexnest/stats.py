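"""Comparisons of standardized indices across network types.

The design is origins (site-year datasets) crossed with network types
(species, female, male). z-score responses are compared with a Gaussian
linear mixed model with a random intercept per origin; sex-composition
species counts with a Poisson model with a log-offset for network richness,
clustered on origin. Omnibus tests are Wald F tests; when the omnibus is
significant at 0.05, each pair of types is refit and tested against the
Bonferroni-corrected threshold 0.05/3.

Wald F denominator degrees of freedom use the containment approximation
(k-1)(g-1) for the type factor in the crossed design (g origins, k types),
and n - p - (g - 1) for models with continuous covariates. Mixed fits that
fail or go singular fall back to a seeded within-origin permutation test;
the result records which route produced it.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05


@dataclass
class FixedEffect:
    term: str
    statistic: float
    p: float


@dataclass
class PairwiseContrast:
    contrast: str  # e.g. "female-male"
    statistic: float
    p: float
    significant: bool


@dataclass
class ComparisonResult:
    """Omnibus fixed-effect test plus Bonferroni-corrected pairwise contrasts."""

    response: str
    fixed_effects: list[FixedEffect]
    pairwise: list[PairwiseContrast] = field(default_factory=list)
    correction_threshold: float = DEFAULT_ALPHA / 3
    method: str = "mixedlm"
    #: fixed-effect coefficient -> (estimate, standard error) from the omnibus fit
    estimates: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def omnibus(self) -> FixedEffect:
        return self.fixed_effects[0]

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "method": self.method,
            "correction_threshold": self.correction_threshold,
            "fixed_effects": [vars(fe) for fe in self.fixed_effects],
            "pairwise": [vars(pc) for pc in self.pairwise],
            "estimates": {k: list(v) for k, v in self.estimates.items()},
        }


def _wald_f(result, term_names: list[str], ddf: int) -> tuple[float, float]:
    """Wald F test that the named fixed-effect coefficients are jointly zero."""
    params = result.params
    idx = [i for i, name in enumerate(params.index) if name in term_names]
    if len(idx) != len(term_names):
        raise RuntimeError(f"terms {term_names} not all present in {list(params.index)}")
    b = params.iloc[idx].to_numpy()
    cov = np.asarray(result.cov_params())[np.ix_(idx, idx)]
    q = len(idx)
    stat = float(b @ np.linalg.solve(cov, b)) / q
    if not np.isfinite(stat) or stat < 0:
        raise RuntimeError("non-finite Wald statistic")
    p = float(sps.f.sf(stat, q, ddf))
    return stat, p


def _fit_mixedlm(df: pd.DataFrame, formula: str):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, data=df, groups=df["origin"])
        try:
            return model.fit(reml=True, method="lbfgs")
        except np.linalg.LinAlgError:
            # lbfgs can hit a singular profiled score when the origin
            # variance runs to the boundary; powell is derivative-free
            return model.fit(reml=True, method="powell")


def _term_names(params_index, prefix: str) -> list[str]:
    return [name for name in params_index if name.startswith(prefix)]


def _perm_omnibus(df: pd.DataFrame, value_col: str, rng: np.random.Generator,
                  n_perm: int = 999) -> tuple[float, float]:
    """Within-origin permutation test for a type effect (fallback route).

    Statistic: between-type sum of squares of origin-centered values; type
    labels are permuted within each origin.
    """
    centered = df[value_col] - df.groupby("origin")[value_col].transform("mean")
    groups = [g.to_numpy() for _, g in centered.groupby(df["network_type"], observed=True)]

    def stat(vals_by_type):
        return sum(len(v) * np.mean(v) ** 2 for v in vals_by_type)

    obs = stat(groups)
    labels = df["network_type"].to_numpy()
    vals = centered.to_numpy()
    origins = df["origin"].to_numpy()
    count = 0
    for _ in range(n_perm):
        perm_labels = labels.copy()
        for o in np.unique(origins):
            sel = origins == o
            perm_labels[sel] = rng.permutation(perm_labels[sel])
        perm_groups = [vals[perm_labels == t] for t in np.unique(labels)]
        if stat(perm_groups) >= obs - 1e-12:
            count += 1
    return float(obs), (1 + count) / (1 + n_perm)


def _perm_paired(d: np.ndarray, rng: np.random.Generator,
                 n_perm: int = 999) -> tuple[float, float]:
    """Sign-flip permutation test on origin-matched differences."""
    obs = abs(float(np.mean(d)))
    count = 0
    for _ in range(n_perm):
        signs = rng.choice([-1.0, 1.0], size=d.size)
        if abs(float(np.mean(signs * d))) >= obs - 1e-12:
            count += 1
    return obs, (1 + count) / (1 + n_perm)


def compare_index(
    data: pd.DataFrame,
    value_col: str = "z",
    response_name: str | None = None,
    alpha: float = DEFAULT_ALPHA,
    fallback_seed: int = 0,
) -> ComparisonResult:
    """Compare a standardized index across network types.

    ``data`` needs columns ``origin``, ``network_type`` and ``value_col``
    (one row per origin-type combination). Fits a random-intercept mixed
    model, reports the omnibus Wald F for network type, and — when
    significant at ``alpha`` — refits each pair of types and flags contrasts
    at the Bonferroni threshold ``alpha / (number of pairs)``.
    """
    df = data.dropna(subset=[value_col]).copy()
    types = sorted(df["network_type"].unique())
    origins = df["origin"].unique()
    if len(types) < 2 or len(origins) < 2:
        raise ValueError("need >=2 network types and >=2 origins")
    n_pairs = len(types) * (len(types) - 1) // 2
    threshold = alpha / n_pairs
    response = response_name or value_col
    ddf_omni = (len(types) - 1) * (len(origins) - 1)

    method = "mixedlm"
    estimates: dict[str, tuple[float, float]] = {}
    try:
        fit = _fit_mixedlm(df, f"{value_col} ~ C(network_type)")
        terms = _term_names(fit.params.index, "C(network_type)")
        stat, p = _wald_f(fit, terms, ddf_omni)
        bse = fit.bse
        estimates = {
            name: (float(fit.params[name]), float(bse[name]))
            for name in ["Intercept", *terms]
        }
    except Exception as exc:  # singular / non-convergent fit
        logger.warning("mixed model failed (%s); using permutation fallback", exc)
        method = "permutation"
        rng = np.random.default_rng(fallback_seed)
        stat, p = _perm_omnibus(df, value_col, rng)

    result = ComparisonResult(
        response=response,
        fixed_effects=[FixedEffect("network_type", stat, p)],
        correction_threshold=threshold,
        method=method,
        estimates=estimates,
    )
    if p >= alpha:
        return result

    for t1, t2 in combinations(types, 2):
        sub = df[df["network_type"].isin([t1, t2])]
        ddf_pair = len(sub["origin"].unique()) - 1
        try:
            fit = _fit_mixedlm(sub, f"{value_col} ~ C(network_type)")
            terms = _term_names(fit.params.index, "C(network_type)")
            pstat, pp = _wald_f(fit, terms, ddf_pair)
        except Exception:
            wide = sub.pivot_table(index="origin", columns="network_type",
                                   values=value_col, observed=True).dropna()
            rng = np.random.default_rng(fallback_seed)
            pstat, pp = _perm_paired(
                (wide[t1] - wide[t2]).to_numpy(), rng
            )
        result.pairwise.append(
            PairwiseContrast(f"{t1}-{t2}", pstat, pp, pp < threshold)
        )
    return result


def compare_sex_composition(
    data: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
) -> ComparisonResult:
    """Compare sex-composition category counts across networks.

    ``data`` needs columns ``origin``, ``category`` (all_female / all_male /
    both), ``count`` and ``total`` (visitor richness of the network). Fits a
    Poisson model with log(total) offset, clustered on origin (exchangeable
    working correlation); omnibus and Bonferroni pairwise contrasts as for
    :func:`compare_index`.
    """
    df = data.copy()
    cats = sorted(df["category"].unique())
    if len(cats) < 2:
        raise ValueError("need >=2 categories")
    n_pairs = len(cats) * (len(cats) - 1) // 2
    threshold = alpha / n_pairs
    g = df["origin"].nunique()

    def _fit_gee(sub):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.gee(
                "count ~ C(category)",
                groups="origin",
                data=sub,
                family=sm.families.Poisson(),
                cov_struct=sm.cov_struct.Exchangeable(),
                offset=np.log(sub["total"].to_numpy()),
            )
            # bias-reduced (Mancl-DeRouen) covariance: the plain sandwich is
            # badly anticonservative with this few clusters
            return model.fit(cov_type="bias_reduced")

    def _fit_glm_fe(sub):
        # documented fallback when the clustered fit is degenerate: plain
        # Poisson GLM absorbing origins as fixed effects
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return smf.glm(
                "count ~ C(category) + C(origin)",
                data=sub,
                family=sm.families.Poisson(),
                offset=np.log(sub["total"].to_numpy()),
            ).fit()

    def _test(sub, ddf):
        try:
            fit = _fit_gee(sub)
            terms = _term_names(fit.params.index, "C(category)")
            return _wald_f(fit, terms, ddf), "poisson_gee"
        except (RuntimeError, np.linalg.LinAlgError, ValueError):
            pass
        fit = _fit_glm_fe(sub)
        terms = _term_names(fit.params.index, "C(category)")
        try:
            return _wald_f(fit, terms, ddf), "poisson_glm_fe"
        except (RuntimeError, np.linalg.LinAlgError):
            if np.max(np.abs(fit.params[terms])) < 1e-6:
                return (0.0, 1.0), "degenerate"  # identical categories
            raise

    ddf = (len(cats) - 1) * (g - 1)
    (stat, p), method = _test(df, ddf)
    result = ComparisonResult(
        response="sex_composition",
        fixed_effects=[FixedEffect("category", stat, p)],
        correction_threshold=threshold,
        method=method,
    )
    if p >= alpha:
        return result
    for c1, c2 in combinations(cats, 2):
        sub = df[df["category"].isin([c1, c2])]
        (pstat, pp), _ = _test(sub, g - 1)
        result.pairwise.append(PairwiseContrast(f"{c1}-{c2}", pstat, pp, pp < threshold))
    return result


def covariate_model(
    data: pd.DataFrame,
    covariate_col: str,
    value_col: str = "z",
) -> ComparisonResult:
    """Test whether a covariate explains a standardized index.

    Mixed model ``value ~ covariate * network_type`` with origin random
    intercept; reports Wald F for the covariate main effect, the type main
    effect, and their interaction.
    """
    df = data.dropna(subset=[value_col, covariate_col]).copy()
    g = df["origin"].nunique()
    # center & scale the covariate: conditions the optimizer and makes the
    # main effect the slope at the mean covariate value
    sd = df[covariate_col].std()
    if sd == 0:
        raise ValueError(f"covariate {covariate_col!r} has zero variance")
    df["_cov"] = (df[covariate_col] - df[covariate_col].mean()) / sd

    method = "mixedlm"
    try:
        fit = _fit_mixedlm(df, f"{value_col} ~ _cov * C(network_type)")
    except Exception as exc:
        logger.warning(
            "covariate mixed model failed (%s); using origin fixed effects", exc
        )
        method = "ols_origin_fe"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = smf.ols(
                f"{value_col} ~ _cov * C(network_type) + C(origin)", data=df
            ).fit()
    names = list(fit.params.index)
    cov_terms = ["_cov"]
    type_terms = [n for n in names if n.startswith("C(network_type)") and ":" not in n]
    inter_terms = [n for n in names if ":" in n and "_cov" in n]
    n_fixed = 1 + len(cov_terms) + len(type_terms) + len(inter_terms)
    ddf = max(len(df) - n_fixed - (g - 1), 1)
    effects = []
    for label, terms in [
        (covariate_col, cov_terms),
        ("network_type", type_terms),
        (f"{covariate_col}:network_type", inter_terms),
    ]:
        try:
            stat, p = _wald_f(fit, terms, ddf)
        except (RuntimeError, np.linalg.LinAlgError):
            stat, p = float("nan"), float("nan")  # not estimable at this size
        effects.append(FixedEffect(label, stat, p))
    return ComparisonResult(
        response=value_col,
        fixed_effects=effects,
        correction_threshold=DEFAULT_ALPHA / 3,
        method=method,
    )


def pearson_swnodf_smod(z_nodf, z_mod) -> tuple[float, float]:
    """Pearson correlation between standardized nestedness and modularity.

    Modularity z-scores are externally supplied (this package does not
    compute modularity). Returns (r, two-sided p).
    """
    x = np.asarray(z_nodf, dtype=float)
    y = np.asarray(z_mod, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >=3 paired values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the inputs")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)
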