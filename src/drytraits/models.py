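"""Mixed-effects gradient models and trait-profile trend detection.

Responses (z-scaled richness, FRI, beta-diversity components) are modelled
against flow intermittence with Gaussian linear mixed models carrying
random intercepts for rivers (and, where measures repeat within sites,
sites nested within rivers).  Fixed effects are tested by likelihood-ratio
tests between ML fits of the full and the nested null models.  Shifts in
community-weighted trait profiles along FI are detected with a simplified
conditional-inference tree: a permutation independence test between FI and
the multivariate modality profile, recursively splitting at the most
discriminating FI threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


class ModelError(ValueError):
    """Raised for invalid model specifications or degenerate inputs."""


def z_transform(values: np.ndarray | pd.Series) -> np.ndarray | pd.Series:
    """Standardize to mean 0, sample s.d. 1 (n-1 denominator)."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ModelError("z-transform needs at least 2 values")
    sd = arr.std(ddof=1)
    if sd == 0:
        raise ModelError("z-transform undefined for constant values")
    z = (arr - arr.mean()) / sd
    if isinstance(values, pd.Series):
        return pd.Series(z, index=values.index, name=values.name)
    return z


def slope_to_raw(slope_z: float, sd_response: float, delta_fi: float = 10.0) -> float:
    """Back-transform a z-scale FI slope to raw response units per
    ``delta_fi`` percentage points of FI."""
    if sd_response <= 0:
        raise ModelError("sd_response must be positive")
    return float(slope_z * sd_response * delta_fi)


@dataclass
class LMMFit:
    """Random-intercept Gaussian mixed model fit.

    ``random_sd`` maps each grouping level (e.g. 'river', 'site') to its
    intercept standard deviation; ``r2_marginal``/``r2_conditional`` are
    the fixed and fixed+random variance fractions of the total.
    """

    formula: str
    criterion: str
    params: pd.Series
    bse: pd.Series
    random_sd: dict[str, float]
    residual_sd: float
    llf: float
    n_params: int
    n_obs: int
    r2_marginal: float
    r2_conditional: float
    converged: bool
    result: object = field(repr=False, default=None)

    def summary_dict(self) -> dict:
        return {
            "formula": self.formula,
            "criterion": self.criterion,
            "estimates": self.params.to_dict(),
            "se": self.bse.to_dict(),
            "random_sd": self.random_sd,
            "residual_sd": self.residual_sd,
            "loglik": self.llf,
            "r2_marginal": self.r2_marginal,
            "r2_conditional": self.r2_conditional,
            "n_obs": self.n_obs,
        }


def fit_lmm(data: pd.DataFrame, formula: str, groups: str,
            nested: str | None = None, criterion: str = "ML") -> LMMFit:
    """Fit a Gaussian mixed model with random intercepts.

    Parameters
    ----------
    formula
        Fixed-effects formula, e.g. ``"z ~ fi * richness_type"``.
    groups
        Column giving the top grouping level (random intercept), e.g. river.
    nested
        Optional column nested within ``groups`` (a second random
        intercept), e.g. site within river.
    criterion
        'ML' (required whenever the fit feeds a likelihood-ratio test of
        fixed effects) or 'REML'.
    """
    import statsmodels.formula.api as smf

    if criterion not in ("ML", "REML"):
        raise ModelError(f"unknown criterion {criterion!r}")
    vc = {nested: f"0 + C({nested})"} if nested else None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, data=data, groups=data[groups],
                            re_formula="1", vc_formula=vc)
        try:
            result = model.fit(reml=(criterion == "REML"))
        except np.linalg.LinAlgError:
            result = model.fit(reml=(criterion == "REML"), method="powell")
        bse = result.bse_fe  # may warn on boundary fits; NaNs are kept

    fe = result.fe_params
    random_sd = {groups: float(np.sqrt(max(result.cov_re.iloc[0, 0], 0.0)))}
    if nested:
        random_sd[nested] = float(np.sqrt(max(result.vcomp[0], 0.0))) if len(result.vcomp) else 0.0
    resid_sd = float(np.sqrt(result.scale))

    design = model.exog
    var_fixed = float(np.var(design @ fe.to_numpy(), ddof=0))
    var_random = float(sum(sd**2 for sd in random_sd.values()))
    total = var_fixed + var_random + result.scale
    n_params = len(fe) + 1 + (1 if nested else 0) + 1  # fe + variances + resid

    return LMMFit(
        formula=formula,
        criterion=criterion,
        params=fe,
        bse=bse,
        random_sd=random_sd,
        residual_sd=resid_sd,
        llf=float(result.llf),
        n_params=n_params,
        n_obs=int(model.nobs),
        r2_marginal=var_fixed / total,
        r2_conditional=(var_fixed + var_random) / total,
        converged=bool(result.converged),
        result=result,
    )


def lrt(full: LMMFit, null: LMMFit) -> tuple[float, int, float]:
    """Likelihood-ratio test of a nested null against the full model.

    Returns (chi2, df, p) with chi2 = 2 (l_full - l_null) and df the
    difference in parameter counts.  Both fits must use ML.
    """
    if full.criterion != "ML" or null.criterion != "ML":
        raise ModelError("likelihood-ratio tests require ML fits")
    chi2 = max(0.0, 2.0 * (full.llf - null.llf))
    df = full.n_params - null.n_params
    if df < 0:
        raise ModelError("null model has more parameters than the full model")
    p = 1.0 if df == 0 else float(stats.chi2.sf(chi2, df))
    return chi2, df, p


# ---------------------------------------------------------------------------
# conditional-inference style trait-trend trees


@dataclass
class TrendNode:
    """One node of a trait-trend tree.

    Leaves have ``threshold=None`` and no children; internal nodes split
    the samples at ``fi <= threshold``.
    """

    n: int
    p_value: float
    mean_profile: pd.Series
    threshold: float | None = None
    children: list["TrendNode"] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "p_value": self.p_value,
            "threshold": self.threshold,
            "mean_profile": self.mean_profile.round(6).to_dict(),
            "children": [c.to_dict() for c in self.children],
        }

    def thresholds(self) -> list[float]:
        out = [] if self.threshold is None else [self.threshold]
        for c in self.children:
            out.extend(c.thresholds())
        return out


@dataclass
class TraitTrendTree:
    """Recursive partitioning of one trait's community profiles along FI."""

    trait: str
    root: TrendNode

    @property
    def root_p(self) -> float:
        return self.root.p_value

    @property
    def n_splits(self) -> int:
        return len(self.root.thresholds())


def _independence_p(y: np.ndarray, fi: np.ndarray, n_perm: int,
                    rng: np.random.Generator) -> float:
    """Monte-Carlo permutation p-value for association between FI and a
    multivariate profile, using a max-type standardized linear statistic."""
    t_obs = fi @ y
    perm = np.empty((n_perm, len(fi)))
    for i in range(n_perm):
        perm[i] = rng.permutation(fi)
    t_perm = perm @ y
    mu = t_perm.mean(axis=0)
    sd = t_perm.std(axis=0, ddof=1)
    # variation at float-noise level means the component is constant
    sd = np.where(sd > 1e-10 * (np.abs(mu) + 1.0), sd, np.inf)
    z_obs = np.max(np.abs((t_obs - mu) / sd))
    z_perm = np.max(np.abs((t_perm - mu) / sd), axis=1)
    return float((1 + np.sum(z_perm >= z_obs - 1e-12)) / (n_perm + 1))


def _best_split(y: np.ndarray, fi: np.ndarray, min_leaf: int) -> float | None:
    """FI threshold maximizing the standardized two-sample statistic,
    subject to both children having at least ``min_leaf`` samples."""
    n = len(fi)
    order = np.argsort(fi)
    fi_sorted = fi[order]
    y_sorted = y[order]
    s = y.sum(axis=0)
    ybar = s / n
    s2 = ((y - ybar) ** 2).sum(axis=0) / (n - 1)
    s2 = np.where(s2 > 0, s2, np.inf)
    csum = np.cumsum(y_sorted, axis=0)

    best_stat, best_cut = -np.inf, None
    for i in range(min_leaf - 1, n - min_leaf):
        if fi_sorted[i] == fi_sorted[i + 1]:
            continue  # cannot separate ties
        n_l = i + 1
        u = csum[i]
        e = n_l / n * s
        var = n_l * (n - n_l) / n * s2
        stat = np.max(np.abs(u - e) / np.sqrt(var))
        if stat > best_stat:
            best_stat = stat
            best_cut = 0.5 * (fi_sorted[i] + fi_sorted[i + 1])
    return best_cut


def trait_trend_tree(profiles: pd.DataFrame, fi: pd.Series | np.ndarray,
                     trait: str = "", alpha: float = 0.05, n_perm: int = 9999,
                     min_leaf: int = 5,
                     seed: int | np.random.Generator = 0) -> TraitTrendTree:
    """Detect FI thresholds at which a trait's community profile shifts.

    ``profiles`` holds one trait's modality columns per sample (rows sum
    to 1); at each node the independence between FI and the profile is
    tested by Monte-Carlo permutation of FI (max-type standardized linear
    statistic); when significant at ``alpha`` the node splits at the FI
    threshold maximizing the two-sample statistic (children of at least
    ``min_leaf`` samples) and recursion continues.  Nodes with constant FI
    or fewer than ``2 * min_leaf`` samples are leaves.
    """
    y_all = profiles.to_numpy(dtype=float)
    fi_all = np.asarray(fi, dtype=float)
    if len(fi_all) != len(y_all):
        raise ModelError("profiles and FI differ in length")
    if len(y_all) < 2 * min_leaf:
        raise ModelError(f"need at least {2 * min_leaf} samples")
    rng = np.random.default_rng(seed)
    cols = profiles.columns

    def build(idx: np.ndarray) -> TrendNode:
        y = y_all[idx]
        f = fi_all[idx]
        mean_profile = pd.Series(y.mean(axis=0), index=cols)
        if len(idx) < 2 * min_leaf or np.ptp(f) == 0:
            return TrendNode(n=len(idx), p_value=1.0, mean_profile=mean_profile)
        p = _independence_p(y, f, n_perm, rng)
        node = TrendNode(n=len(idx), p_value=p, mean_profile=mean_profile)
        if p < alpha:
            cut = _best_split(y, f, min_leaf)
            if cut is not None:
                node.threshold = float(cut)
                left = idx[f <= cut]
                right = idx[f > cut]
                node.children = [build(left), build(right)]
        return node

    root = build(np.arange(len(y_all)))
    return TraitTrendTree(trait=trait, root=root)
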