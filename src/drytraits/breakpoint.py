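"""Davies test, segmented regression, and the random-allocation null model.

The taxonomic-functional richness relationship is characterized by (i) the
Davies test for the presence of a change in slope at an unknown breakpoint,
(ii) segmented (broken-line) least squares estimating the breakpoint and the
slopes on either side, and (iii) an ensemble of the same statistics under
random reallocation of taxa to functional groups, yielding empirical
p-values for the observed parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .groups import FunctionalGrouping

DEFAULT_TAILS = {
    "slope_before": "lower",
    "slope_after": "two-sided",
    "psi": "upper",
    "davies_p": "lower",
}


class BreakpointError(ValueError):
    """Raised for inputs on which breakpoint inference is undefined."""


def _ols(design: np.ndarray, y: np.ndarray):
    xtx = design.T @ design
    try:
        beta = np.linalg.solve(xtx, design.T @ y)
    except np.linalg.LinAlgError:
        beta, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    return beta, resid


def davies_test(x: np.ndarray, y: np.ndarray, k: int = 10) -> float:
    """Davies-bound p-value for a slope change at an unknown breakpoint.

    For ``k`` candidate breakpoints evenly spaced between the 2nd and
    (n-1)th order statistics of x, the Wald statistic t_j of the hinge term
    (x - psi_j)_+ added to the linear fit is computed; with M = max|t_j|
    and V the total variation of the t_j sequence, the upper bound

        p = min(1, 2 Phi(-M) + V exp(-M^2 / 2) / sqrt(8 pi))

    is returned.  Degenerate fits (zero residual variance with no
    identifiable hinge) give p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 10:
        raise BreakpointError("Davies test needs n >= 10")
    if np.ptp(x) == 0:
        raise BreakpointError("x is constant")
    xs = np.sort(x)
    candidates = np.linspace(xs[1], xs[-2], k)
    t = np.zeros(k)
    for j, psi in enumerate(candidates):
        hinge = np.maximum(x - psi, 0.0)
        design = np.column_stack([np.ones(n), x, hinge])
        if np.linalg.matrix_rank(design) < 3:
            t[j] = 0.0
            continue
        beta, resid = _ols(design, y)
        dof = n - 3
        sigma2 = float(resid @ resid) / dof
        if sigma2 <= 1e-20 * max(float(np.var(y)), 1.0):
            # residuals at float-noise level: no identifiable hinge term
            t[j] = 0.0
            continue
        xtx_inv = np.linalg.inv(design.T @ design)
        se = np.sqrt(sigma2 * xtx_inv[2, 2])
        t[j] = beta[2] / se if se > 0 else 0.0
    # Wald statistics are t-distributed (estimated variance): map them to
    # equivalent normal scores before applying the Gaussian-process bound,
    # which removes the small-sample anticonservatism
    dof = n - 3
    with np.errstate(over="ignore"):
        z = stats.norm.isf(stats.t.sf(t, dof))
    t = np.where(np.isfinite(z), z, t)
    m = float(np.max(np.abs(t)))
    v = float(np.sum(np.abs(np.diff(t))))
    p = 2.0 * stats.norm.sf(m) + v * np.exp(-0.5 * m * m) / np.sqrt(8.0 * np.pi)
    return float(min(1.0, p))


@dataclass
class SegmentedFit:
    """Broken-line regression fit: y = intercept + slopes switching at psi."""

    psi: float
    psi_se: float
    psi_ci95: tuple[float, float]
    slope_before: float
    slope_after: float
    intercept: float
    residual_variance: float
    converged: bool
    n_iter: int
    message: str = ""


def _broken_line_rss(x: np.ndarray, y: np.ndarray, psi: float, ones: np.ndarray) -> float:
    design = np.column_stack([ones, x, np.maximum(x - psi, 0.0)])
    _, resid = _ols(design, y)
    return float(resid @ resid)


def _segmented_once(x: np.ndarray, y: np.ndarray, psi: float, tol: float,
                    max_iter: int) -> SegmentedFit | None:
    n = len(x)
    lo, hi = float(np.min(x)), float(np.max(x))
    span = hi - lo
    sd_y = float(np.std(y, ddof=1)) or 1.0
    ones = np.ones(n)
    n_iter = 0
    converged = False
    rss = _broken_line_rss(x, y, psi, ones)
    for n_iter in range(1, max_iter + 1):
        hinge = np.maximum(x - psi, 0.0)
        v = -(x > psi).astype(float)
        design = np.column_stack([ones, x, hinge, v])
        beta, resid = _ols(design, y)
        b = beta[2]  # slope change
        gamma = beta[3]
        if abs(b) < 1e-12:
            return None
        if abs(gamma) < tol * sd_y:
            converged = True
            break
        # step halving on the broken-line RSS keeps the update from
        # oscillating around the optimum (and inside the x-range)
        step = gamma / b
        accepted = False
        for _ in range(30):
            psi_new = psi + step
            if lo < psi_new < hi:
                rss_new = _broken_line_rss(x, y, psi_new, ones)
                if rss_new <= rss + 1e-12:
                    psi, rss = psi_new, rss_new
                    accepted = True
                    break
            step *= 0.5
            if abs(step) < 1e-10 * max(span, 1.0):
                break
        if not accepted:
            if n_iter == 1:
                return None  # first update escaped the range: bad start
            converged = True  # no RSS-improving update left
            break
    # covariance at the final design for psi_se
    hinge = np.maximum(x - psi, 0.0)
    v = -(x > psi).astype(float)
    design = np.column_stack([ones, x, hinge, v])
    beta, resid = _ols(design, y)
    dof = max(n - 4, 1)
    sigma2 = float(resid @ resid) / dof
    try:
        xtx_inv = np.linalg.inv(design.T @ design)
        se_gamma = float(np.sqrt(max(sigma2 * xtx_inv[3, 3], 0.0)))
    except np.linalg.LinAlgError:
        se_gamma = np.nan
    psi_se = se_gamma / abs(beta[2]) if abs(beta[2]) > 0 else np.inf
    return SegmentedFit(
        psi=float(psi),
        psi_se=float(psi_se),
        psi_ci95=(float(psi - 1.96 * psi_se), float(psi + 1.96 * psi_se)),
        slope_before=float(beta[1]),
        slope_after=float(beta[1] + beta[2]),
        intercept=float(beta[0]),
        residual_variance=sigma2,
        converged=converged,
        n_iter=n_iter,
    )


def segmented_fit(x: np.ndarray, y: np.ndarray, psi0: float | None = None,
                  tol: float = 1e-6, max_iter: int = 50) -> SegmentedFit:
    """Broken-line least squares with iteratively refitted breakpoint.

    The working linear model ``y ~ 1 + x + (x - psi)_+ + V`` with
    ``V = -1{x > psi}`` is refitted, updating ``psi <- psi + gamma/beta``
    with gamma the V coefficient and beta the hinge coefficient, until the
    correction term vanishes (|gamma| < tol * sd(y)).  The breakpoint
    standard error is se(gamma)/|beta| and the 95% CI is psi +- 1.96 se.
    If the iteration escapes the x-range, it restarts from a grid of five
    interior quantiles; if all restarts fail a non-converged fit is
    returned with diagnostics.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 6:
        raise BreakpointError("segmented fit needs n >= 6")
    if np.ptp(x) == 0:
        raise BreakpointError("x is constant")
    lo, hi = float(np.min(x)), float(np.max(x))
    ones = np.ones(len(x))
    # coarse profile scan seeds the iteration near the global RSS basin
    scan = np.linspace(lo, hi, 27)[1:-1]
    scan_rss = np.array([_broken_line_rss(x, y, p, ones) for p in scan])
    starts = [float(np.median(x)) if psi0 is None else float(psi0)]
    starts += [float(p) for p in scan[np.argsort(scan_rss)[:3]]]
    starts += [float(np.quantile(x, q)) for q in (0.2, 0.8)]
    fallback = [float(np.quantile(x, q)) for q in (0.35, 0.65)]

    def try_starts(candidates):
        best_fit, best_rss, pending = None, np.inf, None
        tried = set()
        for s in candidates:
            if not (lo < s < hi) or s in tried:
                continue
            tried.add(s)
            fit = _segmented_once(x, y, s, tol, max_iter)
            if fit is None:
                continue
            if fit.converged:
                rss = _broken_line_rss(x, y, fit.psi, ones)
                if rss < best_rss:
                    best_fit, best_rss = fit, rss
            else:
                pending = pending or fit
        return best_fit, pending

    best, last = try_starts(starts)
    if best is None:
        best, last2 = try_starts(fallback)
        last = last or last2
    if best is not None:
        return best
    if last is not None:
        last.message = "iteration limit reached without convergence"
        return last
    return SegmentedFit(
        psi=float(np.median(x)), psi_se=np.inf, psi_ci95=(-np.inf, np.inf),
        slope_before=np.nan, slope_after=np.nan, intercept=np.nan,
        residual_variance=np.nan, converged=False, n_iter=0,
        message="breakpoint escaped the x-range from every start",
    )


def empirical_p(observed: float, simulated: np.ndarray, tail: str) -> float:
    """Add-one empirical p-value of an observed statistic against a null
    ensemble (never exactly zero)."""
    sims = simulated[np.isfinite(simulated)]
    n = len(sims)
    if n == 0:
        return np.nan
    p_lower = (1 + np.sum(sims <= observed)) / (n + 1)
    p_upper = (1 + np.sum(sims >= observed)) / (n + 1)
    if tail == "lower":
        return float(p_lower)
    if tail == "upper":
        return float(p_upper)
    if tail == "two-sided":
        return float(min(1.0, 2.0 * min(p_lower, p_upper)))
    raise ValueError(f"unknown tail {tail!r}")


@dataclass
class NullEnsemble:
    """Random-allocation null for the richness-richness breakpoint.

    ``observed`` and each row of ``simulations`` hold (davies_p, psi,
    slope_before, slope_after); failed simulated fits are kept, flagged
    by ``converged=False``, and excluded from the p-value counts.
    """

    n_sim: int
    mode: str
    observed: dict[str, float]
    simulations: pd.DataFrame
    p_values: dict[str, float]
    tails: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_TAILS))
    n_valid: int = 0


def _functional_richness(presence: np.ndarray, assignment: np.ndarray, n_groups: int
                         ) -> np.ndarray:
    onehot = np.zeros((len(assignment), n_groups))
    onehot[np.arange(len(assignment)), assignment - 1] = 1.0
    return ((presence @ onehot) > 0).sum(axis=1)


def _characterize(x: np.ndarray, y: np.ndarray, k: int) -> tuple[dict[str, float], bool]:
    p = davies_test(x, y, k=k)
    fit = segmented_fit(x, y)
    rec = {
        "davies_p": p,
        "psi": fit.psi,
        "slope_before": fit.slope_before,
        "slope_after": fit.slope_after,
    }
    return rec, fit.converged


def redundancy_null(site_taxa: pd.DataFrame, grouping: FunctionalGrouping,
                    n_sim: int = 9999, mode: str = "uniform",
                    seed: int | np.random.Generator = 0, k_davies: int = 10,
                    tails: dict[str, str] | None = None) -> NullEnsemble:
    """Null distribution of breakpoint statistics under random group labels.

    ``site_taxa`` is a site x taxon boolean presence table.  The observed
    richness-richness relationship (functional on taxonomic, pooled across
    all sites) is characterized by the Davies p-value, the breakpoint and
    the slopes before/after; each of ``n_sim`` simulations reassigns
    functional groups to taxa (mode='uniform': independent uniform over the
    observed number of groups; mode='permute': shuffle of the observed
    labels, preserving group sizes), recomputes per-site functional
    richness, and re-characterizes the relationship.  Empirical p-values
    use the add-one rule with per-parameter tails (defaults: slope_before
    lower, slope_after two-sided, psi upper, davies_p lower).
    """
    if mode not in ("uniform", "permute"):
        raise ValueError(f"unknown mode {mode!r}")
    if grouping.n_groups < 2:
        raise BreakpointError("null model undefined for a single functional group")
    rng = np.random.default_rng(seed)
    tails = dict(DEFAULT_TAILS if tails is None else tails)

    presence = site_taxa.to_numpy(dtype=bool)
    taxa = list(site_taxa.columns)
    assignment = grouping.assignment.loc[taxa].to_numpy(dtype=int)
    n_groups = grouping.n_groups
    tax_richness = presence.sum(axis=1).astype(float)
    obs_fun = _functional_richness(presence, assignment, n_groups).astype(float)
    observed, _ = _characterize(tax_richness, obs_fun, k_davies)

    records = []
    for _ in range(n_sim):
        if mode == "uniform":
            sim_assign = rng.integers(1, n_groups + 1, size=len(taxa))
        else:
            sim_assign = rng.permutation(assignment)
        fun = _functional_richness(presence, sim_assign, n_groups).astype(float)
        try:
            rec, ok = _characterize(tax_richness, fun, k_davies)
        except BreakpointError:
            rec, ok = {k: np.nan for k in observed}, False
        rec["converged"] = ok
        records.append(rec)
    sims = pd.DataFrame(records)

    valid = sims[sims["converged"]]
    p_values = {
        name: empirical_p(observed[name], valid[name].to_numpy(), tails[name])
        for name in ("davies_p", "psi", "slope_before", "slope_after")
    }
    return NullEnsemble(
        n_sim=n_sim, mode=mode, observed=observed, simulations=sims,
        p_values=p_values, tails=tails, n_valid=int(len(valid)),
    )
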