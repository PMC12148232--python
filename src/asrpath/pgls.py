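"""Phylogenetic generalized least squares with maximum-likelihood Pagel's λ.

The model is ``y = X b + e`` with ``e ~ N(0, s2 * V(λ))`` where
``V(λ) = λ C + (1-λ) diag(C)`` and ``C`` is the Brownian-motion covariance
implied by the phylogeny.  λ is profiled out by maximizing the Gaussian
log-likelihood over [0, 1]; coefficients, their standard errors, t and
two-sided p-values (df = n - k) are reported at the ML λ.  On z-scored
variables a group coefficient reads as Cohen's d and a slope as a
correlation-type effect size.

:class:`PGLS` is the model object, :meth:`PGLS.fit` returns a
:class:`PGLSResults`; Wald type-3 (marginal) F-tests, per-group slopes for
interaction designs, quadratic-term comparisons and the simulation power
analysis hang off module-level functions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .phylo import PhyloCovariance, Phylogeny, phylo_covariance
from .traits import gsd_indicator


class PGLSError(ValueError):
    pass


def _cholesky(V: np.ndarray) -> np.ndarray:
    try:
        return linalg.cholesky(V, lower=True)
    except linalg.LinAlgError:
        jitter = 1e-10 * float(np.mean(np.diag(V)))
        try:
            return linalg.cholesky(V + jitter * np.eye(len(V)), lower=True)
        except linalg.LinAlgError as exc:
            raise PGLSError("covariance matrix is not positive definite") from exc


class PGLS:
    """PGLS model for one response and a design matrix with intercept.

    Parameters
    ----------
    endog : array-like, shape (n,)
        Response values, ordered like ``cov.labels``.
    exog : array-like, shape (n, k)
        Design matrix including the intercept column.
    cov : PhyloCovariance or Phylogeny
        Untransformed (λ = 1) phylogenetic covariance; rows must match.
    exog_names : sequence of str, optional
    """

    def __init__(self, endog, exog, cov, exog_names: Sequence[str] | None = None):
        if isinstance(cov, Phylogeny):
            cov = phylo_covariance(cov)
        self.cov = cov
        self.endog = np.asarray(endog, dtype=float).ravel()
        exog = np.asarray(exog, dtype=float)
        if exog.ndim == 1:
            exog = exog[:, None]
        self.exog = exog
        n, k = exog.shape
        if len(self.endog) != n or cov.matrix.shape[0] != n:
            raise PGLSError("endog, exog and covariance sizes disagree")
        if n <= k + 1:
            raise PGLSError(f"too few observations (n={n}) for k={k} coefficients")
        if not np.all(np.isfinite(self.endog)) or not np.all(np.isfinite(exog)):
            raise PGLSError("missing values in model data; subset first")
        self.exog_names = (
            list(exog_names)
            if exog_names is not None
            else [f"x{i}" for i in range(k)]
        )
        rank = np.linalg.matrix_rank(exog)
        if rank < k:
            _, R = np.linalg.qr(exog)
            bad = [
                self.exog_names[i]
                for i in range(k)
                if abs(R[i, i]) < 1e-10 * abs(R[0, 0])
            ]
            raise PGLSError(f"singular design; collinear columns: {bad}")
        self._diag = np.diag(cov.matrix).copy()

    @classmethod
    def from_dataframe(
        cls,
        table: pd.DataFrame,
        response: str,
        predictors: Sequence[str],
        cov,
        interactions: Sequence[tuple[str, str]] = (),
        quadratic: Sequence[str] = (),
        gsd_reference: str = "XY",
    ) -> "PGLS":
        """Build the design from a trait table (rows already aligned to the
        covariance).  A ``gsd`` predictor is coded 0/1 with ``gsd_reference``
        as 0; interaction tuples add product columns; ``quadratic`` names add
        squared columns."""
        work = table.copy()
        if "gsd" in work.columns:
            work["gsd"] = gsd_indicator(work["gsd"], gsd_reference)
        cols: dict[str, np.ndarray] = {"Intercept": np.ones(len(work))}
        for name in predictors:
            cols[name] = pd.to_numeric(work[name]).to_numpy(dtype=float)
        for a, b in interactions:
            cols[f"{a}:{b}"] = cols[a] * cols[b]
        for name in quadratic:
            cols[f"{name}^2"] = cols[name] ** 2
        X = np.column_stack(list(cols.values()))
        y = pd.to_numeric(work[response]).to_numpy(dtype=float)
        return cls(y, X, cov, exog_names=list(cols.keys()))

    # ------------------------------------------------------------- fitting

    def _V(self, lam: float) -> np.ndarray:
        V = lam * self.cov.matrix.copy()
        np.fill_diagonal(V, self._diag)
        return V

    def _profile(self, lam: float):
        """GLS at fixed λ; returns (loglik, beta, XtXinv, rss, logdetV)."""
        L = _cholesky(self._V(lam))
        yw = linalg.solve_triangular(L, self.endog, lower=True)
        Xw = linalg.solve_triangular(L, self.exog, lower=True)
        beta, _, _, _ = np.linalg.lstsq(Xw, yw, rcond=None)
        resid = yw - Xw @ beta
        rss = float(resid @ resid)
        n = len(yw)
        logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
        sigma2_ml = rss / n
        ll = -0.5 * (n * math.log(2 * math.pi * sigma2_ml) + n + logdet)
        return ll, beta, Xw, yw, rss, logdet

    def loglik(self, lam: float) -> float:
        """Profile log-likelihood (β, σ² maximized out) at fixed λ."""
        return self._profile(lam)[0]

    def _optimize_lambda(self, tol: float = 1e-8) -> float:
        grid = np.linspace(0.0, 1.0, 41)
        lls = [self.loglik(g) for g in grid]
        i = int(np.argmax(lls))
        lo = grid[max(i - 1, 0)]
        hi = grid[min(i + 1, len(grid) - 1)]
        if lo == hi:
            return float(grid[i])
        res = optimize.minimize_scalar(
            lambda lam: -self.loglik(lam),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": tol},
        )
        candidates = [(self.loglik(0.0), 0.0), (self.loglik(1.0), 1.0),
                      (lls[i], grid[i]), (-res.fun, float(res.x))]
        best = max(candidates, key=lambda t: t[0])
        return best[1]

    def fit(self, lam: float | str = "ml") -> "PGLSResults":
        """Fit with ``lam="ml"`` (default: profile-ML λ over [0, 1]) or at a
        fixed λ value."""
        if isinstance(lam, str):
            if lam != "ml":
                raise PGLSError(f"unknown lambda method {lam!r}")
            lam_hat = self._optimize_lambda()
        else:
            if not 0.0 <= lam <= 1.0:
                raise PGLSError("lambda must lie in [0, 1]")
            lam_hat = float(lam)
        ll, beta, Xw, yw, rss, _ = self._profile(lam_hat)
        n, k = Xw.shape
        df_resid = n - k
        sigma2 = rss / df_resid
        XtXinv = np.linalg.inv(Xw.T @ Xw)
        cov_params = sigma2 * XtXinv
        bse = np.sqrt(np.diag(cov_params))
        tvals = beta / bse
        pvals = 2.0 * stats.t.sf(np.abs(tvals), df_resid)
        # null (intercept-only) RSS at the same lambda, for R^2
        ones_w = linalg.solve_triangular(
            _cholesky(self._V(lam_hat)), np.ones(n), lower=True
        )
        b0 = float(ones_w @ yw) / float(ones_w @ ones_w)
        rss0 = float(np.sum((yw - ones_w * b0) ** 2))
        r2 = 1.0 - rss / rss0 if rss0 > 0 else np.nan
        n_params = k + 2  # coefficients + sigma^2 + lambda
        return PGLSResults(
            model=self,
            params=pd.Series(beta, index=self.exog_names),
            bse=pd.Series(bse, index=self.exog_names),
            tvalues=pd.Series(tvals, index=self.exog_names),
            pvalues=pd.Series(pvals, index=self.exog_names),
            cov_params=pd.DataFrame(
                cov_params, index=self.exog_names, columns=self.exog_names
            ),
            lam=lam_hat,
            llf=ll,
            aic=-2.0 * ll + 2.0 * n_params,
            rsquared=r2,
            nobs=n,
            df_resid=df_resid,
            resid=yw - Xw @ beta,
            scale=sigma2,
        )


@dataclass
class PGLSResults:
    """Estimates from a PGLS fit (Wald inference at the ML λ)."""

    model: PGLS
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    cov_params: pd.DataFrame
    lam: float
    llf: float
    aic: float
    rsquared: float
    nobs: int
    df_resid: int
    resid: np.ndarray
    scale: float

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        crit = stats.t.ppf(1 - alpha / 2, self.df_resid)
        return pd.DataFrame(
            {
                "lower": self.params - crit * self.bse,
                "upper": self.params + crit * self.bse,
            }
        )

    def summary(self) -> str:
        rows = pd.DataFrame(
            {
                "b": self.params,
                "SE": self.bse,
                "t": self.tvalues,
                "p": self.pvalues,
            }
        )
        head = (
            f"PGLS (ML Pagel's lambda)\n"
            f"n = {self.nobs}, lambda = {self.lam:.3f}, "
            f"R^2 = {self.rsquared:.3f}, logLik = {self.llf:.3f}, "
            f"AIC = {self.aic:.3f}\n"
        )
        return head + rows.to_string(float_format=lambda v: f"{v: .4f}")

    def to_row(self) -> dict:
        """Table-1-shaped record for the first non-intercept coefficient."""
        name = next(n for n in self.params.index if n != "Intercept")
        return {
            "term": name,
            "b": self.params[name],
            "se": self.bse[name],
            "t": self.tvalues[name],
            "p": self.pvalues[name],
            "lambda": self.lam,
            "r2": self.rsquared,
            "n": self.nobs,
        }


# --------------------------------------------------------------------------
# Marginal (type-3) tests and group slopes
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class MarginalTest:
    term: str
    F: float
    df_num: int
    df_den: int
    p: float


def anova_marginal(
    fit: PGLSResults, terms: Mapping[str, Sequence[str]] | None = None
) -> list[MarginalTest]:
    """Type-3 ("marginal") Wald F-tests: each term tested given all others.

    ``terms`` maps a term name to the coefficient names it comprises; by
    default every non-intercept coefficient is its own term.  For a
    single-coefficient term F equals t² exactly.
    """
    names = list(fit.params.index)
    if terms is None:
        terms = {n: [n] for n in names if n != "Intercept"}
    out = []
    V = fit.cov_params.to_numpy()
    for term, cols in terms.items():
        idx = [names.index(c) for c in cols]
        b = fit.params.to_numpy()[idx]
        Vbb = V[np.ix_(idx, idx)]
        try:
            wald = float(b @ np.linalg.solve(Vbb, b))
        except np.linalg.LinAlgError as exc:
            raise PGLSError(f"aliased term {term!r}") from exc
        m = len(idx)
        F = wald / m
        p = float(stats.f.sf(F, m, fit.df_resid))
        out.append(MarginalTest(term, F, m, fit.df_resid, p))
    return out


def group_slopes(
    fit: PGLSResults,
    trait: str,
    groups: Sequence[str] = ("XY", "ZW"),
    interaction: str | None = None,
    alpha: float = 0.05,
) -> dict[str, dict[str, float]]:
    """Per-group trait slopes from an interaction fit (emtrends-style).

    With XY the reference level, slope(XY) = b_trait and
    slope(ZW) = b_trait + b_interaction; the SE follows from the coefficient
    covariance of the linear combination and the CI uses the t distribution
    with the model's residual df.
    """
    names = list(fit.params.index)
    if trait not in names:
        raise PGLSError(f"no coefficient {trait!r} in fit")
    if interaction is None:
        cands = [n for n in names if ":" in n and trait in n.split(":")]
        if not cands:
            raise PGLSError("no interaction coefficient found")
        interaction = cands[0]
    V = fit.cov_params.to_numpy()
    crit = stats.t.ppf(1 - alpha / 2, fit.df_resid)
    out = {}
    for g, grp in enumerate(groups):
        L = np.zeros(len(names))
        L[names.index(trait)] = 1.0
        if g == 1:
            L[names.index(interaction)] = 1.0
        slope = float(L @ fit.params.to_numpy())
        se = math.sqrt(float(L @ V @ L))
        out[grp] = {
            "slope": slope,
            "se": se,
            "lower": slope - crit * se,
            "upper": slope + crit * se,
        }
    return out


# --------------------------------------------------------------------------
# Quadratic-term comparison
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class QuadraticComparison:
    delta_aic: float  # AIC(quadratic) - AIC(linear); positive favors linear
    chi2: float
    p: float
    linear: PGLSResults
    quadratic: PGLSResults


def compare_quadratic(y, x, cov) -> QuadraticComparison:
    """Does a quadratic term improve on the linear PGLS model?

    Both models are fitted with their own ML λ; ΔAIC = AIC(quad) − AIC(lin)
    (positive means the model without the quadratic term is preferred) and
    the LRT has 1 df."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    Xl = np.column_stack([np.ones_like(x), x])
    Xq = np.column_stack([np.ones_like(x), x, x**2])
    fit_l = PGLS(y, Xl, cov, exog_names=["Intercept", "x"]).fit()
    fit_q = PGLS(y, Xq, cov, exog_names=["Intercept", "x", "x^2"]).fit()
    chi2 = max(0.0, 2.0 * (fit_q.llf - fit_l.llf))
    p = float(stats.chi2.sf(chi2, 1))
    return QuadraticComparison(fit_q.aic - fit_l.aic, chi2, p, fit_l, fit_q)


# --------------------------------------------------------------------------
# Simulation power analysis
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PowerResult:
    power: float
    se: float
    n_reps: int
    effect: float
    alpha: float
    n: int


def power_simulation(
    x,
    effect: float,
    n_reps: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    kind: str = "correlation",
) -> PowerResult:
    """Simulation power analysis for a linear model on (phylogenetically
    transformed) data.

    ``x`` is the fixed predictor (e.g., independent contrasts of the real
    predictor).  Each replicate simulates ``y* = effect * x_std + eps`` and
    tests the slope at level ``alpha`` with an ordinary linear model.  For
    ``kind="correlation"`` x is z-scored and ``eps ~ N(0, 1 - effect²)`` so
    the standardized slope equals the target correlation effect size; for
    ``kind="difference"`` (Cohen's d with a 0/1 predictor) ``eps ~ N(0, 1)``.
    """
    if n_reps < 100:
        raise PGLSError("n_reps must be >= 100")
    x = np.asarray(x, dtype=float)
    if np.std(x) == 0:
        raise PGLSError("degenerate predictor (zero variance)")
    if kind == "correlation":
        if abs(effect) >= 1:
            raise PGLSError("correlation effect must satisfy |effect| < 1")
        xs = (x - x.mean()) / x.std(ddof=1)
        sigma = math.sqrt(1.0 - effect**2)
    elif kind == "difference":
        xs = x
        sigma = 1.0
    else:
        raise PGLSError(f"unknown kind {kind!r}")
    n = len(xs)
    rng = np.random.default_rng(seed)
    X = np.column_stack([np.ones(n), xs])
    XtXinv = np.linalg.inv(X.T @ X)
    hits = 0
    crit = stats.t.ppf(1 - alpha / 2, n - 2)
    for _ in range(n_reps):
        y = effect * xs + rng.normal(0.0, sigma, size=n)
        beta = XtXinv @ (X.T @ y)
        resid = y - X @ beta
        s2 = float(resid @ resid) / (n - 2)
        se = math.sqrt(s2 * XtXinv[1, 1])
        if abs(beta[1] / se) > crit:
            hits += 1
    power = hits / n_reps
    se_power = math.sqrt(max(power * (1 - power), 1.0 / n_reps) / n_reps)
    return PowerResult(power, se_power, n_reps, effect, alpha, n)
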