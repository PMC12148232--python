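"""Confirmatory phylogenetic path analysis by d-separation.

The candidate structures are eight directed acyclic graphs over the vertices
GSD (sex-determination system, numerically coded), JMB/AMB (juvenile/adult
mortality bias), MAT (maturation bias) and ASR (adult sex ratio).  Every
model contains AMB→ASR, JMB→ASR, MAT→ASR and GSD→AMB; the ".b" variants add
the direct GSD→ASR edge; models 2/3/4 add GSD→JMB, GSD→MAT, or both.

Each model's testable content is its basis set of independence claims.  Two
fitting flavors are provided:

* ``"santos"`` — Pagel's λ is estimated per variable, the tree is rescaled by
  that λ, independent contrasts are computed per variable on its own rescaled
  tree, and claims are tested by ordinary regressions on the transformed
  data (piecewiseSEM-style).  Exogenous–exogenous pairs are treated as freely
  correlated and therefore excluded from the basis set.
* ``"hardenberg"`` — claims are tested by PGLS with ML λ on the raw data and
  the basis set contains every non-adjacent pair (phylopath-style).

Model fit is summarized by Fisher's C = −2 Σ ln pᵢ (χ² with 2k df) and
models are ranked by the small-sample information criterion
``C + 2 q n / (n − 1 − q)`` (AICc for the santos flavor, CICc for the
hardenberg flavor; the flavors count q differently).  Nested models can also
be compared by a Gaussian likelihood-ratio test on the transformed data.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .phylo import PhyloCovariance, Phylogeny, independent_contrasts, phylo_covariance
from .pgls import PGLS
from .traits import gsd_indicator, model_subset, standardize

VERTICES = ("GSD", "JMB", "AMB", "MAT", "ASR")

#: trait-table column for each path-model vertex
VERTEX_COLUMNS = {"GSD": "gsd", "JMB": "jmb", "AMB": "amb", "MAT": "mat", "ASR": "asr"}

MODEL_IDS = ("m1.a", "m1.b", "m2.a", "m2.b", "m3.a", "m3.b", "m4.a", "m4.b")


class PathError(ValueError):
    pass


@dataclass(frozen=True)
class PathModel:
    """A DAG over the five study variables."""

    id: str
    edges: tuple[tuple[str, str], ...]

    def __post_init__(self):
        for a, b in self.edges:
            if a not in VERTICES or b not in VERTICES:
                raise PathError(f"unknown vertex in edge {a}->{b}")
        if self._has_cycle():
            raise PathError(f"model {self.id} is cyclic")

    def _has_cycle(self) -> bool:
        try:
            self.causal_order()
            return False
        except PathError:
            return True

    @property
    def vertices(self) -> tuple[str, ...]:
        return VERTICES

    def parents(self, v: str) -> tuple[str, ...]:
        return tuple(a for a, b in self.edges if b == v)

    @property
    def exogenous(self) -> tuple[str, ...]:
        return tuple(v for v in VERTICES if not self.parents(v))

    @property
    def endogenous(self) -> tuple[str, ...]:
        return tuple(v for v in VERTICES if self.parents(v))

    def adjacent(self, a: str, b: str) -> bool:
        return (a, b) in self.edges or (b, a) in self.edges

    def causal_order(self) -> tuple[str, ...]:
        """Deterministic topological order (alphabetical tie-break)."""
        placed: list[str] = []
        remaining = set(VERTICES)
        while remaining:
            ready = sorted(
                v for v in remaining if set(self.parents(v)) <= set(placed)
            )
            if not ready:
                raise PathError("cycle detected")
            placed.append(ready[0])
            remaining.discard(ready[0])
        return tuple(placed)

    def is_nested_in(self, other: "PathModel") -> bool:
        return set(self.edges) <= set(other.edges)

    def n_free_parameters(self) -> int:
        """Free parameters under the Gaussian path-model convention:
        saturated covariance among exogenous vertices, one coefficient per
        edge, one residual variance per endogenous vertex."""
        m = len(self.exogenous)
        return m * (m + 1) // 2 + sum(
            len(self.parents(v)) + 1 for v in self.endogenous
        )


def build_model_set() -> dict[str, PathModel]:
    """The eight candidate models; m1.a ⊂ m1.b ⊂ each ".b" expansion."""
    base = (("GSD", "AMB"), ("JMB", "ASR"), ("AMB", "ASR"), ("MAT", "ASR"))
    extras = {"m1": (), "m2": (("GSD", "JMB"),), "m3": (("GSD", "MAT"),),
              "m4": (("GSD", "JMB"), ("GSD", "MAT"))}
    models = {}
    for stem, extra in extras.items():
        models[f"{stem}.a"] = PathModel(f"{stem}.a", base + tuple(extra))
        models[f"{stem}.b"] = PathModel(
            f"{stem}.b", base + tuple(extra) + (("GSD", "ASR"),)
        )
    return {mid: models[mid] for mid in MODEL_IDS}


@dataclass(frozen=True)
class IndependenceClaim:
    """Claim that ``response`` is independent of ``other`` given ``cond``;
    the response is the pair member later in the model's causal order."""

    response: str
    other: str
    cond: tuple[str, ...]

    def __post_init__(self):
        if self.response in self.cond or self.other in self.cond:
            raise PathError("tested variable appears in its conditioning set")

    def __str__(self) -> str:
        cset = "{" + ", ".join(self.cond) + "}"
        return f"{self.response} _||_ {self.other} | {cset}"


def basis_set(model: PathModel, style: str) -> list[IndependenceClaim]:
    """Independence claims for a model under a fitting flavor.

    ``"hardenberg"``: every non-adjacent pair.  ``"santos"``: non-adjacent
    pairs excluding those whose members are both exogenous (their covariance
    is a free parameter, not a claim)."""
    _check_style(style)
    order = model.causal_order()
    rank = {v: i for i, v in enumerate(order)}
    claims = []
    for a, b in itertools.combinations(VERTICES, 2):
        if model.adjacent(a, b):
            continue
        if style == "santos" and not model.parents(a) and not model.parents(b):
            continue
        resp, other = (a, b) if rank[a] > rank[b] else (b, a)
        cond = tuple(
            sorted((set(model.parents(a)) | set(model.parents(b))) - {a, b})
        )
        claims.append(IndependenceClaim(resp, other, cond))
    claims.sort(key=lambda c: (rank[c.response], rank[c.other]))
    return claims


def _check_style(style: str) -> None:
    if style not in ("santos", "hardenberg"):
        raise PathError(f"unknown style {style!r}")


# --------------------------------------------------------------------------
# Fit statistics
# --------------------------------------------------------------------------


def fisher_c(claim_pvalues: Sequence[float]) -> tuple[float, int, float]:
    """Fisher's C = −2 Σ ln pᵢ with df = 2k and its χ² survival p-value.
    A claim p of exactly 0 yields C = inf (certain rejection)."""
    pvals = [float(p) for p in claim_pvalues]
    if not pvals:
        raise PathError("need at least one claim p-value")
    if any(p < 0 or p > 1 for p in pvals):
        raise PathError("claim p-values must lie in [0, 1]")
    df = 2 * len(pvals)
    if any(p == 0 for p in pvals):
        return math.inf, df, 0.0
    C = -2.0 * sum(math.log(p) for p in pvals)
    return C, df, float(stats.chi2.sf(C, df))


def information_criterion(C: float, q: int, n: int, flavor: str = "CICc") -> float:
    """Small-sample information criterion for d-separation path models:
    ``C + 2 q n / (n − 1 − q)`` (AICc when C comes from the santos flavor,
    CICc for the hardenberg flavor)."""
    if flavor not in ("AICc", "CICc"):
        raise PathError(f"unknown flavor {flavor!r}")
    if n <= q + 1:
        raise PathError(f"n={n} too small for q={q}")
    return C + 2.0 * q * n / (n - 1 - q)


def santos_q(model: PathModel) -> int:
    """Parameter count, piecewiseSEM-style: per endogenous regression the
    coefficients including the intercept, plus one residual variance each."""
    return sum(len(model.parents(v)) + 2 for v in model.endogenous)


def hardenberg_q(model: PathModel) -> int:
    """Parameter count, phylopath-style: edges + vertices."""
    return len(model.edges) + len(VERTICES)


# --------------------------------------------------------------------------
# Data preparation
# --------------------------------------------------------------------------


def prepare_path_data(
    table: pd.DataFrame, tree: Phylogeny
) -> tuple[pd.DataFrame, Phylogeny]:
    """Complete cases for the five path variables, z-scored, tree-aligned.
    GSD enters numerically (XY = 0, ZW = 1) before standardization."""
    needed = list(VERTEX_COLUMNS.values())
    sub, pruned = model_subset(table, needed, tree, standardize_scope="subset")
    data = pd.DataFrame(index=sub["species"])
    for vertex, col in VERTEX_COLUMNS.items():
        series = sub[col] if col != "gsd" else gsd_indicator(sub["gsd"])
        series = pd.Series(np.asarray(series, dtype=float), index=data.index)
        data[vertex] = standardize(series).to_numpy()
    return data, pruned


def santos_transform(
    data: pd.DataFrame, tree: Phylogeny
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-variable λ-rescaled independent contrasts (the santos flavor's
    phylogenetic transformation).

    For each column of ``data`` (complete cases, indexed by species matching
    the tree tips) Pagel's λ is estimated by ML from an intercept-only PGLS,
    the tree is rescaled by that λ, and standardized contrasts are computed
    on the rescaled tree.  Rows of the output are aligned across variables by
    contrast node."""
    cov = phylo_covariance(tree)
    missing = set(data.index) - set(cov.labels)
    if missing:
        raise PathError(f"species not in tree: {sorted(missing)[:5]}")
    data = data.loc[list(cov.labels)]
    lambdas: dict[str, float] = {}
    columns: dict[str, np.ndarray] = {}
    node_ids = None
    for col in data.columns:
        y = data[col].to_numpy(dtype=float)
        if np.std(y) == 0:
            raise PathError(f"variable {col!r} has no variance")
        lam = PGLS(y, np.ones((len(y), 1)), cov, ["Intercept"])._optimize_lambda()
        lambdas[col] = lam
        contrasts = independent_contrasts(
            tree.rescale_lambda(lam), data[col]
        )
        columns[col] = contrasts.contrasts
        if node_ids is None:
            node_ids = contrasts.node_ids
        elif node_ids != contrasts.node_ids:  # pragma: no cover - defensive
            raise PathError("contrast nodes misaligned across variables")
    out = pd.DataFrame(columns, index=pd.Index(node_ids, name="node"))
    return out, lambdas


# --------------------------------------------------------------------------
# Claim tests
# --------------------------------------------------------------------------


def _ols_pvalue(
    y: np.ndarray, X: np.ndarray, test_col: int
) -> tuple[float, float, float]:
    """(coef, se, two-sided p) for one column of an OLS fit."""
    n, k = X.shape
    if n <= k:
        raise PathError("too few rows for claim regression")
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < k:
        raise PathError("conditioning set collinear with tested variable")
    resid = y - X @ beta
    s2 = float(resid @ resid) / (n - k)
    XtXinv = np.linalg.inv(X.T @ X)
    se = math.sqrt(s2 * XtXinv[test_col, test_col])
    t = beta[test_col] / se
    p = 2.0 * float(stats.t.sf(abs(t), n - k))
    return float(beta[test_col]), se, p


def test_claim(
    claim: IndependenceClaim,
    data: pd.DataFrame,
    style: str,
    cov: PhyloCovariance | None = None,
    intercept: bool = True,
) -> float:
    """p-value of the independence coefficient for one claim.

    santos: ordinary regression (intercept included by default) of the
    response on the other variable plus the conditioning set, on contrast
    data.  hardenberg: the same regression as a PGLS with ML λ on the raw
    data (``cov`` required)."""
    _check_style(style)
    cols = [claim.other, *claim.cond]
    y = data[claim.response].to_numpy(dtype=float)
    X_parts = [data[c].to_numpy(dtype=float) for c in cols]
    if style == "santos":
        mats = ([np.ones(len(y))] if intercept else []) + X_parts
        X = np.column_stack(mats)
        test_col = 1 if intercept else 0
        _, _, p = _ols_pvalue(y, X, test_col)
        return p
    if cov is None:
        raise PathError("hardenberg claims need the phylogenetic covariance")
    X = np.column_stack([np.ones(len(y))] + X_parts)
    fit = PGLS(y, X, cov, exog_names=["Intercept"] + cols).fit()
    return float(fit.pvalues[claim.other])


# --------------------------------------------------------------------------
# Path coefficients with bootstrap CIs
# --------------------------------------------------------------------------


def fit_path_coefficients(
    model: PathModel,
    data: pd.DataFrame,
    style: str,
    n_boot: int = 500,
    seed: int = 0,
    cov: PhyloCovariance | None = None,
    intercept: bool = True,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Standardized path coefficients with residual-bootstrap percentile CIs.

    Each endogenous vertex is regressed on its parents on the flavor's data
    (contrasts for santos, raw + PGLS for hardenberg; the hardenberg λ is
    estimated once per regression and held fixed across bootstrap refits).
    Coefficients are reported on the standardized scale
    (b · SD(parent)/SD(child), SDs from the analysis data).  The bootstrap
    resamples residuals within each regression — species resampling would
    break the phylogenetic alignment.  Singular bootstrap replicates are
    dropped and counted."""
    _check_style(style)
    if n_boot and n_boot < 100:
        raise PathError("n_boot must be 0 or >= 100")
    rng = np.random.default_rng(seed)
    rows = []
    for child in model.causal_order():
        parents = list(model.parents(child))
        if not parents:
            continue
        y = data[child].to_numpy(dtype=float)
        P = np.column_stack([data[p].to_numpy(dtype=float) for p in parents])
        if style == "santos":
            X = (
                np.column_stack([np.ones(len(y)), P]) if intercept else P
            )
            offset = 1 if intercept else 0
            L = None
        else:
            if cov is None:
                raise PathError("hardenberg coefficients need the covariance")
            X = np.column_stack([np.ones(len(y)), P])
            offset = 1
            fit0 = PGLS(y, X, cov, ["Intercept"] + parents).fit()
            from .pgls import _cholesky  # local import to avoid cycle at top

            V = fit0.lam * cov.matrix.copy()
            np.fill_diagonal(V, np.diag(cov.matrix))
            L = _cholesky(V)
            from scipy.linalg import solve_triangular

            y = solve_triangular(L, y, lower=True)
            X = solve_triangular(L, X, lower=True)
        beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        if rank < X.shape[1]:
            raise PathError(f"singular regression for {child}")
        fitted = X @ beta
        resid = y - fitted
        sd_y = float(np.std(data[child].to_numpy(dtype=float), ddof=1))
        sd_p = [float(np.std(data[p].to_numpy(dtype=float), ddof=1)) for p in parents]
        std_coefs = [beta[offset + j] * sd_p[j] / sd_y for j in range(len(parents))]
        boot = np.full((n_boot, len(parents)), np.nan)
        dropped = 0
        for b in range(n_boot):
            ystar = fitted + rng.choice(resid, size=len(resid), replace=True)
            bstar, _, rank_b, _ = np.linalg.lstsq(X, ystar, rcond=None)
            if rank_b < X.shape[1]:  # pragma: no cover - degenerate resample
                dropped += 1
                continue
            for j in range(len(parents)):
                boot[b, j] = bstar[offset + j] * sd_p[j] / sd_y
        for j, parent in enumerate(parents):
            if n_boot:
                col = boot[:, j]
                col = col[np.isfinite(col)]
                lo, hi = np.percentile(col, [100 * alpha / 2, 100 * (1 - alpha / 2)])
            else:
                lo = hi = np.nan
            rows.append(
                {
                    "edge": f"{parent}->{child}",
                    "coef": std_coefs[j],
                    "lower": lo,
                    "upper": hi,
                    "n_boot": (n_boot - dropped) if n_boot else 0,
                }
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Gaussian path-model likelihood and nested LRT
# --------------------------------------------------------------------------


def model_loglik(model: PathModel, data: pd.DataFrame) -> tuple[float, int]:
    """ML log-likelihood of a recursive Gaussian path model on the given
    (transformed) data, with saturated means, saturated exogenous
    covariances, independent residuals; returns (loglik, n free params)."""
    cols = list(VERTICES)
    X = data[cols].to_numpy(dtype=float)
    n, p = X.shape
    Xc = X - X.mean(axis=0)
    S = (Xc.T @ Xc) / n
    idx = {v: i for i, v in enumerate(cols)}
    B = np.zeros((p, p))
    Psi = np.zeros((p, p))
    exo = [idx[v] for v in model.exogenous]
    Psi[np.ix_(exo, exo)] = S[np.ix_(exo, exo)]
    for child in model.endogenous:
        parents = list(model.parents(child))
        pi = [idx[q] for q in parents]
        ci = idx[child]
        Z = np.column_stack([np.ones(n), X[:, pi]])
        beta, _, _, _ = np.linalg.lstsq(Z, X[:, ci], rcond=None)
        resid = X[:, ci] - Z @ beta
        for j, q in enumerate(pi):
            B[ci, q] = beta[1 + j]
        Psi[ci, ci] = float(resid @ resid) / n
    Imb = np.eye(p) - B
    inv = np.linalg.inv(Imb)
    Sigma = inv @ Psi @ inv.T
    sign, logdet = np.linalg.slogdet(Sigma)
    if sign <= 0:
        raise PathError("implied covariance not positive definite")
    ll = -0.5 * n * (
        p * math.log(2 * math.pi) + logdet + float(np.trace(np.linalg.solve(Sigma, S)))
    )
    return ll, model.n_free_parameters()


def lrt_nested(
    model_small: PathModel, model_large: PathModel, data: pd.DataFrame
) -> tuple[float, int, float]:
    """Likelihood-ratio test between nested path models on transformed data.

    Requires the small model's edge set to be a subset of the large one's.
    The df is the difference in free parameters (equal to the edge difference
    when the exogenous vertices are unchanged)."""
    if not model_small.is_nested_in(model_large):
        raise PathError(
            f"{model_small.id} is not nested in {model_large.id}"
        )
    ll_s, q_s = model_loglik(model_small, data)
    ll_l, q_l = model_loglik(model_large, data)
    ddf = abs(q_l - q_s)
    if q_l >= q_s:
        chi2 = max(0.0, 2.0 * (ll_l - ll_s))
    else:
        chi2 = max(0.0, 2.0 * (ll_s - ll_l))
    p = 1.0 if ddf == 0 else float(stats.chi2.sf(chi2, ddf))
    return chi2, ddf, p


def saturated_model() -> PathModel:
    """Fully connected DAG in the deterministic causal order (for LRT
    calibration against a candidate model)."""
    base_order = ("GSD", "JMB", "AMB", "MAT", "ASR")
    edges = tuple(
        (base_order[i], base_order[j])
        for i in range(5)
        for j in range(i + 1, 5)
    )
    return PathModel("saturated", edges)


# --------------------------------------------------------------------------
# Model-set analysis
# --------------------------------------------------------------------------


@dataclass
class DSepReport:
    model_id: str
    style: str
    claims: list[IndependenceClaim]
    claim_pvalues: list[float]
    C: float
    df: int
    k: int
    q: int
    p: float
    ic: float

    @property
    def ic_flavor(self) -> str:
        return "AICc" if self.style == "santos" else "CICc"


@dataclass
class DSepResults:
    """Ranked d-separation reports for a model set (one flavor)."""

    style: str
    n: int
    reports: dict[str, DSepReport]
    lambdas: dict[str, float] | None = None
    coefficients: pd.DataFrame | None = None

    @property
    def best_model(self) -> str:
        return min(self.reports.values(), key=lambda r: r.ic).model_id

    def table(self) -> pd.DataFrame:
        best_ic = min(r.ic for r in self.reports.values())
        rows = []
        for r in self.reports.values():
            rows.append(
                {
                    "model": r.model_id,
                    "C": r.C,
                    "df": r.df,
                    "k": r.k,
                    "q": r.q,
                    "p": r.p,
                    r.ic_flavor: r.ic,
                    f"d{r.ic_flavor}": r.ic - best_ic,
                }
            )
        out = pd.DataFrame(rows).sort_values(
            out_col := ("AICc" if self.style == "santos" else "CICc")
        )
        return out.reset_index(drop=True)

    def summary(self) -> str:
        head = (
            f"d-separation path analysis ({self.style} flavor), n = {self.n}\n"
            f"best model: {self.best_model}\n"
        )
        return head + self.table().to_string(
            index=False, float_format=lambda v: f"{v:.3f}"
        )


class PathAnalysis:
    """Confirmatory path analysis over a model set.

    Parameters
    ----------
    table : DataFrame
        Trait table with ``species``, ``gsd`` and the four continuous bias
        columns (``asr``, ``jmb``, ``amb``, ``mat``).
    tree : Phylogeny
    models : mapping, optional
        Defaults to the eight-model candidate set.
    style : {"santos", "hardenberg"}
    """

    def __init__(
        self,
        table: pd.DataFrame,
        tree: Phylogeny,
        models: Mapping[str, PathModel] | None = None,
        style: str = "santos",
    ):
        _check_style(style)
        self.style = style
        self.models = dict(models) if models is not None else build_model_set()
        self.data, self.tree = prepare_path_data(table, tree)
        self.cov = phylo_covariance(self.tree)
        if style == "santos":
            self.transformed, self.lambdas = santos_transform(self.data, self.tree)
        else:
            self.transformed, self.lambdas = None, None

    @property
    def nobs(self) -> int:
        return len(self.data)

    def _claim_data(self) -> pd.DataFrame:
        return self.transformed if self.style == "santos" else self.data

    def fit(self, n_boot: int = 0, seed: int = 0) -> DSepResults:
        reports = {}
        for mid, model in self.models.items():
            claims = basis_set(model, self.style)
            pvals = [
                test_claim(
                    c,
                    self._claim_data(),
                    self.style,
                    cov=None if self.style == "santos" else self.cov,
                )
                for c in claims
            ]
            C, df, p = fisher_c(pvals)
            q = santos_q(model) if self.style == "santos" else hardenberg_q(model)
            ic = information_criterion(
                C, q, self.nobs, "AICc" if self.style == "santos" else "CICc"
            )
            reports[mid] = DSepReport(
                mid, self.style, claims, pvals, C, df, len(claims), q, p, ic
            )
        results = DSepResults(self.style, self.nobs, reports, self.lambdas)
        if n_boot:
            best = self.models[results.best_model]
            results.coefficients = fit_path_coefficients(
                best,
                self._claim_data(),
                self.style,
                n_boot=n_boot,
                seed=seed,
                cov=None if self.style == "santos" else self.cov,
            )
        return results
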