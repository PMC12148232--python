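"""Mk-model fitting and stochastic character mapping for the binary
sex-determination character (XY vs ZW).

The character evolves by a continuous-time Markov chain with generator

    Q = [[-q01, q01], [q10, -q10]],   states 0 = XY, 1 = ZW.

``ER`` constrains q01 = q10 (one rate); ``ARD`` frees both.  The likelihood
is computed by Felsenstein's pruning algorithm with an equal (0.5/0.5) root
prior by default, rates are estimated by bounded ML, and models are compared
by AIC.  Stochastic maps sample full character histories conditional on the
tip data — node states from the conditional distributions, then within-branch
histories by uniformization (exact, no rejection bias) — and transitions are
counted per direction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .phylo import Phylogeny, PhyloError

STATES = ("XY", "ZW")
_STATE_INDEX = {"XY": 0, "ZW": 1}


class MkError(ValueError):
    pass


def _transition_matrix(q01: float, q10: float, t: float) -> np.ndarray:
    """Closed-form 2-state P(t) = Pi + exp(-(q01+q10) t) (I - Pi)."""
    s = q01 + q10
    if s == 0.0 or t == 0.0:
        return np.eye(2)
    pi0, pi1 = q10 / s, q01 / s
    e = math.exp(-s * t)
    return np.array(
        [
            [pi0 + pi1 * e, pi1 - pi1 * e],
            [pi0 - pi0 * e, pi1 + pi0 * e],
        ]
    )


def _tip_states(tree: Phylogeny, states: Mapping[str, str] | pd.Series) -> dict:
    if isinstance(states, pd.Series):
        states = states.to_dict()
    out = {}
    for lab in tree.tip_labels:
        if lab not in states:
            raise MkError(f"tip {lab!r} has no character state")
        s = states[lab]
        if s not in _STATE_INDEX:
            raise MkError(f"unknown state {s!r} for tip {lab!r} (need XY/ZW)")
        out[lab] = _STATE_INDEX[s]
    return out


def mk_loglik(
    tree: Phylogeny,
    states: Mapping[str, str] | pd.Series,
    q01: float,
    q10: float,
    root_prior: Sequence[float] = (0.5, 0.5),
) -> float:
    """Pruning-algorithm log-likelihood of the binary Mk model."""
    if q01 < 0 or q10 < 0:
        raise MkError("rates must be non-negative")
    tree._require_lengths()
    tips = _tip_states(tree, states)
    ll, _ = _scaled_loglik(tree, tips, q01, q10, tuple(root_prior))
    return ll


def _scaled_loglik(tree, tips, q01, q10, root_prior) -> tuple[float, dict]:
    """Pruning pass with per-node rescaling; returns (loglik, partials).
    Partials are conditional likelihoods up to a positive per-node factor,
    which is all the downstream state sampling needs."""
    partials: dict[int, np.ndarray] = {}
    log_scale = 0.0
    for node in tree.postorder():
        if node.is_tip:
            vec = np.zeros(2)
            vec[tips[node.label]] = 1.0
        else:
            vec = np.ones(2)
            for child in node.children:
                P = _transition_matrix(q01, q10, child.length)
                vec = vec * (P @ partials[id(child)])
            m = vec.max()
            if m > 0:
                vec = vec / m
                log_scale += math.log(m)
        partials[id(node)] = vec
    root = partials[id(tree.root)]
    like = float(root_prior[0] * root[0] + root_prior[1] * root[1])
    if like <= 0:
        return -math.inf, partials
    return math.log(like) + log_scale, partials


@dataclass
class MkResults:
    """ML fit of the binary Mk model."""

    model: str
    rates: dict[str, float]  # {"XY->ZW": q01, "ZW->XY": q10}
    llf: float
    aic: float
    root_prior: tuple[float, float]
    tree: Phylogeny
    states: dict

    @property
    def q01(self) -> float:
        return self.rates["XY->ZW"]

    @property
    def q10(self) -> float:
        return self.rates["ZW->XY"]

    def summary(self) -> str:
        return (
            f"Mk model ({self.model}): "
            f"q(XY->ZW) = {self.q01:.6g}, q(ZW->XY) = {self.q10:.6g}, "
            f"logLik = {self.llf:.4f}, AIC = {self.aic:.4f}"
        )

    def simulate_maps(self, n_maps: int, seed: int = 0) -> "SimmapSummary":
        return stochastic_maps(self.tree, self.states, self, n_maps, seed)


class MkModel:
    """Binary Mk model of a tip character on a tree.

    ``model`` is ``"ER"`` (equal rates, 1 parameter) or ``"ARD"`` (all rates
    different, 2 parameters)."""

    def __init__(
        self,
        tree: Phylogeny,
        states: Mapping[str, str] | pd.Series,
        model: str = "ER",
        root_prior: Sequence[float] = (0.5, 0.5),
    ):
        if model not in ("ER", "ARD"):
            raise MkError(f"unknown model {model!r}")
        tree._require_lengths()
        if tree.total_length() <= 0:
            raise MkError("tree has zero total depth")
        self.tree = tree
        self.model = model
        self.root_prior = (float(root_prior[0]), float(root_prior[1]))
        self.tips = _tip_states(tree, states)
        self.states = {
            lab: STATES[s] for lab, s in self.tips.items()
        }

    def loglik(self, q01: float, q10: float) -> float:
        ll, _ = _scaled_loglik(
            self.tree, self.tips, q01, q10, self.root_prior
        )
        return ll

    def fit(self) -> MkResults:
        observed = set(self.tips.values())
        height = self.tree.height()
        if len(observed) == 1:
            warnings.warn(
                "single-state data: rates at the zero boundary", stacklevel=2
            )
            ll = self.loglik(0.0, 0.0)
            rates = {"XY->ZW": 0.0, "ZW->XY": 0.0}
            npar = 1 if self.model == "ER" else 2
            return MkResults(
                self.model, rates, ll, -2 * ll + 2 * npar,
                self.root_prior, self.tree, self.states,
            )
        lo, hi = math.log(1e-8 / height), math.log(1e3 / height)
        if self.model == "ER":
            res = optimize.minimize_scalar(
                lambda lr: -self.loglik(math.exp(lr), math.exp(lr)),
                bounds=(lo, hi),
                method="bounded",
                options={"xatol": 1e-10},
            )
            q01 = q10 = math.exp(res.x)
            ll = -res.fun
            npar = 1
        else:
            best = None
            for start in ([0.0, 0.0], [-2.0, 2.0], [2.0, -2.0]):
                start = [s + math.log(1.0 / height) for s in start]
                res = optimize.minimize(
                    lambda lr: -self.loglik(math.exp(lr[0]), math.exp(lr[1])),
                    start,
                    method="L-BFGS-B",
                    bounds=[(lo, hi), (lo, hi)],
                )
                if best is None or res.fun < best.fun:
                    best = res
            q01, q10 = math.exp(best.x[0]), math.exp(best.x[1])
            ll = -best.fun
            npar = 2
        rates = {"XY->ZW": q01, "ZW->XY": q10}
        return MkResults(
            self.model, rates, ll, -2 * ll + 2 * npar,
            self.root_prior, self.tree, self.states,
        )


def fit_mk(
    tree: Phylogeny,
    states: Mapping[str, str] | pd.Series,
    model: str = "ER",
    root_prior: Sequence[float] = (0.5, 0.5),
) -> MkResults:
    """Convenience wrapper: build and fit an :class:`MkModel`."""
    return MkModel(tree, states, model, root_prior).fit()


# --------------------------------------------------------------------------
# Stochastic character mapping
# --------------------------------------------------------------------------


@dataclass
class SimmapSummary:
    """Transition counts over a sample of stochastic character maps."""

    n_maps: int
    counts: pd.DataFrame  # columns: XY->ZW, ZW->XY, total (one row per map)

    @property
    def mean_total(self) -> float:
        return float(self.counts["total"].mean())

    @property
    def mean_xy_to_zw(self) -> float:
        return float(self.counts["XY->ZW"].mean())

    @property
    def mean_zw_to_xy(self) -> float:
        return float(self.counts["ZW->XY"].mean())

    def summary(self) -> str:
        return (
            f"{self.n_maps} stochastic maps: "
            f"mean transitions = {self.mean_total:.2f} "
            f"(XY->ZW {self.mean_xy_to_zw:.2f}, ZW->XY {self.mean_zw_to_xy:.2f})"
        )


def _sample_jump_count(
    rng, a: int, b: int, t: float, mu: float, R: np.ndarray, pab: float
) -> int:
    """Number of uniformized jumps on a branch conditional on endpoints."""
    if mu == 0.0:
        return 0
    u = rng.random()
    acc = 0.0
    Rn = np.eye(2)
    log_pois = -mu * t
    n = 0
    while True:
        term = math.exp(log_pois) * Rn[a, b] / pab
        acc += term
        if u <= acc or n > 10000:
            return n
        n += 1
        log_pois += math.log(mu * t) - math.log(n)
        Rn = Rn @ R


def stochastic_maps(
    tree: Phylogeny,
    states: Mapping[str, str] | pd.Series,
    fit: MkResults,
    n_maps: int,
    seed: int = 0,
) -> SimmapSummary:
    """Sample ``n_maps`` character histories conditional on the tip states and
    the fitted rates; count realized transitions per direction.

    Node states are drawn from their conditional distributions (pruning pass
    plus root draw, then a preorder pass conditioning each child on its
    sampled parent); branch histories conditional on both endpoints are drawn
    by uniformization, which is exact."""
    if n_maps < 1:
        raise MkError("n_maps must be >= 1")
    tree._require_lengths()
    tips = _tip_states(tree, states)
    q01, q10 = fit.q01, fit.q10
    _, partials = _scaled_loglik(tree, tips, q01, q10, fit.root_prior)
    rng = np.random.default_rng(seed)
    mu = max(q01, q10)
    Q = np.array([[-q01, q01], [q10, -q10]])
    R = np.eye(2) + Q / mu if mu > 0 else np.eye(2)
    nodes = list(tree.preorder())
    rows = []
    for _ in range(n_maps):
        node_state: dict[int, int] = {}
        n01 = n10 = 0
        for node in nodes:
            vec = partials[id(node)]
            if node.parent is None:
                w = np.array(fit.root_prior) * vec
            else:
                a = node_state[id(node.parent)]
                P = _transition_matrix(q01, q10, node.length)
                w = P[a, :] * vec
            w = w / w.sum()
            b = int(rng.random() < w[1])
            node_state[id(node)] = b
            if node.parent is not None:
                a = node_state[id(node.parent)]
                pab = _transition_matrix(q01, q10, node.length)[a, b]
                njump = _sample_jump_count(rng, a, b, node.length, mu, R, pab)
                # jump chain bridge: sample states at each virtual jump
                s = a
                Rpow = [np.eye(2)]
                for _k in range(njump):
                    Rpow.append(Rpow[-1] @ R)
                for i in range(1, njump + 1):
                    w0 = R[s, 0] * Rpow[njump - i][0, b]
                    w1 = R[s, 1] * Rpow[njump - i][1, b]
                    nxt = int(rng.random() < w1 / (w0 + w1))
                    if nxt != s:
                        if s == 0:
                            n01 += 1
                        else:
                            n10 += 1
                    s = nxt
        rows.append({"XY->ZW": n01, "ZW->XY": n10, "total": n01 + n10})
    return SimmapSummary(n_maps, pd.DataFrame(rows))


# --------------------------------------------------------------------------
# Parsimony oracle
# --------------------------------------------------------------------------


def fitch_score(tree: Phylogeny, states: Mapping[str, str] | pd.Series) -> int:
    """Fitch parsimony count of state changes for the binary character
    (polytomies resolved the package's deterministic way first)."""
    work = tree.resolve_polytomies()
    tips = _tip_states(work, states)
    score = 0
    sets: dict[int, frozenset] = {}
    for node in work.postorder():
        if node.is_tip:
            sets[id(node)] = frozenset({tips[node.label]})
            continue
        s1, s2 = (sets[id(c)] for c in node.children)
        inter = s1 & s2
        if inter:
            sets[id(node)] = inter
        else:
            sets[id(node)] = s1 | s2
            score += 1
    return score
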