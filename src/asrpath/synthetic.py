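"""Synthetic trees and trait tables with the statistical structure the
analysis assumes, so every pipeline stage is testable at desk scale.

The generator emulates the study conditions: a pure-birth (Yule) tree of a
few hundred tips; a binary sex-determination character with rare transitions
(on the order of 17 changes across a 450-tip tree); continuous sex-bias
traits with Pagel's λ around 0.3 built as a λ-blend of Brownian motion and
independent noise; standardized path-model effects with the magnitudes of
the fitted path coefficients (|b| ≈ 0.2–0.8); and block-wise missingness
that reproduces the per-variable sample sizes and the ~95-species
complete-case subset.  Every function is deterministic under a fixed seed
(numpy PCG64).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .phylo import Node, Phylogeny
from .paths import PathModel, build_model_set

#: standardized path coefficients used by default (m1.b structure)
DEFAULT_COEFFICIENTS = {
    ("GSD", "AMB"): -0.5,
    ("AMB", "ASR"): -0.2,
    ("JMB", "ASR"): -0.25,
    ("MAT", "ASR"): -0.2,
    ("GSD", "ASR"): 0.6,
}

#: marginal missingness fractions mirroring the per-variable sample sizes
#: (of 453 species: ASR 446, BSR 112, JMB 108, AMB 244, MAT 366, GSD 446)
DEFAULT_MISSINGNESS = {
    "gsd": 0.0155,
    "asr": 0.0155,
    "bsr": 0.753,
    "jmb": 0.762,
    "amb": 0.461,
    "mat": 0.192,
}


@dataclass
class GeneratorConfig:
    """Study-condition preset for the synthetic generator."""

    n_tips: int = 453
    birth_rate: float = 1.0
    mk_rates: tuple[float, float] | None = None  # (q XY->ZW, q ZW->XY); None = calibrated
    root_state: str = "ZW"
    trait_lambda: float | Mapping[str, float] = 0.3
    path_model: str = "m1.b"
    coefficients: dict = field(default_factory=lambda: dict(DEFAULT_COEFFICIENTS))
    missingness: dict = field(default_factory=lambda: dict(DEFAULT_MISSINGNESS))
    complete_block: float = 95.0 / 453.0
    min_residual_var: float = 0.05
    seed: int = 0

    def lambda_for(self, var: str) -> float:
        if isinstance(self.trait_lambda, Mapping):
            return float(self.trait_lambda.get(var, 0.3))
        return float(self.trait_lambda)


def paperlike(seed: int = 0, n_tips: int = 453) -> GeneratorConfig:
    """The default study-condition preset."""
    return GeneratorConfig(n_tips=n_tips, seed=seed)


# --------------------------------------------------------------------------
# Trees
# --------------------------------------------------------------------------


def simulate_tree(n_tips: int, seed: int = 0, rng=None) -> Phylogeny:
    """Pure-birth (Yule) tree with ``n_tips`` tips, rescaled to unit height.

    Lineages split at rate ``k·b``; the split lineage is chosen uniformly.
    Tip labels are ``t1 .. tn`` in left-to-right order."""
    if n_tips < 3:
        raise ValueError("n_tips must be >= 3")
    rng = np.random.default_rng(seed) if rng is None else rng
    root = Node()
    active: list[tuple[Node, float]] = []
    for _ in range(2):
        child = root.add_child(Node())
        active.append((child, 0.0))
    t = 0.0
    while len(active) < n_tips:
        k = len(active)
        t += rng.exponential(1.0 / k)
        i = int(rng.integers(k))
        node, birth = active.pop(i)
        node.length = t - birth
        for _ in range(2):
            child = node.add_child(Node())
            active.append((child, t))
    t += rng.exponential(1.0 / len(active))
    for node, birth in active:
        node.length = t - birth
    tree = Phylogeny(root, validate=False)
    for i, tip in enumerate(tree.tips(), start=1):
        tip.label = f"t{i}"
    for node in tree.preorder():
        if node.parent is not None:
            node.length /= t
    return Phylogeny(tree.root)


# --------------------------------------------------------------------------
# Binary character
# --------------------------------------------------------------------------


def simulate_binary_character(
    tree: Phylogeny,
    rates: tuple[float, float],
    seed: int = 0,
    root_state: str = "XY",
    rng=None,
) -> tuple[pd.Series, dict]:
    """Forward simulation of the binary character along the tree.

    ``rates`` is ``(q XY->ZW, q ZW->XY)``.  Returns the per-tip states and a
    truth record with the realized transition counts per direction."""
    q01, q10 = rates
    if q01 < 0 or q10 < 0:
        raise ValueError("rates must be non-negative")
    rng = np.random.default_rng(seed) if rng is None else rng
    state_of = {"XY": 0, "ZW": 1}[root_state]
    out_rates = (q01, q10)
    node_state = {id(tree.root): state_of}
    n01 = n10 = 0
    for node in tree.preorder():
        if node.parent is None:
            continue
        s = node_state[id(node.parent)]
        remaining = node.length
        while True:
            rate = out_rates[s]
            if rate == 0.0:
                break
            dwell = rng.exponential(1.0 / rate)
            if dwell >= remaining:
                break
            remaining -= dwell
            if s == 0:
                n01 += 1
                s = 1
            else:
                n10 += 1
                s = 0
        node_state[id(node)] = s
    states = pd.Series(
        {t.label: ("XY", "ZW")[node_state[id(t)]] for t in tree.tips()}
    )
    truth = {
        "transitions_xy_to_zw": n01,
        "transitions_zw_to_xy": n10,
        "transitions_total": n01 + n10,
        "root_state": root_state,
        "rates": {"XY->ZW": q01, "ZW->XY": q10},
    }
    return states, truth


def calibrated_mk_rates(tree: Phylogeny, target_total: float = 17.0) -> tuple[float, float]:
    """Rates in the rare-transition regime: asymmetric (most changes out of
    the root state) and scaled by total tree length so the expected realized
    transition count is near ``target_total``."""
    L = tree.total_length()
    # with a ZW root and q(ZW->XY) dominant, most lineages stay ZW; the
    # realized count tracks q10 * (time in ZW) + q01 * (time in XY)
    q10 = 1.25 * target_total / L
    q01 = 0.22 * target_total / L
    return (q01, q10)


# --------------------------------------------------------------------------
# Continuous traits
# --------------------------------------------------------------------------


def _brownian_tips(tree: Phylogeny, rng) -> np.ndarray:
    """Standard Brownian motion at the tips, scaled to unit tip variance on
    an ultrametric tree."""
    vals = {id(tree.root): 0.0}
    for node in tree.preorder():
        if node.parent is None:
            continue
        vals[id(node)] = vals[id(node.parent)] + rng.normal(
            0.0, math.sqrt(node.length)
        )
    height = tree.height()
    return np.array([vals[id(t)] for t in tree.tips()]) / math.sqrt(height)


def lambda_noise(tree: Phylogeny, lam: float, rng) -> np.ndarray:
    """Unit-variance noise with Pagel's-λ phylogenetic structure:
    sqrt(λ)·BM + sqrt(1−λ)·iid."""
    n = tree.n_tips
    return math.sqrt(lam) * _brownian_tips(tree, rng) + math.sqrt(
        1.0 - lam
    ) * rng.normal(size=n)


def simulate_traits(
    tree: Phylogeny,
    gsd: pd.Series,
    config: GeneratorConfig,
    seed: int = 0,
    rng=None,
) -> tuple[pd.DataFrame, dict]:
    """Trait table implied by the config's path model.

    Each endogenous variable is the coefficient-weighted sum of its parents
    plus λ-structured residual noise, with the residual variance chosen so
    the total variance is ~1 (so the configured coefficients are on the
    standardized scale).  GSD enters as the standardized 0/1 indicator.  The
    latent standardized traits are then mapped to natural-looking columns:
    sex ratios as proportions around 0.5, biases on a log10-ratio scale.
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    labels = tree.tip_labels
    gsd = gsd.loc[labels]
    g = (gsd == "ZW").astype(float).to_numpy()
    if g.std() > 0:
        g = (g - g.mean()) / g.std(ddof=1)
    latent: dict[str, np.ndarray] = {"GSD": g}
    model = build_model_set()[config.path_model]
    coef = {tuple(k): float(v) for k, v in config.coefficients.items()}
    for vertex in model.causal_order():
        if vertex == "GSD":
            continue
        lam = config.lambda_for(vertex.lower())
        noise = lambda_noise(tree, lam, rng)
        parents = model.parents(vertex)
        systematic = np.zeros(len(labels))
        for parent in parents:
            c = coef.get((parent, vertex), 0.0)
            systematic += c * latent[parent]
        var_sys = float(np.var(systematic)) if parents else 0.0
        resid_sd = math.sqrt(max(config.min_residual_var, 1.0 - var_sys))
        latent[vertex] = systematic + resid_sd * noise
    # BSR: pure lambda-structured noise, unrelated to everything else
    latent["BSR"] = lambda_noise(tree, config.lambda_for("bsr"), rng)
    table = pd.DataFrame(
        {
            "species": labels,
            "gsd": gsd.to_numpy(),
            "asr": np.clip(0.5 + 0.10 * latent["ASR"], 0.0, 1.0),
            "bsr": np.clip(0.5 + 0.05 * latent["BSR"], 0.0, 1.0),
            "jmb": 0.25 * latent["JMB"],
            "amb": 0.25 * latent["AMB"],
            "mat": 0.15 * latent["MAT"],
        }
    )
    truth = {
        "path_model": config.path_model,
        "coefficients": {f"{a}->{b}": c for (a, b), c in coef.items()},
        "trait_lambda": {
            v: config.lambda_for(v.lower()) for v in ("ASR", "JMB", "AMB", "MAT")
        },
    }
    return table, truth


# --------------------------------------------------------------------------
# Missingness
# --------------------------------------------------------------------------


def inject_missingness(
    table: pd.DataFrame,
    fractions: Mapping[str, float],
    seed: int = 0,
    complete_block: float = 0.0,
    rng=None,
) -> pd.DataFrame:
    """Missing-completely-at-random per variable.

    ``fractions`` are marginal missingness fractions per column.  With
    ``complete_block`` > 0, that fraction of species is kept fully observed
    (emulating well-studied species contributing every variable) and the
    remaining rows get correspondingly higher rates so the marginal fractions
    still hold."""
    for col, f in fractions.items():
        if not 0.0 <= f < 1.0:
            raise ValueError(f"missingness fraction for {col!r} outside [0, 1)")
    if not 0.0 <= complete_block < 1.0:
        raise ValueError("complete_block must lie in [0, 1)")
    rng = np.random.default_rng(seed) if rng is None else rng
    out = table.copy()
    n = len(out)
    n_block = int(round(complete_block * n))
    block = np.zeros(n, dtype=bool)
    if n_block:
        block[rng.choice(n, size=n_block, replace=False)] = True
    for col, f in fractions.items():
        if col not in out.columns or f == 0.0:
            continue
        p_adj = min(0.999, f * n / max(n - n_block, 1))
        drop = (~block) & (rng.random(n) < p_adj)
        out.loc[drop, col] = np.nan
    core = [c for c in ("gsd", "asr", "jmb", "amb", "mat") if c in out.columns]
    n_complete = int(out.dropna(subset=core).shape[0])
    if n_complete < 10:
        warnings.warn(
            f"only {n_complete} complete cases after missingness", stacklevel=2
        )
    return out


# --------------------------------------------------------------------------
# Full datasets
# --------------------------------------------------------------------------


@dataclass
class SyntheticDataset:
    tree: Phylogeny
    table: pd.DataFrame
    truth: dict

    def write(self, tree_path, table_path, truth_path=None) -> None:
        self.tree.write(tree_path)
        self.table.to_csv(table_path, index=False)
        if truth_path is not None:
            with open(truth_path, "w") as fh:
                json.dump(self.truth, fh, indent=2, default=float)


def generate(config: GeneratorConfig) -> SyntheticDataset:
    """Tree + trait table + ground-truth record from one config."""
    rng = np.random.default_rng(config.seed)
    tree = simulate_tree(config.n_tips, rng=rng)
    rates = (
        config.mk_rates
        if config.mk_rates is not None
        else calibrated_mk_rates(tree)
    )
    gsd, char_truth = simulate_binary_character(
        tree, rates, root_state=config.root_state, rng=rng
    )
    table, trait_truth = simulate_traits(tree, gsd, config, rng=rng)
    table = inject_missingness(
        table, config.missingness, complete_block=config.complete_block, rng=rng
    )
    core = ["gsd", "asr", "jmb", "amb", "mat"]
    truth = {
        "config": {
            **{
                k: v
                for k, v in asdict(config).items()
                if k not in ("coefficients",)
            },
            "coefficients": {f"{a}->{b}": c for (a, b), c in config.coefficients.items()},
            "mk_rates": list(rates),
        },
        "character": char_truth,
        "traits": trait_truth,
        "n_complete_cases": int(table.dropna(subset=core).shape[0]),
    }
    return SyntheticDataset(tree, table, truth)
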