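"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from frogeye.phylo import Phylogeny, parse_newick, phylo_covariance
from frogeye.synthetic import SimConfig, simulate_allometry, simulate_predictor, simulate_yule_tree


@pytest.fixture
def cherry() -> Phylogeny:
    return parse_newick("(A:1,B:1);")


@pytest.fixture
def hand_tree() -> Phylogeny:
    """((A:1,B:1):1,C:2): all root-to-tip depths 2, C[A,B] = 1."""
    return parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def star_tree() -> Phylogeny:
    return parse_newick("(A:1,B:1,C:1,D:1,E:1);")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260929)


def make_regression_data(
    n_tips: int, seed: int, slope: float = 0.82, lam: float = 0.96,
    sigma2: float | None = None,
):
    """A seeded (tree, covariance, X, y, cfg) bundle for PGLS tests."""
    from frogeye.pgls import design_matrix

    cfg = SimConfig(
        n_species=n_tips, true_slope=slope, lambda_true=lam, seed=seed,
        **({"sigma2": sigma2} if sigma2 is not None else {}),
    )
    tree = simulate_yule_tree(n_tips, cfg.birth_rate, seed)
    cov = phylo_covariance(tree)
    x = simulate_predictor(tree, cfg.predictor_sigma2, seed * 7 + 1, mean=cfg.predictor_mean)
    y = simulate_allometry(tree, x, cfg, seed=seed * 7 + 2)
    X = design_matrix(pd.DataFrame({"x": x}), ["x"])
    return tree, cov, X, y, cfg


def dense_gls(X: np.ndarray, y: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Brute-force GLS coefficients (X' C^-1 X)^-1 X' C^-1 y."""
    Ci = np.linalg.inv(C)
    return np.linalg.solve(X.T @ Ci @ X, X.T @ Ci @ y)


def pic_slope_through_origin(phy: Phylogeny, xs: pd.Series, ys: pd.Series) -> float:
    """Phylogenetically independent contrasts, regression through the origin.

    Felsenstein's pruning recursion, written independently of the GLS path
    it cross-checks. Requires a fully bifurcating tree.
    """
    vals: dict = {}
    contrasts: list[tuple[float, float]] = []
    for node in phy.tree.postorder_node_iter():
        if node.is_leaf():
            vals[node] = (
                float(xs[node.taxon.label]),
                float(ys[node.taxon.label]),
                float(node.edge.length or 0.0),
            )
            continue
        c1, c2 = node.child_nodes()
        x1, y1, b1 = vals[c1]
        x2, y2, b2 = vals[c2]
        denom = np.sqrt(b1 + b2)
        contrasts.append(((x1 - x2) / denom, (y1 - y2) / denom))
        vals[node] = (
            (x1 / b1 + x2 / b2) / (1 / b1 + 1 / b2),
            (y1 / b1 + y2 / b2) / (1 / b1 + 1 / b2),
            float(node.edge.length or 0.0) + b1 * b2 / (b1 + b2),
        )
    cs = np.asarray(contrasts)
    return float(np.sum(cs[:, 0] * cs[:, 1]) / np.sum(cs[:, 0] ** 2))
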