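"""Independent oracles used by the test suite.

Each oracle recomputes a quantity by the most direct route available —
edge-by-edge enumeration, closed forms, exhaustive grid search — and stays
independent of the implementation path it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from langdiv.gls import CorrelationParams, negloglik


def phylosor_bruteforce(tree, taxa_i, taxa_j) -> float:
    """Edge-membership enumeration of PhyloSor on a LanguageTree.

    Walks the dendropy tree node by node; an edge belongs to a set's rooted
    spanning subtree iff any tip below it is in the set.
    """
    taxa_i = set(taxa_i)
    taxa_j = set(taxa_j)
    bl_i = bl_j = shared = 0.0
    for node in tree.dendropy_tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        tips = {leaf.taxon.label for leaf in node.leaf_iter()}
        length = node.edge.length
        hit_i = bool(tips & taxa_i)
        hit_j = bool(tips & taxa_j)
        if hit_i:
            bl_i += length
        if hit_j:
            bl_j += length
        if hit_i and hit_j:
            shared += length
    return 2.0 * shared / (bl_i + bl_j)


def ols_closed_form(y: np.ndarray, X: np.ndarray):
    """Textbook (X'X)^-1 X'y with the Gaussian ML log-likelihood."""
    b = np.linalg.solve(X.T @ X, X.T @ y)
    r = y - X @ b
    n = len(y)
    sigma2 = float(r @ r) / n
    ll = -0.5 * n * (math.log(2.0 * math.pi * sigma2) + 1.0)
    return b, sigma2, ll


def grid_search_gls(y, X, P, d, alphas, betas, gammas):
    """Exhaustive search of the profiled negative log-likelihood."""
    best = (np.inf, None)
    for a, b, g in itertools.product(alphas, betas, gammas):
        try:
            nll = negloglik(CorrelationParams(a, b, g), y, X, P, d)
        except Exception:
            continue
        if nll < best[0]:
            best = (nll, (a, b, g))
    return best


def random_taxonomy(rng: np.random.Generator, max_families=5, max_langs=4,
                    max_depth=3) -> dict[str, tuple[str, ...]]:
    """Random taxonomy table with mixed path depths and isolates."""
    taxonomy: dict[str, tuple[str, ...]] = {}
    n_fam = int(rng.integers(1, max_families + 1))
    for fi in range(n_fam):
        if rng.random() < 0.2:  # isolate
            lid = f"I{fi}"
            taxonomy[lid] = (lid,)
            continue
        fam = f"F{fi}"
        depth = int(rng.integers(1, max_depth + 1))
        n_lang = int(rng.integers(1, max_langs + 1))
        for li in range(n_lang):
            path = [fam]
            for lvl in range(1, depth):
                path.append(f"{fam}g{lvl}s{int(rng.integers(0, 2))}")
            taxonomy[f"{fam}L{li}"] = tuple(path)
    return taxonomy
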