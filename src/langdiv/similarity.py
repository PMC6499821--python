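"""Between-cell similarity: phylogenetic (PhyloSor) and spatial (Gaussian).

Two matrices feed the GLS correlation structure:

* ``P`` — PhyloSor phylogenetic similarity between the language sets of two
  grid cells: twice the branch length shared by the two rooted spanning
  subtrees over the total branch length of the two subtrees.  On the
  star-based language tree this is exactly 1 for identical sets and exactly
  0 for cells sharing no family, because spanning subtrees include the path
  to the root (the family stem edge is shared only when a family is shared).
* ``D`` — Gaussian distance decay ``exp(-(d / gamma)^2)`` of the
  great-circle distance between cell centroids, with decay range ``gamma``
  in km.
"""

from __future__ import annotations

import warnings
from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd

from .tree import LanguageTree, TaxonomyError

EARTH_RADIUS_KM = 6371.0

__all__ = [
    "EARTH_RADIUS_KM",
    "phylosor_pair",
    "phylosor_matrix",
    "greatcircle_matrix",
    "euclidean_matrix",
    "pairwise_distances",
    "gaussian_decay",
    "ensure_unit_diag_pd",
]


def _occupant_mask(
    taxa: Iterable[str], tip_index: dict[str, int]
) -> np.ndarray:
    mask = np.zeros(len(tip_index), dtype=bool)
    taxa = list(taxa)
    if not taxa:
        raise ValueError("empty taxon set (empty cells should be dropped upstream)")
    for t in taxa:
        idx = tip_index.get(t)
        if idx is None:
            raise TaxonomyError("tip not in tree", language_id=t)
        mask[idx] = True
    return mask


def phylosor_pair(
    tree: LanguageTree, taxa_i: Iterable[str], taxa_j: Iterable[str]
) -> float:
    """PhyloSor similarity between two sets of languages.

    ``2 * BL_shared / (BL_i + BL_j)`` where ``BL_i`` is the total branch
    length of the rooted spanning subtree of ``taxa_i`` (path to the root
    included) and ``BL_shared`` the total length of edges lying in both
    spanning subtrees.  Ranges from 0 (no shared family) to 1 (identical
    sets).
    """
    lengths, inc, tip_index = tree.edge_tip_incidence()
    mi = _occupant_mask(taxa_i, tip_index)
    mj = _occupant_mask(taxa_j, tip_index)
    in_i = inc @ mi > 0
    in_j = inc @ mj > 0
    bl_i = float(lengths[in_i].sum())
    bl_j = float(lengths[in_j].sum())
    shared = float(lengths[in_i & in_j].sum())
    return 2.0 * shared / (bl_i + bl_j)


def phylosor_matrix(
    tree: LanguageTree,
    occupants: Sequence[Iterable[str]] | pd.DataFrame,
) -> np.ndarray:
    """Pairwise PhyloSor matrix over grid cells.

    ``occupants`` is either a CellTable (DataFrame with an ``occupants``
    column) or a sequence of per-cell language-id collections.  Symmetric,
    diagonal exactly 1.
    """
    if isinstance(occupants, pd.DataFrame):
        occupants = list(occupants["occupants"])
    lengths, inc, tip_index = tree.edge_tip_incidence()
    occ = np.vstack([_occupant_mask(o, tip_index) for o in occupants])
    # presence[c, e]: edge e is in cell c's spanning subtree
    presence = (occ @ inc.T) > 0
    bl = presence @ lengths
    shared = (presence * lengths) @ presence.T
    S = 2.0 * shared / np.add.outer(bl, bl)
    S = 0.5 * (S + S.T)
    np.fill_diagonal(S, 1.0)
    return S


def greatcircle_matrix(
    lat: np.ndarray | Sequence[float], lon: np.ndarray | Sequence[float]
) -> np.ndarray:
    """Haversine great-circle distance matrix (km) between centroids."""
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if np.any(np.abs(lat) > 90.0):
        raise ValueError("latitude outside [-90, 90]")
    phi = np.radians(lat)
    lam = np.radians(lon)
    dphi = phi[:, None] - phi[None, :]
    dlam = lam[:, None] - lam[None, :]
    a = (
        np.sin(dphi / 2.0) ** 2
        + np.cos(phi)[:, None] * np.cos(phi)[None, :] * np.sin(dlam / 2.0) ** 2
    )
    a = np.clip(a, 0.0, 1.0)
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))
    np.fill_diagonal(d, 0.0)
    return d


def euclidean_matrix(
    x: np.ndarray | Sequence[float], y: np.ndarray | Sequence[float]
) -> np.ndarray:
    """Planar Euclidean distance matrix (km) for toy grids."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    d = np.hypot(x[:, None] - x[None, :], y[:, None] - y[None, :])
    np.fill_diagonal(d, 0.0)
    return d


def pairwise_distances(cells: pd.DataFrame) -> np.ndarray:
    """Centroid distance matrix for a CellTable.

    Uses great-circle distances when geographic centroids (``lat``/``lon``)
    are present, Euclidean distances on ``x``/``y`` otherwise.
    """
    if "lat" in cells.columns and "lon" in cells.columns:
        return greatcircle_matrix(cells["lat"].to_numpy(), cells["lon"].to_numpy())
    return euclidean_matrix(cells["x"].to_numpy(), cells["y"].to_numpy())


def gaussian_decay(d: np.ndarray, gamma: float) -> np.ndarray:
    """Gaussian distance-decay kernel ``exp(-(d / gamma)^2)``."""
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    d = np.asarray(d, dtype=float)
    return np.exp(-((d / gamma) ** 2))


def ensure_unit_diag_pd(
    M: np.ndarray,
    floor: float = 1e-8,
    max_perturbation: float | None = None,
) -> tuple[np.ndarray, float]:
    """Repair a unit-diagonal similarity matrix to positive definiteness.

    Eigenvalues below ``floor`` are clamped to it and the diagonal is
    rescaled back to 1.  Returns ``(repaired, max_entry_change)``; a warning
    reports the largest perturbation, and a :class:`ValueError` is raised if
    it exceeds ``max_perturbation`` (when given).  PhyloSor matrices are not
    guaranteed positive definite, nor is the Gaussian kernel of spherical
    distances, so downstream factorizations route through this repair.
    """
    M = 0.5 * (M + M.T)
    w, V = np.linalg.eigh(M)
    if w.min() >= floor:
        return M, 0.0
    wc = np.clip(w, floor, None)
    R = (V * wc) @ V.T
    s = np.sqrt(np.diag(R))
    R = R / np.outer(s, s)
    R = 0.5 * (R + R.T)
    np.fill_diagonal(R, 1.0)
    delta = float(np.max(np.abs(R - M)))
    warnings.warn(
        f"similarity matrix repaired to PD; max entry change {delta:.3e}",
        RuntimeWarning,
        stacklevel=2,
    )
    if max_perturbation is not None and delta > max_perturbation:
        raise ValueError(
            f"PD repair changed an entry by {delta:.3e} > {max_perturbation:.3e}"
        )
    return R, delta
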