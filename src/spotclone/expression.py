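"""Clone-specific gene-expression deconvolution.

Given inferred clone proportions H (spots x clones) and cell counts N, the
spot expression matrix Y (spots x genes) is modeled as the overdetermined
linear system N'HB = Y, with N' the diagonal cell-count matrix and B the
per-cell average expression of each gene in each clone. B is recovered per
gene by non-negative least squares (no intercept); genes are separable, so
each column of Y is solved independently.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.optimize import lsq_linear

logger = logging.getLogger(__name__)


def build_design_matrix(H: np.ndarray, N: np.ndarray) -> np.ndarray:
    """Design matrix N'H: row s is N_s * H_s."""
    H = np.asarray(H, dtype=float)
    N = np.asarray(N, dtype=float)
    if H.ndim != 2 or N.shape != (H.shape[0],):
        raise ValueError("H must be S x K and N of length S")
    return N[:, None] * H


def deconvolve_clone_expression(
    H: np.ndarray,
    N: np.ndarray,
    Y: np.ndarray,
    depth_normalize: bool = False,
) -> np.ndarray:
    """Solve N'HB = Y for B >= 0 by per-gene bounded least squares.

    Returns the K x G matrix of per-cell clone expression. Deterministic
    given inputs. A rank-deficient design still returns a solution but is
    flagged in the log (non-unique optimum). ``depth_normalize`` optionally
    rescales each spot's expression to the median library size first (off
    by default; raw counts are regressed).
    """
    Y = np.asarray(Y, dtype=float)
    X = build_design_matrix(H, N)
    S, K = X.shape
    if Y.shape[0] != S:
        raise ValueError("Y rows must match the number of spots")
    if S < K:
        logger.warning("underdetermined system: %d spots < %d clones", S, K)
    if np.linalg.matrix_rank(X) < K:
        logger.warning("rank-deficient design; returned solution is not unique")
    if depth_normalize:
        lib = Y.sum(axis=1)
        target = np.median(lib[lib > 0]) if np.any(lib > 0) else 1.0
        scale = np.where(lib > 0, target / np.where(lib > 0, lib, 1.0), 1.0)
        Y = Y * scale[:, None]
    G = Y.shape[1]
    B = np.empty((K, G))
    for g in range(G):
        res = lsq_linear(X, Y[:, g], bounds=(0.0, np.inf))
        B[:, g] = res.x
    return np.maximum(B, 0.0)


def rank_genes_by_clone_expression(
    B: np.ndarray, top_n: int, gene_labels: list[str] | None = None
) -> list[tuple[str, float]]:
    """Top genes by maximum per-cell expression across clones.

    Sorted descending on max_k B_kg; ties break lexicographically on the
    gene label. Returns (label, value) tuples.
    """
    B = np.asarray(B, dtype=float)
    G = B.shape[1]
    if top_n > G:
        raise ValueError(f"top_n={top_n} exceeds the {G} available genes")
    labels = gene_labels if gene_labels is not None else [f"g{j}" for j in range(G)]
    scores = B.max(axis=0)
    order = sorted(range(G), key=lambda j: (-scores[j], labels[j]))
    return [(labels[j], float(scores[j])) for j in order[:top_n]]
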