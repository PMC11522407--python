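"""Hyperparameter estimation from observed spot data.

The expected cells per spot (Lambda) come straight from image-derived cell
counts; the Gamma prior on per-cell site coverage is fitted by mixed-type
log-moment estimators applied to per-mutation average reads per cell; the
Beta shape zeta comes from a user-chosen expected number of clones per spot.
"""

from __future__ import annotations

import logging

import numpy as np

from .model import Hyperparams, zeta_over_K_from_expected_clones

logger = logging.getLogger(__name__)


def per_cell_read_samples(D: np.ndarray, n_cells: np.ndarray) -> np.ndarray:
    """Average reads per cell for each mutation: x_i = mean_s D_is / n_s."""
    D = np.asarray(D, dtype=float)
    n = np.asarray(n_cells, dtype=float)
    if D.ndim != 2 or D.shape[1] == 0:
        raise ValueError("D must be M x S with S >= 1")
    if np.any(n < 1):
        raise ValueError("cell counts must be >= 1")
    return (D / n[None, :]).mean(axis=1)


def estimate_gamma_shape_rate(
    x: np.ndarray, drop_nonpositive: bool = True
) -> tuple[float, float]:
    """Mixed-type log-moment estimators of a Gamma's shape and rate.

    With S1 = sum x_i, Slog = sum ln x_i, Sxlog = sum x_i ln x_i and
    denominator Q = I*Sxlog - Slog*S1:

        shape  = I * S1 / Q        rate = I**2 / Q

    Non-positive samples (sites never observed in any spot) have no
    defined logarithm; by default they are dropped with a logged count,
    otherwise they raise.
    """
    x = np.asarray(x, dtype=float)
    if drop_nonpositive:
        n_bad = int(np.sum(x <= 0))
        if n_bad:
            logger.info("dropping %d non-positive sample(s) from Gamma fit", n_bad)
            x = x[x > 0]
    elif np.any(x <= 0):
        raise ValueError("samples must be strictly positive")
    I = x.size
    if I < 2:
        raise ValueError("need at least two positive samples")
    lx = np.log(x)
    Q = I * float(np.sum(x * lx)) - float(np.sum(lx)) * float(np.sum(x))
    if Q <= 0:
        raise ValueError("degenerate log-moment denominator (constant sample?)")
    r_hat = I * float(np.sum(x)) / Q
    p_hat = I * I / Q
    return r_hat, p_hat


def build_hyperparams(
    cell_counts: np.ndarray,
    D: np.ndarray,
    expected_clones: float,
    K: int,
    fixed_n: bool = False,
) -> Hyperparams:
    """Assemble the full hyperparameter set from data characteristics."""
    cell_counts = np.asarray(cell_counts, dtype=float)
    if D.shape[1] != cell_counts.shape[0]:
        raise ValueError("D columns and cell_counts must agree on spot count")
    x = per_cell_read_samples(D, cell_counts)
    r_hat, p_hat = estimate_gamma_shape_rate(x)
    zeta = zeta_over_K_from_expected_clones(expected_clones, K) * K
    return Hyperparams(
        zeta=zeta, r=r_hat, p=p_hat, Lambda=cell_counts, fixed_n=fixed_n
    )
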