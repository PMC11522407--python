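"""Evaluation statistics for clone-proportion estimates.

Mean average error against simulated truth, major-clone accuracy, random
adjacent/distant spot-pair sampling on the array grid, per-clone Pearson
correlation of clonal composition across pairs, major-clone agreement
within pairs, and the one-sided rank-sum comparison of adjacent versus
distant pair statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


def mean_average_error(H_true: np.ndarray, H_est: np.ndarray) -> float:
    """Mean over spots of the mean absolute per-clone proportion error."""
    H_true = np.asarray(H_true, dtype=float)
    H_est = np.asarray(H_est, dtype=float)
    if H_true.shape != H_est.shape:
        raise ValueError("shape mismatch between true and estimated proportions")
    return float(np.mean(np.abs(H_est - H_true)))


def major_clone_accuracy(H_true: np.ndarray, H_est: np.ndarray) -> float:
    """Fraction of spots whose predicted predominant clone matches truth.

    np.argmax resolves ties to the lowest clone index on both sides.
    """
    H_true = np.asarray(H_true)
    H_est = np.asarray(H_est)
    if H_true.shape != H_est.shape:
        raise ValueError("shape mismatch between true and estimated proportions")
    return float(np.mean(np.argmax(H_est, axis=1) == np.argmax(H_true, axis=1)))


@dataclass
class SpotPairSet:
    """Sampled spot index pairs, either adjacent or distant on the grid.

    Adjacent means both coordinate offsets are at most 1 in absolute
    value; distant means both exceed 1 (absolute offsets — the signed form
    would depend on array orientation).
    """

    pairs: np.ndarray  # n x 2 spot indices
    mode: str

    def __len__(self) -> int:
        return len(self.pairs)


def _qualifying_pairs(coords: np.ndarray, mode: str) -> np.ndarray:
    coords = np.asarray(coords)
    S = coords.shape[0]
    ii, jj = np.triu_indices(S, k=1)
    dx = np.abs(coords[ii, 0] - coords[jj, 0])
    dy = np.abs(coords[ii, 1] - coords[jj, 1])
    if mode == "adjacent":
        ok = (dx <= 1) & (dy <= 1)
    elif mode == "distant":
        ok = (dx > 1) & (dy > 1)
    else:
        raise ValueError("mode must be 'adjacent' or 'distant'")
    return np.column_stack([ii[ok], jj[ok]])


def sample_spot_pairs(
    coords: np.ndarray, n_pairs: int, mode: str, rng: np.random.Generator
) -> SpotPairSet:
    """Sample ``n_pairs`` qualifying spot pairs uniformly without replacement."""
    qualifying = _qualifying_pairs(coords, mode)
    if len(qualifying) < n_pairs:
        raise ValueError(
            f"only {len(qualifying)} {mode} pairs exist; {n_pairs} requested"
        )
    idx = rng.choice(len(qualifying), size=n_pairs, replace=False)
    return SpotPairSet(pairs=qualifying[idx], mode=mode)


def pair_clonal_correlation(H: np.ndarray, pairs: SpotPairSet) -> np.ndarray:
    """Per-clone Pearson correlation of proportions across spot pairs.

    For clone k, correlates the first-member against the second-member
    proportions over the sampled pairs. Clones with zero variance on
    either side yield NaN (reported as missing).
    """
    H = np.asarray(H, dtype=float)
    p = pairs.pairs
    if len(p) < 3:
        raise ValueError("need at least 3 pairs for a correlation")
    out = np.full(H.shape[1], np.nan)
    for k in range(H.shape[1]):
        a, b = H[p[:, 0], k], H[p[:, 1], k]
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            continue
        out[k] = stats.pearsonr(a, b).statistic
    return out


def pair_major_clone_agreement(
    assignments: np.ndarray, pairs: SpotPairSet
) -> float:
    """Fraction of pairs whose two spots carry the same assigned clone."""
    if len(pairs) == 0:
        raise ValueError("empty pair set")
    a = np.asarray(assignments)
    p = pairs.pairs
    return float(np.mean(a[p[:, 0]] == a[p[:, 1]]))


def compare_adjacent_vs_distant(
    values_adj: np.ndarray, values_dist: np.ndarray
) -> tuple[float, float, float]:
    """Medians and one-sided rank-sum p-value for adjacent > distant."""
    values_adj = np.asarray(values_adj, dtype=float)
    values_dist = np.asarray(values_dist, dtype=float)
    if values_adj.size == 0 or values_dist.size == 0:
        raise ValueError("both value vectors must be non-empty")
    res = stats.mannwhitneyu(values_adj, values_dist, alternative="greater")
    return float(np.median(values_adj)), float(np.median(values_dist)), float(res.pvalue)
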