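"""Independent brute-force oracles used by the test suite only."""

from itertools import combinations, permutations

import numpy as np


def dice_bool(a: np.ndarray, b: np.ndarray) -> float:
    """Dice of two boolean grids via direct voxel counting."""
    inter = np.logical_and(a, b).sum()
    return 2.0 * inter / (a.sum() + b.sum())


def brute_force_matching(dsc: np.ndarray, threshold: float):
    """Optimal one-to-one matching by exhaustive enumeration.

    Maximizes (number of pairs, total DSC) over all injective assignments
    whose every pair meets the threshold. Returns a set of (i, j) pairs.
    """
    n_gt, n_pred = dsc.shape
    best = (-1, -1.0, frozenset())
    k_max = min(n_gt, n_pred)
    for k in range(k_max + 1):
        for gt_sub in combinations(range(n_gt), k):
            for pred_perm in permutations(range(n_pred), k):
                pairs = list(zip(gt_sub, pred_perm))
                if any(dsc[i, j] < threshold for i, j in pairs):
                    continue
                total = sum(dsc[i, j] for i, j in pairs)
                cand = (k, total, frozenset(pairs))
                if (cand[0], cand[1]) > (best[0], best[1]):
                    best = cand
    return best[2]


def random_separated_instance_sets(rng, grid=24, max_n=6):
    """Random GT/pred blob pairs in separated clusters on a small grid.

    Construction guarantees the pairwise DSC matrix has at most one
    above-threshold entry per row and column (cross-cluster overlaps are
    zero), the regime where greedy matching must equal the brute-force
    optimum exactly.
    """
    n_gt = rng.integers(1, max_n + 1)
    n_pred = rng.integers(1, max_n + 1)
    # up to 8 well-separated cluster anchors on the grid
    anchors = [(x, y, z) for x in (5, 17) for y in (5, 17) for z in (5, 17)]
    rng.shuffle(anchors)
    gt_masks, pred_masks = [], []
    for m in range(max(n_gt, n_pred)):
        cx, cy, cz = anchors[m % len(anchors)]
        if m < n_gt:
            g = np.zeros((grid, grid, grid), dtype=bool)
            r = rng.integers(1, 4)
            g[cx - r : cx + r, cy - r : cy + r, cz - r : cz + r] = True
            gt_masks.append(g)
        if m < n_pred:
            p = np.zeros((grid, grid, grid), dtype=bool)
            r = rng.integers(1, 4)
            off = rng.integers(-2, 3, size=3)
            p[
                cx + off[0] - r : cx + off[0] + r,
                cy + off[1] - r : cy + off[1] + r,
                cz + off[2] - r : cz + off[2] + r,
            ] = True
            pred_masks.append(p)
    return gt_masks, pred_masks
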