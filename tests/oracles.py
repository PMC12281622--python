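"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately avoid the library's own code paths: matching is a
hand-written recursion instead of scipy's Hopcroft-Karp, and the placement
oracle enumerates translations on a fixed 0.1 Å grid.
"""

import numpy as np


def max_matching_bruteforce(pairs):
    """Maximum one-to-one matching size over (left, right) pairs (recursive)."""
    pairs = sorted(set(pairs))
    lefts = sorted({p[0] for p in pairs})
    adj = {l: sorted(r for (x, r) in pairs if x == l) for l in lefts}

    best = 0

    def rec(i, used_r, count):
        nonlocal best
        if count + (len(lefts) - i) <= best:
            return
        if i == len(lefts):
            best = max(best, count)
            return
        rec(i + 1, used_r, count)  # skip this left node
        for r in adj[lefts[i]]:
            if r not in used_r:
                rec(i + 1, used_r | {r}, count + 1)

    rec(0, frozenset(), 0)
    return best


def grid_translation_oracle(epi_pos, loop_pos, comp_pairs, tol, min_matches, step=0.1):
    """All grid translations matching >= min_matches one-to-one pairs.

    comp_pairs: iterable of (epitope index, loop index) complementary pairs.
    Returns (grid_points, counts) for the passing grid points only.
    """
    comp_pairs = list(comp_pairs)
    if not comp_pairs:
        return np.zeros((0, 3)), []
    centers = np.array([loop_pos[j] - epi_pos[i] for i, j in comp_pairs])
    # a passing translation lies within tol of >= min_matches centers, so the
    # exhaustive lattice only needs to cover the union of balls around centers
    lo = centers.min(axis=0) - tol
    offsets = np.arange(-tol, tol + step / 2, step)
    ball = np.stack(np.meshgrid(offsets, offsets, offsets, indexing="ij"), axis=-1)
    ball = ball.reshape(-1, 3)
    ball = ball[np.linalg.norm(ball, axis=1) <= tol + step]
    lattice_idx = set()
    for c in centers:
        snapped = lo + np.round((c - lo) / step) * step
        for o in ball:
            p = snapped + o
            lattice_idx.add(tuple(np.round((p - lo) / step).astype(int)))
    grid = lo + np.array(sorted(lattice_idx)) * step

    d = np.linalg.norm(grid[:, None, :] - centers[None, :, :], axis=2)
    ok = d <= tol + 1e-9
    candidates = np.nonzero(ok.sum(axis=1) >= min_matches)[0]

    points, counts = [], []
    for g in candidates:
        local = [comp_pairs[k] for k in np.nonzero(ok[g])[0]]
        m = max_matching_bruteforce(local)
        if m >= min_matches:
            points.append(grid[g])
            counts.append(m)
    return np.array(points), counts


def match_count_at(epi_pos, loop_pos, comp_pairs, t, tol):
    """One-to-one match count for a specific translation (brute force)."""
    local = [
        (i, j)
        for i, j in comp_pairs
        if np.linalg.norm(epi_pos[i] + t - loop_pos[j]) <= tol + 1e-9
    ]
    return max_matching_bruteforce(local)


def random_site_instance(rng, tol=0.33, n_planted=4, max_decoys=4):
    """A planted translation-matching instance for oracle comparisons.

    Returns (epi_pos, loop_pos, comp_pairs, t_true).  All sites belong to one
    interaction family with satisfied secondary constraints, so every
    (epitope, loop) pair is complementary and the problem is purely geometric.
    Decoy offsets stay within ±0.8 Å of the planted translation to keep the
    oracle's grid box small.
    """
    t_true = rng.uniform(-2.0, 2.0, 3)
    epi = list(rng.uniform(0, 4.0, (n_planted, 3)))
    loop = [e + t_true + rng.uniform(-0.4, 0.4, 3) * tol for e in epi]
    n_decoys = int(rng.integers(1, max_decoys + 1))
    for _ in range(n_decoys):
        e = rng.uniform(0, 4.0, 3)
        epi.append(e)
        loop.append(e + t_true + rng.uniform(-0.8, 0.8, 3))
    epi, loop = np.array(epi), np.array(loop)
    comp_pairs = [(i, j) for i in range(len(epi)) for j in range(len(loop))]
    return epi, loop, comp_pairs, t_true
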