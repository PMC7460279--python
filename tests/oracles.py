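"""Independent brute-force oracles.

Everything here is deliberately naive (enumerate all pairs, double loops)
and shares no code with the package implementation it checks.
"""

import numpy as np

from galdiv import MISSING


def brute_force_roh(calls, pos, params):
    """Enumerate every index pair, keep maximal valid ranges, select longest-first.

    Returns the selected (start_index, end_index) list sorted by start.
    """
    calls = np.asarray(calls)
    pos = np.asarray(pos, dtype=np.int64)
    n = len(pos)
    if n == 0:
        return []
    a = np.arange(n)[:, None]
    b = np.arange(n)[None, :]
    ns = b - a + 1
    het = np.concatenate(([0], np.cumsum(calls == 1)))
    mis = np.concatenate(([0], np.cumsum(calls == MISSING)))
    gap = np.concatenate(([0], np.cumsum(np.diff(pos) > params.max_gap_kb * 1000.0)))
    length = pos[None, :] - pos[:, None]

    valid = (
        (ns >= params.min_snps)
        & (length >= params.min_length_kb * 1000.0)
        & ((het[b + 1] - het[a]) <= params.max_het)
        & ((mis[b + 1] - mis[a]) <= params.max_missing)
        & ((gap[b] - gap[a]) == 0)
        & (length <= params.min_density_kb_per_snp * 1000.0 * ns)
    )
    # a range is maximal iff it is the only valid range among its superranges
    superranges = np.cumsum(np.cumsum(valid[:, ::-1], axis=1)[:, ::-1], axis=0)
    maximal = valid & (superranges == 1)
    cands = [tuple(x) for x in np.argwhere(maximal)]
    ranked = sorted(cands, key=lambda ab: (-(pos[ab[1]] - pos[ab[0]]), ab[0]))
    taken = []
    for x, y in ranked:
        if all(y < tx or x > ty for tx, ty in taken):
            taken.append((x, y))
    return sorted(taken)


def naive_ibs(calls):
    """Double-loop 1-IBS distances with pairwise deletion."""
    n = calls.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            num = den = 0
            for g1, g2 in zip(calls[i], calls[j]):
                if g1 == MISSING or g2 == MISSING:
                    continue
                num += abs(int(g1) - int(g2))
                den += 1
            d[i, j] = num / (2.0 * den)
    return d


def tally_het_hom(calls):
    """Per-marker (n_het, n_hom, n_valid, p_alt) by explicit counting."""
    m = calls.shape[1]
    out = []
    for j in range(m):
        het = hom = valid = alt = 0
        for g in calls[:, j]:
            if g == MISSING:
                continue
            valid += 1
            alt += int(g)
            if g == 1:
                het += 1
            else:
                hom += 1
        out.append((het, hom, valid, alt / (2.0 * valid) if valid else np.nan))
    return out


def random_tree_distances(n_leaves, rng):
    """A random binary tree over labelled leaves and its additive distance matrix.

    The tree is returned as a (children, parent-branch-length) nested tuple
    structure; distances are exact path sums.
    """
    # distances are computed by merging leaf clusters with accumulated depths
    depths = [{f"L{i}": 0.0} for i in range(n_leaves)]
    d = np.zeros((n_leaves, n_leaves))
    labels = [f"L{i}" for i in range(n_leaves)]
    index = {lab: i for i, lab in enumerate(labels)}
    while len(depths) > 1:
        i, j = sorted(rng.choice(len(depths), size=2, replace=False))
        li = float(rng.uniform(0.1, 1.0))
        lj = float(rng.uniform(0.1, 1.0))
        for leaf_a, da in depths[i].items():
            for leaf_b, db in depths[j].items():
                dist = da + li + lj + db
                d[index[leaf_a], index[leaf_b]] = dist
                d[index[leaf_b], index[leaf_a]] = dist
        merged = {leaf: dep + li for leaf, dep in depths[i].items()}
        merged.update({leaf: dep + lj for leaf, dep in depths[j].items()})
        depths = [depths[k] for k in range(len(depths)) if k not in (i, j)] + [merged]
    return labels, d
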