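"""Independent brute-force oracles used by the texture and statistics tests.

These deliberately re-derive quantities by exhaustive enumeration or direct
formula application, sharing no code with the implementation they check.
"""

import numpy as np


def glcm_bruteforce(levels, mask, offsets, n_levels):
    """Exhaustive double-loop pair counter: symmetrize, normalize, average."""
    shape = levels.shape
    mats = []
    for off in offsets:
        counts = np.zeros((n_levels, n_levels))
        for i in range(shape[0]):
            for j in range(shape[1]):
                for k in range(shape[2]):
                    if not mask[i, j, k]:
                        continue
                    for sign in (1, -1):
                        ii, jj, kk = i + sign * off[0], j + sign * off[1], k + sign * off[2]
                        if 0 <= ii < shape[0] and 0 <= jj < shape[1] and 0 <= kk < shape[2] and mask[ii, jj, kk]:
                            counts[levels[i, j, k] - 1, levels[ii, jj, kk] - 1] += 1
        if counts.sum() > 0:
            mats.append(counts / counts.sum())
    return np.mean(mats, axis=0) if mats else None


def glszm_bruteforce(levels, mask, n_levels):
    """Flood-fill zone census with 26-connectivity."""
    shape = levels.shape
    visited = np.zeros(shape, dtype=bool)
    zones = []  # (level, size)
    neighbors = [
        (a, b, c)
        for a in (-1, 0, 1)
        for b in (-1, 0, 1)
        for c in (-1, 0, 1)
        if (a, b, c) != (0, 0, 0)
    ]
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                if not mask[i, j, k] or visited[i, j, k]:
                    continue
                g = levels[i, j, k]
                stack, size = [(i, j, k)], 0
                visited[i, j, k] = True
                while stack:
                    x, y, z = stack.pop()
                    size += 1
                    for a, b, c in neighbors:
                        xx, yy, zz = x + a, y + b, z + c
                        if (
                            0 <= xx < shape[0] and 0 <= yy < shape[1] and 0 <= zz < shape[2]
                            and mask[xx, yy, zz] and not visited[xx, yy, zz]
                            and levels[xx, yy, zz] == g
                        ):
                            visited[xx, yy, zz] = True
                            stack.append((xx, yy, zz))
                zones.append((g, size))
    counts = np.zeros((n_levels, int(mask.sum())))
    for g, s in zones:
        counts[g - 1, s - 1] += 1
    return counts


def auc_bruteforce(score, label):
    """Pairwise P(case > control) + half ties."""
    s = np.asarray(score, dtype=float)
    y = np.asarray(label, dtype=int)
    cases, controls = s[y == 1], s[y == 0]
    wins = ties = 0
    for c in cases:
        wins += (c > controls).sum()
        ties += (c == controls).sum()
    return (wins + 0.5 * ties) / (len(cases) * len(controls))
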