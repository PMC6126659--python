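"""Independent oracles used to cross-check the implementation.

These deliberately use different algorithms from the package: a quaternion
(Horn) absolute-orientation solver instead of the SVD Kabsch fit, and an
exhaustive enumeration of local alignments instead of dynamic programming.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def horn_rmsd(points_a: np.ndarray, points_b: np.ndarray) -> float:
    """Optimal rigid-superposition rmsd via Horn's quaternion eigenproblem."""
    A = np.asarray(points_a, dtype=float)
    B = np.asarray(points_b, dtype=float)
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    A0, B0 = A - ca, B - cb
    S = A0.T @ B0
    Sxx, Sxy, Sxz = S[0]
    Syx, Syy, Syz = S[1]
    Szx, Szy, Szz = S[2]
    N = np.array(
        [
            [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
            [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
            [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
            [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
        ]
    )
    vals, vecs = np.linalg.eigh(N)
    w, x, y, z = vecs[:, np.argmax(vals)]
    R = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )
    dev = A0 @ R.T - B0
    return float(np.sqrt(np.mean(np.sum(dev**2, axis=1))))


def sw_bruteforce_score(seq_a: str, seq_b: str, matrix, gap_open: float, gap_extend: float) -> float:
    """Best local-alignment score by enumerating every monotone pairing.

    A gap run of length g between consecutive aligned columns costs
    gap_open + (g - 1) * gap_extend; unaligned ends are free. Feasible only
    for short sequences (lengths <= 8 or so).
    """
    n, m = len(seq_a), len(seq_b)
    best = 0.0
    for k in range(1, min(n, m) + 1):
        for ia in combinations(range(n), k):
            for ib in combinations(range(m), k):
                score = 0.0
                for i, j in zip(ia, ib):
                    score += matrix[seq_a[i], seq_b[j]]
                for (i1, j1), (i2, j2) in zip(zip(ia, ib), zip(ia[1:], ib[1:])):
                    ga = i2 - i1 - 1
                    gb = j2 - j1 - 1
                    if ga > 0:
                        score -= gap_open + (ga - 1) * gap_extend
                    if gb > 0:
                        score -= gap_open + (gb - 1) * gap_extend
                best = max(best, score)
    return best
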