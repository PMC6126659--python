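"""Least-squares rigid superposition with outlier rejection.

The core fit is the Kabsch algorithm (SVD of the weighted covariance with
reflection correction). Structures are superposed on Smith-Waterman-paired
C-alpha sets; pairs deviating by more than a cutoff (5 A by default) are
rejected and the fit repeated until the rejected set is stable, matching
common practice for comparing homologous but conformationally distinct
structures. Also houses the crystallographic B-factor to rms-displacement
conversion used to judge whether a domain shift exceeds thermal disorder.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .pairing import ResiduePairing
from .structure_io import CalphaTrace, RigidTransform

__all__ = [
    "SuperpositionResult",
    "DisplacementEstimate",
    "FitError",
    "kabsch_fit",
    "iterative_fit",
    "rotation_angle",
    "rms_displacement_from_b",
]


class FitError(ValueError):
    pass


@dataclass
class SuperpositionResult:
    """Rigid transform mapping set A onto set B, with per-pair bookkeeping."""

    transform: RigidTransform
    rmsd: float
    n_input_pairs: int
    retained: list[int]
    rejected: list[int]
    iterations: int

    def __post_init__(self) -> None:
        if set(self.retained) | set(self.rejected) != set(range(self.n_input_pairs)):
            raise FitError("retained and rejected do not partition the input pairs")
        if self.rmsd < 0:
            raise FitError("negative rmsd")


@dataclass(frozen=True)
class DisplacementEstimate:
    b_factor: float
    rms_displacement: float


def kabsch_fit(
    points_a: np.ndarray,
    points_b: np.ndarray,
    weights: np.ndarray | None = None,
) -> SuperpositionResult:
    """Optimal rigid fit of ``points_a`` onto ``points_b`` (Kabsch, SVD).

    Minimizes the weighted sum of squared deviations of R a + t from b with a
    proper rotation (reflections corrected by flipping the smallest singular
    direction). Needs >= 3 non-collinear pairs.
    """
    A = np.asarray(points_a, dtype=float).reshape(-1, 3)
    B = np.asarray(points_b, dtype=float).reshape(-1, 3)
    if A.shape != B.shape:
        raise FitError(f"point sets differ in shape: {A.shape} vs {B.shape}")
    n = len(A)
    if n < 3:
        raise FitError(f"need at least 3 pairs, got {n}")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise FitError("weights must be nonnegative with positive sum")
        w = w / w.sum()
    ca = w @ A
    cb = w @ B
    A0 = A - ca
    B0 = B - cb
    H = (A0 * w[:, None]).T @ B0
    U, S, Vt = np.linalg.svd(H)
    if S[1] < 1e-12 * max(S[0], 1.0):
        raise FitError("degenerate (collinear) point configuration")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cb - R @ ca
    transform = RigidTransform(R, t)
    dev = transform.apply(A) - B
    rmsd = float(np.sqrt(np.sum(w * np.sum(dev**2, axis=1))))
    return SuperpositionResult(transform, rmsd, n, list(range(n)), [], 1)


def iterative_fit(
    pairing: ResiduePairing,
    trace_a: CalphaTrace,
    trace_b: CalphaTrace,
    cutoff: float = 5.0,
    max_iter: int = 20,
) -> SuperpositionResult:
    """Kabsch fit with iterative rejection of pairs deviating by > ``cutoff`` A.

    Refit on the retained pairs, recompute per-pair deviations over ALL input
    pairs, reject those above the cutoff, and repeat until the rejected set is
    unchanged (or ``max_iter``). The final rmsd is over retained pairs only.
    The rejected set grows monotonically: once rejected, a pair stays out.
    """
    if cutoff <= 0:
        raise FitError("cutoff must be positive")
    if len(pairing) < 3:
        raise FitError(f"need at least 3 pairs, got {len(pairing)}")
    ia = [p[0] for p in pairing.pairs]
    ib = [p[1] for p in pairing.pairs]
    A = trace_a.positions[ia]
    B = trace_b.positions[ib]
    n = len(A)
    retained = np.ones(n, dtype=bool)
    fit = None
    for it in range(1, max_iter + 1):
        if retained.sum() < 3:
            raise FitError(f"fewer than 3 retained pairs at iteration {it}")
        fit = kabsch_fit(A[retained], B[retained])
        dev = np.linalg.norm(fit.transform.apply(A) - B, axis=1)
        new_retained = retained & (dev <= cutoff)
        if new_retained.sum() == retained.sum():
            retained = new_retained
            break
        retained = new_retained
    assert fit is not None
    if retained.sum() < 3:
        raise FitError(f"fewer than 3 retained pairs at iteration {it}")
    final = kabsch_fit(A[retained], B[retained])
    return SuperpositionResult(
        transform=final.transform,
        rmsd=final.rmsd,
        n_input_pairs=n,
        retained=[int(i) for i in np.flatnonzero(retained)],
        rejected=[int(i) for i in np.flatnonzero(~retained)],
        iterations=it,
    )


def rotation_angle(transform: RigidTransform) -> float:
    """Rotation magnitude in degrees, in [0, 180].

    Equivalent to arccos((tr R - 1)/2) but computed as atan2 of the
    antisymmetric-part norm against (tr R - 1)/2, which stays accurate for
    near-identity rotations where arccos loses half the floating-point digits.
    """
    R = transform.rotation
    cos_term = (np.trace(R) - 1.0) / 2.0
    if abs(cos_term) > 1.0 + 1e-12:
        raise FitError(f"rotation trace out of range: {cos_term}")
    w = np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
    sin_term = np.linalg.norm(w) / 2.0
    return math.degrees(math.atan2(sin_term, cos_term))


def rms_displacement_from_b(b_factor: float, isotropic_3d: bool = True) -> DisplacementEstimate:
    """Convert a crystallographic B factor (A^2) to an rms displacement (A).

    Default is the three-dimensional isotropic form sqrt(3 B / (8 pi^2)); the
    one-dimensional form sqrt(B / (8 pi^2)) is available for comparison. At
    B = 100 A^2 the 3-D form gives 1.95 A -- the "about 2 A" scale of thermal
    disorder in a flexible PHY domain.
    """
    if b_factor < 0:
        raise FitError("negative B factor")
    factor = 3.0 if isotropic_3d else 1.0
    return DisplacementEstimate(b_factor, math.sqrt(factor * b_factor / (8.0 * math.pi**2)))
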