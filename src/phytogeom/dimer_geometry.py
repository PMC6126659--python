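"""Dimer-geometry descriptors for phytochrome photosensory modules.

A bacteriophytochrome photosensory module (PCM) is a parallel dimer of
PAS-GAF-PHY subunits. Photoconversion between the red-absorbing Pr and
far-red-absorbing Pfr states repositions the PHY domains while leaving the
PAS-GAF core nearly rigid. This module quantifies that rearrangement with a
small set of descriptors computed from C-alpha coordinates:

* **interface offset angle phi** -- angle between the two subunits' interface
  helix-bundle axes (each bundle axis is the normalized mean of that
  subunit's two interface-helix axes);
* **d-centroids** -- distance between the two PHY-domain C-alpha centroids;
* **opening angle Omega** -- angle subtended by the PHY centroids at a vertex
  placed midway between the C-terminal ends of interface helix 3 (subunit A)
  and helix 6 (subunit B);
* **PHY rotation / translation** -- residual rigid motion of the PHY domain
  after superposing the PAS-GAF cores of two structures (Smith-Waterman
  pairing, iterative Kabsch fit with 5 A outlier rejection);
* chromophore-pocket atom-pair distances (hydrogen-bond geometry).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .pairing import AlignParams, smith_waterman_pair
from .structure_io import (
    CalphaTrace,
    DomainScheme,
    RigidTransform,
    StructureError,
    StructureModel,
    extract_trace,
)
from .superposition import FitError, SuperpositionResult, iterative_fit, kabsch_fit, rotation_angle

__all__ = [
    "HelixAxis",
    "DimerGeometry",
    "DomainMotion",
    "GeometryError",
    "fit_helix_axis",
    "interface_offset_angle",
    "phy_centroid_metrics",
    "domain_rotation",
    "atom_pair_distance",
    "measure_dimer",
    "geometry_table",
]

logger = logging.getLogger(__name__)

#: bundle-axis angles above this are reported as antiparallel (AP)
ANTIPARALLEL_THRESHOLD = 135.0


class GeometryError(ValueError):
    pass


@dataclass(frozen=True)
class HelixAxis:
    """Helix axis oriented N -> C, with the C-alpha centroid as anchor."""

    direction: np.ndarray  # unit 3-vector
    anchor: np.ndarray
    residue_range: tuple[int, int]
    fit_rms: float

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        if abs(np.linalg.norm(d) - 1.0) > 1e-9:
            raise GeometryError("helix axis direction must be a unit vector")
        if self.fit_rms < 0:
            raise GeometryError("negative axis fit rms")


@dataclass
class DimerGeometry:
    phi: float  # degrees
    d_centroids: float  # Angstrom
    omega: float  # degrees
    antiparallel_flag: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.phi <= 90.0 + 1e-9):
            raise GeometryError(f"phi out of range: {self.phi}")
        if not (0.0 <= self.omega <= 180.0 + 1e-9):
            raise GeometryError(f"omega out of range: {self.omega}")
        if self.d_centroids < 0:
            raise GeometryError("negative centroid distance")


@dataclass
class DomainMotion:
    rotation: float  # degrees
    translation: float  # Angstrom, centroid shift after core alignment
    axis: np.ndarray  # unit 3-vector (undefined direction at rotation 0)
    core_fit: SuperpositionResult | None = None
    moving_fit: SuperpositionResult | None = None


# ---------------------------------------------------------------------------
# helix axes and interface angle


def _second_difference_axis(points: np.ndarray) -> np.ndarray:
    """Axis as the null direction of the C-alpha second differences.

    For an ideal helix every second-difference vector points exactly at the
    axis (its component along the axis cancels), so the smallest right
    singular vector of the stacked second differences is the exact axis; this
    avoids the tilt bias a plain principal-axis fit has on short helices.
    """
    s = np.diff(points, n=2, axis=0)
    _, sv, Vt = np.linalg.svd(s, full_matrices=False)
    if sv[1] < 1e-10 * max(sv[0], 1.0):
        raise GeometryError("degenerate helix: second differences are collinear")
    return Vt[-1]


def _refine_cylinder_axis(points: np.ndarray, axis0: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares cylinder fit: minimize the spread of radial distances.

    Returns the refined unit axis and the rms radial scatter (perpendicular
    fit rms). Exact input (constant radius) leaves the axis unchanged.
    """
    centroid = points.mean(axis=0)
    # orthonormal frame around the initial axis
    e1 = np.cross(axis0, [1.0, 0.0, 0.0])
    if np.linalg.norm(e1) < 1e-6:
        e1 = np.cross(axis0, [0.0, 1.0, 0.0])
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis0, e1)

    def residuals(p):
        a1, a2, c1, c2 = p
        u = axis0 + a1 * e1 + a2 * e2
        u = u / np.linalg.norm(u)
        q = centroid + c1 * e1 + c2 * e2
        rel = points - q
        radial = rel - np.outer(rel @ u, u)
        r = np.linalg.norm(radial, axis=1)
        return r - r.mean()

    sol = least_squares(residuals, x0=np.zeros(4), method="lm")
    a1, a2, _, _ = sol.x
    u = axis0 + a1 * e1 + a2 * e2
    u /= np.linalg.norm(u)
    fit_rms = float(np.sqrt(np.mean(sol.fun**2)))
    return u, fit_rms


def fit_helix_axis(trace: CalphaTrace, residue_range: tuple[int, int]) -> HelixAxis:
    """Fit the axis of a helical C-alpha segment, oriented N -> C.

    Initial axis from the second-difference null space (exact for ideal
    helices), refined by a least-squares cylinder fit for noisy coordinates.
    Needs at least 6 residues in the range.
    """
    lo, hi = residue_range
    mask = [i for i, n in enumerate(trace.residue_numbers) if lo <= n <= hi]
    pts = trace.positions[mask]
    if len(pts) < 6:
        raise GeometryError(
            f"helix range {residue_range} has {len(pts)} C-alpha atoms; need >= 6"
        )
    axis = _second_difference_axis(pts)
    axis, fit_rms = _refine_cylinder_axis(pts, axis)
    if axis @ (pts[-1] - pts[0]) < 0:  # orient N -> C
        axis = -axis
    return HelixAxis(axis, pts.mean(axis=0), residue_range, fit_rms)


def interface_offset_angle(
    axes_a: tuple[HelixAxis, HelixAxis],
    axes_b: tuple[HelixAxis, HelixAxis],
) -> tuple[float, bool]:
    """Offset angle phi between the two subunits' helix-bundle axes.

    Each bundle axis is the normalized mean of the subunit's two N->C helix
    directions. The reported phi is folded into [0, 90] degrees; bundles more
    than 135 degrees apart are flagged antiparallel (the "AP" convention).
    """
    bundles = []
    for pair in (axes_a, axes_b):
        mean = (pair[0].direction + pair[1].direction) / 2.0
        norm = np.linalg.norm(mean)
        if norm < 1e-6:
            raise GeometryError("degenerate bundle: helix directions cancel")
        bundles.append(mean / norm)
    cosang = float(np.clip(bundles[0] @ bundles[1], -1.0, 1.0))
    angle = math.degrees(math.acos(cosang))
    antiparallel = angle > ANTIPARALLEL_THRESHOLD
    phi = min(angle, 180.0 - angle)
    return phi, antiparallel


# ---------------------------------------------------------------------------
# PHY centroid metrics


def _domain_points(trace: CalphaTrace, rng: tuple[int, int]) -> np.ndarray:
    lo, hi = rng
    mask = [i for i, n in enumerate(trace.residue_numbers) if lo <= n <= hi]
    return trace.positions[mask]


def _cterm_position(trace: CalphaTrace, rng: tuple[int, int]) -> np.ndarray:
    lo, hi = rng
    best = None
    for i, n in enumerate(trace.residue_numbers):
        if lo <= n <= hi:
            best = i  # residues are ordered, keep the last in range
    if best is None:
        raise GeometryError(f"no C-alpha in helix range {rng}")
    return trace.positions[best]


def phy_centroid_metrics(
    trace_a: CalphaTrace,
    trace_b: CalphaTrace,
    scheme: DomainScheme,
) -> tuple[float, float]:
    """PHY centroid separation (A) and opening angle Omega (degrees).

    The vertex of Omega sits midway between the C-terminal C-alpha of the
    first listed interface helix in subunit A and of the last listed one in
    subunit B ("a point between the ends" of interface helices 3 and 6).
    """
    phy = scheme.range("PHY")
    pa = _domain_points(trace_a, phy)
    pb = _domain_points(trace_b, phy)
    if len(pa) == 0 or len(pb) == 0:
        raise GeometryError("PHY domain residues missing in one subunit")
    ca = pa.mean(axis=0)
    cb = pb.mean(axis=0)
    if not scheme.interface_helices:
        raise GeometryError("scheme defines no interface helices")
    h_first = scheme.interface_helices[0][1]
    h_last = scheme.interface_helices[-1][1]
    vertex = 0.5 * (_cterm_position(trace_a, h_first) + _cterm_position(trace_b, h_last))
    va = ca - vertex
    vb = cb - vertex
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na < 1e-9 or nb < 1e-9:
        raise GeometryError("PHY centroid coincides with the Omega vertex")
    omega = math.degrees(math.acos(float(np.clip(va @ vb / (na * nb), -1.0, 1.0))))
    return float(np.linalg.norm(ca - cb)), omega


# ---------------------------------------------------------------------------
# PHY rotation after core alignment


def _protein_chains(model: StructureModel) -> list[str]:
    out = []
    for cid, residues in model.chains.items():
        if any(not r.het_flag and r.atom("CA") is not None for r in residues):
            out.append(cid)
    return out


def _core_trace(model: StructureModel, chain: str, scheme: DomainScheme, core: tuple[str, ...]) -> CalphaTrace:
    full = extract_trace(model, chain)
    ranges = [scheme.range(d) for d in core]
    idx = [
        i
        for i, n in enumerate(full.residue_numbers)
        if any(lo <= n <= hi for lo, hi in ranges)
    ]
    return full.subset(idx)


def _fit_chains(
    reference: StructureModel,
    mobile: StructureModel,
    ref_chain: str,
    mob_chain: str,
    scheme: DomainScheme,
    core: tuple[str, ...],
    cutoff: float,
    params: AlignParams,
) -> tuple[SuperpositionResult, CalphaTrace, CalphaTrace]:
    ta = _core_trace(mobile, mob_chain, scheme, core)
    tb = _core_trace(reference, ref_chain, scheme, core)
    pairing = smith_waterman_pair(ta, tb, params)
    if len(pairing) < 3:
        raise FitError(
            f"core pairing of {mobile.identifier}:{mob_chain} onto "
            f"{reference.identifier}:{ref_chain} has {len(pairing)} pairs"
        )
    fit = iterative_fit(pairing, ta, tb, cutoff=cutoff)
    return fit, ta, tb


def _joint_core_rmsd(
    reference: StructureModel,
    mobile: StructureModel,
    assign: list[tuple[str, str]],
    scheme: DomainScheme,
    core: tuple[str, ...],
    cutoff: float,
    params: AlignParams,
) -> float:
    """Core rmsd of a chain assignment under ONE rigid fit of the whole dimer.

    A per-chain fit cannot tell the two assignments of a near-symmetric
    homodimer apart (each subunit superposes well on either mate); a joint
    fit of both subunits under a single transform can.
    """
    stacked_a: list[np.ndarray] = []
    stacked_b: list[np.ndarray] = []
    pairs: list[tuple[int, int]] = []
    off_a = off_b = 0
    for rc, mc in assign:
        ta = _core_trace(mobile, mc, scheme, core)
        tb = _core_trace(reference, rc, scheme, core)
        pairing = smith_waterman_pair(ta, tb, params)
        if len(pairing) < 3:
            raise FitError(f"core pairing {mc}->{rc} has {len(pairing)} pairs")
        pairs.extend((ia + off_a, ib + off_b) for ia, ib in pairing.pairs)
        stacked_a.append(ta.positions)
        stacked_b.append(tb.positions)
        off_a += len(ta)
        off_b += len(tb)
    A = np.vstack(stacked_a)
    B = np.vstack(stacked_b)
    trace_a = CalphaTrace(list(range(len(A))), "X" * len(A), A, ("joint", "mobile"))
    trace_b = CalphaTrace(list(range(len(B))), "X" * len(B), B, ("joint", "reference"))
    from .pairing import ResiduePairing

    fit = iterative_fit(ResiduePairing(pairs, 0.0, 1.0), trace_a, trace_b, cutoff=cutoff)
    return fit.rmsd


def match_chains(
    reference: StructureModel,
    mobile: StructureModel,
    scheme: DomainScheme,
    core: tuple[str, ...] = ("PAS", "GAF"),
    cutoff: float = 5.0,
    params: AlignParams | None = None,
) -> list[tuple[str, str]]:
    """Assign mobile chains to reference chains, minimizing the joint core rmsd."""
    params = params or AlignParams()
    ref_chains = _protein_chains(reference)
    mob_chains = _protein_chains(mobile)
    n = min(len(ref_chains), len(mob_chains))
    if n == 0:
        raise GeometryError("no protein chains with C-alpha atoms")
    if n == 1:
        return [(ref_chains[0], mob_chains[0])]
    ref_chains, mob_chains = ref_chains[:2], mob_chains[:2]
    assignments = [
        list(zip(ref_chains, mob_chains)),
        list(zip(ref_chains, reversed(mob_chains))),
    ]
    costs = []
    for assign in assignments:
        try:
            costs.append(_joint_core_rmsd(reference, mobile, assign, scheme, core, cutoff, params))
        except (FitError, GeometryError):
            costs.append(math.inf)
    return assignments[int(np.argmin(costs))]


def domain_rotation(
    reference: StructureModel,
    mobile: StructureModel,
    scheme: DomainScheme,
    core: tuple[str, ...] = ("PAS", "GAF"),
    moving: str = "PHY",
    cutoff: float = 5.0,
    params: AlignParams | None = None,
    chain_pair: tuple[str, str] | None = None,
) -> DomainMotion:
    """Residual PHY-domain motion after superposing the PAS-GAF cores.

    1. Pair core C-alpha atoms (Smith-Waterman) and fit mobile onto reference
       with the >5 A outlier-rejection rule.
    2. Apply that core transform to the whole mobile subunit.
    3. Fit the paired moving-domain C-alpha sets; the rotation is the angle of
       that second transform, the translation is the moving-domain centroid
       shift remaining after step 2.

    Reports the first matched subunit pair (further pairs are logged).
    """
    params = params or AlignParams()
    if chain_pair is None:
        pairs = match_chains(reference, mobile, scheme, core, cutoff, params)
        chain_pair = pairs[0]
        for rc, mc in pairs[1:]:
            try:
                extra = domain_rotation(
                    reference, mobile, scheme, core, moving, cutoff, params, chain_pair=(rc, mc)
                )
                logger.info(
                    "secondary subunit %s->%s: rotation %.2f deg, translation %.2f A",
                    mc, rc, extra.rotation, extra.translation,
                )
            except (FitError, GeometryError) as exc:
                logger.info("secondary subunit %s->%s failed: %s", mc, rc, exc)
    ref_chain, mob_chain = chain_pair

    core_fit, _, _ = _fit_chains(reference, mobile, ref_chain, mob_chain, scheme, core, cutoff, params)
    if len(core_fit.retained) < 50:
        logger.warning(
            "only %d retained core pairs for %s vs %s",
            len(core_fit.retained), mobile.identifier, reference.identifier,
        )

    moving_rng = scheme.range(moving)
    full_mob = extract_trace(mobile, mob_chain)
    full_ref = extract_trace(reference, ref_chain)
    idx_mob = [i for i, n in enumerate(full_mob.residue_numbers) if moving_rng[0] <= n <= moving_rng[1]]
    idx_ref = [i for i, n in enumerate(full_ref.residue_numbers) if moving_rng[0] <= n <= moving_rng[1]]
    tm = full_mob.subset(idx_mob)
    tr = full_ref.subset(idx_ref)
    pairing = smith_waterman_pair(tm, tr, params)
    if len(pairing) < 3:
        raise FitError(f"moving-domain pairing has only {len(pairing)} pairs (stage 3)")
    ia = [p[0] for p in pairing.pairs]
    ib = [p[1] for p in pairing.pairs]
    mob_pts = core_fit.transform.apply(tm.positions[ia])  # step 2: core-aligned mobile
    ref_pts = tr.positions[ib]
    translation = float(np.linalg.norm(mob_pts.mean(axis=0) - ref_pts.mean(axis=0)))
    moving_fit = kabsch_fit(mob_pts, ref_pts)
    angle = rotation_angle(moving_fit.transform)
    R = moving_fit.transform.rotation
    # rotation axis from the antisymmetric part; arbitrary unit vector at 0
    w = np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
    nw = np.linalg.norm(w)
    axis = w / nw if nw > 1e-12 else np.array([0.0, 0.0, 1.0])
    return DomainMotion(angle, translation, axis, core_fit, moving_fit)


# ---------------------------------------------------------------------------
# atom distances


def _resolve_atom(model: StructureModel, sel: tuple) -> np.ndarray:
    chain_id, residue, atom_name = sel
    residues = model.chain(chain_id)
    matches = []
    for res in residues:
        if (isinstance(residue, int) and res.number == residue) or (
            isinstance(residue, str) and res.name == residue
        ):
            a = res.atom(atom_name)
            if a is not None:
                matches.append(a)
    if not matches:
        near = sorted(
            {
                f"{r.name}{r.number}:{a.atom_name}"
                for r in residues
                for a in r.atoms
                if (isinstance(residue, int) and abs(r.number - residue) <= 1)
                or (isinstance(residue, str) and r.name == residue)
            }
        )[:8]
        raise StructureError(
            f"atom {sel!r} not found in {model.identifier}; near misses: {near or 'none'}"
        )
    return matches[0].position


def atom_pair_distance(model: StructureModel, sel_a: tuple, sel_b: tuple) -> float:
    """Euclidean distance (A) between two atoms.

    Selectors are (chain_id, residue, atom_name) with residue given either as
    an author number or as a het residue name (e.g. ``("A", "BLA", "O_D")``
    for a chromophore atom). Sees all atoms, ligands included.
    """
    return float(np.linalg.norm(_resolve_atom(model, sel_a) - _resolve_atom(model, sel_b)))


# ---------------------------------------------------------------------------
# whole-dimer measurement and the report table


def measure_dimer(
    model: StructureModel,
    scheme: DomainScheme,
    chains: tuple[str, str] | None = None,
) -> DimerGeometry:
    """phi, d-centroids and Omega for one two-subunit structure."""
    if chains is None:
        pc = _protein_chains(model)
        if len(pc) < 2:
            raise GeometryError(f"{model.identifier} has {len(pc)} protein chains; need 2")
        chains = (pc[0], pc[1])
    trace_a = extract_trace(model, chains[0])
    trace_b = extract_trace(model, chains[1])
    if len(scheme.interface_helices) < 2:
        raise GeometryError("need two interface helix ranges per subunit")
    (_, h1), (_, h2) = scheme.interface_helices[0], scheme.interface_helices[-1]
    axes_a = (fit_helix_axis(trace_a, h1), fit_helix_axis(trace_a, h2))
    axes_b = (fit_helix_axis(trace_b, h1), fit_helix_axis(trace_b, h2))
    phi, ap = interface_offset_angle(axes_a, axes_b)
    d_cent, omega = phy_centroid_metrics(trace_a, trace_b, scheme)
    return DimerGeometry(phi, d_cent, omega, ap)


TABLE_COLUMNS = [
    "structure",
    "phi_deg",
    "d_centroids_A",
    "omega_deg",
    "phy_rotation_deg",
    "phy_translation_A",
    "core_rmsd_A",
    "n_pairs",
    "flags",
]


def geometry_table(
    reference: StructureModel,
    comparisons: list[StructureModel],
    scheme: DomainScheme,
    cutoff: float = 5.0,
    params: AlignParams | None = None,
    include_reference_row: bool = False,
) -> pd.DataFrame:
    """One row of dimer descriptors per comparison structure.

    With ``include_reference_row`` a leading row for the reference itself is
    added, reporting "ref." for rotation and rmsd as in the printed table.
    Per-row failures are recorded in the row's ``flags`` column; remaining
    rows still compute.
    """
    params = params or AlignParams()
    rows = []
    models = ([reference] if include_reference_row else []) + list(comparisons)
    for k, model in enumerate(models):
        is_ref_row = include_reference_row and k == 0
        row: dict = {c: "" for c in TABLE_COLUMNS}
        row["structure"] = model.identifier
        flags: list[str] = []
        try:
            geom = measure_dimer(model, scheme)
            row["phi_deg"] = "AP" if geom.antiparallel_flag else f"{geom.phi:.1f}"
            row["d_centroids_A"] = f"{geom.d_centroids:.1f}"
            row["omega_deg"] = f"{geom.omega:.1f}"
        except (GeometryError, StructureError, FitError) as exc:
            flags.append(f"geometry: {exc}")
        if is_ref_row:
            row["phy_rotation_deg"] = "ref."
            row["phy_translation_A"] = "ref."
            row["core_rmsd_A"] = "ref."
        else:
            try:
                motion = domain_rotation(reference, model, scheme, cutoff=cutoff, params=params)
                row["phy_rotation_deg"] = f"{motion.rotation:.1f}"
                row["phy_translation_A"] = f"{motion.translation:.1f}"
                row["core_rmsd_A"] = f"{motion.core_fit.rmsd:.2f}"
                row["n_pairs"] = len(motion.core_fit.retained)
            except (GeometryError, StructureError, FitError) as exc:
                flags.append(f"motion: {exc}")
        row["flags"] = ";".join(flags)
        rows.append(row)
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)
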