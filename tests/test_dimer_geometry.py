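import math

import numpy as np
import pytest

from phytogeom.dimer_geometry import (
    GeometryError,
    atom_pair_distance,
    domain_rotation,
    fit_helix_axis,
    geometry_table,
    interface_offset_angle,
    measure_dimer,
    phy_centroid_metrics,
)
from phytogeom.structure_io import (
    AtomRecord,
    CalphaTrace,
    DomainScheme,
    Residue,
    RigidTransform,
    StructureError,
    apply_transform,
)
from phytogeom.synthetic import DimerSpec, make_ideal_helix, make_synthetic_dimer, perturb_domain

from conftest import poly_ala_model, random_rotation


# ---------------------------------------------------------------------------
# helix axis


def test_axis_of_ideal_helix_is_exact():
    helix = make_ideal_helix(12)
    axis = fit_helix_axis(helix, (1, 12))
    assert np.linalg.norm(axis.direction - [0, 0, 1]) < 1e-6
    assert axis.fit_rms < 1e-9


def test_axis_rotates_with_the_helix(rng):
    helix = make_ideal_helix(12)
    for _ in range(10):
        R = random_rotation(rng)
        moved = apply_transform(helix, RigidTransform(R, rng.normal(size=3) * 5))
        axis = fit_helix_axis(moved, (1, 12))
        assert np.linalg.norm(axis.direction - R @ [0, 0, 1]) < 1e-6


def test_axis_robust_to_noise(rng):
    helix = make_ideal_helix(26)
    hits = 0
    for _ in range(100):
        noisy = CalphaTrace(
            helix.residue_numbers,
            helix.residue_codes,
            helix.positions + rng.normal(0, 0.3, helix.positions.shape),
            helix.source,
        )
        axis = fit_helix_axis(noisy, (1, 26))
        ang = math.degrees(math.acos(min(1.0, abs(axis.direction @ [0, 0, 1]))))
        hits += ang < 3.0
    assert hits >= 99


def test_axis_orientation_follows_chain_direction():
    helix = make_ideal_helix(12)
    reversed_trace = CalphaTrace(
        helix.residue_numbers, helix.residue_codes, helix.positions[::-1], helix.source
    )
    fwd = fit_helix_axis(helix, (1, 12)).direction
    rev = fit_helix_axis(reversed_trace, (1, 12)).direction
    np.testing.assert_allclose(fwd, -rev, atol=1e-9)


def test_axis_needs_six_residues():
    helix = make_ideal_helix(12)
    with pytest.raises(GeometryError, match=">= 6"):
        fit_helix_axis(helix, (1, 5))


# ---------------------------------------------------------------------------
# interface offset angle


def _axis(direction):
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    return fit_helix_axis(
        apply_transform(
            make_ideal_helix(12),
            RigidTransform(_rotation_to(d), np.zeros(3)),
        ),
        (1, 12),
    )


def _rotation_to(direction):
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(z, direction)
    s = np.linalg.norm(v)
    c = z @ direction
    if s < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    K = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + K + K @ K * ((1 - c) / s**2)


@pytest.mark.parametrize(
    "dir_b,expected_phi,expected_ap",
    [
        ((0, 0, 1), 0.0, False),
        ((0, math.sin(math.radians(30)), math.cos(math.radians(30))), 30.0, False),
        ((0, math.sin(math.radians(160)), math.cos(math.radians(160))), 20.0, True),
    ],
)
def test_interface_offset_angle(dir_b, expected_phi, expected_ap):
    a = _axis((0, 0, 1))
    b = _axis(dir_b)
    phi, ap = interface_offset_angle((a, a), (b, b))
    assert phi == pytest.approx(expected_phi, abs=1e-6)
    assert ap is expected_ap


def test_degenerate_bundle_rejected():
    up = _axis((0, 0, 1))
    down = _axis((0, 0, -1))
    with pytest.raises(GeometryError, match="degenerate bundle"):
        interface_offset_angle((up, down), (up, up))


# ---------------------------------------------------------------------------
# centroid metrics


def _trace_with_phy_and_helix(phy_points, helix_end, chain="A"):
    """PHY residues 1..n at given points; 'helix' residues 100-110 ending at helix_end."""
    helix = make_ideal_helix(11).positions + (np.asarray(helix_end) - make_ideal_helix(11).positions[-1])
    pts = np.vstack([phy_points, helix])
    nums = list(range(1, len(phy_points) + 1)) + list(range(100, 111))
    return CalphaTrace(nums, "A" * len(nums), pts, ("t", chain))


ISO_SCHEME = DomainScheme(
    domains={"PHY": (1, 4)},
    interface_helices=[("h3", (100, 110)), ("h6", (100, 110))],
)


def test_collinear_centroids_give_180():
    # centroids at +/- x, vertex exactly between them
    ta = _trace_with_phy_and_helix(np.tile([-20.0, 0, 0], (4, 1)), helix_end=(0, 0, 0))
    tb = _trace_with_phy_and_helix(np.tile([20.0, 0, 0], (4, 1)), helix_end=(0, 0, 0))
    d, omega = phy_centroid_metrics(ta, tb, ISO_SCHEME)
    assert d == pytest.approx(40.0)
    assert omega == pytest.approx(180.0, abs=1e-9)


def test_isoceles_opening_angle_by_law_of_cosines():
    # |VA| = |VB| = 33, centroid separation 30 -> law of cosines
    expected = math.degrees(math.acos((33**2 + 33**2 - 30**2) / (2 * 33 * 33)))
    h = math.sqrt(33**2 - 15**2)
    ta = _trace_with_phy_and_helix(np.tile([-15.0, 0, h], (4, 1)), helix_end=(0, 0, 0))
    tb = _trace_with_phy_and_helix(np.tile([15.0, 0, h], (4, 1)), helix_end=(0, 0, 0))
    d, omega = phy_centroid_metrics(ta, tb, ISO_SCHEME)
    assert d == pytest.approx(30.0, abs=1e-9)
    assert omega == pytest.approx(expected, abs=0.1)
    assert omega == pytest.approx(54.1, abs=0.1)  # the reference-geometry magnitudes


def test_missing_phy_rejected():
    ta = _trace_with_phy_and_helix(np.tile([1.0, 0, 0], (4, 1)), helix_end=(0, 0, 0))
    scheme = DomainScheme(domains={"PHY": (900, 950)}, interface_helices=ISO_SCHEME.interface_helices)
    with pytest.raises(GeometryError, match="PHY"):
        phy_centroid_metrics(ta, ta, scheme)


# ---------------------------------------------------------------------------
# whole-dimer descriptors


def test_descriptors_invariant_under_global_rigid_motion(reference_dimer, rng):
    _, model, truth = reference_dimer
    base = measure_dimer(model, truth.scheme)
    for _ in range(5):
        T = RigidTransform(random_rotation(rng), rng.normal(size=3) * 30)
        moved = apply_transform(model, T)
        g = measure_dimer(moved, truth.scheme)
        assert g.phi == pytest.approx(base.phi, abs=1e-6)
        assert g.d_centroids == pytest.approx(base.d_centroids, abs=1e-6)
        assert g.omega == pytest.approx(base.omega, abs=1e-6)


def test_descriptors_symmetric_under_subunit_relabeling(reference_dimer):
    _, model, truth = reference_dimer
    base = measure_dimer(model, truth.scheme, chains=("A", "B"))
    swapped_scheme = DomainScheme(
        domains=truth.scheme.domains,
        interface_helices=list(reversed(truth.scheme.interface_helices)),
    )
    swapped = measure_dimer(model, swapped_scheme, chains=("B", "A"))
    assert swapped.phi == pytest.approx(base.phi, abs=1e-9)
    assert swapped.omega == pytest.approx(base.omega, abs=1e-9)
    assert swapped.d_centroids == pytest.approx(base.d_centroids, abs=1e-9)


def test_domain_rotation_of_identical_structures_is_zero(reference_dimer):
    _, model, truth = reference_dimer
    motion = domain_rotation(model, model, truth.scheme)
    assert motion.rotation == pytest.approx(0.0, abs=1e-9)
    assert motion.translation == pytest.approx(0.0, abs=1e-9)


def test_perturbed_phy_rotation_recovered(reference_dimer):
    _, model, truth = reference_dimer
    scheme = truth.scheme
    junction = scheme.range("PHY")[0]
    # axis through the GAF/PHY junction of chain A
    anchor = next(
        r.atoms[0].position for r in model.chain("A") if r.number == junction
    )
    mutant = perturb_domain(
        model, scheme, "PHY", rotation=25.0, axis_point=anchor, axis_dir=(0.3, 0.9, 0.1)
    )
    motion = domain_rotation(model, mutant, scheme)
    assert motion.rotation == pytest.approx(25.0, abs=0.5)


def test_domain_rotation_noise_degrades_gracefully():
    spec = DimerSpec(phi=40, phy_rotation=10.0, phy_translation=3.0, noise_sigma=0.2, seed=21)
    model, truth = make_synthetic_dimer(spec)
    motion = domain_rotation(truth.reference, model, truth.scheme)
    assert motion.rotation == pytest.approx(10.0, abs=1.0)
    assert motion.translation == pytest.approx(3.0, abs=1.0)


# ---------------------------------------------------------------------------
# atom distances


def test_atom_pair_distance_basics():
    model = poly_ala_model(3)
    model.chains["A"][0].atoms[0] = AtomRecord("A", 1, "", "ALA", "CA", np.zeros(3))
    model.chains["A"][1].atoms[0] = AtomRecord("A", 2, "", "ALA", "CA", np.array([0, 0, 2.8]))
    d = atom_pair_distance(model, ("A", 1, "CA"), ("A", 2, "CA"))
    assert d == pytest.approx(2.8)
    assert d == atom_pair_distance(model, ("A", 2, "CA"), ("A", 1, "CA"))


def test_ligand_atom_addressable_by_het_name():
    model = poly_ala_model(3)
    bla = Residue(
        401, "", "BLA",
        [AtomRecord("A", 401, "", "BLA", "O_D", np.array([0.0, 0.0, 6.6]), het_flag=True)],
        het_flag=True,
    )
    model.chains["A"].append(bla)
    d = atom_pair_distance(model, ("A", "BLA", "O_D"), ("A", 1, "CA"))
    assert d == pytest.approx(np.linalg.norm(np.array([0, 0, 6.6]) - np.array([3.8, 0, 0])))


def test_unresolved_selector_lists_near_misses():
    model = poly_ala_model(3)
    with pytest.raises(StructureError, match="near misses"):
        atom_pair_distance(model, ("A", 2, "NE2"), ("A", 1, "CA"))


# ---------------------------------------------------------------------------
# geometry table


def test_table_self_comparison(reference_dimer):
    _, model, truth = reference_dimer
    table = geometry_table(model, [model], truth.scheme)
    assert len(table) == 1
    row = table.iloc[0]
    assert float(row["phy_rotation_deg"]) == pytest.approx(0.0, abs=1e-6)
    assert float(row["core_rmsd_A"]) == pytest.approx(0.0, abs=1e-6)


def test_table_reference_row_and_recovery():
    settings = [20.0, 32.0, 46.0]
    ref_model, truth = make_synthetic_dimer(DimerSpec(phi=46.0, seed=31))
    models = [make_synthetic_dimer(DimerSpec(phi=phi, seed=31))[0] for phi in settings]
    table = geometry_table(ref_model, models, truth.scheme, include_reference_row=True)
    assert table.iloc[0]["phy_rotation_deg"] == "ref."
    for phi, (_, row) in zip(settings, table.iloc[1:].iterrows()):
        assert float(row["phi_deg"]) == pytest.approx(phi, abs=0.5)
        assert row["flags"] == ""


def test_table_row_failure_does_not_abort_others(reference_dimer):
    _, model, truth = reference_dimer
    broken = poly_ala_model(10, identifier="broken")
    table = geometry_table(model, [broken, model], truth.scheme)
    assert len(table) == 2
    assert table.iloc[0]["flags"] != ""
    assert float(table.iloc[1]["core_rmsd_A"]) == pytest.approx(0.0, abs=1e-6)
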