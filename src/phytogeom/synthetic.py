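"""Synthetic structures and spectra with known ground truth.

Stand-ins for deposited crystal structures and measured spectra: two-subunit
C-alpha models whose interface offset angle, PHY centroid separation, opening
angle and PHY rotation/translation are set exactly by construction (optionally
blurred by Gaussian coordinate noise), and absorption spectra built as
mixtures of Gaussian Pr-like (~700 nm) and Pfr-like (~750 nm) bands on the
240-800 nm grid.

Domains are rigid point clouds (ideal helices plus a filler lattice), not
folded proteins: every descriptor the pipeline measures depends only on
C-alpha geometry, so nothing more is needed for ground-truth testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .spectra import Spectrum
from .structure_io import (
    AtomRecord,
    CalphaTrace,
    DomainScheme,
    Residue,
    RigidTransform,
    StructureError,
    StructureModel,
    write_structure,
)

__all__ = [
    "DimerSpec",
    "BandSpec",
    "DimerGroundTruth",
    "ConstructionError",
    "make_ideal_helix",
    "make_synthetic_dimer",
    "perturb_domain",
    "make_synthetic_spectrum",
    "mutate_sequence",
    "write_fixture",
]

AA_ONE = "ACDEFGHIKLMNPQRSTVWY"
AA_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}

#: fixed, arbitrary directions used for the PHY perturbation ground truth
PERTURB_AXIS = np.array([1.0, 1.0, 1.0]) / math.sqrt(3.0)
PERTURB_SHIFT_DIR = np.array([1.0, 2.0, 2.0]) / 3.0


class ConstructionError(ValueError):
    pass


@dataclass(frozen=True)
class DimerSpec:
    """Requested geometry of a synthetic two-subunit model.

    Defaults mirror a PAS-GAF-PHY photosensory module in the Pr state:
    516 residues per subunit (core 1-325, PHY 326-516), interface offset
    angle 46 deg, PHY centroids 30 A apart subtending a 54 deg opening angle.
    ``phy_rotation``/``phy_translation`` perturb the PHY domains relative to
    the companion reference model that is returned alongside.
    """

    n_core_residues: int = 325
    n_phy_residues: int = 191
    helix_length: int = 26
    phi: float = 46.0
    d_centroids: float = 30.0
    omega: float = 54.0
    phy_rotation: float = 0.0
    phy_translation: float = 0.0
    noise_sigma: float = 0.0
    seed: int = 0
    subunit_separation: float = 14.0
    #: seed for the residue sequence alone; structures that are to be compared
    #: (paired by local alignment) should share it. None -> use ``seed``.
    sequence_seed: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.phi < 90.0):
            raise ConstructionError(f"phi must be in (0, 90) deg, got {self.phi}")
        if not (0.0 < self.omega <= 180.0):
            raise ConstructionError(f"omega must be in (0, 180] deg, got {self.omega}")
        if self.d_centroids <= 0:
            raise ConstructionError("d_centroids must be positive")
        if self.d_centroids / (2.0 * math.sin(math.radians(self.omega) / 2.0)) > 500.0:
            raise ConstructionError(
                "omega too small for the requested d_centroids: the opening-angle "
                "vertex would sit >500 A from the centroids"
            )
        if not (0.0 <= self.phy_rotation <= 180.0):
            raise ConstructionError("phy_rotation must be in [0, 180] deg")
        if self.phy_translation < 0 or self.noise_sigma < 0:
            raise ConstructionError("phy_translation and noise_sigma must be >= 0")
        if self.n_core_residues < 2 * self.helix_length + 14:
            raise ConstructionError("core too small for two interface helices")
        if self.n_phy_residues < 8:
            raise ConstructionError("need at least 8 PHY residues")

    @property
    def helix3_range(self) -> tuple[int, int]:
        n, L = self.n_core_residues, self.helix_length
        return (n - 2 * L - 1, n - L - 2)

    @property
    def helix6_range(self) -> tuple[int, int]:
        n, L = self.n_core_residues, self.helix_length
        return (n - L + 1, n)

    @property
    def scheme(self) -> DomainScheme:
        n = self.n_core_residues
        return DomainScheme(
            domains={
                "PAS": (1, min(120, n - 2 * self.helix_length - 2)),
                "GAF": (min(120, n - 2 * self.helix_length - 2) + 1, n),
                "PHY": (n + 1, n + self.n_phy_residues),
            },
            interface_helices=[
                ("helix3", self.helix3_range),
                ("helix6", self.helix6_range),
            ],
        )


@dataclass
class DimerGroundTruth:
    """Construction-time descriptor values for a synthetic dimer."""

    phi: float
    d_centroids: float
    omega: float
    phy_rotation: float
    phy_translation: float
    scheme: DomainScheme
    sequence: str
    reference: StructureModel


@dataclass(frozen=True)
class BandSpec:
    """Gaussian absorption bands on a wavelength grid.

    ``bands`` is a list of (center nm, width nm, amplitude AU); the default
    grid is the 240-800 nm measurement range at 1 nm steps.
    """

    bands: tuple = ((700.0, 20.0, 1.0),)
    noise_sigma: float = 0.0
    grid: tuple[float, float, float] = (240.0, 800.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        start, stop, step = self.grid
        if not (start < stop and step > 0):
            raise ConstructionError(f"malformed grid {self.grid}")
        for center, width, _amp in self.bands:
            if not (start <= center <= stop):
                raise ConstructionError(f"band center {center} nm outside the grid")
            if width <= 0:
                raise ConstructionError(f"band width must be positive, got {width}")
        if self.noise_sigma < 0:
            raise ConstructionError("noise_sigma must be >= 0")


# ---------------------------------------------------------------------------
# building blocks


def make_ideal_helix(
    n: int,
    rise: float = 1.5,
    twist: float = 100.0,
    radius: float = 2.3,
) -> CalphaTrace:
    """Deterministic ideal alpha-helix C-alpha spiral along +z.

    Standard alpha-helix geometry: 1.5 A rise and 100 deg twist per residue
    on a 2.3 A radius, giving the canonical ~3.8 A consecutive C-alpha
    distance.
    """
    if n < 4:
        raise ConstructionError(f"need at least 4 residues for a helix, got {n}")
    pts = _helix_points(n, rise, twist, radius)
    return CalphaTrace(list(range(1, n + 1)), "A" * n, pts, ("ideal-helix", "A"))


def _helix_points(n: int, rise: float = 1.5, twist: float = 100.0, radius: float = 2.3) -> np.ndarray:
    k = np.arange(n)
    ang = np.radians(twist) * k
    return np.column_stack([radius * np.cos(ang), radius * np.sin(ang), rise * k])


def _lattice_points(n: int, spacing: float = 3.8) -> np.ndarray:
    """Boustrophedon cubic lattice of n points, centered at the origin."""
    side = max(2, math.ceil(n ** (1.0 / 3.0)))
    pts = []
    count = 0
    for iz in range(side + 2):
        for iy in range(side):
            xs = range(side) if iy % 2 == 0 else range(side - 1, -1, -1)
            for ix in xs:
                pts.append((ix * spacing, iy * spacing, iz * spacing))
                count += 1
                if count == n:
                    arr = np.array(pts, dtype=float)
                    return arr - arr.mean(axis=0)
    raise ConstructionError("lattice generation failed")  # pragma: no cover


def _rot_x(angle_deg: float) -> np.ndarray:
    a = math.radians(angle_deg)
    c, s = math.cos(a), math.sin(a)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def _random_sequence(n: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(AA_ONE), size=n))


def mutate_sequence(
    sequence: str,
    rng: np.random.Generator,
    substitution_rate: float = 0.1,
    deletion_rate: float = 0.0,
) -> str:
    """Homolog mode: random substitutions/deletions to exercise the alignment."""
    out = []
    for c in sequence:
        r = rng.random()
        if r < deletion_rate:
            continue
        if r < deletion_rate + substitution_rate:
            out.append(rng.choice([a for a in AA_ONE if a != c]))
        else:
            out.append(c)
    return "".join(out)


def _chain_from_points(
    chain_id: str,
    points: np.ndarray,
    sequence: str,
    b_factors: np.ndarray,
) -> list[Residue]:
    residues = []
    for i, (pos, code) in enumerate(zip(points, sequence), start=1):
        name = AA_THREE[code]
        atom = AtomRecord(
            chain_id=chain_id,
            residue_number=i,
            insertion_code="",
            residue_name=name,
            atom_name="CA",
            position=pos,
            b_factor=float(b_factors[i - 1]),
            occupancy=1.0,
            het_flag=False,
            element="C",
        )
        residues.append(Residue(i, "", name, [atom], False))
    return residues


# ---------------------------------------------------------------------------
# the dimer generator


def _core_template(spec: DimerSpec) -> np.ndarray:
    """Local-frame core C-alpha positions; both interface helices run along +z."""
    n, L = spec.n_core_residues, spec.helix_length
    n_filler = n - 2 * L - 2
    filler = _lattice_points(n_filler) + np.array([0.0, 18.0, 12.0])
    helix3 = _helix_points(L) + np.array([4.5, 0.0, 0.0])
    helix6 = _helix_points(L) + np.array([-4.5, 0.0, 0.0])
    linker = np.array([
        helix3[-1] + (helix6[0] - helix3[-1]) / 3.0,
        helix3[-1] + 2.0 * (helix6[0] - helix3[-1]) / 3.0,
    ])
    return np.vstack([filler, helix3, linker, helix6])


def make_synthetic_dimer(spec: DimerSpec) -> tuple[StructureModel, DimerGroundTruth]:
    """Build a two-chain C-alpha dimer with the requested descriptors.

    At ``noise_sigma = 0`` the pipeline recovers phi, d_centroids and omega
    exactly, and ``domain_rotation(truth.reference, model)`` recovers
    (phy_rotation, phy_translation) exactly: the PHY clouds are rotated about
    their own centroids and shifted by a fixed direction, and the companion
    reference model holds the unperturbed pose. Noise is isotropic Gaussian
    per atom, added last and independently to model and reference.
    """
    _, noise_rng, ref_noise_rng = (
        np.random.default_rng(s) for s in np.random.SeedSequence(spec.seed).spawn(3)
    )
    seq_seed = spec.seed if spec.sequence_seed is None else spec.sequence_seed
    seq_rng = np.random.default_rng(np.random.SeedSequence(seq_seed).spawn(1)[0])
    n_total = spec.n_core_residues + spec.n_phy_residues
    sequence = _random_sequence(n_total, seq_rng)
    scheme = spec.scheme

    core = _core_template(spec)
    R_a = _rot_x(-spec.phi / 2.0)
    R_b = _rot_x(+spec.phi / 2.0)
    shift_b = np.array([spec.subunit_separation, 0.0, 0.0])
    core_a = core @ R_a.T
    core_b = core @ R_b.T + shift_b

    # opening-angle vertex: C-terminal CA of helix3 (A) and helix6 (B)
    h3_end_idx = spec.helix3_range[1] - 1
    h6_end_idx = spec.helix6_range[1] - 1
    vertex = 0.5 * (core_a[h3_end_idx] + core_b[h6_end_idx])

    half = math.radians(spec.omega) / 2.0
    arm = spec.d_centroids / (2.0 * math.sin(half))
    up = np.array([0.0, 0.0, 1.0])
    split = np.array([1.0, 0.0, 0.0])
    cent_a = vertex + arm * (math.cos(half) * up - math.sin(half) * split)
    cent_b = vertex + arm * (math.cos(half) * up + math.sin(half) * split)

    phy_cloud = _lattice_points(spec.n_phy_residues)
    phy_a = phy_cloud @ R_a.T
    phy_a += cent_a - phy_a.mean(axis=0)
    phy_b = phy_cloud @ R_b.T
    phy_b += cent_b - phy_b.mean(axis=0)

    # companion reference: PHY un-perturbed (inverse rotation about the
    # unshifted centroid, inverse shift); cores identical
    t_vec = spec.phy_translation * PERTURB_SHIFT_DIR
    ref_blocks = []
    for phy, cent in ((phy_a, cent_a), (phy_b, cent_b)):
        c_ref = cent - t_vec
        back = RigidTransform.from_axis_angle(PERTURB_AXIS, -spec.phy_rotation, point=c_ref)
        ref_blocks.append(back.apply(phy - t_vec))
    ref_phy_a, ref_phy_b = ref_blocks

    b_factors = np.concatenate([
        np.full(spec.n_core_residues, 50.0),
        np.full(spec.n_phy_residues, 100.0),
    ])

    def assemble(identifier: str, pa, ph_a, pb, ph_b, noise: np.random.Generator) -> StructureModel:
        chain_a = np.vstack([pa, ph_a])
        chain_b = np.vstack([pb, ph_b])
        if spec.noise_sigma > 0:
            chain_a = chain_a + noise.normal(0.0, spec.noise_sigma, chain_a.shape)
            chain_b = chain_b + noise.normal(0.0, spec.noise_sigma, chain_b.shape)
        return StructureModel(
            identifier=identifier,
            chains={
                "A": _chain_from_points("A", chain_a, sequence, b_factors),
                "B": _chain_from_points("B", chain_b, sequence, b_factors),
            },
        )

    model = assemble(f"synthetic-dimer-{spec.seed}", core_a, phy_a, core_b, phy_b, noise_rng)
    reference = assemble(
        f"synthetic-reference-{spec.seed}", core_a, ref_phy_a, core_b, ref_phy_b, ref_noise_rng
    )
    truth = DimerGroundTruth(
        phi=spec.phi,
        d_centroids=spec.d_centroids,
        omega=spec.omega,
        phy_rotation=spec.phy_rotation,
        phy_translation=spec.phy_translation,
        scheme=scheme,
        sequence=sequence,
        reference=reference,
    )
    return model, truth


def perturb_domain(
    model: StructureModel,
    scheme: DomainScheme,
    domain: str,
    rotation: float = 0.0,
    axis_point=(0.0, 0.0, 0.0),
    axis_dir=(0.0, 0.0, 1.0),
    translation=(0.0, 0.0, 0.0),
    chains: tuple[str, ...] | None = None,
) -> StructureModel:
    """Rigidly move one named domain; all other atoms are bitwise unchanged."""
    lo, hi = scheme.range(domain)
    transform = RigidTransform.from_axis_angle(axis_dir, rotation, point=axis_point)
    t = np.asarray(translation, dtype=float)
    out = model.copy()
    targets = chains if chains is not None else tuple(out.chains)
    for cid in targets:
        for res in out.chain(cid):
            if lo <= res.number <= hi:
                res.atoms = [
                    AtomRecord(
                        a.chain_id, a.residue_number, a.insertion_code, a.residue_name,
                        a.atom_name, transform.apply(a.position) + t, a.b_factor,
                        a.occupancy, a.het_flag, a.element,
                    )
                    for a in res.atoms
                ]
    return out


# ---------------------------------------------------------------------------
# spectra


def make_synthetic_spectrum(spec: BandSpec, label: str = "") -> Spectrum:
    """Sum of Gaussian bands plus seeded Gaussian noise on the requested grid."""
    start, stop, step = spec.grid
    wl = np.arange(start, stop + step / 2.0, step)
    ab = np.zeros_like(wl)
    for center, width, amp in spec.bands:
        ab += amp * np.exp(-0.5 * ((wl - center) / width) ** 2)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        ab = ab + rng.normal(0.0, spec.noise_sigma, ab.shape)
    return Spectrum(wl, ab, label or f"synthetic-{spec.seed}")


# ---------------------------------------------------------------------------
# fixtures on disk


def write_fixture(
    spec: DimerSpec,
    out_dir: str | Path,
    stem: str | None = None,
) -> dict:
    """Write a synthetic dimer, its reference and a ground-truth sidecar.

    Returns the sidecar dict; files are ``<stem>.pdb``, ``<stem>_ref.pdb``
    and ``<stem>_truth.yaml``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = stem or f"dimer_seed{spec.seed}"
    model, truth = make_synthetic_dimer(spec)
    write_structure(model, out_dir / f"{stem}.pdb")
    write_structure(truth.reference, out_dir / f"{stem}_ref.pdb")
    sidecar = {
        "model": f"{stem}.pdb",
        "reference": f"{stem}_ref.pdb",
        "phi": truth.phi,
        "d_centroids": truth.d_centroids,
        "omega": truth.omega,
        "phy_rotation": truth.phy_rotation,
        "phy_translation": truth.phy_translation,
        "noise_sigma": spec.noise_sigma,
        "seed": spec.seed,
        "domains": {k: list(v) for k, v in truth.scheme.domains.items()},
        "interface_helices": {k: list(v) for k, v in truth.scheme.interface_helices},
    }
    with open(out_dir / f"{stem}_truth.yaml", "w") as fh:
        yaml.safe_dump(sidecar, fh, sort_keys=False)
    return sidecar
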