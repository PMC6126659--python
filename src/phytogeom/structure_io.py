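"""Coordinate I/O and rigid-body plumbing for the pipeline.

Parses PDB/mmCIF files (via gemmi) into light-weight dataclasses, extracts
C-alpha traces restricted to named domains, and applies rigid transforms.
Conventions owned here and used everywhere downstream:

* coordinates in Angstrom, angles in degrees;
* residue ranges are 1-based inclusive in author numbering;
* altloc handling keeps the highest-occupancy conformer (ties: first label);
* waters and hydrogens are dropped on parse (they play no role in the
  C-alpha geometry); ligands (het records, e.g. the biliverdin chromophore)
  are kept and addressable;
* only the first model of multi-model files is read.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np
import yaml

__all__ = [
    "AtomRecord",
    "Residue",
    "StructureModel",
    "CalphaTrace",
    "DomainScheme",
    "RigidTransform",
    "StructureError",
    "read_structure",
    "write_structure",
    "extract_trace",
    "apply_transform",
    "load_config",
]

#: consecutive C-alpha atoms farther apart than this are reported as a break
CHAIN_BREAK_CUTOFF = 4.5

_WATER_NAMES = {"HOH", "WAT", "DOD"}


class StructureError(ValueError):
    """Raised for unreadable files, empty structures and failed lookups."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom, in author numbering, coordinates in Angstrom."""

    chain_id: str
    residue_number: int
    insertion_code: str
    residue_name: str
    atom_name: str
    position: np.ndarray  # shape (3,)
    b_factor: float = 0.0
    occupancy: float = 1.0
    het_flag: bool = False
    element: str = ""

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise StructureError(f"non-finite or malformed position for {self.atom_name}")
        object.__setattr__(self, "position", pos)
        if self.b_factor < 0:
            raise StructureError(f"negative B factor for {self.atom_name}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise StructureError(f"occupancy outside [0,1] for {self.atom_name}")


@dataclass
class Residue:
    number: int
    insertion_code: str
    name: str
    atoms: list[AtomRecord]
    het_flag: bool = False

    def atom(self, atom_name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.atom_name == atom_name:
                return a
        return None

    @property
    def sort_key(self) -> tuple[int, str]:
        # blank insertion code sorts before lettered ones
        return (self.number, self.insertion_code or "")


@dataclass
class StructureModel:
    """Hierarchical coordinate set: chains -> residues -> atoms."""

    identifier: str
    chains: dict[str, list[Residue]] = field(default_factory=dict)

    @property
    def ligands(self) -> list[Residue]:
        return [r for residues in self.chains.values() for r in residues if r.het_flag]

    def chain(self, chain_id: str) -> list[Residue]:
        try:
            return self.chains[chain_id]
        except KeyError:
            raise StructureError(
                f"chain {chain_id!r} not in {self.identifier!r} "
                f"(has {sorted(self.chains)})"
            ) from None

    def n_atoms(self) -> int:
        return sum(len(r.atoms) for rs in self.chains.values() for r in rs)

    def all_atoms(self) -> Iterable[AtomRecord]:
        for residues in self.chains.values():
            for res in residues:
                yield from res.atoms

    def copy(self) -> "StructureModel":
        return StructureModel(
            identifier=self.identifier,
            chains={
                cid: [Residue(r.number, r.insertion_code, r.name, list(r.atoms), r.het_flag) for r in rs]
                for cid, rs in self.chains.items()
            },
        )


@dataclass
class CalphaTrace:
    """C-alpha positions of one chain (optionally one domain).

    ``breaks`` lists indices i where the i -> i+1 C-alpha distance exceeds
    the chain-break cutoff; breaks are reported, never fatal.
    """

    residue_numbers: list[int]
    residue_codes: str
    positions: np.ndarray  # (n, 3)
    source: tuple[str, str]  # (structure id, chain id)
    breaks: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        if not (len(self.residue_numbers) == len(self.residue_codes) == len(self.positions)):
            raise StructureError("trace field lengths differ")

    def __len__(self) -> int:
        return len(self.residue_numbers)

    def subset(self, indices: Sequence[int]) -> "CalphaTrace":
        idx = list(indices)
        return CalphaTrace(
            [self.residue_numbers[i] for i in idx],
            "".join(self.residue_codes[i] for i in idx),
            self.positions[idx],
            self.source,
        )


@dataclass
class DomainScheme:
    """Named residue ranges (1-based inclusive) per subunit.

    ``interface_helices`` is an ordered list of (name, (start, end)); the
    first listed helix of subunit A and the last listed helix of subunit B
    define the opening-angle vertex downstream.
    """

    domains: dict[str, tuple[int, int]]
    interface_helices: list[tuple[str, tuple[int, int]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ranges = sorted(self.domains.values())
        for (s1, e1), (s2, e2) in zip(ranges, ranges[1:]):
            # partial overlap is an error; full nesting (e.g. the sensory
            # tongue inside PHY) is allowed
            if s2 <= e1 and e2 > e1:
                raise StructureError(f"overlapping domain ranges {(s1, e1)} and {(s2, e2)}")
        for name, (s, e) in list(self.domains.items()) + self.interface_helices:
            if s > e:
                raise StructureError(f"range for {name!r} has start > end")

    def range(self, name: str) -> tuple[int, int]:
        if name in self.domains:
            return self.domains[name]
        for hname, rng in self.interface_helices:
            if hname == name:
                return rng
        raise StructureError(f"unknown domain/helix {name!r} (has {sorted(self.domains)})")

    @classmethod
    def from_dict(cls, d: Mapping) -> "DomainScheme":
        domains = {str(k): (int(v[0]), int(v[1])) for k, v in d.get("domains", {}).items()}
        helices = [(str(k), (int(v[0]), int(v[1]))) for k, v in d.get("interface_helices", {}).items()]
        return cls(domains=domains, interface_helices=helices)


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x -> R x + t."""

    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if np.linalg.norm(R.T @ R - np.eye(3)) > 1e-8 or abs(np.linalg.det(R) - 1.0) > 1e-8:
            raise StructureError("rotation is not proper orthonormal")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_axis_angle(
        cls,
        axis: Sequence[float],
        angle_deg: float,
        point: Sequence[float] = (0.0, 0.0, 0.0),
    ) -> "RigidTransform":
        """Rotation by ``angle_deg`` about the line through ``point`` along ``axis``."""
        axis = np.asarray(axis, dtype=float)
        n = np.linalg.norm(axis)
        if n == 0:
            raise StructureError("zero-length rotation axis")
        k = axis / n
        a = math.radians(angle_deg)
        K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
        R = np.eye(3) + math.sin(a) * K + (1 - math.cos(a)) * (K @ K)
        p = np.asarray(point, dtype=float)
        return cls(R, p - R @ p)

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: x -> self(other(x))."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)


# ---------------------------------------------------------------------------
# parsing


def _pick_altloc(atoms: list[gemmi.Atom]) -> list[gemmi.Atom]:
    """Resolve alternate conformers: highest occupancy, ties to first label."""
    by_name: dict[str, gemmi.Atom] = {}
    for a in atoms:
        prev = by_name.get(a.name)
        if prev is None or a.occ > prev.occ:
            by_name[a.name] = a
    return list(by_name.values())


def read_structure(path: str | Path, format: str = "auto") -> StructureModel:
    """Parse a PDB or mmCIF file into a :class:`StructureModel`.

    Waters and hydrogens are dropped; het records (ligands such as the
    biliverdin chromophore) are kept with ``het_flag`` set. Only the first
    model is read.
    """
    path = Path(path)
    if not path.exists():
        raise StructureError(f"no such coordinate file: {path}")
    fmt = {"pdb": gemmi.CoorFormat.Pdb, "mmcif": gemmi.CoorFormat.Mmcif, "auto": gemmi.CoorFormat.Detect}.get(format)
    if fmt is None:
        raise StructureError(f"unknown format {format!r}; use pdb, mmcif or auto")
    try:
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"could not parse {path}: {exc}") from exc
    st.setup_entities()
    if len(st) == 0:
        raise StructureError(f"no models in {path}")
    model = st[0]
    out = StructureModel(identifier=path.stem)
    for chain in model:
        residues: list[Residue] = []
        for res in chain:
            if res.name in _WATER_NAMES:
                continue
            het = res.het_flag == "H"
            atoms = []
            for a in _pick_altloc(list(res)):
                if a.element == gemmi.Element("H") or a.element == gemmi.Element("D"):
                    continue
                atoms.append(
                    AtomRecord(
                        chain_id=chain.name,
                        residue_number=res.seqid.num,
                        insertion_code=(res.seqid.icode or " ").strip(),
                        residue_name=res.name,
                        atom_name=a.name,
                        position=np.array([a.pos.x, a.pos.y, a.pos.z]),
                        b_factor=max(a.b_iso, 0.0),
                        occupancy=min(max(a.occ, 0.0), 1.0),
                        het_flag=het,
                        element=a.element.name,
                    )
                )
            if atoms:
                residues.append(
                    Residue(res.seqid.num, (res.seqid.icode or " ").strip(), res.name, atoms, het)
                )
        if residues:
            residues.sort(key=lambda r: r.sort_key)
            out.chains[chain.name] = residues
    if out.n_atoms() == 0:
        raise StructureError(f"zero atoms parsed from {path}")
    return out


def _to_gemmi(model: StructureModel) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = model.identifier
    gm = gemmi.Model("1")
    for cid, residues in model.chains.items():
        ch = gemmi.Chain(cid)
        for res in residues:
            gr = gemmi.Residue()
            gr.name = res.name
            gr.seqid = gemmi.SeqId(res.number, res.insertion_code or " ")
            gr.het_flag = "H" if res.het_flag else "A"
            for a in res.atoms:
                ga = gemmi.Atom()
                ga.name = a.atom_name
                ga.pos = gemmi.Position(*a.position)
                ga.b_iso = a.b_factor
                ga.occ = a.occupancy
                ga.element = gemmi.Element(a.element or a.atom_name[:1])
                gr.add_atom(ga)
            ch.add_residue(gr)
        gm.add_chain(ch)
    st.add_model(gm)
    st.setup_entities()
    # keep the author's ATOM/HETATM split (setup_entities may reclassify
    # CA-only synthetic chains as het)
    for ch in st[0]:
        for gr in ch:
            key = None
            for res in model.chains.get(ch.name, []):
                if res.number == gr.seqid.num and res.name == gr.name:
                    key = res
                    break
            gr.het_flag = "H" if (key is not None and key.het_flag) else "A"
    return st


def write_structure(model: StructureModel, path: str | Path, format: str = "auto") -> Path:
    """Serialize a model as minimal PDB or mmCIF (dialect by extension for auto)."""
    path = Path(path)
    if format == "auto":
        format = "mmcif" if path.suffix.lower() in {".cif", ".mmcif"} else "pdb"
    st = _to_gemmi(model)
    if format == "pdb":
        path.write_text(st.make_pdb_string())
    elif format == "mmcif":
        path.write_text(st.make_mmcif_document().as_string())
    else:
        raise StructureError(f"unknown format {format!r}")
    return path


def one_letter(residue_name: str) -> str:
    """3-letter -> 1-letter code; modified residues map to parent, else X."""
    info = gemmi.find_tabulated_residue(residue_name)
    if info is not None and info.is_amino_acid():
        code = info.one_letter_code.upper()
        if code.isalpha():
            return code
    return "X"


def extract_trace(
    structure: StructureModel,
    chain: str,
    domains: DomainScheme | None = None,
    domain: str | None = None,
) -> CalphaTrace:
    """One C-alpha per residue of a chain, optionally restricted to a domain.

    Residues without a CA atom are skipped; chain breaks (consecutive CA
    farther than 4.5 A apart) are recorded in ``trace.breaks``.
    """
    residues = structure.chain(chain)
    lo, hi = (-(10**9), 10**9)
    if domain is not None:
        if domains is None:
            raise StructureError("domain name given without a DomainScheme")
        lo, hi = domains.range(domain)
    nums: list[int] = []
    codes: list[str] = []
    pos: list[np.ndarray] = []
    for res in residues:
        if res.het_flag or not (lo <= res.number <= hi):
            continue
        ca = res.atom("CA")
        if ca is None:
            continue
        nums.append(res.number)
        codes.append(one_letter(res.name))
        pos.append(ca.position)
    arr = np.array(pos, dtype=float).reshape(-1, 3)
    breaks = [
        i
        for i in range(len(arr) - 1)
        if np.linalg.norm(arr[i + 1] - arr[i]) > CHAIN_BREAK_CUTOFF
    ]
    return CalphaTrace(nums, "".join(codes), arr, (structure.identifier, chain), breaks)


def apply_transform(obj, transform: RigidTransform):
    """Apply a rigid motion to a StructureModel or CalphaTrace (returns a copy)."""
    if isinstance(obj, CalphaTrace):
        return CalphaTrace(
            list(obj.residue_numbers),
            obj.residue_codes,
            transform.apply(obj.positions),
            obj.source,
            list(obj.breaks),
        )
    if isinstance(obj, StructureModel):
        out = obj.copy()
        for residues in out.chains.values():
            for res in residues:
                res.atoms = [
                    replace(a, position=transform.apply(a.position)) for a in res.atoms
                ]
        return out
    raise TypeError(f"cannot transform object of type {type(obj).__name__}")


# ---------------------------------------------------------------------------
# configuration


DEFAULT_SCHEME = DomainScheme(
    # PAS-GAF core ends at the kink residue 325; the PHY domain follows.
    domains={"PAS": (1, 120), "GAF": (121, 325), "PHY": (326, 516), "tongue": (435, 485)},
    interface_helices=[("helix3", (296, 325)), ("helix6", (296, 325))],
)


def load_config(path: str | Path) -> dict:
    """Read the YAML pipeline config; returns a plain dict.

    Recognized keys include ``domains``, ``interface_helices``, ``reference``,
    ``comparisons``, ``cutoff``, ``spectra_jobs`` and an optional ``symmetry``
    operator given as 12 row-major numbers (rotation then translation) for
    building a dimer from a monomeric asymmetric unit.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise StructureError(f"config {path} is not a mapping")
    if "symmetry" in cfg:
        vals = [float(x) for x in cfg["symmetry"]]
        if len(vals) != 12:
            raise StructureError("symmetry operator needs 12 numbers (9 rotation + 3 translation)")
        cfg["symmetry"] = RigidTransform(np.array(vals[:9]).reshape(3, 3), np.array(vals[9:]))
    return cfg


def scheme_from_config(cfg: Mapping) -> DomainScheme:
    if "domains" in cfg:
        return DomainScheme.from_dict(cfg)
    return DEFAULT_SCHEME
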