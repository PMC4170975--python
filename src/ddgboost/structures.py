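"""Protein structures: PDB I/O, chain isolation, and coarse toy-fold generators.

The in-memory model is deliberately flat: a :class:`Structure` is an ordered
list of :class:`Atom` records, with residues exposed as views.  This mirrors
how mutation tables address residues (author numbering, chain id) and keeps
every geometric operation a plain array computation.

Real structures are read from fixed-column PDB files.  For self-contained
testing and simulation the module also generates ideal α-helical toy folds in
which every side chain is collapsed to a single pseudo-atom ("SC") placed
along the Cβ direction at a residue-specific distance.  A coarse mutant
builder swaps that pseudo-atom, leaving the backbone untouched; real mutant
structures (e.g. produced by an external modelling tool) can be supplied via
:func:`read_pdb` instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Atom",
    "Structure",
    "Residue",
    "PdbFormatError",
    "read_pdb",
    "write_pdb",
    "isolate_chains",
    "make_toy_fold",
    "make_toy_complex",
    "mutate_residue_simple",
    "AA1TO3",
    "AA3TO1",
    "STANDARD_AA",
    "BACKBONE_NAMES",
    "PSEUDO_SIDECHAIN",
    "WATER_NAMES",
]

# ---------------------------------------------------------------------------
# Constants
# ---------------------------------------------------------------------------

AA1TO3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
AA3TO1 = {v: k for k, v in AA1TO3.items()}
STANDARD_AA = frozenset(AA1TO3)

BACKBONE_NAMES = frozenset({"N", "CA", "C", "O", "OXT"})
WATER_NAMES = frozenset({"HOH", "WAT", "DOD"})

# Single pseudo-side-chain atom per residue type: (distance from CA along the
# Cβ direction, effective vdW radius, element).  Distances grow with side-chain
# size; elements carry the dominant chemistry of the side chain so that the
# contact classifier sees donors/acceptors and charges (Lys/Arg positive
# nitrogen, Asp/Glu negative oxygen).  Glycine has no side-chain atom.
PSEUDO_SIDECHAIN: dict[str, tuple[float, float, str]] = {
    "ALA": (1.53, 1.90, "C"),
    "SER": (1.90, 1.90, "O"),
    "CYS": (2.05, 2.00, "S"),
    "THR": (1.95, 2.00, "O"),
    "PRO": (1.90, 1.95, "C"),
    "VAL": (2.05, 2.20, "C"),
    "ASN": (2.50, 2.05, "O"),
    "ASP": (2.50, 2.00, "O"),
    "ILE": (2.35, 2.30, "C"),
    "LEU": (2.60, 2.30, "C"),
    "MET": (2.90, 2.35, "S"),
    "GLN": (3.10, 2.10, "O"),
    "GLU": (3.10, 2.05, "O"),
    "LYS": (3.50, 2.20, "N"),
    "HIS": (3.10, 2.20, "N"),
    "PHE": (3.40, 2.40, "C"),
    "ARG": (4.10, 2.30, "N"),
    "TYR": (3.90, 2.40, "C"),
    "TRP": (3.90, 2.60, "C"),
}

# Ideal backbone geometry (Engh–Huber-like values).
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.458, 1.525, 1.329, 1.231
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.2, 116.2, 121.7, 120.8
_PHI, _PSI, _OMEGA = -57.0, -47.0, 180.0


class PdbFormatError(ValueError):
    """Raised when a file is not interpretable as a protein PDB entry."""


@dataclass(frozen=True)
class Atom:
    """One atom record; coordinates in Å, author residue numbering."""

    serial: int
    name: str
    element: str
    residue_name: str
    chain_id: str
    residue_seq: int
    insertion_code: str = ""
    x: float = 0.0
    y: float = 0.0
    z: float = 0.0
    is_hetero: bool = False

    @property
    def coord(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    @property
    def residue_id(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_seq, self.insertion_code)


@dataclass(frozen=True)
class Residue:
    """View over the atoms of one residue."""

    chain_id: str
    residue_seq: int
    insertion_code: str
    residue_name: str
    atoms: tuple[Atom, ...]

    @property
    def side_chain_atoms(self) -> tuple[Atom, ...]:
        return tuple(a for a in self.atoms if a.name not in BACKBONE_NAMES)

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"no atom {name!r} in residue {self.residue_name} "
                       f"{self.chain_id}{self.residue_seq}")


@dataclass
class Structure:
    id: str
    atoms: list[Atom] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not any(not a.is_hetero for a in self.atoms):
            raise ValueError(f"structure {self.id!r} has no protein atoms")
        seen: set[tuple] = set()
        for a in self.atoms:
            if not all(math.isfinite(v) for v in (a.x, a.y, a.z)):
                raise ValueError(f"non-finite coordinate in atom {a.serial}")
            if not a.element:
                raise ValueError(f"atom {a.serial} has empty element")
            key = (a.chain_id, a.residue_seq, a.insertion_code, a.name)
            if key in seen:
                raise ValueError(f"duplicate atom {key} in structure {self.id!r}")
            seen.add(key)

    @property
    def chains(self) -> list[str]:
        out: list[str] = []
        for a in self.atoms:
            if not a.is_hetero and a.chain_id not in out:
                out.append(a.chain_id)
        return out

    def residues(self, chain: str | None = None,
                 include_hetero: bool = False) -> list[Residue]:
        groups: dict[tuple, list[Atom]] = {}
        order: list[tuple] = []
        for a in self.atoms:
            if a.is_hetero and not include_hetero:
                continue
            if chain is not None and a.chain_id != chain:
                continue
            key = a.residue_id
            if key not in groups:
                groups[key] = []
                order.append(key)
            groups[key].append(a)
        return [
            Residue(k[0], k[1], k[2], groups[k][0].residue_name, tuple(groups[k]))
            for k in order
        ]

    def get_residue(self, chain: str, residue_seq: int,
                    insertion_code: str = "") -> Residue:
        for r in self.residues(chain):
            if r.residue_seq == residue_seq and r.insertion_code == insertion_code:
                return r
        raise KeyError(f"residue {chain}/{residue_seq}{insertion_code or ''} "
                       f"not found in structure {self.id!r}")

    def coords(self) -> np.ndarray:
        return np.array([[a.x, a.y, a.z] for a in self.atoms], dtype=float)

    def sequence(self, chain: str) -> str:
        return "".join(AA3TO1.get(r.residue_name, "X") for r in self.residues(chain))


# ---------------------------------------------------------------------------
# PDB I/O (fixed columns; first model only)
# ---------------------------------------------------------------------------

def read_pdb(path) -> Structure:
    """Read ATOM/HETATM records from a PDB file.

    Alternate locations are resolved to the highest occupancy (first wins on
    ties); only the first model of a multi-model file is kept; hydrogens are
    retained if present.
    """
    best: dict[tuple, tuple[float, int, Atom]] = {}
    order: list[tuple] = []
    n = 0
    with open(path) as fh:
        for line in fh:
            rec = line[:6]
            if rec == "ENDMDL":
                break
            if rec not in ("ATOM  ", "HETATM"):
                continue
            n += 1
            name = line[12:16].strip()
            altloc = line[16].strip()
            element = line[76:78].strip() or _guess_element(name)
            try:
                occ = float(line[54:60]) if line[54:60].strip() else 1.0
            except ValueError:
                occ = 1.0
            atom = Atom(
                serial=int(line[6:11]),
                name=name,
                element=element,
                residue_name=line[17:20].strip(),
                chain_id=line[21].strip() or " ",
                residue_seq=int(line[22:26]),
                insertion_code=line[26].strip(),
                x=float(line[30:38]),
                y=float(line[38:46]),
                z=float(line[46:54]),
                is_hetero=(rec == "HETATM"),
            )
            key = atom.residue_id + (atom.name,)
            if altloc and key in best:
                if occ > best[key][0]:
                    best[key] = (occ, best[key][1], atom)
                continue
            if key not in best:
                order.append(key)
            best[key] = (occ, len(order), atom)
    if n == 0:
        raise PdbFormatError(f"{path}: no ATOM/HETATM records")
    atoms = [best[k][2] for k in order]
    if not any(not a.is_hetero for a in atoms):
        raise PdbFormatError(f"{path}: no protein (ATOM) records")
    import os
    sid = os.path.splitext(os.path.basename(str(path)))[0]
    return Structure(id=sid, atoms=atoms)


def _guess_element(name: str) -> str:
    if name == "SC":
        return "C"
    stripped = name.lstrip("0123456789")
    return stripped[:1].upper() if stripped else "C"


def write_pdb(structure: Structure, path) -> None:
    """Write fixed-column ATOM/HETATM records (coordinates %8.3f).

    Raises ``ValueError`` on a coordinate that does not fit the 8-column
    field instead of silently truncating.
    """
    lines = []
    for a in structure.atoms:
        for v in (a.x, a.y, a.z):
            if len(f"{v:8.3f}") > 8:
                raise ValueError(f"coordinate {v} overflows PDB 8.3 column")
        rec = "HETATM" if a.is_hetero else "ATOM  "
        name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
        lines.append(
            f"{rec}{a.serial:5d} {name}{'':1s}{a.residue_name:>3s} "
            f"{a.chain_id:1s}{a.residue_seq:4d}{a.insertion_code or ' ':1s}   "
            f"{a.x:8.3f}{a.y:8.3f}{a.z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
            f"{a.element:>2s}  "
        )
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def isolate_chains(structure: Structure, chains) -> Structure:
    """Keep the requested protein chains plus all non-water HETATM ligands."""
    chains = set(chains)
    missing = chains - set(structure.chains)
    if missing:
        raise KeyError(f"chain(s) {sorted(missing)} not in structure "
                       f"{structure.id!r} (has {structure.chains})")
    atoms = [
        a for a in structure.atoms
        if (not a.is_hetero and a.chain_id in chains)
        or (a.is_hetero and a.residue_name not in WATER_NAMES)
    ]
    return Structure(id=structure.id, atoms=atoms)


# ---------------------------------------------------------------------------
# Toy-fold generators
# ---------------------------------------------------------------------------

def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Natural-extension placement of atom D from internal coordinates."""
    theta = math.radians(angle_deg)
    phi = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([
        -bond * math.cos(theta),
        bond * math.sin(theta) * math.cos(phi),
        bond * math.sin(theta) * math.sin(phi),
    ])
    return c + d[0] * bc + d[1] * m + d[2] * n


def _cb_direction(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    # Ideal tetrahedral Cβ construction from backbone N, CA, C.
    b = ca - n
    cc = c - ca
    a = np.cross(b, cc)
    cb = -0.58273431 * a + 0.56802827 * b - 0.54067466 * cc
    return cb / np.linalg.norm(cb)


def make_toy_fold(seed: int, n_residues: int, sequence: str | None = None,
                  chain_id: str = "A", structure_id: str | None = None) -> Structure:
    """Generate an ideal α-helical fold with single-pseudo-atom side chains.

    Deterministic per seed.  The backbone is built from ideal internal
    coordinates (φ=−57°, ψ=−47°, ω=180°); each non-glycine residue carries one
    "SC" pseudo-atom along the Cβ direction at a residue-specific distance.  A
    small seeded coordinate jitter (σ = 0.02 Å) breaks exact symmetry so SASA
    and contact features vary between residues.
    """
    if n_residues < 3:
        raise ValueError("a toy fold needs at least 3 residues")
    rng = np.random.default_rng(seed)
    if sequence is None:
        aas = sorted(STANDARD_AA)
        sequence = "".join(rng.choice(aas) for _ in range(n_residues))
    if len(sequence) != n_residues:
        raise ValueError("sequence length must equal n_residues")
    bad = set(sequence) - STANDARD_AA
    if bad:
        raise ValueError(f"nonstandard amino acid(s) {sorted(bad)}")

    # backbone trace
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([_B_N_CA, 0.0, 0.0])
    th = math.radians(_A_N_CA_C)
    c0 = ca0 + np.array([-_B_CA_C * math.cos(th), _B_CA_C * math.sin(th), 0.0])
    bb = [(n0, ca0, c0)]
    for _ in range(1, n_residues):
        n_prev, ca_prev, c_prev = bb[-1]
        n_i = _place_atom(n_prev, ca_prev, c_prev, _B_C_N, _A_CA_C_N, _PSI)
        ca_i = _place_atom(ca_prev, c_prev, n_i, _B_N_CA, _A_C_N_CA, _OMEGA)
        c_i = _place_atom(c_prev, n_i, ca_i, _B_CA_C, _A_N_CA_C, _PHI)
        bb.append((n_i, ca_i, c_i))

    atoms: list[Atom] = []
    serial = 1
    for i, aa in enumerate(sequence):
        res3 = AA1TO3[aa]
        n_i, ca_i, c_i = bb[i]
        if i + 1 < n_residues:
            n_next = bb[i + 1][0]
            o_i = _place_atom(n_next, ca_i, c_i, _B_C_O, _A_CA_C_O, 180.0)
        else:
            o_i = _place_atom(n_i, ca_i, c_i, _B_C_O, _A_CA_C_O, _PSI + 180.0)
        coords = {"N": n_i, "CA": ca_i, "C": c_i, "O": o_i}
        if res3 != "GLY":
            dist, _radius, _elem = PSEUDO_SIDECHAIN[res3]
            coords["SC"] = ca_i + dist * _cb_direction(n_i, ca_i, c_i)
        for name in ("N", "CA", "C", "O", "SC"):
            if name not in coords:
                continue
            xyz = coords[name] + rng.normal(0.0, 0.02, size=3)
            element = (PSEUDO_SIDECHAIN[res3][2] if name == "SC"
                       else ("N" if name == "N" else
                             "O" if name == "O" else "C"))
            atoms.append(Atom(serial=serial, name=name, element=element,
                              residue_name=res3, chain_id=chain_id,
                              residue_seq=i + 1,
                              x=round(float(xyz[0]), 3),
                              y=round(float(xyz[1]), 3),
                              z=round(float(xyz[2]), 3)))
            serial += 1
    sid = structure_id or f"toy{seed}"
    return Structure(id=sid, atoms=atoms)


def _min_interchain_distance(coords_a: np.ndarray, coords_b: np.ndarray):
    d = np.linalg.norm(coords_a[:, None, :] - coords_b[None, :, :], axis=2)
    i, j = np.unravel_index(np.argmin(d), d.shape)
    return float(d[i, j]), i, j


def make_toy_complex(seed: int, n_res_a: int, n_res_b: int, gap: float = 4.0,
                     sequence_a: str | None = None, sequence_b: str | None = None,
                     structure_id: str | None = None) -> Structure:
    """Two toy folds (chains A and B) with a prescribed closest-approach gap.

    Chain B is rotated head-to-tail and translated so that the minimal
    inter-chain heavy-atom distance equals ``gap`` within 0.1 Å.
    """
    if gap < 0.5:
        raise ValueError("gap must be at least 0.5 Å")
    fa = make_toy_fold(seed, n_res_a, sequence=sequence_a, chain_id="A")
    fb = make_toy_fold(seed + 1, n_res_b, sequence=sequence_b, chain_id="B")
    ca = fa.coords()
    cb = fb.coords()

    def _axis(coords: np.ndarray) -> np.ndarray:
        centred = coords - coords.mean(0)
        _, _, vt = np.linalg.svd(centred)
        ax = vt[0]
        return ax if ax @ (coords[-1] - coords[0]) >= 0 else -ax

    def _rot_between(u: np.ndarray, v: np.ndarray) -> np.ndarray:
        # rotation taking unit vector u onto unit vector v
        w = np.cross(u, v)
        c = float(u @ v)
        if np.linalg.norm(w) < 1e-9:
            if c > 0:
                return np.eye(3)
            p = np.eye(3)[np.argmin(np.abs(u))]
            w = np.cross(u, p)
            w /= np.linalg.norm(w)
            return 2.0 * np.outer(w, w) - np.eye(3)
        k = np.array([[0, -w[2], w[1]], [w[2], 0, -w[0]], [-w[1], w[0], 0]])
        return np.eye(3) + k + k @ k / (1.0 + c)

    # pack the two helices antiparallel, side by side: rotate B so its axis
    # opposes A's, then approach along a perpendicular offset direction
    ax_a = _axis(ca)
    rot = _rot_between(_axis(cb), -ax_a)
    cb = (cb - cb.mean(0)) @ rot.T + ca.mean(0)
    perp = np.cross(ax_a, np.eye(3)[np.argmin(np.abs(ax_a))])
    perp /= np.linalg.norm(perp)
    span = (ca.max(0) - ca.min(0)).max() + (cb.max(0) - cb.min(0)).max()
    t_hi = span + gap + 10.0
    cb0 = cb

    def _gap_at(t: float) -> float:
        return _min_interchain_distance(ca, cb0 + t * perp)[0]

    t_lo = 0.0
    while _gap_at(t_lo) > gap and t_lo > -t_hi:
        t_lo -= 1.0
    lo, hi = t_lo, t_hi
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if _gap_at(mid) < gap:
            lo = mid
        else:
            hi = mid
    cb = cb0 + hi * perp
    d, _, _ = _min_interchain_distance(ca, cb)
    if abs(d - gap) > 0.1:
        raise RuntimeError(f"gap placement failed: wanted {gap}, got {d:.3f}")

    atoms: list[Atom] = []
    serial = 1
    for src, xyz in ((fa, ca), (fb, cb)):
        for a, c in zip(src.atoms, xyz):
            atoms.append(replace(a, serial=serial,
                                 x=round(float(c[0]), 3),
                                 y=round(float(c[1]), 3),
                                 z=round(float(c[2]), 3)))
            serial += 1
    sid = structure_id or f"toycx{seed}"
    return Structure(id=sid, atoms=atoms)


def mutate_residue_simple(structure: Structure, chain: str, residue_seq: int,
                          new_aa: str) -> Structure:
    """Coarse point mutant: backbone kept, side chain replaced by the
    pseudo-atom representation of ``new_aa`` (glycine → no side-chain atom).

    This stands in for a physics-based mutant builder; externally built
    mutant structures can be read with :func:`read_pdb` instead.
    """
    if new_aa not in STANDARD_AA:
        raise ValueError(f"{new_aa!r} is not a standard amino acid code")
    target = structure.get_residue(chain, residue_seq)  # KeyError if absent
    if target.residue_name not in AA3TO1:
        raise ValueError(f"target residue {target.residue_name} is not a "
                         "standard amino acid")
    new3 = AA1TO3[new_aa]
    try:
        n = target.atom("N").coord
        ca = target.atom("CA").coord
        c = target.atom("C").coord
    except KeyError as exc:
        raise ValueError(f"residue {chain}/{residue_seq} lacks backbone "
                         f"atoms needed for mutation: {exc}")
    atoms: list[Atom] = []
    inserted = False
    max_serial = max(a.serial for a in structure.atoms)
    for a in structure.atoms:
        in_target = (not a.is_hetero and a.residue_id ==
                     (chain, residue_seq, target.insertion_code))
        if not in_target:
            atoms.append(a)
            continue
        if a.name in BACKBONE_NAMES:
            atoms.append(replace(a, residue_name=new3))
            if a.name == "C" and new3 != "GLY" and not inserted:
                dist, _radius, elem = PSEUDO_SIDECHAIN[new3]
                xyz = ca + dist * _cb_direction(n, ca, c)
                atoms.append(Atom(serial=max_serial + 1, name="SC",
                                  element=elem, residue_name=new3,
                                  chain_id=chain, residue_seq=residue_seq,
                                  insertion_code=target.insertion_code,
                                  x=round(float(xyz[0]), 3),
                                  y=round(float(xyz[1]), 3),
                                  z=round(float(xyz[2]), 3)))
                inserted = True
        # non-backbone atoms of the target residue are dropped
    return Structure(id=f"{structure.id}_{chain}{residue_seq}{new_aa}",
                     atoms=atoms)
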