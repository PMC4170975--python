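"""Sequence and molecular descriptors for point mutations.

Implements the descriptor categories used by structure-based ΔΔG predictors:

* sequence features — domain length, BLOSUM80 substitution score, and a
  conservation score derived from a multiple sequence alignment;
* molecular features — counts of hydrophobic / hydrophilic / electrostatic
  atom contacts (intra- and inter-chain), solvent-accessible surface areas
  (Shrake–Rupley), and interface burial descriptors for complexes;
* context classification — core (side-chain SASA < 10 Å²), interface (any
  atom within 5 Å of the partner chain) or surface.

Contact classes follow the convention: hydrophobic = carbon–carbon pairs
within 5 Å; hydrophilic = hydrogen-bond donor–acceptor pairs within 4 Å;
electrostatic = opposite-charge atom pairs within 4 Å.  Where a pair
satisfies several definitions the most specific chemistry wins
(electrostatic > hydrophilic > hydrophobic).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .structures import (
    AA1TO3,
    AA3TO1,
    BACKBONE_NAMES,
    PSEUDO_SIDECHAIN,
    STANDARD_AA,
    Structure,
)

__all__ = [
    "ContactCounts",
    "SasaResult",
    "InterfaceDescriptor",
    "MutationRecord",
    "FeatureVector",
    "classify_atom_contact",
    "count_contacts",
    "compute_sasa",
    "is_core_residue",
    "interface_residues",
    "interface_sasa",
    "classify_mutation_context",
    "blosum80_score",
    "conservation_score",
    "build_feature_vector",
    "feature_registry",
    "CORE_SASA_CUTOFF",
    "INTERFACE_CUTOFF",
    "HYDROPHOBIC_CUTOFF",
    "POLAR_CUTOFF",
    "VDW_RADII",
]

# ---------------------------------------------------------------------------
# Cutoffs and chemistry tables
# ---------------------------------------------------------------------------

HYDROPHOBIC_CUTOFF = 5.0   # Å, carbon–carbon
POLAR_CUTOFF = 4.0         # Å, donor–acceptor and charged pairs
INTERFACE_CUTOFF = 5.0     # Å, any-atom distance to the partner chain
CORE_SASA_CUTOFF = 10.0    # Å², side-chain SASA below which a residue is core

VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20}

# Charged side-chain atoms by (residue, atom name); pseudo side chains carry
# the charge of their parent residue.
_POSITIVE = {("LYS", "NZ"), ("ARG", "NH1"), ("ARG", "NH2"), ("ARG", "NE"),
             ("LYS", "SC"), ("ARG", "SC")}
_NEGATIVE = {("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2"),
             ("ASP", "SC"), ("GLU", "SC")}


def _atom_radius(atom) -> float:
    if atom.name == "SC":
        try:
            return PSEUDO_SIDECHAIN[atom.residue_name][1]
        except KeyError:
            raise ValueError(f"no pseudo-atom radius for {atom.residue_name}")
    try:
        return VDW_RADII[atom.element]
    except KeyError:
        raise ValueError(f"no van der Waals radius for element {atom.element!r}")


def _is_positive(atom) -> bool:
    return (atom.residue_name, atom.name) in _POSITIVE


def _is_negative(atom) -> bool:
    if (atom.residue_name, atom.name) in _NEGATIVE:
        return True
    return atom.name == "OXT"  # C-terminal carboxylate


def _is_donor(atom) -> bool:
    # backbone and side-chain nitrogens donate; Cys/Met sulfur treated as donor
    return atom.element == "N" or (atom.element == "S")


def _is_acceptor(atom) -> bool:
    return atom.element in ("O", "S")


def classify_atom_contact(a1, a2, distance: float) -> str:
    """Classify one atom pair as electrostatic, hydrophilic, hydrophobic or none.

    Precedence is electrostatic > hydrophilic > hydrophobic so that each pair
    receives exactly one class.
    """
    if distance < 0:
        raise ValueError("distance must be non-negative")
    for a in (a1, a2):
        if a.element not in VDW_RADII and a.name != "SC":
            raise ValueError(f"unknown element {a.element!r}")
    if distance <= POLAR_CUTOFF:
        if (_is_positive(a1) and _is_negative(a2)) or \
           (_is_negative(a1) and _is_positive(a2)):
            return "electrostatic"
        if (_is_donor(a1) and _is_acceptor(a2)) or \
           (_is_acceptor(a1) and _is_donor(a2)):
            return "hydrophilic"
    if distance <= HYDROPHOBIC_CUTOFF and a1.element == "C" and a2.element == "C":
        return "hydrophobic"
    return "none"


@dataclass(frozen=True)
class ContactCounts:
    hydrophobic_intra: int = 0
    hydrophilic_intra: int = 0
    electrostatic_intra: int = 0
    hydrophobic_inter: int = 0
    hydrophilic_inter: int = 0
    electrostatic_inter: int = 0


def _atom_flags(structure: Structure):
    """Vectorized chemistry flags per atom."""
    ats = structure.atoms
    pos = np.array([_is_positive(a) for a in ats])
    neg = np.array([_is_negative(a) for a in ats])
    don = np.array([_is_donor(a) for a in ats])
    acc = np.array([_is_acceptor(a) for a in ats])
    carbon = np.array([a.element == "C" for a in ats])
    return pos, neg, don, acc, carbon


def count_contacts(structure: Structure, chain: str, residue_seq: int) -> ContactCounts:
    """Count classified contacts between one residue and its surroundings.

    Intra-residue pairs are excluded; sequence neighbours are included.
    Intra = partner atom on the same chain, inter = on another chain.
    """
    res = structure.get_residue(chain, residue_seq)  # KeyError if absent
    ats = structure.atoms
    coords = structure.coords()
    in_res = np.array([(not a.is_hetero) and a.residue_id == res.atoms[0].residue_id
                       for a in ats])
    same_chain = np.array([a.chain_id == chain and not a.is_hetero for a in ats])
    pos, neg, don, acc, carbon = _atom_flags(structure)

    ri = np.where(in_res)[0]
    rj = np.where(~in_res)[0]
    if ri.size == 0 or rj.size == 0:
        return ContactCounts()
    d = np.linalg.norm(coords[ri][:, None, :] - coords[rj][None, :, :], axis=2)

    elec = (np.outer(pos[ri], neg[rj]) | np.outer(neg[ri], pos[rj])) & (d <= POLAR_CUTOFF)
    philic = (np.outer(don[ri], acc[rj]) | np.outer(acc[ri], don[rj])) \
        & (d <= POLAR_CUTOFF) & ~elec
    phobic = np.outer(carbon[ri], carbon[rj]) & (d <= HYDROPHOBIC_CUTOFF) \
        & ~elec & ~philic

    intra = same_chain[rj][None, :]
    return ContactCounts(
        hydrophobic_intra=int((phobic & intra).sum()),
        hydrophilic_intra=int((philic & intra).sum()),
        electrostatic_intra=int((elec & intra).sum()),
        hydrophobic_inter=int((phobic & ~intra).sum()),
        hydrophilic_inter=int((philic & ~intra).sum()),
        electrostatic_inter=int((elec & ~intra).sum()),
    )


# ---------------------------------------------------------------------------
# Solvent-accessible surface area (Shrake–Rupley)
# ---------------------------------------------------------------------------

@dataclass
class SasaResult:
    atom_sasa: np.ndarray                     # Å², ordered like structure.atoms
    residue_sasa: dict                        # residue_id -> total Å²
    side_chain_sasa: dict                     # residue_id -> side-chain Å²
    structure_total: float = 0.0


from functools import lru_cache


@lru_cache(maxsize=8)
def _golden_spiral(n: int) -> np.ndarray:
    """Deterministic, nearly uniform unit-sphere point set."""
    k = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (k + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    phi = k * math.pi * (3.0 - math.sqrt(5.0))
    pts = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    pts.setflags(write=False)
    return pts


_SASA_CACHE: dict = {}
_SASA_CACHE_MAX = 512


def compute_sasa(structure: Structure, probe: float = 1.4,
                 n_points: int = 960) -> SasaResult:
    """Numeric SASA by testing sphere points against neighbouring atoms.

    Deterministic (golden-spiral point set), rotation/translation invariant to
    within the angular resolution of the point set (≤ 0.5 % at 960 points).
    Results are memoized on a digest of coordinates and radii, so repeated
    calls on identical geometry (e.g. a shared partner chain across many
    mutations) are free.
    """
    if not structure.atoms:
        raise ValueError("empty structure")
    if n_points < 92:
        raise ValueError("n_points must be at least 92")
    ats = structure.atoms
    coords = structure.coords()
    radii = np.array([_atom_radius(a) for a in ats]) + probe

    import hashlib
    meta = ",".join(f"{a.chain_id}{a.residue_seq}{a.insertion_code}{a.name}"
                    f"{int(a.is_hetero)}" for a in ats)
    key = (probe, n_points,
           hashlib.md5(coords.tobytes() + radii.tobytes()
                       + meta.encode()).hexdigest())
    if key in _SASA_CACHE:
        return _SASA_CACHE[key]
    result = _compute_sasa_impl(ats, coords, radii, n_points)
    if len(_SASA_CACHE) >= _SASA_CACHE_MAX:
        _SASA_CACHE.pop(next(iter(_SASA_CACHE)))
    _SASA_CACHE[key] = result
    return result


@lru_cache(maxsize=8)
def _refinement_offsets(n_points: int) -> np.ndarray:
    """Tangent-plane sub-point offsets used to sharpen occlusion boundaries."""
    cell = math.sqrt(4.0 * math.pi / n_points)
    offs = [(0.0, 0.0)]
    for ring, rad, twist in ((6, 0.38, 0.0), (6, 0.19, 0.26)):
        for t in range(ring):
            ang = 2.0 * math.pi * t / ring + twist
            offs.append((rad * cell * math.cos(ang),
                         rad * cell * math.sin(ang)))
    arr = np.array(offs)
    arr.setflags(write=False)
    return arr


def _compute_sasa_impl(ats, coords, radii, n_points) -> SasaResult:
    sphere = _golden_spiral(n_points)
    offs = _refinement_offsets(n_points)
    cell = math.sqrt(4.0 * math.pi / n_points)

    n = len(ats)
    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
    cutoff2 = (radii[:, None] + radii[None, :]) ** 2
    atom_sasa = np.empty(n)
    for i in range(n):
        nb = np.where((d2[i] < cutoff2[i]) & (np.arange(n) != i))[0]
        if nb.size == 0:
            atom_sasa[i] = 4.0 * math.pi * radii[i] ** 2
            continue
        cnb = coords[nb]
        rnb = radii[nb]
        pts = coords[i] + radii[i] * sphere
        dd = np.sqrt(((pts[:, None, :] - cnb[None, :, :]) ** 2).sum(axis=2))
        margin = (dd - rnb[None, :]).min(axis=1)
        band = radii[i] * cell
        frac = float((margin > band).mean())
        # points close to an occluder surface are re-estimated on a local
        # deterministic sub-grid, sharpening the buried/exposed boundary
        bidx = np.where((margin <= band) & (margin >= -band))[0]
        if bidx.size:
            u = sphere[bidx]
            pole = np.where(np.abs(u[:, 2:3]) < 0.9,
                            np.array([0.0, 0.0, 1.0]),
                            np.array([1.0, 0.0, 0.0]))
            t1 = np.cross(u, pole)
            t1 /= np.linalg.norm(t1, axis=1, keepdims=True)
            t2 = np.cross(u, t1)
            sub = (u[:, None, :] + offs[None, :, 0:1] * t1[:, None, :]
                   + offs[None, :, 1:2] * t2[:, None, :])
            sub /= np.linalg.norm(sub, axis=2, keepdims=True)
            sp = coords[i] + radii[i] * sub
            sdd = np.sqrt(((sp[:, :, None, :] - cnb[None, None, :, :]) ** 2)
                          .sum(axis=3))
            exposed = (sdd - rnb[None, None, :]).min(axis=2) > 0.0
            frac += float(exposed.mean(axis=1).sum()) / n_points
        atom_sasa[i] = frac * 4.0 * math.pi * radii[i] ** 2

    residue_sasa: dict = {}
    side_chain: dict = {}
    for a, s in zip(ats, atom_sasa):
        if a.is_hetero:
            continue
        rid = a.residue_id
        residue_sasa[rid] = residue_sasa.get(rid, 0.0) + float(s)
        side_chain.setdefault(rid, 0.0)
        if a.name not in BACKBONE_NAMES:
            side_chain[rid] += float(s)
    return SasaResult(atom_sasa=atom_sasa, residue_sasa=residue_sasa,
                      side_chain_sasa=side_chain,
                      structure_total=float(atom_sasa.sum()))


def is_core_residue(structure: Structure, chain: str, residue_seq: int,
                    sasa: SasaResult | None = None) -> bool:
    """Core = side-chain SASA strictly below 10 Å² (probe 1.4 Å).

    Glycine has no side-chain atoms; its Cα SASA is used as the proxy so that
    exposed glycines are not spuriously classified as core.
    """
    res = structure.get_residue(chain, residue_seq)
    if sasa is None:
        sasa = compute_sasa(structure)
    rid = res.atoms[0].residue_id
    if res.residue_name == "GLY" or not res.side_chain_atoms:
        idx = [i for i, a in enumerate(structure.atoms)
               if a.residue_id == rid and a.name == "CA"]
        value = float(sasa.atom_sasa[idx].sum()) if idx else 0.0
    else:
        value = sasa.side_chain_sasa[rid]
    return value < CORE_SASA_CUTOFF


def interface_residues(structure: Structure, chain_a: str, chain_b: str) -> dict:
    """Residues with any atom within 5 Å of any atom of the opposite chain.

    Returns ``{chain_a: set of (residue_seq, insertion_code), chain_b: ...}``.
    """
    for c in (chain_a, chain_b):
        if c not in structure.chains:
            raise KeyError(f"chain {c!r} not in structure {structure.id!r}")
    ats = structure.atoms
    coords = structure.coords()
    ia = np.array([a.chain_id == chain_a and not a.is_hetero for a in ats])
    ib = np.array([a.chain_id == chain_b and not a.is_hetero for a in ats])
    ai, bi = np.where(ia)[0], np.where(ib)[0]
    out = {chain_a: set(), chain_b: set()}
    if ai.size and bi.size:
        d = np.linalg.norm(coords[ai][:, None, :] - coords[bi][None, :, :], axis=2)
        close = d <= INTERFACE_CUTOFF
        for k in np.where(close.any(axis=1))[0]:
            a = ats[ai[k]]
            out[chain_a].add((a.residue_seq, a.insertion_code))
        for k in np.where(close.any(axis=0))[0]:
            a = ats[bi[k]]
            out[chain_b].add((a.residue_seq, a.insertion_code))
    return out


@dataclass(frozen=True)
class InterfaceDescriptor:
    interface_sasa_total: float
    interface_sasa_hydrophobic: float
    interface_sasa_hydrophilic: float
    interface_residues: dict


def _chain_only(structure: Structure, chain: str) -> Structure:
    atoms = [a for a in structure.atoms if a.chain_id == chain and not a.is_hetero]
    return Structure(id=f"{structure.id}_{chain}", atoms=atoms)


def interface_sasa(structure: Structure, chain_a: str, chain_b: str,
                   probe: float = 1.4, n_points: int = 960) -> InterfaceDescriptor:
    """Buried interface area: protomer SASA sum minus complex SASA.

    The hydrophobic part is the burial summed over carbon atoms, the
    hydrophilic part over N/O/S atoms.  Values are clipped at zero.
    """
    for c in (chain_a, chain_b):
        if c not in structure.chains:
            raise KeyError(f"chain {c!r} not in structure {structure.id!r}")
    sub = Structure(id=structure.id, atoms=[
        a for a in structure.atoms
        if a.chain_id in (chain_a, chain_b) and not a.is_hetero])
    sa = compute_sasa(_chain_only(structure, chain_a), probe, n_points)
    sb = compute_sasa(_chain_only(structure, chain_b), probe, n_points)
    sc = compute_sasa(sub, probe, n_points)
    iso = np.concatenate([sa.atom_sasa, sb.atom_sasa])
    burial = iso - sc.atom_sasa
    carbon = np.array([a.element == "C" for a in sub.atoms])
    total = max(0.0, float(burial.sum()))
    return InterfaceDescriptor(
        interface_sasa_total=total,
        interface_sasa_hydrophobic=max(0.0, float(burial[carbon].sum())),
        interface_sasa_hydrophilic=max(0.0, float(burial[~carbon].sum())),
        interface_residues=interface_residues(structure, chain_a, chain_b),
    )


# ---------------------------------------------------------------------------
# Mutation records and context classification
# ---------------------------------------------------------------------------

@dataclass
class MutationRecord:
    dataset_id: str
    structure_id: str
    chain: str
    residue_seq: int
    wt_aa: str
    mut_aa: str
    ddg_exp: float | None = None
    family: str | None = None
    context: str | None = None   # core | interface | surface

    def __post_init__(self) -> None:
        if self.wt_aa not in STANDARD_AA or self.mut_aa not in STANDARD_AA:
            raise ValueError(f"nonstandard amino acid in {self.wt_aa}->{self.mut_aa}")
        if self.wt_aa == self.mut_aa:
            raise ValueError("wild-type and mutant amino acids must differ")


def classify_mutation_context(wt: Structure, mutation: MutationRecord,
                              partner_chain: str | None = None,
                              sasa: SasaResult | None = None) -> str:
    """core / interface / surface for one mutation.

    Interface takes precedence over core: a buried residue within 5 Å of the
    partner chain is trained with the interface model.
    """
    res = wt.get_residue(mutation.chain, mutation.residue_seq)
    if AA3TO1.get(res.residue_name) != mutation.wt_aa:
        raise ValueError(
            f"wild-type mismatch at {mutation.chain}{mutation.residue_seq}: "
            f"structure has {res.residue_name}, table says {mutation.wt_aa}")
    if partner_chain is not None:
        iface = interface_residues(wt, mutation.chain, partner_chain)
        if (mutation.residue_seq, res.insertion_code) in iface[mutation.chain]:
            return "interface"
    if is_core_residue(wt, mutation.chain, mutation.residue_seq, sasa=sasa):
        return "core"
    return "surface"


# ---------------------------------------------------------------------------
# Sequence features
# ---------------------------------------------------------------------------

_BLOSUM80 = None


def blosum80_score(wt_aa: str, mut_aa: str) -> int:
    """BLOSUM80 substitution score (1/3-bit units) for an amino-acid pair."""
    global _BLOSUM80
    for aa in (wt_aa, mut_aa):
        if aa not in STANDARD_AA:
            raise ValueError(f"{aa!r} is not a standard amino acid code")
    if _BLOSUM80 is None:
        from Bio.Align import substitution_matrices
        _BLOSUM80 = substitution_matrices.load("BLOSUM80")
    return int(_BLOSUM80[wt_aa, mut_aa])


def conservation_score(alignment, column: int, mut_aa: str,
                       pseudocount: float = 1.0) -> float:
    """SIFT-like conservation: smoothed frequency of ``mut_aa`` at a column,
    normalized by the column's most frequent residue.

    ``alignment`` is a list of equal-length aligned sequences (or any object
    with that iteration behaviour); gap characters ``-``/``.`` are excluded
    from counts.  Returns a value in [0, 1]; 1 means the mutant amino acid is
    (one of) the most frequent at that position.
    """
    seqs = [str(s) for s in alignment]
    if not seqs:
        raise ValueError("empty alignment")
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("alignment sequences differ in length")
    if not 0 <= column < length:
        raise ValueError(f"column {column} outside alignment of length {length}")
    if mut_aa not in STANDARD_AA:
        raise ValueError(f"{mut_aa!r} is not a standard amino acid code")
    col = [s[column].upper() for s in seqs if s[column] not in "-."]
    if not col:
        raise ValueError(f"column {column} is all gaps")
    n = len(col)
    denom = n + 20.0 * pseudocount
    freqs = {aa: (col.count(aa) + pseudocount) / denom for aa in STANDARD_AA}
    return freqs[mut_aa] / max(freqs.values())


# ---------------------------------------------------------------------------
# Feature registry and vector assembly
# ---------------------------------------------------------------------------

_CONTACT_FIELDS = ("hydrophobic_intra", "hydrophilic_intra", "electrostatic_intra",
                   "hydrophobic_inter", "hydrophilic_inter", "electrostatic_inter")

_SEQ_FEATURES = ("domain_length", "blosum80", "conservation")
_IFACE_FEATURES = ("if_sasa_total_wt", "if_sasa_hydrophobic_wt",
                   "if_sasa_hydrophilic_wt", "if_sasa_total_mut",
                   "d_if_sasa_total")


def feature_registry(energy_terms) -> list[str]:
    """Fixed feature order: sequence, molecular, interface-only, energy.

    ``energy_terms`` is the ordered list of energy-term names; each term
    contributes wt, mut, and difference features, plus the total-energy
    difference ``ddg_energy``.  ``is_interface`` is the mask-companion
    indicator for the interface-only block.
    """
    names: list[str] = list(_SEQ_FEATURES)
    for v in ("wt", "mut"):
        names += [f"{v}_contacts_{f}" for f in _CONTACT_FIELDS]
    names += [f"d_contacts_{f}" for f in _CONTACT_FIELDS]
    names += ["d_contacts_hydrophobic_total"]
    names += ["wt_residue_sasa", "wt_sidechain_sasa",
              "mut_residue_sasa", "mut_sidechain_sasa",
              "d_residue_sasa", "d_sidechain_sasa"]
    names += ["is_interface"]
    names += list(_IFACE_FEATURES)
    for v in ("wt", "mut"):
        names += [f"{v}_{t}" for t in energy_terms]
    # the dG difference is the ΔΔG feature itself; listing it once keeps the
    # registry free of exact duplicates
    names += [f"d_{t}" for t in energy_terms if t != "dG"]
    names += ["ddg_energy"]
    return names


@dataclass
class FeatureVector:
    """Ordered mapping of descriptor name → value with an interface mask."""

    names: list[str]
    values: np.ndarray
    masked: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return dict(zip(self.names, self.values.tolist()))

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])


def build_feature_vector(wt: Structure, mut: Structure, mutation: MutationRecord,
                         energy_wt, energy_mut,
                         conservation: float | None = None,
                         alignment_length: int | None = None,
                         partner_chain: str | None = None,
                         wt_sasa: SasaResult | None = None,
                         wt_contacts: ContactCounts | None = None,
                         wt_interface: InterfaceDescriptor | None = None,
                         sasa_n_points: int = 240) -> FeatureVector:
    """Assemble the fixed-order descriptor vector for one mutation.

    ``mutation.context`` must already be set.  Interface-only descriptors are
    masked (value 0, ``is_interface`` = 0, listed in ``masked``) for core and
    surface mutations.  Precomputed wild-type results can be passed to avoid
    recomputation when many mutations share a structure.
    """
    if mutation.context not in ("core", "interface", "surface"):
        raise ValueError("mutation.context must be classified before featurizing")
    if list(energy_wt.terms) != list(energy_mut.terms):
        raise ValueError("energy term registries differ between wt and mut")

    term_names = list(energy_wt.terms)
    names = feature_registry(term_names)
    vals: dict[str, float] = {}

    chain, seq = mutation.chain, mutation.residue_seq
    vals["domain_length"] = float(alignment_length if alignment_length
                                  else len(wt.sequence(chain)))
    vals["blosum80"] = float(blosum80_score(mutation.wt_aa, mutation.mut_aa))
    vals["conservation"] = float(conservation if conservation is not None else 0.5)

    cc_wt = wt_contacts if wt_contacts is not None else count_contacts(wt, chain, seq)
    cc_mut = count_contacts(mut, chain, seq)
    for f in _CONTACT_FIELDS:
        vals[f"wt_contacts_{f}"] = float(getattr(cc_wt, f))
        vals[f"mut_contacts_{f}"] = float(getattr(cc_mut, f))
        vals[f"d_contacts_{f}"] = float(getattr(cc_mut, f) - getattr(cc_wt, f))
    vals["d_contacts_hydrophobic_total"] = (
        vals["d_contacts_hydrophobic_intra"] + vals["d_contacts_hydrophobic_inter"])

    s_wt = wt_sasa if wt_sasa is not None else compute_sasa(wt, n_points=sasa_n_points)
    s_mut = compute_sasa(mut, n_points=sasa_n_points)
    rid = wt.get_residue(chain, seq).atoms[0].residue_id
    vals["wt_residue_sasa"] = s_wt.residue_sasa[rid]
    vals["wt_sidechain_sasa"] = s_wt.side_chain_sasa[rid]
    vals["mut_residue_sasa"] = s_mut.residue_sasa[rid]
    vals["mut_sidechain_sasa"] = s_mut.side_chain_sasa[rid]
    vals["d_residue_sasa"] = vals["mut_residue_sasa"] - vals["wt_residue_sasa"]
    vals["d_sidechain_sasa"] = vals["mut_sidechain_sasa"] - vals["wt_sidechain_sasa"]

    masked: list[str] = []
    if mutation.context == "interface" and partner_chain is not None:
        vals["is_interface"] = 1.0
        iw = wt_interface if wt_interface is not None else \
            interface_sasa(wt, chain, partner_chain, n_points=sasa_n_points)
        im = interface_sasa(mut, chain, partner_chain, n_points=sasa_n_points)
        vals["if_sasa_total_wt"] = iw.interface_sasa_total
        vals["if_sasa_hydrophobic_wt"] = iw.interface_sasa_hydrophobic
        vals["if_sasa_hydrophilic_wt"] = iw.interface_sasa_hydrophilic
        vals["if_sasa_total_mut"] = im.interface_sasa_total
        vals["d_if_sasa_total"] = im.interface_sasa_total - iw.interface_sasa_total
    else:
        vals["is_interface"] = 0.0
        for f in _IFACE_FEATURES:
            vals[f] = 0.0
            masked.append(f)

    for t in term_names:
        vals[f"wt_{t}"] = float(energy_wt.terms[t])
        vals[f"mut_{t}"] = float(energy_mut.terms[t])
        if t != "dG":
            vals[f"d_{t}"] = float(energy_mut.terms[t] - energy_wt.terms[t])
    vals["ddg_energy"] = float(energy_mut.total - energy_wt.total)

    arr = np.array([vals[n] for n in names], dtype=float)
    active = np.array([n not in masked for n in names])
    if not np.isfinite(arr[active]).all():
        raise ValueError("non-finite value among active features")
    return FeatureVector(names=names, values=arr, masked=masked)


# ---------------------------------------------------------------------------
# Feature-table I/O (TSV; masked features written as NA)
# ---------------------------------------------------------------------------

_META_COLS = ("dataset_id", "structure_id", "chain", "position", "wt_aa",
              "mut_aa", "context", "family", "ddg_exp")


def write_feature_table(path, vectors: list[FeatureVector],
                        mutations: list[MutationRecord]) -> None:
    """One row per mutation: metadata columns, then the feature registry."""
    if len(vectors) != len(mutations):
        raise ValueError("one feature vector per mutation required")
    if not vectors:
        raise ValueError("nothing to write")
    names = vectors[0].names
    with open(path, "w") as fh:
        fh.write("\t".join(list(_META_COLS) + names) + "\n")
        for fv, m in zip(vectors, mutations):
            if fv.names != names:
                raise ValueError("inconsistent feature registries across rows")
            meta = [m.dataset_id, m.structure_id, m.chain, str(m.residue_seq),
                    m.wt_aa, m.mut_aa, m.context or "",
                    m.family or "", "" if m.ddg_exp is None else repr(m.ddg_exp)]
            vals = ["NA" if n in fv.masked else repr(v)
                    for n, v in zip(names, fv.values.tolist())]
            fh.write("\t".join(meta + vals) + "\n")


def read_feature_table(path):
    """Read a feature TSV.  Returns (X, feature_names, mutations, y) where
    masked ``NA`` cells become 0 (the ``is_interface`` indicator preserves the
    mask) and ``y`` is None when no experimental ΔΔG column is populated."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"chain": str})
    names = [c for c in df.columns if c not in _META_COLS]
    X = df[names].replace("NA", np.nan).astype(float).fillna(0.0).to_numpy()
    mutations = []
    for _, row in df.iterrows():
        mutations.append(MutationRecord(
            dataset_id=str(row["dataset_id"]),
            structure_id=str(row["structure_id"]),
            chain=str(row["chain"]),
            residue_seq=int(row["position"]),
            wt_aa=str(row["wt_aa"]),
            mut_aa=str(row["mut_aa"]),
            ddg_exp=None if pd.isna(row["ddg_exp"]) else float(row["ddg_exp"]),
            family=None if pd.isna(row["family"]) or row["family"] == ""
            else str(row["family"]),
            context=None if pd.isna(row["context"]) or row["context"] == ""
            else str(row["context"]),
        ))
    y = None
    if df["ddg_exp"].notna().all():
        y = df["ddg_exp"].astype(float).to_numpy()
    return X, names, mutations, y
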