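"""Per-structure energy terms via a pluggable backend.

Two backends share one term vocabulary (torsional, disulfide, electrostatics,
hydrogen bonds, van der Waals, clashes, solvation, ...):

* :func:`simplified_stability` / :func:`simplified_binding` — a dependency-free
  empirical potential computed from geometry alone (contact counts, clash
  detection and buried surface areas).  It produces kcal/mol-scale numbers and
  is deterministic and rigid-motion invariant, but it makes no claim of
  physical accuracy; it exists so the full pipeline runs end-to-end without an
  external force field.
* :func:`read_energy_table` — an adapter ingesting externally computed per-term
  tables (e.g. from a licensed empirical force field) in TSV form, so that
  real energy features drop in unchanged.

Sign convention: lower (more negative) total ΔG = more stable; ΔΔG =
ΔG(mutant) − ΔG(wild type), positive = destabilizing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .features import (
    POLAR_CUTOFF,
    HYDROPHOBIC_CUTOFF,
    _atom_flags,
    _atom_radius,
)
from .structures import Structure

__all__ = [
    "ENERGY_TERM_NAMES",
    "EnergyTerms",
    "EnergyWeights",
    "simplified_stability",
    "simplified_binding",
    "ddg",
    "read_energy_table",
    "write_energy_table",
]

# Canonical term vocabulary (abbreviations as used in empirical force fields):
# t torsional, diS disulfide, E electrostatics, ion ionization, dS_mc/dS_sc
# main/side-chain entropy, Hdipole helix dipole, cb covalent bond, sb salt
# bridge, hb hydrogen bond, cisb cysteine bond, wb water bridge, vdW van der
# Waals, clashes steric clashes, solv_ap/solv_po apolar/polar solvation,
# dG total.
ENERGY_TERM_NAMES = (
    "t", "diS", "E", "ion", "dS_mc", "dS_sc", "Hdipole", "cb", "sb", "hb",
    "cisb", "wb", "vdW", "clashes", "solv_ap", "solv_po", "dG",
)


@dataclass
class EnergyTerms:
    """Ordered term-name → kcal/mol mapping; ``dG`` holds the total."""

    terms: dict[str, float]

    def __post_init__(self) -> None:
        if "dG" not in self.terms:
            raise ValueError("energy terms must include the total 'dG'")
        for k, v in self.terms.items():
            if not math.isfinite(v):
                raise ValueError(f"non-finite energy term {k}={v}")

    @property
    def total(self) -> float:
        return self.terms["dG"]

    def same_registry(self, other: "EnergyTerms") -> bool:
        return list(self.terms) == list(other.terms)


@dataclass(frozen=True)
class EnergyWeights:
    """Fixed default weights giving kcal/mol-scale outputs.

    vdw: per hydrophobic contact (favorable); hb: per donor–acceptor pair
    ≤ 4 Å; elec_opp / elec_like: per opposite-/like-charge pair ≤ 4 Å;
    clash: per non-bonded heavy-atom pair closer than 0.6·(r₁+r₂);
    solv_ap / solv_po: kcal/mol per Å² of buried apolar / polar area.
    """

    vdw: float = 0.10
    hb: float = 0.60
    elec_opp: float = 1.00
    elec_like: float = 0.50
    clash: float = 4.00
    solv_ap: float = 0.025
    solv_po: float = 0.010


DEFAULT_WEIGHTS = EnergyWeights()


def _pair_counts(structure: Structure):
    """Unique inter-residue atom-pair counts by contact class, plus clashes."""
    ats = structure.atoms
    n = len(ats)
    coords = structure.coords()
    pos, neg, don, acc, carbon = _atom_flags(structure)
    rid = {}
    res_index = np.empty(n, dtype=int)
    for i, a in enumerate(ats):
        key = (a.is_hetero,) + a.residue_id
        res_index[i] = rid.setdefault(key, len(rid))
    radii = np.array([_atom_radius(a) for a in ats])
    heavy = np.array([a.element != "H" for a in ats])

    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
    upper = np.triu(np.ones((n, n), dtype=bool), k=1)
    diff_res = res_index[:, None] != res_index[None, :]
    pair_ok = upper & diff_res

    elec_opp = (np.outer(pos, neg) | np.outer(neg, pos)) & (d <= POLAR_CUTOFF) & pair_ok
    elec_like = (np.outer(pos, pos) | np.outer(neg, neg)) & (d <= POLAR_CUTOFF) \
        & pair_ok & ~np.eye(n, dtype=bool)
    philic = (np.outer(don, acc) | np.outer(acc, don)) & (d <= POLAR_CUTOFF) \
        & pair_ok & ~elec_opp
    phobic = np.outer(carbon, carbon) & (d <= HYDROPHOBIC_CUTOFF) \
        & pair_ok & ~elec_opp & ~philic

    # bonded = same residue (already excluded) or the sequential backbone
    # C(i)–N(i+1) link and its 1-3 partners; approximate by exempting
    # backbone-atom pairs of residues adjacent in author numbering.
    bb = np.array([a.name in ("N", "CA", "C", "O", "OXT") for a in ats])
    seq = np.array([a.residue_seq for a in ats])
    chain_code = np.array([hash(a.chain_id) for a in ats])
    same_chain = chain_code[:, None] == chain_code[None, :]
    adjacent = same_chain & (np.abs(seq[:, None] - seq[None, :]) == 1)
    bonded_adj = adjacent & np.outer(bb, bb)
    clash = pair_ok & np.outer(heavy, heavy) & ~bonded_adj \
        & (d < 0.6 * (radii[:, None] + radii[None, :]))

    return {
        "hydrophobic": int(phobic.sum()),
        "hydrophilic": int(philic.sum()),
        "elec_opp": int(elec_opp.sum()),
        "elec_like": int((elec_like & upper).sum()),
        "clashes": int(clash.sum()),
    }


def _buried_areas(structure: Structure, n_points: int):
    """Apolar (carbon) and polar (N/O/S) area buried relative to free atoms."""
    from .features import compute_sasa

    sasa = compute_sasa(structure, n_points=n_points)
    radii = np.array([_atom_radius(a) for a in structure.atoms]) + 1.4
    iso = 4.0 * math.pi * radii ** 2
    burial = iso - sasa.atom_sasa
    carbon = np.array([a.element == "C" for a in structure.atoms])
    return float(burial[carbon].sum()), float(burial[~carbon].sum())


def simplified_stability(structure: Structure,
                         weights: EnergyWeights = DEFAULT_WEIGHTS,
                         sasa_n_points: int = 240) -> EnergyTerms:
    """Geometry-derived stability energy over the canonical term registry.

    vdW = −w·(hydrophobic contacts); hb = −w·(donor–acceptor pairs ≤ 4 Å);
    E = −w·(opposite-charge pairs) + w'·(like-charge pairs); clashes =
    +w·(severe steric overlaps); solv_ap = −w·(buried apolar area);
    solv_po = +w·(buried polar area).  Terms with no geometric stand-in are 0;
    ``dG`` is the sum.
    """
    if not structure.atoms:
        raise ValueError("empty structure")
    counts = _pair_counts(structure)
    ap, po = _buried_areas(structure, sasa_n_points)
    terms = {name: 0.0 for name in ENERGY_TERM_NAMES}
    terms["vdW"] = -weights.vdw * counts["hydrophobic"]
    terms["hb"] = -weights.hb * counts["hydrophilic"]
    terms["E"] = (-weights.elec_opp * counts["elec_opp"]
                  + weights.elec_like * counts["elec_like"])
    terms["clashes"] = weights.clash * counts["clashes"]
    terms["solv_ap"] = -weights.solv_ap * ap
    terms["solv_po"] = weights.solv_po * po
    terms["dG"] = sum(v for k, v in terms.items() if k != "dG")
    return EnergyTerms(terms=terms)


def simplified_binding(structure: Structure, chain_a: str, chain_b: str,
                       weights: EnergyWeights = DEFAULT_WEIGHTS,
                       sasa_n_points: int = 240) -> EnergyTerms:
    """Binding energy: terms(complex) − terms(A alone) − terms(B alone)."""
    for c in (chain_a, chain_b):
        if c not in structure.chains:
            raise KeyError(f"chain {c!r} not in structure {structure.id!r}")
    sub = Structure(id=structure.id, atoms=[
        a for a in structure.atoms
        if a.chain_id in (chain_a, chain_b) and not a.is_hetero])
    only_a = Structure(id=f"{structure.id}_{chain_a}", atoms=[
        a for a in sub.atoms if a.chain_id == chain_a])
    only_b = Structure(id=f"{structure.id}_{chain_b}", atoms=[
        a for a in sub.atoms if a.chain_id == chain_b])
    e_ab = simplified_stability(sub, weights, sasa_n_points)
    e_a = simplified_stability(only_a, weights, sasa_n_points)
    e_b = simplified_stability(only_b, weights, sasa_n_points)
    terms = {k: e_ab.terms[k] - e_a.terms[k] - e_b.terms[k]
             for k in ENERGY_TERM_NAMES if k != "dG"}
    terms["dG"] = sum(terms.values())
    # restore canonical order
    ordered = {name: terms[name] for name in ENERGY_TERM_NAMES}
    return EnergyTerms(terms=ordered)


def ddg(wt: EnergyTerms, mut: EnergyTerms) -> float:
    """ΔΔG = ΔG(mutant) − ΔG(wild type), kcal/mol."""
    if not wt.same_registry(mut):
        raise ValueError("energy term registries differ")
    return mut.total - wt.total


def read_energy_table(path) -> dict:
    """Read a TSV of per-term energies: columns ``id``, ``variant`` (wt|mut),
    then one column per term name.  Returns id → (wt EnergyTerms, mut
    EnergyTerms); both variants are required for every id."""
    import csv

    rows: dict[str, dict[str, EnergyTerms]] = {}
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or \
                reader.fieldnames[:2] != ["id", "variant"]:
            raise ValueError(f"{path}: expected columns id, variant, <terms>")
        term_cols = reader.fieldnames[2:]
        for line in reader:
            variant = line["variant"]
            if variant not in ("wt", "mut"):
                raise ValueError(f"{path}: bad variant {variant!r}")
            try:
                terms = {t: float(line[t]) for t in term_cols}
            except (TypeError, ValueError):
                raise ValueError(f"{path}: non-numeric energy value in row "
                                 f"{line['id']}/{variant}")
            rows.setdefault(line["id"], {})[variant] = EnergyTerms(terms=terms)
    out = {}
    for mid, pair in rows.items():
        if set(pair) != {"wt", "mut"}:
            raise ValueError(f"{path}: id {mid!r} lacks a "
                             f"{'mut' if 'wt' in pair else 'wt'} row")
        out[mid] = (pair["wt"], pair["mut"])
    return out


def write_energy_table(pairs: dict, path) -> None:
    """Inverse of :func:`read_energy_table`."""
    first = next(iter(pairs.values()))
    term_cols = list(first[0].terms)
    with open(path, "w") as fh:
        fh.write("\t".join(["id", "variant"] + term_cols) + "\n")
        for mid, (wt, mut) in pairs.items():
            for variant, et in (("wt", wt), ("mut", mut)):
                vals = "\t".join(repr(et.terms[t]) for t in term_cols)
                fh.write(f"{mid}\t{variant}\t{vals}\n")
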