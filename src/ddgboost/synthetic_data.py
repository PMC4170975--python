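"""Self-contained synthetic datasets for end-to-end pipeline testing.

Generates families of toy proteins (α-helical monomers and two-chain
dimers), point-mutation sets over them, descriptor vectors computed by the
real feature/energy modules, and ground-truth ΔΔG values produced by a known
nonlinear function of a few designated informative features plus Gaussian
noise.  Because the target-generating function is known, recovery of the
signal (held-out correlation, importance ranking of the informative
features) is a checkable property of the whole pipeline.

The generator deliberately embeds sequence redundancy: a configurable
fraction of the proteins in each family are ≥ 90 % identical to another
family member, which the curation stage must detect and collapse.

What this emulates — and what it does not: the statistical shape of a
ΔΔG training table (family structure, redundancy, mixed core/interface
contexts, noisy targets), not the thermodynamics of real proteins.  Toy
helices with single-pseudo-atom side chains are too loosely packed for any
residue to pass the strict side-chain-SASA < 10 Å² core test, so monomer
mutations are sampled over all residues (classified core/surface as they
fall) while dimer mutations are sampled over interface residues.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .energy import EnergyTerms, simplified_binding, simplified_stability
from .features import (
    FeatureVector,
    MutationRecord,
    build_feature_vector,
    classify_mutation_context,
    compute_sasa,
    conservation_score,
    count_contacts,
    interface_residues,
    interface_sasa,
)
from .structures import (
    AA3TO1,
    STANDARD_AA,
    Structure,
    make_toy_complex,
    make_toy_fold,
)

__all__ = [
    "SyntheticSpec",
    "SyntheticProtein",
    "generate_structures",
    "generate_training_table",
    "default_effect_function",
]

_AAS = sorted(STANDARD_AA)


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for the synthetic benchmark.

    Defaults give ≈ 2000 mutations (5 families × 4 proteins × 100 mutations)
    with kcal/mol-scale targets and noise σ = 0.5 kcal/mol; half of the
    proteins in each family are near-duplicates (≥ 90 % identity) of a family
    mate, exercising the redundancy-reduction stage.
    """

    seed: int = 0
    n_families: int = 5
    proteins_per_family: int = 4
    mutations_per_protein: int = 100
    noise_sigma: float = 0.5
    redundancy_fraction: float = 0.5
    monomer_length: int = 24
    dimer_chain_length: int = 14
    dimer_gap: float = 3.0
    sasa_n_points: int = 144
    informative_features: tuple[str, ...] = (
        "ddg_energy", "d_contacts_hydrophobic_intra", "conservation")

    def __post_init__(self) -> None:
        if self.n_families < 2:
            raise ValueError("need at least 2 families (family CV requires it)")
        if self.proteins_per_family < 1 or self.mutations_per_protein < 1:
            raise ValueError("counts must be positive")
        if not 0.0 <= self.redundancy_fraction < 1.0:
            raise ValueError("redundancy_fraction must be in [0, 1)")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass
class SyntheticProtein:
    protein_id: str
    family: str
    kind: str                      # monomer | dimer
    structure: Structure
    sequences: tuple[str, ...]     # one per chain


def _mutate_sequence(rng, seq: str, n_changes: int) -> str:
    pos = rng.choice(len(seq), size=min(n_changes, len(seq)), replace=False)
    out = list(seq)
    for p in pos:
        choices = [a for a in _AAS if a != out[p]]
        out[p] = choices[rng.integers(len(choices))]
    return "".join(out)


def generate_structures(spec: SyntheticSpec) -> list[SyntheticProtein]:
    """Family-labelled toy proteins, deterministic per seed.

    Families alternate monomer/dimer.  The first protein of a family is the
    founder; each later protein derives from a random earlier family member,
    with probability ``redundancy_fraction`` as a near-duplicate (≤ 8 %
    of positions substituted, hence ≥ 90 % identity) and otherwise as a
    diverged relative (≈ 35 % substituted).
    """
    rng = np.random.default_rng(spec.seed)
    proteins: list[SyntheticProtein] = []
    for f in range(spec.n_families):
        fam = f"fam{f}"
        kind = "monomer" if f % 2 == 0 else "dimer"
        n_chains = 1 if kind == "monomer" else 2
        length = spec.monomer_length if kind == "monomer" else spec.dimer_chain_length
        member_seqs: list[tuple[str, ...]] = []
        for p in range(spec.proteins_per_family):
            if p == 0:
                seqs = tuple("".join(rng.choice(_AAS) for _ in range(length))
                             for _ in range(n_chains))
            else:
                base = member_seqs[rng.integers(len(member_seqs))]
                if rng.random() < spec.redundancy_fraction:
                    n_changes = max(1, int(0.08 * length))
                else:
                    n_changes = max(2, int(0.35 * length))
                seqs = tuple(_mutate_sequence(rng, s, n_changes) for s in base)
            member_seqs.append(seqs)
            pid = f"{fam}_p{p}"
            sseed = int(rng.integers(0, 2 ** 31 - 1))
            if kind == "monomer":
                structure = make_toy_fold(sseed, length, sequence=seqs[0],
                                          structure_id=pid)
            else:
                structure = make_toy_complex(sseed, length, length,
                                             gap=spec.dimer_gap,
                                             sequence_a=seqs[0],
                                             sequence_b=seqs[1],
                                             structure_id=pid)
            proteins.append(SyntheticProtein(protein_id=pid, family=fam,
                                             kind=kind, structure=structure,
                                             sequences=seqs))
    return proteins


def default_effect_function(z_ddg, z_dhyd, z_cons, is_core):
    """Ground-truth ΔΔG (kcal/mol) from standardized informative features:
    1.5·z(ΔΔG_energy) + 0.8·z(Δ hydrophobic contacts) − 0.6·z(conservation)
    + 0.5·z(ΔΔG_energy) for core-context mutations."""
    return (1.5 * z_ddg + 0.8 * z_dhyd - 0.6 * z_cons
            + 0.5 * z_ddg * is_core)


def _zscore(v: np.ndarray) -> np.ndarray:
    s = v.std()
    if s == 0:
        raise ValueError("informative feature has zero variance in this dataset")
    return (v - v.mean()) / s


def generate_training_table(spec: SyntheticSpec):
    """Full synthetic training table.

    Returns ``(X, y, mutations, feature_names, proteins)``: the feature
    matrix computed by the features+energy modules, noisy ground-truth
    targets, mutation records (family labels filled), the feature registry,
    and the generated proteins.
    """
    proteins = generate_structures(spec)
    rng = np.random.default_rng(spec.seed + 1)
    npts = spec.sasa_n_points

    vectors: list[FeatureVector] = []
    mutations: list[MutationRecord] = []
    for prot in proteins:
        s = prot.structure
        if prot.kind == "dimer":
            partner = "B"
            iface = interface_residues(s, "A", "B")
            eligible = sorted(seq for seq, _ in iface["A"])
            if not eligible:
                raise ValueError(f"{prot.protein_id}: no interface residues")
        else:
            partner = None
            eligible = [r.residue_seq for r in s.residues("A")]
        wt_sasa = compute_sasa(s, n_points=npts)
        if prot.kind == "dimer":
            e_wt = simplified_binding(s, "A", "B", sasa_n_points=npts)
            iface_wt = interface_sasa(s, "A", "B", n_points=npts)
        else:
            e_wt = simplified_stability(s, sasa_n_points=npts)
            iface_wt = None
        wt_contact_cache: dict[int, object] = {}
        fam_seqs = [p.sequences[0] for p in proteins if p.family == prot.family]

        for _ in range(spec.mutations_per_protein):
            pos = int(eligible[rng.integers(len(eligible))])
            wt_aa = AA3TO1[s.get_residue("A", pos).residue_name]
            mut_aa = _AAS[rng.integers(20)]
            while mut_aa == wt_aa:
                mut_aa = _AAS[rng.integers(20)]
            rec = MutationRecord(
                dataset_id=f"{prot.protein_id}_{wt_aa}{pos}{mut_aa}",
                structure_id=prot.protein_id, chain="A", residue_seq=pos,
                wt_aa=wt_aa, mut_aa=mut_aa, family=prot.family)
            rec.context = classify_mutation_context(s, rec, partner, sasa=wt_sasa)
            from .structures import mutate_residue_simple
            mut_s = mutate_residue_simple(s, "A", pos, mut_aa)
            if prot.kind == "dimer":
                e_mut = simplified_binding(mut_s, "A", "B", sasa_n_points=npts)
            else:
                e_mut = simplified_stability(mut_s, sasa_n_points=npts)
            cons = conservation_score(fam_seqs, pos - 1, mut_aa)
            if pos not in wt_contact_cache:
                wt_contact_cache[pos] = count_contacts(s, "A", pos)
            fv = build_feature_vector(
                s, mut_s, rec, e_wt, e_mut,
                conservation=cons, alignment_length=len(prot.sequences[0]),
                partner_chain=partner, wt_sasa=wt_sasa,
                wt_contacts=wt_contact_cache[pos],
                wt_interface=iface_wt, sasa_n_points=npts)
            vectors.append(fv)
            mutations.append(rec)

    names = vectors[0].names
    X = np.array([fv.values for fv in vectors])
    idx = {n: names.index(n) for n in spec.informative_features}
    z_ddg = _zscore(X[:, idx["ddg_energy"]])
    z_dhyd = _zscore(X[:, idx["d_contacts_hydrophobic_intra"]])
    z_cons = _zscore(X[:, idx["conservation"]])
    is_core = np.array([1.0 if m.context == "core" else 0.0 for m in mutations])
    y = default_effect_function(z_ddg, z_dhyd, z_cons, is_core)
    y = y + rng.normal(0.0, spec.noise_sigma, size=len(y))
    for m, v in zip(mutations, y):
        m.ddg_exp = float(v)
    return X, y, mutations, names, proteins
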