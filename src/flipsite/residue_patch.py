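"""Construction of 5-hydroxymethylcytosine (5hmC) force-field parameters.

CHARMM-style parameters exist for 5-methylcytosine (5mC) but not for its
oxidation product 5hmC.  The 5hmC residue is built from the 5mC parameters
by exchanging one methyl hydrogen for a hydroxyl group whose partial
charges (and atom types) are taken from a serine hydroxyl; the residual
charge is redistributed uniformly over the remaining CH2 group (carbon and
its two hydrogens) so that the residue's total charge is exactly
conserved.  The patch is expressed as a :class:`PatchSpec` that can be
applied to an in-memory :class:`~flipsite.structure_io.Topology` or
emitted as a CHARMM-RTF ``PRES`` block.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .errors import StructureError
from .structure_io import (
    ROLE_ACCEPTOR,
    ROLE_DONOR,
    ROLE_HYDROGEN,
    Atom,
    ResidueParameters,
    Topology,
)

#: Default names for the added hydroxyl atoms of the 5hmC residue.
HYDROXYL_O_NAME = "OH5"
HYDROXYL_H_NAME = "HO5"

_CHARGE_TOL = 1e-12


@dataclass(frozen=True)
class AtomTemplate:
    """An atom to be added by a patch: name, CHARMM type, charge, roles."""

    name: str
    type: str
    charge: float
    roles: frozenset = frozenset()


@dataclass
class PatchSpec:
    """A residue modification: deletions, additions, charge shifts, bonds."""

    target_residue_name: str
    deleted_atoms: tuple = ()
    added_atoms: tuple = ()
    charge_adjustments: dict = field(default_factory=dict)
    new_bonds: tuple = ()

    def __post_init__(self):
        added_names = {a.name for a in self.added_atoms}
        for atom in self.added_atoms:
            in_bond = any(
                atom.name in pair for pair in self.new_bonds
            )
            if not in_bond:
                raise StructureError(
                    f"added atom {atom.name!r} participates in no new bond"
                )
        for a, b in self.new_bonds:
            for name in (a, b):
                if name in self.deleted_atoms:
                    raise StructureError(
                        f"new bond ({a}, {b}) references deleted atom {name!r}"
                    )
        del added_names


def _element_of(name: str, atype: str) -> str:
    for candidate in (name, atype):
        stripped = candidate.strip().lstrip("0123456789'")
        if stripped:
            return stripped[0].upper()
    return "X"


def find_methyl_group(residue: ResidueParameters) -> tuple:
    """Locate a methyl group: a carbon bonded to exactly three hydrogens.

    Returns ``(carbon_name, [h1, h2, h3])`` with hydrogens in declaration
    order.  Raises :class:`StructureError` if no methyl group exists.
    """
    for name, atype, _q in residue.atoms:
        if _element_of(name, atype) != "C":
            continue
        hydrogens = [
            nb for nb in residue.neighbor_names(name)
            if _element_of(nb, residue.atom_type(nb)) == "H"
        ]
        if len(hydrogens) == 3:
            ordered = [n for n in residue.atom_names if n in hydrogens]
            return name, ordered
    raise StructureError(
        f"residue {residue.name}: no methyl group (C bonded to 3 H) found"
    )


def find_hydroxyl_group(residue: ResidueParameters) -> tuple:
    """Locate a hydroxyl: an oxygen bonded to exactly one hydrogen.

    Returns ``(oxygen_name, hydrogen_name)``; the first match in
    declaration order wins.
    """
    for name, atype, _q in residue.atoms:
        if _element_of(name, atype) != "O":
            continue
        neighbors = residue.neighbor_names(name)
        hydrogens = [
            nb for nb in neighbors
            if _element_of(nb, residue.atom_type(nb)) == "H"
        ]
        if len(hydrogens) == 1:
            return name, hydrogens[0]
    raise StructureError(
        f"residue {residue.name}: no hydroxyl (O bonded to one H) found"
    )


def build_5hmc_patch(
    mc_residue: ResidueParameters,
    serine_residue: ResidueParameters,
    hydroxyl_o_name: str = HYDROXYL_O_NAME,
    hydroxyl_h_name: str = HYDROXYL_H_NAME,
) -> PatchSpec:
    """Build the 5mC -> 5hmC patch by methyl-H -> hydroxyl substitution.

    The first methyl hydrogen (declaration order) is deleted; an O-H pair
    is added bonded as C-O-H, with charges and atom types copied verbatim
    from the serine hydroxyl; the carbon and the two remaining hydrogens
    each receive one third of the residual charge so the residue's net
    charge is unchanged (asserted to 1e-12 e).
    """
    c_name, (h_del, h_keep1, h_keep2) = find_methyl_group(mc_residue)
    ser_o, ser_h = find_hydroxyl_group(serine_residue)

    q_c = mc_residue.atom_charge(c_name)
    q_hdel = mc_residue.atom_charge(h_del)
    q_h1 = mc_residue.atom_charge(h_keep1)
    q_h2 = mc_residue.atom_charge(h_keep2)
    q_o = serine_residue.atom_charge(ser_o)
    q_oh = serine_residue.atom_charge(ser_h)

    # Uniform shift over the CH2 group restoring the original group charge.
    shift = (q_hdel - q_o - q_oh) / 3.0

    patch = PatchSpec(
        target_residue_name=mc_residue.name,
        deleted_atoms=(h_del,),
        added_atoms=(
            AtomTemplate(
                name=hydroxyl_o_name,
                type=serine_residue.atom_type(ser_o),
                charge=q_o,
                roles=frozenset({ROLE_DONOR, ROLE_ACCEPTOR}),
            ),
            AtomTemplate(
                name=hydroxyl_h_name,
                type=serine_residue.atom_type(ser_h),
                charge=q_oh,
                roles=frozenset({ROLE_HYDROGEN}),
            ),
        ),
        charge_adjustments={
            c_name: q_c + shift,
            h_keep1: q_h1 + shift,
            h_keep2: q_h2 + shift,
        },
        new_bonds=(
            (c_name, hydroxyl_o_name),
            (hydroxyl_o_name, hydroxyl_h_name),
        ),
    )

    old_group = q_c + q_hdel + q_h1 + q_h2
    new_group = (
        patch.charge_adjustments[c_name]
        + patch.charge_adjustments[h_keep1]
        + patch.charge_adjustments[h_keep2]
        + q_o + q_oh
    )
    if abs(new_group - old_group) > _CHARGE_TOL:
        raise StructureError(
            f"patch charge imbalance {new_group - old_group:.3e} e"
        )
    return patch


def patched_residue_parameters(
    mc_residue: ResidueParameters,
    patch: PatchSpec,
    name: str = "5HMC",
) -> ResidueParameters:
    """Apply *patch* at the parameter level, yielding the 5hmC residue table."""
    if mc_residue.name != patch.target_residue_name:
        raise StructureError(
            f"patch targets {patch.target_residue_name!r}, "
            f"got residue {mc_residue.name!r}"
        )
    for del_name in patch.deleted_atoms:
        if del_name not in mc_residue.atom_names:
            raise StructureError(
                f"residue {mc_residue.name}: atom {del_name!r} to delete "
                f"is not present (patch already applied?)"
            )
    atoms = []
    for n, t, q in mc_residue.atoms:
        if n in patch.deleted_atoms:
            continue
        if n in patch.charge_adjustments:
            q = patch.charge_adjustments[n]
        atoms.append((n, t, q))
    atoms.extend((a.name, a.type, a.charge) for a in patch.added_atoms)
    bonds = [
        (a, b) for a, b in mc_residue.bonds
        if a not in patch.deleted_atoms and b not in patch.deleted_atoms
    ]
    bonds.extend(patch.new_bonds)
    donors = list(mc_residue.donors)
    acceptors = list(mc_residue.acceptors)
    for tmpl in patch.added_atoms:
        if ROLE_ACCEPTOR in tmpl.roles:
            acceptors.append(tmpl.name)
    for tmpl in patch.added_atoms:
        if ROLE_DONOR in tmpl.roles:
            hyd = next(
                (
                    t.name for t in patch.added_atoms
                    if ROLE_HYDROGEN in t.roles
                    and any(set(p) == {tmpl.name, t.name} for p in patch.new_bonds)
                ),
                None,
            )
            donors.append((hyd, tmpl.name))
    return ResidueParameters(
        name=name, atoms=atoms, bonds=bonds, donors=donors, acceptors=acceptors
    )


def apply_patch(
    topology: Topology,
    residue: tuple,
    patch: PatchSpec,
) -> Topology:
    """Apply *patch* to the residue ``(chain, residue_id)`` of *topology*.

    Added atoms are appended at the end of the residue's atom block;
    untouched residues keep their atoms field-for-field (indices may shift
    to keep them consistent with list positions).  Deleting an atom with
    more than one covalent bond, or a patch addressed to a residue that
    does not match the target name, is an error.
    """
    chain, residue_id = residue
    res = topology.residue(chain, residue_id)  # raises if absent
    if res.residue_name != patch.target_residue_name:
        raise StructureError(
            f"residue {chain}:{residue_id} is {res.residue_name!r}, patch "
            f"targets {patch.target_residue_name!r}"
        )
    name_to_index = {topology.atoms[i].name: i for i in res.atom_indices}
    for del_name in patch.deleted_atoms:
        if del_name not in name_to_index:
            raise StructureError(
                f"residue {chain}:{residue_id}: atom {del_name!r} to delete "
                f"is not present (patch already applied?)"
            )
        bonded = topology.neighbors(name_to_index[del_name])
        if len(bonded) > 1:
            raise StructureError(
                f"deleting {del_name!r} would leave dangling bonds "
                f"({len(bonded)} partners)"
            )
    for adj_name in patch.charge_adjustments:
        if adj_name not in name_to_index:
            raise StructureError(
                f"residue {chain}:{residue_id}: no atom {adj_name!r} "
                f"for charge adjustment"
            )
    for a, b in patch.new_bonds:
        for end in (a, b):
            if end not in name_to_index and \
                    end not in {t.name for t in patch.added_atoms}:
                raise StructureError(
                    f"new bond ({a}, {b}): atom {end!r} unknown (dangling)"
                )

    deleted_indices = {name_to_index[n] for n in patch.deleted_atoms}
    last_kept = max(
        (i for i in res.atom_indices if i not in deleted_indices),
        default=max(res.atom_indices),
    )

    new_atoms: list[Atom] = []
    old_to_new: dict[int, int] = {}
    for atom in topology.atoms:
        if atom.index in deleted_indices:
            continue
        updated = atom
        if atom.index in res.atom_indices and atom.name in patch.charge_adjustments:
            updated = replace(atom, charge=patch.charge_adjustments[atom.name])
        old_to_new[atom.index] = len(new_atoms)
        new_atoms.append(replace(updated, index=len(new_atoms)))
        if atom.index == last_kept:
            for tmpl in patch.added_atoms:
                new_atoms.append(
                    Atom(
                        index=len(new_atoms),
                        name=tmpl.name,
                        element=_element_of(tmpl.name, tmpl.type),
                        residue_name=res.residue_name,
                        residue_id=residue_id,
                        chain=chain,
                        charge=tmpl.charge,
                        roles=tmpl.roles,
                    )
                )

    added_index = {
        t.name: next(
            a.index for a in new_atoms
            if a.name == t.name and a.residue_id == residue_id
            and a.chain == chain
        )
        for t in patch.added_atoms
    }
    bonds = set()
    for a, b in topology.bonds:
        if a in deleted_indices or b in deleted_indices:
            continue
        bonds.add((old_to_new[a], old_to_new[b]))
    for a_name, b_name in patch.new_bonds:
        ia = added_index.get(a_name, None)
        if ia is None:
            ia = old_to_new[name_to_index[a_name]]
        ib = added_index.get(b_name, None)
        if ib is None:
            ib = old_to_new[name_to_index[b_name]]
        bonds.add((min(ia, ib), max(ia, ib)))
    return Topology(new_atoms, bonds)


def patch_to_pres(patch: PatchSpec, pres_name: str = "5HMC") -> str:
    """Emit the patch as a CHARMM-RTF ``PRES`` block (diffable text form)."""
    lines = [f"PRES {pres_name}  0.00  ! built 5mC -> 5hmC substitution"]
    for name in patch.deleted_atoms:
        lines.append(f"DELETE ATOM {name}")
    for name, q in patch.charge_adjustments.items():
        lines.append(f"ATOM {name:<5s} ADJ   {q: .6f}")
    for tmpl in patch.added_atoms:
        lines.append(f"ATOM {tmpl.name:<5s} {tmpl.type:<5s} {tmpl.charge: .6f}")
    for a, b in patch.new_bonds:
        lines.append(f"BOND {a} {b}")
    for tmpl in patch.added_atoms:
        if ROLE_DONOR in tmpl.roles:
            hyd = next(
                (t.name for t in patch.added_atoms if ROLE_HYDROGEN in t.roles),
                None,
            )
            if hyd is not None:
                lines.append(f"DONO {hyd} {tmpl.name}")
        if ROLE_ACCEPTOR in tmpl.roles:
            lines.append(f"ACCE {tmpl.name}")
    return "\n".join(lines) + "\n"
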