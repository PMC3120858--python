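"""Structures, topologies with charges, trajectories and tabular data.

This module houses the shared coordinate data model (:class:`Atom`,
:class:`Topology`, :class:`Frame`, :class:`Trajectory`,
:class:`EnergySeries`) and the readers/writers for the supported external
formats:

* PDB (``ATOM``/``HETATM``/``MODEL``/``ENDMDL``) via biotite,
* a CHARMM-RTF dialect (``RESI``/``PRES``/``ATOM``/``BOND``/``DONO``/``ACCE``),
* trajectories as DCD (binary, via MDAnalysis), multi-model PDB, or a
  plain-text ``xyz-csv`` fallback documented below,
* CSV interaction-energy tables (columns ``time_ps``, ``v_el_kcalmol``,
  ``v_vdw_kcalmol``).

Unit conventions throughout the package: distances in Angstrom, energies in
kcal/mol, times in ps, charges in elementary-charge units.  Internal atom
indices are 0-based; residue ids are kept verbatim from the source file
(PDB convention is 1-based).  Lennard-Jones well depths are stored as
non-negative magnitudes (the CHARMM files' negative sign convention is
normalized away on ingest).
"""

from __future__ import annotations

import io
import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    RTFParseError,
    SchemaError,
    StructureError,
    StructureParseError,
    UnsupportedFormatError,
)

logger = logging.getLogger("flipsite")

# Atom role annotations used by the hydrogen-bond and water machinery.
ROLE_DONOR = "donor"
ROLE_HYDROGEN = "hydrogen"
ROLE_ACCEPTOR = "acceptor"
ROLE_WATER = "water"
_VALID_ROLES = frozenset({ROLE_DONOR, ROLE_HYDROGEN, ROLE_ACCEPTOR, ROLE_WATER})

#: Residue names recognized as water when assigning the ``water`` role.
WATER_RESIDUE_NAMES = frozenset({"HOH", "WAT", "TIP3", "TIP", "SPC", "SOL", "H2O"})

#: Columns of the CSV interaction-energy table schema.
ENERGY_TABLE_COLUMNS = ("time_ps", "v_el_kcalmol", "v_vdw_kcalmol")

# Unicode prime / right-quote characters that appear in nucleotide atom
# names ("C4′") are normalized to the ASCII apostrophe on ingest.
_PRIME_CHARS = {"′": "'", "’": "'", "´": "'", "ʹ": "'"}


def normalize_atom_name(name: str) -> str:
    """Map unicode prime characters in *name* to the ASCII apostrophe."""
    out = name
    for src, dst in _PRIME_CHARS.items():
        if src in out:
            out = out.replace(src, dst)
    if out != name:
        logger.info("normalized atom name %r -> %r", name, out)
    return out


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Atom:
    """One atom with identity, force-field parameters and role annotations.

    ``charge`` (e), ``lj_epsilon`` (kcal/mol, stored >= 0),
    ``lj_rmin_half`` (Rmin/2, Angstrom) and ``mass`` (amu) are ``None``
    until merged from a charge topology.
    """

    index: int
    name: str
    element: str
    residue_name: str
    residue_id: int
    chain: str
    charge: float | None = None
    lj_epsilon: float | None = None
    lj_rmin_half: float | None = None
    mass: float | None = None
    roles: frozenset = frozenset()

    def __post_init__(self):
        if self.lj_epsilon is not None and self.lj_epsilon < 0.0:
            raise StructureError(
                f"atom {self.name}: lj_epsilon must be stored as a "
                f"non-negative magnitude, got {self.lj_epsilon}"
            )
        bad = set(self.roles) - _VALID_ROLES
        if bad:
            raise StructureError(f"atom {self.name}: unknown roles {sorted(bad)}")


@dataclass(frozen=True)
class Residue:
    """A group of atoms sharing (chain, residue_id, residue_name)."""

    chain: str
    residue_id: int
    residue_name: str
    atom_indices: tuple

    @property
    def key(self):
        return (self.chain, self.residue_id)


class Topology:
    """Ordered atom list plus covalent bonds and residue grouping.

    Bonds are stored as sorted 0-based index pairs.  Residues partition the
    atom list by (chain, residue_id, residue_name).  Validation enforces
    bond indices in range and, for every atom carrying the ``hydrogen``
    role, exactly one covalent bond to a heavy atom.
    """

    def __init__(self, atoms: Sequence[Atom], bonds: Iterable[tuple] = ()):
        self.atoms: list[Atom] = list(atoms)
        for i, atom in enumerate(self.atoms):
            if atom.index != i:
                raise StructureError(
                    f"atom {atom.name}: stored index {atom.index} != position {i}"
                )
        n = len(self.atoms)
        norm = set()
        for a, b in bonds:
            if not (0 <= a < n and 0 <= b < n):
                raise StructureError(f"bond ({a}, {b}) out of range for {n} atoms")
            if a == b:
                raise StructureError(f"self-bond on atom index {a}")
            norm.add((min(a, b), max(a, b)))
        self.bonds: frozenset = frozenset(norm)
        self._neighbors: dict[int, list[int]] | None = None
        self._residues: list[Residue] | None = None
        self._validate_hydrogens()

    # -- construction helpers ------------------------------------------------

    def _validate_hydrogens(self):
        for atom in self.atoms:
            if ROLE_HYDROGEN in atom.roles:
                heavy = [
                    j for j in self.neighbors(atom.index)
                    if ROLE_HYDROGEN not in self.atoms[j].roles
                    and self.atoms[j].element != "H"
                ]
                if len(heavy) != 1:
                    raise StructureError(
                        f"hydrogen-role atom {atom.name} (index {atom.index}) "
                        f"must be bonded to exactly one heavy atom, "
                        f"found {len(heavy)}"
                    )

    # -- basic queries -------------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def neighbors(self, i: int) -> list[int]:
        if self._neighbors is None:
            nb: dict[int, list[int]] = {k: [] for k in range(self.n_atoms)}
            for a, b in sorted(self.bonds):
                nb[a].append(b)
                nb[b].append(a)
            self._neighbors = nb
        return self._neighbors[i]

    @property
    def residues(self) -> list[Residue]:
        if self._residues is None:
            order: dict[tuple, list[int]] = {}
            for atom in self.atoms:
                key = (atom.chain, atom.residue_id, atom.residue_name)
                order.setdefault(key, []).append(atom.index)
            self._residues = [
                Residue(chain=c, residue_id=r, residue_name=n, atom_indices=tuple(ix))
                for (c, r, n), ix in order.items()
            ]
        return self._residues

    def residue(self, chain: str, residue_id: int) -> Residue:
        for res in self.residues:
            if res.chain == chain and res.residue_id == residue_id:
                return res
        raise StructureError(f"no residue {residue_id} in chain {chain!r}")

    @property
    def has_charges(self) -> bool:
        return all(a.charge is not None for a in self.atoms)

    @property
    def total_charge(self) -> float:
        if not self.has_charges:
            raise StructureError("total_charge requested but some charges unset")
        return float(sum(a.charge for a in self.atoms))

    def select(
        self,
        *,
        name=None,
        resname=None,
        chain=None,
        resid=None,
        role=None,
    ) -> np.ndarray:
        """Return sorted atom indices matching all given criteria.

        Each criterion accepts a scalar or a collection of allowed values.
        """
        def as_set(x):
            if x is None:
                return None
            if isinstance(x, (str, int)):
                return {x}
            return set(x)

        names, resnames, chains, resids, roles = map(
            as_set, (name, resname, chain, resid, role)
        )
        out = []
        for atom in self.atoms:
            if names is not None and atom.name not in names:
                continue
            if resnames is not None and atom.residue_name not in resnames:
                continue
            if chains is not None and atom.chain not in chains:
                continue
            if resids is not None and atom.residue_id not in resids:
                continue
            if roles is not None and not (set(atom.roles) & roles):
                continue
            out.append(atom.index)
        return np.asarray(out, dtype=int)


@dataclass
class Frame:
    """One coordinate frame: N x 3 Angstrom array, optional box, time in ps."""

    coordinates: np.ndarray
    time: float = 0.0
    box: np.ndarray | None = None

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise StructureError(
                f"coordinates must be (N, 3), got {self.coordinates.shape}"
            )
        if not np.all(np.isfinite(self.coordinates)):
            raise StructureError("non-finite coordinates in frame")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (3,):
                raise UnsupportedFormatError(
                    "only orthorhombic boxes (3 edge lengths) are supported"
                )

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[0]


class Trajectory:
    """Time-ordered frames with fixed nominal spacing ``dt`` (ps)."""

    def __init__(self, frames: Sequence[Frame], dt: float):
        frames = list(frames)
        if not frames:
            raise StructureError("trajectory must contain at least one frame")
        n = frames[0].n_atoms
        for k, f in enumerate(frames):
            if f.n_atoms != n:
                raise StructureError(
                    f"frame {k} has {f.n_atoms} atoms, expected {n}"
                )
        times = np.array([f.time for f in frames], dtype=float)
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise StructureError("frame times must be strictly increasing")
        self.frames = frames
        self.dt = float(dt)

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, k) -> Frame:
        return self.frames[k]

    def __iter__(self):
        return iter(self.frames)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_atoms(self) -> int:
        return self.frames[0].n_atoms

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames], dtype=float)

    @property
    def coordinates(self) -> np.ndarray:
        """All coordinates stacked as (n_frames, n_atoms, 3)."""
        return np.stack([f.coordinates for f in self.frames])


@dataclass
class EnergySeries:
    """Per-frame electrostatic / van-der-Waals interaction energies.

    ``state_label`` distinguishes the bound state (ligand with
    protein+solvent) from the free state (ligand with solvent alone).
    Lengths are validated; finiteness is enforced by the table reader, not
    here, so that downstream consumers can raise frame-naming errors on NaN.
    """

    state_label: str
    times: np.ndarray
    v_el: np.ndarray
    v_vdw: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.v_el = np.asarray(self.v_el, dtype=float)
        self.v_vdw = np.asarray(self.v_vdw, dtype=float)
        if not (len(self.times) == len(self.v_el) == len(self.v_vdw)):
            raise SchemaError(
                f"energy series arrays must have equal length, got "
                f"{len(self.times)}/{len(self.v_el)}/{len(self.v_vdw)}"
            )

    def __len__(self) -> int:
        return len(self.times)

    def window(self, t_start: float, t_stop: float) -> "EnergySeries":
        """Restrict to frames with ``t_start < t <= t_stop`` (half-open)."""
        mask = (self.times > t_start) & (self.times <= t_stop)
        if not np.any(mask):
            raise ValueError(
                f"window ({t_start}, {t_stop}] ps selects no frames"
            )
        meta = dict(self.metadata)
        meta["window_ps"] = (float(t_start), float(t_stop))
        return EnergySeries(
            state_label=self.state_label,
            times=self.times[mask],
            v_el=self.v_el[mask],
            v_vdw=self.v_vdw[mask],
            metadata=meta,
        )


# --------------------------------------------------------------------------
# CHARMM-RTF dialect
# --------------------------------------------------------------------------

@dataclass
class ResidueParameters:
    """Per-residue parameters from an RTF ``RESI``/``PRES`` block.

    ``atoms`` is an ordered list of (name, type, charge); ``bonds`` are
    intra-residue atom-name pairs; ``donors`` are (hydrogen_name,
    heavy_name) pairs; ``acceptors`` are acceptor heavy-atom names.
    """

    name: str
    atoms: list = field(default_factory=list)
    bonds: list = field(default_factory=list)
    donors: list = field(default_factory=list)
    acceptors: list = field(default_factory=list)
    is_patch: bool = False
    deleted_atoms: list = field(default_factory=list)

    @property
    def atom_names(self) -> list:
        return [a[0] for a in self.atoms]

    def atom_charge(self, name: str) -> float:
        for n, _t, q in self.atoms:
            if n == name:
                return q
        raise StructureError(f"residue {self.name}: no atom named {name!r}")

    def atom_type(self, name: str) -> str:
        for n, t, _q in self.atoms:
            if n == name:
                return t
        raise StructureError(f"residue {self.name}: no atom named {name!r}")

    @property
    def net_charge(self) -> float:
        return float(sum(q for _n, _t, q in self.atoms))

    def neighbor_names(self, name: str) -> list:
        out = []
        for a, b in self.bonds:
            if a == name:
                out.append(b)
            elif b == name:
                out.append(a)
        return out


def read_charge_topology(source) -> dict:
    """Parse an RTF-dialect charge topology into residue parameter tables.

    Supported records: ``RESI``/``PRES`` headers, ``ATOM name type charge``,
    ``BOND``/``DOUB`` name pairs (``+``/``-`` prefixed inter-residue partners
    are skipped), ``DONO[R] [hydrogen] heavy`` and ``ACCE[PTOR] heavy``
    lines, ``DELE ATOM name`` inside patches.  ``!`` starts a comment.

    Returns a dict mapping residue name to :class:`ResidueParameters`.
    """
    text = _as_text(source)
    residues: dict[str, ResidueParameters] = {}
    current: ResidueParameters | None = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("!", 1)[0].strip()
        if not line:
            continue
        if line.startswith("*"):
            continue  # title card
        fields = line.split()
        rec = fields[0].upper()
        if rec in ("RESI", "PRES"):
            if len(fields) < 2:
                raise RTFParseError(f"line {lineno}: {rec} record without a name")
            current = ResidueParameters(name=fields[1], is_patch=(rec == "PRES"))
            if current.name in residues:
                raise RTFParseError(
                    f"line {lineno}: duplicate residue block {current.name!r}"
                )
            residues[current.name] = current
        elif rec == "ATOM":
            if current is None:
                raise RTFParseError(f"line {lineno}: ATOM outside a residue block")
            if len(fields) < 4:
                raise RTFParseError(
                    f"line {lineno}: ATOM needs name, type and charge"
                )
            name = normalize_atom_name(fields[1])
            try:
                charge = float(fields[3])
            except ValueError:
                raise RTFParseError(
                    f"line {lineno}: non-numeric charge {fields[3]!r} "
                    f"for atom {name!r}"
                ) from None
            if name in current.atom_names:
                raise RTFParseError(
                    f"line {lineno}: duplicate atom name {name!r} "
                    f"in residue {current.name}"
                )
            current.atoms.append((name, fields[2], charge))
        elif rec in ("BOND", "DOUB", "TRIP"):
            if current is None:
                raise RTFParseError(f"line {lineno}: {rec} outside a residue block")
            names = [normalize_atom_name(f) for f in fields[1:]]
            if len(names) % 2:
                raise RTFParseError(f"line {lineno}: odd atom count on {rec} line")
            for a, b in zip(names[0::2], names[1::2]):
                if a.startswith(("+", "-")) or b.startswith(("+", "-")):
                    continue  # inter-residue bond, outside scope
                current.bonds.append((a, b))
        elif rec.startswith("DONO"):
            if current is None:
                raise RTFParseError(f"line {lineno}: donor outside a residue block")
            names = [normalize_atom_name(f) for f in fields[1:]]
            if len(names) == 1:
                current.donors.append((None, names[0]))
            elif len(names) >= 2:
                current.donors.append((names[0], names[1]))
        elif rec.startswith("ACCE"):
            if current is None:
                raise RTFParseError(f"line {lineno}: acceptor outside a residue block")
            if len(fields) >= 2:
                current.acceptors.append(normalize_atom_name(fields[1]))
        elif rec in ("DELE", "DELETE"):
            if current is None or not current.is_patch:
                raise RTFParseError(
                    f"line {lineno}: DELETE only valid inside a PRES block"
                )
            if len(fields) >= 3 and fields[1].upper() == "ATOM":
                current.deleted_atoms.extend(
                    normalize_atom_name(f) for f in fields[2:]
                )
        elif rec in ("MASS", "DECL", "DEFA", "AUTO", "GROU", "GROUP", "IC",
                     "IMPR", "IMPH", "CMAP", "ANGL", "DIHE", "PATC", "END"):
            continue  # recognized but not needed
        else:
            logger.debug("RTF line %d: ignoring record %r", lineno, rec)
    if not residues:
        raise RTFParseError("no RESI/PRES blocks found")
    return residues


def merge_parameters(
    topology: Topology,
    residue_params: Mapping[str, ResidueParameters],
    lj_by_type: Mapping[str, tuple] | None = None,
    mass_by_type: Mapping[str, float] | None = None,
) -> Topology:
    """Assign charges, roles, bonds (and optionally LJ/mass) from an RTF table.

    Atom order is never changed.  Every atom must be matched by name inside
    its residue's parameter block, otherwise a :class:`StructureError` is
    raised — no atom is left without a charge silently.  Donor/acceptor/
    hydrogen annotations become :class:`Atom` roles; residues whose name is
    in :data:`WATER_RESIDUE_NAMES` additionally get the ``water`` role.
    """
    new_atoms: list[Atom] = [None] * topology.n_atoms
    bonds = set(topology.bonds)
    for res in topology.residues:
        params = residue_params.get(res.residue_name)
        if params is None:
            raise StructureError(
                f"no parameters for residue {res.residue_name!r} "
                f"({res.chain}:{res.residue_id})"
            )
        name_to_index = {}
        for i in res.atom_indices:
            atom = topology.atoms[i]
            if atom.name in name_to_index:
                raise StructureError(
                    f"duplicate atom name {atom.name!r} in residue "
                    f"{res.chain}:{res.residue_id}"
                )
            name_to_index[atom.name] = i
        donor_heavies = {h for _hyd, h in params.donors}
        donor_hydrogens = {hyd for hyd, _h in params.donors if hyd is not None}
        for i in res.atom_indices:
            atom = topology.atoms[i]
            if atom.name not in params.atom_names:
                raise StructureError(
                    f"atom {atom.name!r} of residue {res.residue_name} "
                    f"({res.chain}:{res.residue_id}) not in parameter table"
                )
            atype = params.atom_type(atom.name)
            roles = set(atom.roles)
            if atom.name in donor_heavies:
                roles.add(ROLE_DONOR)
            if atom.name in params.acceptors:
                roles.add(ROLE_ACCEPTOR)
            if atom.name in donor_hydrogens or atom.element == "H" \
                    or atype.upper().startswith("H"):
                roles.add(ROLE_HYDROGEN)
            if res.residue_name in WATER_RESIDUE_NAMES:
                roles.add(ROLE_WATER)
            lj_eps, lj_rmin = (None, None)
            if lj_by_type is not None:
                if atype not in lj_by_type:
                    raise StructureError(
                        f"no LJ parameters for atom type {atype!r}"
                    )
                lj_eps, lj_rmin = lj_by_type[atype]
                lj_eps = abs(float(lj_eps))  # normalize CHARMM sign convention
            mass = None
            if mass_by_type is not None:
                mass = mass_by_type.get(atype)
            new_atoms[i] = replace(
                atom,
                charge=params.atom_charge(atom.name),
                roles=frozenset(roles),
                lj_epsilon=lj_eps if lj_by_type is not None else atom.lj_epsilon,
                lj_rmin_half=lj_rmin if lj_by_type is not None else atom.lj_rmin_half,
                mass=mass if mass_by_type is not None else atom.mass,
            )
        for a_name, b_name in params.bonds:
            if a_name in name_to_index and b_name in name_to_index:
                ia, ib = name_to_index[a_name], name_to_index[b_name]
                bonds.add((min(ia, ib), max(ia, ib)))
    return Topology(new_atoms, bonds)


# --------------------------------------------------------------------------
# PDB structures
# --------------------------------------------------------------------------

def _as_text(source) -> str:
    if isinstance(source, Path):
        return source.read_text()
    if isinstance(source, str):
        if "\n" not in source and Path(source).is_file():
            return Path(source).read_text()
        return source
    if hasattr(source, "read"):
        data = source.read()
        return data.decode() if isinstance(data, bytes) else data
    raise TypeError(f"cannot read text from {type(source)!r}")


def _guess_element(atom_name: str) -> str:
    stripped = atom_name.strip().lstrip("0123456789'\"*")
    if not stripped:
        return "X"
    two = stripped[:2].upper()
    if two in ("CL", "BR", "NA", "MG", "ZN", "FE", "MN", "CA") and \
            len(atom_name.strip()) > 1 and atom_name.strip()[1].islower():
        return two.capitalize()
    return stripped[0].upper()


def _prevalidate_pdb(text: str):
    n_atoms = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        n_atoms += 1
        if len(line) < 54:
            raise StructureParseError(
                f"line {lineno}: ATOM/HETATM record shorter than the "
                f"fixed-width coordinate columns"
            )
        for lo, hi, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
            fld = line[lo:hi].strip()
            try:
                float(fld)
            except ValueError:
                raise StructureParseError(
                    f"line {lineno}: malformed {what} coordinate field {fld!r}"
                ) from None
        try:
            int(line[22:26].strip())
        except ValueError:
            raise StructureParseError(
                f"line {lineno}: malformed residue sequence number "
                f"{line[22:26].strip()!r}"
            ) from None
    if n_atoms == 0:
        raise StructureParseError("no ATOM/HETATM records found (empty input)")


def read_structure(source) -> tuple:
    """Read a PDB structure into a (Topology, list-of-Frames) pair.

    Multi-model files produce one topology (from the first model) and one
    frame per model; frame ``time`` is the 0-based model index (no physical
    time is encoded in PDB).  Charges and LJ parameters are left unset, to
    be merged from a charge topology.  Unicode prime characters in atom
    names are normalized to ASCII apostrophes.
    """
    import biotite.structure.io.pdb as pdb_io

    text = _as_text(source)
    for src, dst in _PRIME_CHARS.items():
        if src in text:
            logger.info("normalizing unicode prime %r to %r in PDB input", src, dst)
            text = text.replace(src, dst)
    _prevalidate_pdb(text)
    try:
        pdb_file = pdb_io.PDBFile.read(io.StringIO(text))
        stack = pdb_file.get_structure(model=None)
    except Exception as exc:  # pragma: no cover - biotite internal failures
        raise StructureParseError(f"PDB parse failed: {exc}") from exc

    n_models, n_atoms = stack.coord.shape[0], stack.coord.shape[1]
    atoms = []
    for i in range(n_atoms):
        name = normalize_atom_name(str(stack.atom_name[i]))
        element = str(stack.element[i]).strip()
        if not element:
            element = _guess_element(name)
        element = element.capitalize() if len(element) > 1 else element.upper()
        atoms.append(
            Atom(
                index=i,
                name=name,
                element=element,
                residue_name=str(stack.res_name[i]),
                residue_id=int(stack.res_id[i]),
                chain=str(stack.chain_id[i]),
            )
        )
    topology = Topology(atoms)
    frames = [
        Frame(coordinates=np.asarray(stack.coord[m], dtype=float), time=float(m))
        for m in range(n_models)
    ]
    return topology, frames


def write_structure(topology: Topology, frames, dest=None) -> str | None:
    """Write (multi-model) PDB text for *frames* of *topology*.

    *frames* may be a single :class:`Frame`, a list of frames, or a
    :class:`Trajectory`.  Returns the text if *dest* is None, otherwise
    writes to the path/stream.
    """
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb_io

    if isinstance(frames, Frame):
        frames = [frames]
    elif isinstance(frames, Trajectory):
        frames = frames.frames
    arrays = []
    for frame in frames:
        if frame.n_atoms != topology.n_atoms:
            raise StructureError(
                f"frame has {frame.n_atoms} atoms, topology has "
                f"{topology.n_atoms}"
            )
        arr = struc.AtomArray(topology.n_atoms)
        arr.coord = np.asarray(frame.coordinates, dtype=np.float32)
        arr.atom_name = np.array([a.name for a in topology.atoms], dtype="U6")
        arr.res_name = np.array([a.residue_name for a in topology.atoms], dtype="U5")
        arr.res_id = np.array([a.residue_id for a in topology.atoms], dtype=int)
        arr.chain_id = np.array([a.chain for a in topology.atoms], dtype="U4")
        arr.element = np.array([a.element for a in topology.atoms], dtype="U2")
        arr.hetero = np.array(
            [a.residue_name in WATER_RESIDUE_NAMES for a in topology.atoms]
        )
        arrays.append(arr)
    stack = struc.stack(arrays)
    pdb_file = pdb_io.PDBFile()
    pdb_file.set_structure(stack)
    buf = io.StringIO()
    pdb_file.write(buf)
    text = buf.getvalue()
    if dest is None:
        return text
    if isinstance(dest, (str, Path)):
        Path(dest).write_text(text)
    else:
        dest.write(text)
    return None


# --------------------------------------------------------------------------
# Trajectories
# --------------------------------------------------------------------------

_XYZ_CSV_COLUMNS = ("frame", "time_ps", "atom", "x", "y", "z")


def read_trajectory(
    source,
    format: str,
    n_atoms: int | None = None,
    topology: Topology | None = None,
    dt: float | None = None,
) -> Trajectory:
    """Read a trajectory in ``dcd``, ``multi-model-pdb`` or ``xyz-csv`` format.

    ``dcd`` and ``multi-model-pdb`` carry no trustworthy physical time
    stamps, so ``dt`` (ps) is required for them and frames are stamped
    ``0, dt, 2*dt, ...``; ``xyz-csv`` carries an explicit ``time_ps``
    column.  Atom counts are validated against *topology* or *n_atoms*
    when given.  A truncated final frame is dropped with a warning.
    """
    if topology is not None:
        n_atoms = topology.n_atoms
    fmt = format.lower().replace("_", "-")
    if fmt in ("pdb", "multi-model-pdb"):
        if dt is None:
            raise ConfigurationError(
                "dt (ps) is required for multi-model PDB input: the format "
                "carries no time stamps"
            )
        top, frames = read_structure(source)
        if n_atoms is not None and top.n_atoms != n_atoms:
            raise StructureError(
                f"trajectory atom count {top.n_atoms} != expected {n_atoms}"
            )
        stamped = [
            Frame(coordinates=f.coordinates, time=k * dt, box=f.box)
            for k, f in enumerate(frames)
        ]
        return Trajectory(stamped, dt=dt)
    if fmt == "xyz-csv":
        df = pd.read_csv(io.StringIO(_as_text(source)),
                         float_precision="round_trip")
        missing = [c for c in _XYZ_CSV_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"xyz-csv missing column(s) {missing}")
        frames = []
        counts = df.groupby("frame", sort=True).size()
        expected = n_atoms if n_atoms is not None else int(counts.iloc[0])
        for frame_idx in counts.index:
            sub = df[df["frame"] == frame_idx].sort_values("atom")
            if len(sub) != expected:
                if frame_idx == counts.index[-1]:
                    warnings.warn(
                        f"dropping truncated final frame {frame_idx} "
                        f"({len(sub)}/{expected} atoms)"
                    )
                    logger.warning("dropped truncated final frame %s", frame_idx)
                    continue
                raise StructureError(
                    f"frame {frame_idx} has {len(sub)} atoms, expected {expected}"
                )
            frames.append(
                Frame(
                    coordinates=sub[["x", "y", "z"]].to_numpy(dtype=float),
                    time=float(sub["time_ps"].iloc[0]),
                )
            )
        if dt is None:
            times = [f.time for f in frames]
            dt = times[1] - times[0] if len(times) > 1 else 1.0
        return Trajectory(frames, dt=dt)
    if fmt == "dcd":
        if dt is None:
            raise ConfigurationError(
                "dt (ps) is required for DCD input: header time stamps are "
                "not trusted"
            )
        from MDAnalysis.coordinates.DCD import DCDReader

        reader = DCDReader(str(source))
        coords = [np.array(ts.positions, dtype=float) for ts in reader]
        reader.close()
        if n_atoms is not None and coords and coords[0].shape[0] != n_atoms:
            raise StructureError(
                f"trajectory atom count {coords[0].shape[0]} != expected {n_atoms}"
            )
        frames = [Frame(coordinates=c, time=k * dt) for k, c in enumerate(coords)]
        return Trajectory(frames, dt=dt)
    raise UnsupportedFormatError(f"unknown trajectory format {format!r}")


def write_trajectory(
    trajectory: Trajectory,
    dest,
    format: str,
    topology: Topology | None = None,
) -> str | None:
    """Write a trajectory as ``dcd``, ``multi-model-pdb`` or ``xyz-csv``.

    ``xyz-csv`` stores coordinates with 17 significant digits and therefore
    round-trips float64 exactly; PDB rounds to 1e-3 Angstrom and DCD to
    float32.
    """
    fmt = format.lower().replace("_", "-")
    if fmt in ("pdb", "multi-model-pdb"):
        if topology is None:
            raise ConfigurationError("topology is required to write PDB")
        return write_structure(topology, trajectory, dest)
    if fmt == "xyz-csv":
        rows = []
        for k, frame in enumerate(trajectory):
            for a in range(frame.n_atoms):
                x, y, z = frame.coordinates[a]
                rows.append((k, frame.time, a, x, y, z))
        df = pd.DataFrame(rows, columns=list(_XYZ_CSV_COLUMNS))
        text = df.to_csv(index=False, float_format="%.17g")
        if dest is None:
            return text
        if isinstance(dest, (str, Path)):
            Path(dest).write_text(text)
        else:
            dest.write(text)
        return None
    if fmt == "dcd":
        import MDAnalysis as mda

        u = mda.Universe.empty(trajectory.n_atoms, trajectory=True)
        with mda.Writer(
            str(dest), n_atoms=trajectory.n_atoms, format="DCD",
            dt=trajectory.dt,
        ) as writer:
            for frame in trajectory:
                u.atoms.positions = frame.coordinates
                writer.write(u.atoms)
        return None
    raise UnsupportedFormatError(f"unknown trajectory format {format!r}")


# --------------------------------------------------------------------------
# Energy tables
# --------------------------------------------------------------------------

def read_energy_table(source, state_label: str = "bound") -> EnergySeries:
    """Read a CSV energy table (``time_ps,v_el_kcalmol,v_vdw_kcalmol``)."""
    df = pd.read_csv(io.StringIO(_as_text(source)),
                     float_precision="round_trip")
    missing = [c for c in ENERGY_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"energy table missing column(s) {missing}")
    values = df[list(ENERGY_TABLE_COLUMNS)].to_numpy(dtype=float)
    if values.size and not np.all(np.isfinite(values)):
        bad = np.argwhere(~np.isfinite(values))
        raise SchemaError(
            f"non-finite value in energy table at row {int(bad[0][0])}"
        )
    return EnergySeries(
        state_label=state_label,
        times=df["time_ps"].to_numpy(dtype=float),
        v_el=df["v_el_kcalmol"].to_numpy(dtype=float),
        v_vdw=df["v_vdw_kcalmol"].to_numpy(dtype=float),
    )


def write_energy_table(series: EnergySeries, dest=None) -> str | None:
    """Write an :class:`EnergySeries` as CSV with >= 12 significant digits."""
    df = pd.DataFrame(
        {
            "time_ps": series.times,
            "v_el_kcalmol": series.v_el,
            "v_vdw_kcalmol": series.v_vdw,
        }
    )
    text = df.to_csv(index=False, float_format="%.17g")
    if dest is None:
        return text
    if isinstance(dest, (str, Path)):
        Path(dest).write_text(text)
    else:
        dest.write(text)
    return None
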