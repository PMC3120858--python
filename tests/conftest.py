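"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately naive re-derivations (pure-Python double
loops, exhaustive triplet enumeration, networkx graph distances) so that
they share no code path with the package implementation they check.
"""

import math

import numpy as np
import pytest

from flipsite.structure_io import Atom, Frame, Topology


# --------------------------------------------------------------------------
# random systems
# --------------------------------------------------------------------------

def _unit(rng):
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def build_random_hbond_system(rng, n_molecules=30, box=12.0):
    """Random small molecules with donor/acceptor roles in a box.

    Includes unbonded donors and acceptors, dual-role atoms, and short
    covalent chains placing acceptors at graph distance 2 (excluded) and 3
    (allowed) from a donor, so the exclusion rule is exercised.
    """
    atoms, bonds, coords = [], [], []

    def add(name, element, resid, roles, pos):
        atoms.append(
            Atom(index=len(atoms), name=name, element=element,
                 residue_name="MOL", residue_id=resid, chain="A",
                 roles=frozenset(roles))
        )
        coords.append(np.asarray(pos, dtype=float))
        return len(atoms) - 1

    for m in range(n_molecules):
        pos = rng.uniform(0.0, box, 3)
        kind = int(rng.integers(0, 5))
        rid = m + 1
        if kind == 0:  # plain donor X-H
            x = add(f"D{m}", "N", rid, {"donor"}, pos)
            h = add(f"HD{m}", "H", rid, {"hydrogen"}, pos + _unit(rng))
            bonds.append((x, h))
        elif kind == 1:  # plain acceptor
            add(f"A{m}", "O", rid, {"acceptor"}, pos)
        elif kind == 2:  # dual donor+acceptor (water-oxygen-like)
            x = add(f"W{m}", "O", rid, {"donor", "acceptor"}, pos)
            h = add(f"HW{m}", "H", rid, {"hydrogen"}, pos + _unit(rng))
            bonds.append((x, h))
        elif kind == 3:  # D-B-A chain: acceptor 2 bonds from donor (excluded)
            d = add(f"D{m}", "N", rid, {"donor"}, pos)
            h = add(f"HD{m}", "H", rid, {"hydrogen"}, pos + _unit(rng))
            b = add(f"B{m}", "C", rid, set(), pos + np.array([1.4, 0, 0]))
            a = add(f"A{m}", "O", rid, {"acceptor"},
                    pos + np.array([2.6, 0.5, 0]))
            bonds.extend([(d, h), (d, b), (b, a)])
        else:  # D-B1-B2-A chain: acceptor 3 bonds away (allowed)
            d = add(f"D{m}", "N", rid, {"donor"}, pos)
            h = add(f"HD{m}", "H", rid, {"hydrogen"}, pos + _unit(rng))
            b1 = add(f"B{m}a", "C", rid, set(), pos + np.array([1.4, 0, 0]))
            b2 = add(f"B{m}b", "C", rid, set(), pos + np.array([2.4, 0.9, 0]))
            a = add(f"A{m}", "O", rid, {"acceptor"},
                    pos + np.array([3.0, 1.8, 0.4]))
            bonds.extend([(d, h), (d, b1), (b1, b2), (b2, a)])
    return Topology(atoms, bonds), Frame(np.asarray(coords))


def build_random_charged_system(rng, n_a=50, n_b=50, spacing=3.0):
    """Two disjoint random groups with charges and LJ parameters.

    Positions are jittered lattice points (minimum separation about
    2 Angstrom, the closest physically sensible nonbonded contact), so the
    steep r^-12 wall never amplifies float round-off past the comparison
    tolerance.
    """
    n = n_a + n_b
    side = int(np.ceil(n ** (1.0 / 3.0)))
    lattice = np.array(
        [(i, j, k) for i in range(side) for j in range(side)
         for k in range(side)], dtype=float
    ) * spacing
    chosen = rng.choice(len(lattice), size=n, replace=False)
    coords = lattice[chosen] + rng.uniform(-0.5, 0.5, (n, 3))
    atoms = [
        Atom(index=i, name=f"X{i}", element="C", residue_name="RND",
             residue_id=1 + (i >= n_a), chain="A",
             charge=float(rng.uniform(-1.0, 1.0)),
             lj_epsilon=float(rng.uniform(0.01, 0.3)),
             lj_rmin_half=float(rng.uniform(1.0, 2.2)))
        for i in range(n)
    ]
    return (Topology(atoms), Frame(coords),
            np.arange(n_a), np.arange(n_a, n))


# --------------------------------------------------------------------------
# oracles
# --------------------------------------------------------------------------

def brute_force_hbonds(topology, frame, criteria):
    """Exhaustive (D, H, A) triplet enumeration with no spatial pruning.

    Independent re-derivation of the geometric criteria: networkx graph
    distances for the two-covalent-bond exclusion, math-module scalar
    geometry for distances and angles.
    """
    import networkx as nx

    graph = nx.Graph()
    graph.add_nodes_from(range(topology.n_atoms))
    graph.add_edges_from(topology.bonds)
    near = dict(nx.all_pairs_shortest_path_length(graph, cutoff=2))
    coords = frame.coordinates
    out = set()
    for d in range(topology.n_atoms):
        if "donor" not in topology.atoms[d].roles:
            continue
        for h in range(topology.n_atoms):
            if "hydrogen" not in topology.atoms[h].roles:
                continue
            if (min(d, h), max(d, h)) not in topology.bonds:
                continue
            for a in range(topology.n_atoms):
                if "acceptor" not in topology.atoms[a].roles:
                    continue
                if a == d or a == h:
                    continue
                if a in near.get(d, {}):
                    continue  # within two covalent bonds of the donor
                da = math.dist(coords[d], coords[a])
                if da > criteria.max_da_distance:
                    continue
                v1 = coords[d] - coords[h]
                v2 = coords[a] - coords[h]
                cosang = float(np.dot(v1, v2)
                               / (np.linalg.norm(v1) * np.linalg.norm(v2)))
                angle = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
                if angle >= criteria.min_dha_angle - 1e-9:
                    out.add((d, h, a))
    return frozenset(out)


def naive_nonbonded(topology, frame, group_a, group_b, scheme):
    """Pure-Python double-loop pair energies with CHARMM switching."""
    coulomb = 332.0636
    ron2 = scheme.switch_start**2
    roff2 = scheme.cutoff**2
    v_el = 0.0
    v_vdw = 0.0
    for i in group_a:
        ai = topology.atoms[int(i)]
        for j in group_b:
            aj = topology.atoms[int(j)]
            r = math.dist(frame.coordinates[int(i)], frame.coordinates[int(j)])
            r2 = r * r
            if r2 <= ron2:
                s = 1.0
            elif r2 >= roff2:
                s = 0.0
            else:
                s = ((roff2 - r2) ** 2 * (roff2 + 2.0 * r2 - 3.0 * ron2)
                     / (roff2 - ron2) ** 3)
            v_el += coulomb * ai.charge * aj.charge / (scheme.dielectric * r) * s
            eps = math.sqrt(ai.lj_epsilon * aj.lj_epsilon)
            rmin = ai.lj_rmin_half + aj.lj_rmin_half
            v_vdw += eps * ((rmin / r) ** 12 - 2.0 * (rmin / r) ** 6) * s
    return v_el, v_vdw


# --------------------------------------------------------------------------
# fixtures
# --------------------------------------------------------------------------

@pytest.fixture
def toy_params():
    from flipsite.synthetic_data import toy_residue_parameters

    return toy_residue_parameters()


#: Hand-written 20-atom PDB fixture: two protein residues, one nucleotide
#: (with primed atom names), two waters.
MINI_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      12.560   6.351  -6.512  1.00  0.00           C
ATOM      3  C   ALA A   1      13.044   7.213  -5.345  1.00  0.00           C
ATOM      4  O   ALA A   1      12.323   8.112  -4.897  1.00  0.00           O
ATOM      5  CB  ALA A   1      13.262   4.995  -6.446  1.00  0.00           C
ATOM      6  N   SER A   2      14.261   6.959  -4.869  1.00  0.00           N
ATOM      7  CA  SER A   2      14.853   7.702  -3.756  1.00  0.00           C
ATOM      8  C   SER A   2      16.350   7.432  -3.661  1.00  0.00           C
ATOM      9  O   SER A   2      16.904   6.628  -4.413  1.00  0.00           O
ATOM     10  CB  SER A   2      14.158   7.342  -2.440  1.00  0.00           C
ATOM     11  OG  SER A   2      14.699   8.091  -1.361  1.00  0.00           O
ATOM     12  P    DC B   5       2.143  -3.541   4.286  1.00  0.00           P
ATOM     13  O1P  DC B   5       1.021  -4.372   4.790  1.00  0.00           O
ATOM     14  O2P  DC B   5       3.412  -4.221   3.925  1.00  0.00           O
ATOM     15  O5'  DC B   5       1.611  -2.676   3.047  1.00  0.00           O
ATOM     16  C5'  DC B   5       0.438  -1.871   3.222  1.00  0.00           C
ATOM     17  C4'  DC B   5       0.173  -1.041   1.979  1.00  0.00           C
ATOM     18  O3'  DC B   5      -1.796  -0.017   1.066  1.00  0.00           O
HETATM   19  O   HOH W 101       5.000   5.000   5.000  1.00  0.00           O
HETATM   20  O   HOH W 102       7.500   5.000   5.000  1.00  0.00           O
"""


@pytest.fixture
def mini_pdb_text():
    return MINI_PDB


#: Manual character-level transcription of MINI_PDB: (name, residue_name,
#: residue_id, chain, x, y, z) per atom, in file order.
MINI_PDB_EXPECTED = [
    ("N", "ALA", 1, "A", 11.104, 6.134, -6.504),
    ("CA", "ALA", 1, "A", 12.560, 6.351, -6.512),
    ("C", "ALA", 1, "A", 13.044, 7.213, -5.345),
    ("O", "ALA", 1, "A", 12.323, 8.112, -4.897),
    ("CB", "ALA", 1, "A", 13.262, 4.995, -6.446),
    ("N", "SER", 2, "A", 14.261, 6.959, -4.869),
    ("CA", "SER", 2, "A", 14.853, 7.702, -3.756),
    ("C", "SER", 2, "A", 16.350, 7.432, -3.661),
    ("O", "SER", 2, "A", 16.904, 6.628, -4.413),
    ("CB", "SER", 2, "A", 14.158, 7.342, -2.440),
    ("OG", "SER", 2, "A", 14.699, 8.091, -1.361),
    ("P", "DC", 5, "B", 2.143, -3.541, 4.286),
    ("O1P", "DC", 5, "B", 1.021, -4.372, 4.790),
    ("O2P", "DC", 5, "B", 3.412, -4.221, 3.925),
    ("O5'", "DC", 5, "B", 1.611, -2.676, 3.047),
    ("C5'", "DC", 5, "B", 0.438, -1.871, 3.222),
    ("C4'", "DC", 5, "B", 0.173, -1.041, 1.979),
    ("O3'", "DC", 5, "B", -1.796, -0.017, 1.066),
    ("O", "HOH", 101, "W", 5.000, 5.000, 5.000),
    ("O", "HOH", 102, "W", 7.500, 5.000, 5.000),
]
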