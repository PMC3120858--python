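"""Toy systems and trajectories with planted, machine-readable ground truth.

The real study system — a protein pocket holding a flipped, methylated
nucleotide, solvated and simulated for tens of nanoseconds — is emulated
here at toy scale so that every pipeline stage can be tested without any
simulation or download:

* a ~20-atom pocket with donor/acceptor annotations and a flipped
  nucleotide residue carrying a patchable methyl group,
* hydrogen bonds that exist exactly during scheduled frame ranges
  (donor-acceptor distance 2.9 Angstrom, D-H-A angle 165 degrees inside
  the ranges; the acceptor retreats to 4.6 Angstrom outside, a full
  Angstrom beyond the default distance criterion, so detection never
  sits on the criterion boundary),
* waters that hop between fixed sites on a planted schedule,
* optional i.i.d. Gaussian per-atom jitter with known variance (closed
  forms for RMSF/RMSD expectations), and
* stationary Gaussian interaction-energy series with known population
  means for LIE estimation.

Every generator is a pure function of (spec, seed) and returns a truth
record; downstream recovery tests read expectations only from the truth
record.

Frame spacing defaults to 5 ps — the interval at which hydrogen bonds and
binding-site waters are monitored — and the canned LIE study conditions
reproduce the scale of the published comparison: a 57 ns production run
analysed over its last 10 ns (2000 frames at 5 ps).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import StructureError
from .structure_io import (
    ROLE_ACCEPTOR,
    ROLE_DONOR,
    ROLE_HYDROGEN,
    ROLE_WATER,
    Atom,
    EnergySeries,
    Frame,
    ResidueParameters,
    Topology,
    Trajectory,
    read_charge_topology,
)

# -- study-scale constants -------------------------------------------------

#: Monitoring interval for hydrogen bonds and pocket waters (ps).
STUDY_FRAME_SPACING_PS = 5.0
#: Length of one production simulation (ps).
STUDY_PRODUCTION_LENGTH_PS = 57_000.0
#: Length of the equilibrated averaging window at the end of a run (ps).
STUDY_ANALYSIS_WINDOW_PS = 10_000.0

# Planted hydrogen-bond geometry (Angstrom / degrees).  Inside a scheduled
# range the pair sits comfortably inside the default criteria; outside, the
# acceptor is a full Angstrom beyond the distance cutoff.
HBOND_ACTIVE_DA = 2.9
HBOND_INACTIVE_DA = 4.6
HBOND_ACTIVE_ANGLE = 165.0
HBOND_DH_LENGTH = 1.0

_LJ_BY_ELEMENT = {
    "H": (0.046, 0.2245, 1.008),
    "C": (0.070, 1.9924, 12.011),
    "N": (0.200, 1.8500, 14.007),
    "O": (0.120, 1.7000, 15.999),
    "P": (0.585, 2.1500, 30.974),
}


def _atom(index, name, element, resname, resid, chain, charge, roles=()):
    eps, rmin, mass = _LJ_BY_ELEMENT[element]
    return Atom(
        index=index, name=name, element=element, residue_name=resname,
        residue_id=resid, chain=chain, charge=charge,
        lj_epsilon=eps, lj_rmin_half=rmin, mass=mass,
        roles=frozenset(roles),
    )


# -- specs and truth records ----------------------------------------------

FrameRanges = Sequence[tuple]


@dataclass(frozen=True)
class HBondPlant:
    """One scheduled hydrogen bond: a label and half-open frame ranges."""

    label: str
    ranges: tuple

    def __post_init__(self):
        object.__setattr__(
            self, "ranges", tuple((int(a), int(b)) for a, b in self.ranges)
        )


@dataclass(frozen=True)
class WaterPlant:
    """A water occupying a site during half-open frame ranges."""

    water: str
    site: int
    ranges: tuple

    def __post_init__(self):
        object.__setattr__(
            self, "ranges", tuple((int(a), int(b)) for a, b in self.ranges)
        )


@dataclass(frozen=True)
class ToyComplexSpec:
    """Study conditions of a toy pocket/nucleotide/water system."""

    n_frames: int = 200
    dt: float = STUDY_FRAME_SPACING_PS
    hbond_schedule: tuple = ()
    water_schedule: tuple = ()
    fluctuation_sigmas: Mapping = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.n_frames < 1:
            raise StructureError("n_frames must be >= 1")
        if self.dt <= 0:
            raise StructureError("dt must be positive")
        for plant in tuple(self.hbond_schedule) + tuple(self.water_schedule):
            for a, b in plant.ranges:
                if not (0 <= a < b <= self.n_frames):
                    raise StructureError(
                        f"schedule range ({a}, {b}) outside "
                        f"[0, {self.n_frames})"
                    )
        for name, sigma in dict(self.fluctuation_sigmas).items():
            if sigma < 0:
                raise StructureError(f"negative sigma for atom {name!r}")
        labels = [p.label for p in self.hbond_schedule]
        if len(set(labels)) != len(labels):
            raise StructureError("duplicate hydrogen-bond labels in schedule")
        object.__setattr__(self, "hbond_schedule", tuple(self.hbond_schedule))
        object.__setattr__(self, "water_schedule", tuple(self.water_schedule))


@dataclass
class ToyComplexTruth:
    """Planted ground truth of :func:`make_toy_complex`."""

    hbond_triplets: dict      # label -> (donor, hydrogen, acceptor) indices
    hbond_presence: dict      # label -> bool array (n_frames,)
    site_positions: dict      # site -> (3,) Angstrom
    site_anchor_index: dict   # site -> pocket anchor atom index
    site_occupants: dict      # site -> per-frame residue_id or None
    water_resids: dict        # water label -> residue_id
    alignment_indices: np.ndarray
    nucleotide: tuple         # (chain, residue_id) of the flipped residue
    methyl_atoms: tuple       # (carbon_name, (h1, h2, h3))
    backbone_indices: np.ndarray
    sigmas: np.ndarray        # per-atom fluctuation sigma (Angstrom)


def _ranges_to_mask(ranges, n_frames) -> np.ndarray:
    mask = np.zeros(n_frames, dtype=bool)
    for a, b in ranges:
        mask[a:b] = True
    return mask


def make_toy_complex(spec: ToyComplexSpec):
    """Build a toy pocket + nucleotide + waters system with planted truth.

    Returns ``(topology, trajectory, truth)``.  The geometry is engineered
    so that every scheduled hydrogen bond satisfies the default detection
    criteria exactly during its ranges and violates the distance criterion
    by more than one Angstrom outside them, and each scheduled water sits
    exactly at its site position during its ranges (parked far away
    otherwise).  Per-atom Gaussian jitter is added only for atoms named in
    ``fluctuation_sigmas``.  Output is a pure function of the spec
    (including its seed).
    """
    n_frames, dt = spec.n_frames, spec.dt
    plants = spec.hbond_schedule
    waters_sched = spec.water_schedule

    # feasibility: one water per site per frame, one site per water per frame
    site_frame: dict = {}
    water_frame: dict = {}
    for plant in waters_sched:
        mask = _ranges_to_mask(plant.ranges, n_frames)
        for k in np.flatnonzero(mask):
            key = (plant.site, int(k))
            if key in site_frame and site_frame[key] != plant.water:
                raise StructureError(
                    f"infeasible schedule: waters {site_frame[key]!r} and "
                    f"{plant.water!r} share site {plant.site} at frame {k}"
                )
            site_frame[key] = plant.water
            wkey = (plant.water, int(k))
            if wkey in water_frame and water_frame[wkey] != plant.site:
                raise StructureError(
                    f"infeasible schedule: water {plant.water!r} occupies "
                    f"two sites at frame {k}"
                )
            water_frame[wkey] = plant.site

    water_labels = sorted({p.water for p in waters_sched})
    site_ids = sorted({p.site for p in waters_sched})

    atoms: list[Atom] = []
    base: list[np.ndarray] = []

    def add(name, element, resname, resid, chain, charge, xyz, roles=()):
        atoms.append(
            _atom(len(atoms), name, element, resname, resid, chain,
                  charge, roles)
        )
        base.append(np.asarray(xyz, dtype=float))
        return len(atoms) - 1

    bonds: list[tuple] = []

    # --- pocket residue (chain P, resid 1) --------------------------------
    align_idx = [
        add("CA1", "C", "POC", 1, "P", 0.0, (0.0, 0.0, -20.0)),
        add("CA2", "C", "POC", 1, "P", 0.0, (12.0, 0.0, -20.0)),
        add("CA3", "C", "POC", 1, "P", 0.0, (0.0, 12.0, -20.0)),
    ]

    # planted-bond donors on a wide circle in the z = 0 plane
    n_bonds = len(plants)
    radius_d = max(25.0, 20.0 * max(n_bonds, 1) / (2.0 * math.pi))
    # D-H-A triangle: angle at H fixed, leg lengths fixed -> angle at D
    angle_h = math.radians(HBOND_ACTIVE_ANGLE)
    angle_a = math.asin(math.sin(angle_h) * HBOND_DH_LENGTH / HBOND_ACTIVE_DA)
    angle_d = math.pi - angle_h - angle_a

    donor_geoms = []  # (d_idx, h_idx, a_idx, d_pos, u)
    for k, plant in enumerate(plants):
        theta = 2.0 * math.pi * k / max(n_bonds, 1)
        u = np.array([math.cos(theta), math.sin(theta), 0.0])
        d_pos = radius_d * u
        h_pos = d_pos + HBOND_DH_LENGTH * (
            math.cos(angle_d) * u + math.sin(angle_d) * np.array([0.0, 0.0, 1.0])
        )
        d_idx = add(f"ND{k + 1}", "N", "POC", 1, "P", -0.31, d_pos,
                    roles={ROLE_DONOR})
        h_idx = add(f"HD{k + 1}", "H", "POC", 1, "P", 0.31, h_pos,
                    roles={ROLE_HYDROGEN})
        bonds.append((d_idx, h_idx))
        donor_geoms.append((plant, d_idx, h_idx, d_pos, u))

    # water-site anchor atoms
    radius_s = max(10.0, 8.0 * max(len(site_ids), 1) / (2.0 * math.pi))
    site_positions = {}
    site_anchor_index = {}
    for j, site in enumerate(site_ids):
        theta = 2.0 * math.pi * j / max(len(site_ids), 1)
        pos = np.array(
            [radius_s * math.cos(theta), radius_s * math.sin(theta), 15.0]
        )
        site_positions[site] = pos
        site_anchor_index[site] = add(
            f"SA{site}", "C", "POC", 1, "P", 0.0, pos
        )

    # filler carbons padding the pocket to ~20 atoms
    n_fill = max(0, 20 - len(atoms))
    for f in range(n_fill):
        add(f"CF{f + 1}", "C", "POC", 1, "P", 0.0,
            (-15.0 + 5.0 * f, -12.0, -20.0))

    # --- flipped nucleotide (chain D, resid 2) ----------------------------
    backbone_indices = []
    for j, name in enumerate(
        ("C4'", "P", "O1P", "O2P", "O5'", "C5'", "C3'", "O3'")
    ):
        element = name[0]
        backbone_indices.append(
            add(name, element, "5MC", 2, "D", 0.0,
                (-5.25 + 1.5 * j, 0.0, 8.0))
        )
    n1 = add("N1", "N", "5MC", 2, "D", 0.0, (0.0, 0.0, 5.0))
    c5 = add("C5", "C", "5MC", 2, "D", 0.0, (1.4, 0.0, 5.0))
    c5m = add("C5M", "C", "5MC", 2, "D", -0.27, (2.8, 0.0, 5.0))
    bonds.extend([(n1, c5), (c5, c5m)])
    h_dirs = [
        np.array([1.0, 0.0, 0.0]),
        np.array([-0.333, 0.943, 0.0]),
        np.array([-0.333, -0.471, 0.816]),
    ]
    methyl_h = []
    for j, direction in enumerate(h_dirs):
        h = add(f"H5{j + 1}", "H", "5MC", 2, "D", 0.09,
                np.array([2.8, 0.0, 5.0]) + 1.09 * direction,
                roles={ROLE_HYDROGEN})
        bonds.append((c5m, h))
        methyl_h.append(f"H5{j + 1}")

    # planted-bond acceptors live on the nucleotide residue
    acceptor_info = []
    for plant, d_idx, h_idx, d_pos, u in donor_geoms:
        a_idx = add(
            f"OA{len(acceptor_info) + 1}", "O", "5MC", 2, "D", -0.40,
            d_pos + HBOND_ACTIVE_DA * u, roles={ROLE_ACCEPTOR},
        )
        acceptor_info.append((plant, d_idx, h_idx, a_idx, d_pos, u))

    # --- waters (chain W) -------------------------------------------------
    water_resids = {}
    water_atoms = {}
    h1_off = np.array([0.9572, 0.0, 0.0])
    h2_off = np.array([-0.2399, 0.9266, 0.0])
    for i, label in enumerate(water_labels):
        resid = 101 + i
        park = np.array([-30.0 + 12.0 * i, 40.0, 40.0])
        o = add("OH2", "O", "HOH", resid, "W", -0.834, park,
                roles={ROLE_WATER, ROLE_DONOR, ROLE_ACCEPTOR})
        h1 = add("H1", "H", "HOH", resid, "W", 0.417, park + h1_off,
                 roles={ROLE_WATER, ROLE_HYDROGEN})
        h2 = add("H2", "H", "HOH", resid, "W", 0.417, park + h2_off,
                 roles={ROLE_WATER, ROLE_HYDROGEN})
        bonds.extend([(o, h1), (o, h2)])
        water_resids[label] = resid
        water_atoms[label] = (o, h1, h2, park)

    topology = Topology(atoms, bonds)
    base_coords = np.asarray(base)

    sigmas = np.zeros(topology.n_atoms)
    sigma_map = dict(spec.fluctuation_sigmas)
    for atom in topology.atoms:
        if atom.name in sigma_map:
            sigmas[atom.index] = float(sigma_map[atom.name])

    # presence masks
    hbond_presence = {
        plant.label: _ranges_to_mask(plant.ranges, n_frames)
        for plant, *_ in acceptor_info
    }
    water_masks: dict = {}
    for plant in waters_sched:
        by_site = water_masks.setdefault(plant.water, {})
        mask = _ranges_to_mask(plant.ranges, n_frames)
        if plant.site in by_site:
            by_site[plant.site] = by_site[plant.site] | mask
        else:
            by_site[plant.site] = mask

    rng = np.random.default_rng(spec.seed)
    frames = []
    for t in range(n_frames):
        coords = base_coords.copy()
        for plant, d_idx, h_idx, a_idx, d_pos, u in acceptor_info:
            da = HBOND_ACTIVE_DA if hbond_presence[plant.label][t] \
                else HBOND_INACTIVE_DA
            coords[a_idx] = d_pos + da * u
        for label, by_site in water_masks.items():
            o, h1, h2, park = water_atoms[label]
            pos = park
            for site, mask in by_site.items():
                if mask[t]:
                    pos = site_positions[site]
                    break
            coords[o] = pos
            coords[h1] = pos + h1_off
            coords[h2] = pos + h2_off
        jitter_idx = np.flatnonzero(sigmas > 0)
        if jitter_idx.size:
            coords[jitter_idx] += rng.normal(
                0.0, sigmas[jitter_idx][:, None], size=(jitter_idx.size, 3)
            )
        frames.append(Frame(coordinates=coords, time=t * dt))
    trajectory = Trajectory(frames, dt=dt)

    site_occupants = {}
    for site in site_ids:
        occ: list = [None] * n_frames
        for plant in waters_sched:
            if plant.site != site:
                continue
            mask = _ranges_to_mask(plant.ranges, n_frames)
            for k in np.flatnonzero(mask):
                occ[int(k)] = water_resids[plant.water]
        site_occupants[site] = occ

    truth = ToyComplexTruth(
        hbond_triplets={
            plant.label: (d_idx, h_idx, a_idx)
            for plant, d_idx, h_idx, a_idx, *_ in acceptor_info
        },
        hbond_presence=hbond_presence,
        site_positions=site_positions,
        site_anchor_index=site_anchor_index,
        site_occupants=site_occupants,
        water_resids=water_resids,
        alignment_indices=np.asarray(align_idx, dtype=int),
        nucleotide=("D", 2),
        methyl_atoms=("C5M", tuple(methyl_h)),
        backbone_indices=np.asarray(backbone_indices, dtype=int),
        sigmas=sigmas,
    )
    return topology, trajectory, truth


def make_energy_series(
    mean_el: float,
    mean_vdw: float,
    sd_el: float,
    sd_vdw: float,
    n: int,
    seed: int,
    dt: float = STUDY_FRAME_SPACING_PS,
    state_label: str = "bound",
):
    """Stationary Gaussian energy series with known population means.

    Frames are i.i.d. draws; times run ``dt, 2 dt, ..., n dt``.  Returns
    ``(series, truth)`` where the truth record stores the population
    means and standard deviations.
    """
    if n < 1:
        raise StructureError("n must be >= 1")
    if sd_el < 0 or sd_vdw < 0:
        raise StructureError("standard deviations must be >= 0")
    rng = np.random.default_rng(seed)
    v_el = mean_el + sd_el * rng.standard_normal(n)
    v_vdw = mean_vdw + sd_vdw * rng.standard_normal(n)
    series = EnergySeries(
        state_label=state_label,
        times=dt * np.arange(1, n + 1),
        v_el=v_el,
        v_vdw=v_vdw,
    )
    truth = {
        "mean_el": float(mean_el),
        "mean_vdw": float(mean_vdw),
        "sd_el": float(sd_el),
        "sd_vdw": float(sd_vdw),
        "n": int(n),
    }
    return series, truth


def make_fluctuation_trajectory(
    base: Frame,
    sigmas,
    n_frames: int,
    seed: int,
    dt: float = STUDY_FRAME_SPACING_PS,
):
    """Trajectory of i.i.d. Gaussian jitter around a base frame.

    ``sigmas`` is a scalar or per-atom array of per-coordinate standard
    deviations (Angstrom).  The truth record stores the closed-form
    expected RMSF, ``sigma * sqrt(3)`` per atom.
    """
    sig = np.broadcast_to(
        np.asarray(sigmas, dtype=float), (base.n_atoms,)
    ).copy()
    if np.any(sig < 0):
        raise StructureError("sigmas must be >= 0")
    rng = np.random.default_rng(seed)
    frames = []
    for t in range(n_frames):
        noise = rng.normal(0.0, 1.0, size=(base.n_atoms, 3)) * sig[:, None]
        frames.append(
            Frame(coordinates=base.coordinates + noise, time=t * dt)
        )
    truth = {
        "sigmas": sig,
        "expected_rmsf": sig * math.sqrt(3.0),
    }
    return Trajectory(frames, dt=dt), truth


# -- canned residue parameters --------------------------------------------

#: CHARMM-style serine hydroxyl charges (O -0.66 e, H +0.43 e) drive the
#: 5mC -> 5hmC charge transfer; the toy methyl uses C -0.27 e, H +0.09 e.
TOY_RTF = """\
* toy residue topology: methylated cytosine fragment, serine, water
*
RESI 5MC  0.00
ATOM N1   NN2  -0.13
ATOM C5   CN3   0.04
ATOM C5M  CN9  -0.27
ATOM H51  HN9   0.09
ATOM H52  HN9   0.09
ATOM H53  HN9   0.09
ATOM O2   ON1  -0.40
ATOM H1   HN2   0.49
BOND N1 C5  C5 C5M
BOND C5M H51  C5M H52  C5M H53
BOND N1 H1
DONO H1 N1
ACCE O2

RESI SER  0.00
ATOM N    NH1  -0.47
ATOM HN   H     0.31
ATOM CA   CT1   0.07
ATOM HA   HB    0.09
ATOM CB   CT2   0.05
ATOM HB1  HA    0.09
ATOM HB2  HA    0.09
ATOM OG   OH1  -0.66
ATOM HG1  H     0.43
BOND N HN  N CA  CA HA  CA CB
BOND CB HB1  CB HB2  CB OG  OG HG1
DONO HG1 OG
ACCE OG

RESI TIP3  0.00
ATOM OH2  OT  -0.834
ATOM H1   HT   0.417
ATOM H2   HT   0.417
BOND OH2 H1  OH2 H2
DONO H1 OH2
DONO H2 OH2
ACCE OH2
"""


def toy_rtf_text() -> str:
    """RTF-dialect text for the toy 5mC fragment, serine and water."""
    return TOY_RTF


def toy_residue_parameters() -> dict:
    """Parsed parameter tables of :func:`toy_rtf_text`."""
    return read_charge_topology(TOY_RTF)


# -- canned LIE study conditions ------------------------------------------

#: Population means (v_el, v_vdw in kcal/mol) for each complex, region and
#: state of the synthetic LIE study emulation.  The closed-form dG values
#: are -25.00 / -17.06 kcal/mol (whole complex, 5mC / 5hmC) and
#: -20.00 / -13.35 kcal/mol (15-Angstrom pocket region), i.e. planted
#: ddG = -7.94 (whole) and -6.65 (pocket) kcal/mol at alpha = 1,
#: beta = 0.5.  Per-frame SDs (el 110, vdw 15) put the 5-block standard
#: error at ~3.5 kcal/mol for 2000 analysed frames.
STUDY_ENERGY_MEANS = {
    "5mc": {
        "whole": {"bound": (-300.0, -80.0), "free": (-282.0, -66.0)},
        "pocket": {"bound": (-180.0, -60.0), "free": (-166.0, -48.0)},
    },
    "5hmc": {
        "whole": {"bound": (-295.0, -78.0), "free": (-282.94, -68.0)},
        "pocket": {"bound": (-176.0, -58.0), "free": (-166.65, -50.0)},
    },
}
STUDY_ENERGY_SDS = (110.0, 15.0)


def make_study_energy_series(seed: int, n_frames: int | None = None):
    """Bound/free energy series for both complexes and regions.

    Returns ``(series, truth)`` where ``series[complex][region][state]``
    is a full-length production series (57 ns at 5 ps spacing by default)
    and the truth record carries the planted means and closed-form
    dG / ddG values.  Restrict to the last 10 ns with
    :func:`flipsite.lie_energy.last_window` before averaging.
    """
    if n_frames is None:
        n_frames = int(round(STUDY_PRODUCTION_LENGTH_PS / STUDY_FRAME_SPACING_PS))
    sd_el, sd_vdw = STUDY_ENERGY_SDS
    seed_seq = np.random.SeedSequence(seed)
    children = seed_seq.spawn(8)
    series: dict = {}
    truth: dict = {"means": STUDY_ENERGY_MEANS, "sds": STUDY_ENERGY_SDS,
                   "delta_g": {}, "ddg": {}}
    k = 0
    for complex_label, regions in STUDY_ENERGY_MEANS.items():
        series[complex_label] = {}
        for region, states in regions.items():
            series[complex_label][region] = {}
            for state, (mean_el, mean_vdw) in states.items():
                child_seed = int(children[k].generate_state(1)[0] % (2**31))
                k += 1
                s, _t = make_energy_series(
                    mean_el, mean_vdw, sd_el, sd_vdw, n_frames,
                    seed=child_seed, state_label=state,
                )
                series[complex_label][region][state] = s
            b = states["bound"]
            f = states["free"]
            dg = 1.0 * (b[0] - f[0]) + 0.5 * (b[1] - f[1])
            truth["delta_g"].setdefault(complex_label, {})[region] = dg
    for region in ("whole", "pocket"):
        truth["ddg"][region] = (
            truth["delta_g"]["5mc"][region] - truth["delta_g"]["5hmc"][region]
        )
    return series, truth
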