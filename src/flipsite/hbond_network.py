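"""Geometric hydrogen-bond detection and occupancy timelines.

A hydrogen bond D-H...A is recorded when the donor-acceptor heavy-atom
distance is at or below ``max_da_distance`` and the D-H-A angle is at or
above ``min_dha_angle``, with H covalently bonded to D.  Pairs whose
donor and acceptor are within two covalent bonds of each other are
excluded (they cannot form a meaningful hydrogen bond).  The default
criteria (3.5 Angstrom, 120 degrees) follow the widely used geometric
convention; they are configurable and recorded in exported metadata,
since published analyses rarely state their exact cutoffs.

Bond identity across frames is keyed by the (donor, hydrogen, acceptor)
atom-index triplet, so a water molecule keeps its identity by residue
while it stays in the pocket.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, StructureError
from .structure_io import (
    ROLE_ACCEPTOR,
    ROLE_DONOR,
    ROLE_HYDROGEN,
    Frame,
    Topology,
    Trajectory,
)

#: Default donor-acceptor distance cutoff (Angstrom).
DEFAULT_MAX_DA_DISTANCE = 3.5
#: Default minimum donor-hydrogen-acceptor angle (degrees).
DEFAULT_MIN_DHA_ANGLE = 120.0


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond criteria."""

    max_da_distance: float = DEFAULT_MAX_DA_DISTANCE
    min_dha_angle: float = DEFAULT_MIN_DHA_ANGLE

    def __post_init__(self):
        if self.max_da_distance <= 0:
            raise ConfigurationError("max_da_distance must be positive")
        if not (0 < self.min_dha_angle <= 180):
            raise ConfigurationError("min_dha_angle must lie in (0, 180]")


@dataclass
class HBondTimeline:
    """Per-frame presence records for donor-H-acceptor triplets."""

    bonds: list            # list of (d, h, a) index triplets, sorted
    presence: np.ndarray   # bool, shape (n_bonds, n_frames)
    frame_times: np.ndarray
    labels: dict = field(default_factory=dict)  # triplet -> user alias
    criteria: HBondCriteria = field(default_factory=HBondCriteria)

    def __post_init__(self):
        self.presence = np.asarray(self.presence, dtype=bool)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.presence.shape != (len(self.bonds), len(self.frame_times)):
            raise StructureError(
                f"presence shape {self.presence.shape} does not match "
                f"{len(self.bonds)} bonds x {len(self.frame_times)} frames"
            )
        if len(set(self.bonds)) != len(self.bonds):
            raise StructureError("a bond may appear at most once in a timeline")

    @property
    def n_frames(self) -> int:
        return len(self.frame_times)

    @property
    def occupancies(self) -> np.ndarray:
        return self.presence.mean(axis=1)


def _pairs_within_two_bonds(topology: Topology) -> set:
    """All unordered atom pairs separated by <= 2 covalent bonds."""
    excluded = set()
    for i in range(topology.n_atoms):
        first = topology.neighbors(i)
        for j in first:
            excluded.add((min(i, j), max(i, j)))
            for k in topology.neighbors(j):
                if k != i:
                    excluded.add((min(i, k), max(i, k)))
    return excluded


def _donor_hydrogen_pairs(topology: Topology) -> list:
    pairs = []
    for atom in topology.atoms:
        if ROLE_DONOR not in atom.roles:
            continue
        for j in topology.neighbors(atom.index):
            if ROLE_HYDROGEN in topology.atoms[j].roles:
                pairs.append((atom.index, j))
    return pairs


def detect_hbonds(
    topology: Topology,
    frame: Frame,
    criteria: HBondCriteria | None = None,
) -> frozenset:
    """Detect hydrogen bonds in one frame.

    Returns a frozenset of (donor, hydrogen, acceptor) atom-index
    triplets.  Requires donor/hydrogen/acceptor role annotations on the
    topology and explicit hydrogens bonded to their donors.
    """
    if criteria is None:
        criteria = HBondCriteria()
    if frame.n_atoms != topology.n_atoms:
        raise StructureError(
            f"frame has {frame.n_atoms} atoms, topology {topology.n_atoms}"
        )
    if not any(atom.roles for atom in topology.atoms):
        raise ConfigurationError(
            "topology carries no donor/acceptor/hydrogen role annotations; "
            "merge a charge topology or use an annotated synthetic system"
        )
    acceptors = np.array(
        [a.index for a in topology.atoms if ROLE_ACCEPTOR in a.roles],
        dtype=int,
    )
    dh_pairs = _donor_hydrogen_pairs(topology)
    if acceptors.size == 0 or not dh_pairs:
        return frozenset()
    excluded = _pairs_within_two_bonds(topology)
    coords = frame.coordinates
    acc_xyz = coords[acceptors]
    found = []
    cos_min = np.cos(np.deg2rad(criteria.min_dha_angle))
    for d, h in dh_pairs:
        delta = acc_xyz - coords[d]
        dist = np.linalg.norm(delta, axis=1)
        mask = (dist <= criteria.max_da_distance) & (acceptors != d)
        if not np.any(mask):
            continue
        cand = acceptors[mask]
        hd = coords[d] - coords[h]
        ha = acc_xyz[mask] - coords[h]
        norm_hd = np.linalg.norm(hd)
        norm_ha = np.linalg.norm(ha, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            cos_ang = (ha @ hd) / (norm_ha * norm_hd)
        # angle >= min  <=>  cos(angle) <= cos(min)
        ang_ok = cos_ang <= cos_min + 1e-12
        for a, ok in zip(cand, ang_ok):
            if not ok or a == h:
                continue
            key = (min(d, int(a)), max(d, int(a)))
            if key in excluded:
                continue
            found.append((d, h, int(a)))
    return frozenset(found)


def hbond_timeline(
    trajectory: Trajectory,
    topology: Topology,
    criteria: HBondCriteria | None = None,
    selection=None,
    labels: dict | None = None,
) -> HBondTimeline:
    """Monitor hydrogen bonds over a trajectory.

    The timeline contains the union of per-frame detections; with a
    *selection*, only bonds with at least one participating atom in the
    selection are kept.  ``labels`` maps triplets to user-chosen integer
    aliases (occurrence-figure numbering is presentation metadata, never
    derived).
    """
    if criteria is None:
        criteria = HBondCriteria()
    if trajectory.n_frames == 0:
        raise StructureError("empty trajectory")
    sel = None if selection is None else set(np.asarray(selection, dtype=int).tolist())
    per_frame = []
    universe = set()
    for frame in trajectory:
        det = detect_hbonds(topology, frame, criteria)
        if sel is not None:
            det = frozenset(t for t in det if (set(t) & sel))
        per_frame.append(det)
        universe |= det
    bonds = sorted(universe)
    index = {b: i for i, b in enumerate(bonds)}
    presence = np.zeros((len(bonds), trajectory.n_frames), dtype=bool)
    for k, det in enumerate(per_frame):
        for b in det:
            presence[index[b], k] = True
    return HBondTimeline(
        bonds=bonds,
        presence=presence,
        frame_times=trajectory.times,
        labels=dict(labels or {}),
        criteria=criteria,
    )


def occupancy_summary(
    timeline: HBondTimeline,
    stable_threshold: float = 0.5,
) -> pd.DataFrame:
    """Per-bond occupancy fractions and the stable-bond flag.

    Occupancy is the fraction of frames in which the bond is present; a
    bond is *stable* when its occupancy is at or above
    ``stable_threshold``.  Returns a DataFrame with columns ``donor``,
    ``hydrogen``, ``acceptor``, ``label``, ``occupancy``, ``stable``,
    sorted by descending occupancy.
    """
    if not (0.0 <= stable_threshold <= 1.0):
        raise ConfigurationError("stable_threshold must lie in [0, 1]")
    occ = timeline.occupancies
    rows = []
    for (d, h, a), o in zip(timeline.bonds, occ):
        rows.append(
            {
                "donor": d,
                "hydrogen": h,
                "acceptor": a,
                "label": timeline.labels.get((d, h, a)),
                "occupancy": float(o),
                "stable": bool(o >= stable_threshold),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["donor", "hydrogen", "acceptor", "label", "occupancy", "stable"],
    )
    return df.sort_values("occupancy", ascending=False, kind="stable") \
             .reset_index(drop=True)


def _run_length_encode(mask: np.ndarray) -> str:
    """RLE of a boolean record, e.g. '0:10=absent,10:20=present,...'."""
    if mask.size == 0:
        return ""
    edges = np.flatnonzero(np.diff(mask.astype(int)))
    starts = np.concatenate(([0], edges + 1))
    stops = np.concatenate((edges + 1, [mask.size]))
    parts = [
        f"{s}:{e}={'present' if mask[s] else 'absent'}"
        for s, e in zip(starts, stops)
    ]
    return ",".join(parts)


def timeline_to_tsv(timeline: HBondTimeline, dest=None) -> str | None:
    """Export a timeline as TSV: triplet, label, occupancy, RLE presence."""
    rows = []
    for (d, h, a), occ, rec in zip(
        timeline.bonds, timeline.occupancies, timeline.presence
    ):
        rows.append(
            {
                "donor": d,
                "hydrogen": h,
                "acceptor": a,
                "label": timeline.labels.get((d, h, a)),
                "occupancy": occ,
                "presence_rle": _run_length_encode(rec),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["donor", "hydrogen", "acceptor", "label",
                 "occupancy", "presence_rle"],
    )
    df.attrs["criteria"] = (
        f"max_da_distance={timeline.criteria.max_da_distance} A, "
        f"min_dha_angle={timeline.criteria.min_dha_angle} deg"
    )
    header = (
        f"# hydrogen-bond timeline; criteria: {df.attrs['criteria']}\n"
    )
    text = header + df.to_csv(sep="\t", index=False)
    if dest is None:
        return text
    from pathlib import Path

    if isinstance(dest, (str, Path)):
        Path(dest).write_text(text)
    else:
        dest.write(text)
    return None


def occurrence_plot_table(timeline: HBondTimeline) -> pd.DataFrame:
    """Long-form (time_ps, bond_label) table of bond occurrences.

    One row per (frame, bond) pair in which the bond is present —
    the layout of an occurrence timeline plot, with each vertical line
    marking a single observed hydrogen bond.
    """
    rows = []
    for i, (d, h, a) in enumerate(timeline.bonds):
        label = timeline.labels.get((d, h, a), i + 1)
        times = timeline.frame_times[timeline.presence[i]]
        for t in times:
            rows.append({"time_ps": t, "bond_label": label})
    return pd.DataFrame(rows, columns=["time_ps", "bond_label"])
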