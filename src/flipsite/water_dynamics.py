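"""Water residency in the binding site and conserved-water sites.

A *conserved water* is a position in the pocket-aligned frame that is
persistently occupied, possibly by exchanging water molecules: site
identity is positional, not molecular.  Each frame is superposed onto the
first frame using the pocket-alignment atoms, water oxygen positions are
transformed into that common frame, and positions are clustered greedily
(densest position first, deterministic tie-breaks).  Sites with residency
at or above ``min_residency`` are reported, sorted by residency; a site
centroid can then be compared against a crystallographic reference water
by plain Euclidean distance in the same pocket frame.

Defaults — cluster radius 1.5 Angstrom, minimum residency 0.5, sites
defined by the water oxygen only — follow common hydration-site analysis
conventions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import StructureError
from .structure_io import (
    ROLE_WATER,
    Topology,
    Trajectory,
    WATER_RESIDUE_NAMES,
)
from .structural_metrics import superpose

DEFAULT_CLUSTER_RADIUS = 1.5
DEFAULT_MIN_RESIDENCY = 0.5


@dataclass
class WaterSite:
    """A persistently occupied water position in the pocket-aligned frame."""

    centroid: np.ndarray          # (3,) Angstrom, pocket frame
    residency: float              # fraction of frames occupied
    occupants: list               # per-frame water residue_id or None

    def __post_init__(self):
        self.centroid = np.asarray(self.centroid, dtype=float)
        if not np.all(np.isfinite(self.centroid)):
            raise StructureError("non-finite site centroid")
        if not (0.0 <= self.residency <= 1.0):
            raise StructureError(f"residency {self.residency} outside [0, 1]")

    @property
    def exchange_count(self) -> int:
        """Number of occupant-identity changes over occupied frames."""
        ids = [o for o in self.occupants if o is not None]
        return sum(1 for a, b in zip(ids, ids[1:]) if a != b)


def water_oxygen_indices(topology: Topology) -> list:
    """(atom_index, residue_id) for each water oxygen, in atom order.

    Waters are recognized by the ``water`` role or by residue name; the
    oxygen is the water atom whose element is O.
    """
    out = []
    for atom in topology.atoms:
        is_water = ROLE_WATER in atom.roles \
            or atom.residue_name in WATER_RESIDUE_NAMES
        if is_water and atom.element == "O":
            out.append((atom.index, atom.residue_id))
    return out


def site_water_occupancy(
    trajectory: Trajectory,
    topology: Topology,
    site_center,
    radius: float,
) -> list:
    """Per-frame sorted lists of water residue ids within the site.

    The site center is the geometric centroid of the ``site_center`` atom
    subset, recomputed each frame; a water counts when its oxygen lies
    within *radius* of that centroid.
    """
    if radius <= 0:
        raise StructureError("radius must be positive")
    center_idx = np.asarray(site_center, dtype=int)
    if center_idx.size == 0:
        raise StructureError("site_center selection is empty")
    waters = water_oxygen_indices(topology)
    if not waters:
        warnings.warn("no water residues in topology; occupancy lists empty")
        return [[] for _ in range(trajectory.n_frames)]
    o_idx = np.array([i for i, _r in waters], dtype=int)
    resids = np.array([r for _i, r in waters], dtype=int)
    out = []
    for frame in trajectory:
        centroid = frame.coordinates[center_idx].mean(axis=0)
        dist = np.linalg.norm(frame.coordinates[o_idx] - centroid, axis=1)
        out.append(sorted(resids[dist <= radius].tolist()))
    return out


def conserved_water_sites(
    trajectory: Trajectory,
    topology: Topology,
    pocket_alignment,
    cluster_radius: float = DEFAULT_CLUSTER_RADIUS,
    min_residency: float = DEFAULT_MIN_RESIDENCY,
) -> list:
    """Identify conserved water sites in the pocket-aligned frame.

    Every frame is superposed onto frame 0 using the ``pocket_alignment``
    atom subset (>= 3 non-collinear atoms; degenerate sets raise).  All
    water-oxygen positions are pooled in that frame and clustered
    greedily: the position with the most neighbours within
    ``cluster_radius`` seeds a site (ties broken by earliest frame, then
    lowest atom index), member positions are consumed, and the procedure
    repeats.  A site's occupant in a frame is the member water nearest
    the centroid; residency is the fraction of frames with an occupant.
    """
    align_idx = np.asarray(pocket_alignment, dtype=int)
    waters = water_oxygen_indices(topology)
    if not waters:
        warnings.warn("no water residues in topology; no sites")
        return []
    ref = trajectory[0].coordinates[align_idx]
    n_frames = trajectory.n_frames

    points = []       # (3,) pocket-frame position
    meta = []         # (frame, atom_index, residue_id)
    for k, frame in enumerate(trajectory):
        result = superpose(ref, frame.coordinates[align_idx])
        for i, resid in waters:
            points.append(result.apply(frame.coordinates[i]))
        meta.extend((k, i, r) for i, r in waters)
    pts = np.asarray(points)
    meta = np.asarray(meta, dtype=int)

    remaining = np.ones(len(pts), dtype=bool)
    sites = []
    while np.any(remaining):
        idx = np.flatnonzero(remaining)
        sub = pts[idx]
        d = np.linalg.norm(sub[:, None, :] - sub[None, :, :], axis=2)
        counts = (d <= cluster_radius).sum(axis=1)
        best = counts.max()
        cand = np.flatnonzero(counts == best)
        # deterministic tie-break: earliest frame, then lowest atom index
        order = np.lexsort((meta[idx[cand], 1], meta[idx[cand], 0]))
        seed = cand[order[0]]
        members = idx[np.flatnonzero(d[seed] <= cluster_radius)]
        centroid = pts[members].mean(axis=0)
        occupants: list = [None] * n_frames
        best_dist = np.full(n_frames, np.inf)
        for m in members:
            k, _i, resid = meta[m]
            dist = float(np.linalg.norm(pts[m] - centroid))
            if dist < best_dist[k]:
                best_dist[k] = dist
                occupants[k] = int(resid)
        residency = sum(o is not None for o in occupants) / n_frames
        sites.append(
            WaterSite(centroid=centroid, residency=residency,
                      occupants=occupants)
        )
        remaining[members] = False
    sites = [s for s in sites if s.residency >= min_residency]
    sites.sort(key=lambda s: -s.residency)
    return sites


def compare_to_reference(site: WaterSite, reference_water) -> float:
    """Distance (Angstrom) from a site centroid to a reference water oxygen.

    Both must be expressed in the same pocket-aligned coordinate frame —
    the analogue of comparing a simulation's conserved water against the
    crystallographic water after superposition.
    """
    ref = np.asarray(reference_water, dtype=float)
    if ref.shape != (3,):
        raise StructureError(f"reference water must be (3,), got {ref.shape}")
    return float(np.linalg.norm(site.centroid - ref))


def site_report(sites, dest=None) -> str | None:
    """TSV report: centroid, residency, exchange count per site."""
    rows = [
        {
            "site": i,
            "x": s.centroid[0],
            "y": s.centroid[1],
            "z": s.centroid[2],
            "residency": s.residency,
            "exchange_count": s.exchange_count,
        }
        for i, s in enumerate(sites)
    ]
    df = pd.DataFrame(
        rows, columns=["site", "x", "y", "z", "residency", "exchange_count"]
    )
    text = df.to_csv(sep="\t", index=False, float_format="%.6f")
    if dest is None:
        return text
    from pathlib import Path

    if isinstance(dest, (str, Path)):
        Path(dest).write_text(text)
    else:
        dest.write(text)
    return None
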