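"""Rigid-body superposition, RMSD time series and RMSF profiles.

Superposition uses the Kabsch algorithm (SVD with sign correction so that
only proper rotations are returned — reflections would silently corrupt
RMSD).  RMSD series support distinct *fit* and *report* selections, which
is how terminal residues are excluded from the reported deviation while
the fit stays on the full backbone (or vice versa).  RMSF is
atom-positional by default; mass weighting is available but off, matching
the usual "atom-positional" convention for stability monitoring.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import StructureError
from .structure_io import Frame, Topology, Trajectory


@dataclass
class SuperpositionResult:
    """Optimal rigid transform mapping mobile onto reference coordinates.

    ``rotation`` is proper orthogonal (det = +1); the transform is
    ``x' = rotation @ x + translation``; ``rmsd`` is the minimum RMSD in
    Angstrom achieved by that transform.
    """

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, coordinates: np.ndarray) -> np.ndarray:
        return np.asarray(coordinates, dtype=float) @ self.rotation.T \
            + self.translation


def _check_not_collinear(coords: np.ndarray, weights: np.ndarray):
    center = np.average(coords, axis=0, weights=weights)
    centered = coords - center
    sv = np.linalg.svd(centered, compute_uv=False)
    scale = max(sv[0], 1.0)
    if sv.size < 2 or sv[1] <= 1e-8 * scale:
        raise StructureError(
            "reference coordinates are collinear (or coincident): the "
            "optimal rotation is not unique"
        )


def superpose(
    reference: np.ndarray,
    mobile: np.ndarray,
    weights: np.ndarray | None = None,
) -> SuperpositionResult:
    """Kabsch-optimal rigid superposition of *mobile* onto *reference*.

    Both inputs are (N, 3) arrays with N >= 3 and a non-collinear
    reference.  Optional per-atom *weights* produce the weighted-optimal
    transform and weighted RMSD.
    """
    ref = np.asarray(reference, dtype=float)
    mob = np.asarray(mobile, dtype=float)
    if ref.shape != mob.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise StructureError(
            f"coordinate shapes must match and be (N, 3), got "
            f"{ref.shape} vs {mob.shape}"
        )
    n = ref.shape[0]
    if n < 3:
        raise StructureError(f"superposition needs >= 3 atoms, got {n}")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise StructureError("weights must be non-negative with positive sum")
    _check_not_collinear(ref, w)

    wsum = w.sum()
    ref_c = np.average(ref, axis=0, weights=w)
    mob_c = np.average(mob, axis=0, weights=w)
    a = ref - ref_c
    b = mob - mob_c
    h = (b * w[:, None]).T @ a
    u, _s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    if d == 0:
        d = 1.0
    corr = np.diag([1.0, 1.0, d])
    rotation = vt.T @ corr @ u.T
    translation = ref_c - rotation @ mob_c
    moved = b @ rotation.T + ref_c
    diff = moved - ref
    rmsd = float(np.sqrt(np.sum(w[:, None] * diff**2) / wsum))
    return SuperpositionResult(rotation=rotation, translation=translation,
                               rmsd=rmsd)


def rmsd_value(
    reference: np.ndarray,
    mobile: np.ndarray,
    weights: np.ndarray | None = None,
) -> float:
    """Minimum RMSD between two coordinate sets (convenience wrapper)."""
    return superpose(reference, mobile, weights=weights).rmsd


def _indices(selection, n_atoms: int) -> np.ndarray:
    if selection is None:
        return np.arange(n_atoms)
    idx = np.asarray(selection, dtype=int)
    if idx.size == 0:
        raise StructureError("empty atom selection")
    if idx.min() < 0 or idx.max() >= n_atoms:
        raise StructureError(
            f"selection indices out of range for {n_atoms} atoms"
        )
    return idx


def rmsd_series(
    trajectory: Trajectory,
    reference: Frame,
    selection=None,
    fit_selection=None,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Per-frame RMSD (Angstrom) against *reference* after superposition.

    Each frame is superposed on ``fit_selection`` (default: the report
    selection) and the RMSD is reported over ``selection``.  Distinct
    selections implement subset semantics such as excluding mobile
    terminal residues from the reported deviation.
    """
    n = reference.n_atoms
    if trajectory.n_atoms != n:
        raise StructureError(
            f"trajectory has {trajectory.n_atoms} atoms, reference {n}"
        )
    sel = _indices(selection, n)
    fit = _indices(fit_selection, n) if fit_selection is not None else sel
    ref_fit = reference.coordinates[fit]
    ref_sel = reference.coordinates[sel]
    w_fit = None if weights is None else np.asarray(weights)[fit]
    out = np.empty(trajectory.n_frames)
    for k, frame in enumerate(trajectory):
        result = superpose(ref_fit, frame.coordinates[fit], weights=w_fit)
        moved = result.apply(frame.coordinates[sel])
        diff = moved - ref_sel
        if weights is None:
            out[k] = np.sqrt(np.mean(np.sum(diff**2, axis=1)))
        else:
            w = np.asarray(weights, dtype=float)[sel]
            out[k] = np.sqrt(np.sum(w[:, None] * diff**2) / w.sum())
    return out


def rmsf(
    trajectory: Trajectory,
    selection=None,
    window: tuple | None = None,
    topology: Topology | None = None,
    per_residue: bool = False,
    align: bool = True,
):
    """Per-atom root-mean-square fluctuation (Angstrom) over a frame window.

    ``window`` is a (start, stop) frame-index range, half-open, defaulting
    to the whole trajectory; it must span at least two frames.  Frames are
    first superposed on *selection* onto the window's first frame (disable
    with ``align=False`` for pre-aligned input), then
    ``rmsf_i = sqrt(mean_t |x_i(t) - <x_i>|^2)``.  With
    ``per_residue=True`` (requires *topology*), returns a dict mapping
    (chain, residue_id) to the mean RMSF over that residue's selected
    atoms.
    """
    n = trajectory.n_atoms
    sel = _indices(selection, n)
    start, stop = window if window is not None else (0, trajectory.n_frames)
    if not (0 <= start < stop <= trajectory.n_frames):
        raise StructureError(
            f"window {window} outside trajectory of {trajectory.n_frames} frames"
        )
    if stop - start < 2:
        raise StructureError("rmsf window must span at least 2 frames")
    coords = trajectory.coordinates[start:stop][:, sel, :]
    if align:
        ref = coords[0]
        aligned = np.empty_like(coords)
        aligned[0] = ref
        for k in range(1, coords.shape[0]):
            aligned[k] = superpose(ref, coords[k]).apply(coords[k])
        coords = aligned
    mean = coords.mean(axis=0)
    fluct = np.sqrt(np.mean(np.sum((coords - mean) ** 2, axis=2), axis=0))
    if not per_residue:
        return fluct
    if topology is None:
        raise StructureError("per_residue RMSF requires a topology")
    by_atom = dict(zip(sel.tolist(), fluct))
    out = {}
    for res in topology.residues:
        values = [by_atom[i] for i in res.atom_indices if i in by_atom]
        if values:
            out[(res.chain, res.residue_id)] = float(np.mean(values))
    return out
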