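"""Pairwise nonbonded energies and Linear Interaction Energy estimates.

The binding free energy of a ligand is approximated by the linear
interaction energy (LIE) model,

    dG = alpha * (<V_el>_bound - <V_el>_free)
       + beta  * (<V_vdw>_bound - <V_vdw>_free),

where <V_el> and <V_vdw> are trajectory averages of the ligand's
electrostatic and van-der-Waals interaction energies with its
surroundings in the bound state (ligand with protein + solvent) and the
free state (ligand with solvent alone).  Under the linear response
approximation the weights are alpha = 1 and beta = 0.5.

Pair energies are computed in direct space with a CHARMM-style switching
function (default switch-on 12 Angstrom, cutoff 14 Angstrom) — LIE
conventionally uses pairwise-decomposable direct-space energies; Ewald
reciprocal-space terms cannot be attributed to a group pair.  Conventions
pinned for reproducibility: Coulomb constant 332.0636 kcal*A/(mol*e^2);
Lorentz-Berthelot/CHARMM combining, Rmin_ij = Rmin_i/2 + Rmin_j/2 and
eps_ij = sqrt(eps_i * eps_j).

Uncertainties are attached by block averaging (5 blocks by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, StructureError
from .structure_io import EnergySeries, Frame, Topology, Trajectory

#: Coulomb constant in kcal*Angstrom/(mol*e^2), CHARMM convention.
COULOMB_CONSTANT = 332.0636

#: Atom names of the DNA backbone used for flipped-state restraints.
DNA_BACKBONE_ATOM_NAMES = (
    "C4'", "P", "O1P", "O2P", "O5'", "C5'", "C3'", "O3'",
)

DEFAULT_ALPHA = 1.0
DEFAULT_BETA = 0.5


@dataclass(frozen=True)
class NonbondedScheme:
    """Direct-space nonbonded scheme: cutoff/switching and dielectric."""

    cutoff: float = 14.0
    switch_start: float = 12.0
    dielectric: float = 1.0
    combining_rule: str = "lorentz-berthelot-charmm"

    def __post_init__(self):
        if not (0 < self.switch_start < self.cutoff):
            raise ConfigurationError(
                f"need 0 < switch_start < cutoff, got "
                f"{self.switch_start} / {self.cutoff}"
            )
        if self.dielectric <= 0:
            raise ConfigurationError("dielectric must be positive")
        if self.combining_rule != "lorentz-berthelot-charmm":
            raise ConfigurationError(
                f"unknown combining rule {self.combining_rule!r}"
            )


def switching_function(r, scheme: NonbondedScheme):
    """CHARMM switching function S(r): 1 below switch_start, 0 beyond cutoff.

    Between the two radii,
    S = (roff^2 - r^2)^2 (roff^2 + 2 r^2 - 3 ron^2) / (roff^2 - ron^2)^3,
    which is continuous (with continuous first derivative) at both ends.
    """
    r = np.asarray(r, dtype=float)
    ron2 = scheme.switch_start**2
    roff2 = scheme.cutoff**2
    r2 = r**2
    mid = (roff2 - r2) ** 2 * (roff2 + 2.0 * r2 - 3.0 * ron2) \
        / (roff2 - ron2) ** 3
    s = np.where(r2 <= ron2, 1.0, np.where(r2 >= roff2, 0.0, mid))
    return s if s.ndim else float(s)


def nonbonded_interaction(
    topology: Topology,
    frame: Frame,
    group_a,
    group_b,
    scheme: NonbondedScheme | None = None,
) -> tuple:
    """Electrostatic and van-der-Waals interaction energy between two groups.

    Returns ``(v_el, v_vdw)`` in kcal/mol, each pair term multiplied by the
    switching function.  Groups must be disjoint and fully parameterized
    (charges and LJ parameters on every atom).  A pair closer than 0.1
    Angstrom raises — that is a clash, most likely duplicated atoms.
    """
    if scheme is None:
        scheme = NonbondedScheme()
    ia = np.asarray(group_a, dtype=int)
    ib = np.asarray(group_b, dtype=int)
    if ia.size == 0 or ib.size == 0:
        raise StructureError("interaction groups must be non-empty")
    if set(ia.tolist()) & set(ib.tolist()):
        raise StructureError("interaction groups overlap")
    for idx in np.concatenate([ia, ib]):
        atom = topology.atoms[int(idx)]
        if atom.charge is None or atom.lj_epsilon is None \
                or atom.lj_rmin_half is None:
            raise StructureError(
                f"atom {atom.name} (index {atom.index}) lacks charge/LJ "
                f"parameters"
            )
    coords = frame.coordinates
    qa = np.array([topology.atoms[int(i)].charge for i in ia])
    qb = np.array([topology.atoms[int(i)].charge for i in ib])
    ea = np.array([topology.atoms[int(i)].lj_epsilon for i in ia])
    eb = np.array([topology.atoms[int(i)].lj_epsilon for i in ib])
    ra = np.array([topology.atoms[int(i)].lj_rmin_half for i in ia])
    rb = np.array([topology.atoms[int(i)].lj_rmin_half for i in ib])

    delta = coords[ia][:, None, :] - coords[ib][None, :, :]
    r = np.linalg.norm(delta, axis=2)
    if np.any(r < 0.1):
        k = np.argwhere(r < 0.1)[0]
        raise StructureError(
            f"clash: atoms {int(ia[k[0]])} and {int(ib[k[1]])} are "
            f"{r[k[0], k[1]]:.3f} A apart (< 0.1 A; duplicated atom?)"
        )
    s = switching_function(r, scheme)
    v_el = float(
        np.sum(
            COULOMB_CONSTANT * np.outer(qa, qb) / (scheme.dielectric * r) * s
        )
    )
    eps_ij = np.sqrt(np.outer(ea, eb))
    rmin_ij = ra[:, None] + rb[None, :]
    ratio6 = (rmin_ij / r) ** 6
    v_vdw = float(np.sum(eps_ij * (ratio6**2 - 2.0 * ratio6) * s))
    return v_el, v_vdw


def interaction_series(
    trajectory: Trajectory,
    topology: Topology,
    group_a,
    group_b,
    scheme: NonbondedScheme | None = None,
    window: tuple | None = None,
    state_label: str = "bound",
) -> EnergySeries:
    """Per-frame interaction energies between two groups over a time window.

    ``window`` is a ps range ``(t_start, t_stop]``, half-open on the left,
    defaulting to the whole trajectory.  Window and scheme are recorded in
    the series metadata.
    """
    if scheme is None:
        scheme = NonbondedScheme()
    times = trajectory.times
    if window is None:
        mask = np.ones(len(times), dtype=bool)
    else:
        t0, t1 = window
        mask = (times > t0) & (times <= t1)
        if not np.any(mask):
            raise StructureError(
                f"window ({t0}, {t1}] ps overlaps no trajectory frames"
            )
    sel = np.flatnonzero(mask)
    v_el = np.empty(sel.size)
    v_vdw = np.empty(sel.size)
    for out_k, k in enumerate(sel):
        v_el[out_k], v_vdw[out_k] = nonbonded_interaction(
            topology, trajectory[int(k)], group_a, group_b, scheme
        )
    meta = {
        "scheme": {
            "cutoff_A": scheme.cutoff,
            "switch_start_A": scheme.switch_start,
            "dielectric": scheme.dielectric,
            "combining_rule": scheme.combining_rule,
            "coulomb_constant": COULOMB_CONSTANT,
        },
    }
    if window is not None:
        meta["window_ps"] = (float(window[0]), float(window[1]))
    return EnergySeries(
        state_label=state_label,
        times=times[mask],
        v_el=v_el,
        v_vdw=v_vdw,
        metadata=meta,
    )


def last_window(times, duration_ps: float) -> tuple:
    """The half-open ps window covering the last *duration_ps* of *times*.

    E.g. the conventional "average over the last 10 ns" of an equilibrated
    series: ``last_window(series.times, 10_000.0)``.
    """
    t = np.asarray(times, dtype=float)
    if t.size == 0:
        raise StructureError("empty time array")
    return (float(t[-1] - duration_ps), float(t[-1]))


@dataclass
class LIEResult:
    """LIE estimate: state averages, weights, dG and block-average SE."""

    alpha: float
    beta: float
    mean_v_el_bound: float
    mean_v_vdw_bound: float
    mean_v_el_free: float
    mean_v_vdw_free: float
    delta_g: float
    n_frames_used: int
    window: tuple | None = None
    se_delta_g: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        expected = (
            self.alpha * (self.mean_v_el_bound - self.mean_v_el_free)
            + self.beta * (self.mean_v_vdw_bound - self.mean_v_vdw_free)
        )
        if abs(expected - self.delta_g) > 1e-9:
            raise StructureError(
                f"stored delta_g {self.delta_g} violates the LIE identity "
                f"(expected {expected})"
            )


def _check_finite(series: EnergySeries, what: str):
    for name, arr in (("v_el", series.v_el), ("v_vdw", series.v_vdw)):
        bad = np.flatnonzero(~np.isfinite(arr))
        if bad.size:
            raise StructureError(
                f"{what} series: non-finite {name} at frame {int(bad[0])} "
                f"(t = {series.times[int(bad[0])]} ps)"
            )


def _block_means(arr: np.ndarray, n_blocks: int) -> np.ndarray:
    n = len(arr)
    usable = n - (n % n_blocks)
    return arr[:usable].reshape(n_blocks, -1).mean(axis=1)


def lie_delta_g(
    bound: EnergySeries,
    free: EnergySeries,
    alpha: float = DEFAULT_ALPHA,
    beta: float = DEFAULT_BETA,
    n_blocks: int = 5,
) -> LIEResult:
    """LIE binding free energy from bound- and free-state energy series.

    dG = alpha * (<V_el>_b - <V_el>_f) + beta * (<V_vdw>_b - <V_vdw>_f).
    The standard error of dG is estimated by block averaging with
    ``n_blocks`` contiguous blocks per series.
    """
    if len(bound) == 0 or len(free) == 0:
        raise StructureError("bound and free series must be non-empty")
    _check_finite(bound, "bound")
    _check_finite(free, "free")
    mean_el_b = float(bound.v_el.mean())
    mean_vdw_b = float(bound.v_vdw.mean())
    mean_el_f = float(free.v_el.mean())
    mean_vdw_f = float(free.v_vdw.mean())
    delta_g = alpha * (mean_el_b - mean_el_f) + beta * (mean_vdw_b - mean_vdw_f)

    se = None
    nb = min(n_blocks, len(bound), len(free))
    if nb >= 2:
        dg_blocks = (
            alpha * (_block_means(bound.v_el, nb) - _block_means(free.v_el, nb))
            + beta * (_block_means(bound.v_vdw, nb) - _block_means(free.v_vdw, nb))
        )
        se = float(np.std(dg_blocks, ddof=1) / np.sqrt(nb))

    window = bound.metadata.get("window_ps")
    return LIEResult(
        alpha=alpha,
        beta=beta,
        mean_v_el_bound=mean_el_b,
        mean_v_vdw_bound=mean_vdw_b,
        mean_v_el_free=mean_el_f,
        mean_v_vdw_free=mean_vdw_f,
        delta_g=float(delta_g),
        n_frames_used=len(bound) + len(free),
        window=window,
        se_delta_g=se,
        metadata={
            "n_blocks": nb,
            "bound_state_label": bound.state_label,
            "free_state_label": free.state_label,
        },
    )


@dataclass
class DeltaDeltaG:
    """Difference of LIE binding free energies between two complexes."""

    delta_g_5mc: float
    delta_g_5hmc: float
    ddg: float
    region_label: str

    def __post_init__(self):
        if abs(self.ddg - (self.delta_g_5mc - self.delta_g_5hmc)) > 1e-9:
            raise StructureError("stored ddg violates ddg = dG_5mC - dG_5hmC")


def ddg(
    result_5mc: LIEResult,
    result_5hmc: LIEResult,
    region_label: str = "whole",
) -> DeltaDeltaG:
    """ddG = dG(5mC complex) - dG(5hmC complex) for a region.

    Both results must share alpha and beta; ``region_label`` (e.g.
    ``whole`` vs ``pocket``) is propagated verbatim.
    """
    if result_5mc.alpha != result_5hmc.alpha \
            or result_5mc.beta != result_5hmc.beta:
        raise ConfigurationError(
            f"mismatched LIE weights: ({result_5mc.alpha}, {result_5mc.beta}) "
            f"vs ({result_5hmc.alpha}, {result_5hmc.beta})"
        )
    return DeltaDeltaG(
        delta_g_5mc=result_5mc.delta_g,
        delta_g_5hmc=result_5hmc.delta_g,
        ddg=result_5mc.delta_g - result_5hmc.delta_g,
        region_label=region_label,
    )


def pocket_selection(
    topology: Topology,
    frame0: Frame,
    target_residue: tuple,
    cutoff: float = 15.0,
) -> np.ndarray:
    """Whole residues within *cutoff* of the target residue in frame 0.

    A residue is included when any of its atoms lies within *cutoff* of
    any target-residue atom in the starting conformation; the selection is
    fixed thereafter.  The target residue itself is always included
    (distance 0).
    """
    chain, resid = target_residue
    target = topology.residue(chain, resid)  # raises if absent
    target_xyz = frame0.coordinates[list(target.atom_indices)]
    out = []
    for res in topology.residues:
        xyz = frame0.coordinates[list(res.atom_indices)]
        d = np.linalg.norm(
            xyz[:, None, :] - target_xyz[None, :, :], axis=2
        )
        if d.min() <= cutoff:
            out.extend(res.atom_indices)
    return np.asarray(sorted(out), dtype=int)


def flipped_backbone_selection(topology: Topology, dna_chains) -> np.ndarray:
    """Atoms of the DNA backbone restraint set within the given chains.

    Selects exactly the atoms named C4', P, O1P, O2P, O5', C5', C3', O3'
    (the set restrained harmonically to keep separately simulated DNA in
    the flipped state).  An empty result is logged as a warning, not an
    error — e.g. when a protein chain is passed.
    """
    if isinstance(dna_chains, str):
        dna_chains = {dna_chains}
    chains = set(dna_chains)
    names = set(DNA_BACKBONE_ATOM_NAMES)
    out = [
        a.index for a in topology.atoms
        if a.chain in chains and a.name in names
    ]
    if not out:
        warnings.warn(
            f"no DNA backbone atoms found in chain(s) {sorted(chains)}"
        )
    return np.asarray(out, dtype=int)


def restraint_spec(
    topology: Topology,
    selection,
    force_constant: float | None = None,
    dest=None,
) -> str | None:
    """Emit a restraint selection as two-column index/name text.

    The force constant column is a placeholder unless given (kcal/mol/A^2).
    """
    fc = "FC_PLACEHOLDER" if force_constant is None else f"{force_constant:g}"
    lines = ["# index\tatom_name\tforce_constant"]
    for i in np.asarray(selection, dtype=int):
        lines.append(f"{int(i)}\t{topology.atoms[int(i)].name}\t{fc}")
    text = "\n".join(lines) + "\n"
    if dest is None:
        return text
    from pathlib import Path

    if isinstance(dest, (str, Path)):
        Path(dest).write_text(text)
    else:
        dest.write(text)
    return None
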