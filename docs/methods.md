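# Methods

This note documents the models and procedures implemented in `flipsite`,
the defaults they use, the synthetic data they are validated against, and
the design choices made where conventions genuinely diverge.

## Coordinate and unit model

Distances are Å, energies kcal/mol, times ps, charges elementary-charge
units, masses amu.  Atom indices are 0-based internally; residue ids are
kept verbatim from source files (PDB is 1-based).  Lennard-Jones well
depths are stored as non-negative magnitudes; files using the CHARMM
negative-sign convention are normalized on ingest.  Unicode prime
characters in nucleotide atom names (`C4′`) are mapped to the ASCII
apostrophe and the mapping is logged, since input files vary.  Only
orthorhombic boxes are accepted; triclinic input raises an explicit
unsupported-format error.

Structure I/O is delegated to biotite (PDB), MDAnalysis (binary DCD) and
pandas (CSV/TSV tables).  The CHARMM-RTF-dialect reader
(`RESI`/`PRES`/`ATOM`/`BOND`/`DONO`/`ACCE`/`DELETE`) is implemented here.
Trajectory formats without trustworthy time stamps (DCD, multi-model PDB)
require an explicit frame spacing `dt`; the plain-text `xyz-csv` fallback
(`frame,time_ps,atom,x,y,z`, 17 significant digits) round-trips float64
coordinates exactly and is the recommended archival form for small
systems.

## Hydrogen-bond detection

A bond D–H⋯A is recorded per frame when

* d(D, A) ≤ `max_da_distance` (default 3.5 Å),
* ∠(D, H, A) ≥ `min_dha_angle` (default 120°),
* H is covalently bonded to D, and
* D and A are separated by more than two covalent bonds.

The defaults are the widely used geometric convention; published analyses
rarely state their exact criteria, so both parameters are configurable
and recorded in exported metadata rather than guessed.  Distances are
computed without periodic imaging (the complex is assumed kept whole); a
minimum-image mode is deliberately out of scope.  Bond identity across
frames is the (donor, hydrogen, acceptor) atom-index triplet, so a water
keeps its identity by residue while resident in the pocket.  Occupancy is
the fraction of frames a bond is present; a bond is "stable" at occupancy
≥ `stable_threshold` (default 0.5).  Integer bond labels as they appear
in occurrence figures are user-supplied aliases, never derived —
published numbering schemes are figure-specific.

Correctness is established against an exhaustive triplet-enumeration
oracle (no spatial pruning, independent graph-distance computation via
networkx) with exact set equality on random ≤ 200-atom systems.

## Conserved waters

A conserved water is a *position*, not a molecule: a pocket-frame
location persistently occupied by possibly exchanging waters.  Every
frame is superposed onto frame 0 using a user-chosen pocket-alignment
atom set (≥ 3 non-collinear atoms); water-oxygen positions are pooled in
that common frame and clustered greedily — the position with the most
neighbours within `cluster_radius` (default 1.5 Å) seeds a site, ties
broken by earliest frame then lowest atom index for determinism; member
positions are consumed and the procedure repeats.  A site's occupant in a
frame is its nearest member water; residency is the fraction of occupied
frames, and sites below `min_residency` (default 0.5) are dropped.
Site centroids are compared to a reference (e.g. crystallographic) water
by plain Euclidean distance in the same pocket frame.  Binding-site
occupancy monitoring uses a sphere (default 3.5 Å) around the per-frame
centroid of a site-defining atom subset; the radius is a package default,
configurable, since "in and around the binding site" has no canonical
numeric definition.

## Superposition, RMSD, RMSF

Superposition is the Kabsch algorithm via SVD with the determinant sign
correction, so only proper rotations are returned — an unguarded SVD can
return a reflection and silently corrupt RMSD.  Collinear or
near-collinear references (second singular value ≤ 1e-8 of the largest)
are rejected.  The implementation is cross-checked in the tests against
MDAnalysis's quaternion-based QCP method to 1e-8 and against a large
random-rotation search as an optimality bound.

RMSD series superpose each frame on a *fit* selection and report over a
possibly different selection; that is how terminal residues are excluded
from the reported deviation ("subset" curves) without changing the fit.
Which residues count as terminal is a user-supplied list — there is no
robust structural definition.  RMSF aligns the frames of the requested
window to the window's first frame, then computes
`rmsf_i = sqrt(mean_t |x_i(t) − ⟨x_i⟩|²)`; per-residue profiles average
over residue atoms.  Mass weighting exists but is off by default,
matching the atom-positional convention of stability monitoring.

## 5mC → 5hmC residue patch

CHARMM-style parameters exist for 5-methylcytosine but not for
5-hydroxymethylcytosine.  The patch builder:

1. locates the methyl group (carbon bonded to exactly three hydrogens)
   in the 5mC residue parameters and deletes its *first* hydrogen in
   declaration order (the choice is geometric bookkeeping only; parameter
   content is unaffected),
2. adds an O–H pair bonded C–O–H whose charges *and atom types* are
   copied byte-for-byte from a serine hydroxyl (oxygen bonded to exactly
   one hydrogen, first match in declaration order),
3. shifts the residual charge uniformly over the CH₂ carbon and its two
   remaining hydrogens, so the residue's net charge is conserved exactly
   (asserted to 1e-12 e).

"Adjust the CH₂ charges accordingly" admits several schemes; the uniform
shift is the smallest perturbation confined to the chemically modified
group and is therefore the package's choice.  The patch is applied either
at the parameter level or to an in-memory topology, and can be emitted as
a CHARMM `PRES` block for diffing against published residue topology
tables.  Applying a patch twice fails fast (the deleted hydrogen is
gone), as does addressing it to a residue of the wrong name.

## Nonbonded energies and LIE

Interaction energies between two disjoint atom groups are direct-space
pair sums:

* electrostatics: `332.0636 · q_i q_j / (ε r) · S(r)`,
* Lennard-Jones: `ε_ij [(R_ij/r)¹² − 2 (R_ij/r)⁶] · S(r)` with CHARMM
  combining (`R_ij = Rmin_i/2 + Rmin_j/2`, `ε_ij = √(ε_i ε_j)`),
* `S(r)` the CHARMM switching function, 1 below 12 Å, 0 beyond 14 Å
  (both radii configurable; continuity is verified by numeric scan).

Ewald summation is deliberately not used: LIE conventionally works with
pairwise-decomposable direct-space energies, and reciprocal-space terms
cannot be attributed to a group pair.  The scheme, including the pinned
Coulomb constant, is recorded in all output metadata.  Pairs closer than
0.1 Å raise a clash error (almost always duplicated atoms).

`lie_delta_g` takes bound- and free-state energy series, averages each
component, and applies α = 1, β = 0.5 (linear response defaults).  Time
windows are half-open ps intervals `(t_start, t_stop]`; `last_window`
implements the convention of averaging only the final, equilibrated
stretch of a production run — for a 57 ns series sampled every 5 ps, the
last 10 ns is exactly 2000 frames.  The standard error is estimated by
block averaging with 5 contiguous blocks by default; with n blocks the
block SE is an estimator of σ/√n_frames, which the tests verify scales as
1/√n across two decades.  ΔΔG is the difference of two LIE estimates with
identical weights; the pocket region is all residues with any atom within
15 Å of any flipped-nucleotide atom in the starting conformation, fixed
thereafter.  The flipped-state restraint selection is exactly the atoms
named C4′, P, O1P, O2P, O5′, C5′, C3′, O3′ in the DNA chains.

## Competition-assay quantification

For each replicate, the bound-DNA-per-protein ratio of substrate x is
`(fluor_x / calib_x) / (protein_fluor / calib_protein)`.  Label bias is
removed by dividing by the ratios of a control experiment that used
same-sequence substrates with swapped labels; this *ratiometric* model is
the minimal correction consistent with removing label/detection
efficiency differences — the exact algebraic form used in any given lab
is rarely printed, so the assumption is flagged in every output.  The
corrected pair is normalized by its sum, giving relative ratios in [0, 1]
summing to one; replicates are summarized as mean ± sample SD (n − 1).
The invariants (sum-to-one, label-swap antisymmetry, control
idempotence) hold exactly and are property-tested.

## Synthetic data: what it emulates and what it does not

`make_toy_complex` builds a ~20-atom pocket, a flipped nucleotide with a
patchable methyl group and the 8 named backbone atoms, and scheduled
waters.  Scheduled hydrogen bonds are planted at donor–acceptor distance
2.9 Å and D–H–A angle 165° during their frame ranges, and the acceptor
retreats to 4.6 Å outside them — both comfortably clear of the default
criteria, so recovery tests never sit on a criterion boundary.  Scheduled
waters sit exactly at their site positions, parked > 10 Å away otherwise.
Frame spacing defaults to 5 ps, the interval at which hydrogen bonds and
pocket waters are monitored; the default toy run is 200 frames (1 ns
equivalent), chosen so the full test suite runs in seconds.  Optional
per-atom Gaussian jitter with known σ feeds the closed-form RMSF
expectation σ√3.

`make_study_energy_series` emulates the LIE comparison at study scale:
57 ns of 5 ps-spaced frames per state, analysed over the last 10 ns
(2000 frames).  The published comparison reports only the ΔΔG values
(−7.94 kcal/mol whole-complex, −6.65 kcal/mol pocket) and a ~3–4 kcal/mol
uncertainty, never the per-state averages, so the generator plants
per-state population means whose closed form reproduces those ΔΔG values
and per-frame SDs (110 kcal/mol electrostatic, 15 kcal/mol
van-der-Waals) that put the 5-block standard error of each ΔG near
3.5 kcal/mol.  A single estimate of ΔΔG from these series therefore
scatters by ~5 kcal/mol across seeds — that is the point: the emulation
reproduces the stated precision of the method, not a sharpened version
of it.

What the synthetic systems do **not** emulate: solvent at scale,
correlated (non-i.i.d.) frame-to-frame dynamics, periodic boundary
effects, realistic chemistry of the pocket, or conformational
transitions.  Passing tests demonstrate that the *analysis* is correct
and exactly recovers planted signals; they say nothing about force-field
accuracy or sampling convergence on real trajectories.

## Numerical choices and degenerate inputs

* Coulomb constant pinned to 332.0636 kcal·Å/(mol·e²) for
  bit-reproducibility.
* Greedy water clustering tie-breaks: earliest frame, then lowest atom
  index.
* Superposition rejects < 3 atoms and collinear references; RMSF rejects
  windows shorter than 2 frames; empty trajectories and empty selections
  raise rather than return empty results.
* `EnergySeries` permits NaN at construction so that the LIE estimator
  can reject it with an error naming the offending frame; the CSV reader
  enforces finiteness at the boundary instead.
* Truncated final trajectory frames are dropped with a logged warning;
  mid-stream atom-count mismatches are hard errors.

## Known limitations

* No periodic-image distance mode in hydrogen-bond or water analysis.
* The RTF reader covers the residue-topology subset needed here, not
  full CHARMM stream files (no `MASS`/`IC`/`CMAP` semantics).
* LIE block averaging assumes stationarity of the analysed window; the
  window choice is the user's responsibility.
* The pocket selection is fixed from the starting conformation by
  design; residues drifting in or out during a run do not update it.
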