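# Methods

`rrmagg` implements the computational analyses used to characterize
oligomerization of the tandem RNA-recognition-motif domains (RRM1–RRM2,
residues 102–267) of TDP-43: interface interaction occupancies, MM-PBSA
energy bookkeeping, geometric descriptors, dynamical cross-correlation maps,
and the repeatable-superimposing construction that grows periodic helical
aggregates from overlapping tetramers.  The package analyses coordinate
ensembles; it does not run molecular dynamics, docking, or
Poisson–Boltzmann solvers.

## Data model

A multi-model PDB file stands in for an MD trajectory: one `MODEL` block per
frame, identical atom identities throughout (`StructureEnsemble`).  Author
residue numbering is preserved verbatim so residue citations (Asp174,
Lys176, …) mean the same thing everywhere.  Hydrogens are first-class atoms:
the hydrogen-bond and ionic criteria need them, and structures lacking them
produce criterion-specific warnings or errors rather than silent
approximations.  Alternate locations other than blank/"A" are dropped with
a warning; single-frame files are written without `MODEL` records.
Coordinates are Å, angles degrees, energies kcal/mol throughout.

Secondary structure and interface edges are *supplied*, never computed: an
annotation table maps residue ranges to (domain, SSE, edge).  The four edges
follow the shoulder/head taxonomy of the RRM12 monomer — `head-1` the α1/α2
helix face of RRM1, `head-2` the β-sheet tail of RRM2, `shoulder12-β` the
β-sheet-layer face, `shoulder12-α` the α-linker plus RRM2 α2.  The shipped
default ranges for RRM12 are an interpretation of the verbal edge
definitions; the file format makes them fully replaceable.

## Interaction criteria and occupancies

A hydrogen bond requires donor–acceptor distance < 3.5 Å **and**
donor–proton–acceptor angle > 120° for at least one attached proton; a
hydrophobic contact requires a side-chain C–C distance < 4.5 Å between
apolar residues; an ionic interaction requires < 5.0 Å between the
side-chain HN group of Arg/Lys and a carboxylate O of Asp/Glu.  All
inequalities are strict, as conventionally printed; the boundary tests
assert exclusion at equality (for the angle via a realized-threshold probe,
since an exactly-120° float geometry is not stably constructible).

Donor/acceptor chemistry (which N/O/S atoms donate or accept per residue
type) is a module-level table of standard amino-acid chemistry, editable by
users.  Chemically equivalent protons (Lys HZ1–3, Arg HH11–22) collapse into
wildcard groups (`HZ*`, `HH*`), so an H-bond that alternates protons within
a group counts as one event across frames.  Event identity is
(kind, partner-atom/group identifiers); occupancy is the percentage of
frames in which the criterion holds; per-interface totals are exact sums of
the reported events of one kind and may exceed 100%.  The default reporting
floor is 20% (matching the smallest occupancies listed in the published
tables) and can be set to 0.  All frames are used; no stride.

Missing side-chain protons on a basic residue demote the ionic criterion to
an N–O distance at the same cutoff, flagged `approximate` in the output.

## Energy bookkeeping

The MM-PBSA combination algebra is

    ΔG_np      = ΔE_vdw + ΔG_np/solv
    ΔG_pb      = ΔE_ele + ΔG_pb/solv
    ΔH_binding = ΔG_np + ΔG_pb + ΔE_int
    ΔG_binding = ΔH_binding − TΔS

with TΔS stored as the printed product (never split into T and ΔS).  The
package performs no PB/SA computation by design: it is a bookkeeping and
validation layer for precomputed components.

Published tables print values rounded to 2 decimals, so a derived cell
recomputed from k printed inputs can legitimately differ from its printed
value by up to 0.005·k (plus 0.005 for its own rounding).  The consistency
checker uses exactly this slack: a cell is *consistent* when it matches
within the accumulated print-rounding bound, and anything beyond is flagged
with its magnitude — never corrected.  Two checks run per model: every
derived quantity against the raw components, and the printed chain
ΔG = ΔH(printed) − TΔS.  On the packaged reference table for the five dimer
binding modes this flags the two shoulder-to-head columns (printed ΔH − TΔS
≠ printed ΔG) and the transposed ΔG_np/ΔG_pb rows of the three weaker
models, while the two shoulder-to-shoulder columns and the head-to-head
ΔG_binding reproduce exactly.

Crucial residues of a per-residue decomposition are those contributing more
than 2 kcal/mol of binding energy, i.e. decomposition values strictly below
−2 kcal/mol, sorted strongest-first.

## Geometry

Helix axes are estimated by PCA of the Cα trace refined by a cylinder fit
(minimizing the variance of radial distances to the axis), which removes the
tilt bias plain PCA picks up from incomplete helical turns; axes are
oriented N→C.  Inter-helix angles are reported on the full [0, 180°] range
(obtuse crossings like 104.3° are not folded to ≤ 90°).  Mass-centre
distances are unweighted centroid separations by default, with a
mass-weighted option.  The "β-sheet layer" of a monomer is the Cα set of
the annotated β1–β5 strands of RRM1 (configurable), and the layer distance
of a dimer is the centroid separation of the two monomers' layers.

Dimer-mode classification counts inter-monomer residue pairs with any
heavy-atom contact below 4.5 Å (the hydrophobic cutoff, reused because no
separate classification cutoff is established), attributes each contacting
residue to its annotated edge, and labels the dimer by the dominant
edge–edge pair: SαSβ and SβSβ (shoulder-to-shoulder), SβH1α1-like and
SβH1α2-like (shoulder-to-head), H1H1 (head-to-head).  The α1/α2 refinement
of shoulder-to-head modes is decided by which helix dominates the head-1
side of the interface — a package convention, since the published mode names
are not derivable from contacts alone.  No inter-monomer contacts →
`unclassified`.

## Superposition, fluctuations, correlations

Rigid superposition is Kabsch's SVD solution with determinant correction,
cross-checked in the test suite against an independent closed-form
quaternion (Horn) oracle to 1e-9.  RMSF uses Cα as the representative atom
(a backbone option exists) after two passes of fitting every frame to the
ensemble mean.  The DCCM is

    C_ij = ⟨Δr_i·Δr_j⟩ / sqrt(⟨|Δr_i|²⟩ ⟨|Δr_j|²⟩)

over one representative atom (Cα) per residue, with optional superposition
onto the ensemble mean first.  Zero-variance atoms get zero off-diagonal
correlation (diagonal 1) with a warning.  Superposition before DCCM is a
toggle: it is what one wants for real trajectories containing rigid drift,
but for synthetic ensembles without drift the fitting itself induces
spurious correlations (a displaced block drags the optimal rotation), so
the parameter-recovery tests run with fitting off and rigid-motion
invariance is tested separately with fitting on.

## Screw decomposition and assembly propagation

Any rigid transform decomposes into a rotation by
angle = arccos((trace R − 1)/2) about an axis plus a signed rise along it.
The axis direction follows the right-hand rule for positive angle (the rise
carries the sign — flipping the axis would invert the rotation); a point on
the axis solves (I − R)p = t⊥.  For angle → 0 the axis defaults to the
normalized translation (or +z for the identity), keeping the degenerate
limit continuous.  Recomposition reproduces the source transform to < 1e-6 Å
on test points.

The repeatable-superimposing builder merges two assemblies by Kabsch-fitting
the Cα atoms of a designated shared unit (whole-atom option available),
deleting every duplicated unit (Cα RMSD below `dedup_rmsd_tol`, default
1.0 Å), and concatenating the rest in aggregation-axis order.  Merges and
propagations run a clash census — heavy-atom contacts below 2.5 Å between
non-adjacent units — and fail (or warn, if requested) on any hit.  Both
tolerances are explicit parameters because no published values exist for
them; imperfect periodicity between real tetramers must be reconciled by an
explicit tolerance choice, not a guess.  Chains are re-lettered A, B, C, …
on flattening, with a provenance map back to source units, and every
construction appends the transform and shared-unit RMSD to a log that is
emitted as JSON next to the output PDB.

The two-path octamer construction grows either rightward (path 1: the left
dimer of the second tetramer overlaps the right end of the growing
assembly) or leftward (path 2), one merge per step until the target size.
For consistent periodic seeds the two paths produce congruent assemblies —
reproduced on synthetic ground truth to RMSD < 0.1 Å — and for a seed whose
β-layer plane contains the screw-axis direction the layer normal stays
perpendicular to the aggregation axis at every unit (the cross-β geometry
of amyloid-like fibrils).

## Synthetic data

The generator provides every input the analyses need, with a known answer
planted behind each one:

* **Toy monomer** — a Cα trace of residues 102–267 with ideal-geometry SSEs
  (helix rise 1.5 Å / twist 100° / radius 2.3 Å; strand rise 3.3 Å; strand
  spacing 4.8 Å — textbook values, stated as generator constants).  The
  shape is an elongated slab whose four edges are extremal in distinct
  directions, so planted interfaces are unambiguous.  Loops are interpolated
  between SSE anchors.
* **Dimers** — a second copy placed by a known rigid transform.  Planted
  interactions add minimal side-chain proxy atoms (one donor/acceptor/
  charged group per planted residue, with the residue renamed to a matching
  amino-acid type) positioned so that the target distance/angle is met
  exactly in the noise-free structure; a planting that would need a proxy
  more than ~8 Å from its Cα (an implied backbone distortion beyond 1 Å) is
  an error.  Planted hydrogen bonds use an uncharged Gln→Asn pair so they
  never double as ionic events.  `make_dimer_for_mode` orients a chosen edge
  pair face-to-face, pushes the units to a 6.5 Å minimum Cα separation
  (too far for accidental contacts), and plants proxy contacts only between
  the facing edge residues.
* **Ensembles** — base structure plus iid Gaussian noise per atom
  (σ default 0.1 Å), shared latent displacements per correlation block, and
  per-frame Bernoulli(p) toggling of planted interactions (the contact atom
  is displaced 6 Å beyond the cutoff in absent frames).  A ground-truth
  manifest records every planted presence series and block membership.  All
  randomness flows from one seed; identical seeds give byte-identical PDB
  output.
* **Periodic tetramers** — (D, S·D) and (S·D, S²·D) for a screw step S with
  nonzero rise: the exact overlapping-seed precondition of the two-path
  construction.

What the generator does *not* emulate: force-field sampling, rotamer
chemistry, correlated backbone dynamics beyond shared-latent blocks, or the
structural strain of real docked oligomers.  Passing the recovery suite
therefore demonstrates that the analysis machinery measures what was
planted, not that real TDP-43 trajectories would yield any particular
value; published MD-derived numbers (layer distances, RMSF profiles,
interface energies) require the original trajectories and are out of reach
by construction.

## Problem sizes and numerical choices

Parameter-recovery checks run at the sizes their statistics need: planted
occupancy at 500 frames (binomial 3σ ≈ 5% at p = 0.84), occupancy
convergence at 10⁴ frames (|error| < 1.5%), DCCM block contrast at 5000
frames (within-block > 0.8 from latent σ 0.3 Å over noise σ 0.1 Å, i.e. an
expected per-axis correlation of 0.09/0.10), RMSF closed form (σ√3) at 10⁴
frames within 2%.  Superposition tolerances: identity/recovery to 1e-9,
screw recomposition to 1e-6 Å, assembly periodicity to 1e-6.  The toy
monomer ensembles keep the whole default test run and the acceptance script
in the seconds-to-minutes range on one CPU.

## Known limitations

* The annotation-supplied SSE/edge model cannot follow secondary-structure
  changes along a trajectory (the published analyses report such changes
  qualitatively; detecting them is out of scope).
* The hydrogen-bond chemistry table covers the 20 standard amino acids;
  modified residues need table edits.
* `classify_dimer_mode` assumes exactly two annotated units; higher
  oligomers must be classified interface by interface.
* Interaction scanning is O(candidates²) per frame — fine for interface
  selections, not intended for all-against-all scans of large complexes.
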