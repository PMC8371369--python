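# rrmagg

Analysis toolkit for oligomerization of the tandem RNA-recognition-motif
domains (RRM1–RRM2) of TDP-43, the protein whose amyloid-like aggregation is
implicated in ALS and FTLD.  Given coordinate ensembles (multi-model PDB
files standing in for MD trajectory snapshots) and residue annotations, the
package:

* classifies **dimer binding modes** from interface edge contacts
  (shoulder-to-shoulder SαSβ/SβSβ, shoulder-to-head SβH1α1/SβH1α2,
  head-to-head H1H1);
* detects **hydrogen bonds** (D–A < 3.5 Å, D–H–A > 120°), **hydrophobic
  contacts** (C–C < 4.5 Å) and **ionic interactions** (Arg/Lys HN to
  Asp/Glu O < 5.0 Å) and reports per-event **occupancies** — the percentage
  of frames in which each criterion holds — plus per-interface totals;
* does **MM-PBSA bookkeeping**: ΔG_np = ΔE_vdw + ΔG_np/solv,
  ΔG_pb = ΔE_ele + ΔG_pb/solv, ΔH = ΔG_np + ΔG_pb + ΔE_int,
  ΔG = ΔH − TΔS, with a consistency checker that validates published
  component tables against this algebra (flagging, never repairing,
  defective cells) and a per-residue decomposition filter (crucial residues
  contribute < −2 kcal/mol);
* computes **geometric descriptors** (helix axes and crossing angles,
  mass-centre distances, β-sheet-layer separations, per-residue RMSF,
  **dynamical cross-correlation maps** C_ij = ⟨Δr_i·Δr_j⟩/√(⟨Δr_i²⟩⟨Δr_j²⟩));
* grows **periodic helical assemblies** with the repeatable-superimposing
  method: Kabsch-superpose a shared building unit of two overlapping
  oligomers, delete the duplicate, iterate — and reports the screw
  parameters (aggregation axis, twist and rise per unit) of the resulting
  rope-like aggregate.

Every analysis is validated by parameter recovery on seeded synthetic
structures whose geometry, occupancies, correlations and transforms are
planted with known values (`rrmagg.synthetic`).

## Worked example

```python
import numpy as np
import rrmagg as r

# a synthetic RRM12-like monomer with annotated edges, and a dimer whose
# interface contacts are planted between the two β-sheet-layer edges
monomer, ann = r.make_toy_monomer(r.GeneratorSpec(seed=0))
dimer, dann = r.make_dimer_for_mode(monomer, ann, "shoulder12-β", "shoulder12-β")
mode = r.classify_dimer_mode(dimer, dann)
print("mode:", mode.label, "/", mode.group)

# a 500-frame ensemble with one hydrogen bond planted at 84% occupancy
# and one salt bridge at 55%
tr = r.RigidTransform(np.eye(3), np.array([0.0, -12.0, 0.0]))
planted = [r.PlantedInteraction("hbond", 108, 108, 3.4, 150.0, p=0.84),
           r.PlantedInteraction("ionic", 132, 132, 4.8, p=0.55)]
d2, _ = r.make_dimer(monomer, ann, tr, planted)
ens, truth = r.make_ensemble(d2, r.NoiseModel(sigma=0.02), 500, seed=11)
totals = r.occupancy_scan(ens, r.CriteriaConfig(),
                          (r.select(ens.topology, "chain A"),
                           r.select(ens.topology, "chain B")),
                          min_occupancy=0.0)
for e in totals.events:
    print(e.kind, e.partner_a[2:], e.partner_b[2:], round(e.occupancy, 1))
```

prints

```
mode: SβSβ / shoulder-to-shoulder
hbond ('GLN', 'NE2-HE21') ('ASN', 'OD1') 83.6
ionic ('ASP', 'O*') ('LYS', 'HN*') 53.6
```

— the planted binding mode is recovered, and the measured occupancies are
the planted probabilities up to binomial sampling error at 500 frames
(83.6% vs p = 0.84; 53.6% vs p = 0.55).

Energy bookkeeping on the packaged reference table of MM-PBSA components
for the five TDP-43 RRM12 dimer models:

```python
from rrmagg.energetics import load_reference_components, COMPONENT_FIELDS
table = r.load_reference_components()
comp = r.EnergyComponents(*(float(table.loc["SaSb/D", f]) for f in COMPONENT_FIELDS))
d = r.derive_energies(comp)
print(f"dG_np={d.dG_np:.2f} dH={d.dH_binding:.2f} dG={d.dG_binding:.2f}")
# dG_np=-166.71 dH=-108.03 dG=-57.67   (kcal/mol)
```

The most stable mode (SαSβ, ΔG ≈ −57.7 kcal/mol) binds through the RRM1
β-sheet layers; `r.consistency_report(table)` additionally flags the two
shoulder-to-head columns of the reference table whose printed ΔH − TΔS does
not reproduce the printed ΔG.

## Command line

```
rrmagg generate --mode SbSb --frames 100 --out-prefix syn   # synthetic data + truth manifest
rrmagg classify syn.pdb --annotation syn.annotation.tsv
rrmagg interactions syn.pdb --chains A,B
rrmagg dccm syn.pdb
rrmagg energetics components.tsv
rrmagg assemble syn.pdb --units 6 --twist 25 --rise 60
rrmagg init-config && rrmagg run --config rrmagg.yaml         # full pipeline
```

## Layout

| module | contents |
| --- | --- |
| `rrmagg.core` | atoms/structures/ensembles, PDB I/O, selections, edge annotations |
| `rrmagg.superpose` | Kabsch, RMSD/RMSF, screw decomposition |
| `rrmagg.descriptors` | helix axes/angles, centroid and layer distances, dimer-mode classification |
| `rrmagg.interactions` | H-bond/hydrophobic/ionic criteria, occupancy scans |
| `rrmagg.correlations` | dynamical cross-correlation maps |
| `rrmagg.energetics` | MM-PBSA bookkeeping, consistency checking, decomposition filtering |
| `rrmagg.assembly` | repeatable-superimposing merges, propagation, two-path builds |
| `rrmagg.synthetic` | seeded generators with ground-truth manifests |
| `rrmagg.cli` | pipeline orchestration and the `rrmagg` command |

See `docs/methods.md` for the model conventions, tolerances and known
limitations.
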