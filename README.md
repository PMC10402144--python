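# alphared

Confidence-gated protein–protein docking: AlphaFold-style confidence
analysis, backbone-flexibility metrics, DockQ quality scoring, and a
temperature replica-exchange Monte Carlo docking engine with
pLDDT-directed flexible refinement.

## The problem

Structure predictors such as AlphaFold-multimer produce a complex model
together with a per-residue confidence, pLDDT ∈ [0, 100], stored in the
PDB B-factor column. The prediction of the *binding orientation* is often
wrong even when each monomer is accurate, and the per-residue confidence
turns out to carry the signal: averaging pLDDT over the interfacial
residues (any heavy atom within 8 Å of the partner) yields the
**interface-pLDDT**, a strong discriminator of docking quality. This
package implements a docking protocol built on that observation:

* **interface-pLDDT ≤ 85** — the predicted orientation is distrusted:
  randomize the ligand around the receptor, run a global rigid-body
  replica-exchange Monte Carlo search, cluster the sampled decoys to five
  diverse low-energy centers, then refine each center with flexible local
  docking;
* **interface-pLDDT > 85** — the orientation is trusted: run flexible
  local docking directly from the predicted coordinates.

During local docking, backbone moves are directed at the **mobile
residues** — contiguous runs with pLDDT < 80 — using backrub-style
rotations of a segment's interior about the axis through its anchor Cα
atoms, mixed 3:1 with small rigid-body moves (1 Å / 3°). Global docking
uses 8 trajectories of 4 Å / 8° rigid moves across three replicas at
inverse temperatures 1/1.5, 1/3 and 1/5 (kcal/mol)⁻¹ with periodic
temperature swaps.

Model quality is scored with the standard machinery of the field:

* **LDDT** (local distance difference test) — the superposition-free
  fraction of Cα–Cα distances (within a 10 Å inclusion radius in the
  reference) conserved to within 0.5 / 1 / 2 / 4 Å;
* **per-residue RMSD** between conformers after one global Kabsch
  superposition;
* **DockQ** = (f_nat + s(iRMSD, 1.5) + s(LRMSD, 8.5)) / 3 with
  s(x, d) = 1/(1 + (x/d)²), mapped to CAPRI categories
  (incorrect < 0.23 ≤ acceptable ≤ 0.49 < medium ≤ 0.8 < high).

Everything runs on plain PDB files; a built-in synthetic-fixture module
generates two-chain toy complexes with a planted bound pose, a
hinge-perturbed unbound conformer, and pLDDT correlated with the
displacement, so the whole pipeline is testable without any downloads.

## Worked example

```python
from alphared import *
from alphared.toys import ToyComplexSpec, generate_toy_complex
from alphared.pipeline import PipelineConfig, run_alphared

toy = generate_toy_complex(ToyComplexSpec(seed=1))   # bound / unbound / model
rep = confidence_report(toy.model, toy.partition)
print(f"interface-pLDDT {rep.interface_plddt:.1f} -> {rep.gate.value}")

report = run_alphared(toy.model, PipelineConfig(seed=7), native=toy.bound)
print(f"model DockQ {report.model_dockq.dockq:.3f} -> "
      f"refined DockQ {report.top_dockq.dockq:.3f}")
```

prints

```
interface-pLDDT 92.3 -> local_dock
model DockQ 0.891 -> refined DockQ 0.990
```

The fixture's model carries the unbound (hinge-swung) backbone at the
planted pose, so its interface is confident (92.3 > 85) and the pipeline
routes to local docking; pLDDT-directed backbone sampling then recovers
the bound hinge conformation, lifting DockQ from 0.891 (already high
quality) to 0.990. The same protocol from the shell:

```sh
alphared fixture --out fix --seed 1
alphared run fix/model.pdb --partition A_B --native fix/bound.pdb --out run1
alphared dockq fix/model.pdb fix/bound.pdb --partition A_B
```

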