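# helixswitch

Geometric and interfacial analysis of the G-protein **α5 helix-switch** at the
activated-GPCR interface.

Active G-protein-coupled receptors (R\*) catalyse GDP/GTP exchange in the Gα
subunit by repositioning the C-terminal α5 helix, whose far C-terminus (GαCT)
binds in the receptor's cytoplasmic crevice. Between the GDP-bound
intermediate complex (R\*·G<sup>GDP</sup>) and the nucleotide-free complex
(R\*·G<sup>empty</sup>), α5 undergoes a screw-like motion — a rotation of
about 60° around its own helix axis combined with a ~1.5 Å translation along
it — that shifts its contact register with the conserved receptor positions
(R<sup>3.50</sup> of the D(E)RY motif, the main-chain carbonyl at 3.54) by one
residue toward the C-terminus.

This package is for structural bioinformaticians and molecular modellers who
need to quantify that kind of helix repositioning from docking poses or MD
trajectories:

* **`model_io`** — multi-model PDB read/write (the trajectory format), an
  atom-selection language, and anchor-propagated Ballesteros–Weinstein generic
  numbering (`R131` ↦ `3.50`, `I135` ↦ `3.54`, …).
* **`geometry`** — Kabsch superposition; helix-axis fitting (total
  least-squares line through sliding 4-Cα centroids, rise and twist per
  residue); the restricted screw fit

  d = ⟨(x′ᵢ − xᵢ)·û⟩,  θ = atan2( Σᵢ û·(pᵢ × p′ᵢ), Σᵢ pᵢ·p′ᵢ )

  where û is the axis direction and pᵢ the axis-perpendicular components —
  the operational definition of "rotation about the helix axis"; and the free
  Chasles screw decomposition as a cross-check.
* **`pose_analysis`** — single-linkage clustering of pose ensembles at a
  fixed RMSD cut height (1.5 Å default), contact fingerprints, and
  register-based state assignment (`empty` vs `gdp_intermediate`, shift 0
  vs +1).
* **`interface_analysis`** — hydrogen bonds (3.5 Å / 120° heavy-atom
  geometry), cation-π contacts (ring centroid–cation ≤ 6 Å, face-on ≤ 45°),
  Shrake–Rupley buried and apolar-buried interface area, bridging interface
  waters.
* **`trajectory_metrics`** — receptor-frame alignment, rotation/RMSD/
  distance/tilt traces with running averages, and switch-event calling
  (persistent drop of the smoothed RMSD-to-target below 2 Å).
* **`synthetic`** — seeded generators for every input: ideal α-helical
  peptides, two-register interface scenes with waters, planted-switch
  trajectories with ground truth, and pose sets with planted clusters.
* **`pipeline` / `helixswitch` CLI** — the two workflows end to end.

## Worked example

Recover a planted screw motion:

```python
from helixswitch import (fit_helix_axis, screw_about_axis, select,
                         recompose, ScrewParameters)
from helixswitch.synthetic import build_ideal_helix

helix = build_ideal_helix()                      # ideal 11-mer, poly-Ala
axis = fit_helix_axis(select(helix, "name CA").coords)
print(f"rise  = {axis.rise_per_residue:.3f} A/residue")
print(f"twist = {axis.twist_per_residue:.2f} deg/residue")

switched = helix.with_coords(
    recompose(ScrewParameters(axis, 60.0, 1.5, 0.0)).apply(helix.coords))
sp = screw_about_axis(helix, switched, axis)
print(f"angle = {sp.angle:.3f} deg, slide = {sp.translation_along_axis:.3f} A, "
      f"residual = {sp.residual_rmsd:.2e} A")
```

```
rise  = 1.500 A/residue
twist = 99.62 deg/residue
angle = 60.000 deg, slide = 1.500 A, residual = 8.90e-16 A
```

The fitted axis reproduces canonical α-helix geometry (1.5 Å rise, ≈3.6
residues per turn), and the screw fit recovers the planted 60°/1.5 Å motion
to machine precision.

From the shell, generate a trajectory with a switch planted at 50 ns
(0.3 Å coordinate noise) and analyse it:

```bash
printf 'kind: switch_trajectory\nseed: 5\nn_frames: 120\nonset_time: 50\n' > demo.yaml
helixswitch simulate demo.yaml --out sim
helixswitch run-traj --traj sim/frames.pdb --ref sim/reference.pdb \
    --target sim/target.pdb --times sim/times.csv --anchors sim/anchors.csv \
    --out out
```

The switch report (`out/switch.json`) reads

```json
{"detected": true, "onset_time_ns": 49.0, "onset_index": 49, "final_state": "empty", ...}
```

— the event is called one frame before the planted onset (the smoothed
RMSD-to-target crosses the 2 Å threshold slightly ahead of the logistic
midpoint), and the end-of-trajectory contact fingerprint classifies the final
pose as the nucleotide-free (`empty`) register. `out/series.csv` holds the
tidy rotation/RMSD/tilt traces with running averages; the final rotation is
within noise of the planted 60°.

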