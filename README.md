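# peptifiber

Analysis pipeline for the self-assembly of aryl-appended tripeptides:
quantifying dimer association from molecular configurations, screening for
fibrillation-capable nucleation seeds, and constructing and characterizing
helical protofibers.

## Who this is for

Researchers studying peptide self-assembly who have molecular configurations
or trajectories of one or two labelled monomers (multi-model PDB or XYZ) and
want reproducible, testable answers to three questions: *how strongly do two
monomers associate and through which chemical regions*, *which dimer
configurations can nucleate a fiber*, and *what does the fiber built from
such a seed look like*. No molecular-dynamics engine is involved; the
package analyses geometry it is given, and ships a synthetic-data generator
that builds configurations with planted ground truth so every stage can be
verified end to end.

## The model

**Covered area.** Association between monomers 1 and 2 is measured through
solvent-accessible surface area (SASA, Shrake–Rupley sphere-point method).
For each atom of monomer *i*,

```
covered(atom) = SASA(atom | partner deleted) − SASA(atom | full dimer)
CA_i  = Σ_atoms covered(atom),      CA_T = CA_1 + CA_2
```

Each monomer's atoms are partitioned into an **aromatic region** (the Phe
side chain plus the appended aryl unit) and a **peptide region** (the Phe
backbone plus the Val and Asp residues), giving CA_i,a and CA_i,p with
CA_i = CA_i,a + CA_i,p + CA_i,other exactly. Dissociated frames give
CA_T = 0 exactly. 2D population maps of any two association coordinates
report percent of simulation time, with CA_T = 0 frames excluded and
book-kept separately.

**Seed screen.** A frame is a nucleation-seed candidate when nested
geometric filters pass: marker-carbon distances D1 < 0.6 nm and D2 < 0.6 nm
with CA_T,a > 2.5 nm²; additionally D3 < 0.8 nm; additionally both
intra-monomer ring-plane angles (Phe ring vs appended aryl ring, oriented
normals) inside 120° ± 20°. Occupancies are percent of total frames.

**Protofiber.** The seed dimer defines a screw transform (optimal rotation
superposition, then axis/angle/rise decomposition). Applying it n−1 times
stacks an n-monomer helical fiber whose pitch and periodicity follow
`pitch = rise · 360/|twist|`. Characterization: helix fit from monomer
centroids (cylinder-refined axis, azimuth/axial regression), a geometric
hydrogen-bond census (donor–acceptor ≤ 0.35 nm, D–H···A linearity deviation
≤ 25°), and per-residue-group solvent exposure of interior monomers
relative to the free monomer.

## Worked example

```python
from peptifiber import (GeneratorSpec, analyze_trajectory, classify_frames,
                        make_association_trajectory, make_fiber, build_fiber,
                        measure_helix, hbond_census)
from peptifiber.fiber import sequential_pair

# a 100-frame two-monomer trajectory; 27 frames planted in the
# aromatic-stacked seed geometry, the rest fully dissociated
spec = GeneratorSpec(seed=23, n_frames=100, contact_fraction=0.27)
traj, truth = make_association_trajectory(spec)
records = analyze_trajectory(traj)
report = classify_frames(records)
print(f"stage 1 (D1/D2/CATa): {report.fraction_d1d2:.1f}%")
print(f"+D3:                  {report.fraction_d3:.1f}%")
print(f"+ring angles:         {report.fraction_seed:.1f}%")

# build a 20-mer from a seed pair and characterize it
fiber, params, planted = make_fiber(GeneratorSpec(seed=31, noise_sigma=0.0))
built = build_fiber(sequential_pair(fiber, 1), 20)
pitch, per_turn = measure_helix(built)
backbone, other = hbond_census(built)
print(f"pitch {pitch:.3f} nm, {per_turn:.2f} monomers/turn, "
      f"{backbone} backbone H-bonds")
```

Output:

```
stage 1 (D1/D2/CATa): 27.0%
+D3:                  27.0%
+ring angles:         27.0%
pitch 2.200 nm, 6.00 monomers/turn, 19 backbone H-bonds
```

The three identical stage fractions say every planted contact frame passes
all three filters — the generator's aromatic-stack geometry is a full seed,
and the dissociated frames pass none. The built fiber reproduces the planted
screw parameters (rise 0.3667 nm, twist 60° → 2.2 nm pitch, 6 monomers per
turn) and one planted Val-N→Phe-O hydrogen bond per sequential pair.

The same run is available from the shell:

```
peptifiber synth assoc --seed 23 --n-frames 100 --contact-fraction 0.27 --out assoc
peptifiber analyze --traj assoc.pdb --config assoc.annot --out records.tsv
peptifiber seed-scan --records records.tsv --out seed_report.tsv
peptifiber run --config pipeline.toml --out outdir   # full pipeline from TOML
```

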