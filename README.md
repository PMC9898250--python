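# abctraj

Trajectory analysis for ABC-transporter molecular dynamics.

ABC exporters such as MRP1 alternate between inward-facing (IF) and
outward-facing (OF) conformations while two nucleotide-binding domains (NBDs)
dimerise around ATP. `abctraj` implements the analysis layer used to
characterise such simulations:

* **Conformational descriptors** — the intracellular (IC) and extracellular
  (EC) opening angles between centre-of-mass vectors over fixed
  half-transporter TMH groups, the NBD centre-of-mass distance, the signed NBD
  rocking-twist dihedral, the Walker-A-glycine/signature-serine Cα distances
  of the two nucleotide-binding sites, helix tilts, RMSD/RMSF and ABC-core
  PCA with per-domain motion shares, plus projection of structures and frames
  into the shared (IC angle, EC angle, NBD distance, NBD twist) space.
* **Free-energy landscapes** — Gaussian-mixture density estimation over
  descriptor pairs (EM capped at 20 iterations, K = 2…12 chosen by 3-fold
  cross-validated likelihood), an 80×80 grid of F = −kT ln p, and
  gradient-ascent core-state extraction with basin populations.
* **Pore profiles** — largest-inscribed-sphere radii per z-slab
  (radius(z) = max_c min_i(|c−r_i| − vdW_i)) with bootstrapped time series at
  fixed bilayer depths z = 18, 5, −15, −22 Å.
* **Membrane structure** — lipid tail order parameters
  S_CD = ⟨(3cos²θ−1)/2⟩, leaflet-resolved 2D densities, per-lipid
  protein-contact occupancies with 50 %/80 % hotspot thresholds, thickness
  fields, and a two-term continuum deformation free energy
  ΔG = ∫[(K_A/2)(2u/h₀)² + (K_C/2)(∇²u)²]dA.
* **Networks and allostery** — DCCM over Cα/coarse-node anchors, contact maps
  with same-residue/neighbour exclusions, Girvan–Newman communities, Gaussian
  mutual information (MI = −½ ln(1−ρ²)), and communication efficiency between
  residue sets as the effective conductance of the g = MI × contact resistor
  network, with per-node current betweenness decomposed by component class
  (protein / lipid / ligand) and segment. Lipids contribute three nodes each
  (head + two tails), ATP-like ligands three (purine, ribose, triphosphate),
  LTX-like substrates three (glutathione, tail, acid), sterols and ions one.
* **Interactions** — H-bond detection (donor–acceptor ≤ 3.5 Å and D–H···A
  angle ≥ 120°), truncated Coulomb/Lennard-Jones ligand–site potentials, and
  π-stacking centroid distances.
* **Synthetic systems** — pseudo-transporters, bilayers and ligands with
  *known* ground truth (prescribed descriptor targets, planted correlations,
  analytic tail order), so every estimator above is validated without running
  MD.

## Worked example

```python
from abctraj import TransporterSpec, make_transporter, make_trajectory
from abctraj import descriptors as desc

spec = TransporterSpec(ic_angle=30.0, ec_angle=10.0,
                       nbd_distance=40.0, nbd_twist=60.0)
topo, frame, scheme = make_transporter(spec)
traj = make_trajectory([(frame, 1.0)], n_frames=10000, noise_sigma=0.5, seed=1)

ic = desc.ic_angle(traj.coords, topo, scheme)
d, tw = desc.nbd_distance_and_twist(traj.coords, topo, scheme)
print(f"IC angle  {ic.mean():.3f} deg")
print(f"NBD dist  {d.mean():.3f} A,  twist {tw.mean():.3f} deg")
```

prints

```
IC angle  29.999 deg
NBD dist  40.001 A,  twist 60.003 deg
```

i.e. with 0.5 Å of per-atom thermal jitter over 10,000 frames, the descriptor
estimators recover the generator's build targets (30°, 40 Å, 60°) to a few
hundredths of their values — the sample means converge on the ground truth at
the expected 1/√n rate.

The same objects drive the CLI:

```sh
abctraj generate --out sys --seed 7 --frames 100
abctraj descriptors --traj sys.pdb --scheme sys.scheme.yaml --out desc.tsv
abctraj landscape   --traj sys.pdb --scheme sys.scheme.yaml --out land.tsv
```

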