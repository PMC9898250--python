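# Methods

## Scope and model of the data

`abctraj` analyses multi-frame Cartesian coordinate sets (Å) of an
ABC-transporter-like system: a protein with twelve transmembrane helices
(TMH1–12), two nucleotide-binding domains (NBD1/NBD2), a pre-TMH1 lasso
domain (L0) and four coupling helices, optionally embedded in a lipid bilayer
with bound ligands. Conventions: 1-based residue numbering; the membrane
normal is z with the bilayer centre at z = 0, located operationally as the
midpoint of the two phosphate-marker mean z values; boxes are orthorhombic
and inter-atomic distances use the minimal-image convention, while group
centres of mass (COMs) are taken on whole groups. Which residues constitute
each descriptor group is not hard-coded: a YAML *selection scheme* maps group
names (`tmh{1..12}_{ic,ec}`, `nbd1/2`, `nbd1_lobe/2_lobe`, `l0`, coupling
helices, binding-site sets, Gly/Ser anchor pairs) to residue ids, because
per-system selections differ between proteins.

## Conformational descriptors

* **IC angle** (substrate-entry opening): angle between two vectors from the
  COM of the whole extracellular region to the COMs of the IC regions of
  TMH{1,2,3,6,10,11} and TMH{4,5,7,8,9,12}.
* **EC angle / EC distance** (substrate-release opening): angle between
  vectors from the COM of both NBDs to the COMs of the EC regions of
  TMH{1,2,9,10,11,12} and TMH{3,4,5,6,7,8}; the EC distance is the distance
  between those two EC COMs. Exactly coincident EC halves return (0°, 0 Å).
* **NBD distance and rocking-twist**: COM distance of the two NBDs, and the
  signed dihedral COM(lobe1)–COM(NBD1)–COM(NBD2)–COM(lobe2), right-handed
  about the NBD1→NBD2 axis, in (−180°, 180°]. Lobe membership is a scheme
  entry defaulting to the N-terminal half of each NBD, since lobe definitions
  vary between studies.
* **NBS Gly–Ser distances**: Cα–Cα minimal-image distances pairing the
  Walker A glycine of one NBD with the ABC-signature serine of the other.
* COMs are mass-weighted by default (a flag disables weighting) and use
  backbone atoms (N, CA, C, O) of the selected residues; in the synthetic
  fixtures all pseudo-atoms carry 12 amu so weighted and geometric COMs
  coincide and descriptor math is isolated from mass bookkeeping.
* **Helix tilt**: angle between the largest-variance eigenvector of a helix's
  Cα cloud (oriented IC→EC) and the bilayer normal, folded to [0°, 90°]. For
  an ideal α-helix the principal axis deviates from the geometric axis by a
  residual that decays with helix length (≲0.5° at 37 residues); tests use
  helices long enough for that residual to be negligible.
* **Superposition** is a standard Kabsch fit with the sign correction that
  enforces a proper rotation. **RMSF** aligns each frame to the trajectory
  average, recomputes the average once, and measures √⟨|r_i − ⟨r_i⟩|²⟩.
  Fitting a rigid body absorbs 6 degrees of freedom, so on an N-atom body
  the recovered RMSF of isotropic jitter σ is σ√3·√(1 − 2/N); validation uses
  N large enough for this to vanish inside the tolerance.
* **PCA** acts on the ABC core (backbone of TMH1–12 + NBD1 + NBD2) after
  core superposition; explained variance is λ_k/Σλ and the per-domain share
  of a component is its summed squared loading over each domain's Cartesian
  triplets (TMD1, TMD2, NBD1, NBD2 shares sum to 1).

## Free-energy landscapes

2D descriptor samples are modelled with a Gaussian mixture: for each K in
[2, 12] an EM fit with seeded k-means++ initialisation, at most 20
iterations and covariance eigenvalues floored at 1e-6 is scored by 3-fold
cross-validated held-out log-likelihood; the best K is refitted on all
samples. Samples are put into a canonical lexicographic order first, making
the fit invariant to sample permutation. The landscape is F = −kT ln p on an
80×80 grid over user ranges, minimum shifted to 0, with cells below 1e-6 of
the peak density masked — the landscape only pictures the neighbourhood of
the sampled minima. kT defaults to reduced units (kT = 1); any factor (e.g.
0.616 kcal/mol at 310 K) rescales F linearly.

Core states are basins of steepest ascent on the density grid
(8-neighbourhood, cells visited in decreasing density; near-ties within a
1e-9 relative tolerance attach to the existing basin so that symmetric peaks
discretised onto the grid stay whole). Basins whose peak density is below 5 %
of the global peak merge into the strongest adjacent basin; populations are
basin density sums normalised over the unmasked region. This gradient-basin
rule is a deliberate simplification of inflection-point state-boundary
criteria; the two need not coincide on shallow shoulders.

Convergence of a descriptor series is assessed by equal contiguous block
averages; the series is flagged converged when the last two block means
differ by less than one pooled block standard deviation.

## Pore profiles

The pore radius at depth z is the radius of the largest sphere centred in
the slab: max over (x, y) of min_i(|c − r_i| − vdW_i), over heavy atoms
within ±7.5 Å of z. The maximisation is a deterministic multi-start compass
search (5 seeds: the previous slab's centre ± 2 Å offsets; step halving from
1 Å to 1e-4 Å), chosen over stochastic annealing for bitwise
reproducibility; radii are capped at 15 Å and flagged when the cap or an
empty slab is hit. Defaults: z-step 1 Å, vdW radii from the topology or the
bundled element table. Time evolution at fixed depths (18, 5, −15, −22 Å)
reports per-window means with bootstrap standard deviations over resampled
snapshots.

## Membrane analyses

S_CD(k) averages (3cos²θ − 1)/2 over frames, lipids and the hydrogens of
carbon k (θ against z). Leaflet assignment uses the head-marker z sign
relative to the bilayer centre at each frame, which handles flip-flop by
reassignment. 2D densities histogram the species marker (phosphate bead for
PC/PE, hydroxyl bead for sterols) per leaflet, normalised per Å² per frame,
so the grid integral equals the per-frame molecule count. Occupancy is the
fraction of frames a lipid keeps any heavy atom within 6 Å (default; the
threshold semantics, 50 %/80 %, are separate from the contact cutoff) of the
protein selection. Thickness is the distance between the two leaflets'
phosphate mean-z surfaces per xy cell; cells missing one leaflet are filled
from neighbours and flagged.

The deformation free energy is the two-term quadratic continuum functional
ΔG = ∫[(K_A/2)(2u/h₀)² + (K_C/2)(∇²u)²]dA with u = (h − h₀)/2, evaluated by
periodic central differences. Defaults K_A = 0.6 kcal·mol⁻¹·Å⁻²
(= 60 kcal·mol⁻¹·nm⁻²) and K_C = 2000 kcal·mol⁻¹·Å²
(= 20 kcal·mol⁻¹·nm²) are plausible fluid-bilayer moduli and are inputs, not
fitted constants. The functional is positive-definite, so ΔG ≥ 0 for any
non-flat field; negative "stabilisation" values only arise as differences
against a user-supplied reference energy, and are reported as exactly that.
The discrete Laplacian underestimates k² by ≈(kΔ)²/12, so quadrature
accuracy statements assume ≥ 18 cells per corrugation wavelength.

## Networks and allostery

Coarse nodes: one per protein residue anchored on Cα; three per phospholipid
(head + two tails, anchored on the phosphate bead and mid-tail carbons);
three per ATP-like ligand (purine, ribose, triphosphate) and LTX-like
substrate (glutathione, tail, acid); one per sterol or ion. DCCM is the
normalised anchor-displacement covariance; zero-variance nodes are zeroed
off-diagonal and logged. Contact maps count frames with any heavy-atom pair
within 4.5 Å (default), zeroing same-residue and sequence-neighbour pairs
(the standard notSameResidue/notNeighboring exclusions). Communities are
Girvan–Newman partitions (edge distance −log|C_ij| on the contact-filtered
graph, edges at contact ≥ 0.75) selected by maximum modularity, with the
connected-components partition included as a candidate so a cohesive graph
can remain one community.

Mutual information defaults to the Gaussian closed form
MI = −½ ln(1 − ρ²) with ρ the DCCM entry; a histogram estimator is available
behind a flag for non-Gaussian checks. Communication efficiency between a
source and a sink residue set treats g_ij = MI_ij × contact_ij as electrical
conductances: both sets are short-circuited into super-nodes, unit current
is injected, and the grounded graph Laplacian is solved within the source's
connected component (detached islands carry no current and would make the
system singular); efficiency is the effective conductance and each node's
betweenness is the total current through it, summable by component class and
segment. "Efficiency" has no universally printed formula in the allosteric
network literature; the effective-conductance definition used here is
self-consistent, exactly testable against Kirchhoff spanning-tree
enumeration, and monotone in every edge conductance.

## Interactions

H-bonds require donor–acceptor distance ≤ 3.5 Å **and** D–H···A angle
(vertex at the hydrogen — the vertex convention is a package choice) ≥ 120°;
both cutoffs are inclusive. Ligand–site Coulomb (k_e = 332.06
kcal·Å·mol⁻¹·e⁻², relative dielectric configurable) and Lennard-Jones sums
(Lorentz–Berthelot combination) truncate plainly at 10 Å with no switching —
they are comparative tools, not converged electrostatics. H-bond fractions
and energies are computed per replica and aggregated as mean ± sd over
replicas treated as independent samples.

## Synthetic systems: what they emulate and what they do not

The generators produce systems whose ground truth is known by construction:

* `make_transporter` places helix segments and NBD point clouds so that the
  group COMs realise the requested IC/EC angles, NBD distance and twist
  *exactly* (atom clouds have exactly zero-mean offsets); Gaussian jitter of
  chosen σ is added on top. Canonical build targets used throughout testing
  are IC 30°, EC 10°, d_NBD 40 Å, twist 60° with σ = 0.5 Å — values inside
  the IF regime of real transporters.
* `make_trajectory` draws frames i.i.d. from a weighted mixture of reference
  frames with per-atom isotropic noise; planted correlations are injected as
  shared latent Gaussians scaled to an exact target Pearson ρ
  (s = σ√(ρ/(1−ρ)) on both members of a pair). This tests estimators, not
  physics: there is no force field, no inertia and no time correlation.
* `make_membrane` builds two leaflets on a lattice (≥ 60 Å² per lipid
  enforced); each C–H vector is exactly bilayer-perpendicular with
  probability 2·s and isotropic otherwise, so the ensemble S_CD equals −s
  analytically for any target order s ∈ [0, 0.5].
* `make_ligand` builds ATP-like/LTX-like/sterol-like pseudo-molecules with
  the three/three/one sub-body split used by the network node model, round
  point charges (−1 e per phosphate bead) and labelled donors/acceptors so
  energy oracles are hand-checkable.

Passing tests on these systems demonstrates the correctness of the
estimators (geometry, statistics, solvers) under known ground truth. They do
not demonstrate anything about force-field accuracy, sampling convergence of
real MD, time-correlated dynamics, or real lipid chemistry — frames here are
exchangeable by construction, whereas MD frames are autocorrelated.

## Numerical choices and limitations

* Determinism: every stochastic component takes an explicit seed; identical
  seeds give bitwise-identical outputs.
* Validation problem sizes: 10,000 frames for descriptor recovery (sample
  means within 2 % of targets at σ = 0.5 Å), 50,000 samples for landscape
  weight ratios (ΔF within 0.1 kT of −ln(w₂/w₁)), 20,000 frames for MI
  (within 5 % of the closed form), 5,000 C–H samples for the isotropic S_CD
  limit (|S_CD| < 0.02).
* Multi-model PDB is the on-disk trajectory format; masses, charges, vdW
  radii and segment roles travel in a JSON sidecar because the PDB format
  cannot carry them. No mmCIF, no binary trajectory formats, no force-field
  topology parsing.
* The pore search assumes a z-aligned channel; curved axes are out of scope.
* Landscapes are 2D only; no kinetics between core states.
* The deformation functional omits tilt–curvature coupling and boundary
  conditions of full continuum membrane solvers; results are comparative.
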