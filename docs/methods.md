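# Methods

## The sampler

`retamd` implements reconnaissance temperature-accelerated molecular
dynamics (re-TAMD): an enhanced-sampling scheme for letting a flexible
ligand (a peptide chain) explore the surface of a receptor without either
staying trapped in its binding pocket or escaping to the bulk.

### Extended dynamics

The physical coordinates **x** evolve by underdamped Langevin dynamics
under the extended potential

    U_κ(x, z) = V(x) + ½ κ ‖θ(x) − z‖²,

where θ(x) are N collective variables (CVs) — here always the unweighted
geometric centers of disjoint groups of ligand atoms — and z are slowly
evolving CV *targets*.  The targets follow overdamped Langevin dynamics at
an *artificial* thermal energy β̄⁻¹,

    γ̄ ż = κ (θ(x) − z) + √(2 γ̄ β̄⁻¹) η(t).

With κ large enough that z ≈ θ(x) and z slower than x, the target
trajectory effectively samples the free-energy surface F(z) of the physical
system at the artificial temperature; β̄⁻¹ > β⁻¹ lets it cross barriers the
physical temperature alone would not.

Defaults follow the published all-atom protocol: κ = 100 kcal/(mol·Å²),
γ = 2 ps⁻¹, β⁻¹ = 0.6 kcal/mol (≈300 K).  The published target friction
γ̄ = 0.02 ps⁻¹ belongs to an engine whose z-equation units differ from the
bare-mobility convention used here; toy-model defaults use γ̄ = 2 ps⁻¹,
which keeps the explicit Euler–Maruyama target step stable
(κ·dt/γ̄ = 0.25 < 1) while the targets still evolve much more slowly than
the thermostatted velocities.

### Discretization

* **x**: BAOAB splitting.  Chosen for its accurate configurational sampling
  at moderate timesteps; with γ → 0 and zero noise it reduces to velocity
  Verlet (energy drift < 10⁻⁴ relative over 10⁴ steps at dt = 10⁻³ of the
  oscillation period — tested).  Forces in kcal/(mol·Å) are converted to
  amu·Å²/ps² accelerations with the factor 418.4.
* **z**: Euler–Maruyama.  The z-equation is integrated as written, with γ̄ a
  bare mobility; the stationary law var(z − θ) = β̄⁻¹/κ then holds in Å²
  with energies in kcal/mol, and no unit conversion enters.  The O(dt)
  variance bias of the explicit scheme is ≤ κ·dt/(2γ̄) relative and is kept
  ≲ 4% by the default steps.
* **Noise**: one master seed spawns three independent substreams (physical
  noise, target noise, acceptance uniforms), so target rejections never
  desynchronize the physical trajectory and runs are bit-reproducible on
  one platform.

### Adaptive artificial temperature

β̄⁻¹ is refreshed every step from the smallest ligand-receptor atom-pair
distance min(D):

    β̄⁻¹ = k / min(D) + h.

A ligand pressed against the receptor is strongly agitated; one drifting
away cools toward h.  Presets (k in Å·kcal/mol, h in kcal/mol):
(c, k, h) = (0.02, 40, 10) for the 13-mer with 3 CVs, (0.02, 30, 10) for
the 7-mer with 2 CVs, (0.7, 30, 10) for the 3-mer with 1 CV.

### Soft-ratcheting filter

Each proposed target move z′ is tested against the distances D_i from each
target point to its nearest receptor atom.  If at least one proposed D_i
decreases, the move is accepted unconditionally.  Otherwise it is accepted
with probability min(1, f₁f₂⋯f_N), where

    f_i = exp[−(D_i − D_i′)²] / (c·D_i²),

with distances as bare Å-numerics.  Larger c is stricter: the typeset form
divides the whole exponential by c·D², which is the reading consistent with
raising c to keep light peptides from drifting off the surface.  The
alternative reading exp[−ΔD²/(c·D²)] (in which larger c is *more*
permissive) is available via `ratchet_form="exponent-scaled"` for
comparison only.  Individual f_i are not capped; only the product is.  On
rejection the previous targets are retained.  D_i in the test uses the
proposed targets themselves (not the post-step CVs), matching the
"new target values" framing.  A run window with zero acceptances raises a
warning, not an error.

## Toy systems

### Double well

One particle in V(x) = B[(x₁/a)² − 1]² plus harmonic confinement in the
perpendicular directions, with the free energy along the CV obtained by
quadrature of the κ-restrained Boltzmann integral (adaptive quadrature and
a 20001-point Simpson rule agree to 10⁻⁸; exponent-shifting avoids
underflow in the wings).  Validation studies use parameter sets chosen once
for the regime the TAMD theory assumes (fast physical relaxation, slower
targets, enough barrier recrossings for converged histograms):

* stationary-law study: B = 1.5 kcal/mol, separation 3 Å, κ = 50, γ = 20,
  γ̄ = 3, β̄⁻¹ = 6, dt = 0.003 ps, 10⁶ steps, 24 histogram bins — the
  residual total-variation distance ≈ 0.02–0.04 is dominated by the finite
  adiabatic-separation bias plus well-occupancy counting noise;
* equilibrium study (β̄ = β): harmonic V with k = 10, κ = 50, 10⁵ steps;
  the exact Gaussian of U_κ has per-component var(x) = β⁻¹/k,
  var(z) = β⁻¹(k+κ)/(kκ), cov = β⁻¹/k, checked by batch means;
* acceleration study: B = 4.0 ≈ β̄⁻¹ ≫ β⁻¹ (β̄⁻¹ = 5β⁻¹ = 3), first
  passage of x₁ through the barrier top compared pairwise against plain
  Langevin dynamics at the same seeds (caps 4×10⁵ / 6×10⁴ steps; a capped
  plain run counts as a TAMD win only when TAMD actually crossed).

### Coarse-grained complex

A deterministic generator (`make_cg_complex(n_receptor, ligand_length,
seed)`) emulating a peptide bound in a surface pocket of a reader-domain:

* receptor: 210 beads (≈ one per residue of a small reader domain) on a
  16-Å Fibonacci sphere with 0.15-Å seeded roughness, each harmonically
  tethered (k = 10 kcal/(mol·Å²)) to its reference site — a rigid-ish blob;
* ligand: a 3–13 bead chain (bond 3.8 Å, k = 100; angle k = 2 around 166°)
  with cyclic partial charges covering both the polar (|q| ≥ 0.2) and
  hydrophobic (|q| < 0.2) contact classes; bead mass 20 amu;
* pocket: the two receptor beads nearest the central ligand bead (the
  anchoring residue, playing the acylated-lysine part) are raised along
  their radial rays to 3.8 Å from it, forming a concave collar, and carry
  Gaussian attraction wells (depth 4.0 kcal/mol, minimum 3.3 Å, width
  1.2 Å) acting on that bead only;
* everything else: soft-sphere repulsion (k = 10, σ = 3 Å) between ligand
  beads and all receptor beads and between non-bonded ligand beads, and a
  flat-bottom spherical confinement (radius 25 Å, k = 5) standing in for
  the finite simulation box.

The binding strength and pocket geometry were fixed by a one-time
calibration sweep so that, across seeds, plain Langevin dynamics at
β⁻¹ = 0.6 kcal/mol holds the anchor bead in the pocket for ≳95% of a
10⁴-step run while the 13-mer re-TAMD preset dissociates it within the
first ~10³ steps and keeps it diffusing along the surface (pocket residence
typically 2–8%, occasionally up to ~15% for unlucky seeds).  The low
physical friction (γ = 0.5 ps⁻¹ for toy runs) and light beads are what give
the dragged chain enough lateral mobility to circumnavigate the receptor
within the run length; dt = 0.005 ps with frames every 50 steps.

What the generator does *not* emulate: solvent and hydrodynamics, sequence-
specific side-chain packing, backbone dihedral chemistry (beads have no
N/CA/C atoms, so the dihedral analysis is exercised on separately
constructed backbone chains), and the rugged all-atom energy landscape.
Passing tests therefore demonstrate the *mechanisms* — adaptive heating,
ratcheted surface diffusion, contact bookkeeping — not quantitative
agreement with any specific protein system.

## Analysis pipeline

A contact is a receptor-atom/ligand-atom pair strictly closer than 4 Å
(all atoms participate; both the "smaller than" boundary convention and the
4 Å default follow the published analysis).  Classes per contact:
hydrophobic iff both |q| < 0.2 e; polar iff the charges have opposite
signs; a pair may carry both labels, either, or neither; "total" counts
every contact once.  A configuration switch makes the classes disjoint
(polar additionally requiring both |q| ≥ 0.2) for sensitivity checks.

Per-residue profiles sum atomic contact counts over all frames and rescale
by the largest per-residue *total* sum, so every scaled value lies in
[0, 1], the busiest residue is exactly 1, and class ≤ total is preserved;
per-atom counts are rescaled by the largest per-atom total the same way.
Hot-spot lists select residues whose largest scaled atomic count exceeds a
threshold (0.5 for the frequent-contact list, 0.8 for hot spots).
Contact-fraction tables report, per binding-site residue, the percentage of
frames with any atom pair to the probe residue under the cutoff, printed to
one decimal.  Zero-contact trajectories yield an all-zero profile with a
flag rather than NaNs.

Backbone (φ, ψ) dihedrals use the IUPAC right-handed sign convention and
are computed in float64 (the bundled PDB toolkit returns float32 angles,
which is not precise enough for the 10⁻⁹-degree rigid-motion invariance
this module guarantees); results are cross-checked against MDAnalysis in
the test suite.  Terminal residues carry no φ (first) or ψ (last);
residues missing a backbone atom are skipped with a warning.  Histograms
default to 5° bins.

Contact maps are exported as standard PDB with 100 × the scaled per-residue
value in the B-factor column; atoms with strictly zero recorded contacts
get occupancy 0 so viewers can gray them out.

## I/O and reproducibility

Structures and multi-model trajectories are standard PDB (via biotite);
partial charges and masses live in a sidecar TSV keyed by 1-based atom
serial, because PDB has no charge field and nonstandard columns would break
other readers.  Receptor atoms map to chain A, ligand to chain B.  Per-step
scalars (z, θ, D_i, min(D), β̄⁻¹, accepted, prob) are TSV with a commented
header.  A run directory archives its YAML config and seed; config + seed
reproduce a trajectory bit-identically on one platform.

## Numerical choices and degenerate inputs

* min(D) uses physical ligand atoms; D_i uses target points — both against
  the nearest receptor atom (the simplest reading consistent with a
  point-to-domain distance).
* `adaptive_beta_bar` rejects non-positive distances; `ratchet_factor`
  rejects D_old = 0 (the formula divides by D²).
* Contact cutoff comparisons are strict; a pair at exactly 4.0 Å is not a
  contact.
* CV groups must be non-empty, in-range, and reference ligand atoms only;
  runs with ratcheting or adaptation require a non-empty receptor
  partition, while the vanilla-TAMD reduction (both disabled) runs on
  bare systems.
* Internal indexing is 0-based; residue numbering in files is 1-based.
* No periodic boundaries: toys run in open space with the flat-bottom
  confinement.

## Known limitations

* The acceptance statistics of the ratchet are exact, but the *stationary
  law* of re-TAMD with ratcheting on is not characterized analytically
  (the filter deliberately breaks detailed balance); only the vanilla-TAMD
  reduction is validated against closed-form laws.
* The Euler–Maruyama target step requires κ·dt/γ̄ < 1; configurations
  violating this will diverge rather than be silently clipped.
* Free-energy estimation from re-TAMD output is out of scope — the method
  is a reconnaissance tool, not an estimator of F(z).
* The CLI runs simulations on the built-in toy generator only; running a
  PDB-derived system requires supplying a `Potential` through the library
  API, since no general force field is bundled.
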