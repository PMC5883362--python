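# retamd

Reconnaissance temperature-accelerated molecular dynamics (re-TAMD): a
desk-scale sampler for studying how a flexible peptide ligand explores a
receptor surface, with the matching contact-mapping and dihedral-analysis
pipeline.

## The problem and the method

Encounter complexes form through a *free-diffusion* stage in which a
peptide samples a protein's surface before committing to a binding site.
Plain molecular dynamics cannot reach this regime on a workstation: the
bound state is too deep and the interesting events too rare.

re-TAMD extends temperature-accelerated molecular dynamics (TAMD).  The
physical system **x** obeys Langevin dynamics under the extended potential

    U_κ(x, z) = V(x) + ½ κ ‖θ(x) − z‖²,

where the collective variables θ(x) are geometric centers of peptide
residue groups and z are their slowly evolving targets, themselves
following overdamped Langevin dynamics at an artificial thermal energy
β̄⁻¹ > β⁻¹.  re-TAMD adds two controls:

1. **Distance-adaptive temperature** — β̄⁻¹ = k/min(D) + h, with min(D)
   the smallest peptide-receptor atom distance, so the peptide is agitated
   hardest exactly when it is stuck against the surface;
2. **Soft ratcheting** — a proposed target move that takes every CV target
   farther from the receptor survives only with probability
   min(1, Π_i exp[−(D_i − D_i′)²]/(c·D_i²)); any move bringing one target
   closer is accepted outright.  The peptide therefore diffuses *along*
   the surface instead of escaping to the bulk.

The package provides the integrators (BAOAB for x, Euler–Maruyama for z),
the re-TAMD controller, deterministic toy-system generators (a double well
with quadrature free energy, and a coarse-grained receptor/ligand complex),
the trajectory-analysis pipeline (4-Å contacts classified polar vs
hydrophobic by a 0.2 e partial-charge rule, per-residue profiles rescaled
to [0, 1], contact-fraction tables, hot-spot lists, φ/ψ dihedrals, B-factor
contact maps), and PDB/TSV/YAML I/O with a CLI.

## Worked example

Dissociate a 13-bead peptide from the pocket of the coarse-grained
receptor and compare with a plain-MD control:

```python
import retamd

cfg = retamd.preset_config("pt13", seed=1)      # c=0.02, k=40, h=10, 3 CVs
complex_ = retamd.make_cg_complex(seed=1)

md = retamd.run_plain_md(complex_.system, complex_.potential, cfg.params)
rt = retamd.run_retamd(complex_.system, complex_.potential,
                       complex_.cvdef, cfg.params)

from retamd.toysystems import pocket_contact_fraction
print(f"plain MD pocket residence: {pocket_contact_fraction(complex_, md.trajectory):.3f}")
print(f"re-TAMD  pocket residence: {pocket_contact_fraction(complex_, rt.trajectory):.3f}")
print(f"re-TAMD acceptance rate:   {rt.acceptance_rate:.3f}")
```

Output:

```
plain MD pocket residence: 0.975
re-TAMD  pocket residence: 0.080
re-TAMD acceptance rate:   0.995
```

Plain Langevin dynamics at β⁻¹ = 0.6 kcal/mol keeps the anchor bead in the
pocket for 97.5% of the 10⁴-step run; under the re-TAMD preset it
dissociates within the first ~10³ steps and spends the rest of the run
diffusing over the receptor surface (8% residual pocket contact), while
the permissive ratchet (99.5% acceptance) keeps it from escaping to the
bulk.  `rt.records` holds the per-step z, θ, D_i, min(D), β̄⁻¹ and
acceptance bookkeeping as a DataFrame.

The same runs from the shell:

```bash
retamd simulate --preset pt13 --seed 1 --out-dir run13
retamd contacts --pdb run13/trajectory.pdb --charges run13/charges.tsv \
                --traj run13/trajectory.pdb --out contacts.tsv
retamd hotspots --pdb run13/trajectory.pdb --charges run13/charges.tsv \
                --traj run13/trajectory.pdb --threshold 0.8
```

## Layout

```
src/retamd/
  model.py        domain types, CV evaluation, distance geometry
  dynamics.py     potentials, noise streams, BAOAB and target steps
  controller.py   adaptive temperature, soft ratcheting, run loops
  toysystems.py   double well, harmonic well, CG complex generator
  analysis.py     contacts, profiles, fractions, hot spots, dihedrals
  io.py           PDB/TSV readers and writers
  config.py       run configs, presets
  cli.py          command-line interface
docs/methods.md   model assumptions, parameter rationale, limitations
```
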