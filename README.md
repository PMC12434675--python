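# crossbeta

Analysis and synthetic-data toolkit for studying the degradation of
cross-β (amyloid) filaments under oscillating external electric
fields, built around the tau paired-helical-filament (PHF) and
straight-filament (SF) decamer topologies.

The package has two halves:

* **Analysis** of structures and trajectories (multi-model PDB):
  Kabsch–Sander secondary-structure assignment and β-strand-content
  series, three classes of Cα contact fractions (intrapeptide 1.25 nm /
  interpeptide 0.8 nm / interprotofilament 1.0 nm), central-chain
  anchored RMSF, β-sheet twist dihedral, Shrake–Rupley SASA and
  protofilament interface area, and one/two-phase exponential decay
  fits with slow-phase half-lives and Student's t comparisons.
* **Synthetic data** so every stage is testable without μs-scale MD:
  an idealized cross-β decamer builder (two pentameric protofilaments
  of C-shaped 77-residue tau G304–E380 peptides, in-register stacking
  at 4.75 Å rise, PHF-like symmetric or SF-like offset interface,
  geometry good enough for DSSP), a kinematic perturbation generator,
  noisy decay-trace generation, and a charged elastic-network model
  driven by `E(t) = E0·cos(2πνt)` integrated with overdamped Langevin
  dynamics.

Internally everything is nanometres/picoseconds/kJ·mol⁻¹; PDB files
are Å, areas are reported in Å², field strengths in mV/nm and
frequencies in GHz.

## CLI

```bash
# build an idealized decamer (phf or sf) as PDB
crossbeta build --topology phf --out fibril.pdb

# field-driven elastic-network Brownian dynamics -> multi-model PDB
crossbeta simulate --structure fibril.pdb --e0 200 --frequency 1 \
    --steps 20000 --stride 200 --seed 1 --out traj.pdb

# kinematic perturbations from a YAML schedule
crossbeta perturb --structure fibril.pdb --schedule schedule.yaml \
    --frames 100 --out perturbed.pdb

# analyses (CSV/JSON outputs)
crossbeta analyze ss        --traj perturbed.pdb --out beta.csv
crossbeta analyze contacts  --traj traj.pdb      --out contacts.csv
crossbeta analyze rmsf      --traj traj.pdb      --out rmsf.csv
crossbeta analyze twist     --traj perturbed.pdb --out twist.csv
crossbeta analyze interface --structure fibril.pdb --out interface.json

# synthetic decay traces and model fitting
crossbeta generate --sigma 0.02 --runs 3 --seed 7 --out traces.csv
crossbeta fit-decay --input traces.csv --model all --out fits.json

# full condition grid (control + 3 frequencies x 2 strengths),
# half-life table and mean±SD decay series, reproducible from one seed
crossbeta run --seed 1 --outdir results/
```

Exit codes: 0 ok, 1 input error, 2 numerical failure.

A schedule file looks like:

```yaml
events:
  - kind: turn_jitter        # flexibility burst on residues 340-350
    sigma_nm: 0.08
  - kind: separation         # protofilament b drifts away
    start_frame: 40
    velocity_nm_per_frame: 0.2
```

## Package layout

| module                | contents |
| --------------------- | -------- |
| `fibril_model`        | tau core sequence/segments, charges, chain→protofilament/stack bookkeeping |
| `structure_io`        | PDB structure + multi-model trajectory I/O (nm) |
| `secondary_structure` | Kabsch–Sander H-bond energy, {E,H,C} assignment, β-content series |
| `contacts`            | reference contact sets and per-class/per-residue survival fractions |
| `flexibility`         | Kabsch superposition, central-chain anchored RMSF |
| `geometry`            | twist dihedral, Shrake–Rupley SASA, interface area |
| `kinetics`            | four decay models, multi-start fits, half-lives, t-test |
| `synthetic_fibril`    | idealized decamer builder, decay-trace generator, perturbation schedules |
| `field_dynamics`      | charged ENM + oscillating field, overdamped Langevin integrator |
| `cli`                 | `crossbeta` command-line pipeline |
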