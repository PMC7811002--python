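# qeqpot

Charge-equilibration neural network interatomic potentials in pure
numpy/scipy: second- (2G), third- (3G) and fourth-generation (4G)
high-dimensional neural network potentials with

- atom-centered symmetry-function descriptors with analytic gradients,
- per-element feed-forward networks (two tanh hidden layers, linear output),
- Gaussian-charge electrostatics with erf-screened Coulomb kernels, dense
  constrained charge equilibration (Qeq), and Ewald summation for neutral
  periodic cells,
- analytic forces including the dE_short/dQ . dQ/dR chain through the Qeq
  solve (implicit differentiation of the augmented saddle-point system),
- two-stage training (charges first, then residual energies + forces),
- a synthetic ground-truth generator reproducing four non-local
  charge-transfer benchmark scenarios (protonated chain, trimer ions,
  cluster vacancy, doped slab) so everything is testable offline.

The 4G construction: atomic networks predict environment-dependent
electronegativities; a charge-equilibration solve distributes the total
charge globally; the resulting charges feed both the long-range
electrostatic energy and (as an extra input) the short-range atomic energy
networks. That makes energies, forces and charges sensitive to global
charge state and distant compositional changes, which purely local (2G/3G)
models provably cannot represent — the test suite asserts both sides of
this dichotomy.

## CLI

One entry point, `qeqpot`, with five subcommands:

```sh
# generate a labelled synthetic dataset (extended XYZ)
qeqpot gen-data --scenario trimer_ions --n 200 --seed 1 --out data.xyz

# two-stage training (config optional; YAML)
qeqpot train --generation 4g --config config.yaml --data data.xyz --out model.ckpt

# metrics block (energy meV/atom, forces eV/A, charges 1e-3 e; RMSE and MAE)
qeqpot eval --model model.ckpt --data data.xyz

# energies/forces/charges for each frame
qeqpot predict --model model.ckpt --data data.xyz --out pred.xyz

# gradient-descent geometry optimization (threshold in Ha/Bohr)
qeqpot optimize --model model.ckpt --data data.xyz --out opt.xyz --fmax 1e-4
```

Example `config.yaml`:

```yaml
descriptors:
  cutoff_bohr: 8.0      # symmetry-function cutoff (converted internally)
  n_radial: 6
screening:
  inner: 2.0            # Angstrom; outer defaults to the descriptor cutoff
electro:
  hardness: {Ag: 0.5}   # initial values; trained for 4G
training:
  epochs: 2000
  lr: 0.02
  lr_final: 0.001
  w_e: 1.0
  w_f: 10.0
  split_fraction: 0.9
  seed: 1
```

Per-epoch metrics are logged to `<model>.log.jsonl`.

## File formats and units

Extended XYZ with `Lattice`, `Properties=species:S:1:pos:R:3[:forces:R:3][:charge:R:1]`,
`energy=<eV>`, `total_charge=<e>`, `pbc="T T T"`. Files carry Angstrom / eV /
eV/A; the internal core is atomic units (Ha, Ha/Bohr, e; Bohr inside the
electrostatics). Model checkpoints are JSON.

## Package layout

| module | contents |
| --- | --- |
| `qeqpot.structures` | `Structure`/`ReferenceRecord`, extended-XYZ I/O, periodic neighbor lists, perturbation |
| `qeqpot.descriptors` | ACSF values + analytic gradients, parameter generators |
| `qeqpot.atomic_nets` | small dense networks: forward, input/parameter gradients, batched forms |
| `qeqpot.qeq` | Qeq matrix assembly, constrained solve, Ewald, implicit derivatives, screening |
| `qeqpot.potential` | 2G/3G/4G assembly: charges, energy, analytic forces, geometry optimization, checkpoints |
| `qeqpot.training` | dataset split, two-stage fitting (Adam, block-batched), metrics |
| `qeqpot.synthetic` | ground-truth surrogate + the four benchmark scenario generators |
| `qeqpot.cli` | `qeqpot` command-line entry point |
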