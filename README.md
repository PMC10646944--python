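# eqff — hybrid equivariant-NN / force-field interatomic potential

`eqff` implements a hybrid machine-learning/force-field potential for
molecular simulation: a strictly local equivariant neural network predicts
short-range energies and atom-in-molecule properties (partial charges,
atomic volumes), and those properties parameterize physically-motivated
long-range terms — charge-penetration-corrected Coulomb electrostatics and
Tkatchenko–Scheffler dispersion. The package is aimed at method developers
and computational chemists who want a transparent, pure-Python/numpy
reference implementation of this model family, including its staged
training procedure and a small NVT molecular-dynamics engine.

## The model

Every directed atom pair (i, j) within a cutoff r_c is embedded as a
scalar feature vector x_ij and equivariant tensor features V_ij^{nlp}
(channel n, rotational order l, parity p), built from

* a smooth sine/cosine **positional encoding** of each element's (period,
  group) coordinates in the periodic table — so chemically similar species
  get similar encodings and the encoding extends to fictitious
  interpolated "elements";
* a Bessel radial basis B(R_ij) with a polynomial cutoff envelope f_c and
  real spherical harmonics Y^{lp}(R̂_ij);
* an Allegro-style sequence of interaction layers: an equivariant
  neighborhood summary Γ_i^{nlp}, channel-wise tensor products Γ ⊗ V over
  all symmetry-allowed paths, a scalar latent MLP with a
  normalization-preserving mixing coefficient α, and a learned linear
  filtering of the tensor paths.

Three independent MLP heads map [x_ij^{2B} ‖ x_ij] to pairwise outputs
that aggregate into per-atom properties: local energies E^NN_i, an
antisymmetrized charge exchange q_i = Σ_j (δq_ij − δq_ji) (exactly neutral
by construction), and positive volume ratios v_i/v_i^free. The total
energy is

    V = Σ_i E^NN_i + Σ_{i<j} E^C_ij + Σ_{i<j} E^D_ij + Σ_i E^ref_i

with E^C a damped Coulomb term between valence populations N_i − q_i
(damping f(r) = 1 − e^{−kr}; the bare k_e q_i q_j / R law is recovered at
long range; Ewald summation under periodic boundary conditions), E^D the
pairwise TS dispersion −f_damp(R) C6_ij/R^6 whose homonuclear C6 and van
der Waals radii scale with the predicted volume ratios, and E^ref the
isolated-atom reference energies that fix the dissociation asymptote.
Forces are exact gradients of this energy, computed with the package's own
reverse-mode autodiff engine (which also supports the double backward
needed by force-matching losses).

With the full-size hyperparameters (256 scalar features, 10 channels,
l_max = 2, 3 layers, r_c = 5.2 Å) the model has ≈1.22 million trainable
parameters.

## Worked example

```python
import numpy as np
from eqff import AtomicSystem, Model
from eqff.presets import reduced_config

cfg = reduced_config()                       # desk-scale architecture
cfg.reference_energies = {"O": -900.0, "H": -313.6}
model = Model(cfg, seed=0)                   # random (untrained) weights

water = AtomicSystem(["O", "H", "H"],
                     [[0.000, 0.000, 0.000],
                      [0.957, 0.000, 0.000],
                      [-0.240, 0.927, 0.000]])
bd = model.compute(water)
```

prints (via the fields of `bd`):

```
E_NN         =     0.1126 kcal/mol
E_coulomb    =   -12.5970 kcal/mol
E_dispersion =    -0.0009 kcal/mol
E_reference  = -1527.2000 kcal/mol
E_total      = -1539.6853 kcal/mol
charges      = [ 0.1813 -0.0907 -0.0907] (sum: 0.0e+00)
volume ratios= [0.6518 0.6476 0.6476]
|F| max      = 9.9544 kcal/mol/A
```

The numbers themselves are those of an untrained model — what matters is
the structure: the energy decomposes into the four terms of the
functional form, the charges sum to zero exactly, the volume ratios are
positive, and the forces are the exact gradient of the printed energy
(verified against finite differences in the test suite). Pull the two
hydrogens beyond every cutoff and `E_total` returns exactly
`E_reference = -1527.2`: the dissociation asymptote is built in, trained
or not.

Training on synthetic labeled data and running MD from the shell:

```bash
eqff synth-data --n-records 2000 --out data.jsonl
eqff train --data data.jsonl --epochs 60 --checkpoint model.eqff
eqff dissociation-scan --checkpoint model.eqff --pair H,H --out scan.dat
eqff md --checkpoint model.eqff --xyz start.xyz --steps 1000 --out traj.xyz
```

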