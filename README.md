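# dnaclamp

Analysis toolkit for single-molecule force-spectroscopy studies of DNA
bis-intercalation. The package grew out of optical-tweezers work on the
anticancer peptide Thiocoraline, a bis-intercalator that clamps two
consecutive base pairs, elongates the duplex by ~0.68 nm per bound
ligand, and dissociates over hours through a long-lived
mono-intercalated intermediate. It is written for biophysicists who
stretch or unzip single DNA molecules and want a tested, reusable
implementation of the full analysis chain — from raw force-extension
text files to binding thermodynamics, microscopic kinetic rates and
base-pair-resolved footprints.

## What it computes

**Polymer elasticity** (`dnaclamp.polymer`). dsDNA follows the
Marko–Siggia worm-like chain with the seven-term polynomial correction,

    F(l) = (kBT/Lp) [ 1/(4(1−l)²) − 1/4 + l + Σ_{i=2..7} a_i l^i ],

with l = x/l0 (inextensible) or l = x/l0 − F/S (extensible); ssDNA uses
the extensible freely-jointed chain. Levenberg–Marquardt fitting of
(l0, Lp, S) over any force window.

**Binding thermodynamics** (`dnaclamp.binding`). Contour-length change
converts to a binding fraction, ν = (l0^lig − l0^DNA)/(Δl0·N_bp), and a
titration of l0 against ligand concentration is fit with the
McGhee–von Hippel isotherm

    ν = ([L]/Kd) (1 − nν)^n / (1 − nν + ν)^{n−1}

for the dissociation constant Kd and binding-site size n. An exact
finite-lattice transfer-matrix calculation is included as an
independent cross-check of the isotherm.

**Three-state kinetics** (`dnaclamp.kinetics`). Each site hops between
unbound (U), mono-intercalated (M) and bis-intercalated (B) states with
Bell force-dependent rates k(F) = k(0)·exp(F·x†/kBT). The linear master
equation is solved by eigen-decomposition; wash-off, force-jump and
intercalation protocols are simulated (deterministically or by
Gillespie sampling); double-exponential relaxation fits map analytically
onto the microscopic rates (α_off = √(k_slow·k_fast),
α_on′ = k_slow + k_fast − 2α_off for the default exit multiplicity).

**Unzipping footprinting** (`dnaclamp.footprint`). Equilibrium
force–distance curves of a hairpin are predicted from nearest-neighbor
duplex energies plus the elasticity of released ssDNA, dsDNA handles and
the optical trap. Each measured point is assigned an open-base-pair
number n by matching theoretical curves; ligand-binding events appear as
excess peaks of the unzip n-histogram over the rezip histogram and are
scored per dinucleotide step as p_norm(B_i) = (N_i/S_i)/Σ_j(N_j/S_j).

**Synthetic data** (`dnaclamp.synth`). Seeded generators emulate all
three experiment families — titration FECs, kinetic traces, unzip/rezip
pairs with planted binding events — so every stage is testable without
instrument data.

## Worked example

Recover the microscopic kinetics from simulated wash-off experiments:

```python
import numpy as np
from dnaclamp.kinetics import (ALL_B, fit_bell, fit_relaxation,
                               microscopic_from_macroscopic,
                               simulate_protocol, thiocoraline_model)

model = thiocoraline_model()          # x_on' = 0.12 nm, x_off = -0.29 nm
forces = np.array([5.0, 12.0, 19.0, 26.0, 33.0, 40.0])
ks, kf = [], []
for F in forces:
    trace = simulate_protocol(model, "washoff", force=F, ligand_nM=100.0, p0=ALL_B)
    fit = fit_relaxation(trace, n_exponentials=2)
    kf.append(fit.rates[0]); ks.append(fit.rates[1])
a_off, a_onp = microscopic_from_macroscopic(np.array(ks), np.array(kf))
off, _ = fit_bell(forces, a_off)
onp, _ = fit_bell(forces, a_onp)
print(f"x_off = {off.x_dagger:.3f} nm, x_on' = {onp.x_dagger:.3f} nm, "
      f"dx_eq = {onp.x_dagger - off.x_dagger:.3f} nm")
```

prints

```
x_off = -0.290 nm, x_on' = 0.120 nm, dx_eq = 0.410 nm
```

i.e. the round trip through trace fitting and the eigenvalue mapping
returns the generating transition-state distances exactly; their
difference, 0.41 nm, is the extension change of the mono-to-bis step —
about 60% of the 0.68 nm full bis-intercalation elongation, consistent
with an intermediate that carries ~0.28 nm of it.

The same chain is available from the shell:

```
dnaclamp washoff --output-dir out/
dnaclamp simulate --output-dir out/ --seed 1
dnaclamp titrate --titration out/titration.tsv --output-dir out/
```

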