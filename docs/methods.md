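# Methods

This note records the models implemented in `dnaclamp`, the defaults
and units of their parameters, what the synthetic-data generators do
and do not emulate, and the numerical and design choices made where the
underlying physics left room.

## Elasticity

dsDNA is a worm-like chain in the Marko–Siggia interpolation with the
seven-term polynomial correction (coefficients a₂…a₇ =
−0.5164228, −2.737418, 16.07497, −38.87607, 39.49944, −14.17718). The
extensible variant adds enthalpic stretching through l = x/l0 − F/S;
its force at given extension is found by bracketed Brent root finding
on the implicit relation (tolerance 1e−12 in force), and its inverse by
60-step bisection of the monotone force law (≈1e−14 in relative
extension), which closes the round trip x→F→x to better than 1e−8
relative. Temperature enters only through kBT, default 4.114 pN·nm
(298 K) — the working temperature is not otherwise modelled.

ssDNA is an extensible freely-jointed chain with Kuhn length 1.35 nm,
contour 0.59 nm per base and stretch modulus 800 pN, standard values
for ~100 mM monovalent salt; all are fields of `FjcParams`.

`fit_wlc` minimizes extension residuals at the measured forces
(Levenberg–Marquardt via lmfit), because the extensible model is
explicit in that direction; any subset of (l0, Lp, S) may float.
Defaults for generated dsDNA: Lp = 48 nm, S = 1200 pN.

## Binding

A bound bis-intercalator elongates the duplex by Δl0 = 2d = 0.68 nm
(two base-pair rises); Δl0 is held fixed in titration fits rather than
floated, since the contour data alone cannot separate Δl0 from ν. The
McGhee–von Hippel isotherm is solved for ν by bracketed bisection on
[0, 1/n − 1e−12], where the residual is monotone and the root unique.
The titration fit parametrizes Kd logarithmically (positivity), weights
rows by 1/sd² when uncertainties are present, and flags "no detectable
binding" when the largest contour change is below 0.1% of the naked
value. The exact occupancy of non-overlapping n-mers on a finite
lattice (transfer recursion Z_i = Z_{i−1} + z·Z_{i−n}, with the ligand
count from the activity derivative) serves as an independent oracle;
it is capped at 24 sites, where it already agrees with the isotherm to
a few percent.

## Three-state kinetics

States per available site: unbound U, mono-intercalated M,
bis-intercalated B, with

    dU/dt = −α_on U + α_off M
    dM/dt =  α_on U − (α_on′ + α_off) M + m·α_off B
    dB/dt =  α_on′ M − m·α_off B

α_on = k_a·[L] (bimolecular, default k_a = 1.7e4 M⁻¹s⁻¹, optional Bell
distance x_on, default 0), and α_on′, α_off follow the Bell law
k(F) = k(0)·exp(F·x†/kBT). The reference parameterization for
Thiocoraline uses x†_on′ = +0.12 nm, x†_off = −0.29 nm and zero-force
rates mapped from the measured macroscopic wash-off rates
(k_slow(0) = 6.2e−4 s⁻¹, k_fast(0) = 3.4e−3 s⁻¹).

The exit multiplicity m of B→M is ambiguous in a scheme where "either
moiety" can leave: the package defaults to m = 1, which keeps the
inverse eigenvalue mapping feasible for any k_fast > k_slow (by AM–GM)
and yields a zero-force intermediate lifetime 1/α_off(0) ≈ 11.5 min, on
the reported ~10-minute scale; m = 2 is selectable and its mapping
raises an explicit infeasibility error when α_on′ would go negative.

A second known ambiguity: mapping the *fitted exponential* macroscopic
laws through the eigenvalue relations does not produce an exactly
exponential α_on′(F) (its effective slope is even slightly negative),
whereas per-force inversion of measured rates gives the positive
x†_on′ used here. `model_from_macroscopic` therefore mirrors the
experimental procedure — invert per force, then refit Bell laws — and
the acceptance round trip is built on simulated traces, which closes
exactly regardless of this choice.

Propagation is by eigen-decomposition of the 3×3 generator (the matrix
is diagonalizable for all parameterizations of interest; agreement
with adaptive Runge–Kutta is tested to 1e−8). Wash-off signals at
[L] = 0 are exact double exponentials of the decoupled (M, B) block;
the observable is the fractional elongation χ = p_B + φ·p_M with
φ = 0.4 (the intermediate carries 40% of the bis elongation, i.e.
φ·Δl0 ≈ 0.28 nm per ligand). χ maps to extension through the unique
affine function with χ(U) = 0 at the naked contour and χ(B) = 1 at the
saturated contour (ν = 1/n).

Relaxation traces are sampled log-uniformly in time (wash-off
eigenvalues separate by >10³ at 40 pN; linear grids starve the fast
mode). Double-exponential fits are started both from a geometric split
(k, k/10) of the single-exponential rate and from a tail-peeling
estimate, keeping the lower-residual solution; rates are reported
sorted and a separation below 1.5× raises a degeneracy warning. Bell
fits are linear regressions of ln k on F.

For the parameter-free titration prediction, the equilibrium per-site
occupancy is converted to an effective binding fraction ν_eff =
(p_B + φ·p_M)/n using the site density 1/n from the isotherm fit.

## Unzipping and footprinting

Duplex stability uses the unified nearest-neighbor ΔH/ΔS set (packaged
as `data/nn_unified.json`, swappable) with the per-step entropic salt
correction 0.368·ln[Mon⁺] cal mol⁻¹K⁻¹, evaluated at 298 K and 100 mM
by default; per-base-pair opening costs are the step energies, the
loop-closing base pair taking the sequence mean. Helix initiation
terms are not included — footprinting only ever uses energy
*differences* along the stem.

The equilibrium force–distance curve treats the trap position as the
control variable: for each state with n open base pairs the force
balancing trap (F/k_trap, default 70 pN/µm), handles (extensible WLC of
2×29 bp) and released ssDNA (FJC of 2n bases) is found by vectorized
bisection on a precomputed elastic grid (force range 0–30 pN, 2000
points, linear interpolation), and the total free energy is the opening
cost plus the elastic Helmholtz energies (Legendre transforms of the
tabulated Gibbs integrals). Boltzmann weights over a ±150-bp moving
window centered on the free-energy minimum give the mean force and mean
open-bp number; states that cannot balance the position within the
force grid are excluded rather than clipped (clipping silently
mis-ranks them). A sampling mode draws one fork state per position
from the same distribution, emulating instrument snapshots of the
hopping fork.

Open-base-pair assignment inverts x_th(n, f) = x_bead + x_handles +
x_ssDNA(2n) at the measured force — affine in n, so the integer argmin
is the rounded continuous solution, ties broken toward smaller n,
clamped to [0, N]. Curve alignment fits two multiplicative factors
(distance, force) within [0.95, 1.05] by bounded least squares against
the predicted curve and flags factors pinned at the bounds.

Event detection histograms assigned n (1-bp bins) for the unzip and
rezip sweeps. A bin is enriched when the unzip count exceeds 5× the
local rezip level (±10 bp mean, floored at 0.5) *and* is Poisson
incompatible with that level at p < 1e−4; runs of ≥3 enriched bins
(gaps ≤2 bridged) form events. The event position is a Gaussian fit —
refined on the near-rupture points (upper 30% of the force excess,
within 1.5 pN of the rupture maximum), where the fork is pinned at the
clamp; truncating the fit window would bias the mean, so the refined
histogram uses the pinned points' full range. Rupture force is the
cluster maximum; the local baseline is the mean unzipping force within
±15 bp of the cluster (theoretical curve if available, else the rezip
sweep).

Scoring maps an event at Gaussian mean n̂ to the dinucleotide step
starting at base pair ⌊n̂⌋ + offset. The default offset is +2 bp,
calibrated on synthetic curves with planted events: the fork stalls one
base pair short of the clamped step, and the thermal mean of the stall
lies slightly below the pin. The offset remains a configuration knob —
on real data it should be re-calibrated against a known site.
Dinucleotides collapse to the 10 strand-symmetric classes; degeneracies
come from a direct scan of the stem; p_norm is the degeneracy-weighted
share. Events at CG steps contribute their two flanking bases to an
A-T vs C-G frequency table. An optional rupture-force threshold keeps
only events exceeding the local baseline by a stated margin.

## Synthetic data

Generators emit the same text dialects the loaders read and record
their seed and ground truth.

*Titration curves*: binding fraction from the isotherm at
(Kd = 77 nM, n = 3.84 bp), quenched contour l0(1+2ν) on a 24-kb
template, extensible-WLC extension over 0–40 pN; the equilibrium
variant recomputes the occupancy at every force through the kinetic
model, reproducing the force-induced intercalation that depresses
apparent persistence length in naive fits. Titration tables use nine
concentrations spanning 0–1000 nM with 2% multiplicative Gaussian
noise on contour lengths.

*Kinetic traces*: delegate to the protocol simulator; optional
per-site Gillespie sampling over N independent sites; optional mapping
to extension through the WLC curves of naked and saturated DNA.

*Unzip pairs*: the unzip sweep samples the Boltzmann fork distribution
with the ligand's stabilization (default 10 kBT) added to the opening
cost of the clamped step; ligand removal is modelled as a kinetic
rupture — the fork stays pinned until the force exceeds the local
unzipping baseline by a seeded random excess of 6 ± 1.5 pN, matching
the observation that binding peaks ride several pN above the sawtooth —
after which the ligand is stripped and the curve continues ligand-free.
The rezip sweep is always ligand-free; optional rezip-side artifacts
emulate transiently stabilized misfolds that delay refolding and must
not be called as binding. Noise defaults: 0.1 pN on force, 2 nm on
distance, the scale of 1-kHz data filtered to 10 Hz.

What the generators do *not* emulate: instrument drift and baseline
wander, bead rotation artifacts, the kinetics of fork hopping within a
sweep (samples are drawn independently per trap position), sequence-
dependent ligand on-rates, and cooperative binding between adjacent
sites. Passing tests therefore demonstrate correctness of the analysis
chain under idealized stationary noise, not robustness to instrumental
systematics.

## Problem sizes and tolerances

The test suite and the acceptance script run the wash-off round trip at
six forces with 400-point traces; the titration study uses 100 seeds;
the footprinting recovery study uses a 480-bp construct with 0.5-nm
position spacing and 20 planted events over 14 curve pairs plus 8
ligand-free pairs; the long-hairpin prediction uses a 6.8-kb stem at
3-nm spacing. These sizes were chosen so each stage exercises the same
statistics as the corresponding experiment while a full run stays in
the minutes range on one core.
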