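# Methods

## Scope and model

`cdftkit` implements the frontier-orbital branch of Conceptual Density
Functional Theory (CDFT) for reactivity prospection of drug-like molecules,
together with the "Koopmans in DFT" (KID) validation step that justifies
using orbital energies in the first place. It does **not** run any
electronic-structure calculation: its inputs are the HOMO/LUMO energies of
the neutral molecule, optionally the SOMO of its radical anion, optionally
the ground-state total energies of the N−1/N/N+1 electron systems, and
optionally electron densities of those three states on cube grids. All
energies are handled internally in eV (hartree accepted on input;
1 hartree = 27.211386245988 eV).

### KID compliance

For an exact functional, the ionization-energy and Janak theorems give
−I = ϵH and (approximately, for the affinity side) −A = ϵL, with I and A the
vertical ΔSCF ionization energy and electron affinity at fixed geometry.
The residuals

    J_I  = ϵH + E(N−1) − E(N)
    J_A  = ϵL + E(N) − E(N+1)
    J_HL = sqrt(J_I² + J_A²)
    ΔSL  = ϵ_SOMO(anion) − ϵL(neutral)

measure the deviation for a practical functional. No numeric compliance
threshold is standard; the package's default verdict is
`J_HL ≤ 0.15 eV` and, when the SOMO is available, `|ΔSL| ≤ 0.15 eV`
independently. 0.15 eV comfortably accepts the ≲0.12 eV residuals typical
of well-behaved range-separated/screened-exchange functionals in aqueous
continuum solvent while rejecting the order-of-1-eV failures of
conventional semilocal functionals; it is configurable everywhere it is
used. ΔSL participates in the verdict only when a SOMO is present; absent
ground-state energies mark the KID columns absent rather than failing the
run, since the descriptor tables need only ϵH and ϵL.

### Global descriptors

With ϵH < ϵL (eV):

| descriptor | formula | units |
|---|---|---|
| electronegativity | χ = −(ϵH+ϵL)/2 | eV |
| chemical potential | μ = −χ | eV |
| global hardness | η = ϵL − ϵH | eV |
| global softness | S = 1/η | eV⁻¹ |
| electrophilicity index | ω = χ²/(2η) | eV |
| electrodonating power | ω⁻ = (3ϵH+ϵL)²/(16η) | eV |
| electroaccepting power | ω⁺ = (ϵH+3ϵL)²/(16η) | eV |
| net electrophilicity | Δω± = ω⁻ + ω⁺ | eV |
| nucleophilicity index | N = ϵH − ϵH(TCE) | eV |

Two conventions deserve a note. Hardness is taken as the full gap (no ½
factor) and softness as its plain reciprocal (not 1/(2η)); both are forced
by the packaged apratoxin reference table (1/5.02 = 0.199 → printed 0.20).
The identity ω⁻ − ω⁺ = χ holds algebraically and is enforced as a property
test.

The nucleophilicity index is referenced to tetracyanoethylene (TCE), whose
ϵH depends on the functional/basis/solvent combination. The default
reference, −8.79 eV, is the least-squares (mean-offset) calibration over
the seven packaged (ϵH, N) apratoxin pairs, with residual sd ≈ 0.005 eV; it
is only valid for data produced at the same model chemistry
(MN12SX/Def2TZVP, SMD water) and must be overridden otherwise
(`calibrate_nucleophilicity_reference` recovers it from any pair list).

Classification follows the polar-organic-reactivity scales: electrophiles
strong for ω > 1.5 eV, moderate for 0.8 < ω < 1.5 eV, marginal below;
nucleophiles strong for N > 3 eV, moderate for 2 ≤ N ≤ 3 eV, marginal
below. The electrophile scale's strict inequalities leave ω = 1.5 and
ω = 0.8 unassigned; this package assigns each boundary to the weaker class
(1.5 → moderate, 0.8 → marginal). Caveat: the source narrative for the
apratoxin set describes every peptide except A as a *moderate*
electrophile, which contradicts its own quoted scale (most of the set has
ω > 1.5 → strong); the package applies the scale as quoted and makes no
attempt to match that sentence. A second caveat: apratoxin D's ω computed
from the 2-decimal printed orbital energies is 1.4917 — just below the
1.5 boundary that its printed (unrounded-input) value 1.50 sits on — so
boundary-adjacent class labels are not robust to input rounding.

### pKa QSAR

pKa = 16.3088 − 0.8268·η (η in eV), a one-descriptor affine model
regressed on amino acids and short peptides. It is a screening-level
estimate only. The externally predicted pKa column packaged with the
apratoxin reference data does **not** follow this formula (e.g. row A: QSAR
12.16 vs external 12.90, and identical external values 12.90 occur for
rows with different η); the package reports the QSAR value and any
external value side by side and never reconciles them.

### Local descriptors

The Fukui function ∂ρ/∂N is not directly computable; the package uses the
standard finite-difference realization at frozen geometry and external
potential: f⁺ = ρ_{N+1} − ρ_N, f⁻ = ρ_N − ρ_{N−1}, and the dual descriptor
DD = f⁺ − f⁻. DD > 0 marks electrophilic-attack sites, DD < 0 nucleophilic
ones; `sign_partition` exports the two lobes as separate cubes (default
isovalue 0) for rendering in any volumetric viewer — rendering itself is
out of scope. Condensed (per-atom) variants accept populations from any
charge-partitioning scheme; no partitioning is implemented. Grid integrals
are plain Riemann sums (value sum × voxel volume), which is exactly the
quadrature against which the synthetic densities are normalized.

## Synthetic data

The generators stand in for the upstream quantum-chemistry outputs:

* **Energy records.** HOMO ~ U(−6.5, −5.8) eV and LUMO ~ U(−1.9, −1.1) eV
  (the range of the apratoxin set), arbitrary neutral total energy, and
  N±1 total energies constructed as E(N−1) = E(N) − ϵH + r_I,
  E(N+1) = E(N) + ϵL − r_A with r ~ Normal(0, σ); σ defaults to 0.05 eV,
  the order of the residuals a KID-compliant functional produces. Because
  the residuals are injected into the *total* energies, J_I and J_A equal
  the drawn residuals exactly (up to ~1e−12 eV float cancellation), making
  recovery tests sharp. The drawn values are returned as a ground-truth
  table. SOMO = ϵL + Normal(0, 0.03 eV).
* **Density triplets.** Sums of isotropic Gaussians at shared random
  centers (widths 0.8–1.6 bohr, per-state random amplitudes so the Fukui
  fields have spatial structure) on a cubic grid (default 24³ over a
  10-bohr box; 64³ in the heavier identity checks), renormalized
  *numerically* so grid integrals equal N−1, N, N+1 exactly on the Riemann
  quadrature. They are not realistic molecular densities — no cusps,
  shells, or asymptotics — so passing integral/identity tests validates
  the field arithmetic and I/O, not chemistry.
* **Log texts.** A minimal, versioned dialect (documented in
  `cdftkit.logparse`) that the parser inverts exactly; real logs are
  expected to be pre-converted to it or to the CSV schema.

All generators are driven by `numpy.random.default_rng(seed)`: identical
specs give bit-identical outputs across platforms.

## Numerical choices

* Cube values are written as fixed-width scientific notation with an
  8-digit mantissa, six per line, guaranteeing read-back within 1e−6
  relative (header fields at fixed 6-decimal precision; synthetic atom
  positions are generated at that precision so round-trips are exact).
  Negative atom counts on input follow the skip-one-extra-line convention;
  lengths are always treated as bohr.
* Display rounding mirrors the reference tables (3 decimals for KID,
  2 for descriptors/pKa); CSV/Markdown tables are display artifacts, the
  JSON mirror carries full precision, and all comparisons in code use
  unrounded values.
* Boundary assignments in classification are documented above;
  `kid_assess` uses ≤ comparisons at the tolerance.
* Problem sizes in the test suite (200–500 synthetic molecules for
  residual-scale recovery, 16³ grids for routine field tests and one 64³
  triplet for the heavier identity check, 10⁴ random draws for the
  algebraic-invariant sweep) were chosen as the smallest sizes at which
  the statistical checks are stable.

## Known limitations

* Frozen-geometry finite differences: relaxation upon electron gain/loss
  is ignored by construction, as in any vertical-Fukui treatment.
* The printed apratoxin reference data carries 2-decimal energies, so
  recomputed descriptors can differ from the printed ones by up to ~0.015
  (and one net-electrophilicity cell by marginally more, since the printed
  gap of row B differs from its printed LUMO−HOMO by one final-digit
  unit); exact agreement is only expected where rounding is benign.
* The nucleophilicity reference and the pKa coefficients are
  model-chemistry- and dataset-specific parameters, not constants.
* No molecular structure handling: the package never sees geometries
  except as cube-file atom lines.
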