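# cdftkit

Conceptual-DFT reactivity prospection for candidate therapeutic molecules.

Given frontier-orbital energies (HOMO ϵH, LUMO ϵL, optionally the radical
anion's SOMO) and optionally ΔSCF total energies and electron-density cube
files of the N−1/N/N+1 electron states, `cdftkit` computes:

* **KID ("Koopmans in DFT") compliance diagnostics** — the residuals
  J_I = ϵH + E(N−1) − E(N), J_A = ϵL + E(N) − E(N+1),
  J_HL = √(J_I² + J_A²) and ΔSL = ϵ_SOMO − ϵL, with a configurable
  pass/fail verdict, validating that the producing functional's orbital
  energies can stand in for −I and −A;
* **global reactivity descriptors** — electronegativity χ = −(ϵH+ϵL)/2,
  chemical potential μ = −χ, hardness η = ϵL−ϵH, softness S = 1/η,
  electrophilicity ω = χ²/(2η), electrodonating/accepting powers
  ω∓ = (3ϵH+ϵL)²/16η and (ϵH+3ϵL)²/16η, net electrophilicity
  Δω± = ω⁻+ω⁺, and the nucleophilicity index N = ϵH − ϵH(TCE), with
  strong/moderate/marginal electrophile and nucleophile classification;
* **a hardness pKa QSAR** — pKa = 16.3088 − 0.8268 η;
* **local reactivity fields** — finite-difference Fukui functions
  f⁺ = ρ_{N+1}−ρ_N, f⁻ = ρ_N−ρ_{N−1} and the dual descriptor
  DD = f⁺−f⁻ on Gaussian-cube grids, condensed per-atom variants, and
  sign-partitioned cubes (DD>0 / DD<0) ready for visualization.

It is aimed at computational medicinal chemists screening small batches of
candidates (the packaged worked example is the apratoxin A–G family of
cytotoxic marine cyclodepsipeptides) from upstream DFT outputs; no
electronic-structure calculation is performed here. A synthetic-data
module generates energy records with known injected Koopmans residuals and
density triplets with known electron counts, so the entire pipeline is
testable without quantum-chemistry software.

## Worked example

The seven packaged apratoxin records carry the printed HOMO/LUMO/SOMO
energies (eV). From the shell:

```bash
cdftkit fixture --out apratoxins.csv
cdftkit descriptors apratoxins.csv
```

prints

```text
id,chi,eta,omega,softness,nucleophilicity,omega_minus,omega_plus,net_electrophilicity,mu,electrophile_class,nucleophile_class
A,3.73,5.02,1.39,0.2,2.55,4.95,1.22,6.17,-3.73,moderate,moderate
B,3.97,4.46,1.77,0.22,2.59,5.8,1.83,7.63,-3.97,strong,moderate
...
G,3.96,4.33,1.81,0.23,2.67,5.86,1.91,7.77,-3.96,strong,moderate
```

Reading row A: χ = 3.73 eV and η = 5.02 eV make apratoxin A the hardest
(least reactive) member of the set; ω = 1.39 eV puts it in the *moderate*
electrophile band (0.8 < ω ≤ 1.5 eV) while the rest of the family is
strong; N = 2.55 eV relative to the tetracyanoethylene reference makes it
— like all seven — a *moderate* nucleophile (2 ≤ N ≤ 3 eV). The same
batch through the QSAR:

```bash
cdftkit pka apratoxins.csv
```

```text
id,eta,pka_qsar
A,5.02,12.16
B,4.46,12.62
...
```

i.e. mildly basic predicted pKa values decreasing with hardness. The same
results are available from Python:

```python
from cdftkit import apratoxin_fixture, compute_all
d = compute_all(apratoxin_fixture()[0])
print(round(d.omega, 2), d.electrophile_class)   # 1.39 moderate
```

Other verbs: `cdftkit kid` (KID diagnostics from records that include the
N±1 total energies), `cdftkit local` (Fukui/dual-descriptor cubes from a
density triplet), `cdftkit simulate` (synthetic records with ground
truth), `cdftkit report` (full bundle: CSV + JSON + Markdown tables), and
`cdftkit ingest` (schema validation). See `docs/methods.md` for the model,
conventions and known caveats of the printed reference data.

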