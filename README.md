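# hxguide

Hydrogen-exchange-guided protein conformational sampling.

Hydrogen exchange (HX) monitoring — by NMR at residue resolution or by mass
spectrometry (MS) at peptide resolution — reports how strongly each backbone
amide is shielded from solvent, but it cannot produce a structural model on
its own. `hxguide` closes that loop for structural biologists and modelers:
it predicts HX observables from atomic coordinates, quantifies the fit of a
model against experimental HX data, and runs a Monte Carlo conformational
search whose moves concentrate on the regions where that fit is worst, so
that low-resolution HX data can steer a search toward the protein state
that produced it.

## The model

Protection of residue *i* in conformation *C* is attributed to backbone
hydrogen bonding and atomic packing around its amide hydrogen:

    ln P_i(C) = β_h · N_i^h(C) + β_c · N_i^c(C)        (β_h = 2, β_c = 0.35)

where `N_i^h` counts backbone carbonyl oxygens within 2.4 Å of the amide H
and `N_i^c` counts heavy atoms within 6.5 Å, excluding residues *i*−2 … *i*+2
of the same chain in both counts. Residue-level deuterium uptake follows
pseudo-first-order kinetics in the EX2 limit,

    d_i(t) = 1 − exp(−(k_i^int / P_i) · t),

with `k_i^int` the intrinsic (unstructured-chain) exchange rate. Peptide
uptake `D_j(t)` averages `d_i(t)` over the peptide's residues, skipping its
first two residues (back-exchange) and prolines. Fit quality is measured by
`e(i) = |ln P_i^der − ln P_i^obs|` for HX-NMR and
`E(j) = Σ_{t∈T} |D_j^der(t) − D_j^obs(t)|` for HX-MS, aggregated into an
average error; HX-NMR free energies convert via ΔG_i = R·T·ln P_i
(R = 0.0019872036 kcal K⁻¹ mol⁻¹, T = 298.15 K).

The guided search iterates: explore conformations from a starting structure
(backbone-dihedral, loop, rigid-body and minimization moves, Metropolis-
accepted on a pluggable energy-like score), pick the conformation with the
lowest average HX error, convert its residual per-residue mismatch into a
normalized sampling-bias map, and explore again from there — until the fit
stops improving.

## Worked example

`examples/03_guided_recovery.py` recovers a 24-residue helix from a fully
extended start, using only uptake curves derived from the helix:

```text
initial average peptide error: 3.674
iteration 1 (unbiased): best error 0.245 (406 conformations)
iteration 2 (  biased): best error 0.232 (302 conformations)
iteration 3 (  biased): best error 0.228 (339 conformations)
final error: 0.228  [max_iterations]
error reduced by 94%
C-alpha RMSD of recovered model to the true target: 4.06 A
```

The initial error of 3.674 is the average `E(j)` of the extended model —
each peptide's uptake is nearly 1 at every time point while the helix
exchanges slowly. The protocol rebuilds the protection pattern (helical
hydrogen bonds plus packing), cutting the error by 94%; the remaining
mismatch corresponds to frayed chain ends. The other examples show the
forward model (`01`), fitting and bias-map construction (`02`), and the
synthetic-data generator (`04`).

A thin CLI mirrors the library for shell use:

```sh
hxguide synth --sequence ADKLMNQEARNDCEFGHKLA --motif alpha_helix -o helix.pdb
hxguide predict helix.pdb --mode residue -o lnp.csv
hxguide fit model.pdb --obs hxms.csv --kint rates.csv -o report.csv --bias-out bias.csv
hxguide guide start.pdb --obs hxms.csv --kint rates.csv --iterations 5 --moves 2000 -o out/
```

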