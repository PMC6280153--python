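"""Score a structure against experimental HX data and derive a sampling bias.

Uses a synthetic 'experiment': uptake curves derived from a helix, with
Gaussian noise standing in for measurement scatter. An extended chain of
the same sequence is then fit against those curves; the per-peptide errors
E(j) = sum_t |D_der - D_obs| localize the mismatch, and the bias map turns
them into a per-residue sampling distribution.
"""

import numpy as np
import pandas as pd

import hxguide as hx

seq = "ADKLMNQEARNDCEFGHKLA"
target = hx.build_ideal_chain(hx.ChainSpec(seq, motif="alpha_helix"))
model = hx.build_ideal_chain(hx.ChainSpec(seq, motif="extended"))
kint = pd.DataFrame({"chain": "A", "residue": range(2, len(seq) + 1),
                     "kint_per_s": 1.0})

observed, _ = hx.make_synthetic_hx(target, kint, mode="peptide",
                                   noise_sd=0.02, seed=11)

derived = hx.predict_hx_dataset(
    model, kint, mode="peptide",
    peptides=[(c.chain, c.start, c.end) for c in observed],
    times=observed[0].times)
report = hx.peptide_errors(derived, observed)

print(f"{report.n} peptides compared; average error "
      f"{hx.average_error(report):.3f}")
print("per-peptide errors E(j):")
for pid, e in zip(report.items, report.errors):
    print(f"  {pid:>8}  {e:.3f}")
edges, counts = hx.error_histogram(report, 0.5)
print("error histogram (bin width 0.5):", list(counts))

residues = [(r.chain, r.resseq) for r in model.residues]
bias = hx.bias_map(report, residues)
print("\nbias map (weights sum to 1; high weight = sample here):")
print(bias.to_frame().round(4).to_string(index=False))
print("... an extended model mismatches helix-derived data everywhere, so "
      "the bias is nearly flat; localized mismatch would concentrate it.")
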