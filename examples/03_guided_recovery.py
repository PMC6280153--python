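"""HX-guided conformational recovery, scaled to seconds.

Target: an ideal 24-residue helix. Start: the same sequence fully extended.
'Experimental' data: the noiseless forward model of the target. The guided
protocol alternates exploration and re-biasing: each iteration explores
from the best-fitting conformation so far, with move sites drawn from the
residual per-residue mismatch.
"""

import pandas as pd

import hxguide as hx

n = 24
target = hx.build_ideal_chain(hx.ChainSpec("A" * n, motif="alpha_helix"))
start = hx.build_ideal_chain(hx.ChainSpec("A" * n, motif="extended"))
kint = pd.DataFrame({"chain": "A", "residue": range(2, n + 1),
                     "kint_per_s": 1.0})
observed, _ = hx.make_synthetic_hx(target, kint, mode="peptide", noise_sd=0.0)

result = hx.guided_protocol(start, observed, kint,
                            max_iterations=3, moves_per_iteration=600,
                            tolerance=0.0, seed=1)

print(f"initial average peptide error: {result.initial_error:.3f}")
for it in result.iterations:
    tag = "unbiased" if it.bias_used is None else "biased"
    print(f"iteration {it.index} ({tag:>8}): best error {it.best_error:.3f} "
          f"({it.n_nodes} conformations)")
print(f"final error: {result.final_error:.3f}  [{result.stop_reason}]")
print(f"error reduced by "
      f"{100 * (1 - result.final_error / result.initial_error):.0f}%")

rmsd = hx.rmsd(result.final_conformation, target,
               hx.AtomSelection(kind="calpha"))
print(f"C-alpha RMSD of recovered model to the true target: {rmsd:.2f} A")
print("... the error drop shows the sampler rebuilding the protection "
      "pattern (helical H-bonds and packing) encoded in the HX data.")
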