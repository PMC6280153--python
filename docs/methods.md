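# Methods

This note documents the models implemented in `hxguide`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical and design decisions a maintainer would want
recorded.

## Forward model: structure → HX observables

Protection is modeled phenomenologically: `ln P_i = β_h·N_i^h + β_c·N_i^c`
with `β_h = 2` and `β_c = 0.35` (unitless, `HxModelParams.beta_h/beta_c`).
`N_i^h` is the number of backbone carbonyl oxygens within 2.4 Å of the
amide hydrogen of residue *i*; `N_i^c` the number of heavy atoms within
6.5 Å of the same hydrogen. Both counts exclude atoms belonging to residues
*i*−2 … *i*+2 of the *same chain*, measured in sequential residue order (so
numbering gaps in a PDB file do not widen the window). The window is never
applied across chains: in a dimer, a partner-chain atom at hydrogen-bond
distance protects normally, which is precisely the signal interchain HX
experiments carry. "Backbone oxygen" means the carbonyl O (and C-terminal
OXT/OT variants); side-chain oxygens are excluded. Prolines and the first
residue of each chain carry no exchangeable amide (`monitorable=False`) and
are excluded from counts, averages and fits throughout.

Residue uptake assumes EX2 pseudo-first-order kinetics,
`d_i(t) = 1 − exp(−(k_int,i / P_i)·t)`. Peptide uptake averages the uptake
*fractions* of the peptide's residues, always dropping the first two raw
positions of the peptide (back-exchange convention; a proline in those
positions is not "compensated" by shifting the window) and dropping
prolines independently. `ln P` is capped at 700 before exponentiation; the
cap is orders of magnitude beyond any realistic count and exists only to
keep `exp` finite.

Counting is k-d-tree accelerated (`scipy.spatial.cKDTree`) and is tested
for exact agreement against an exhaustive O(n²) distance-matrix oracle on
randomized multi-chain structures, including boundary and window rules.
The boundary convention is a closed ball (distance ≤ cutoff); since
coordinates are continuous this choice is measure-zero but is pinned down
so the oracle and the tree agree bit-for-bit. A vectorized evaluation path
(`HxEvaluator`) precomputes candidate pools and exclusion masks per
topology for the sampler's inner loop and is tested to reproduce the
reference path exactly.

## Intrinsic rates

The primary path is a user-supplied measured rate table (`chain, residue,
kint_per_s`), validated for coverage and positivity. The built-in
predictor implements the classic poly-DL-alanine reference scheme —
acid/base/water catalysis channels with the standard reference rates
(log₁₀ k at 293 K: 1.62, 10.05, −1.5), activation energies (14, 17, 19
kcal/mol) and the heavy-water ion product pK_D = 15.05 — modulated by
log-additive nearest-neighbor side-chain factors. The per-residue factor
table is an *approximate* parameterization of the published inductive and
steric effects, adequate for qualitative work and pipeline exercise;
quantitative studies should supply a measured table. Every test of
downstream machinery uses explicit tables, so nothing in the package's
validated behavior depends on the approximate factors.

## Goodness of fit and bias maps

Residue mode compares `ln P` values over the intersection of derived and
observed tables (`e(i) = |Δ ln P|`); peptide mode compares curves matched
by (chain, start, end) with identical time grids
(`E(j) = Σ_t |ΔD|`). Replicate experimental curves are averaged per time
point at load time. Errors aggregate into an arithmetic mean and a
fixed-width histogram.

The bias map converts a fit report into a sampling distribution over all
residues. Peptide-mode raw weight of a residue is the mean `E(j)` of the
peptides covering it (zero if uncovered — an uncovered residue carries no
experimental signal); residue mode uses `e(i)` directly. The profile is
smoothed by a ±2-residue moving average (within chains only), floored at
5% of the maximum raw weight so no region ever becomes unsampleable
(preserving ergodicity; with an all-zero report the floor makes the map
uniform), and normalized to sum to 1. The mapping is linear and monotone:
raising a peptide's error never lowers the weight of residues it covers.

## Sampler

Conformations are full-atom arrays sharing an immutable topology, so a
move copies one coordinate array. Backbone dihedral rotations move the
segment on the lighter side of the pivot bond (lever-arm rule), preserving
all bond lengths and angles to machine precision; a cheap geometry check
(finite coordinates, backbone bonds within 0.5 Å of standard) rejects
degenerate candidates.

Move kinds (`MoveSet`):

- **dihedral** — either an incremental Gaussian step on one residue's
  (φ, ψ) (s.d. 15°), or, with probability `resample_prob = 0.6`, a
  *Ramachandran-guided resample*: a 1–5-residue segment has its (φ, ψ)
  re-drawn from one of the favored basins (α, β, PPII, α_L) with 10°
  jitter. The resample component plays the role fragment insertion plays
  in full-atom samplers. It exists because the incremental-only move set
  demonstrably cannot nucleate secondary structure against a clash-aware
  score: in the helix-recovery benchmark, incremental moves plus tree
  search achieved no error reduction over 6000 moves, while the mixed
  proposal reaches ~95%.
- **loop** — 2–6 consecutive residues receive small anti-correlated
  (φ, ψ) changes (s.d. 6°), a cheap stand-in for loop moves without exact
  closure (kinematic loop closure is out of scope).
- **rigid_body** — whole-chain rotation/translation (8°, 1 Å s.d.),
  attempted only on multi-chain structures; sub-chain selections are
  rejected because they would require loop closure.
- **minimize** — greedy coordinate descent in dihedral space: each step
  visits one residue cyclically and keeps the best of four ±8° probes if
  it improves the score; the score never increases.

The default score is a deliberately simple energy stand-in, not a force
field: a soft-sphere clash penalty over non-bonded heavy-atom pairs within
2.7 Å (weight 25), a −1 reward per backbone H-bond (same counting rule as
the forward model), and a Ramachandran plausibility penalty (quadratic in
angular distance beyond 30° from the nearest favored basin). Any callable
`conformation → float` can replace it (`score_fn`), which is the intended
seam for plugging in a real molecular mechanics or knowledge-based scorer.

Exploration grows a rooted tree. Parent selection mixes depth-first
continuation (probability 0.5: expand the most recently accepted node)
with global restarts by softmax over negative scores at the acceptance
temperature; pure softmax selection gives a tree of expected depth
~2·ln n, far too shallow to travel anywhere in dihedral space, which is
why the continuation component exists. Candidates are Metropolis-accepted
on the score (default temperature 1.0 score units). All stochastic draws
flow from one seeded `numpy` generator; runs are exactly reproducible.

The guided protocol runs exploration in iterations with a per-iteration
move budget (replacing wall-clock budgets with deterministic counts;
defaults are sized for minutes-scale desk runs). Iteration 1 is unbiased;
afterwards the node with the lowest average HX error becomes the next
start and its residual errors become the next bias map. The best-so-far
error is carried forward, so per-iteration best errors are monotone
non-increasing by construction. The run stops when the improvement falls
below `tolerance` (reported as "converged" — the threshold for a "good
fit" is a user decision, exposed, with no claimed default) or at
`max_iterations`.

Side chains are not modeled beyond C-β on generated structures; contact
counts therefore use the atoms present. This systematically undercounts
`N^c` relative to full-atom structures (a full side chain contributes
several heavy atoms within 6.5 Å), so absolute `ln P` values from
C-β-only models are comparable to each other but not to full-atom-derived
values — consistent targets (e.g. synthetic data from the same
representation) are required.

## Synthetic data

`build_ideal_chain` constructs chains by natural-extension (NeRF) from
standard backbone geometry (N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å,
C=O 1.231 Å, Engh–Huber-style angles), trans peptide bonds (ω = 180°), an
amide H on the external bisector of C(prev)–N–CA at 1.01 Å, and C-β
placed with L-amino-acid chirality. Named motifs: α-helix (−57°, −47°)
and extended (−139°, 135°).

`digest` emulates HX-MS proteolysis with overlapping windows: starts
every `step` residues, lengths cycling deterministically through
[min, max] (defaults 6–20, matching typical proteolytic peptides), plus a
final window so the C-terminus is covered; coverage is 100% whenever
`step ≤ min`. `make_synthetic_hx` derives the exact forward-model dataset
and adds independent Gaussian noise — in uptake-fraction units (MS mode,
clipped to [0, 1]) or ln P units (NMR mode, clipped at 0). The default
labeling schedule is 10 s, 30 s, 1 min, 5 min, 15 min.

What this emulates and what it does not: the generator reproduces the
*structure* of real HX-MS datasets (peptide maps, time grids, replicate
scatter via seeds) but not correlated noise between overlapping peptides,
back-exchange variability, EX1 kinetics, pH/temperature dependence of the
β parameters, or isotope envelopes. Tests passing on synthetic data
therefore validate the computational machinery, not the phenomenological
model's accuracy on real proteins.

The noise calibration check compares the mean peptide error against the
folded-Gaussian expectation `Σ_t E|N(0, sd)| = n_t·sd·√(2/π)`. Boundary
clipping makes the measured value sit a few percent below that
expectation; the calibration fixture uses a rate table giving a uniform
observed rate of 3.5×10⁻³ s⁻¹ so that every time point stays inside the
experiment's dynamic range and the clipping bias stays small.

## Problem sizes used in the checks

The recovery benchmark uses a 40-residue chain, 3 iterations of 2000
moves, and 5 seeds for the biased-vs-unbiased comparison (equal total
budgets of 6000 moves per arm); oracle-equivalence runs 100 random dimers
of 200–2000 atoms. These sizes were chosen so the full suite completes in
minutes on a single CPU while each check still has clear statistical
headroom.

## Known limitations

- The default score is qualitative; conformations it favors are plausible
  backbones, not refined models. Use `score_fn` for serious work.
- No side-chain packing, no loop closure, no parallel search.
- The intrinsic-rate factor table is approximate (see above).
- mmCIF files, insertion codes, and chains with missing backbone atoms
  are rejected rather than repaired.
- The HX model assumes EX2 throughout; EX1 regimes are out of scope.
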