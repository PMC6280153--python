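"""Ground-truth fixtures: ideal-geometry chains, peptide digests and
synthetic HX datasets.

Chains are built residue-by-residue from standard backbone bond lengths and
angles (Engh-Huber-style values) with requested (phi, psi) dihedrals and
trans peptide bonds; besides the backbone each residue carries its amide H
and, for non-glycine, a C-beta. Digests emulate HX-MS proteolysis with
overlapping 6-20-residue peptides. Synthetic datasets are the exact forward
model of a conformation plus optional independent Gaussian noise, which
stands in for experimental scatter (replicate averaging is emulated by
generating several datasets with distinct seeds).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .forward import HxModelParams, PeptideCurve, predict_hx_dataset
from .geometry import place_atom
from .structure import Conformation, ONE_TO_THREE, place_amide_hydrogens

__all__ = [
    "ChainSpec",
    "DigestSpec",
    "MOTIF_ANGLES",
    "build_ideal_chain",
    "digest",
    "make_synthetic_hx",
    "DEFAULT_TIME_POINTS",
]

# Backbone geometry constants (Angstrom / degrees)
_B_N_CA = 1.458
_B_CA_C = 1.525
_B_C_N = 1.329
_B_C_O = 1.231
_B_CA_CB = 1.521
_A_C_N_CA = 121.7
_A_N_CA_C = 111.2
_A_CA_C_N = 116.2
_A_CA_C_O = 120.8
_A_N_CA_CB = 110.4

MOTIF_ANGLES = {
    "alpha_helix": (-57.0, -47.0),
    "extended": (-139.0, 135.0),
}

# HX-MS-style labeling schedule (s): 10 s, 30 s, 1 min, 5 min, 15 min
DEFAULT_TIME_POINTS = (10.0, 30.0, 60.0, 300.0, 900.0)


@dataclass(frozen=True)
class ChainSpec:
    """Recipe for one ideal chain: 1-letter sequence plus either a named
    motif or explicit per-residue (phi, psi) in degrees."""

    sequence: str
    motif: str | None = "alpha_helix"
    phi_psi: tuple | None = None       # sequence of (phi, psi) pairs
    chain_id: str = "A"

    def angles(self) -> list[tuple[float, float]]:
        if not self.sequence:
            raise ValueError("sequence must be non-empty")
        if self.phi_psi is not None:
            pairs = [(float(p), float(s)) for p, s in self.phi_psi]
            if len(pairs) != len(self.sequence):
                raise ValueError("phi_psi length must match sequence")
            return pairs
        if self.motif not in MOTIF_ANGLES:
            raise ValueError(f"unknown motif {self.motif!r}")
        return [MOTIF_ANGLES[self.motif]] * len(self.sequence)


@dataclass(frozen=True)
class DigestSpec:
    """Proteolytic digest emulation: peptide lengths in [min_len, max_len],
    successive peptide starts `step` residues apart."""

    min_len: int = 6
    max_len: int = 20
    step: int = 3

    def __post_init__(self):
        if not (1 <= self.min_len <= self.max_len):
            raise ValueError("need 1 <= min_len <= max_len")
        if self.step < 1:
            raise ValueError("step must be >= 1")


def build_ideal_chain(spec: ChainSpec) -> Conformation:
    """Construct a full-backbone conformation (N, CA, C, O, amide H, and
    C-beta for non-Gly) from standard geometry and the requested dihedrals;
    omega is fixed at 180 degrees (trans)."""
    seq = spec.sequence.upper()
    for ch in seq:
        if ch not in ONE_TO_THREE:
            raise ValueError(f"unknown residue letter {ch!r}")
    angles = spec.angles()
    n = len(seq)

    # backbone trace: N, CA, C per residue via NeRF
    N = np.zeros((n, 3))
    CA = np.zeros((n, 3))
    C = np.zeros((n, 3))
    N[0] = [0.0, 0.0, 0.0]
    CA[0] = [_B_N_CA, 0.0, 0.0]
    C[0] = place_atom(np.array([0.0, 1.0, 0.0]), N[0], CA[0],
                      _B_CA_C, _A_N_CA_C, 57.0)
    for i in range(1, n):
        phi_i, _ = angles[i]
        _, psi_prev = angles[i - 1]
        N[i] = place_atom(N[i - 1], CA[i - 1], C[i - 1],
                          _B_C_N, _A_CA_C_N, psi_prev)
        CA[i] = place_atom(CA[i - 1], C[i - 1], N[i],
                           _B_N_CA, _A_C_N_CA, 180.0)       # omega = trans
        C[i] = place_atom(C[i - 1], N[i], CA[i],
                          _B_CA_C, _A_N_CA_C, phi_i)

    chain_ids, res_seq, res_names, atom_names, elements, xyz = [], [], [], [], [], []

    def add(resi: int, name: str, element: str, pos: np.ndarray):
        chain_ids.append(spec.chain_id)
        res_seq.append(resi + 1)
        res_names.append(ONE_TO_THREE[seq[resi]])
        atom_names.append(name)
        elements.append(element)
        xyz.append(pos)

    for i in range(n):
        _, psi_i = angles[i]
        add(i, "N", "N", N[i])
        add(i, "CA", "C", CA[i])
        if seq[i] != "G":
            # C-beta from the local tetrahedral frame (L-amino acid chirality)
            cb = place_atom(C[i], N[i], CA[i], _B_CA_CB, _A_N_CA_CB, 122.6)
            add(i, "CB", "C", cb)
        add(i, "C", "C", C[i])
        o = place_atom(N[i], CA[i], C[i], _B_C_O, _A_CA_C_O, psi_i + 180.0)
        add(i, "O", "O", o)

    conf = Conformation(chain_ids, res_seq, res_names, atom_names, elements,
                        np.array(xyz))
    return place_amide_hydrogens(conf)


def digest(sequence_length: int, spec: DigestSpec | None = None,
           first_residue: int = 1) -> tuple[list[tuple[int, int]], float]:
    """Overlapping peptide windows over a chain.

    Returns (bounds, coverage): 1-based inclusive (start, end) pairs and the
    fraction of residues covered by at least one peptide. Peptide lengths
    cycle deterministically through [min_len, max_len]; when min_len ==
    max_len every peptide has that length.
    """
    spec = spec or DigestSpec()
    L = sequence_length
    if spec.min_len > L:
        raise ValueError(f"min peptide length {spec.min_len} exceeds chain "
                         f"length {L}")
    span = spec.max_len - spec.min_len + 1
    bounds: list[tuple[int, int]] = []
    k = 0
    start = 1
    while start + spec.min_len - 1 <= L:
        length = spec.min_len + (k % span)
        end = min(start + length - 1, L)
        if end - start + 1 >= spec.min_len:
            bounds.append((start, end))
        start += spec.step
        k += 1
    # ensure the C-terminal residues are reachable by one last window
    if bounds and bounds[-1][1] < L and L - spec.min_len + 1 > bounds[-1][0]:
        bounds.append((L - spec.min_len + 1, L))
    covered = np.zeros(L, dtype=bool)
    for s, e in bounds:
        covered[s - 1:e] = True
    offset = first_residue - 1
    bounds = [(s + offset, e + offset) for s, e in bounds]
    return bounds, float(covered.mean())


def make_synthetic_hx(conf: Conformation, kint_table, mode: str = "peptide",
                      digest_spec: DigestSpec | None = None,
                      times=DEFAULT_TIME_POINTS,
                      noise_sd: float = 0.0,
                      seed: int | None = None,
                      params: HxModelParams | None = None,
                      peptides=None):
    """Synthetic HX dataset derived from a conformation.

    Runs the exact forward model, then adds independent Gaussian noise
    (uptake-fraction units in MS mode, ln P units in NMR mode; MS uptakes
    clipped to [0, 1], lnP clipped at 0). Returns (observed, truth) where
    `truth` is the noiseless dataset.
    """
    if noise_sd < 0:
        raise ValueError("noise sd must be non-negative")
    params = params or HxModelParams()
    rng = np.random.default_rng(seed)

    if mode == "residue":
        truth = predict_hx_dataset(conf, mode="residue", params=params)
        observed = truth.copy()
        if noise_sd > 0:
            observed["lnP"] = np.clip(
                observed["lnP"] + rng.normal(0.0, noise_sd, len(observed)),
                0.0, None)
        return observed, truth

    if mode != "peptide":
        raise ValueError(f"unknown mode {mode!r}")
    if peptides is None:
        chain = conf.chains()[0]
        first = conf.topology.res_seq[0]
        nres = sum(1 for r in conf.residues if r.chain == chain)
        bounds, _ = digest(nres, digest_spec, first_residue=int(first))
        peptides = [(chain, s, e) for s, e in bounds]
    truth = predict_hx_dataset(conf, kint_table, mode="peptide",
                               peptides=peptides, times=times, params=params)
    observed = []
    for c in truth:
        up = c.uptake.copy()
        if noise_sd > 0:
            up = np.clip(up + rng.normal(0.0, noise_sd, up.shape), 0.0, 1.0)
        observed.append(PeptideCurve(c.peptide_id, c.chain, c.start, c.end,
                                     c.times.copy(), up, c.sequence))
    return observed, truth
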