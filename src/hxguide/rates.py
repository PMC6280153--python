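"""Intrinsic (unstructured-chain) amide exchange rates.

The primary path is a user-supplied measured rate table, validated and
passed through. The built-in predictor is a convenience implementation of
the classic poly-DL-alanine reference scheme with nearest-neighbor
side-chain corrections: exchange is the sum of acid-, base- and
water-catalyzed channels,

    kint = kA * [D+] + kB * [OD-] + kW,

each channel scaled by log-additive factors contributed by the residue's own
side chain and by the preceding residue's side chain, with Arrhenius
temperature scaling from the 293 K reference. The reference-rate constants,
activation energies and heavy-water ion product below are the standard
literature values; the per-residue neighbor factors are an approximate
parameterization of the published inductive/steric effects — adequate for
qualitative work and for exercising the pipeline, but quantitative studies
should supply a measured table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["intrinsic_rates"]

# Reference rates for poly-DL-alanine at 293 K (per minute; molar for kA/kB).
_LOG_KA_REF = 1.62      # M^-1 min^-1
_LOG_KB_REF = 10.05     # M^-1 min^-1
_LOG_KW_REF = -1.5      # min^-1
_PKD = 15.05            # heavy-water ion product at 293 K
_EA_ACID = 14.0         # kcal/mol
_EA_BASE = 17.0
_EA_WATER = 19.0
_R = 0.0019872036       # kcal K^-1 mol^-1
_T_REF = 293.0          # K

# Approximate nearest-neighbor log10 factors:
# (acid_self, acid_left, base_self, base_right->?).
# Convention: for the amide of residue i, the acid/base rate factors are
#   self(residue i) + left(residue i-1)
# i.e. "self" is the side chain attached to the exchanging amide's residue,
# "left" the preceding side chain. Values capture the known qualitative
# inductive (charged/polar accelerate base catalysis, retard acid) and
# steric (beta-branched retard) effects.
_FACTORS: dict[str, tuple[float, float, float, float]] = {
    # res: (acid_self, acid_left, base_self, base_left)
    "A": (0.00, 0.00, 0.00, 0.00),
    "R": (-0.59, -0.32, 0.08, 0.22),
    "N": (-0.58, -0.13, 0.49, 0.32),
    "D": (0.90, 0.58, -0.30, -0.18),
    "C": (-0.54, -0.46, 0.62, 0.55),
    "G": (-0.22, 0.22, 0.27, 0.17),
    "Q": (-0.47, -0.27, 0.06, 0.20),
    "E": (-0.90, -0.31, -0.11, -0.15),
    "H": (-0.80, -0.51, 0.80, 0.83),
    "I": (-0.91, -0.59, -0.73, -0.23),
    "L": (-0.57, -0.13, -0.58, -0.21),
    "K": (-0.56, -0.29, -0.04, 0.12),
    "M": (-0.64, -0.28, -0.01, 0.11),
    "F": (-0.52, -0.43, -0.24, 0.06),
    "P": (0.00, -0.19, 0.00, -0.24),
    "S": (-0.44, -0.39, 0.37, 0.30),
    "T": (-0.79, -0.47, -0.07, 0.20),
    "W": (-0.40, -0.44, -0.41, -0.11),
    "Y": (-0.41, -0.37, -0.27, 0.05),
    "V": (-0.74, -0.30, -0.70, -0.14),
}


def _arrhenius(log_k_ref: float, ea: float, temperature: float) -> float:
    k_ref = 10.0 ** log_k_ref
    return k_ref * np.exp(-ea / _R * (1.0 / temperature - 1.0 / _T_REF))


def intrinsic_rates(sequence: str, pD: float = 7.0, temperature: float = 293.0,
                    user_table: pd.DataFrame | None = None,
                    chain: str = "A") -> pd.DataFrame:
    """Per-residue intrinsic exchange rates (s^-1) for a 1-letter sequence.

    Residue numbering is 1-based along `sequence`. Position 1 (chain
    N-terminus) and prolines are not monitorable and are omitted from the
    output. If `user_table` (columns chain, residue, kint_per_s) is given it
    is validated — every monitorable residue covered, all rates positive —
    and returned unchanged.
    """
    monitorable = [i for i in range(2, len(sequence) + 1)
                   if sequence[i - 1] != "P"]

    if user_table is not None:
        have = {(str(r.chain), int(r.residue)) for r in user_table.itertuples()}
        for i in monitorable:
            if (chain, i) not in have:
                raise ValueError(f"user rate table missing monitorable residue "
                                 f"{chain}:{i}")
        if (user_table["kint_per_s"] <= 0).any():
            bad = user_table[user_table["kint_per_s"] <= 0].iloc[0]
            raise ValueError(f"non-positive intrinsic rate at "
                             f"{bad['chain']}:{int(bad['residue'])}")
        return user_table

    bad = set(sequence) - set(_FACTORS)
    if bad:
        raise ValueError(f"non-standard residue letters: {sorted(bad)}")

    ka0 = _arrhenius(_LOG_KA_REF, _EA_ACID, temperature)
    kb0 = _arrhenius(_LOG_KB_REF, _EA_BASE, temperature)
    kw0 = _arrhenius(_LOG_KW_REF, _EA_WATER, temperature)
    conc_d = 10.0 ** (-pD)
    conc_od = 10.0 ** (pD - _PKD)

    rows = []
    for i in monitorable:
        self_aa = sequence[i - 1]
        left_aa = sequence[i - 2]
        fa = _FACTORS[self_aa][0] + _FACTORS[left_aa][1]
        fb = _FACTORS[self_aa][2] + _FACTORS[left_aa][3]
        k_min = (ka0 * 10.0 ** fa * conc_d
                 + kb0 * 10.0 ** fb * conc_od
                 + kw0 * 10.0 ** fb)
        rows.append({"chain": chain, "residue": i, "kint_per_s": k_min / 60.0})
    return pd.DataFrame(rows)
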