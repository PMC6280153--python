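import numpy as np
import pandas as pd
import pytest

import hxguide as hx
from hxguide.forward import HxModelParams, monitorable_mask


@pytest.fixture(scope="session")
def params():
    return HxModelParams()


@pytest.fixture(scope="session")
def helix12():
    return hx.build_ideal_chain(hx.ChainSpec("A" * 12, motif="alpha_helix"))


@pytest.fixture(scope="session")
def extended12():
    return hx.build_ideal_chain(hx.ChainSpec("A" * 12, motif="extended"))


@pytest.fixture(scope="session")
def tripeptide():
    return hx.build_ideal_chain(hx.ChainSpec("AAA", motif="extended"))


def uniform_kint(conf, rate=1.0):
    """kint table covering every monitorable residue of a conformation."""
    t = conf.topology
    mon = monitorable_mask(conf)
    rows = [{"chain": t.res_chain[k], "residue": int(t.res_seq[k]),
             "kint_per_s": rate} for k in range(conf.n_residues) if mon[k]]
    return pd.DataFrame(rows)


def random_multichain(rng, n_res_a=None, n_res_b=None):
    """Two randomly coiled chains pushed near each other: a dimer-like
    fixture with genuine cross-chain contacts."""
    if n_res_a is None:
        n_res_a = int(rng.integers(8, 40))
    if n_res_b is None:
        n_res_b = int(rng.integers(8, 40))

    def coil(n, chain_id):
        letters = np.array(list("ACDEFGHIKLMNQRSTVWY"))  # no proline here
        seq = "".join(rng.choice(letters, n))
        phi_psi = [(float(rng.uniform(-150, -40)), float(rng.uniform(-60, 160)))
                   for _ in range(n)]
        return hx.build_ideal_chain(
            hx.ChainSpec(seq, motif=None, phi_psi=phi_psi, chain_id=chain_id))

    a = coil(n_res_a, "A")
    b = coil(n_res_b, "B")
    # push chain B against chain A with a random rigid placement
    shift = a.coords.mean(axis=0) - b.coords.mean(axis=0) + rng.normal(0, 4.0, 3)
    chain_ids = np.concatenate([a.chain_ids, b.chain_ids])
    res_seq = np.concatenate([a.res_seq, b.res_seq])
    res_names = np.concatenate([a.res_names, b.res_names])
    atom_names = np.concatenate([a.atom_names, b.atom_names])
    elements = np.concatenate([a.elements, b.elements])
    coords = np.vstack([a.coords, b.coords + shift])
    return hx.Conformation(chain_ids, res_seq, res_names, atom_names,
                           elements, coords)


def brute_force_counts(conf, params):
    """O(n^2) reference for Nh/Nc, written directly from the counting rule:
    distances from each amide H to every candidate atom, excluding residues
    i-w..i+w of the same chain."""
    t = conf.topology
    mon = monitorable_mask(conf)
    w = params.sequence_exclusion_halfwidth
    is_bb_o = np.isin(conf.atom_names, ("O", "OT1", "OT2", "OXT", "O1", "O2"))
    is_heavy = conf.elements != "H"
    out = {}
    for k in range(conf.n_residues):
        if not mon[k]:
            continue
        h = conf.coords[t.idx_H[k]]
        nh = nc = 0
        for i in range(conf.n_atoms):
            r = t.atom_res_ordinal[i]
            if (t.res_chain[r] == t.res_chain[k]
                    and abs(t.res_seq_index[r] - t.res_seq_index[k]) <= w):
                continue
            d = np.linalg.norm(conf.coords[i] - h)
            if is_bb_o[i] and d <= params.hbond_cutoff:
                nh += 1
            if is_heavy[i] and d <= params.contact_cutoff:
                nc += 1
        out[(t.res_chain[k], int(t.res_seq[k]))] = (nh, nc)
    return out
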