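"""Phenomenological hydrogen-exchange forward model.

Protection from exchange is attributed to backbone hydrogen bonding and to
atomic packing around each amide hydrogen:

    ln P_i = beta_h * Nh_i + beta_c * Nc_i

where Nh_i counts backbone carbonyl oxygens within a short cutoff of the
amide hydrogen of residue i, Nc_i counts heavy atoms within a larger cutoff,
and in both counts residues i-2..i+2 of the same chain are excluded (their
atoms are trivially close). Residue-level deuterium uptake follows
pseudo-first-order kinetics, d_i(t) = 1 - exp(-(kint_i / P_i) t), and
peptide-level uptake is the average over the peptide's residues after
dropping the first two (back-exchange) and any proline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structure import Conformation, StructureError

__all__ = [
    "HxModelParams",
    "ResidueHx",
    "PeptideCurve",
    "monitorable_mask",
    "count_hbonds",
    "count_contacts",
    "hx_counts",
    "log_protection",
    "deuterium_fraction",
    "peptide_uptake",
    "lnP_from_deltaG",
    "deltaG_from_lnP",
    "predict_hx_dataset",
]

_LNP_CAP = 700.0  # guards exp() overflow; never binds for realistic counts


@dataclass(frozen=True)
class HxModelParams:
    """Parameters of the protection-factor model and uptake bookkeeping.

    beta_h, beta_c
        Weights of the hydrogen-bond and heavy-atom-contact counts in ln P.
    hbond_cutoff, contact_cutoff
        Distance cutoffs (Angstrom) from the amide hydrogen for the two counts.
    sequence_exclusion_halfwidth
        Residues i-w..i+w of the same chain are excluded from both counts.
    backexchange_skip
        Leading residues of each peptide dropped from uptake averages.
    gas_constant, temperature
        Used by the Delta-G <-> ln P conversion (kcal/mol scale).
    """

    beta_h: float = 2.0
    beta_c: float = 0.35
    hbond_cutoff: float = 2.4
    contact_cutoff: float = 6.5
    sequence_exclusion_halfwidth: int = 2
    backexchange_skip: int = 2
    gas_constant: float = 0.0019872036   # kcal K^-1 mol^-1
    temperature: float = 298.15          # K

    def __post_init__(self):
        if self.hbond_cutoff <= 0 or self.contact_cutoff <= 0:
            raise ValueError("cutoffs must be positive")
        if self.beta_h < 0 or self.beta_c < 0:
            raise ValueError("beta_h and beta_c must be non-negative")


@dataclass
class ResidueHx:
    """Per-residue exchange state: counts, protection, observed rate."""

    chain: str
    residue: int
    kint: float | None = None        # s^-1
    n_hbonds: int | None = None
    n_contacts: int | None = None
    lnP: float | None = None
    monitorable: bool = True

    @property
    def kobs(self) -> float | None:
        if not self.monitorable or self.kint is None or self.lnP is None:
            return None
        return self.kint / np.exp(min(self.lnP, _LNP_CAP))


@dataclass
class PeptideCurve:
    """Deuterium-uptake kinetics of one proteolytic peptide."""

    peptide_id: str
    chain: str
    start: int                       # first residue (inclusive, PDB numbering)
    end: int                         # last residue (inclusive)
    times: np.ndarray                # seconds, strictly increasing
    uptake: np.ndarray               # fractions in [0, 1], parallel to times
    sequence: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.uptake = np.asarray(self.uptake, dtype=float)
        if self.start >= self.end:
            raise ValueError(f"peptide {self.peptide_id}: start must be < end")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError(f"peptide {self.peptide_id}: time points must "
                             "be strictly increasing")
        if self.uptake.shape != self.times.shape:
            raise ValueError(f"peptide {self.peptide_id}: uptake/time length mismatch")
        if np.any((self.uptake < -1e-9) | (self.uptake > 1 + 1e-9)):
            raise ValueError(f"peptide {self.peptide_id}: uptake outside [0, 1]")


# ---------------------------------------------------------------------------
# Counting
# ---------------------------------------------------------------------------

def monitorable_mask(conf: Conformation) -> np.ndarray:
    """Per-residue flag: True unless proline or first residue of its chain."""
    t = conf.topology
    mask = t.res_name != "PRO"
    first = t.res_seq_index == 0
    return mask & ~first


def _count_arrays(conf: Conformation, params: HxModelParams
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized Nh/Nc for all residues; -1 where not monitorable.

    Candidate partners within the cutoff are found with a k-d tree and then
    filtered by the same-chain sequence-exclusion window. The window never
    applies across chains, so a dimer partner protects normally.
    """
    t = conf.topology
    mon = monitorable_mask(conf)
    nres = conf.n_residues
    nh = np.full(nres, -1, dtype=int)
    nc = np.full(nres, -1, dtype=int)

    h_res = [k for k in range(nres) if mon[k]]
    for k in h_res:
        if t.idx_H[k] < 0:
            raise StructureError(
                f"residue {t.res_chain[k]}:{t.res_seq[k]} has no amide H; "
                "run place_amide_hydrogens first (or check the monitorable flag)")

    heavy = conf.elements != "H"
    is_backbone_O = np.isin(conf.atom_names, ("O", "OT1", "OT2", "OXT", "O1", "O2"))
    bb_o_idx = np.flatnonzero(is_backbone_O)
    heavy_idx = np.flatnonzero(heavy)

    atom_res = t.atom_res_ordinal
    res_chain = t.res_chain
    res_sidx = t.res_seq_index
    w = params.sequence_exclusion_halfwidth

    tree_o = cKDTree(conf.coords[bb_o_idx]) if len(bb_o_idx) else None
    tree_h = cKDTree(conf.coords[heavy_idx]) if len(heavy_idx) else None

    for k in h_res:
        hpos = conf.coords[t.idx_H[k]]

        def _count(tree, pool_idx, cutoff):
            if tree is None:
                return 0
            cand = pool_idx[tree.query_ball_point(hpos, cutoff)]
            if len(cand) == 0:
                return 0
            rk = atom_res[cand]
            same_chain = res_chain[rk] == res_chain[k]
            in_window = np.abs(res_sidx[rk] - res_sidx[k]) <= w
            return int(np.count_nonzero(~(same_chain & in_window)))

        nh[k] = _count(tree_o, bb_o_idx, params.hbond_cutoff)
        nc[k] = _count(tree_h, heavy_idx, params.contact_cutoff)
    return nh, nc, mon


def count_hbonds(conf: Conformation, residue: int, params: HxModelParams | None = None,
                 chain: str | None = None) -> int:
    """Number of backbone carbonyl oxygens within `hbond_cutoff` of the amide
    hydrogen of `residue`, excluding residues i-w..i+w of the same chain."""
    params = params or HxModelParams()
    chain = chain if chain is not None else conf.chains()[0]
    k = conf.residue_ordinal(chain, residue)
    nh, _, mon = _count_arrays(conf, params)
    if not mon[k]:
        raise StructureError(f"residue {chain}:{residue} is not monitorable "
                             "(proline or chain N-terminus)")
    return int(nh[k])


def count_contacts(conf: Conformation, residue: int, params: HxModelParams | None = None,
                   chain: str | None = None) -> int:
    """Number of heavy atoms within `contact_cutoff` of the amide hydrogen of
    `residue`, with the same sequence-exclusion window."""
    params = params or HxModelParams()
    chain = chain if chain is not None else conf.chains()[0]
    k = conf.residue_ordinal(chain, residue)
    _, nc, mon = _count_arrays(conf, params)
    if not mon[k]:
        raise StructureError(f"residue {chain}:{residue} is not monitorable "
                             "(proline or chain N-terminus)")
    return int(nc[k])


def hx_counts(conf: Conformation, params: HxModelParams | None = None) -> pd.DataFrame:
    """Nh/Nc/lnP table for every monitorable residue of the conformation."""
    params = params or HxModelParams()
    nh, nc, mon = _count_arrays(conf, params)
    t = conf.topology
    rows = []
    for k in range(conf.n_residues):
        if not mon[k]:
            continue
        rows.append({
            "chain": t.res_chain[k],
            "residue": int(t.res_seq[k]),
            "resname": t.res_name[k],
            "n_hbonds": int(nh[k]),
            "n_contacts": int(nc[k]),
            "lnP": log_protection(int(nh[k]), int(nc[k]), params),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Closed-form pieces
# ---------------------------------------------------------------------------

def log_protection(n_hbonds: float, n_contacts: float,
                   params: HxModelParams | None = None) -> float:
    """ln P = beta_h * Nh + beta_c * Nc."""
    params = params or HxModelParams()
    if n_hbonds < 0 or n_contacts < 0:
        raise ValueError("counts must be non-negative")
    return params.beta_h * n_hbonds + params.beta_c * n_contacts


def deuterium_fraction(kint: float, lnP: float, t) -> float | np.ndarray:
    """Fraction of deuterium incorporated after time t (s):
    d = 1 - exp(-(kint / P) t) with P = exp(lnP)."""
    t = np.asarray(t, dtype=float)
    if kint <= 0:
        raise ValueError("kint must be positive")
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    kobs = kint / np.exp(min(lnP, _LNP_CAP))
    out = 1.0 - np.exp(-kobs * t)
    return float(out) if out.ndim == 0 else out


def lnP_from_deltaG(deltaG: float, params: HxModelParams | None = None) -> float:
    """ln P from a free energy of stabilization (kcal/mol): Delta G = RT ln P."""
    params = params or HxModelParams()
    return deltaG / (params.gas_constant * params.temperature)


def deltaG_from_lnP(lnP: float, params: HxModelParams | None = None) -> float:
    """Free energy of stabilization (kcal/mol) from ln P."""
    params = params or HxModelParams()
    return lnP * params.gas_constant * params.temperature


# ---------------------------------------------------------------------------
# Peptide-level uptake
# ---------------------------------------------------------------------------

def peptide_uptake(residue_uptake: Mapping[int, np.ndarray],
                   bounds: tuple[int, int],
                   monitorable: Mapping[int, bool],
                   times: Sequence[float],
                   params: HxModelParams | None = None,
                   chain: str = "A",
                   peptide_id: str | None = None) -> PeptideCurve:
    """Average residue uptake curves into a peptide curve.

    The first `backexchange_skip` residues of the peptide are always dropped
    (back-exchange convention, counted on raw positions), and non-monitorable
    residues (prolines) are dropped independently of that.
    """
    params = params or HxModelParams()
    start, end = bounds
    included = [r for r in range(start + params.backexchange_skip, end + 1)
                if monitorable.get(r, False)]
    if not included:
        raise ValueError(f"peptide {start}-{end}: no includable residues after "
                         "back-exchange and proline exclusions")
    stack = np.vstack([np.asarray(residue_uptake[r], dtype=float) for r in included])
    curve = stack.mean(axis=0)
    return PeptideCurve(peptide_id or f"{chain}:{start}-{end}", chain,
                        start, end, np.asarray(times, dtype=float), curve)


class HxEvaluator:
    """Repeated HX prediction over conformations sharing one topology.

    Precomputes candidate-atom pools and the sequence-exclusion masks once,
    so per-conformation work is two k-d-tree queries plus vectorized
    arithmetic. Produces exactly the same counts as :func:`hx_counts`; the
    sampler uses this path to evaluate thousands of conformations.
    """

    def __init__(self, conf: Conformation, params: HxModelParams | None = None):
        self.params = params or HxModelParams()
        t = conf.topology
        self.topology = t
        mon = monitorable_mask(conf)
        self.mon_ord = np.flatnonzero(mon)
        self.h_idx = t.idx_H[self.mon_ord]
        if np.any(self.h_idx < 0):
            k = self.mon_ord[np.argmax(self.h_idx < 0)]
            raise StructureError(
                f"residue {t.res_chain[k]}:{t.res_seq[k]} has no amide H; "
                "run place_amide_hydrogens first")
        self.o_idx = np.flatnonzero(np.isin(
            conf.atom_names, ("O", "OT1", "OT2", "OXT", "O1", "O2")))
        self.heavy_idx = np.flatnonzero(conf.elements != "H")
        w = self.params.sequence_exclusion_halfwidth
        res_of = t.atom_res_ordinal

        def _excluded(cand: np.ndarray) -> np.ndarray:
            rk = res_of[cand]
            same = t.res_chain[rk][None, :] == t.res_chain[self.mon_ord][:, None]
            win = np.abs(t.res_seq_index[rk][None, :]
                         - t.res_seq_index[self.mon_ord][:, None]) <= w
            return same & win

        self.excl_o = _excluded(self.o_idx)
        self.excl_heavy = _excluded(self.heavy_idx)
        # row lookup: (chain, resseq) -> row in the monitorable arrays
        self.row_of = {(t.res_chain[k], int(t.res_seq[k])): r
                       for r, k in enumerate(self.mon_ord)}

    def counts(self, conf: Conformation) -> tuple[np.ndarray, np.ndarray]:
        """(Nh, Nc) arrays over monitorable residues (row order of mon_ord)."""
        X = conf.coords
        nmon = len(self.mon_ord)
        nh = np.zeros(nmon, dtype=int)
        nc = np.zeros(nmon, dtype=int)
        hpos = X[self.h_idx]
        if len(self.o_idx):
            hits = cKDTree(X[self.o_idx]).query_ball_point(
                hpos, self.params.hbond_cutoff)
            for r, lst in enumerate(hits):
                if lst:
                    nh[r] = int(np.count_nonzero(~self.excl_o[r, lst]))
        if len(self.heavy_idx):
            hits = cKDTree(X[self.heavy_idx]).query_ball_point(
                hpos, self.params.contact_cutoff)
            for r, lst in enumerate(hits):
                if lst:
                    nc[r] = int(np.count_nonzero(~self.excl_heavy[r, lst]))
        return nh, nc

    def log_protection(self, conf: Conformation) -> np.ndarray:
        nh, nc = self.counts(conf)
        return self.params.beta_h * nh + self.params.beta_c * nc


# ---------------------------------------------------------------------------
# Whole-dataset prediction
# ---------------------------------------------------------------------------

def _kint_lookup(kint_table) -> dict[tuple[str, int], float]:
    """Accept a DataFrame (chain, residue, kint_per_s) or a mapping."""
    if isinstance(kint_table, pd.DataFrame):
        return {(str(r.chain), int(r.residue)): float(r.kint_per_s)
                for r in kint_table.itertuples()}
    return {(str(c), int(r)): float(v) for (c, r), v in kint_table.items()}


def predict_hx_dataset(conf: Conformation,
                       kint_table=None,
                       mode: str = "residue",
                       peptides: Sequence[tuple] | pd.DataFrame | None = None,
                       times: Sequence[float] | None = None,
                       params: HxModelParams | None = None):
    """Derive an HX dataset from a conformation.

    mode="residue" returns a DataFrame (chain, residue, resname, n_hbonds,
    n_contacts, lnP) over monitorable residues; mode="peptide" returns a list
    of :class:`PeptideCurve` for the given peptide bounds and time points
    (kint_table required). Peptides may be (start, end), (chain, start, end)
    tuples or a DataFrame with chain/start/end columns.
    """
    params = params or HxModelParams()
    table = hx_counts(conf, params)
    if mode == "residue":
        return table
    if mode != "peptide":
        raise ValueError(f"unknown mode {mode!r}")
    if peptides is None or times is None:
        raise ValueError("peptide mode needs peptides and times")
    if kint_table is None:
        raise ValueError("peptide mode needs a kint table")
    kint = _kint_lookup(kint_table)
    times = np.asarray(times, dtype=float)

    lnp = {(r.chain, r.residue): r.lnP for r in table.itertuples()}
    t_top = conf.topology
    mon = {(t_top.res_chain[k], int(t_top.res_seq[k])): bool(m)
           for k, m in enumerate(monitorable_mask(conf))}

    if isinstance(peptides, pd.DataFrame):
        pep_list = [(str(r.chain), int(r.start), int(r.end),
                     str(getattr(r, "peptide_id", f"{r.chain}:{r.start}-{r.end}")))
                    for r in peptides.itertuples()]
    else:
        pep_list = []
        default_chain = conf.chains()[0]
        for p in peptides:
            if len(p) == 2:
                pep_list.append((default_chain, int(p[0]), int(p[1]),
                                 f"{default_chain}:{p[0]}-{p[1]}"))
            else:
                pep_list.append((str(p[0]), int(p[1]), int(p[2]),
                                 f"{p[0]}:{p[1]}-{p[2]}"))

    curves = []
    for chain, start, end, pid in pep_list:
        d_by_res = {}
        mon_by_res = {}
        for r in range(start, end + 1):
            key = (chain, r)
            mon_by_res[r] = mon.get(key, False)
            if mon_by_res[r]:
                if key not in kint:
                    raise ValueError(f"no intrinsic rate for residue {chain}:{r}")
                d_by_res[r] = deuterium_fraction(kint[key], lnp[key], times)
        curve = peptide_uptake(d_by_res, (start, end), mon_by_res, times,
                               params, chain=chain, peptide_id=pid)
        seq = ""
        for r in range(start, end + 1):
            try:
                k = conf.residue_ordinal(chain, r)
                from .structure import THREE_TO_ONE
                seq += THREE_TO_ONE.get(t_top.res_name[k], "X")
            except StructureError:
                seq += "-"
        curve.sequence = seq
        curves.append(curve)
    return curves
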