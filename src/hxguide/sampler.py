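"""Monte Carlo conformational exploration with optional HX-mismatch bias.

The explorer incrementally grows a tree of conformations rooted at a
starting structure. Each step selects an existing node (softmax favoring
low score), a move kind (backbone dihedral perturbation, composite loop
move, rigid-body chain motion, or short greedy minimization), and a move
site — drawn from a :class:`~hxguide.fit.BiasMap` when one is supplied so
that regions with the largest HX mismatch are perturbed most often — then
Metropolis-accepts the perturbed conformation on an energy-like score.

The default score is a deliberately simple stand-in for a molecular
force field (soft-sphere clash penalty, backbone hydrogen-bond reward,
Ramachandran-basin plausibility penalty); any callable mapping a
conformation to a number can replace it.

The guided protocol iterates: explore, pick the conformation that best fits
the experimental HX data, convert the residual mismatch into a bias map,
and explore again from there, until the fit stops improving.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .fit import BiasMap, FitReport, bias_map, peptide_errors, residue_errors
from .forward import HxModelParams, predict_hx_dataset
from .structure import Conformation, StructureError

__all__ = [
    "MoveSet",
    "ScoreWeights",
    "ExplorationGraph",
    "ProtocolResult",
    "perturb_dihedral",
    "rigid_body_move",
    "score",
    "minimize",
    "explore",
    "guided_protocol",
]

_STANDARD_BONDS = {"N-CA": 1.458, "CA-C": 1.525, "C-N": 1.329}
_BOND_TOLERANCE = 0.5


@dataclass(frozen=True)
class MoveSet:
    """Enabled move kinds and their magnitudes.

    dihedral_sd: s.d. (degrees) of single-residue phi/psi perturbations.
    loop_sd: s.d. (degrees) of per-residue angles in composite loop moves
    (2-6 consecutive residues, anti-correlated phi/psi to limit lever-arm
    displacement). rigid_* set chain-level rigid-body magnitudes; rigid-body
    moves are only attempted on multi-chain structures. minimize_steps is
    the number of greedy descent sweeps in a minimization move.
    """

    kinds: tuple[str, ...] = ("dihedral", "loop", "minimize")
    weights: tuple[float, ...] | None = (0.45, 0.35, 0.2)
    dihedral_sd: float = 15.0
    loop_sd: float = 6.0
    rigid_translation_sd: float = 1.0   # Angstrom
    rigid_rotation_sd: float = 8.0      # degrees
    minimize_steps: int = 4
    # Ramachandran-guided proposals: with this probability a dihedral move
    # re-draws the (phi, psi) of a short segment (up to resample_max_len
    # residues) from a favored-basin center plus jitter, instead of an
    # incremental Gaussian step. This plays the role fragment insertion plays
    # in full-atom samplers: it lets secondary structure nucleate, which
    # incremental steps essentially never do against a clash-aware score.
    resample_prob: float = 0.6
    resample_max_len: int = 5
    resample_jitter: float = 10.0       # degrees

    def __post_init__(self):
        if not self.kinds:
            raise ValueError("at least one move kind must be enabled")
        bad = set(self.kinds) - {"dihedral", "loop", "rigid_body", "minimize"}
        if bad:
            raise ValueError(f"unknown move kinds: {sorted(bad)}")
        for v in (self.dihedral_sd, self.loop_sd, self.rigid_translation_sd,
                  self.rigid_rotation_sd):
            if v <= 0:
                raise ValueError("move magnitudes must be positive")
        if self.minimize_steps < 1:
            raise ValueError("minimize_steps must be >= 1")
        if self.weights is not None and len(self.weights) != len(self.kinds):
            raise ValueError("weights must match kinds")

    def kind_probabilities(self) -> np.ndarray:
        w = np.ones(len(self.kinds)) if self.weights is None else np.asarray(self.weights, float)
        return w / w.sum()


@dataclass(frozen=True)
class ScoreWeights:
    """Weights of the default score terms (lower total is better)."""

    clash: float = 25.0
    hbond: float = 1.0
    rama: float = 1.0
    clash_cutoff: float = 2.7     # Angstrom, heavy-atom soft-sphere onset
    rama_tolerance: float = 30.0  # degrees of free play around each basin


# Favored (phi, psi) basin centers: alpha helix, beta sheet, polyproline II,
# left-handed helix.
_RAMA_BASINS = np.array([(-63.0, -43.0), (-120.0, 135.0),
                         (-75.0, 150.0), (57.0, 47.0)])


@dataclass
class MoveRecord:
    kind: str
    chain: str | None = None
    residue: int | None = None          # PDB resseq of the move site
    detail: dict = field(default_factory=dict)


@dataclass
class Node:
    node_id: int
    conformation: Conformation
    score: float
    parent: int | None = None
    move: MoveRecord | None = None
    error: float | None = None


class ExplorationGraph:
    """Tree of sampled conformations (every non-root node has one parent)."""

    def __init__(self, root: Conformation, root_score: float,
                 root_error: float | None = None):
        self.nodes: list[Node] = [Node(0, root, root_score, None, None, root_error)]
        self.log: list[str] = []
        self.attempts: list[MoveRecord] = []    # every attempted move, accepted or not

    @property
    def root(self) -> Node:
        return self.nodes[0]

    def __len__(self) -> int:
        return len(self.nodes)

    def add(self, conformation: Conformation, score: float, parent: int,
            move: MoveRecord, error: float | None = None) -> Node:
        node = Node(len(self.nodes), conformation, score, parent, move, error)
        self.nodes.append(node)
        return node

    def edges(self) -> list[tuple[int, int, MoveRecord]]:
        return [(n.parent, n.node_id, n.move) for n in self.nodes[1:]]

    def best_by_score(self) -> Node:
        return min(self.nodes, key=lambda n: n.score)

    def best_by_error(self) -> Node:
        scored = [n for n in self.nodes if n.error is not None]
        if not scored:
            raise ValueError("no node carries a fit error")
        return min(scored, key=lambda n: n.error)


# ---------------------------------------------------------------------------
# Elementary moves
# ---------------------------------------------------------------------------

def _rotate_segment(coords: np.ndarray, moving: np.ndarray,
                    origin: np.ndarray, axis: np.ndarray,
                    angle_deg: float) -> None:
    axis = axis / np.linalg.norm(axis)
    rot = Rotation.from_rotvec(np.radians(angle_deg) * axis)
    coords[moving] = rot.apply(coords[moving] - origin) + origin


def _perturb_ordinal(conf: Conformation, k: int, dphi: float, dpsi: float
                     ) -> Conformation:
    """Rotate phi/psi of residue ordinal k; the smaller side of each pivot
    bond moves (lever-arm rule), so internal geometry is exactly preserved
    either way. The moving-atom partition is cached on the shared topology."""
    plan = conf.topology.dihedral_move_plan(k)
    coords = conf.coords.copy()
    for (moving, sign, ia, ib), angle in zip(plan, (dphi, dpsi)):
        if angle != 0.0 and len(moving):
            _rotate_segment(coords, moving, coords[ia],
                            coords[ib] - coords[ia], sign * angle)
    return conf.with_coords(coords)


def perturb_dihedral(conf: Conformation, residue: int, dphi: float, dpsi: float,
                     chain: str | None = None) -> Conformation:
    """Change the backbone phi/psi of `residue` by (dphi, dpsi) degrees.

    All atoms downstream of each rotated bond move rigidly; bond lengths
    and angles are untouched. The segment on the lighter side of the pivot
    bond is the one that moves, which minimizes global displacement.
    """
    if not (np.isfinite(dphi) and np.isfinite(dpsi)):
        raise ValueError("angle changes must be finite")
    chain = chain if chain is not None else conf.chains()[0]
    k = conf.residue_ordinal(chain, residue)
    return _perturb_ordinal(conf, k, dphi, dpsi)


def _set_phi_psi(conf: Conformation, k: int, phi_t: float, psi_t: float
                 ) -> Conformation:
    """Rotate residue ordinal k so its (phi, psi) equal the targets; angles
    undefined at chain termini are left alone."""
    from .geometry import dihedral as _dih
    t = conf.topology
    X = conf.coords
    dphi = dpsi = 0.0
    if t.prev_C[k] >= 0:
        phi = _dih(X[t.prev_C[k]], X[t.idx_N[k]], X[t.idx_CA[k]], X[t.idx_C[k]])
        dphi = phi_t - phi
    if t.next_N[k] >= 0:
        psi = _dih(X[t.idx_N[k]], X[t.idx_CA[k]], X[t.idx_C[k]], X[t.next_N[k]])
        dpsi = psi_t - psi
    return _perturb_ordinal(conf, k, dphi, dpsi)


def rigid_body_move(conf: Conformation, chain: str,
                    rotation_deg: Sequence[float] = (0.0, 0.0, 0.0),
                    translation: Sequence[float] = (0.0, 0.0, 0.0),
                    residue_range: tuple[int, int] | None = None) -> Conformation:
    """Rigidly rotate (about the unit centroid) and translate one chain.

    `residue_range` may name a contiguous whole chain only: moving a
    sub-segment of a covalent chain would require loop closure, which this
    sampler does not do, so such selections raise an error.
    """
    mask = conf.chain_ids == chain
    if not mask.any():
        raise StructureError(f"no chain {chain!r}")
    if residue_range is not None:
        res_in_chain = conf.res_seq[mask]
        lo, hi = residue_range
        if lo > res_in_chain.min() or hi < res_in_chain.max():
            raise StructureError(
                "rigid-body selection splits a covalent chain; whole-chain "
                "moves only (no loop closure)")
    coords = conf.coords.copy()
    idx = np.flatnonzero(mask)
    center = coords[idx].mean(axis=0)
    rot = Rotation.from_euler("xyz", rotation_deg, degrees=True)
    coords[idx] = rot.apply(coords[idx] - center) + center + np.asarray(translation, float)
    return conf.with_coords(coords)


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def _clash_energy(conf: Conformation, cutoff: float) -> float:
    heavy = np.flatnonzero(conf.elements != "H")
    if len(heavy) < 2:
        return 0.0
    tree = cKDTree(conf.coords[heavy])
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if len(pairs) == 0:
        return 0.0
    ia, ib = heavy[pairs[:, 0]], heavy[pairs[:, 1]]
    t = conf.topology
    ra, rb = t.atom_res_ordinal[ia], t.atom_res_ordinal[ib]
    same_chain = t.res_chain[ra] == t.res_chain[rb]
    bonded_near = same_chain & (np.abs(ra - rb) <= 1)
    keep = ~bonded_near
    if not keep.any():
        return 0.0
    d = np.linalg.norm(conf.coords[ia[keep]] - conf.coords[ib[keep]], axis=1)
    overlap = (cutoff - d) / cutoff
    return float(np.sum(overlap * overlap))


def _hbond_count(conf: Conformation, params: HxModelParams) -> int:
    """Total backbone H...O pairs within the hbond cutoff, outside the
    sequence-exclusion window (same counting rule as the forward model)."""
    t = conf.topology
    h_idx = t.idx_H[t.idx_H >= 0]
    o_mask = np.isin(conf.atom_names, ("O", "OT1", "OT2", "OXT"))
    o_idx = np.flatnonzero(o_mask)
    if len(h_idx) == 0 or len(o_idx) == 0:
        return 0
    tree = cKDTree(conf.coords[o_idx])
    total = 0
    res_of = t.atom_res_ordinal
    hits = tree.query_ball_point(conf.coords[h_idx], params.hbond_cutoff)
    for h_atom, lst in zip(h_idx, hits):
        if not lst:
            continue
        rk = res_of[h_atom]
        cand = o_idx[lst]
        ro = res_of[cand]
        same = t.res_chain[ro] == t.res_chain[rk]
        window = np.abs(t.res_seq_index[ro] - t.res_seq_index[rk]) <= \
            params.sequence_exclusion_halfwidth
        total += int(np.count_nonzero(~(same & window)))
    return total


def _rama_energy(conf: Conformation, tolerance: float) -> float:
    phi, psi = conf.backbone_dihedrals()[:2]
    ok = np.isfinite(phi) & np.isfinite(psi)
    if not ok.any():
        return 0.0
    pp = np.stack([phi[ok], psi[ok]], axis=1)          # (n, 2)
    diff = pp[:, None, :] - _RAMA_BASINS[None, :, :]   # (n, basins, 2)
    diff = (diff + 180.0) % 360.0 - 180.0
    dist = np.sqrt(np.sum(diff * diff, axis=2)).min(axis=1)
    excess = np.maximum(0.0, dist - tolerance) / 90.0
    return float(np.sum(excess * excess))


def score(conf: Conformation, weights: ScoreWeights | None = None,
          params: HxModelParams | None = None) -> float:
    """Deterministic energy-like score (lower is better): soft-sphere clash
    penalty + backbone hydrogen-bond reward + Ramachandran plausibility
    penalty. A stand-in with the right qualitative ordering, not a force
    field; pass any callable to the explorer to replace it."""
    weights = weights or ScoreWeights()
    params = params or HxModelParams()
    s = weights.clash * _clash_energy(conf, weights.clash_cutoff)
    s -= weights.hbond * _hbond_count(conf, params)
    s += weights.rama * _rama_energy(conf, weights.rama_tolerance)
    return float(s)


# ---------------------------------------------------------------------------
# Minimization
# ---------------------------------------------------------------------------

def minimize(conf: Conformation, steps: int,
             score_weights: ScoreWeights | None = None,
             score_fn: Callable[[Conformation], float] | None = None,
             step_deg: float = 8.0) -> Conformation:
    """Greedy coordinate descent in backbone dihedral space.

    Each step visits one residue (cyclically) and keeps the best of four
    probes (phi +- step, psi +- step) if it improves the score; the score
    therefore never increases. Deterministic.
    """
    if steps <= 0:
        raise ValueError("steps must be positive")
    fn = score_fn or (lambda c: score(c, score_weights))
    current = conf
    cur_score = fn(current)
    nres = conf.n_residues
    for step_i in range(steps):
        k = step_i % nres
        best, best_score = None, cur_score
        for dphi, dpsi in ((step_deg, 0.0), (-step_deg, 0.0),
                           (0.0, step_deg), (0.0, -step_deg)):
            try:
                cand = _perturb_ordinal(current, k, dphi, dpsi)
            except StructureError:
                continue
            s = fn(cand)
            if s < best_score:
                best, best_score = cand, s
        if best is not None:
            current, cur_score = best, best_score
    return current


# ---------------------------------------------------------------------------
# Exploration
# ---------------------------------------------------------------------------

def _check_geometry(conf: Conformation) -> bool:
    """Cheap sanity check: finite coordinates and backbone bond lengths
    within 0.5 A of standard values."""
    if not np.all(np.isfinite(conf.coords)):
        return False
    t = conf.topology
    X = conf.coords
    ok = (t.idx_N >= 0) & (t.idx_CA >= 0) & (t.idx_C >= 0)
    n_ca = np.linalg.norm(X[t.idx_CA[ok]] - X[t.idx_N[ok]], axis=1)
    ca_c = np.linalg.norm(X[t.idx_C[ok]] - X[t.idx_CA[ok]], axis=1)
    if np.any(np.abs(n_ca - _STANDARD_BONDS["N-CA"]) > _BOND_TOLERANCE):
        return False
    if np.any(np.abs(ca_c - _STANDARD_BONDS["CA-C"]) > _BOND_TOLERANCE):
        return False
    m = t.prev_C >= 0
    c_n = np.linalg.norm(X[t.idx_N[m]] - X[t.prev_C[m]], axis=1)
    return not np.any(np.abs(c_n - _STANDARD_BONDS["C-N"]) > _BOND_TOLERANCE)


def _bias_ordinals(conf: Conformation, bias: BiasMap | None
                   ) -> tuple[np.ndarray, np.ndarray]:
    """(ordinals, probabilities) for move-site selection."""
    nres = conf.n_residues
    if bias is None:
        return np.arange(nres), np.full(nres, 1.0 / nres)
    t = conf.topology
    lookup = {(t.res_chain[k], int(t.res_seq[k])): k for k in range(nres)}
    ords, probs = [], []
    for ch, res, w in zip(bias.chains, bias.residues, bias.weights):
        k = lookup.get((str(ch), int(res)))
        if k is not None:
            ords.append(k)
            probs.append(w)
    probs = np.asarray(probs, float)
    if probs.sum() <= 0:
        raise ValueError("bias map assigns no mass to this structure")
    return np.asarray(ords, dtype=np.intp), probs / probs.sum()


def explore(start: Conformation, n_moves: int,
            move_set: MoveSet | None = None,
            bias: BiasMap | None = None,
            seed: int = 0,
            score_weights: ScoreWeights | None = None,
            temperature: float = 1.0,
            score_fn: Callable[[Conformation], float] | None = None,
            error_fn: Callable[[Conformation], float] | None = None,
            continue_prob: float = 0.5) -> ExplorationGraph:
    """Grow an exploration tree of `n_moves` attempted perturbations.

    Node selection mixes depth-first progress with global restarts: with
    probability `continue_prob` the most recently accepted node is expanded
    (so trajectories get deep enough to actually travel), otherwise a node
    is drawn by softmax over negative scores at `temperature`. Move sites
    are drawn from `bias` (uniform when absent); candidates are
    Metropolis-accepted on the score. When `error_fn` is given, every
    accepted node (and the root) is annotated with its HX fit error.
    Fully reproducible for a given seed.
    """
    if n_moves <= 0:
        raise ValueError("n_moves must be positive")
    move_set = move_set or MoveSet()
    fn = score_fn or (lambda c: score(c, score_weights))
    rng = np.random.default_rng(seed)
    root_err = error_fn(start) if error_fn is not None else None
    graph = ExplorationGraph(start, fn(start), root_err)

    ords, site_p = _bias_ordinals(start, bias)
    kinds = list(move_set.kinds)
    kind_p = move_set.kind_probabilities()
    multi_chain = len(start.chains()) > 1
    t = start.topology

    scores = [graph.root.score]
    last_accepted = 0
    nres_total = start.n_residues

    for _ in range(n_moves):
        if rng.random() < continue_prob:
            parent_id = last_accepted
        else:
            s_arr = np.asarray(scores)
            logits = -(s_arr - s_arr.min()) / max(temperature, 1e-9)
            w = np.exp(logits - logits.max())
            parent_id = int(rng.choice(len(s_arr), p=w / w.sum()))
        parent = graph.nodes[parent_id]

        kind = kinds[int(rng.choice(len(kinds), p=kind_p))]
        if kind == "rigid_body" and not multi_chain:
            kind = "dihedral"
        k_site = int(ords[rng.choice(len(ords), p=site_p)])
        record = MoveRecord(kind, chain=t.res_chain[k_site],
                            residue=int(t.res_seq[k_site]))
        graph.attempts.append(record)
        try:
            if kind == "dihedral":
                if rng.random() < move_set.resample_prob:
                    length = int(rng.integers(1, move_set.resample_max_len + 1))
                    basin = _RAMA_BASINS[int(rng.integers(0, len(_RAMA_BASINS)))]
                    cand = parent.conformation
                    chain_k = t.res_chain[k_site]
                    applied = 0
                    for j in range(length):
                        kk = k_site + j
                        if kk >= nres_total or t.res_chain[kk] != chain_k:
                            break
                        cand = _set_phi_psi(
                            cand, kk,
                            basin[0] + rng.normal(0.0, move_set.resample_jitter),
                            basin[1] + rng.normal(0.0, move_set.resample_jitter))
                        applied += 1
                    record.detail = {"resample": True, "length": applied,
                                     "basin": basin.tolist()}
                else:
                    dphi = rng.normal(0.0, move_set.dihedral_sd)
                    dpsi = rng.normal(0.0, move_set.dihedral_sd)
                    cand = _perturb_ordinal(parent.conformation, k_site, dphi, dpsi)
                    record.detail = {"dphi": dphi, "dpsi": dpsi}
            elif kind == "loop":
                length = int(rng.integers(2, 7))
                cand = parent.conformation
                chain_k = t.res_chain[k_site]
                for j in range(length):
                    kk = k_site + j
                    if kk >= start.n_residues or t.res_chain[kk] != chain_k:
                        break
                    d = rng.normal(0.0, move_set.loop_sd)
                    dpsi = -0.8 * d + rng.normal(0.0, 0.5 * move_set.loop_sd)
                    cand = _perturb_ordinal(cand, kk, d, dpsi)
                record.detail = {"length": length}
            elif kind == "rigid_body":
                chain = t.res_chain[k_site]
                rot = rng.normal(0.0, move_set.rigid_rotation_sd, 3)
                trans = rng.normal(0.0, move_set.rigid_translation_sd, 3)
                cand = rigid_body_move(parent.conformation, chain, rot, trans)
                record.detail = {"rotation": rot.tolist(),
                                 "translation": trans.tolist()}
            else:  # minimize
                cand = minimize(parent.conformation, move_set.minimize_steps,
                                score_weights, score_fn)
                record.detail = {"steps": move_set.minimize_steps}
        except StructureError as exc:
            graph.log.append(f"move {kind} at {record.chain}:{record.residue} "
                             f"failed: {exc}")
            continue

        if not _check_geometry(cand):
            graph.log.append(f"move {kind} at {record.chain}:{record.residue} "
                             "rejected: degenerate geometry")
            continue

        s_new = fn(cand)
        delta = s_new - parent.score
        if delta <= 0 or rng.random() < np.exp(-delta / max(temperature, 1e-9)):
            err = error_fn(cand) if error_fn is not None else None
            node = graph.add(cand, s_new, parent_id, record, err)
            scores.append(s_new)
            last_accepted = node.node_id
    return graph


# ---------------------------------------------------------------------------
# Guided protocol
# ---------------------------------------------------------------------------

@dataclass
class IterationRecord:
    index: int                       # 1-based iteration number
    best_error: float                # best-so-far average error
    iteration_best_error: float      # best error among this iteration's nodes
    bias_used: BiasMap | None
    n_nodes: int


@dataclass
class ProtocolResult:
    iterations: list[IterationRecord]
    final_conformation: Conformation
    final_report: FitReport
    initial_error: float
    final_error: float
    stop_reason: str

    @property
    def best_errors(self) -> list[float]:
        return [it.best_error for it in self.iterations]


def _make_error_fn(observed, kint_table, params: HxModelParams
                   ) -> tuple[Callable[[Conformation], float],
                              Callable[[Conformation], FitReport]]:
    """(average-error fn, full-report fn) against `observed`.

    The error fn runs on a precomputed :class:`HxEvaluator` (conformations
    inside one protocol share a topology), the report fn on the plain
    prediction path; both produce identical numbers.
    """
    from .forward import HxEvaluator, _kint_lookup

    state: dict = {}

    if isinstance(observed, pd.DataFrame):
        def report_fn(conf: Conformation) -> FitReport:
            derived = predict_hx_dataset(conf, mode="residue", params=params)
            return residue_errors(derived, observed)

        def error_fn(conf: Conformation) -> float:
            if "ev" not in state:
                ev = HxEvaluator(conf, params)
                rows, obs_vals = [], []
                for rec in observed.itertuples():
                    r = ev.row_of.get((str(rec.chain), int(rec.residue)))
                    if r is not None:
                        rows.append(r)
                        obs_vals.append(float(rec.lnP))
                if not rows:
                    raise ValueError("no residues shared between derived and "
                                     "observed tables")
                state.update(ev=ev, rows=np.array(rows, dtype=np.intp),
                             obs=np.array(obs_vals))
            ev = state["ev"]
            lnp = ev.log_protection(conf)
            return float(np.abs(lnp[state["rows"]] - state["obs"]).mean())
    else:
        curves = list(observed)
        peptides = [(c.chain, c.start, c.end) for c in curves]
        times = curves[0].times

        def report_fn(conf: Conformation) -> FitReport:
            derived = predict_hx_dataset(conf, kint_table, mode="peptide",
                                         peptides=peptides, times=times,
                                         params=params)
            return peptide_errors(derived, curves)

        def error_fn(conf: Conformation) -> float:
            if "ev" not in state:
                ev = HxEvaluator(conf, params)
                kint = _kint_lookup(kint_table)
                t_arr = np.asarray(times, dtype=float)
                pep_rows, obs_mat = [], []
                kvec = np.full(len(ev.mon_ord), np.nan)
                for (ch, res), rate in kint.items():
                    r = ev.row_of.get((ch, res))
                    if r is not None:
                        kvec[r] = rate
                for c in curves:
                    rows = [ev.row_of[(c.chain, r)]
                            for r in range(c.start + params.backexchange_skip,
                                           c.end + 1)
                            if (c.chain, r) in ev.row_of]
                    if not rows:
                        raise ValueError(f"peptide {c.peptide_id}: no "
                                         "includable residues")
                    if np.any(np.isnan(kvec[rows])):
                        raise ValueError(f"peptide {c.peptide_id}: missing "
                                         "intrinsic rate")
                    pep_rows.append(np.array(rows, dtype=np.intp))
                    obs_mat.append(c.uptake)
                state.update(ev=ev, kvec=kvec, t_arr=t_arr,
                             pep_rows=pep_rows, obs_mat=obs_mat)
            ev = state["ev"]
            lnp = ev.log_protection(conf)
            kobs = state["kvec"] / np.exp(np.minimum(lnp, 700.0))
            d = 1.0 - np.exp(-np.outer(kobs, state["t_arr"]))
            total = 0.0
            for rows, obs_up in zip(state["pep_rows"], state["obs_mat"]):
                total += float(np.abs(d[rows].mean(axis=0) - obs_up).sum())
            return total / len(state["pep_rows"])

    return error_fn, report_fn


def guided_protocol(start: Conformation, observed, kint_table=None,
                    max_iterations: int = 5, moves_per_iteration: int = 2000,
                    tolerance: float = 0.01, seed: int = 0,
                    move_set: MoveSet | None = None,
                    params: HxModelParams | None = None,
                    score_weights: ScoreWeights | None = None,
                    temperature: float = 1.0,
                    score_fn: Callable[[Conformation], float] | None = None,
                    bias_halfwidth: int = 2,
                    bias_floor: float | None = None) -> ProtocolResult:
    """Iterative HX-guided exploration.

    `observed` is either a residue-level lnP DataFrame (chain, residue, lnP)
    or a list of experimental :class:`PeptideCurve` (kint_table required).
    Iteration 1 explores without bias; after each iteration the node with
    the lowest average HX error becomes the next start, and its residual
    errors become the next bias map. Stops when the improvement in
    best-so-far average error falls below `tolerance`, or after
    `max_iterations`. Best-so-far errors are monotone non-increasing by
    construction.
    """
    if max_iterations < 1:
        raise ValueError("max_iterations must be >= 1")
    params = params or HxModelParams()
    error_fn, report_fn = _make_error_fn(observed, kint_table, params)

    seed_rng = np.random.default_rng(seed)
    iter_seeds = seed_rng.integers(0, 2**31 - 1, size=max_iterations)

    residue_list = [(r.chain, r.resseq) for r in start.residues]

    current = start
    best_conf = start
    best_error = error_fn(start)
    initial_error = best_error
    bias: BiasMap | None = None
    iterations: list[IterationRecord] = []
    stop_reason = "max_iterations"

    for it in range(1, max_iterations + 1):
        graph = explore(current, moves_per_iteration, move_set=move_set,
                        bias=bias, seed=int(iter_seeds[it - 1]),
                        score_weights=score_weights, temperature=temperature,
                        score_fn=score_fn, error_fn=error_fn)
        node = graph.best_by_error()
        improved = node.error < best_error
        if improved:
            best_conf, prev = node.conformation, best_error
            improvement = prev - node.error
            best_error = node.error
        else:
            improvement = 0.0
        iterations.append(IterationRecord(it, best_error, node.error, bias,
                                          len(graph)))
        if improvement < tolerance:
            stop_reason = "converged"
            break
        report = report_fn(best_conf)
        bias = bias_map(report, residue_list, smoothing_halfwidth=bias_halfwidth,
                        floor=bias_floor)
        current = best_conf

    final_report = report_fn(best_conf)
    return ProtocolResult(iterations, best_conf, final_report,
                          initial_error, best_error, stop_reason)
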