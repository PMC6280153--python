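"""Protein structures as flat atom arrays, PDB I/O, amide-hydrogen
reconstruction, and structure-comparison utilities (RMSD, radius of gyration).

A :class:`Conformation` stores one model as parallel per-atom arrays plus a
derived residue table. Atom identity (chain, residue number, names) is shared
between conformations produced by coordinate-only updates, which keeps the
Monte Carlo sampler cheap: a move copies a coordinate array, nothing else.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import gemmi
import numpy as np

from .geometry import dihedral, kabsch_rmsd, plain_rmsd

__all__ = [
    "Conformation",
    "AtomSelection",
    "StructureError",
    "read_pdb",
    "write_pdb",
    "place_amide_hydrogens",
    "rmsd",
    "radius_of_gyration",
]


class StructureError(ValueError):
    """Raised for malformed or inconsistent structures."""


THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

_ATOMIC_MASS = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
                "S": 32.06, "SE": 78.971, "P": 30.974}

# Amide hydrogen names accepted as already present (e.g. NMR structures).
_AMIDE_H_NAMES = ("H", "HN", "D", "DN")

N_H_BOND_LENGTH = 1.01  # Angstrom


@dataclass(frozen=True)
class _Residue:
    chain: str
    resseq: int
    name: str
    seq_index: int          # 0-based sequential position within its chain
    atom_start: int         # [atom_start, atom_stop) slice into atom arrays
    atom_stop: int


class _Topology:
    """Residue bookkeeping derived from the per-atom identity arrays.

    Shared between all conformations that differ only in coordinates.
    """

    def __init__(self, chain_ids, res_seq, res_names, atom_names):
        n = len(atom_names)
        boundaries = [0]
        for i in range(1, n):
            if chain_ids[i] != chain_ids[i - 1] or res_seq[i] != res_seq[i - 1]:
                boundaries.append(i)
        boundaries.append(n)

        self.residues: list[_Residue] = []
        self.atom_res_ordinal = np.empty(n, dtype=np.intp)
        seq_index = 0
        prev_chain = None
        for k in range(len(boundaries) - 1):
            lo, hi = boundaries[k], boundaries[k + 1]
            chain = chain_ids[lo]
            if chain != prev_chain:
                seq_index = 0
                prev_chain = chain
            self.residues.append(_Residue(chain, int(res_seq[lo]), res_names[lo],
                                          seq_index, lo, hi))
            self.atom_res_ordinal[lo:hi] = k
            seq_index += 1

        nres = len(self.residues)
        self.res_chain = np.array([r.chain for r in self.residues])
        self.res_seq = np.array([r.resseq for r in self.residues], dtype=int)
        self.res_name = np.array([r.name for r in self.residues])
        self.res_seq_index = np.array([r.seq_index for r in self.residues], dtype=int)
        self._lookup = {(r.chain, r.resseq): k for k, r in enumerate(self.residues)}

        def _find(names: tuple[str, ...]) -> np.ndarray:
            idx = np.full(nres, -1, dtype=np.intp)
            for k, r in enumerate(self.residues):
                for i in range(r.atom_start, r.atom_stop):
                    if atom_names[i] in names:
                        idx[k] = i
                        break
            return idx

        self.idx_N = _find(("N",))
        self.idx_CA = _find(("CA",))
        self.idx_C = _find(("C",))
        self.idx_O = _find(("O", "OT1", "O1"))
        self.idx_H = _find(_AMIDE_H_NAMES)

        self._atom_names = np.asarray(atom_names)
        self._chain_ids = np.asarray(chain_ids)
        self._move_cache: dict = {}

        # neighbor bookkeeping (same chain only), for vectorized dihedrals
        self.prev_C = np.full(nres, -1, dtype=np.intp)
        self.prev_CA = np.full(nres, -1, dtype=np.intp)
        self.next_N = np.full(nres, -1, dtype=np.intp)
        for k in range(nres):
            if k > 0 and self.res_chain[k - 1] == self.res_chain[k]:
                self.prev_C[k] = self.idx_C[k - 1]
                self.prev_CA[k] = self.idx_CA[k - 1]
            if k + 1 < nres and self.res_chain[k + 1] == self.res_chain[k]:
                self.next_N[k] = self.idx_N[k + 1]

    def ordinal(self, chain: str, resseq: int) -> int:
        try:
            return self._lookup[(chain, resseq)]
        except KeyError:
            raise StructureError(f"no residue {resseq} in chain {chain!r}") from None

    def dihedral_move_plan(self, k: int):
        """Cached ((moving_idx, sign, pivot_from, pivot_to) for phi, same for
        psi) of residue ordinal k. `sign` is -1 when the lever-arm rule picks
        the N-terminal side of the pivot bond (rotated by the negated angle,
        which produces the identical internal change)."""
        plan = self._move_cache.get(k)
        if plan is not None:
            return plan
        if min(self.idx_N[k], self.idx_CA[k], self.idx_C[k]) < 0:
            raise StructureError(f"residue ordinal {k}: incomplete backbone")
        chain = self.res_chain[k]
        chain_atoms = np.flatnonzero(self._chain_ids == chain)
        res_of = self.atom_res_ordinal
        sidx_of_atom = self.res_seq_index[res_of]
        sidx = self.res_seq_index[k]
        res_atoms = chain_atoms[res_of[chain_atoms] == k]
        names = self._atom_names
        later = chain_atoms[sidx_of_atom[chain_atoms] > sidx]

        def halves(axis_from, axis_to, cside_extra):
            cside = np.concatenate([cside_extra, later]).astype(np.intp)
            excl = set(cside.tolist()) | {axis_from, axis_to}
            nside = np.array([i for i in chain_atoms if i not in excl],
                             dtype=np.intp)
            if len(cside) <= len(nside):
                return cside, 1.0, axis_from, axis_to
            return nside, -1.0, axis_from, axis_to

        iN, iCA, iC = self.idx_N[k], self.idx_CA[k], self.idx_C[k]
        amide_h = ("H", "HN", "D", "DN")
        phi_extra = np.array([i for i in res_atoms
                              if i != iN and i != iCA and names[i] not in amide_h],
                             dtype=np.intp)
        psi_extra = np.array([i for i in res_atoms
                              if names[i] in ("O", "OXT", "OT1", "OT2")],
                             dtype=np.intp)
        plan = (halves(iN, iCA, phi_extra), halves(iCA, iC, psi_extra))
        self._move_cache[k] = plan
        return plan


class Conformation:
    """Full-atom protein conformation.

    Parameters are parallel per-atom sequences: chain id, PDB residue number
    (1-based, as printed in the source file), 3-letter residue name, atom
    name, element symbol, and an (n, 3) coordinate array in Angstrom.
    """

    def __init__(self, chain_ids: Sequence[str], res_seq: Sequence[int],
                 res_names: Sequence[str], atom_names: Sequence[str],
                 elements: Sequence[str], coords: np.ndarray,
                 _topology: _Topology | None = None):
        self.chain_ids = np.asarray(chain_ids, dtype="U4")
        self.res_seq = np.asarray(res_seq, dtype=int)
        self.res_names = np.asarray(res_names, dtype="U4")
        self.atom_names = np.asarray(atom_names, dtype="U5")
        self.elements = np.asarray(elements, dtype="U2")
        self.coords = np.array(coords, dtype=float)
        if self.coords.shape != (len(self.atom_names), 3):
            raise StructureError("coords must be (n_atoms, 3)")
        self._top = _topology or _Topology(self.chain_ids, self.res_seq,
                                           self.res_names, self.atom_names)

    # -- basic introspection -------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def n_residues(self) -> int:
        return len(self._top.residues)

    @property
    def residues(self) -> list[_Residue]:
        return self._top.residues

    @property
    def topology(self) -> _Topology:
        return self._top

    def chains(self) -> list[str]:
        out: list[str] = []
        for r in self._top.residues:
            if not out or out[-1] != r.chain:
                out.append(r.chain)
        return out

    def sequence(self, chain: str | None = None) -> str:
        """One-letter sequence of `chain` (default: first chain)."""
        chain = chain if chain is not None else self.chains()[0]
        return "".join(THREE_TO_ONE.get(r.name, "X")
                       for r in self._top.residues if r.chain == chain)

    def residue_ordinal(self, chain: str, resseq: int) -> int:
        return self._top.ordinal(chain, resseq)

    def with_coords(self, coords: np.ndarray) -> "Conformation":
        """New conformation sharing identity arrays, with fresh coordinates."""
        return Conformation(self.chain_ids, self.res_seq, self.res_names,
                            self.atom_names, self.elements, coords,
                            _topology=self._top)

    def copy(self) -> "Conformation":
        return self.with_coords(self.coords.copy())

    # -- derived geometry ----------------------------------------------------

    def backbone_dihedrals(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-residue (phi, psi, omega) in degrees; NaN where undefined
        (chain termini)."""
        t = self._top
        nres = self.n_residues
        phi = np.full(nres, np.nan)
        psi = np.full(nres, np.nan)
        omega = np.full(nres, np.nan)
        X = self.coords
        bb_ok = (t.idx_N >= 0) & (t.idx_CA >= 0) & (t.idx_C >= 0)

        m = bb_ok & (t.prev_C >= 0)
        if m.any():
            phi[m] = dihedral(X[t.prev_C[m]], X[t.idx_N[m]],
                              X[t.idx_CA[m]], X[t.idx_C[m]])
        m = bb_ok & (t.prev_C >= 0) & (t.prev_CA >= 0)
        if m.any():
            omega[m] = dihedral(X[t.prev_CA[m]], X[t.prev_C[m]],
                                X[t.idx_N[m]], X[t.idx_CA[m]])
        m = bb_ok & (t.next_N >= 0)
        if m.any():
            psi[m] = dihedral(X[t.idx_N[m]], X[t.idx_CA[m]],
                              X[t.idx_C[m]], X[t.next_N[m]])
        return phi, psi, omega

    def validate_backbone(self) -> None:
        """Raise :class:`StructureError` if any residue lacks N/CA/C/O."""
        t = self._top
        for k, r in enumerate(t.residues):
            for name, idx in (("N", t.idx_N), ("CA", t.idx_CA),
                              ("C", t.idx_C), ("O", t.idx_O)):
                if idx[k] < 0:
                    raise StructureError(
                        f"residue {r.name} {r.resseq} in chain {r.chain!r} "
                        f"is missing backbone atom {name}")

    def __repr__(self) -> str:  # pragma: no cover
        return (f"<Conformation {self.n_residues} residues, {self.n_atoms} atoms, "
                f"chains {self.chains()}>")


@dataclass(frozen=True)
class AtomSelection:
    """Deterministic atom predicate: by chain, residue-number range and atom
    class (``all`` / ``heavy`` / ``calpha`` / ``backbone``)."""

    kind: str = "heavy"
    chains: tuple[str, ...] | None = None
    residue_range: tuple[int, int] | None = None   # inclusive resseq bounds
    predicate: Callable[[str, int, str, str], bool] | None = field(default=None)

    def indices(self, conf: Conformation) -> np.ndarray:
        mask = np.ones(conf.n_atoms, dtype=bool)
        if self.kind == "heavy":
            mask &= conf.elements != "H"
        elif self.kind == "calpha":
            mask &= conf.atom_names == "CA"
        elif self.kind == "backbone":
            mask &= np.isin(conf.atom_names, ("N", "CA", "C", "O"))
        elif self.kind != "all":
            raise ValueError(f"unknown selection kind {self.kind!r}")
        if self.chains is not None:
            mask &= np.isin(conf.chain_ids, self.chains)
        if self.residue_range is not None:
            lo, hi = self.residue_range
            mask &= (conf.res_seq >= lo) & (conf.res_seq <= hi)
        if self.predicate is not None:
            extra = np.array([self.predicate(c, int(s), rn, an)
                              for c, s, rn, an in zip(conf.chain_ids, conf.res_seq,
                                                      conf.res_names, conf.atom_names)])
            mask &= extra
        return np.flatnonzero(mask)


# ---------------------------------------------------------------------------
# PDB I/O (via gemmi)
# ---------------------------------------------------------------------------

def read_pdb(path, model: int = 1, include_hetero: bool = False) -> Conformation:
    """Read a PDB file into a :class:`Conformation`.

    Keeps amino-acid residues only (waters/ligands dropped unless
    `include_hetero`), resolves alternate locations to the highest-occupancy
    copy (ties: first encountered), rejects insertion codes, and uses MODEL
    `model` (1-based) of multi-model files. Every kept residue must carry a
    complete N/CA/C/O backbone.
    """
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    if len(st) == 0:
        raise StructureError(f"{path}: no ATOM records")
    if model < 1 or model > len(st):
        raise StructureError(f"{path}: model {model} not present "
                             f"({len(st)} models)")
    mdl = st[model - 1]

    chain_ids, res_seq, res_names, atom_names, elements, xyz = [], [], [], [], [], []
    prev_seq: dict[str, int] = {}
    for chain in mdl:
        for res in chain:
            info = gemmi.find_tabulated_residue(res.name)
            is_aa = info is not None and info.is_amino_acid()
            if not is_aa and not include_hetero:
                continue
            if res.name == "HOH":
                continue
            if res.seqid.icode not in (" ", "", "\x00"):
                raise StructureError(
                    f"insertion code {res.seqid.icode!r} at residue "
                    f"{res.seqid.num} chain {chain.name!r} is not supported")
            if chain.name in prev_seq and res.seqid.num <= prev_seq[chain.name]:
                raise StructureError(
                    f"residue numbers not strictly increasing in chain "
                    f"{chain.name!r} at {res.seqid.num}")
            prev_seq[chain.name] = res.seqid.num
            # resolve altlocs: highest occupancy wins, ties to first seen
            best: dict[str, gemmi.Atom] = {}
            for atom in res:
                cur = best.get(atom.name)
                if cur is None or atom.occ > cur.occ:
                    best[atom.name] = atom
            for atom in res:   # preserve file atom order
                if best.get(atom.name) is not atom:
                    continue
                chain_ids.append(chain.name)
                res_seq.append(res.seqid.num)
                res_names.append(res.name)
                atom_names.append(atom.name)
                elements.append(atom.element.name.upper())
                xyz.append([atom.pos.x, atom.pos.y, atom.pos.z])
                del best[atom.name]

    if not atom_names:
        raise StructureError(f"{path}: no amino-acid atoms found")
    conf = Conformation(chain_ids, res_seq, res_names, atom_names, elements,
                        np.array(xyz))
    conf.validate_backbone()
    return conf


def write_pdb(conf: Conformation, path) -> None:
    """Write standard PDB ATOM records (3-decimal coordinates, TER between
    chains) via gemmi."""
    st = gemmi.Structure()
    st.name = "hxguide"
    mdl = gemmi.Model("1")
    cur_chain = None
    chain_obj = None
    res_obj = None
    cur_res_key = None
    for i in range(conf.n_atoms):
        ch = str(conf.chain_ids[i])
        if ch != cur_chain:
            chain_obj = gemmi.Chain(ch)
            mdl.add_chain(chain_obj)
            chain_obj = mdl[-1]
            cur_chain = ch
            cur_res_key = None
        key = (ch, int(conf.res_seq[i]))
        if key != cur_res_key:
            res_obj = gemmi.Residue()
            res_obj.name = str(conf.res_names[i])
            res_obj.seqid = gemmi.SeqId(int(conf.res_seq[i]), " ")
            chain_obj.add_residue(res_obj)
            res_obj = chain_obj[-1]
            cur_res_key = key
        atom = gemmi.Atom()
        atom.name = str(conf.atom_names[i])
        el = str(conf.elements[i]).capitalize()
        atom.element = gemmi.Element(el)
        atom.pos = gemmi.Position(*conf.coords[i])
        atom.occ = 1.0
        atom.b_iso = 0.0
        res_obj.add_atom(atom)
    st.add_model(mdl)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# Amide hydrogen reconstruction
# ---------------------------------------------------------------------------

def place_amide_hydrogens(conf: Conformation) -> Conformation:
    """Add the backbone amide hydrogen to every residue that can carry one.

    The hydrogen is placed 1.01 A from N, in the C(prev)-N-CA plane, along
    the external bisector of the C(prev)-N-CA angle — i.e. trans to the
    preceding carbonyl oxygen (standard planar sp2 amide construction).
    Prolines and chain N-terminal residues are skipped; residues that already
    carry a backbone amide H (NMR models) are left untouched. Idempotent.
    """
    t = conf.topology
    new_atoms: list[tuple[int, str, str, np.ndarray]] = []  # (insert_after, ...)
    for k, r in enumerate(t.residues):
        if r.name == "PRO":
            continue
        if k == 0 or t.res_chain[k - 1] != r.chain:
            continue                     # chain N-terminus: not monitorable
        if t.idx_H[k] >= 0:
            continue                     # already present: preserve
        iN, iCA = t.idx_N[k], t.idx_CA[k]
        iCprev = t.idx_C[k - 1]
        if min(iN, iCA, iCprev) < 0:
            raise StructureError(
                f"cannot place amide H at {r.chain}:{r.resseq}: incomplete backbone")
        N, CA, Cp = conf.coords[iN], conf.coords[iCA], conf.coords[iCprev]
        u = N - Cp
        u /= np.linalg.norm(u)
        v = N - CA
        v /= np.linalg.norm(v)
        h_dir = u + v
        h_dir /= np.linalg.norm(h_dir)
        new_atoms.append((iN, r.chain, "H", N + N_H_BOND_LENGTH * h_dir))
    if not new_atoms:
        return conf

    insert_after = {i: pos for (i, _, _, pos) in new_atoms}
    chain_ids, res_seq, res_names, atom_names, elements, xyz = [], [], [], [], [], []
    for i in range(conf.n_atoms):
        chain_ids.append(conf.chain_ids[i])
        res_seq.append(conf.res_seq[i])
        res_names.append(conf.res_names[i])
        atom_names.append(conf.atom_names[i])
        elements.append(conf.elements[i])
        xyz.append(conf.coords[i])
        if i in insert_after:
            chain_ids.append(conf.chain_ids[i])
            res_seq.append(conf.res_seq[i])
            res_names.append(conf.res_names[i])
            atom_names.append("H")
            elements.append("H")
            xyz.append(insert_after[i])
    return Conformation(chain_ids, res_seq, res_names, atom_names, elements,
                        np.array(xyz))


# ---------------------------------------------------------------------------
# Structure comparison
# ---------------------------------------------------------------------------

def _matched_indices(a: Conformation, b: Conformation,
                     selection: AtomSelection) -> tuple[np.ndarray, np.ndarray]:
    ia, ib = selection.indices(a), selection.indices(b)
    if len(ia) != len(ib):
        raise StructureError(
            f"selection sizes differ: {len(ia)} vs {len(ib)} atoms")
    for p, q in zip(ia, ib):
        ka = (a.chain_ids[p], int(a.res_seq[p]), a.atom_names[p])
        kb = (b.chain_ids[q], int(b.res_seq[q]), b.atom_names[q])
        if ka != kb:
            raise StructureError(f"atom mismatch: {ka} vs {kb}")
    return ia, ib


def rmsd(a: Conformation, b: Conformation,
         selection: AtomSelection | None = None, superpose: bool = True) -> float:
    """Root-mean-square deviation between matched atoms of two conformations,
    in Angstrom. With `superpose` (default) an optimal least-squares rigid
    superposition (Kabsch) is applied first."""
    selection = selection or AtomSelection(kind="heavy")
    ia, ib = _matched_indices(a, b, selection)
    if len(ia) == 0:
        raise StructureError("empty selection")
    pa, pb = a.coords[ia], b.coords[ib]
    return kabsch_rmsd(pa, pb) if superpose else plain_rmsd(pa, pb)


def radius_of_gyration(conf: Conformation,
                       selection: AtomSelection | None = None,
                       mass_weighted: bool = False) -> float:
    """Radius of gyration of the selected atoms, in Angstrom.

    Default is the uniform-weight RMS distance from the centroid over heavy
    atoms; `mass_weighted` switches to atomic-mass weights.
    """
    selection = selection or AtomSelection(kind="heavy")
    idx = selection.indices(conf)
    if len(idx) == 0:
        raise StructureError("empty selection")
    pts = conf.coords[idx]
    if mass_weighted:
        w = np.array([_ATOMIC_MASS.get(str(e), 12.0) for e in conf.elements[idx]])
    else:
        w = np.ones(len(idx))
    center = np.average(pts, axis=0, weights=w)
    return float(np.sqrt(np.average(np.sum((pts - center) ** 2, axis=1), weights=w)))


def rg_from_coords(coords: np.ndarray) -> float:
    """Uniform-weight radius of gyration of a bare coordinate array."""
    pts = np.asarray(coords, dtype=float)
    c = pts.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum((pts - c) ** 2, axis=1))))
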