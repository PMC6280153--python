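"""Goodness-of-fit between structurally derived and experimental HX data,
and conversion of the mismatch into per-residue sampling weights.

Residue mode compares log protection factors, e(i) = |lnP_der(i) - lnP_obs(i)|;
peptide mode compares uptake curves, E(j) = sum_t |D_der(t) - D_obs(t)| over
the experimental time points. Either error set aggregates into an average
and a histogram, and maps onto the sequence as a normalized, smoothed,
floored weight profile used to focus conformational moves on poorly fitting
regions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .forward import PeptideCurve

__all__ = [
    "FitReport",
    "BiasMap",
    "residue_errors",
    "peptide_errors",
    "average_error",
    "error_histogram",
    "bias_map",
]


@dataclass
class FitReport:
    """Per-item HX fit errors.

    mode is "residue" or "peptide"; `items` identifies each compared item
    ((chain, residue) or peptide id); for peptide mode `coverage` holds the
    (chain, start, end) span of each peptide, in item order.
    """

    mode: str
    items: list
    errors: np.ndarray
    coverage: list | None = None

    def __post_init__(self):
        self.errors = np.asarray(self.errors, dtype=float)
        if np.any(self.errors < 0):
            raise ValueError("errors must be non-negative")

    @property
    def n(self) -> int:
        return len(self.errors)

    @property
    def average(self) -> float:
        return average_error(self)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"item_id": [str(i) for i in self.items],
                             "error": self.errors})


@dataclass
class BiasMap:
    """Per-residue sampling distribution over the protein (sums to 1)."""

    chains: list
    residues: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        self.residues = np.asarray(self.residues, dtype=int)
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")
        s = self.weights.sum()
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1 (got {s})")

    def sample_index(self, rng: np.random.Generator) -> int:
        """Draw a residue position (index into residues) from the map."""
        return int(rng.choice(len(self.weights), p=self.weights))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"chain": self.chains, "residue": self.residues,
                             "weight": self.weights})


def residue_errors(derived: pd.DataFrame, observed: pd.DataFrame) -> FitReport:
    """e(i) = |lnP_der - lnP_obs| over residues present in both tables.

    Both tables need columns chain, residue, lnP. Residues present in only
    one table are silently omitted.
    """
    merged = derived.merge(observed, on=["chain", "residue"],
                           suffixes=("_der", "_obs"))
    if merged.empty:
        raise ValueError("no residues shared between derived and observed tables")
    err = np.abs(merged["lnP_der"].to_numpy() - merged["lnP_obs"].to_numpy())
    items = [(str(c), int(r)) for c, r in zip(merged["chain"], merged["residue"])]
    return FitReport("residue", items, err)


def peptide_errors(derived: Sequence[PeptideCurve],
                   observed: Sequence[PeptideCurve]) -> FitReport:
    """E(j) = sum over time points of |D_der(t) - D_obs(t)|, matched by
    (chain, start, end). Time-point lists must be identical per peptide."""
    der = {(c.chain, c.start, c.end): c for c in derived}
    items, errs, cov = [], [], []
    for obs in observed:
        key = (obs.chain, obs.start, obs.end)
        if key not in der:
            continue
        d = der[key]
        if len(d.times) != len(obs.times) or np.any(d.times != obs.times):
            bad = (set(map(float, d.times)) ^ set(map(float, obs.times)))
            t = sorted(bad)[0] if bad else float(obs.times[0])
            raise ValueError(f"peptide {obs.peptide_id}: time point mismatch "
                             f"at t={t} s")
        items.append(obs.peptide_id)
        errs.append(float(np.abs(d.uptake - obs.uptake).sum()))
        cov.append(key)
    if not items:
        raise ValueError("no peptides shared between derived and observed curves")
    return FitReport("peptide", items, np.array(errs), coverage=cov)


def average_error(report: FitReport) -> float:
    """Arithmetic mean of the per-item errors."""
    if report.n == 0:
        raise ValueError("empty fit report")
    return float(report.errors.mean())


def error_histogram(report: FitReport, bin_width: float
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of errors with fixed-width bins starting at 0; returns
    (bin_edges, counts). Counts sum to the number of items."""
    if report.n == 0:
        raise ValueError("empty fit report")
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    top = max(float(report.errors.max()), bin_width)
    nbins = int(np.ceil(top / bin_width - 1e-12)) or 1
    edges = np.arange(nbins + 1) * bin_width
    counts, _ = np.histogram(np.minimum(report.errors, edges[-1] - 1e-12),
                             bins=edges)
    return edges, counts


def bias_map(report: FitReport, residue_list: Sequence[tuple[str, int]],
             smoothing_halfwidth: int = 2,
             floor: float | None = None) -> BiasMap:
    """Turn fit errors into a per-residue sampling distribution.

    Residue mode: raw weight of residue i is its e(i) (0 if uncompared).
    Peptide mode: raw weight is the mean E(j) over the peptides covering the
    residue (0 if uncovered), then smoothed by a +-halfwidth moving average.
    Finally a floor is added (default 5% of the max raw weight; uniform if
    all weights are zero) and the profile is normalized to sum 1, so every
    residue always keeps a nonzero sampling probability.
    """
    chains = [c for c, _ in residue_list]
    residues = np.array([r for _, r in residue_list], dtype=int)
    n = len(residue_list)
    raw = np.zeros(n)

    if report.mode == "residue":
        emap = {item: e for item, e in zip(report.items, report.errors)}
        for idx, key in enumerate(residue_list):
            raw[idx] = emap.get((str(key[0]), int(key[1])), 0.0)
    elif report.mode == "peptide":
        if report.coverage is None:
            raise ValueError("peptide report lacks coverage spans")
        sums = np.zeros(n)
        hits = np.zeros(n)
        pos = {(str(c), int(r)): idx for idx, (c, r) in enumerate(residue_list)}
        for (chain, start, end), e in zip(report.coverage, report.errors):
            for r in range(start, end + 1):
                idx = pos.get((str(chain), r))
                if idx is not None:
                    sums[idx] += e
                    hits[idx] += 1
        raw = np.divide(sums, hits, out=np.zeros(n), where=hits > 0)
    else:
        raise ValueError(f"unknown report mode {report.mode!r}")

    if smoothing_halfwidth > 0:
        # moving average within each chain block; never smooths across chains
        w = smoothing_halfwidth
        smoothed = np.empty(n)
        block_start = 0
        for idx in range(1, n + 1):
            if idx == n or chains[idx] != chains[block_start]:
                for j in range(block_start, idx):
                    lo = max(block_start, j - w)
                    hi = min(idx, j + w + 1)
                    smoothed[j] = raw[lo:hi].mean()
                block_start = idx
        raw = smoothed

    if floor is None:
        floor = 0.05 * raw.max() if raw.max() > 0 else 1.0
    raw = raw + floor
    if raw.sum() == 0:
        raw = np.ones(n)
    return BiasMap(chains, residues, raw / raw.sum())
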