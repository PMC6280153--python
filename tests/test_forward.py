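import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hxguide as hx
from hxguide.forward import HxEvaluator, hx_counts
from hxguide.structure import Conformation, StructureError

from conftest import brute_force_counts, random_multichain, uniform_kint


class TestClosedForms:
    @pytest.mark.parametrize("nh,nc,expected", [
        (0, 0, 0.0),
        (1, 10, 5.5),      # 2*1 + 0.35*10
        (2, 20, 11.0),
    ])
    def test_log_protection(self, nh, nc, expected):
        assert hx.log_protection(nh, nc) == pytest.approx(expected, abs=1e-12)

    def test_deuterium_fraction_values(self):
        assert hx.deuterium_fraction(1.0, 0.0, 0.0) == 0.0
        assert hx.deuterium_fraction(1.0, 0.0, math.log(2)) == pytest.approx(0.5, abs=1e-12)
        assert hx.deuterium_fraction(1.0, 50.0, 1e6) == pytest.approx(0.0, abs=1e-9)
        with pytest.raises(ValueError):
            hx.deuterium_fraction(1.0, 0.0, -1.0)

    def test_deltaG_conversion(self):
        assert hx.deltaG_from_lnP(0.0) == 0.0
        assert hx.deltaG_from_lnP(1.0) == pytest.approx(0.59249, abs=1e-5)

    @given(st.floats(-20, 20))
    @settings(max_examples=50, deadline=None)
    def test_deltaG_lnP_inverse_pair(self, x):
        assert hx.deltaG_from_lnP(hx.lnP_from_deltaG(x)) == pytest.approx(x, abs=1e-12)

    @given(st.floats(0.001, 100), st.floats(0, 15), st.floats(0.1, 1e5))
    @settings(max_examples=100, deadline=None)
    def test_uptake_bounds_and_monotonicity(self, kint, lnp, t):
        d = hx.deuterium_fraction(kint, lnp, t)
        assert 0.0 <= d <= 1.0
        assert hx.deuterium_fraction(kint, lnp, 2 * t) >= d
        # decreasing in protection at fixed kint, t; strict away from saturation
        d_more = hx.deuterium_fraction(kint, lnp + 1.0, t)
        assert d_more <= d
        if 1e-12 < d < 1.0 - 1e-12:
            assert d_more < d


class TestCounting:
    def test_isolated_tripeptide_all_in_window(self, tripeptide):
        assert hx.count_hbonds(tripeptide, 2) == 0
        assert hx.count_contacts(tripeptide, 2) == 0

    def test_exclusion_window_blocks_previous_residue(self, tripeptide):
        # force O of residue 1 to sit 2.0 A from the amide H of residue 2:
        # inside the cutoff but inside the i-2..i+2 window, so not counted
        t = tripeptide.topology
        coords = tripeptide.coords.copy()
        h = coords[t.idx_H[1]]
        coords[t.idx_O[0]] = h + np.array([2.0, 0.0, 0.0])
        conf = tripeptide.with_coords(coords)
        assert hx.count_hbonds(conf, 2) == 0

    def _with_probe_atom(self, base, distance):
        """Append a single-heavy-atom chain B at `distance` from the amide H
        of residue 2 of chain A."""
        t = base.topology
        h = base.coords[t.idx_H[1]]
        probe = h + np.array([distance, 0.0, 0.0])
        return Conformation(
            np.append(base.chain_ids, "B"), np.append(base.res_seq, 1),
            np.append(base.res_names, "GLY"), np.append(base.atom_names, "CA"),
            np.append(base.elements, "C"), np.vstack([base.coords, probe]))

    def test_contact_cutoff_boundary(self, tripeptide):
        assert hx.count_contacts(self._with_probe_atom(tripeptide, 6.4), 2) == 1
        assert hx.count_contacts(self._with_probe_atom(tripeptide, 6.6), 2) == 0

    def test_cross_chain_atoms_never_window_excluded(self, tripeptide):
        # chain B residue 1 is at the same sequence position as the probe
        # residue's neighbors, yet still counts: the window is per-chain
        conf = self._with_probe_atom(tripeptide, 2.0)
        assert hx.count_contacts(conf, 2) == 1

    def test_unmonitorable_residue_rejected(self, tripeptide):
        with pytest.raises(StructureError, match="monitorable"):
            hx.count_hbonds(tripeptide, 1)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_on_random_dimers(self, seed, params):
        rng = np.random.default_rng(seed)
        conf = random_multichain(rng)
        expected = brute_force_counts(conf, params)
        table = hx_counts(conf, params)
        assert len(table) == len(expected)
        for row in table.itertuples():
            assert (row.n_hbonds, row.n_contacts) == expected[(row.chain, row.residue)]

    def test_fast_evaluator_matches_reference_path(self, params):
        rng = np.random.default_rng(99)
        conf = random_multichain(rng)
        ev = HxEvaluator(conf, params)
        nh, nc = ev.counts(conf)
        table = hx_counts(conf, params)
        assert np.array_equal(nh, table["n_hbonds"].to_numpy())
        assert np.array_equal(nc, table["n_contacts"].to_numpy())

    def test_hbonds_never_exceed_contacts(self, helix12, params):
        # every counted oxygen is a heavy atom within the larger cutoff
        table = hx_counts(helix12, params)
        assert (table["n_hbonds"] <= table["n_contacts"]).all()


class TestPeptideUptake:
    def test_backexchange_skips_first_two(self):
        uptakes = {1: [0.9], 2: [0.8], 3: [0.4], 4: [0.2]}
        mon = {r: True for r in uptakes}
        curve = hx.peptide_uptake(uptakes, (1, 4), mon, [10.0])
        assert curve.uptake[0] == pytest.approx(0.3)

    def test_constant_uptake_is_preserved(self):
        uptakes = {r: [0.42] for r in range(1, 7)}
        mon = {r: True for r in uptakes}
        curve = hx.peptide_uptake(uptakes, (1, 6), mon, [60.0])
        assert curve.uptake[0] == pytest.approx(0.42)

    def test_proline_excluded_independently(self):
        uptakes = {4: [0.2]}
        mon = {1: True, 2: True, 3: False, 4: True}
        curve = hx.peptide_uptake(uptakes, (1, 4), mon, [10.0])
        assert curve.uptake[0] == pytest.approx(0.2)

    def test_no_includable_residues_errors(self):
        with pytest.raises(ValueError, match="1-2"):
            hx.peptide_uptake({}, (1, 2), {1: True, 2: True}, [10.0])


class TestIntrinsicRates:
    def test_user_table_passes_through(self):
        table = pd.DataFrame({"chain": "A", "residue": [2, 3],
                              "kint_per_s": [1.0, 2.0]})
        out = hx.intrinsic_rates("AAA", user_table=table)
        assert out is table

    def test_user_table_must_cover_monitorable_residues(self):
        table = pd.DataFrame({"chain": "A", "residue": [2], "kint_per_s": [1.0]})
        with pytest.raises(ValueError, match="A:3"):
            hx.intrinsic_rates("AAA", user_table=table)

    def test_non_positive_rates_rejected(self):
        table = pd.DataFrame({"chain": "A", "residue": [2, 3],
                              "kint_per_s": [1.0, -2.0]})
        with pytest.raises(ValueError, match="non-positive"):
            hx.intrinsic_rates("AAA", user_table=table)

    def test_predicted_rates_positive_and_complete(self):
        out = hx.intrinsic_rates("AGDKLMPQRSTVWYNECFHI")
        assert (out["kint_per_s"] > 0).all()
        # position 1 and the proline are not monitorable
        assert set(out["residue"]) == set(range(2, 21)) - {7}

    def test_only_adjacent_residues_matter(self):
        base = hx.intrinsic_rates("AAAAAAA")
        near = hx.intrinsic_rates("AAAGAAA")     # mutate residue 4
        far = hx.intrinsic_rates("AAAAAAG")      # mutate residue 7

        def rate(df, i):
            return float(df.loc[df["residue"] == i, "kint_per_s"].iloc[0])

        assert rate(near, 4) != rate(base, 4)    # own side chain
        assert rate(near, 5) != rate(base, 5)    # left neighbor effect
        assert rate(near, 2) == rate(base, 2)    # three away: untouched
        assert rate(far, 4) == rate(base, 4)


class TestPredictDataset:
    def test_residue_mode_omits_prolines_and_n_terminus(self):
        conf = hx.build_ideal_chain(hx.ChainSpec("APAGPA"))
        table = hx.predict_hx_dataset(conf, mode="residue")
        assert set(table["residue"]) == {3, 4, 6}

    def test_peptide_mode_equals_manual_composition(self, params):
        conf = hx.build_ideal_chain(hx.ChainSpec("A" * 10, motif="alpha_helix"))
        kint = uniform_kint(conf, 2.0)
        times = [10.0, 100.0]
        curves = hx.predict_hx_dataset(conf, kint, mode="peptide",
                                       peptides=[(2, 8)], times=times)
        # by hand: counts -> lnP -> residue uptake -> average over residues
        # 4..8 (first two of the peptide dropped by back-exchange)
        manual = np.zeros(2)
        for r in range(4, 9):
            nh = hx.count_hbonds(conf, r, params)
            nc = hx.count_contacts(conf, r, params)
            lnp = hx.log_protection(nh, nc, params)
            manual += np.array([hx.deuterium_fraction(2.0, lnp, t) for t in times])
        manual /= 5
        assert np.allclose(curves[0].uptake, manual, atol=1e-12)

    def test_self_consistency_zero_error(self):
        conf = hx.build_ideal_chain(hx.ChainSpec("ADKLMNQEARNDCE", motif="alpha_helix"))
        kint = uniform_kint(conf)
        derived = hx.predict_hx_dataset(conf, mode="residue")
        report = hx.residue_errors(derived, derived[["chain", "residue", "lnP"]])
        assert report.average == 0.0

    def test_compact_more_protected_than_extended(self):
        seq = "ADKLMNQEARNDCEFGHKLA"
        compact = hx.build_ideal_chain(hx.ChainSpec(seq, motif="alpha_helix"))
        extended = hx.build_ideal_chain(hx.ChainSpec(seq, motif="extended"))
        lnp_c = hx.predict_hx_dataset(compact, mode="residue")["lnP"].mean()
        lnp_e = hx.predict_hx_dataset(extended, mode="residue")["lnP"].mean()
        assert lnp_c > lnp_e
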