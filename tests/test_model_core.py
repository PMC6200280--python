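"""Unit tests of the ODE right-hand side, readouts and invariants."""

import numpy as np
import pytest

from pd1tcr import (
    PerturbationFlags,
    SpeciesState,
    TotalPools,
    correction_factor,
    readouts,
    rhs,
)
from pd1tcr.model import SPECIES_NAMES

from _reference import random_valid_state, reference_rhs


class TestCorrectionFactor:
    @pytest.mark.parametrize(
        "pd1p1, pd1p2, lckT, k, expected",
        [
            (0.0, 0.0, 100.0, 41.0, 1.0),          # empty phospho-pool
            (2050.0, 2050.0, 100.0, 41.0, 0.0),    # exactly at the cap
            (1025.0, 1025.0, 100.0, 41.0, 0.5),    # halfway to the cap
            (5000.0, 5000.0, 100.0, 41.0, 0.0),    # beyond the cap: clamped
        ],
    )
    def test_values(self, pd1p1, pd1p2, lckT, k, expected):
        assert correction_factor(pd1p1, pd1p2, lckT, k) == pytest.approx(expected)

    def test_zero_lck_is_undefined(self):
        with pytest.raises(ValueError, match="lckT"):
            correction_factor(10.0, 0.0, 0.0, 41.0)

    def test_negative_phospho_rejected(self):
        with pytest.raises(ValueError):
            correction_factor(-1.0, 0.0, 100.0, 41.0)


class TestRhs:
    def test_empty_system_is_stationary(self, default_params):
        deriv = rhs(SpeciesState(), TotalPools(), default_params)
        assert all(v == 0.0 for v in deriv.to_array())

    def test_matches_independent_transcription(self, default_params, rng):
        """The packaged kernel agrees with a second, independently
        organized transcription of the equation list to 1e-12 relative
        on 100 random valid states."""
        k = dict(default_params.items())
        for _ in range(100):
            s, q = random_valid_state(rng)
            got = rhs(SpeciesState(**s), TotalPools(**q), default_params).to_array()
            want = np.array([reference_rhs(s, q, k)[n] for n in SPECIES_NAMES])
            scale = np.maximum(np.abs(want), 1e-30)
            assert np.all(np.abs(got - want) / scale <= 1e-12)

    def test_family_totals_conserved_by_construction(self, default_params, rng):
        """The PD-1 family (PD1 + PD1p1 + PD1p2 + CP1 + CP2) and the Shp2
        family (free Shp2 + CP1 + CP2) have exactly zero net flux."""
        idx = {n: i for i, n in enumerate(SPECIES_NAMES)}
        for _ in range(20):
            s, q = random_valid_state(rng)
            d = rhs(SpeciesState(**s), TotalPools(**q), default_params).to_array()
            pd1_flux = sum(d[idx[n]] for n in ("pd1", "pd1p1", "pd1p2", "cp1", "cp2"))
            shp2_flux = sum(d[idx[n]] for n in ("shp2_free", "cp1", "cp2"))
            assert abs(pd1_flux) < 1e-12 * max(1.0, np.abs(d).max())
            assert abs(shp2_flux) < 1e-12 * max(1.0, np.abs(d).max())

    def test_dephosphorylation_requires_bound_shp2(self, default_params, rng):
        """With CP1 = CP2 = 0 every dephosphorylation flux vanishes: the
        derivatives are insensitive to all CP-catalysed rate constants."""
        s, q = random_valid_state(rng)
        s["cp1"] = s["cp2"] = 0.0
        q["shp2T"] = s["shp2_free"]
        boosted = default_params.replace(
            k_dp_cd3=99.0, k_dp_cd28=99.0, k_dpa_yiya=99.0, k_dpi_yi=99.0,
            k_dpi_yiya=99.0, k_dpa_ya=99.0, k_dpa_pi=99.0, k_dp_cp2=99.0,
        )
        base = rhs(SpeciesState(**s), TotalPools(**q), default_params).to_array()
        perturbed = rhs(SpeciesState(**s), TotalPools(**q), boosted).to_array()
        np.testing.assert_array_equal(base, perturbed)

    def test_phosphorylation_requires_active_lck(self, default_params, rng):
        """With no active Lck, every Lck-catalysed flux vanishes."""
        s, q = random_valid_state(rng)
        s["lck_yiya"] = s["lck_ya"] = 0.0
        boosted = default_params.replace(
            k_p_cd3=99.0, k_p_cd28=99.0, k_p_pd1=99.0, k_p1_zap=99.0, k_p2_zap=99.0
        )
        base = rhs(SpeciesState(**s), TotalPools(**q), default_params).to_array()
        perturbed = rhs(SpeciesState(**s), TotalPools(**q), boosted).to_array()
        np.testing.assert_array_equal(base, perturbed)

    def test_negative_state_rejected(self, default_params):
        state = SpeciesState(cd3a=-1.0)
        with pytest.raises(ValueError, match="negative"):
            rhs(state, TotalPools(cd3T=100.0), default_params)

    def test_flags_zero_term_groups(self, default_params, rng):
        """Switching off Shp2's Lck catalysis freezes the Lck equations
        to their auto-phosphorylation-only form."""
        s, q = random_valid_state(rng)
        flags = PerturbationFlags(shp2_lck_catalysis=False)
        d = rhs(SpeciesState(**s), TotalPools(**q), default_params, flags)
        manual = default_params.replace(
            k_dpa_yiya=0.0, k_dpi_yi=0.0, k_dpi_yiya=0.0, k_dpa_ya=0.0, k_dpa_pi=0.0
        )
        d_manual = rhs(SpeciesState(**s), TotalPools(**q), manual)
        np.testing.assert_array_equal(d.to_array(), d_manual.to_array())


class TestReadouts:
    def test_empty_state_gives_zero_aggregates(self):
        obs = readouts(SpeciesState(), TotalPools(lckT=1.0, shp2T=1.0,
                                                  pi3kT=1.0, zap70T=1.0))
        assert obs.phospho_cd3 == 0.0
        assert obs.phospho_cd28 == 0.0
        assert obs.pct_bound_shp2 == 0.0
        assert obs.pct_active_lck == 0.0

    def test_equal_lck_split_gives_half_active(self):
        state = SpeciesState(lck_yiya=25.0, lck_ya=25.0, lck_yi=25.0, lck_pi=0.0)
        obs = readouts(state, TotalPools(lckT=100.0))
        assert obs.pct_active_lck == pytest.approx(50.0)
        assert obs.lck_active == pytest.approx(50.0)

    def test_zap70_site_aggregates(self):
        state = SpeciesState(zap70a1=2.0, zap70a2=3.0)
        obs = readouts(state, TotalPools(zap70T=10.0, cd3T=10.0))
        assert obs.zap70_pY315 == pytest.approx(5.0)
        assert obs.zap70_pY493 == pytest.approx(3.0)

    def test_aggregates_are_stated_sums(self, rng):
        s, q = random_valid_state(rng)
        obs = readouts(SpeciesState(**s), TotalPools(**q))
        assert obs.phospho_cd3 == pytest.approx(
            s["cd3a"] + s["zap70i"] + s["zap70a1"] + s["zap70a2"]
        )
        assert obs.phospho_lat == pytest.approx(
            s["lata"] + s["gadsa"] + s["slp76i"] + s["slp76a"]
        )
        assert obs.lck_pY505 == pytest.approx(s["lck_yi"] + s["lck_yiya"] + s["lck_pi"])
        assert obs.lck_pY394 == pytest.approx(s["lck_ya"] + s["lck_yiya"] + s["lck_pi"])
        assert 0.0 <= obs.pct_bound_shp2 <= 100.0
        assert 0.0 <= obs.pct_active_lck <= 100.0

    def test_percentage_with_empty_pool_is_undefined(self):
        obs = readouts(SpeciesState(), TotalPools())
        assert np.isnan(obs.pct_bound_shp2)
        with pytest.raises(ValueError, match="undefined"):
            obs.require("pct_bound_shp2")


class TestStateValidation:
    def test_pool_bound_breach_detected(self):
        state = SpeciesState(cd3a=150.0)
        with pytest.raises(ValueError, match="cd3T"):
            state.validate(TotalPools(cd3T=100.0))

    def test_array_round_trip(self, rng):
        s, _ = random_valid_state(rng)
        state = SpeciesState(**s)
        assert SpeciesState.from_array(state.to_array()) == state
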