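"""Dissociation-junction and composition-balanced stitching, plus the
derived overall/selectivity/rate-limiting quantities."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import glycoprofile as gp
from glycoprofile.constants import round_half_away
from glycoprofile.energy_io import SpeciesEnergy
from tests.conftest import blueprint_for, stitched_profile


def make_species(label, energy, step="s", model="QM2"):
    return SpeciesEnergy(label, step, model, "B3LYP", "b", "cpcm", energy)


def toy_steps(de1=10.0, de_im1=2.0, de2=8.0, rxn2=-3.0):
    k = gp.HARTREE_TO_KCALMOL
    first = gp.relative_energies(
        [make_species("RC", -100.0), make_species("TS1", -100.0 + de1 / k),
         make_species("IM1", -100.0 + de_im1 / k)],
        "RC", name="fructosylation",
    )
    second = gp.relative_energies(
        [make_species("IM2", -80.0), make_species("TS2", -80.0 + de2 / k),
         make_species("PC2", -80.0 + rxn2 / k)],
        "IM2", name="hydrolysis",
    )
    return first, second


class TestJunctionSpec:
    def test_components_sum_to_offset(self):
        j = gp.JunctionSpec("IM1", "IM2",
                            components={"dE_im1_rel_rc": 0.1, "dG_diss": 3.1})
        assert j.offset_kcal == pytest.approx(3.2, abs=1e-12)

    def test_inconsistent_components_rejected(self):
        with pytest.raises(ValueError, match="components"):
            gp.JunctionSpec("IM1", "IM2", offset_kcal=5.0,
                            components={"dG_diss": 3.1})

    def test_offset_required(self):
        with pytest.raises(ValueError):
            gp.JunctionSpec("IM1", "IM2")


class TestStitchBras:
    def test_reference_hydrolysis_placement(self, table3, table5, qm3_steps):
        """Published arithmetic: step barrier 17.6 + junction offset 3.2
        puts the hydrolysis TS at 20.8 relative to RC."""
        bp = blueprint_for("B3LYP", table3.loc["B3LYP"], table5.loc["B3LYP"])
        profile, _ = stitched_profile(bp)
        assert round_half_away(profile.energy("TS2")) == 20.8
        assert round_half_away(profile.energy("TS3")) == 26.2
        assert profile.energy("RC") == 0.0

    def test_null_junction_is_plain_concatenation(self):
        first, second = toy_steps()
        j = gp.JunctionSpec("IM1", "IM2", offset_kcal=0.0)
        profile = gp.stitch_bras(first, second, j)
        for lab, rel in second.relative_kcal.items():
            assert profile.energy(lab) == pytest.approx(rel, abs=1e-12)

    def test_same_offset_reproduces_both_branch_activations(self, table3, table5):
        """One junction offset per functional, calibrated on the hydrolysis
        branch, must land the transfructosylation TS on its published
        height within 0.1 kcal/mol (exactly for B3LYP and M06-2X)."""
        for functional in table3.index:
            bp = blueprint_for(functional, table3.loc[functional],
                               table5.loc[functional])
            profile, _ = stitched_profile(bp)
            act_t = profile.energy("TS3")
            expected = table5.loc[functional, "act_transfructosylation"]
            assert act_t == pytest.approx(expected, abs=0.1 + 1e-9)
            if functional in ("B3LYP", "M06-2X"):
                assert round_half_away(act_t) == expected

    def test_missing_junction_species_is_lookup_error(self):
        first, second = toy_steps()
        with pytest.raises(KeyError, match="IM9"):
            gp.stitch_bras(first, second,
                           gp.JunctionSpec("IM1", "IM9", offset_kcal=1.0))

    def test_shift_invariance_of_offset(self):
        first, second = toy_steps()
        p0 = gp.stitch_bras(first, second, gp.JunctionSpec("IM1", "IM2", offset_kcal=2.0))
        p1 = gp.stitch_bras(first, second, gp.JunctionSpec("IM1", "IM2", offset_kcal=5.5))
        for lab in ("IM2", "TS2", "PC2"):
            assert p1.energy(lab) - p0.energy(lab) == pytest.approx(3.5, abs=1e-12)
        for lab in ("RC", "TS1", "IM1"):
            assert p1.energy(lab) == p0.energy(lab)


class TestCalibrateJunctionOffset:
    @pytest.mark.parametrize(
        "overall,step,expected", [(20.8, 17.6, 3.2), (24.9, 22.6, 2.3), (7.0, 7.0, 0.0)]
    )
    def test_inversion(self, overall, step, expected):
        assert gp.calibrate_junction_offset(overall, step) == pytest.approx(
            expected, abs=1e-12
        )


class TestStitchBalanced:
    def test_degenerate_ledger_matches_relative_energies(self):
        first, _ = toy_steps()
        ledger = gp.BalancedLedger(auxiliaries={})
        profile = gp.stitch_balanced(first.species, ledger, "RC")
        for lab, rel in first.relative_kcal.items():
            assert profile.energy(lab) == pytest.approx(rel, abs=1e-12)

    def test_common_auxiliary_cancels(self):
        first, _ = toy_steps()
        water = ("H2O", -76.4, 1)
        ledger = gp.BalancedLedger(
            auxiliaries={lab: [water] for lab in ("RC", "TS1", "IM1")}
        )
        profile = gp.stitch_balanced(first.species, ledger, "RC")
        for lab, rel in first.relative_kcal.items():
            assert profile.energy(lab) == pytest.approx(rel, abs=1e-9)

    def test_one_sided_water_matches_hand_sum(self):
        # two-state toy: reference A plus one water balances state B
        a = make_species("A", -500.0)
        b = make_species("B", -576.35)
        ledger = gp.BalancedLedger(auxiliaries={"A": [("H2O", -76.4, 1)]})
        profile = gp.stitch_balanced([a, b], ledger, "A")
        # hand arithmetic: (-576.35) - (-500.0 + -76.4) = 0.05 au
        assert profile.energy("B") == pytest.approx(
            0.05 * gp.HARTREE_TO_KCALMOL, abs=1e-9
        )

    def test_composition_mismatch_lists_deficit(self):
        a = make_species("A", -500.0)
        b = make_species("B", -423.55)
        ledger = gp.BalancedLedger(
            auxiliaries={},
            formulas={"A": "C6H12O6", "B": "C6H10O5"},
        )
        with pytest.raises(ValueError, match="deficit"):
            gp.stitch_balanced([a, b], ledger, "A")

    def test_balancing_waters_fix_composition(self):
        a = make_species("A", -500.0)
        b = make_species("B", -423.55)
        ledger = gp.BalancedLedger(
            auxiliaries={"B": [("H2O", -76.4, 1)]},
            formulas={"A": "C6H12O6", "B": "C6H10O5", "H2O": "H2O"},
        )
        profile = gp.stitch_balanced([a, b], ledger, "A")
        assert profile.energy("B") == pytest.approx(
            ((-423.55 - 76.4) - (-500.0)) * gp.HARTREE_TO_KCALMOL, abs=1e-9
        )


@settings(max_examples=100, deadline=None)
@given(
    aux_energy=st.floats(-100, 0, allow_nan=False),
    count=st.integers(1, 3),
    e_b=st.floats(-450, -400, allow_nan=False),
)
def test_balanced_ledger_neutrality_property(aux_energy, count, e_b):
    """Auxiliaries present identically on all states never change any
    relative energy."""
    a = make_species("A", -500.0)
    b = make_species("B", e_b)
    bare = gp.stitch_balanced([a, b], gp.BalancedLedger(auxiliaries={}), "A")
    aux = ("X", aux_energy, count)
    dressed = gp.stitch_balanced(
        [a, b], gp.BalancedLedger(auxiliaries={"A": [aux], "B": [aux]}), "A"
    )
    assert dressed.energy("B") == pytest.approx(bare.energy("B"), abs=1e-6)


class TestOverallQuantities:
    def test_overall_barrier_reference_values(self, table3, table5):
        for functional, expected_h, expected_t in (
            ("B3LYP", 20.8, 26.2), ("M06-2X", 24.9, 29.8)
        ):
            bp = blueprint_for(functional, table3.loc[functional],
                               table5.loc[functional])
            profile, _ = stitched_profile(bp)
            assert round_half_away(gp.overall_barrier(profile, "hydrolysis")) == expected_h
            assert round_half_away(
                gp.overall_barrier(profile, "transfructosylation")
            ) == expected_t

    def test_overall_reaction_energy_reference_values(self, table3, table5):
        bp = blueprint_for("B3LYP", table3.loc["B3LYP"], table5.loc["B3LYP"])
        profile, _ = stitched_profile(bp)
        assert round_half_away(
            gp.overall_reaction_energy(profile, "transfructosylation")
        ) == 11.5
        assert round_half_away(
            gp.overall_reaction_energy(profile, "hydrolysis")
        ) == -9.8

    def test_reaction_energy_equals_offset_plus_step(self):
        first, second = toy_steps(rxn2=-3.0)
        j = gp.JunctionSpec("IM1", "IM2", offset_kcal=2.5)
        profile = gp.stitch_bras(first, second, j)
        assert gp.overall_reaction_energy(profile, "hydrolysis") == pytest.approx(
            2.5 + gp.step_reaction_energy(second), abs=1e-12
        )

    def test_trivial_ts_at_zero(self):
        first, second = toy_steps(de2=0.0)
        profile = gp.stitch_bras(first, second,
                                 gp.JunctionSpec("IM1", "IM2", offset_kcal=0.0))
        assert gp.overall_barrier(profile, "hydrolysis") == 0.0

    def test_missing_branch_is_error(self):
        first, second = toy_steps()
        profile = gp.stitch_bras(first, second,
                                 gp.JunctionSpec("IM1", "IM2", offset_kcal=0.0))
        with pytest.raises(KeyError):
            gp.overall_barrier(profile, "transfructosylation")

    def test_span_mode_accounts_for_downhill_intermediates(self):
        first, second = toy_steps(de1=6.0, de2=8.0)
        # place the second half's reference below RC: span from that minimum
        profile = gp.stitch_bras(first, second,
                                 gp.JunctionSpec("IM1", "IM2", offset_kcal=-5.0))
        assert gp.overall_barrier(profile, "hydrolysis") == pytest.approx(3.0)
        assert gp.overall_barrier(profile, "hydrolysis", mode="span") == (
            pytest.approx(8.0)
        )

    def test_difference_identity(self, table3, table5):
        """overall(trans) − overall(hyd) == ΔΔE exactly: offsets cancel."""
        for functional in table3.index:
            bp = blueprint_for(functional, table3.loc[functional],
                               table5.loc[functional])
            profile, steps = stitched_profile(bp)
            diff = gp.overall_barrier(profile, "transfructosylation") - (
                gp.overall_barrier(profile, "hydrolysis")
            )
            dd = gp.selectivity_dd(gp.step_barrier(steps["hydrolysis"]),
                                   gp.step_barrier(steps["transfructosylation"]))
            assert diff == pytest.approx(dd, abs=1e-9)


class TestSelectivity:
    @pytest.mark.parametrize(
        "de2,de3,expected",
        [(17.6, 23.0, 5.4), (20.0, 27.0, 7.0), (4.2, 4.2, 0.0)],
    )
    def test_dd(self, de2, de3, expected):
        assert gp.selectivity_dd(de2, de3) == pytest.approx(expected, abs=1e-12)

    def test_reference_column(self, table3):
        for functional, row in table3.iterrows():
            assert gp.selectivity_dd(row["dE2"], row["dE3"]) == pytest.approx(
                row["ddE"], abs=1e-9
            )


class TestRateLimitingStep:
    def test_deglycosylation_limits_reference_cycle(self, table3, table5):
        """TS1 at 17.5 vs hydrolysis TS at 20.8: the second step limits."""
        bp = blueprint_for("B3LYP", table3.loc["B3LYP"], table5.loc["B3LYP"])
        profile, _ = stitched_profile(bp)
        winners, height = gp.rate_limiting_step(profile, "hydrolysis")
        assert winners == ["TS2"]
        assert round_half_away(height) == 20.8

    def test_raised_first_ts_wins(self):
        first, second = toy_steps(de1=30.0, de2=8.0)
        profile = gp.stitch_bras(first, second,
                                 gp.JunctionSpec("IM1", "IM2", offset_kcal=0.0))
        winners, height = gp.rate_limiting_step(profile, "hydrolysis")
        assert winners == ["TS1"]
        assert height == pytest.approx(30.0)

    def test_tie_reported_as_tie(self):
        first, second = toy_steps(de1=10.0, de2=8.0)
        profile = gp.stitch_bras(first, second,
                                 gp.JunctionSpec("IM1", "IM2", offset_kcal=2.0))
        winners, _ = gp.rate_limiting_step(profile, "hydrolysis", tie_tol=1e-6)
        assert sorted(winners) == ["TS1", "TS2"]
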