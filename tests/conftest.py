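import pandas as pd
import pytest

import glycoprofile as gp


@pytest.fixture(scope="session")
def fixtures():
    return gp.packaged_fixtures()


@pytest.fixture(scope="session")
def qm3_records(fixtures):
    return gp.load_species_table(fixtures["table2_qm3_absolute"])


@pytest.fixture(scope="session")
def qm3_steps(qm3_records):
    steps = gp.steps_from_records(qm3_records)
    return {key[2]: step for key, step in steps.items()}


@pytest.fixture(scope="session")
def table3(fixtures):
    return pd.read_csv(fixtures["table3_barriers"], sep="\t", index_col="functional")


@pytest.fixture(scope="session")
def table5(fixtures):
    return pd.read_csv(fixtures["table5_bras"], sep="\t", index_col="functional")


def blueprint_for(functional, t3row, t5row):
    """Blueprint realising one functional's published step/overall energetics.

    The junction offset is calibrated on the hydrolysis branch
    (offset = overall activation − step barrier), then decomposed into
    ΔE(IM1 rel RC) + ΔG_diss using the published ΔG_diss.
    """
    offset = gp.calibrate_junction_offset(t5row["act_hydrolysis"], t3row["dE2"])
    return gp.CycleBlueprint(
        de1=t3row["dE1"],
        de2=t3row["dE2"],
        de3=t3row["dE3"],
        de_im1=offset - t5row["dG_diss"],
        dg_diss=t5row["dG_diss"],
        rxn2=t5row["rxn_hydrolysis"] - offset,
        rxn3=t5row["rxn_transfructosylation"] - offset,
        functional=functional,
    )


def stitched_profile(blueprint, seed=None, noise=None):
    """Run the full pipeline on a blueprint: generate → steps → stitch → merge."""
    bp = blueprint
    if seed is not None or noise is not None:
        import dataclasses

        bp = dataclasses.replace(
            bp,
            seed=bp.seed if seed is None else seed,
            noise_kcal=bp.noise_kcal if noise is None else noise,
        )
    records = gp.make_cycle_energies(bp)
    steps = {k[2]: s for k, s in gp.steps_from_records(records).items()}
    branches = []
    for branch, ref in (("hydrolysis", "IM2"), ("transfructosylation", "IM3")):
        junction = gp.JunctionSpec(
            "IM1", ref,
            components={"dE_im1_rel_rc": bp.de_im1, "dG_diss": bp.dg_diss},
        )
        branches.append(gp.stitch_bras(steps["fructosylation"], steps[branch], junction))
    return gp.merge_branches(*branches), steps
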