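import numpy as np
import pytest

from foragestat import (
    Assay,
    Condition,
    ExperimentTable,
    PlateRecord,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20250930)


def make_exit_plate(plate_id, strain, condition, remaining, *, placed=10,
                    control_group="cohort1", minutes=60.0):
    return PlateRecord(
        plate_id=plate_id,
        strain=strain,
        control_group=control_group,
        condition=condition,
        assay=Assay.MULTISENSORY,
        worms_placed=placed,
        worms_remaining=remaining,
        fructose_molarity=3.0,
        deprivation_minutes=minutes if condition is Condition.FOOD_DEPRIVED else 0.0,
        batch="batch0",
    )


@pytest.fixture
def small_table():
    """2 strains x 2 conditions, 3 plates each, plus one chemotaxis plate."""
    records = []
    counts = {
        ("WT", Condition.FED): [8, 9, 7],
        ("WT", Condition.FOOD_DEPRIVED): [2, 3, 1],
        ("mut-1", Condition.FED): [8, 8, 9],
        ("mut-1", Condition.FOOD_DEPRIVED): [7, 8, 6],
    }
    for (strain, cond), remaining in counts.items():
        for i, rem in enumerate(remaining):
            records.append(
                make_exit_plate(f"{strain}-{cond.value}-{i}", strain, cond, rem)
            )
    records.append(
        PlateRecord(
            plate_id="chem-0",
            strain="WT",
            control_group="cohort1",
            condition=Condition.FED,
            assay=Assay.CHEMOTAXIS,
            worms_placed=10,
            worms_at_odor=7,
            worms_at_control=2,
            batch="batch0",
        )
    )
    return ExperimentTable(records)
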