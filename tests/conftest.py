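import datetime

import pytest

from nbslmap.vf_core import (
    BlindSpotLocation,
    VFRecord,
    location_grid_24_2,
)


def make_record(
    patient_id="P1",
    eye="R",
    test_date=datetime.date(2016, 5, 1),
    age=60.0,
    se=-0.2,
    md=0.0,
    psd_abnormal=False,
    ght="WNL",
    fl=0.05,
    fp=0.02,
    fn=0.02,
    nbsl=(14, -2),
    pd_value=0.0,
    right_eye_format=None,
):
    """A well-formed record; PD values constant at the eye's true locations."""
    grid = location_grid_24_2()
    if right_eye_format is None:
        right_eye_format = eye == "R"
    mirror = eye == "L" and not right_eye_format
    locs = (
        [type(p)(-p.h_deg, p.v_deg) for p in grid.analysis_locations]
        if mirror
        else list(grid.analysis_locations)
    )
    return VFRecord(
        patient_id=patient_id,
        eye=eye,
        test_date=test_date,
        age=age,
        se_diopters=se,
        md_db=md,
        psd_abnormal=psd_abnormal,
        ght=ght,
        fixation_loss_rate=fl,
        fp_rate=fp,
        fn_rate=fn,
        nbsl=BlindSpotLocation(*nbsl),
        pd_values={p: pd_value for p in locs},
        right_eye_format=right_eye_format,
    )


@pytest.fixture
def grid():
    return location_grid_24_2()
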