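import datetime as dt

import pytest

from lungscreen import MorphologyProfile, NoduleObservation, SizeMeasurement

D0 = dt.date(2030, 1, 6)


def solid_obs(
    volume=None,
    diameter=None,
    *,
    nodule_id="n1",
    date=D0,
    registration="prevalent",
    morphology=None,
    **morph_kwargs,
):
    """Build a solid-nodule observation; morphology flags as kwargs."""
    if morphology is None:
        morphology = MorphologyProfile(**morph_kwargs)
    return NoduleObservation(
        nodule_id=nodule_id,
        scan_date=date,
        density="solid",
        whole=SizeMeasurement(volume_mm3=volume, mean_diameter_mm=diameter),
        morphology=morphology,
        registration=registration,
    )


def part_solid_obs(
    solid_volume=None,
    solid_diameter=None,
    whole_diameter=20.0,
    *,
    nodule_id="n1",
    date=D0,
    registration="prevalent",
    morphology=None,
    **morph_kwargs,
):
    if morphology is None:
        morphology = MorphologyProfile(**morph_kwargs)
    return NoduleObservation(
        nodule_id=nodule_id,
        scan_date=date,
        density="part_solid",
        whole=SizeMeasurement(mean_diameter_mm=whole_diameter),
        solid_component=SizeMeasurement(
            volume_mm3=solid_volume, mean_diameter_mm=solid_diameter
        ),
        morphology=morphology,
        registration=registration,
    )


def non_solid_obs(
    diameter,
    *,
    nodule_id="n1",
    date=D0,
    registration="prevalent",
    morphology=None,
    **morph_kwargs,
):
    if morphology is None:
        morphology = MorphologyProfile(**morph_kwargs)
    return NoduleObservation(
        nodule_id=nodule_id,
        scan_date=date,
        density="non_solid",
        whole=SizeMeasurement(mean_diameter_mm=diameter),
        morphology=morphology,
        registration=registration,
    )


@pytest.fixture
def builders():
    return solid_obs, part_solid_obs, non_solid_obs
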