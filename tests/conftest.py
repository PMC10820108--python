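import numpy as np
import pytest

from snackprofiler.gnpd_io import CodedValue, ProductRecord


def make_record(
    record_id="R1",
    name="Dried Apple",
    energy=100.0,
    serving_g=40.0,
    category=None,
    **panel_values,
):
    """A fully numeric product record; panel nutrients default to zero."""
    panel = {"energy": CodedValue.numeric(energy)}
    defaults = dict(
        saturated_fat=0.0, trans_fat=0.0, cholesterol=0.0, sodium=0.0,
        total_sugar=0.0, added_sugar=0.0, fiber=0.0, protein=0.0,
        potassium=0.0, vitamin_d=0.0, calcium=0.0, iron=0.0,
    )
    defaults.update(panel_values)
    for nutrient, value in defaults.items():
        panel[nutrient] = CodedValue.numeric(float(value))
    r = ProductRecord(record_id=record_id, name=name, serving_g=serving_g, panel=panel)
    r.category = category
    return r


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture
def rng():
    return np.random.default_rng(20240)
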