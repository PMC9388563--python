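import numpy as np
import pandas as pd
import pytest

from tiicsig.cell_table_io import DEFAULT_MARKERS


def cell_row(
    cell_id,
    patient_id="p1",
    roi_id="r1",
    roi_class="TC",
    compartment="stroma",
    x=10.0,
    y=10.0,
    tumour=0,
    positive=(),
    **roi_geom,
):
    row = {
        "cell_id": cell_id,
        "patient_id": patient_id,
        "roi_id": roi_id,
        "roi_class": roi_class,
        "compartment": compartment,
        "x_um": x,
        "y_um": y,
        "is_tumour_cell": tumour,
    }
    for m in DEFAULT_MARKERS:
        row[m] = 1 if m in positive else 0
    row.update(roi_geom)
    return row


@pytest.fixture
def make_cell_csv(tmp_path):
    """Write a list of cell-row dicts to a CSV and return its path."""

    counter = {"n": 0}

    def _write(rows, name=None):
        counter["n"] += 1
        path = tmp_path / (name or f"cells_{counter['n']}.csv")
        pd.DataFrame(rows).to_csv(path, index=False)
        return path

    return _write


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_study():
    """A deterministic 8-patient synthetic study, shared across tests."""
    from tiicsig.synthetic_data import SimulationConfig, simulate_cohort

    return simulate_cohort(SimulationConfig(n_patients=8, seed=42))
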