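import numpy as np
import pandas as pd
import pytest

from arsig.simulate import SimulationConfig, build_design


@pytest.fixture(scope="session")
def unit_effect_config():
    """Small experiment where every planted effect is exactly +-1.0 2log."""
    return SimulationConfig(
        n_probes=1000,
        ar_response_multiplier={"PC346C": 1.0, "PC346DCC": 0.0,
                                "PC346Flu1": 1.0, "PC346Flu2": 1.0},
        flut_agonism={"PC346C": 0.0, "PC346DCC": 0.0,
                      "PC346Flu1": 0.0, "PC346Flu2": 1.0},
        frac_low_intensity=0.3,
        seed=11,
    )


@pytest.fixture(scope="session")
def published_tables():
    from arsig.pipeline import load_published_tables

    return load_published_tables()


def make_single_condition_spots(m_by_array, a=10.0, probe_ids=None):
    """Six-array single-condition spot tables from per-array M values.

    ``m_by_array`` is a (n_probes, 6) array of log-ratios (stimulated over
    vehicle); intensities are built at constant A so M is exact.  Returns
    (spots, design) for cell line PC346C / R1881 with the standard dye-swap
    layout.
    """
    m_by_array = np.asarray(m_by_array, float)
    n, n_arrays = m_by_array.shape
    assert n_arrays == 6
    design = build_design()
    design = design[(design.cell_line == "PC346C") & (design.treatment == "R1881")]
    design = design.reset_index(drop=True)
    if probe_ids is None:
        probe_ids = [f"P{i:04d}" for i in range(n)]
    tables = []
    for k, row in enumerate(design.itertuples(index=False)):
        m = m_by_array[:, k]
        stim = 2.0 ** (a + m / 2.0)
        veh = 2.0 ** (a - m / 2.0)
        cy3, cy5 = (stim, veh) if row.dye_orientation == "stim_cy3" else (veh, stim)
        tables.append(pd.DataFrame({
            "array_id": row.array_id,
            "subarray_id": "S1",
            "probe_id": probe_ids,
            "genbank_id": probe_ids,
            "symbol": [f"G{i}" for i in range(n)],
            "control_flag": False,
            "cy3": cy3,
            "cy5": cy5,
        }))
    return pd.concat(tables, ignore_index=True), design
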