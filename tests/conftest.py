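import numpy as np
import pytest

import sdtails as st

#: production system parameters: 280 nm electronic gap, mixed dephasing +
#: relaxation coupling, room temperature
GAP_CM1 = 35650.0
ALPHA_Z = 0.37
ALPHA_X = 0.34
TEMP_K = 300.0

SINGLE_FORMS = ["displaced_drude", "ubo", "rlc"]
ALL_FORMS = SINGLE_FORMS + ["ohmic_2pk", "superohmic_2pk"]


@pytest.fixture(scope="session")
def table1():
    return st.thymine_water_table()


@pytest.fixture(scope="session")
def system():
    return st.SystemSpec(GAP_CM1, ALPHA_Z, ALPHA_X, TEMP_K)


@pytest.fixture(scope="session")
def solvent_model(table1):
    df = table1[table1["omega_cm1"] == 0]
    return st.assemble_from_table(df, "drude_lorentz")


@pytest.fixture(scope="session")
def runs_500fs(table1, system):
    """Reduced-depth 0.5 ps runs: solvent-only + the three single-peak forms."""
    report = st.run_comparison(
        table1,
        SINGLE_FORMS,
        system,
        depth=2,
        t_final_fs=500.0,
        dt_out_fs=0.25,
    )
    assert (report.metrics["error"] == "").all()
    return report


@pytest.fixture(scope="session")
def runs_50fs(table1, system, solvent_model):
    """Short fine-grained runs of all five forms plus the solvent reference."""
    out = {}
    exp = st.bcf_expansion(solvent_model, TEMP_K, 8)
    out["solvent_only"] = st.propagate(
        system, exp, depth=2, t_final_fs=50.0, dt_out_fs=0.05
    )
    for form in ALL_FORMS:
        model = st.assemble_from_table(table1, form)
        exp = st.bcf_expansion(model, TEMP_K, 8)
        out[form] = st.propagate(
            system, exp, depth=2, t_final_fs=50.0, dt_out_fs=0.05
        )
    return out


@pytest.fixture(scope="session")
def solvent_deep_run(system, solvent_model):
    """Depth-converged solvent-only run for dephasing-time extraction."""
    exp = st.bcf_expansion(solvent_model, TEMP_K, 8)
    return st.propagate(system, exp, depth=4, t_final_fs=100.0, dt_out_fs=0.05)
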