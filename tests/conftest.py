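"""Shared fixtures: expensive forward solutions are computed once per session."""

import numpy as np
import pytest

from indentfit.fem import MeshSpec, OgdenParams
from indentfit.fem.solver import FEModel


@pytest.fixture(scope="session")
def fe_model_n1():
    return FEModel(MeshSpec(N=1))


@pytest.fixture(scope="session")
def fe_model_n3():
    return FEModel(MeshSpec(N=3))


@pytest.fixture(scope="session")
def solution_r3_n3(fe_model_n3):
    """Forward solve of the identified R3 set (c=7 kPa, m=12) to 25 mm."""
    depths = [6.25, 12.5, 18.75, 25.0]
    return fe_model_n3.solve(OgdenParams(7.0, 12.0), 25.0, n_steps=8, snapshots=depths)


@pytest.fixture(scope="session")
def solution_truth_n1(fe_model_n1):
    """Planted ground truth (c=10 kPa, m=20) on the coarse mesh."""
    depths = [6.25, 12.5, 18.75, 25.0]
    return fe_model_n1.solve(OgdenParams(10.0, 20.0), 25.0, n_steps=8, snapshots=depths)


@pytest.fixture(scope="session")
def convergence_report():
    """Mesh-convergence study (N=1..3 vs N=6 reference) at 20 mm."""
    from indentfit.fem.convergence import mesh_convergence

    return mesh_convergence(N_values=(1, 2, 3), reference_N=6, delta=20.0, n_steps=8)
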