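"""Shared fixtures: default instrument, small reconstruction systems, and a
session-scoped smoke pipeline run."""

from __future__ import annotations

import numpy as np
import pytest

from fmpi import io_cli
from fmpi import recon as rc
from fmpi import scanner_sim as ss


@pytest.fixture(scope="session")
def geometry() -> ss.ScannerGeometry:
    return ss.ScannerGeometry()


@pytest.fixture(scope="session")
def spion() -> ss.SpionModel:
    return ss.SpionModel()


@pytest.fixture(scope="session")
def grid17() -> rc.GridSpec:
    """Desk-scale 2D reconstruction grid (17 x 17 at 1.75 mm)."""
    return rc.GridSpec(n_xy=17, voxel_size=1.75, z_slices=1)


@pytest.fixture(scope="session")
def system17(geometry, spion, grid17) -> rc.SystemMatrix:
    return rc.build_system_matrix(geometry, spion, grid17, [3, 5, 7, 9])


@pytest.fixture(scope="session")
def inv17(system17) -> rc.InverseOperator:
    return rc.select_singular_vectors(system17)


@pytest.fixture(scope="session")
def system3d(geometry, spion) -> rc.SystemMatrix:
    """3D-mode system: 2nd+3rd harmonics, 5 z slices, coarse in-plane grid."""
    grid = rc.GridSpec(n_xy=11, voxel_size=2.5, z_slices=5)
    return rc.build_system_matrix(geometry, spion, grid, [2, 3])


@pytest.fixture(scope="session")
def inv3d(system3d) -> rc.InverseOperator:
    return rc.select_singular_vectors(system3d)


@pytest.fixture(scope="session")
def calibrated_gain(geometry, spion, inv17) -> float:
    return rc.calibrate_signal_gain(geometry, spion, inv17)


@pytest.fixture(scope="session")
def frame_times(geometry) -> np.ndarray:
    """Timestamps of the standard 30 min protocol (300 acquired frames)."""
    times, _ = ss.frame_schedule(geometry, 1800.0)
    return times


@pytest.fixture(scope="session")
def smoke_run(tmp_path_factory):
    """One complete reduced-scale pipeline run shared across tests."""
    out = tmp_path_factory.mktemp("smoke")
    cfg = io_cli.load_config(
        {
            "seed": 7,
            "duration": 600.0,
            "output_dir": str(out),
            "recon": {"n_xy": 11, "voxel_size": 2.5, "harmonics": [3, 5]},
            "glm": {"optimize": False},
        }
    )
    report = io_cli.cli_run_all(cfg)
    return {"cfg": cfg, "report": report, "out": out}
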