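"""Shared fixtures: small grids, bar problems, and session-scoped
expensive artefacts (homogenization table, reference phantom)."""

from __future__ import annotations

import numpy as np
import pytest

from sgbr.image import ImageVolume
from sgbr.geometry import ScaffoldSpec, generate_scaffold
from sgbr.materials import MaterialModel, DEFAULT_MATERIALS
from sgbr.voxfem import LoadCase, DirichletBC, Load


def face_mask(shape, axis, idx):
    m = np.zeros(shape, dtype=bool)
    sl = [slice(None)] * 3
    sl[axis] = idx
    m[tuple(sl)] = True
    return m


@pytest.fixture(scope="session")
def gyroid_cell_fine():
    """Single gyroid unit cell, 3.5 mm, 50% solid, 0.1 mm spacing."""
    spec = ScaffoldSpec("gyroid", 3.5, 0.5, voxel_spacing=0.1)
    mask, iso = generate_scaffold(spec)
    return mask, iso


@pytest.fixture(scope="session")
def gyroid_cell_coarse():
    """Coarse (12^3) gyroid cell used for homogenization fixtures."""
    spec = ScaffoldSpec("gyroid", 3.5, 0.5, voxel_spacing=3.5 / 12)
    mask, iso = generate_scaffold(spec)
    return mask


@pytest.fixture(scope="session")
def property_table(gyroid_cell_coarse):
    from sgbr.homogenize import build_property_table
    return build_property_table(
        gyroid_cell_coarse,
        {1: DEFAULT_MATERIALS["ls_pek"], 2: DEFAULT_MATERIALS["new_bone"]},
        n_samples=6, scaffold_label=1, new_bone_label=2,
        descriptor="gyroid 3.5mm 50%")


@pytest.fixture(scope="session")
def reference_phantom():
    from sgbr.synthetic import PhantomSpec, make_phantom
    return make_phantom(PhantomSpec(screw_patches=0))


@pytest.fixture(scope="session")
def reference_growth_run(reference_phantom, property_table):
    """One full 24-week ingrowth run under the reference conditions."""
    from sgbr.synthetic import make_load_case
    from sgbr.growth import GrowthConfig, run_simulation, REFERENCE_GROWTH_LOAD
    case = make_load_case(reference_phantom, REFERENCE_GROWTH_LOAD, "bonded")
    cfg = GrowthConfig()
    state, used = run_simulation(reference_phantom.labels, cfg,
                                 property_table, case)
    return {"phantom": reference_phantom, "case": case, "cfg": used,
            "state": state}


def uniaxial_bar_case(shape):
    """Roller-supported bar loaded along +x; exact uniaxial state."""
    return LoadCase(
        dirichlet=[
            DirichletBC(face_mask(shape, 0, 0), (0,), face="-x"),
            DirichletBC(face_mask(shape, 1, 0), (1,), face="-y"),
            DirichletBC(face_mask(shape, 2, 0), (2,), face="-z"),
        ],
        loads=[],
    )


@pytest.fixture
def pek():
    return MaterialModel("pek", 2400.0, 0.3, sigma_max=80.0, K_Ic=1.05)


@pytest.fixture
def bone():
    return MaterialModel("bone", 12000.0, 0.3, sigma_max=150.0, K_Ic=1.46)
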