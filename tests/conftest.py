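"""Shared fixtures: small synthetic structures and densities.

Everything is generated programmatically; the heavier density/bank fixtures
are session-scoped so projection tests share one synthesis.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from fusemotion import em_projection as em
from fusemotion import simulate
from fusemotion.structures import AtomRecord, Structure


def make_structure(coords, chain="A", start=1, atom_name="CA", element="C") -> Structure:
    atoms = [
        AtomRecord(
            chain_id=chain,
            residue_number=start + i,
            insertion_code="",
            residue_name="ALA",
            atom_name=atom_name,
            element=element,
            occupancy=1.0,
            position=np.asarray(p, dtype=float),
        )
        for i, p in enumerate(coords)
    ]
    return Structure(atoms=atoms, label="fixture")


@pytest.fixture(scope="session")
def rod() -> Structure:
    s, _ = simulate.gen_rod_structure(seed=0)
    return s


@pytest.fixture(scope="session")
def rod_domains():
    _, defs = simulate.gen_rod_structure(seed=0)
    return {d.name: d for d in defs}


@pytest.fixture(scope="session")
def asym_structure(rod) -> Structure:
    """Rod with an off-axis lobe: orientation is identifiable up to Friedel."""
    lobe = [
        dataclasses.replace(
            a,
            position=a.position + np.array([22.0, 0.0, 0.0]),
            residue_number=a.residue_number + 1000,
        )
        for a in rod.atoms[60:100]
    ]
    return Structure(atoms=rod.atoms + lobe, label="rod+lobe")


@pytest.fixture(scope="session")
def asym_density(asym_structure) -> em.DensityGrid:
    return em.synthesize_density(asym_structure, voxel_size=6.0, resolution=25.0)


@pytest.fixture(scope="session")
def asym_bank(asym_density):
    return em.build_template_bank(asym_density, angular_step=15.0)


@pytest.fixture(scope="session")
def gaussian_blob() -> em.DensityGrid:
    """Spherically symmetric 3D Gaussian, σ = 10 Å, on a 4 Å grid."""
    n, voxel, sigma = 48, 4.0, 10.0
    ax = (np.arange(n) - (n - 1) / 2.0) * voxel
    z, y, x = np.meshgrid(ax, ax, ax, indexing="ij")
    vox = np.exp(-(x**2 + y**2 + z**2) / (2 * sigma**2))
    return em.DensityGrid(voxels=vox, voxel_size=voxel, origin=np.zeros(3), resolution=25.0)
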