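"""Shared fixtures: small phantoms with exactly known ground truth."""

from __future__ import annotations

import numpy as np
import pytest

from psmaquant import LesionSpec, PhantomSpec, SUVVolume, generate_phantom


@pytest.fixture
def box_lesion_spec() -> PhantomSpec:
    """One 3×3×3-voxel cubic lesion on 4 mm voxels: volume exactly 1.728 cm³.

    The box is centred on a voxel centre with half-width one voxel, so the
    voxel-centre rule selects exactly 27 voxels.
    """
    return PhantomSpec(
        grid_shape=(24, 24, 24),
        voxel_size_mm=(4.0, 4.0, 4.0),
        background_suv=0.5,
        lesions=(LesionSpec(center_mm=(30.0, 30.0, 30.0),
                            radii_mm=(4.0, 4.0, 4.0),
                            peak_suv=10.0, shape="box"),),
        seed=7,
    )


@pytest.fixture
def two_sphere_spec() -> PhantomSpec:
    """Two disjoint spherical lesions over a liver sphere, noise/blur free."""
    return PhantomSpec(
        grid_shape=(48, 48, 48),
        voxel_size_mm=(4.0, 4.0, 4.0),
        background_suv=0.5,
        liver_center_mm=(96.0, 96.0, 96.0),
        liver_radius_mm=40.0,
        liver_mean_suv=5.0,
        liver_sd_suv=0.4,
        lesions=(
            LesionSpec.sphere((40.0, 40.0, 140.0), 12.0, peak_suv=15.0),
            LesionSpec.sphere((150.0, 150.0, 40.0), 8.0, peak_suv=11.0),
        ),
        seed=11,
    )


@pytest.fixture
def two_sphere_phantom(two_sphere_spec):
    vol, truths = generate_phantom(two_sphere_spec)
    return vol, truths


def flood_fill_components(mask: np.ndarray) -> list[set[tuple[int, int, int]]]:
    """Independent 26-connectivity component oracle: BFS over voxel tuples."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    comps: list[set[tuple[int, int, int]]] = []
    neighbours = [
        (dx, dy, dz)
        for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ]
    shape = mask.shape
    for start in zip(*np.nonzero(mask)):
        if seen[start]:
            continue
        comp = set()
        stack = [tuple(int(c) for c in start)]
        seen[start] = True
        while stack:
            v = stack.pop()
            comp.add(v)
            for d in neighbours:
                w = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
                if all(0 <= wi < si for wi, si in zip(w, shape)) and mask[w] and not seen[w]:
                    seen[w] = True
                    stack.append(w)
        comps.append(comp)
    return comps
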