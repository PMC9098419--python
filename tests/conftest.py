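"""Shared fixtures: phantoms, sphere boundaries, and cached experiment runs."""

import dataclasses
import math

import numpy as np
import pytest
from scipy import ndimage

from boneseg import ImageVolume, Modality, default_spec, generate
from boneseg import boundary_tracking as bt


@pytest.fixture(scope="session")
def spec():
    return default_spec()


@pytest.fixture(scope="session")
def small_spec():
    """A half-scale phantom for fast unit tests (not the study conditions)."""
    s = default_spec()
    return dataclasses.replace(s, bone_semiaxes=(11.0, 9.0, 7.0), margin_mm=4.0)


@pytest.fixture(scope="session")
def t1_phantom(spec):
    return generate(spec, Modality.MRI_T1VIBE)


@pytest.fixture(scope="session")
def noiseless_spec(spec):
    return dataclasses.replace(spec, noise_sd={m: 0.0 for m in spec.noise_sd})


@pytest.fixture(scope="session")
def noiseless_t1_phantom(noiseless_spec):
    return generate(noiseless_spec, Modality.MRI_T1VIBE)


@pytest.fixture(scope="session")
def sphere_boundary():
    """Analytic sphere rasterized to per-slice boundary rings.

    Returns (BoundarySet, ImageVolume, radius_mm); ring pixels are the
    one-pixel boundary of the analytic disk mask on each slice, so the ring
    is centred on the true circle without radius rounding.
    """
    R, sp = 10.0, 0.5
    n = int(2 * (R + 3) / sp)
    half = (n / 2 - 0.5) * sp
    vol = ImageVolume(np.zeros((n, n, n)), (sp, sp, sp), origin=(-half, -half, -half))
    ax = np.arange(n) * sp - half
    X, Y = np.meshgrid(ax, ax, indexing="ij")
    bset = bt.BoundarySet()
    for k in range(n):
        z = ax[k]
        r2 = R * R - z * z
        if r2 <= 0:
            continue
        mask = (X**2 + Y**2) <= r2
        if mask.sum() < 9:
            continue
        ring = mask & ~ndimage.binary_erosion(mask)
        rr, cc = np.nonzero(ring)
        bset.boundary[k] = set(zip(rr.tolist(), cc.tolist()))
    return bset, vol, R


@pytest.fixture(scope="session")
def flat_slab_mesh():
    """Closed slab mesh with a planar +x face flagged as the articular
    region — the geometry on which the signed-distance arithmetic is exact."""
    from boneseg import build_mesh
    from boneseg.model_building import SurfaceMesh

    sp, n = 0.5, 60
    half = (n / 2 - 0.5) * sp
    vol = ImageVolume(np.zeros((n, n, n)), (sp, sp, sp), origin=(-half,) * 3)
    ring = set()
    for i in range(10, 50):
        ring |= {(10, i), (49, i), (i, 10), (i, 49)}
    bset = bt.BoundarySet(boundary={k: set(ring) for k in range(10, 50)})
    mesh = build_mesh(bset, vol, smoothing_iters=0)
    flags = mesh.vertices[:, 0] > mesh.vertices[:, 0].max() - 0.25
    return SurfaceMesh(mesh.vertices, mesh.faces, flags)
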