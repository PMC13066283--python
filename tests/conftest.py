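"""Shared fixtures: small reconstruction problems built once per session."""

from __future__ import annotations

import numpy as np
import pytest

import petbench as pb


@pytest.fixture(scope="session")
def disc16():
    """16x16 constant-disc scene with a noisy low-count acquisition."""
    scene = pb.generate_phantom("constant_disc", dims=(16, 16), contrast=2.0, seed=11)
    geom = pb.default_geometry(scene, n_views=8)
    sim = pb.simulate_acquisition(
        scene, geom=geom, counts_target=5e4, dead_fraction=0.02, seed=5
    )
    return scene, geom, sim


@pytest.fixture(scope="session")
def problem16(disc16):
    """OSEM start, kappa/epsilon/delta and prior for the 16x16 scene."""
    scene, geom, sim = disc16
    scheme = pb.make_subsets(geom.n_views, 4)
    mask = scene.vois.object_mask
    x_osem = pb.osem(sim.counts, geom, sim.factors, scheme, 2, object_mask=mask)
    kappa = pb.kappa_from_osem(x_osem, sim.counts, geom, sim.factors)
    eps = pb.epsilon_from_osem(x_osem)
    prior = pb.PriorParams(beta=1.0, kappa=kappa, epsilon=eps)
    delta = 1e-6 * float(x_osem.values.max())
    return dict(
        scene=scene, geom=geom, sim=sim, scheme=scheme, mask=mask,
        x_osem=x_osem, prior=prior, delta=delta,
    )


@pytest.fixture(scope="session")
def nema32():
    """32x32 image-quality-like scene (hot inserts) with moderate counts."""
    scene = pb.generate_phantom("nema_like", dims=(32, 32), contrast=4.0, seed=3)
    geom = pb.default_geometry(scene, n_views=16)
    sim = pb.simulate_acquisition(scene, geom=geom, counts_target=2e5, seed=9)
    return scene, geom, sim
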