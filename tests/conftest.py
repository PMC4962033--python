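"""Shared fixtures: phantom subjects at two sizes, reused across modules."""

from __future__ import annotations

import numpy as np
import pytest

from lungflow4d import DiseaseConfig, VentilationProtocol
from lungflow4d.pipeline import PhantomRunConfig, SubjectResult, run_phantom_subject

STUDY_SEED = 1  # fixed study seed for the full-size phantom subject


@pytest.fixture(scope="session")
def protocol() -> VentilationProtocol:
    return VentilationProtocol()


@pytest.fixture(scope="session")
def e2e_result() -> SubjectResult:
    """Full-size imaging run: 16 endpoints, 128^3 grid, 16 frames."""
    cfg = PhantomRunConfig(disease=DiseaseConfig.healthy(seed=STUDY_SEED),
                           seed=STUDY_SEED)
    return run_phantom_subject(cfg)


@pytest.fixture(scope="session")
def small_phantom():
    """Small rendered phantom (4 endpoints, 96^3) for geometry tests."""
    from lungflow4d.phantom import generate_tree, render_volumes, simulate_compartments

    h = 20.0
    m = 6.0 * h
    domain = ((m, m, m), (96 * h - m,) * 3)
    tree = generate_tree(2, domain=domain, seed=0)
    sim = simulate_compartments(tree, VentilationProtocol(),
                                DiseaseConfig.healthy(seed=0))
    series, truth = render_volumes(tree, sim, (96, 96, 96), h, texture_seed=3)
    return tree, sim, series, truth


def match_endpoints(result: SubjectResult) -> dict[int, int]:
    """Map each measured endpoint id to the index of the nearest true
    compartment (by distal-node position)."""
    meas = result.tree.endpoint_positions()
    true = np.array([c.center for c in result.truth.compartments])
    return {
        result.tree.endpoint_ids[i]: int(np.argmin(np.linalg.norm(true - meas[i], axis=1)))
        for i in range(len(meas))
    }
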