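"""Shared fixtures.

The full-pipeline finite-element runs (both morphotypes, five bite cases) are
session-scoped so the morphotype-contrast, truncation-sensitivity and
lever-consistency checks all reuse the same solves.
"""

from __future__ import annotations

import numpy as np
import pytest

from ichthyofea import compare, pipeline, skull


@pytest.fixture(scope="session")
def mini_params() -> skull.MorphotypeParams:
    """A small, fast skull for unit tests (~4k elements)."""
    return skull.MorphotypeParams(
        label="mini",
        total_skull_length=150.0,
        rostrum_fraction=0.55,
        rostrum_base_height=14.0,
        rostrum_base_width=12.0,
        taper_exponent=1.2,
        cranium_height=30.0,
        cranium_width=28.0,
        orbit_diameter=16.0,
        target_edge_length=3.0,
        random_seed=0,
    )


@pytest.fixture(scope="session")
def mini_mesh(mini_params) -> skull.SkullMesh:
    return skull.build_skull_mesh(mini_params)


@pytest.fixture(scope="session")
def mini_policy():
    """Node-count policy scaled to the mini mesh's surface density (the
    published counts assume a far finer mesh)."""
    from ichthyofea.muscles import NodeCountPolicy

    base = NodeCountPolicy()
    return NodeCountPolicy(counts={k: max(1, -(-v // 4)) for k, v in base.counts.items()})


@pytest.fixture(scope="session")
def robust_params() -> skull.MorphotypeParams:
    return skull.load_preset("robust")


@pytest.fixture(scope="session")
def gracile_params() -> skull.MorphotypeParams:
    return skull.load_preset("gracile")


@pytest.fixture(scope="session")
def comparison_default():
    """Both morphotypes at preset granularity: summaries, full results."""
    summaries, results = pipeline.comparison_summaries(edge_scale=1.0, seed=0)
    return summaries, results


@pytest.fixture(scope="session")
def comparison_refined():
    """One mesh-refinement level up (0.8x target edge length)."""
    summaries, results = pipeline.comparison_summaries(edge_scale=0.8, seed=0)
    return summaries, results


@pytest.fixture(scope="session")
def contrast_default(comparison_default) -> compare.StressContrast:
    return compare.stress_contrast(comparison_default[0])


@pytest.fixture(scope="session")
def contrast_refined(comparison_refined) -> compare.StressContrast:
    return compare.stress_contrast(comparison_refined[0])
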