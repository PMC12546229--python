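"""Shared fixtures: small synthetic trees and scan pairs generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from treereg import TreeSpec, generate_tree, simulate_two_stations
from treereg.pipeline import register_pair


@pytest.fixture(scope="session")
def fast_spec() -> TreeSpec:
    """Coarsely sampled tree for unit tests that only need plausible geometry."""
    return TreeSpec(surface_sampling=0.004, ground_sampling=0.03,
                    ground_extent=0.6, n_branches=8, seed=42)


@pytest.fixture(scope="session")
def fast_tree(fast_spec):
    return generate_tree(fast_spec)


@pytest.fixture(scope="session")
def default_pair():
    """One scan pair at the full study conditions (2 mm sampling and noise)."""
    spec = TreeSpec(seed=3)
    tree = generate_tree(spec)
    return simulate_two_stations(tree, seed=7, spec=spec)


@pytest.fixture(scope="session")
def default_result(default_pair):
    """Full pipeline run on the default pair (shared across test modules)."""
    return register_pair(default_pair.source, default_pair.target, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
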