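"""Shared fixtures: small phantoms and session-scoped pipeline runs.

The expensive end-to-end experiments are session-scoped so the module
tests and the acceptance tests measure the same single run.
"""

from __future__ import annotations

import numpy as np
import pytest

from axosta import phantom, workflows


@pytest.fixture(scope="session")
def unit_reference():
    """One fully decorated 96-nm unit, 30-A voxels, 32-cube."""
    return phantom.render_decorated_average(
        phantom.DecorationFlags(), 30.0, (32, 32, 32)
    )


@pytest.fixture(scope="session")
def doublet_volume_clean():
    """Noise-free straight doublet, 2 um, 20-A voxels."""
    return phantom.render_doublet_filament(extent_ang=20000.0,
                                           voxel_size_ang=20.0)


@pytest.fixture(scope="session")
def registry_outcome():
    return workflows.registry_experiment(seed=1)


@pytest.fixture(scope="session")
def cp_split_outcome():
    return workflows.cp_split_experiment(seed=1)


@pytest.fixture(scope="session")
def asymmetry_outcome():
    return workflows.asymmetry_experiment(seed=0, n_tomograms=20)


@pytest.fixture(scope="session")
def twisted_profile():
    """Expanded-average angular profile under randomised ring twist."""
    return workflows.context_contrast_experiment(
        seed=0, n_tomograms=20, twist_sd_deg=40.0
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
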