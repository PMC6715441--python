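"""Shared fixtures: small rendered scenes reused across the suite.

Rendering and the full segmentation chain are the expensive steps, so one
small (3x3-quad) scene and its pipeline output are computed once per session
and shared; tests that need different conditions render their own scenes.
"""

from __future__ import annotations

import numpy as np
import pytest

from raftsense import (
    BsdpParams,
    random_scene,
    render_array_background,
    render_signal_stack,
    run_pipeline,
    reduced_geometry,
)


@pytest.fixture(scope="session")
def geom3():
    return reduced_geometry(3, 3)


@pytest.fixture(scope="session")
def scene_small(geom3):
    """A 3x3-quad scene with four colonies under default study conditions."""
    spec = random_scene(seed=1, geometry=geom3, n_colonies=4)
    background = render_array_background(spec)
    signal, truth = render_signal_stack(spec)
    return {"spec": spec, "background": background, "signal": signal, "truth": truth}


@pytest.fixture(scope="session")
def pipeline_small(scene_small):
    mask, diagnostics = run_pipeline(
        scene_small["signal"], scene_small["background"], keep_intermediates=True
    )
    return {"mask": mask, "diagnostics": diagnostics, **scene_small}


@pytest.fixture(scope="session")
def blank_scene(geom3):
    """Same study conditions but no cells seeded."""
    spec = random_scene(seed=3, geometry=geom3, n_colonies=0)
    background = render_array_background(spec)
    signal, truth = render_signal_stack(spec)
    return {"spec": spec, "background": background, "signal": signal, "truth": truth}
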