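"""Shared fixtures: small phantoms and the two desk-scale experiment runs.

The expensive experiments (classifier training, full pipeline on held-out
volumes) run once per session; every test that needs a trained model or a
measured accuracy reuses the same run.
"""

from __future__ import annotations

import numpy as np
import pytest

from octtm import (
    CI_LARGE_STAGE,
    CI_SMALL_STAGE,
    OracleObjectClassifier,
    PhantomConfig,
    PipelineConfig,
    generate_phantom,
)
from octtm.phantom import (
    DeepStructureConfig,
    FixedPatternConfig,
    SaturationConfig,
)
from octtm.experiments import (
    classifier_curves_experiment,
    pipeline_accuracy_experiment,
)

ACCEPTANCE_SEED = 1


def bruteforce_components(binary: np.ndarray):
    """Independent flood-fill oracle: 8-connected components of a binary image.

    Returns a list of dicts with area, bbox (corner_x, corner_z, width,
    height) and the set of pixel coordinates, found by explicit stack-based
    flood fill.
    """
    binary = np.asarray(binary, dtype=bool)
    h, w = binary.shape
    seen = np.zeros_like(binary)
    comps = []
    for i in range(h):
        for j in range(w):
            if not binary[i, j] or seen[i, j]:
                continue
            stack = [(i, j)]
            seen[i, j] = True
            pixels = []
            while stack:
                a, b = stack.pop()
                pixels.append((a, b))
                for da in (-1, 0, 1):
                    for db in (-1, 0, 1):
                        na, nb = a + da, b + db
                        if 0 <= na < h and 0 <= nb < w and binary[na, nb] and not seen[na, nb]:
                            seen[na, nb] = True
                            stack.append((na, nb))
            zs = [p[0] for p in pixels]
            xs = [p[1] for p in pixels]
            comps.append({
                "area": len(pixels),
                "bbox": (min(xs), min(zs), max(xs) - min(xs) + 1, max(zs) - min(zs) + 1),
                "pixels": set(pixels),
            })
    return comps


def noise_free_config(seed: int = 5, with_structures: bool = True) -> PhantomConfig:
    """Phantom with all noise and line artifacts disabled."""
    return PhantomConfig.ci(
        seed=seed,
        fixed_pattern=FixedPatternConfig(count=0),
        saturation_lines=SaturationConfig(count=0),
        deep_structures=(
            PhantomConfig.ci().deep_structures if with_structures
            else DeepStructureConfig(count=0)
        ),
        speckle=0.0,
        background_sd=0.0,
    )


@pytest.fixture(scope="session")
def ci_phantom():
    """A default (noisy, artifact-bearing) CI-geometry phantom."""
    return generate_phantom(PhantomConfig.ci(seed=11))


@pytest.fixture(scope="session")
def noise_free_phantom():
    return generate_phantom(noise_free_config())


@pytest.fixture(scope="session")
def oracle_pipeline_config(noise_free_phantom):
    _, labels = noise_free_phantom
    return PipelineConfig(
        large_params=CI_LARGE_STAGE,
        small_params=CI_SMALL_STAGE,
        large_classifier=OracleObjectClassifier(labels),
        small_classifier=OracleObjectClassifier(labels),
    )


@pytest.fixture(scope="session")
def curves_run():
    """Coarse-stage classifier training diagnostics (runs once)."""
    return classifier_curves_experiment(seed=ACCEPTANCE_SEED)


@pytest.fixture(scope="session")
def pipeline_run():
    """Full two-stage pipeline scored on held-out phantoms (runs once)."""
    return pipeline_accuracy_experiment(seed=ACCEPTANCE_SEED)
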