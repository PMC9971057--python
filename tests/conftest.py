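"""Shared fixtures: small synthetic stimulus sets built at test time."""

import numpy as np
import pytest

from glimpsekit.baseline import build_saliency
from glimpsekit.stimuli import ClassTemplate, make_stimulus_set


@pytest.fixture(scope="session")
def small_set():
    """A 4-class stimulus set with one confusable pair (1, 2)."""
    return make_stimulus_set(n_classes=4, per_class=8, seed=11)


@pytest.fixture(scope="session")
def small_saliency(small_set):
    _, templates = small_set
    return build_saliency(templates, mode="diff")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def toy_templates(n: int, shape=(6, 5), seed=0) -> list[ClassTemplate]:
    """Random non-negative templates for oracle tests on tiny images."""
    gen = np.random.default_rng(seed)
    return [
        ClassTemplate(mean_image=gen.uniform(0.05, 1.0, size=shape), class_id=cid)
        for cid in range(1, n + 1)
    ]
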