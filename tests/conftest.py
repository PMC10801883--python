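import datetime as dt

import numpy as np
import pandas as pd
import pytest

from gazemorph.io import Condition, Trial
from gazemorph.synth import (
    ConditionSpec,
    GeneratorSpec,
    generate_experiment,
    generate_face_layout,
)


def make_trial(
    t_ms,
    x,
    y,
    on_image=None,
    trial_id="t0",
    condition=None,
    image_extent=(28.0, 21.0),
    fixation_window=(-1000, 0),
):
    """Hand-built trial from raw arrays (no generator involved)."""
    t_ms = np.asarray(t_ms, dtype=np.int64)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if on_image is None:
        on_image = (t_ms >= 0) & np.isfinite(x)
    samples = pd.DataFrame(
        {"t_ms": t_ms, "x_dva": x, "y_dva": y, "on_image": np.asarray(on_image, dtype=bool)}
    )
    return Trial(
        trial_id=trial_id,
        monkey_id="M1",
        session_id="S000b",
        session_date=dt.date(2022, 1, 3),
        condition=condition or Condition(),
        image_id="img000",
        image_extent=image_extent,
        samples=samples,
        fixation_window=fixation_window,
    )


@pytest.fixture(scope="session")
def small_experiment():
    """A small but complete experiment: baseline + two injection conditions."""
    spec = GeneratorSpec(
        seed=7,
        n_images=3,
        n_baseline_sessions=3,
        trials_per_session=4,
        conditions=(
            ConditionSpec("face_patch", "right", 10, 2, 1.4),
            ConditionSpec("control", "left", 10, 1, 0.25),
        ),
    )
    return generate_experiment(spec)


@pytest.fixture(scope="session")
def face_layout():
    spec = GeneratorSpec(seed=3)
    rng = np.random.default_rng(3)
    lm, twin = generate_face_layout(spec, 0, rng)
    return lm


@pytest.fixture(scope="session")
def landmark_pair():
    spec = GeneratorSpec(seed=4)
    rng = np.random.default_rng(4)
    return generate_face_layout(spec, 1, rng)
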