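import numpy as np
import pandas as pd
import pytest

from habselect import (
    SyntheticConfig,
    build_ru_stack,
    generate_landscape,
    generate_telemetry,
)


def make_config(seed=11, beta_class0=0.0, n_animals=3, n_classes=4,
                points=150, **kw):
    """Small study-scale config; beta_class0 sets selection for cover class 0."""
    n_egvs = n_classes + 5
    beta = np.zeros((n_animals, n_egvs))
    beta[:, 0] = beta_class0
    return SyntheticConfig(
        seed=seed,
        grid_rows=90,
        grid_cols=90,
        n_cover_classes=n_classes,
        n_animals=n_animals,
        points_per_animal_per_period=points,
        selection_coefficients=beta,
        **kw,
    )


@pytest.fixture(scope="session")
def null_sim():
    """beta = 0: use proportional to availability."""
    cfg = make_config(seed=21, beta_class0=0.0)
    cover, continuous = generate_landscape(cfg)
    stack = build_ru_stack(cfg, cover, continuous)
    telemetry, truth = generate_telemetry(cfg, stack)
    return cfg, cover, continuous, stack, telemetry, truth


@pytest.fixture(scope="session")
def strong_sim():
    """Strong positive selection for cover class 0."""
    cfg = make_config(seed=33, beta_class0=3.0, n_classes=6)
    cover, continuous = generate_landscape(cfg)
    stack = build_ru_stack(cfg, cover, continuous)
    telemetry, truth = generate_telemetry(cfg, stack)
    return cfg, cover, continuous, stack, telemetry, truth


@pytest.fixture(scope="session")
def standard_normal_rut():
    """An RU-table-shaped frame of i.i.d. standard normals (4 EGVs)."""
    rng = np.random.default_rng(7)
    n = 2000
    df = pd.DataFrame(rng.standard_normal((n, 4)), columns=list("abcd"))
    df.insert(0, "ru_id", np.arange(n))
    return df
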