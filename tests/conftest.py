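import numpy as np
import pandas as pd
import pytest

from scmpanel import GeneratorConfig, SalesPanel, StudyWindows, generate_panel


@pytest.fixture
def toy_windows():
    """10-week study: pre 1-4, intervention 5-6, post 7-10."""
    return StudyWindows(pre=(1, 2, 3, 4), intervention=(5, 6), post=(7, 8, 9, 10))


@pytest.fixture
def default_windows():
    return StudyWindows.default(52)


def make_panel(sales, treated_id=None, week_start=1, meta=None):
    sales = np.asarray(sales, dtype=float)
    n, t = sales.shape
    brand_ids = [f"B{i}" for i in range(n)]
    return SalesPanel(
        brand_ids=brand_ids,
        week_index=np.arange(week_start, week_start + t),
        sales=sales,
        treated_id=treated_id or brand_ids[0],
        brand_meta=meta,
    )


@pytest.fixture(scope="session")
def default_scenario():
    """Default 52-brand generated panel with the injected effect (seed 7)."""
    cfg = GeneratorConfig(seed=7)
    panel, truth = generate_panel(cfg)
    return cfg, panel, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def long_csv(tmp_path):
    """Write a small long-format panel CSV and return its path."""

    def _write(frame: pd.DataFrame, name="panel.csv"):
        path = tmp_path / name
        frame.to_csv(path, index=False)
        return path

    return _write
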