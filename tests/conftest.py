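import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from nmrage.containers import SpectraMatrix
from nmrage.synthetic import CohortDesign, GroupSpec
from nmrage.templates import default_urine_templates, templates_within

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


def make_meta(sample_ids, genotype="WT", week="15", fluid="urine", batch="B1"):
    n = len(sample_ids)
    return pd.DataFrame({
        "sample_id": sample_ids,
        "mouse_id": [f"m{i:02d}" for i in range(n)],
        "genotype": [genotype] * n,
        "week": [week] * n,
        "fluid": [fluid] * n,
        "batch": [batch] * n,
    })


def make_matrix(X, ppm=None, sample_ids=None, **meta_kw) -> SpectraMatrix:
    X = np.asarray(X, dtype=float)
    if ppm is None:
        ppm = np.linspace(10.0, 0.5, X.shape[1])
    if sample_ids is None:
        sample_ids = [f"s{i:02d}" for i in range(X.shape[0])]
    return SpectraMatrix(ppm, X, make_meta(sample_ids, **meta_kw))


def small_design(**overrides) -> CohortDesign:
    """Reduced-grid cohort design used throughout the tests: 0.5-4.0 ppm
    at 0.001 ppm so simulations stay fast, with only the templates whose
    signals fit on that grid."""
    grid = overrides.pop("grid", (0.5, 4.0, 0.001))
    templates = overrides.pop(
        "templates", templates_within(default_urine_templates(), grid[0], grid[1])
    )
    kw = dict(
        templates=templates,
        groups=[GroupSpec("WT", "15", 4), GroupSpec("WT", "60", 4)],
        grid=grid,
        seed=0,
    )
    kw.update(overrides)
    return CohortDesign(**kw)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
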