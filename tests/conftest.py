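import numpy as np
import pytest
from hypothesis import settings

from phaseboot import ExpressionSeries, default_timepoints, generate_templates

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def timepoints():
    return default_timepoints()  # 0, 4, ..., 44 h


@pytest.fixture(scope="session")
def templates(timepoints):
    return generate_templates(timepoints, period_T=24.0, k=3)


@pytest.fixture()
def cosine_series(timepoints):
    """Noise-free rhythmic profile peaking at 8 h (phase 2*pi/3)."""

    def make(peak_hour=8.0, baseline=2.0, amplitude=1.0, gene_id="cos"):
        phi = 2 * np.pi * peak_hour / 24.0
        values = baseline + amplitude * np.cos(2 * np.pi * timepoints / 24.0 - phi)
        return ExpressionSeries(gene_id=gene_id, values=values, timepoints=timepoints)

    return make
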