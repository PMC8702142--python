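import numpy as np
import pandas as pd
import pytest

from forcekin.kinship import prepare_markers
from forcekin.simulate import build_panel_skeleton, generate_population_frequencies
from forcekin.workflow import make_fixture


@pytest.fixture(scope="session")
def small_panel():
    """~5% scale panel with Balding-Nichols population frequencies."""
    skeleton = build_panel_skeleton(
        n_kinship=150, n_ii=10, n_ai=30, n_pi=10, n_x=20, n_y=60, seed=11
    )
    return generate_population_frequencies(skeleton, seed=12)


@pytest.fixture(scope="session")
def markers_eur(small_panel):
    return prepare_markers(small_panel, "EUR")


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("fixture")
    return make_fixture(
        out / "fx", seed=5, n_kinship=80, n_ii=10, n_ai=20, n_pi=10,
        n_x=16, n_y=60,
    )


def unlinked_markers(n, freqs=None, seed=0):
    """Markers each on their own chromosome (no linkage)."""
    rng = np.random.default_rng(seed)
    f = rng.uniform(0.2, 0.8, n) if freqs is None else np.asarray(freqs)
    return pd.DataFrame(
        {
            "snp_id": [f"u{i}" for i in range(n)],
            "chrom": [f"c{i}" for i in range(n)],
            "pos_cm": np.zeros(n),
            "freq": f,
        }
    )


def linked_markers(positions_cm, freqs, chrom="1"):
    return pd.DataFrame(
        {
            "snp_id": [f"m{i}" for i in range(len(positions_cm))],
            "chrom": chrom,
            "pos_cm": np.asarray(positions_cm, dtype=float),
            "freq": np.asarray(freqs, dtype=float),
        }
    )
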