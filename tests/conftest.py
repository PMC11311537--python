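import json
from pathlib import Path

import pytest

from mzqckit.cv import load_obo
from mzqckit.synthetic import ExperimentSpec, generate_experiment, toy_obo

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def toy_store():
    return load_obo(toy_obo())


@pytest.fixture(scope="session")
def small_experiment():
    """Scaled-down 8-run experiment for fast unit tests."""
    spec = ExperimentSpec(seed=5, ms1_per_run=12, ms2_per_ms1=5)
    runs, psm_tables, truth = generate_experiment(spec)
    return spec, runs, psm_tables, truth


@pytest.fixture(scope="session")
def full_experiment():
    """The default study-shaped experiment: 8 runs, 1000 accepted PSMs each."""
    spec = ExperimentSpec(seed=11)
    runs, psm_tables, truth = generate_experiment(spec)
    return spec, runs, psm_tables, truth


@pytest.fixture(scope="session")
def synthetic_schema():
    return json.loads((DATA_DIR / "mzqc_schema.synthetic.json").read_text())
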