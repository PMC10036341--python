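import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from npforge import SynthConfig, annotate_precursor, build_catalog, gen_precursors


@pytest.fixture(scope="session")
def default_cfg():
    return SynthConfig(seed=20230310)


@pytest.fixture(scope="session")
def small_catalog():
    """Annotated catalog from a small generated precursor set."""
    cfg = SynthConfig(seed=7, n_precursors=20)
    records, truths = gen_precursors(cfg)
    annotations = [annotate_precursor(r) for r in records]
    return cfg, records, truths, annotations, build_catalog(annotations)
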