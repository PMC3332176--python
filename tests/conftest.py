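import numpy as np
import pytest

from dermseg import pipeline, synthetic


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def lesion_fixture():
    """Default synthetic lesion (contrast 60, noise sigma 10)."""
    spec = synthetic.LesionSpec(seed=0)
    image, mask = synthetic.generate(spec)
    return spec, image, mask.astype(int)


@pytest.fixture(scope="session")
def two_region():
    """Block-aligned noiseless two-level fixture."""
    image, mask = synthetic.two_region_image()
    return image, mask.astype(int)


@pytest.fixture(scope="session")
def suite_results():
    """The 9-fixture evaluation suite segmented by all three wavelet methods.

    Computed once per session; each entry carries the generating spec, the
    ground truth and one PipelineResult per method.
    """
    rows = []
    for spec in synthetic.suite_specs(9, base_seed=0):
        image, mask = synthetic.generate(spec)
        row = {"spec": spec, "gt": mask.astype(int)}
        for method in ("wfcm", "wkmeans", "wcpsfcm"):
            row[method] = pipeline.run(image, method=method)
        rows.append(row)
    return rows
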