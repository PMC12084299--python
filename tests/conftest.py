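import numpy as np
import pandas as pd
import pytest

import imcspace as m


@pytest.fixture(scope="session")
def small_spec():
    """Tiny two-group cohort spec used across test modules."""
    return m.SyntheticCohortSpec(
        n_samples_per_group={"control": 2, "pSS": 2},
        rois_per_sample=1,
        roi_width=200,
        roi_height=200,
        mean_cells_per_roi=250,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    """Generated tiny cohort: (rois, true cell table, ground truth)."""
    return m.generate_cohort(small_spec)


def random_typed_roi(seed, n=120, types=("A", "B", "C"), p=None, side=200.0, roi_id="r1"):
    """Uniform random cells with random type labels (no spatial structure)."""
    rng = np.random.default_rng(seed)
    cells = pd.DataFrame(
        {
            "cell_id": np.arange(1, n + 1),
            "roi_id": roi_id,
            "sample_id": "s1",
            "group": "g",
            "x": rng.uniform(0, side, n),
            "y": rng.uniform(0, side, n),
        }
    )
    cells["cell_type"] = rng.choice(list(types), size=n, p=p)
    return cells


@pytest.fixture
def typed_roi():
    return random_typed_roi(1)
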