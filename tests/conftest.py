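import numpy as np
import pandas as pd
import pytest

from ielscore.io_annotations import NucleusRecord, SlideAnnotation
from ielscore.synthetic_data import CohortSimParams, SlideSimParams, simulate_cohort, simulate_slide


@pytest.fixture
def unit_square_annotation():
    """One 100x100 px square region with a handful of hand-placed nuclei."""
    square = np.array([[0, 0], [100, 0], [100, 100], [0, 100]], dtype=float)
    nuclei = [
        NucleusRecord(50, 50, "epithelial"),
        NucleusRecord(10, 10, "epithelial"),
        NucleusRecord(60, 40, "iel"),
        NucleusRecord(200, 200, "epithelial"),  # outside
    ]
    return SlideAnnotation("sq", nuclei, [square], base_mpp=1.0)


@pytest.fixture(scope="session")
def small_slide():
    """A modest synthetic slide (~1.5k nuclei) with its ground truth."""
    from ielscore.synthetic_data import blob_polygon

    rng = np.random.default_rng(7)
    poly = blob_polygon(rng, center=(700, 700), mean_radius=450)
    params = SlideSimParams(seed=7, regions=[poly], epi_density=1800, iel_fraction=0.1)
    return simulate_slide(params)


@pytest.fixture(scope="session")
def cohort_with_scores():
    """A 219-slide synthetic cohort with scores and consensus features."""
    params = CohortSimParams(seed=11, with_features=True)
    records, truth = simulate_cohort(params)
    scores = pd.DataFrame(
        {
            "slide_id": [r.slide_id for r in records],
            "iel_c": truth["score"],
            "iel_pc": truth["score_pc"],
        }
    )
    return records, scores, truth
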