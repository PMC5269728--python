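"""Shared builders for synthetic scan records."""
from __future__ import annotations

import numpy as np
import pytest

from pymsp import msp, templates

OUTWARD_GRID = np.arange(750.0, 349.0, -2.0)
RETURN_GRID = np.arange(351.0, 750.0, 2.0)
MERGED_GRID = np.arange(350.5, 750.0, 2.0)


def template_scans(lambda_max, density=0.02, baseline=0.005, noise_sd=0.0,
                   rng=None, include_beta=True):
    """Outward/return scan pair shaped like a pigment template."""
    def absorbance(grid):
        a = baseline + density * templates.pigment_absorbance(
            lambda_max, grid, include_beta=include_beta)
        if noise_sd > 0:
            a = a + rng.normal(0.0, noise_sd, size=len(grid))
        return a

    return (msp.SpectralScan(OUTWARD_GRID.copy(), absorbance(OUTWARD_GRID), "outward"),
            msp.SpectralScan(RETURN_GRID.copy(), absorbance(RETURN_GRID), "return"))


def template_record(lambda_max, putative_class="LWS", density=0.02,
                    baseline=0.005, noise_sd=0.0, rng=None,
                    cell_id="cell", bird_id="bird", population="popA",
                    morphology="single cone", post_bleach=None):
    outward, return_ = template_scans(lambda_max, density, baseline,
                                      noise_sd, rng)
    return msp.MSPRecord(cell_id=cell_id, bird_id=bird_id,
                         population=population,
                         putative_class=putative_class,
                         outward=outward, return_=return_,
                         post_bleach=post_bleach, morphology=morphology)


def merged_template(lambda_max, density=0.02, baseline=0.005, noise_sd=0.0,
                    rng=None, **normalize_kwargs):
    outward, return_ = template_scans(lambda_max, density, baseline,
                                      noise_sd, rng)
    return msp.normalize(msp.merge_scans(outward, return_),
                         **normalize_kwargs)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
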