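"""Bundled reference tables of published univariate ACE estimates.

The CSVs under ``data/`` re-enter the published maximum-likelihood variance
components (a2, c2, e2 with 95% CIs) and hypothesis-test p-values for the
48-measure genetic parcellation panel of a midlife male twin cohort: 24
regional surface-area (SA) and 24 regional mean-thickness (CT) phenotypes,
one row per hemisphere x region.  They serve as fixed inputs for summary
checks (e.g. heritability medians, the shared-environment screen), not as
fitted output of this package.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

_FILES = {"SA": "sa_univariate_reference.csv",
          "CT": "ct_univariate_reference.csv"}


def load_reference_estimates(measure: str) -> pd.DataFrame:
    """Published univariate ACE table for one measure type ('SA' or 'CT')."""
    if measure not in _FILES:
        raise ValueError("measure must be 'SA' or 'CT'")
    with resources.files("twingraph.data").joinpath(_FILES[measure]).open() as fh:
        return pd.read_csv(fh)


def heritability_median(measure: str) -> float:
    """Median a2 across the 24 regional estimates of one measure type."""
    return float(load_reference_estimates(measure)["a2"].median())
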