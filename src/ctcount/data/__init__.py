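"""Packaged reference tables.

``species_summary()`` returns the per-species summary of the eight-species
orchid study (means, standard errors, sample sizes and P:O variances for
pollen and ovule counts, with the pollination strategy of each species),
as printed in the published summary table.  These are inputs for the
summary-statistics layer, not computed results.
"""

from importlib import resources

import pandas as pd

__all__ = ["species_summary"]


def species_summary() -> pd.DataFrame:
    """Per-species published count summaries (one row per species)."""
    with resources.files(__package__).joinpath("species_summary.csv").open() as fh:
        return pd.read_csv(fh)
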