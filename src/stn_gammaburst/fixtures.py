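"""Packaged clinical and electrode-localization fixtures.

``table1.tsv`` holds the per-patient clinical details of the 16-patient
cohort (age, disease duration, UPDRS-III scores with and without
medication, percent UPDRS improvement under chronic stimulation,
medication decrease after surgery); missing entries are explicit ``NA``
and never imputed.  ``localization.tsv`` flags, for every contact pair
of the 14 imaging-controlled patients, whether at least one contact lay
inside the subthalamic nucleus, with one exclusion reason per excluded
pair (below the target border, dorso-lateral to it, or outside).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

EXCLUSION_REASONS = ("below_border", "dorso_lateral", "outside")


def _read(name: str) -> pd.DataFrame:
    with resources.files("stn_gammaburst.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", na_values=["NA"])


def load_table1() -> pd.DataFrame:
    """Per-patient clinical table; NA marks unavailable archive data."""
    return _read("table1.tsv")


def load_localization() -> pd.DataFrame:
    """Per contact pair: in-STN flag and exclusion reason when excluded."""
    df = _read("localization.tsv")
    df["exclusion_reason"] = df["exclusion_reason"].fillna("")
    return df
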