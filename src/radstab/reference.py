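"""Packaged reference data: the 108-feature stable set.

The CSV ships with the package and holds, per feature, its category tag
(TA = original-image features, LOG = Laplacian-of-Gaussian, WF = wavelet)
and the overall median ICC across all stability experiments, ordered by
decreasing median ICC.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_stable_feature_table"]


def load_stable_feature_table() -> pd.DataFrame:
    """The reference stable-feature set (108 rows), indexed by feature id."""
    ref = resources.files("radstab.data").joinpath("top108_stable_features.csv")
    with ref.open("r") as fh:
        df = pd.read_csv(fh)
    return df.set_index("feature")
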