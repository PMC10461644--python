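"""Packaged reference datasets.

``load_rgc_profiles`` returns the per-cell intrinsic membrane-property table
for alpha retinal ganglion cells recorded in whole-cell current clamp from the
bovine (n = 10) and mouse (n = 9) ex vivo retina.  Columns follow the
nine-parameter profile: vm (mV), rn (MΩ), tau (ms), sag (mV), steady_freq
(Hz), max_freq (Hz), fa (dimensionless), amplitude (spike amplitude; the
source table labels this column in pA, but the quantity is the measured
voltage difference between spike peak and threshold), sw (ms).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_rgc_profiles"]


def load_rgc_profiles() -> pd.DataFrame:
    """Per-cell intrinsic profiles for bovine and mouse alpha RGCs."""
    ref = resources.files("retinaphys") / "data" / "rgc_intrinsic_profiles.tsv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")
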