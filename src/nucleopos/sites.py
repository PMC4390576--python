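"""Reference E. coli chromosome frame and reporter insertion sites.

The nine insertion sites of the H-NS-regulated fluorescent reporter:
three mirror pairs near the origin (LO/RO), mid-replichore (LM/RM) and
terminus region (LT/RT) plus three neighbourhood controls (LT1, LT2 at
~18 kb and ~135 kb from LT; RT1 at ~66 kb from RT).  Coordinates are
1-based on the E. coli K-12 chromosome; orientation is the strand of
the promoter-reporter unit.
"""
from __future__ import annotations

import pandas as pd

from .genome import GenomeLayout, relative_position

__all__ = ["ECOLI_K12_LAYOUT", "REPORTER_SITES", "reporter_sites_frame"]

# E. coli K-12 MG1655 chromosome: length, oriC and dif (terminus) midpoints.
ECOLI_K12_LAYOUT = GenomeLayout(length=4_641_652, oriC=3_925_860, ter=1_588_774, circular=True)

# (label, position, orientation)
REPORTER_SITES: tuple[tuple[str, int, int], ...] = (
    ("LO", 3_383_900, +1),
    ("RO", 4_437_900, -1),
    ("LM", 2_715_500, -1),
    ("RM", 500_700, +1),
    ("LT", 2_185_400, -1),
    ("RT", 1_027_600, +1),
    ("LT2", 2_050_100, +1),
    ("RT1", 1_093_500, +1),
    ("LT1", 2_167_700, +1),
)


def reporter_sites_frame(layout: GenomeLayout = ECOLI_K12_LAYOUT) -> pd.DataFrame:
    """Site table with the relative map position m' annotated."""
    df = pd.DataFrame(REPORTER_SITES, columns=["site_label", "position", "orientation"])
    df["m_prime"] = [relative_position(p, layout) for p in df["position"]]
    return df
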