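"""Published worked-example data.

A reference cross-tabulation of modal subgroup memberships from a
chiropractic low back pain cohort (n = 928): rows are the seven subgroups
of a single-stage solution over 112 mixed-type baseline variables, columns
the nine subgroups of a two-stage solution over six domain-derived
categorical variables on the same patients. It is the one fully printed
data object of that study and serves here as the fixture for the
cross-tabulation arithmetic (margins, grand total, flags, prevalences).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

SINGLE_STAGE_LABELS = [f"SS {k}" for k in range(1, 8)]
TWO_STAGE_LABELS = [f"TS {k}" for k in range(1, 10)]

# Joint counts of modal membership; row margins 192,154,136,132,130,109,75,
# column margins 219,161,127,113,71,69,74,45,49, grand total 928.
LBP_MEMBERSHIP_COUNTS = np.array([
    [26, 79, 27, 36, 0, 14, 3, 6, 1],    # SS 1
    [0, 69, 4, 2, 0, 31, 29, 19, 0],     # SS 2
    [113, 3, 13, 4, 2, 0, 0, 1, 0],      # SS 3
    [17, 3, 30, 28, 33, 1, 12, 8, 0],    # SS 4
    [4, 4, 44, 14, 12, 20, 29, 2, 1],    # SS 5
    [56, 0, 6, 5, 22, 0, 0, 0, 20],      # SS 6
    [3, 3, 3, 24, 2, 3, 1, 9, 27],       # SS 7
])


def lbp_membership_crosstab() -> pd.DataFrame:
    """The reference 7x9 membership count matrix as a labelled DataFrame."""
    return pd.DataFrame(LBP_MEMBERSHIP_COUNTS.copy(),
                        index=list(SINGLE_STAGE_LABELS),
                        columns=list(TWO_STAGE_LABELS))
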