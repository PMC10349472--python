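"""Small built-in reference tables.

These are literature-scale summary tables used as worked inputs for the
reporting functions; they are data, not fitted quantities.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["cryo_storage_batch_times"]

# Weekly batch times (mean +/- SD over 12 replicates: 3 biological x 4
# technical) of C. glutamicum cultures inoculated from cryo stocks stored
# at -80 degC vs -20 degC, tracked over six weeks of storage. SDs carry a
# 4-min error floor (the measurement cycle time).
_CRYO_ROWS = [
    # week, storage_c, mean_h, sd_h
    (0, -80, 12.73, 0.06), (0, -20, 12.80, 0.11),
    (1, -80, 12.51, 0.07), (1, -20, 13.51, 0.23),
    (2, -80, 12.86, 0.07), (2, -20, 13.64, 0.24),
    (3, -80, 12.77, 0.07), (3, -20, 13.93, 0.07),
    (4, -80, 12.94, 0.07), (4, -20, 13.97, 0.11),
    (5, -80, 12.99, 0.09), (5, -20, 14.23, 0.07),
    (6, -80, 12.78, 0.07), (6, -20, 13.95, 0.09),
]


def cryo_storage_batch_times() -> pd.DataFrame:
    """Six-week cryo-storage stability study: batch times per week/condition.

    Returns a long table with columns ``week, condition, mean_h, sd_h``
    where ``condition`` is the storage temperature in degC (-80 or -20)
    and every cell summarises 12 replicate cultivations.
    """
    df = pd.DataFrame(_CRYO_ROWS, columns=["week", "condition", "mean_h", "sd_h"])
    df["n_replicates"] = 12
    return df
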