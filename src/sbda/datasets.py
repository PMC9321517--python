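"""Bundled reference data.

``IMF_ENERGY_RATIOS`` is a published reference table of respiration-band
energy ratios E_rj/E_j for IMFs 4-7, measured on one-minute breathing
segments from fifteen overnight radar recordings (one row per subject).
The lower- and higher-order IMFs fell outside the respiration band and
were not tabulated.  The table exercises the IMF selection rule
(ratio >= delta_r, delta_r = 0.5) on real measured values without needing
the original recordings.
"""

from __future__ import annotations

import numpy as np

__all__ = ["IMF_ENERGY_RATIOS", "IMF_ENERGY_RATIO_COLUMNS"]

#: IMF orders covered by the columns of :data:`IMF_ENERGY_RATIOS`.
IMF_ENERGY_RATIO_COLUMNS: tuple[int, ...] = (4, 5, 6, 7)

#: Measured band-energy ratios, shape (15 subjects, 4 IMFs).
IMF_ENERGY_RATIOS: np.ndarray = np.array(
    [
        [0.0241, 0.6642, 0.5175, 0.4550],
        [0.1725, 0.7565, 0.6546, 0.4040],
        [0.0495, 0.6554, 0.5013, 0.6563],
        [0.2752, 0.6701, 0.5753, 0.0051],
        [0.1694, 0.7490, 0.5828, 0.2768],
        [0.3934, 0.8145, 0.6163, 0.6916],
        [0.5834, 0.6768, 0.5548, 0.2016],
        [0.0545, 0.7918, 0.5246, 0.3457],
        [0.2868, 0.6443, 0.6721, 0.1725],
        [0.5909, 0.7223, 0.5038, 0.0341],
        [0.0836, 0.7718, 0.6402, 0.0020],
        [0.0728, 0.6104, 0.5225, 0.1039],
        [0.2947, 0.6174, 0.6390, 0.2253],
        [0.1167, 0.6145, 0.5879, 0.1146],
        [0.2936, 0.6250, 0.5956, 0.4659],
    ]
)


def select_imfs_from_ratios(ratios: np.ndarray, delta_r: float = 0.5) -> tuple[int, ...]:
    """Apply the selection rule ratio >= delta_r to one row of the table,
    returning the selected IMF orders (numbered per
    :data:`IMF_ENERGY_RATIO_COLUMNS`)."""
    ratios = np.asarray(ratios, dtype=float)
    return tuple(
        order for order, r in zip(IMF_ENERGY_RATIO_COLUMNS, ratios) if r >= delta_r
    )
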