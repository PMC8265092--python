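"""Parameter grids of the simulation study and published reference values.

The study crosses six degrees of outcome clustering (cluster-level error
SDs chosen so that the expected sample ICC sits at the midpoint of a target
acceptance range) with a continuum of explanatory-variable clustering
(cluster shift SDs drawn uniformly), and, for a binary explanatory
variable, four target prevalences.
"""

from __future__ import annotations

import math
from typing import NamedTuple


class IccLevel(NamedTuple):
    """One degree of outcome clustering.

    sd_u        : SD of the cluster-level error u_j
    icc_range   : closed interval of admissible sample ICC (accept-reject)
    label       : the midpoint ICC the level is referred to by
    """

    sd_u: float
    icc_range: tuple[float, float]
    label: float


#: The six clustering levels: SD_u chosen so SD_u^2/(SD_u^2+1) sits at the
#: midpoint of the acceptance range.
ICC_LEVELS: tuple[IccLevel, ...] = (
    IccLevel(0.0316, (0.0005, 0.00149), 0.001),
    IccLevel(0.05485, (0.0025, 0.00349), 0.003),
    IccLevel(0.1005, (0.005, 0.0149), 0.01),
    IccLevel(0.1759, (0.025, 0.0349), 0.03),
    IccLevel(0.3333, (0.05, 0.149), 0.1),
    IccLevel(0.6547, (0.25, 0.349), 0.3),
)

#: Target prevalences examined for a binary explanatory variable.
TARGET_PREVALENCES: tuple[float, ...] = (0.05, 0.1, 0.2, 0.4)

#: Upper bound of the U[0, b] distribution the cluster-shift SD is drawn from.
SD_SHIFT_MAX: dict[str, float] = {"continuous": 20.0, "binary": 0.05}

#: Published coverage (%) of the true slope by 95% CIs, "Total" column,
#: indexed by midpoint ICC label.  Reference values for side-by-side
#: comparison output only; they feed no computation.
REFERENCE_COVERAGE_TOTAL_RI: dict[float, float] = {
    0.001: 95.08, 0.003: 95.33, 0.01: 94.80,
    0.03: 94.87, 0.1: 94.76, 0.3: 94.75,
}
REFERENCE_COVERAGE_TOTAL_OLS: dict[float, float] = {
    0.001: 94.08, 0.003: 92.30, 0.01: 84.75,
    0.03: 69.39, 0.1: 47.80, 0.3: 30.36,
}


def icc_from_components(sd_u: float, sd_e: float = 1.0) -> float:
    """ICC = SD_u^2 / (SD_u^2 + SD_e^2): the share of outcome variance
    (after the explanatory variable) lying between clusters."""
    if sd_u < 0 or sd_e <= 0:
        raise ValueError("require sd_u >= 0 and sd_e > 0")
    vu = sd_u * sd_u
    return vu / (vu + sd_e * sd_e)


def sd_u_for_icc(icc: float, sd_e: float = 1.0) -> float:
    """Invert the ICC mapping: the SD_u giving expected ICC `icc`."""
    if not 0 <= icc < 1:
        raise ValueError("icc must lie in [0, 1)")
    return sd_e * math.sqrt(icc / (1.0 - icc))


def level_for_label(label: float) -> IccLevel:
    """Look up one of the six study levels by its midpoint label."""
    for lev in ICC_LEVELS:
        if lev.label == label:
            return lev
    raise KeyError(f"no ICC level labelled {label!r}")
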