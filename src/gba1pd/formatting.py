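"""Number formatting conventions used in the study tables.

Percentages and odds ratios in the frequency tables are *truncated* (not
rounded) to one decimal: 1/6 prints as 16.6%, 2/3 as 66.6%, an odds ratio of
1.6957 as 1.6.  The demographics table instead rounds effect estimates to two
decimals.  Both conventions are exposed so callers can match either table.
"""

from __future__ import annotations

import math
from typing import Optional


def truncate(value: float, decimals: int = 1) -> float:
    """Truncate toward zero at the given number of decimals."""
    factor = 10.0**decimals
    return math.trunc(value * factor) / factor


def trunc_pct(fraction: Optional[float], decimals: int = 1) -> str:
    """Format a fraction as a truncated percentage string ("16.6%")."""
    if fraction is None:
        return "undefined"
    pct = truncate(fraction * 100.0, decimals)
    return f"{pct:.{decimals}f}%"


def trunc_or(value: float) -> str:
    """Odds ratio, frequency-table style: truncated to one decimal."""
    return f"{truncate(value, 1):.1f}"


def round_or(value: float) -> str:
    """Odds ratio, demographics-table style: rounded to two decimals."""
    return f"{value:.2f}"
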