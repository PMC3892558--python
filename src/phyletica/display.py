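"""Report-precision conventions.

All statistics are carried at full double precision internally; these helpers
apply the fixed display conventions used in every table the pipeline writes:

* per-trait spread values (f) are truncated to 3 decimals,
* mapped percentages are truncated to 2 decimals,
* group shares are rounded to the nearest integer percent.

Truncation (floor toward zero) rather than round-half conventions is used for
fractional displays so that, e.g., a trait present in 1 of 652 organisms
reports f = 0.001 and a 1871/1924 mapping rate reports 97.24%.
"""

from __future__ import annotations

import math

__all__ = ["truncate", "display_f", "display_percent", "round_half_up"]

# guards against float artefacts such as 0.1*3 = 0.30000000000000004
_EPS = 1e-9


def truncate(value: float, decimals: int) -> float:
    """Truncate ``value`` toward zero at ``decimals`` decimal places."""
    factor = 10.0**decimals
    scaled = value * factor
    if scaled >= 0:
        out = math.floor(scaled + _EPS)
    else:
        out = math.ceil(scaled - _EPS)
    return out / factor


def display_f(f: float) -> float:
    """Per-trait spread value at report precision (3 decimals, truncated)."""
    return truncate(f, 3)


def display_percent(value: float, decimals: int = 2) -> float:
    """Percentage at report precision (truncated)."""
    return truncate(value, decimals)


def round_half_up(value: float) -> int:
    """Round to the nearest integer, halves away from zero."""
    if value >= 0:
        return int(math.floor(value + 0.5 + _EPS))
    return int(math.ceil(value - 0.5 - _EPS))
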