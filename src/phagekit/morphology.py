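"""Virion morphometry arithmetic from electron-microscopy measurements."""

from __future__ import annotations

from .errors import InvalidInputError

__all__ = ["head_to_tail_percent"]


def head_to_tail_percent(head_diameter_nm: float, tail_length_nm: float) -> float:
    """Head diameter as a percentage of tail length.

    The classic siphovirus-style proportion check: e.g. a 54 nm head on a
    148 nm tail gives ~36%.  Returns the unrounded percentage.
    """
    if head_diameter_nm <= 0 or tail_length_nm <= 0:
        raise InvalidInputError("virion dimensions must be positive")
    return 100.0 * head_diameter_nm / tail_length_nm
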