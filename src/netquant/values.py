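"""Descriptor result container with special-value flags.

Descriptors applied to arbitrary networks can legitimately produce
special values — infinite (``Inf``) or undefined (``NA``/``NaN``) — and
these must stay visible rather than being coerced to ordinary numbers.
:class:`DescriptorValue` carries the numeric value together with a flag
so downstream tabulation can serialize and exclude them explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["DescriptorValue", "DescriptorWarning"]


class DescriptorWarning(UserWarning):
    """Warning category for descriptors returning special values."""


@dataclass(frozen=True)
class DescriptorValue:
    """A named scalar descriptor value.

    ``flag`` is derived from the value: ``"finite"``, ``"infinite"`` for
    ``+/-inf`` or ``"undefined"`` for NaN.  Undefined values are never
    silently turned into zeros.
    """

    name: str
    value: float

    @property
    def flag(self) -> str:
        if math.isnan(self.value):
            return "undefined"
        if math.isinf(self.value):
            return "infinite"
        return "finite"

    @property
    def is_finite(self) -> bool:
        return self.flag == "finite"

    def __float__(self) -> float:
        return float(self.value)
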