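"""EQ-5D-5L health states.

The EQ-5D-5L instrument describes self-perceived health on five dimensions
(mobility, self-care, usual activities, pain/discomfort, anxiety/depression),
each rated on five ordinal severity levels: 1 = no problems through
5 = extreme problems / unable to.  A health state is the 5-tuple of levels,
so the state space has exactly 5**5 = 3125 members.
"""

from __future__ import annotations

import itertools
from typing import Iterator, NamedTuple

#: Dimension short codes, in the instrument's canonical order.
DIMENSIONS = ("mobility", "self_care", "usual_activities",
              "pain_discomfort", "anxiety_depression")

#: Conventional two-letter codes used in survey file columns.
DIMENSION_CODES = ("mo", "sc", "ua", "pd", "ad")

N_STATES = 5 ** 5

LEVELS = (1, 2, 3, 4, 5)


class HealthState(NamedTuple):
    """One EQ-5D-5L response: a severity level (1-5) per dimension."""

    mobility: int
    self_care: int
    usual_activities: int
    pain_discomfort: int
    anxiety_depression: int

    def validate(self) -> "HealthState":
        for dim, level in zip(DIMENSIONS, self):
            if not isinstance(level, (int,)) or isinstance(level, bool) \
                    or not 1 <= level <= 5:
                raise InvalidStateError(
                    f"{dim} level must be an integer in 1..5, got {level!r}")
        return self

    def dichotomize(self) -> tuple[bool, bool, bool, bool, bool]:
        """Per-dimension "no problem" flags: True iff the level is 1.

        This is the dichotomisation used for dimension-specific
        no-problem prevalences and disability-free life expectancies.
        """
        return tuple(level == 1 for level in self)  # type: ignore[return-value]

    def __str__(self) -> str:  # e.g. "11213"
        return "".join(str(l) for l in self)


class InvalidStateError(ValueError):
    """A level outside 1..5 or a malformed state tuple."""


PERFECT_HEALTH = HealthState(1, 1, 1, 1, 1)
WORST_STATE = HealthState(5, 5, 5, 5, 5)


def enumerate_states() -> list[HealthState]:
    """All 3125 health states, in lexicographic order of the level tuple.

    The first element is (1,1,1,1,1) and the last is (5,5,5,5,5).
    """
    return [HealthState(*levels)
            for levels in itertools.product(LEVELS, repeat=5)]


def iter_states() -> Iterator[HealthState]:
    """Lazy variant of :func:`enumerate_states`, same order."""
    for levels in itertools.product(LEVELS, repeat=5):
        yield HealthState(*levels)


def dichotomize(state: HealthState) -> tuple[bool, ...]:
    """Functional alias for :meth:`HealthState.dichotomize`."""
    return HealthState(*state).validate().dichotomize()
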