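"""Ordered response scales used by the questionnaire instruments.

Every threshold rule in the symptom engine compares positions on one of
these total orderings, never raw strings, so "at least quite a bit" or
"more than 6 months" are well-defined and testable at the boundaries.
"""

from __future__ import annotations

from typing import Sequence


class OrderedScale:
    """A totally ordered categorical response scale.

    Levels are stored lowest-to-highest. Comparisons are by index, so
    ``scale.at_least(value, "quite_a_bit")`` means the response is at or
    above that level on the instrument's Likert ordering.
    """

    def __init__(self, name: str, levels: Sequence[str]):
        self.name = name
        self.levels = tuple(levels)
        self._index = {lvl: i for i, lvl in enumerate(self.levels)}
        if len(self._index) != len(self.levels):
            raise ValueError(f"duplicate levels in scale {name!r}")

    def index(self, value: str) -> int:
        try:
            return self._index[value]
        except KeyError:
            raise ValueError(
                f"{value!r} is not a level of scale {self.name!r}; "
                f"expected one of {self.levels}"
            ) from None

    def __contains__(self, value: object) -> bool:
        return value in self._index

    def at_least(self, value: str, threshold: str) -> bool:
        return self.index(value) >= self.index(threshold)

    def above(self, value: str, threshold: str) -> bool:
        return self.index(value) > self.index(threshold)

    def __repr__(self) -> str:  # pragma: no cover
        return f"OrderedScale({self.name!r}, {self.levels!r})"


#: How much the symptom hampered normal activities (WPI and ROME items).
#: "Troublesome" requires quite_a_bit or worse.
HAMPER = OrderedScale(
    "hamper",
    ["not_at_all", "a_little", "somewhat", "quite_a_bit", "a_lot", "very_much"],
)

#: ROME-III symptom frequency. "Troublesome" (frequency route) requires
#: often or more.
FREQUENCY_ROME = OrderedScale(
    "frequency_rome",
    ["never", "sometimes", "often", "most_of_the_time", "always"],
)

#: CDC symptom inventory frequency. "Troublesome" requires at least
#: a_few_times_a_week.
FREQUENCY_CDC = OrderedScale(
    "frequency_cdc",
    ["never", "rarely", "monthly", "a_few_times_a_week", "everyday"],
)

#: SCL-90 somatization severity. Persistence = moderately or worse at
#: both waves.
SEVERITY_SCL = OrderedScale(
    "severity_scl",
    ["not_at_all", "a_little", "moderately", "quite_a_bit", "extremely"],
)

#: Symptom duration, coarsened to the categories the rules distinguish.
#: The WPI rule is inclusive ("6 months or longer" -> >= six_months);
#: the ROME/CDC rules are strict ("longer than 6 months" -> > six_months,
#: i.e. over_six_months only). Keeping an exact six_months level makes
#: the two boundary conventions separately testable.
DURATION = OrderedScale(
    "duration",
    ["not_present", "under_three_months", "three_to_six_months",
     "six_months", "over_six_months"],
)

SCALES = {s.name: s for s in (HAMPER, FREQUENCY_ROME, FREQUENCY_CDC, SEVERITY_SCL, DURATION)}
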