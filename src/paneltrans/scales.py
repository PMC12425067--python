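"""Scoring of the three symptom scales and the nine-item childhood-adversity inventory.

All scales are scored from raw item responses collected at each interview
wave:

* **CESD-8** — eight binary depressive-symptom items; items 4 and 6 are
  positively worded and therefore reverse scored.  Totals run 0–8; a total at
  or above the configurable cutoff (default 4) flags depressive symptoms.
* **JSS-4** — four sleep-disturbance items on a 1–3 Likert scale
  (1 = "most of the time" … 3 = "rarely or never").  Items 1–3 ask about
  disturbed sleep and are reverse coded so that larger values mean more
  disturbance; item 4 asks about waking rested and is kept on its raw
  orientation.  Totals run 4–12, higher = worse sleep; a total at or above
  the cutoff (default 5) flags insomnia.
* **TICS-m** — cognitive screen summing the memory, attention and
  calculation domain scores (0–27, higher = better); a total at or below the
  cutoff (default 11) flags cognitive impairment.

The adversity inventory holds nine binary items grouped into three
non-exclusive types: trauma & violence (items 1–4), family dysfunction
(items 5–7) and social problems (items 8–9).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "ScaleScores",
    "ACEProfile",
    "score_cesd8",
    "score_jss4",
    "score_ticsm",
    "score_aces",
    "DEPRESSION_CUTOFF",
    "INSOMNIA_CUTOFF",
    "IMPAIRMENT_CUTOFF",
]

DEPRESSION_CUTOFF = 4  # CESD-8 total >= cutoff flags depressive symptoms
INSOMNIA_CUTOFF = 5  # JSS-4 total >= cutoff flags insomnia
IMPAIRMENT_CUTOFF = 11  # TICS-m total <= cutoff flags cognitive impairment

# positions (0-based) of the reverse-scored CESD-8 items (items 4 and 6)
_CESD_REVERSE = (3, 5)

# 0-based item ranges of the three adversity types
_TRAUMA_ITEMS = range(0, 4)
_FAMILY_ITEMS = range(4, 7)
_SOCIAL_ITEMS = range(7, 9)

ACE_ITEM_LABELS = (
    "major_fire_or_disaster",
    "fired_weapon_in_combat",
    "victim_of_physical_attack",
    "life_threatening_illness",
    "mother_neglect",
    "parental_substance_problems",
    "physical_abuse_by_parents",
    "repeated_school_year",
    "trouble_with_police",
)


@dataclass(frozen=True)
class ScaleScores:
    """Scored symptom scales for one participant-wave."""

    cesd8_total: int | None = None
    depression_flag: bool | None = None
    jss4_total: int | None = None
    insomnia_flag: bool | None = None
    ticsm_total: int | None = None
    cognitive_impairment_flag: bool | None = None


@dataclass(frozen=True)
class ACEProfile:
    """Nine-item childhood-adversity inventory with derived groupings."""

    items: tuple[bool, ...]
    total: int
    type_trauma_violence: bool
    type_family_dysfunction: bool
    type_social_problems: bool
    count_category: str  # one of "0", "1", "2", "3+"
    any_ace: bool


def score_cesd8(items, cutoff: int = DEPRESSION_CUTOFF) -> ScaleScores:
    """Score the 8-item depression scale.

    ``items`` are the eight raw binary responses in questionnaire order.
    Items 4 and 6 (positive affect) are reverse scored: a "yes" on those
    contributes 0 to the total.
    """
    items = list(items)
    if len(items) != 8:
        raise ValueError(f"CESD-8 expects 8 items, got {len(items)}")
    total = 0
    for idx, raw in enumerate(items):
        if raw not in (0, 1, False, True):
            raise ValueError(f"CESD-8 item {idx + 1} must be 0/1, got {raw!r}")
        x = int(raw)
        total += (1 - x) if idx in _CESD_REVERSE else x
    return ScaleScores(cesd8_total=total, depression_flag=total >= cutoff)


def score_jss4(items, cutoff: int = INSOMNIA_CUTOFF, reverse_items=(0, 1, 2)) -> ScaleScores:
    """Score the 4-item sleep scale so that higher totals mean worse sleep.

    Raw responses are 1 ("most of the time") to 3 ("rarely or never").  By
    default items 1–3 are reverse coded (4 - x) and item 4 is kept raw; the
    set of reverse-coded items is configurable because published wordings of
    the scale disagree on item orientation.
    """
    items = list(items)
    if len(items) != 4:
        raise ValueError(f"JSS-4 expects 4 items, got {len(items)}")
    total = 0
    for idx, raw in enumerate(items):
        if raw not in (1, 2, 3):
            raise ValueError(f"JSS-4 item {idx + 1} must be in 1..3, got {raw!r}")
        total += (4 - raw) if idx in reverse_items else raw
    return ScaleScores(jss4_total=total, insomnia_flag=total >= cutoff)


def score_ticsm(memory: int, attention: int, calculation: int,
                cutoff: int = IMPAIRMENT_CUTOFF) -> ScaleScores:
    """Score the modified cognitive-status interview (memory + attention + calculation)."""
    for name, val in (("memory", memory), ("attention", attention), ("calculation", calculation)):
        if val < 0:
            raise ValueError(f"TICS-m {name} domain must be non-negative, got {val}")
    total = int(memory) + int(attention) + int(calculation)
    if total > 27:
        raise ValueError(f"TICS-m total must be <= 27, got {total}")
    return ScaleScores(ticsm_total=total, cognitive_impairment_flag=total <= cutoff)


def score_aces(items) -> ACEProfile:
    """Build the adversity profile from the nine binary inventory items.

    The three type flags are non-exclusive: carrying items from more than
    one group sets more than one flag.
    """
    items = tuple(bool(x) for x in items)
    if len(items) != 9:
        raise ValueError(f"adversity inventory expects 9 items, got {len(items)}")
    total = sum(items)
    if total == 0:
        category = "0"
    elif total == 1:
        category = "1"
    elif total == 2:
        category = "2"
    else:
        category = "3+"
    return ACEProfile(
        items=items,
        total=total,
        type_trauma_violence=any(items[i] for i in _TRAUMA_ITEMS),
        type_family_dysfunction=any(items[i] for i in _FAMILY_ITEMS),
        type_social_problems=any(items[i] for i in _SOCIAL_ITEMS),
        count_category=category,
        any_ace=total > 0,
    )
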