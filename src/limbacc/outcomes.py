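"""Lower-limb impairment outcomes: strength, sensation, spasticity.

Strength is the lower extremity motor score (LEMS): the sum of manual muscle
test scores over the L2-S1 myotomes of both legs, ten scores of 0-5 giving a
total of 0 (total paralysis) to 50 (normal). Sensation is the summed
light-touch score over the ten lower-limb dermatomes, each 0-2, giving 0-20.
Spasticity is assessed with the Modified Ashworth Scale (MAS) at four sites
(knee flexors and ankle plantarflexors bilaterally) and collapsed to three
categories: *none* (all sites 0), *mild* (some tone but every site below 2),
*moderate* (any site 2 or higher).
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ValidationError

#: MAS symbols in clinical order; "1+" sits strictly between 1 and 2.
MAS_LEVELS = ("0", "1", "1+", "2", "3", "4")
_MAS_RANK = {"0": 0.0, "1": 1.0, "1+": 1.5, "2": 2.0, "3": 3.0, "4": 4.0}

SPASTICITY_CATEGORIES = ("none", "mild", "moderate")


def lems(motor_scores) -> int:
    """Sum ten myotome motor scores (each 0-5) into the LEMS (0-50)."""
    scores = list(motor_scores)
    if len(scores) != 10:
        raise ValidationError(f"LEMS requires exactly 10 motor scores, got {len(scores)}")
    for s in scores:
        if s != int(s) or not 0 <= int(s) <= 5:
            raise ValidationError(f"motor score {s!r} outside 0-5")
    return int(sum(int(s) for s in scores))


def light_touch_score(lt_scores) -> int:
    """Sum ten dermatome light-touch scores (each 0-2) into the total (0-20)."""
    scores = list(lt_scores)
    if len(scores) != 10:
        raise ValidationError(
            f"light-touch score requires exactly 10 values, got {len(scores)}"
        )
    for s in scores:
        if s != int(s) or not 0 <= int(s) <= 2:
            raise ValidationError(f"light-touch score {s!r} outside 0-2")
    return int(sum(int(s) for s in scores))


def mas_rank(symbol) -> float:
    """Ordinal rank of a MAS symbol; '1+' maps to 1.5 so that '1+' < 2."""
    key = str(symbol)
    if key not in _MAS_RANK:
        raise ValidationError(f"invalid MAS score {symbol!r}; expected one of {MAS_LEVELS}")
    return _MAS_RANK[key]


def categorize_mas(mas_scores) -> str:
    """Collapse four site-level MAS scores into none/mild/moderate.

    none: all four sites score 0. moderate: any site scores >= 2.
    mild: anything in between (some tone, every site < 2; '1+' counts as < 2).
    """
    scores = list(mas_scores)
    if len(scores) != 4:
        raise ValidationError(f"expected exactly 4 MAS site scores, got {len(scores)}")
    ranks = [mas_rank(s) for s in scores]
    if all(r == 0 for r in ranks):
        return "none"
    if any(r >= 2 for r in ranks):
        return "moderate"
    return "mild"


@dataclass
class ImpairmentOutcomes:
    """The three modeled outcomes for one participant."""

    participant_id: str
    lems: int
    light_touch: int
    mas_scores: tuple  # four MAS symbols: knee L/R, ankle L/R

    def __post_init__(self):
        if not 0 <= self.lems <= 50:
            raise ValidationError("lems outside 0-50")
        if not 0 <= self.light_touch <= 20:
            raise ValidationError("light_touch outside 0-20")
        self.mas_scores = tuple(str(s) for s in self.mas_scores)
        self.mas_category = categorize_mas(self.mas_scores)
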