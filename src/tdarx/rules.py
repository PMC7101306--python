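"""Semi-quantitative colour-coding rules for clinical fields.

Every clinical field and joint channel maps to an ordered colour category
(green < yellow < orange < red, in increasing clinical severity), e.g.
rheumatoid factor: green below 15 IU/mL, yellow from 15 to just under 30,
red at 30 and above.  Orange is reachable only from the two ultrasound
scores.  Boundary convention: a value equal to a cutoff takes the severer
colour; the MMP-3 rule is the one exception (yellow up to and including
120 ng/mL, red strictly above), reflecting how its cutoffs are printed.

The rules are total over each field's valid domain and monotone for numeric
fields, which the decoder and the augmentation guard both rely on.
"""

from __future__ import annotations

import math
import numbers
from dataclasses import dataclass, field as dc_field
from enum import Enum
from typing import Mapping

from .records import (CLINICAL_FIELDS, JOINT_CHANNELS, parse_joint_field_id)

INF = math.inf


class Category(str, Enum):
    GREEN = "green"
    YELLOW = "yellow"
    ORANGE = "orange"
    RED = "red"
    BACKGROUND = "background"
    MISSING = "missing"


#: Global severity scale for the four coding colours.
SEVERITY = {Category.GREEN: 0, Category.YELLOW: 1,
            Category.ORANGE: 2, Category.RED: 3}


@dataclass(frozen=True)
class Band:
    """One contiguous interval of a numeric rule."""

    category: Category
    lo: float
    hi: float
    lo_incl: bool = True
    hi_incl: bool = False

    def contains(self, v: float) -> bool:
        above = v > self.lo or (self.lo_incl and v == self.lo)
        below = v < self.hi or (self.hi_incl and v == self.hi)
        return above and below


@dataclass(frozen=True)
class NumericRule:
    """Ordered, contiguous, gap-free bands over a numeric domain."""

    bands: tuple[Band, ...]
    domain: tuple[float, float] = (0.0, INF)

    def __post_init__(self):
        for a, b in zip(self.bands, self.bands[1:]):
            if a.hi != b.lo or a.hi_incl == b.lo_incl:
                raise ValueError("bands must be contiguous and non-overlapping")

    def categorize(self, v) -> Category:
        if not isinstance(v, numbers.Real) or isinstance(v, bool):
            raise ValueError(f"expected a number, got {v!r}")
        v = float(v)
        lo, hi = self.domain
        if not (lo <= v <= hi):
            raise ValueError(f"value {v} outside domain [{lo}, {hi}]")
        for band in self.bands:
            if band.contains(v):
                return band.category
        raise ValueError(f"no band contains {v}")  # unreachable for total rules

    def band_for(self, category: Category) -> Band:
        for band in self.bands:
            if band.category is category:
                return band
        raise KeyError(category)

    @property
    def ordered_categories(self) -> tuple[Category, ...]:
        return tuple(b.category for b in self.bands)


@dataclass(frozen=True)
class CategoricalRule:
    """Finite value -> category mapping (flags, gender, 0-3 scores)."""

    mapping: Mapping
    ordered_categories: tuple[Category, ...] = ()

    def categorize(self, v) -> Category:
        if isinstance(v, numbers.Real) and not isinstance(v, (bool,)):
            v = int(v) if float(v) == int(v) else v
        elif hasattr(v, "item"):  # numpy bools
            v = bool(v.item()) if v in (True, False) else v
        try:
            return self.mapping[v]
        except (KeyError, TypeError):
            raise ValueError(f"value {v!r} not in rule domain {list(self.mapping)}")


def _bands(*spec) -> tuple[Band, ...]:
    """spec: alternating category, cutoff, category, cutoff, ..., category."""
    cats = spec[0::2]
    cuts = spec[1::2]
    out = []
    lo = 0.0
    for cat, cut in zip(cats, cuts):
        out.append(Band(cat, lo, cut, lo_incl=True, hi_incl=False))
        lo = cut
    out.append(Band(cats[-1], lo, INF, lo_incl=True, hi_incl=True))
    return tuple(out)


G, Y, O, R = Category.GREEN, Category.YELLOW, Category.ORANGE, Category.RED


def _flag_rule(positive: Category) -> CategoricalRule:
    return CategoricalRule({False: G, True: positive}, (G, positive))


_SCORE_RULE = CategoricalRule({0: G, 1: Y, 2: O, 3: R}, (G, Y, O, R))


@dataclass(frozen=True)
class RuleSet:
    """The full field -> colour-category rule table (clinical + joint channels)."""

    clinical: Mapping[str, object]
    channels: Mapping[str, object]
    version: str = "table2-v1"

    def rule_for(self, field_id: str):
        if field_id in self.clinical:
            return self.clinical[field_id]
        _, _, channel = parse_joint_field_id(field_id)
        return self.channels[channel]

    def categorize(self, field_id: str, value) -> Category:
        if value is None:
            return Category.MISSING
        try:
            return self.rule_for(field_id).categorize(value)
        except ValueError as exc:
            raise ValueError(f"{field_id}: {exc}") from None

    def ordered_categories(self, field_id: str) -> tuple[Category, ...]:
        return self.rule_for(field_id).ordered_categories

    def drift(self, field_id: str, a: Category, b: Category) -> int:
        """Rank distance between two categories on this field's own scale."""
        order = self.ordered_categories(field_id)
        return abs(order.index(a) - order.index(b))


def default_rules() -> RuleSet:
    """The shipped rule table (all printed cutoffs)."""
    clinical = {
        "rf": NumericRule(_bands(G, 15.0, Y, 30.0, R)),
        "acpa": NumericRule(_bands(G, 4.5, R)),
        "esr": NumericRule(_bands(G, 10.0, Y, 20.0, R)),
        "onset_days": NumericRule(_bands(Y, 42.0, R)),
        "crp": NumericRule(_bands(Y, 0.3, R)),
        "ana": NumericRule(_bands(G, 40.0, Y, 160.0, R)),
        # printed as "yellow < 120, 121 <= red": the gap is closed by keeping
        # 120 itself yellow and everything above it red
        "mmp3": NumericRule((Band(Y, 0.0, 120.0, True, True),
                             Band(R, 120.0, INF, False, True))),
        "wbc": NumericRule(_bands(G, 4000.0, Y, 8000.0, R)),
        "gender": CategoricalRule({"male": Y, "female": R}, (Y, R)),
        "skin_abnormality": _flag_rule(Y),
        "body_temperature": NumericRule(_bands(G, 37.5, Y, 38.0, R)),
        "trunk_pain": _flag_rule(Y),
        "patient_vas": NumericRule(_bands(G, 10.0, Y, 50.0, R),
                                   domain=(0.0, 100.0)),
        "doctor_vas": NumericRule(_bands(G, 10.0, Y, 50.0, R),
                                  domain=(0.0, 100.0)),
    }
    channels = {
        "a": _flag_rule(R),
        "b": _flag_rule(R),
        "c": _flag_rule(R),
        "d": _SCORE_RULE,
        "e": _SCORE_RULE,
    }
    return RuleSet(clinical=clinical, channels=channels)


def discretize_field(field_id: str, value, rules: RuleSet | None = None) -> Category:
    """Colour category of ``value`` for ``field_id`` (raises on unknown field
    or out-of-domain value)."""
    rules = rules or default_rules()
    rules.rule_for(field_id)  # raises KeyError for unknown fields
    return rules.categorize(field_id, value)


def discretize_record(record, rules: RuleSet | None = None) -> dict[str, Category]:
    """Categories of all 164 fields (14 clinical + 150 joint channels)."""
    from .records import all_field_ids, get_field

    rules = rules or default_rules()
    return {fid: rules.categorize(fid, get_field(record, fid))
            for fid in all_field_ids()}


# ---------------------------------------------------------------------------
# Palette
# ---------------------------------------------------------------------------

RGB = tuple[int, int, int]


@dataclass(frozen=True)
class Palette:
    """Category -> 8-bit RGB mapping used by the renderer and decoder.

    Any two categories must be at least 100 apart in Euclidean RGB distance
    so that decoding by nearest colour is unambiguous even after mild
    raster degradation.
    """

    colors: Mapping[Category, RGB] = dc_field(default_factory=lambda: {
        Category.GREEN: (0, 176, 80),
        Category.YELLOW: (255, 255, 0),
        Category.ORANGE: (255, 140, 0),
        Category.RED: (255, 0, 0),
        Category.BACKGROUND: (255, 255, 255),
        Category.MISSING: (128, 128, 128),
    })

    def __post_init__(self):
        d = self.min_distance()
        if d < 100:
            raise ValueError(f"palette colours too close (min distance {d:.1f})")

    def __getitem__(self, category: Category) -> RGB:
        return self.colors[category]

    def min_distance(self) -> float:
        cats = list(self.colors)
        dmin = INF
        for i, a in enumerate(cats):
            for b in cats[i + 1:]:
                d = math.dist(self.colors[a], self.colors[b])
                dmin = min(dmin, d)
        return dmin


def default_palette() -> Palette:
    return Palette()
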