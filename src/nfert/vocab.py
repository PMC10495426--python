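"""Controlled vocabularies for the fertilization dataset.

The reconstruction works on a fixed set of 21 crop groups, 13 fertilizer
types (11 synthetic plus crop residues and manure), two application
placements, and an 11-group aggregation used by the crop-wise fertilizer
consumption surveys (FUBC).  Everything downstream indexes into these
ordered tuples, so they live in one place.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: The 21 crop groups of the published product, in record order.
CROPS: tuple[str, ...] = (
    "Barley", "Cassava", "Cotton", "Fruits", "Groundnut", "Maize", "Millet",
    "Oilpalm", "Potato", "Rapeseed", "Rye", "Rice", "Sorghum", "Soybean",
    "Sugarbeet", "Sugarcane", "Sunflower", "Sweetpotato", "Vegetables",
    "Wheat", "Other crops",
)

#: The 11 aggregate crop groups used by the FUBC consumption surveys.
FUBC_GROUPS: tuple[str, ...] = (
    "Rice", "Maize", "Wheat", "Other cereals", "Sugar crops", "Oil palm",
    "Other oil crops", "Cotton", "Soybean", "Vegetables and fruits",
    "Other crops",
)

#: Many-to-one map from the 21 crop groups onto the 11 FUBC groups.
CROP_TO_FUBC: dict[str, str] = {
    "Rice": "Rice",
    "Maize": "Maize",
    "Wheat": "Wheat",
    "Barley": "Other cereals",
    "Sorghum": "Other cereals",
    "Millet": "Other cereals",
    "Rye": "Other cereals",
    "Sugarbeet": "Sugar crops",
    "Sugarcane": "Sugar crops",
    "Oilpalm": "Oil palm",
    "Sunflower": "Other oil crops",
    "Rapeseed": "Other oil crops",
    "Groundnut": "Other oil crops",
    "Cotton": "Cotton",
    "Soybean": "Soybean",
    "Vegetables": "Vegetables and fruits",
    "Fruits": "Vegetables and fruits",
    "Potato": "Other crops",
    "Sweetpotato": "Other crops",
    "Cassava": "Other crops",
    "Other crops": "Other crops",
}

#: 13 fertilizer types: 11 synthetic (SN) types, then crop residues and manure.
FERTILIZER_TYPES: tuple[str, ...] = (
    "AA", "AN", "AS", "CAN", "NS", "ONS", "Urea", "AP", "NK", "NPK", "ONP",
    "CR", "MA",
)
SN_TYPES: tuple[str, ...] = FERTILIZER_TYPES[:11]

PLACEMENTS: tuple[str, str] = ("Surface", "Deep")

#: Nitrogen input classes carried through the amount/rate reconstruction.
CLASSES: tuple[str, str, str] = ("SN", "MA", "CR")

#: The 11 rain-fed annual crops considered suitable for no-till adoption.
NOTILL_CROPS: tuple[str, ...] = (
    "Soybean", "Wheat", "Maize", "Barley", "Rapeseed", "Sunflower",
    "Sorghum", "Cotton", "Millet", "Groundnut", "Vegetables",
)


@dataclass(frozen=True)
class Vocabulary:
    """Bundle of the controlled vocabularies, validated on construction."""

    crop_groups: tuple[str, ...] = CROPS
    fubc_crop_groups: tuple[str, ...] = FUBC_GROUPS
    crop_to_fubc: dict[str, str] = field(default_factory=lambda: dict(CROP_TO_FUBC))
    fertilizer_types: tuple[str, ...] = FERTILIZER_TYPES
    placements: tuple[str, ...] = PLACEMENTS
    classes: tuple[str, ...] = CLASSES
    notill_crops: tuple[str, ...] = NOTILL_CROPS

    def __post_init__(self) -> None:
        self.validate()

    @property
    def sn_types(self) -> tuple[str, ...]:
        """The synthetic fertilizer types (all types except CR and MA)."""
        return tuple(f for f in self.fertilizer_types if f not in ("CR", "MA"))

    def fubc_group_of(self, crop: str) -> str:
        return self.crop_to_fubc[crop]

    def crops_in_fubc_group(self, group: str) -> tuple[str, ...]:
        return tuple(c for c in self.crop_groups if self.crop_to_fubc[c] == group)

    def validate(self) -> None:
        if len(self.crop_groups) != 21:
            raise ValueError(f"expected 21 crop groups, got {len(self.crop_groups)}")
        if len(self.fertilizer_types) != 13:
            raise ValueError("expected 13 fertilizer types")
        if len(self.placements) != 2:
            raise ValueError("expected 2 placements")
        missing = set(self.crop_groups) - set(self.crop_to_fubc)
        if missing:
            raise ValueError(f"crops without a FUBC group: {sorted(missing)}")
        bad = set(self.crop_to_fubc.values()) - set(self.fubc_crop_groups)
        if bad:
            raise ValueError(f"unknown FUBC groups in map: {sorted(bad)}")
        if set(self.sn_types) & {"CR", "MA"}:
            raise ValueError("sn_types must exclude CR and MA")
        unknown = set(self.notill_crops) - set(self.crop_groups)
        if unknown:
            raise ValueError(f"no-till crops outside vocabulary: {sorted(unknown)}")


DEFAULT_VOCAB = Vocabulary()
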