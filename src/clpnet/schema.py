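"""Item schemas for ordinal symptom questionnaires.

The default instrument is the 12-item General Health Questionnaire
(GHQ-12; each item scored 0-3, higher = poorer mental health after
recoding) plus a single loneliness item scored 1-3.
"""

from __future__ import annotations

from dataclasses import dataclass, replace


@dataclass(frozen=True)
class ItemSchema:
    """Scale definition for one ordinal questionnaire item.

    Parameters
    ----------
    item_id
        Short machine-readable label, unique within a schema.
    scale_min, scale_max
        Inclusive bounds of the Likert scale.
    reverse_coded
        If True, :func:`clpnet.panel.recode_items` reflects the item as
        ``scale_min + scale_max - x`` so that higher values indicate
        poorer symptom expression.
    label
        Optional human-readable item text.
    """

    item_id: str
    scale_min: int
    scale_max: int
    reverse_coded: bool = False
    label: str = ""

    def __post_init__(self) -> None:
        if self.scale_min >= self.scale_max:
            raise ValueError(
                f"item {self.item_id!r}: scale_min ({self.scale_min}) must be "
                f"< scale_max ({self.scale_max})"
            )

    @property
    def n_categories(self) -> int:
        return self.scale_max - self.scale_min + 1


# (item_id, label, positively worded). Positively worded GHQ items are the
# ones that need reverse-coding when responses arrive on the raw scale.
_GHQ_ITEMS = [
    ("ghq_concentrate", "Able to concentrate", True),
    ("ghq_sleep", "Lost much sleep", False),
    ("ghq_useful", "Playing a useful part", True),
    ("ghq_decisions", "Capable of making decisions", True),
    ("ghq_stress", "Under stress", False),
    ("ghq_overcome", "Could not overcome difficulties", False),
    ("ghq_enjoy", "Enjoy normal activities", True),
    ("ghq_face_problems", "Can face up to problems", True),
    ("ghq_depressed", "Feeling unhappy and depressed", False),
    ("ghq_confidence", "Losing confidence", False),
    ("ghq_worthless", "Thinking of self as worthless", False),
    ("ghq_happy", "Feeling reasonably happy", True),
]

GHQ_ITEM_IDS = [item_id for item_id, _, _ in _GHQ_ITEMS]
LONELINESS_ITEM_ID = "loneliness"


def default_schema(recoded: bool = True) -> list[ItemSchema]:
    """The 13-item default schema: 12 GHQ items (0-3) plus loneliness (1-3).

    Parameters
    ----------
    recoded
        If True (default) the data are assumed to already be on the
        "higher = worse" scale and no item is flagged for reverse coding.
        If False, the six positively worded GHQ items are flagged.
    """
    items = [
        ItemSchema(item_id, 0, 3, reverse_coded=(positive and not recoded), label=label)
        for item_id, label, positive in _GHQ_ITEMS
    ]
    items.append(
        ItemSchema(LONELINESS_ITEM_ID, 1, 3, reverse_coded=False, label="Feeling lonely")
    )
    return items


def with_reverse_flags(schema: list[ItemSchema], flagged: set[str]) -> list[ItemSchema]:
    """Return a copy of *schema* with ``reverse_coded`` set for *flagged* ids."""
    return [replace(s, reverse_coded=s.item_id in flagged) for s in schema]
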