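"""Fee-item schemas for DRG claims.

A fee-item schema enumerates the billable item codes a hospital reports
per discharge case, together with a display label and an audit category.
The default schema has 17 items spanning drug, material and examination
fees (the three categories insurers audit separately) plus common
per-case fees such as accommodation and psychiatric care.
"""

from __future__ import annotations

from dataclasses import dataclass, field

CATEGORIES = ("drug", "material", "examination", "other")


@dataclass(frozen=True)
class FeeItem:
    """One billable fee item: a short code, a label, and an audit category."""

    item_id: str
    label: str
    category: str

    def __post_init__(self) -> None:
        if not self.item_id:
            raise ValueError("item_id must be non-empty")
        if self.category not in CATEGORIES:
            raise ValueError(
                f"category {self.category!r} not one of {CATEGORIES}"
            )


@dataclass(frozen=True)
class FeeItemSchema:
    """An ordered, duplicate-free collection of fee items."""

    items: tuple[FeeItem, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.items:
            raise ValueError("schema must contain at least one fee item")
        ids = [it.item_id for it in self.items]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValueError(f"duplicate item ids in schema: {sorted(dupes)}")

    @property
    def item_ids(self) -> tuple[str, ...]:
        return tuple(it.item_id for it in self.items)

    def __len__(self) -> int:
        return len(self.items)

    def __contains__(self, item_id: str) -> bool:
        return item_id in self.item_ids

    def __getitem__(self, item_id: str) -> FeeItem:
        for it in self.items:
            if it.item_id == item_id:
                return it
        raise KeyError(item_id)

    def category_map(self) -> dict[str, str]:
        """Map item_id -> category for every item in the schema."""
        return {it.item_id: it.category for it in self.items}

    def items_in_category(self, category: str) -> tuple[str, ...]:
        return tuple(
            it.item_id for it in self.items if it.category == category
        )

    def to_dict(self) -> list[dict[str, str]]:
        return [
            {"item_id": it.item_id, "label": it.label, "category": it.category}
            for it in self.items
        ]

    @classmethod
    def from_dict(cls, entries: list[dict[str, str]]) -> "FeeItemSchema":
        return cls(
            tuple(
                FeeItem(e["item_id"], e["label"], e["category"])
                for e in entries
            )
        )


def default_schema() -> FeeItemSchema:
    """The default 17-item fee schema.

    Item identities are generic: insurers publish fee categories, not a
    canonical 17-item list, so the schema names typical inpatient fee
    items under the audited drug / material / examination categories and
    an "other" bucket for per-case hotel and professional fees.
    """
    return FeeItemSchema(
        (
            FeeItem("DRUG01", "oral medication", "drug"),
            FeeItem("DRUG02", "injectable medication", "drug"),
            FeeItem("DRUG03", "chemotherapy agents", "drug"),
            FeeItem("DRUG04", "pharmacy service", "drug"),
            FeeItem("MAT01", "surgical materials", "material"),
            FeeItem("MAT02", "blood plasma", "material"),
            FeeItem("MAT03", "implants", "material"),
            FeeItem("MAT04", "dressings and consumables", "material"),
            FeeItem("EXAM01", "laboratory tests", "examination"),
            FeeItem("EXAM02", "radiology and imaging", "examination"),
            FeeItem("EXAM03", "pathology", "examination"),
            FeeItem("EXAM04", "functional examination", "examination"),
            FeeItem("OTH01", "physician fee", "other"),
            FeeItem("OTH02", "accommodation (room) fee", "other"),
            FeeItem("OTH03", "nursing fee", "other"),
            FeeItem("OTH04", "treatment and procedures", "other"),
            FeeItem("OTH05", "psychiatry fee", "other"),
        )
    )
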