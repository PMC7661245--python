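"""Flat item table: data model, validation, CSV read/write.

An item bank is a calibrated collection of polytomous questionnaire items.
Each item carries its wording, the ordered response-option labels shown to
the respondent, and its graded-response-model parameters: one discrimination
``a > 0`` and ``K - 1`` strictly increasing thresholds ``b_1 < ... < b_{K-1}``
for ``K`` response categories.

The on-disk format is a UTF-8 CSV with a mandatory header row and columns

    id, question, a, b1, ..., bM [, response1, ..., responseK]

Rows may leave trailing ``b`` columns blank, so a single file can mix items
with different numbers of categories (e.g. 4- and 5-option items, as real
PROM banks do). When the ``response*`` columns are absent, option labels
default to ``"0" .. "K-1"``. Categories are always coded ``0 .. K-1``
internally regardless of label text.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Item",
    "ItemBank",
    "BankFormatError",
    "BankValidationError",
    "read_flat_table",
    "write_flat_table",
]


class BankFormatError(ValueError):
    """The file does not conform to the flat item table dialect."""


class BankValidationError(ValueError):
    """An item's parameters violate the graded response model constraints."""


@dataclass(frozen=True)
class Item:
    """One polytomous GRM-calibrated item.

    Parameters
    ----------
    item_id
        Unique identifier within its bank.
    wording
        Question text shown to the respondent.
    option_labels
        Ordered labels of the K response categories (K >= 2).
    discrimination
        GRM slope ``a``; must be positive.
    thresholds
        GRM location parameters ``b_1 < ... < b_{K-1}``.
    """

    item_id: str
    wording: str
    option_labels: tuple[str, ...]
    discrimination: float
    thresholds: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.item_id:
            raise BankValidationError("item_id must be a non-empty string")
        if len(self.option_labels) < 2:
            raise BankValidationError(
                f"item {self.item_id!r}: needs at least 2 response options"
            )
        if len(self.option_labels) != len(self.thresholds) + 1:
            raise BankValidationError(
                f"item {self.item_id!r}: {len(self.option_labels)} option labels "
                f"require {len(self.option_labels) - 1} thresholds, "
                f"got {len(self.thresholds)}"
            )
        if not np.isfinite(self.discrimination) or self.discrimination <= 0:
            raise BankValidationError(
                f"item {self.item_id!r}: discrimination must be positive, "
                f"got {self.discrimination}"
            )
        b = np.asarray(self.thresholds, dtype=float)
        if not np.all(np.isfinite(b)):
            raise BankValidationError(
                f"item {self.item_id!r}: thresholds must be finite"
            )
        if np.any(np.diff(b) <= 0):
            raise BankValidationError(
                f"item {self.item_id!r}: thresholds must be strictly increasing, "
                f"got {tuple(self.thresholds)}"
            )

    @property
    def n_categories(self) -> int:
        return len(self.option_labels)


@dataclass(frozen=True)
class ItemBank:
    """Ordered, validated collection of :class:`Item` with id lookup."""

    items: tuple[Item, ...]
    name: str = "bank"
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.items) == 0:
            raise BankValidationError("item bank must contain at least one item")
        index: dict[str, int] = {}
        for pos, item in enumerate(self.items):
            if item.item_id in index:
                raise BankValidationError(f"duplicate item_id {item.item_id!r}")
            index[item.item_id] = pos
        object.__setattr__(self, "_index", index)

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)

    def __contains__(self, item_id: str) -> bool:
        return item_id in self._index

    def __getitem__(self, item_id: str) -> Item:
        try:
            return self.items[self._index[item_id]]
        except KeyError:
            raise KeyError(f"unknown item_id {item_id!r}") from None

    def position(self, item_id: str) -> int:
        """Zero-based position of an item in bank (file) order."""
        return self._index[item_id]

    @property
    def item_ids(self) -> tuple[str, ...]:
        return tuple(item.item_id for item in self.items)


_REQUIRED_COLUMNS = ("id", "question", "a", "b1")


def read_flat_table(path, *, name: str | None = None) -> ItemBank:
    """Read a flat item table CSV into a validated :class:`ItemBank`.

    Raises
    ------
    BankFormatError
        If the file is empty, lacks a required column, or a parameter cell
        cannot be parsed as a number.
    BankValidationError
        If a row encodes invalid GRM parameters (named by item id).
    """
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise BankFormatError(f"empty item table: {path}") from None
    for col in _REQUIRED_COLUMNS:
        if col not in df.columns:
            raise BankFormatError(f"missing required column {col!r} in {path}")
    if len(df) == 0:
        raise BankFormatError(f"item table has a header but no item rows: {path}")

    b_cols = _numbered(df.columns, "b")
    r_cols = _numbered(df.columns, "response")

    items = []
    for _, row in df.iterrows():
        item_id = row["id"].strip()
        thresholds = []
        for col in b_cols:
            cell = row[col].strip()
            if cell == "":
                break  # trailing blanks: this item has fewer categories
            thresholds.append(_parse_number(cell, col, item_id))
        k = len(thresholds) + 1
        labels = []
        for col in r_cols[:k]:
            cell = row[col].strip()
            if cell == "":
                break
            labels.append(cell)
        if len(labels) != k:
            labels = [str(c) for c in range(k)]
        items.append(
            Item(
                item_id=item_id,
                wording=row["question"],
                option_labels=tuple(labels),
                discrimination=_parse_number(row["a"].strip(), "a", item_id),
                thresholds=tuple(thresholds),
            )
        )
    return ItemBank(items=tuple(items), name=name or str(path))


def write_flat_table(bank: ItemBank, path) -> None:
    """Write a bank to CSV so that :func:`read_flat_table` reproduces it exactly.

    Numeric parameters are written with ``repr`` round-trip precision.
    """
    max_b = max(len(item.thresholds) for item in bank)
    max_k = max(item.n_categories for item in bank)
    columns = (
        ["id", "question", "a"]
        + [f"b{j}" for j in range(1, max_b + 1)]
        + [f"response{j}" for j in range(1, max_k + 1)]
    )
    rows = []
    for item in bank:
        row = {
            "id": item.item_id,
            "question": item.wording,
            "a": repr(float(item.discrimination)),
        }
        for j, b in enumerate(item.thresholds, start=1):
            row[f"b{j}"] = repr(float(b))
        for j, label in enumerate(item.option_labels, start=1):
            row[f"response{j}"] = label
        rows.append(row)
    pd.DataFrame(rows, columns=columns).fillna("").to_csv(path, index=False)


def _numbered(columns, prefix: str) -> list[str]:
    """Columns named ``prefix1, prefix2, ...`` in numeric order."""
    found = {}
    for col in columns:
        if col.startswith(prefix) and col[len(prefix):].isdigit():
            found[int(col[len(prefix):])] = col
    return [found[j] for j in sorted(found)]


def _parse_number(cell: str, col: str, item_id: str) -> float:
    try:
        return float(cell)
    except ValueError:
        raise BankFormatError(
            f"item {item_id!r}: column {col!r} value {cell!r} is not a number"
        ) from None
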