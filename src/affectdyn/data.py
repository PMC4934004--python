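"""Core data containers and the long-format CSV schema.

The on-disk interchange format is a long CSV with one row per answered prompt
item::

    person_id, group, day, prompt_index, item, intensity, pleasantness, distress

``item`` is either ``"distress"`` (single-item distress studies), an emotion
label, or ``"no emotion"``.  ``pleasantness`` is only filled for the
"emotion but cannot name it" item.  Unanswered prompts are simply absent;
``prompt_index`` keeps the original within-day position so lag gaps remain
detectable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

LONG_COLUMNS = [
    "person_id",
    "group",
    "day",
    "prompt_index",
    "item",
    "intensity",
    "pleasantness",
    "distress",
]


@dataclass
class EmaRecord:
    """One answered prompt item."""

    person_id: str
    group: str
    day: int
    prompt_index: int
    item: str
    intensity: Optional[int] = None
    pleasantness: Optional[str] = None
    distress: Optional[float] = None


@dataclass
class EmaSeries:
    """Ordered ratings of one person.

    ``data`` has columns ``day``, ``prompt_index``, ``y`` with
    ``(day, prompt_index)`` strictly increasing.  Missing prompts are absent
    rows, not NaNs.
    """

    person_id: str
    group: str
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        need = {"day", "prompt_index", "y"}
        if not need.issubset(self.data.columns):
            raise ValueError(f"EmaSeries.data must have columns {sorted(need)}")
        if len(self.data) > 1:
            d = self.data["day"].to_numpy()
            p = self.data["prompt_index"].to_numpy()
            ok = (d[1:] > d[:-1]) | ((d[1:] == d[:-1]) & (p[1:] > p[:-1]))
            if not ok.all():
                raise ValueError("(day, prompt_index) must be strictly increasing")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def values(self) -> np.ndarray:
        return self.data["y"].to_numpy(dtype=float)


def records_to_frame(records: list[EmaRecord]) -> pd.DataFrame:
    """Stack :class:`EmaRecord` objects into the long-format frame."""
    rows = [
        (r.person_id, r.group, r.day, r.prompt_index, r.item, r.intensity, r.pleasantness, r.distress)
        for r in records
    ]
    return pd.DataFrame(rows, columns=LONG_COLUMNS)


def write_long_csv(frame: pd.DataFrame, path) -> None:
    missing = [c for c in LONG_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"long-format frame missing columns: {missing}")
    frame.to_csv(path, index=False, columns=LONG_COLUMNS)


def read_long_csv(path) -> pd.DataFrame:
    frame = pd.read_csv(
        path,
        dtype={"person_id": str, "group": str, "item": str, "pleasantness": "string"},
    )
    missing = [c for c in LONG_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    frame["day"] = frame["day"].astype(int)
    frame["prompt_index"] = frame["prompt_index"].astype(int)
    return frame
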