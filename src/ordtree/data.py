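"""Frequency tables and study designs for aggregated MPT data.

Responses are aggregated over items within each tree (item homogeneity), so a
participant's data are one count vector per tree.  Tables read/write as
delimited text with one row per participant and one ``tree:category`` column
per cell; the per-tree item counts travel in ``# items:`` header comments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import MPTModel

__all__ = ["StudyDesign", "FrequencyTable", "bell_design"]


@dataclass(frozen=True)
class StudyDesign:
    """Items presented per tree per participant, plus condition metadata."""

    items_per_tree: dict[str, int]
    n_participants: int
    conditions: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        for tree, n in self.items_per_tree.items():
            if n < 0:
                raise ValueError(f"negative item count for tree {tree!r}")

    @property
    def trials_per_participant(self) -> int:
        return sum(self.items_per_tree.values())


def bell_design(
    n_participants: int = 138,
    condition_labels: Sequence[str] = ("pleasant", "disgusting"),
    new_item_split: tuple[int, int] = (20, 20),
    items_per_source: int = 10,
) -> StudyDesign:
    """The source-monitoring design of the Bell-style face/behavior studies.

    Two within-subject face conditions; per condition 10 studied items per
    source (congruent/incongruent behavior description) and — with the default
    even split of the 40 new faces — 20 new items, i.e. 80 trials per
    participant in total.
    """
    labels = tuple(condition_labels)
    if len(labels) != 2 or labels[0] == labels[1]:
        raise ValueError("need two distinct condition labels")
    items: dict[str, int] = {}
    for cond, n_new in zip(labels, new_item_split):
        items[f"source_A_{cond}"] = items_per_source
        items[f"source_B_{cond}"] = items_per_source
        items[f"new_{cond}"] = n_new
    return StudyDesign(items_per_tree=items, n_participants=n_participants, conditions=labels)


@dataclass
class FrequencyTable:
    """Per-participant response counts per tree and category."""

    participants: tuple[str, ...]
    categories: dict[str, tuple[str, ...]]  # tree -> ordered category labels
    counts: dict[str, np.ndarray]  # tree -> (n_participants, n_categories) ints
    items_per_tree: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.participants)
        for tree, arr in self.counts.items():
            arr = np.asarray(arr, dtype=int)
            self.counts[tree] = arr
            if arr.shape != (n, len(self.categories[tree])):
                raise ValueError(
                    f"tree {tree!r}: counts shape {arr.shape} does not match "
                    f"{n} participants x {len(self.categories[tree])} categories"
                )
            if np.any(arr < 0):
                raise ValueError(f"tree {tree!r}: negative counts")
            items = self.items_per_tree.get(tree)
            if items is not None and not np.all(arr.sum(axis=1) == items):
                raise ValueError(
                    f"tree {tree!r}: per-participant counts do not sum to the "
                    f"designed {items} items"
                )
        if not self.items_per_tree:
            self.items_per_tree = {
                tree: int(arr.sum(axis=1)[0]) if len(arr) else 0
                for tree, arr in self.counts.items()
            }

    @property
    def n_participants(self) -> int:
        return len(self.participants)

    @property
    def trees(self) -> tuple[str, ...]:
        return tuple(self.counts)

    def design(self, conditions: tuple[str, ...] = ()) -> StudyDesign:
        return StudyDesign(
            items_per_tree=dict(self.items_per_tree),
            n_participants=self.n_participants,
            conditions=conditions,
        )

    def check_against_model(self, model: MPTModel) -> None:
        for tree in model.trees:
            if tree.name not in self.counts:
                raise ValueError(f"data lack counts for model tree {tree.name!r}")
            if self.categories[tree.name] != tree.categories:
                raise ValueError(
                    f"tree {tree.name!r}: data categories {self.categories[tree.name]} "
                    f"!= model categories {tree.categories}"
                )

    # ---- delimited-text I/O -------------------------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        data = {"participant": list(self.participants)}
        for tree, cats in self.categories.items():
            for j, cat in enumerate(cats):
                data[f"{tree}:{cat}"] = self.counts[tree][:, j]
        return pd.DataFrame(data)

    def write_csv(self, path: str | Path) -> None:
        path = Path(path)
        header = "".join(
            f"# items: {tree}={n}\n" for tree, n in self.items_per_tree.items()
        )
        path.write_text(header + self.to_dataframe().to_csv(index=False))

    @classmethod
    def from_dataframe(
        cls, frame: pd.DataFrame, items_per_tree: Mapping[str, int] | None = None
    ) -> "FrequencyTable":
        if "participant" in frame.columns:
            participants = tuple(str(v) for v in frame["participant"])
            frame = frame.drop(columns=["participant"])
        else:
            participants = tuple(str(i) for i in range(len(frame)))
        categories: dict[str, list[str]] = {}
        columns: dict[str, list[str]] = {}
        for col in frame.columns:
            if ":" not in col:
                raise ValueError(f"column {col!r} is not of the form 'tree:category'")
            tree, cat = col.rsplit(":", 1)
            categories.setdefault(tree, []).append(cat)
            columns.setdefault(tree, []).append(col)
        counts = {
            tree: frame[cols].to_numpy(dtype=int) for tree, cols in columns.items()
        }
        return cls(
            participants=participants,
            categories={t: tuple(c) for t, c in categories.items()},
            counts=counts,
            items_per_tree=dict(items_per_tree) if items_per_tree else {},
        )

    @classmethod
    def read_csv(cls, path: str | Path) -> "FrequencyTable":
        path = Path(path)
        items: dict[str, int] = {}
        body_lines: list[str] = []
        for line in path.read_text().splitlines():
            if line.startswith("# items:"):
                tree, _, n = line.removeprefix("# items:").strip().partition("=")
                items[tree.strip()] = int(n)
            elif not line.startswith("#"):
                body_lines.append(line)
        from io import StringIO

        frame = pd.read_csv(StringIO("\n".join(body_lines)))
        return cls.from_dataframe(frame, items_per_tree=items or None)
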