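"""Tag counting, normalization and abundance classification.

Builds the two-library count table at the center of the analysis: one row
per distinct 26-nt tag with raw counts in the W and F libraries, counts
normalized to one million and to 100,000 tags, and UniTag/singleton
status. A *singleton* is a tag seen exactly once across the combined
libraries; a *UniTag* is seen at least twice (so a tag with one copy in
each library is a UniTag). Abundance classes partition the
copies-per-million scale at 100 / 1,000 / 5,000: values ≤ 100 are low,
(100, 1,000] mid, (1,000, 5,000] high, and > 5,000 very high.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Union

import numpy as np
import pandas as pd

from ._util import percentage
from .extraction import Tag

LIBRARIES = ("W", "F")
#: Class boundaries on the copies-per-million scale (upper bounds, inclusive).
CLASS_BOUNDARIES = (100.0, 1000.0, 5000.0)
CLASS_ORDER = ("very_high", "high", "mid", "low")
_CLASS_TITLES = {
    "very_high": "very high-abundant (> 5,000 copies/million)",
    "high": "high-abundant (> 1,000 - 5,000 copies/million)",
    "mid": "mid-abundant (> 100 - 1,000 copies/million)",
    "low": "low-abundant (<= 100 copies/million)",
}

TABLE_COLUMNS = [
    "raw_W",
    "raw_F",
    "norm_W",
    "norm_F",
    "norm100k_W",
    "norm100k_F",
    "status",
]


def _tag_sequence(tag: Union[Tag, str]) -> str:
    return tag.sequence if isinstance(tag, Tag) else str(tag)


def count_tags(tags_by_library: Mapping[str, Iterable[Union[Tag, str]]]) -> pd.DataFrame:
    """Count tag multisets into a table with one row per distinct tag.

    ``tags_by_library`` maps library labels (must be a subset of W/F) to
    tag multisets. Raw counts per library sum to the input multiset sizes.
    """
    unknown = set(tags_by_library) - set(LIBRARIES)
    if unknown:
        raise ValueError(f"unknown libraries {sorted(unknown)}; expected {LIBRARIES}")
    counters = {
        lib: Counter(_tag_sequence(t) for t in tags_by_library.get(lib, ()))
        for lib in LIBRARIES
    }
    all_tags = sorted(set().union(*counters.values()))
    table = pd.DataFrame(
        {
            f"raw_{lib}": [counters[lib].get(t, 0) for t in all_tags]
            for lib in LIBRARIES
        },
        index=pd.Index(all_tags, name="tag"),
    )
    return table


def classify_unitags(table: pd.DataFrame) -> pd.DataFrame:
    """Set ``status``: singleton when the combined count is 1, else unitag."""
    combined = table["raw_W"] + table["raw_F"]
    table = table.copy()
    table["status"] = np.where(combined >= 2, "unitag", "singleton")
    return table


def normalize(table: pd.DataFrame) -> pd.DataFrame:
    """Add copies-per-million and per-100,000 columns at full precision."""
    table = table.copy()
    for lib in LIBRARIES:
        total = table[f"raw_{lib}"].sum()
        if total == 0:
            raise ValueError(f"library {lib} has zero sequenced tags")
        table[f"norm_{lib}"] = table[f"raw_{lib}"] * (1e6 / total)
        table[f"norm100k_{lib}"] = table[f"raw_{lib}"] * (1e5 / total)
    return table


def abundance_class(norm):
    """Map copies-per-million value(s) to an abundance class label.

    Scalar in, scalar out; array-like in, numpy array out.
    """
    arr = np.asarray(norm, dtype=float)
    if (arr < 0).any():
        raise ValueError("copies-per-million values must be >= 0")
    low, mid, high = CLASS_BOUNDARIES
    labels = np.select(
        [arr <= low, arr <= mid, arr <= high],
        ["low", "mid", "high"],
        default="very_high",
    )
    if np.isscalar(norm):
        return str(labels[()])
    return labels


@dataclass
class LibrarySummary:
    """Library features: depths, diversity, and abundance-class breakdowns.

    ``class_unitag_counts`` counts each library's detected UniTags by that
    library's own copies-per-million (a tag can sit in different classes
    in W and F); the total column is the sum of the two library columns,
    and its percentages are shares of that sum. ``class_copy_numbers``
    sums copies-per-million per class, so each library column totals 10^6
    and the percentage column is the share of the combined 2x10^6.
    """

    sequenced: dict[str, int]
    unitags: dict[str, int]
    singletons: dict[str, int]
    class_unitag_counts: pd.DataFrame
    class_copy_numbers: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        """Render the summary as one table (report layout)."""
        rows: list[tuple] = []
        for name, d in (
            ("Sequenced tags", self.sequenced),
            ("Number of unique transcripts (UniTags)", self.unitags),
            ("Number of singletons", self.singletons),
        ):
            rows.append((name, d["W"], d["F"], d["total"], ""))
        rows.append(("Abundance classes of UniTags", "", "", "", ""))
        for cls in CLASS_ORDER:
            rec = self.class_unitag_counts.loc[cls]
            rows.append(
                (_CLASS_TITLES[cls], rec["W"], rec["F"], rec["total"], rec["pct"])
            )
        rows.append(("Copy number of tags in abundance classes", "", "", "", ""))
        for cls in CLASS_ORDER:
            rec = self.class_copy_numbers.loc[cls]
            rows.append(
                (
                    _CLASS_TITLES[cls],
                    round(rec["W"], 1),
                    round(rec["F"], 1),
                    round(rec["total"], 1),
                    rec["pct"],
                )
            )
        return pd.DataFrame(rows, columns=["feature", "W", "F", "total", "pct"])


def summarize_library(table: pd.DataFrame) -> LibrarySummary:
    """Summarize a normalized, status-classified count table."""
    if len(table) == 0:
        empty = pd.DataFrame(
            0.0,
            index=pd.Index(CLASS_ORDER, name="class"),
            columns=["W", "F", "total", "pct"],
        )
        zeros = {"W": 0, "F": 0, "total": 0}
        return LibrarySummary(dict(zeros), dict(zeros), dict(zeros), empty.copy(), empty)

    required = {"norm_W", "norm_F", "status"}
    if not required <= set(table.columns):
        raise ValueError("table must be normalized and status-classified first")

    sequenced = {lib: int(table[f"raw_{lib}"].sum()) for lib in LIBRARIES}
    sequenced["total"] = sequenced["W"] + sequenced["F"]
    is_unitag = table["status"] == "unitag"
    unitags = {
        lib: int((is_unitag & (table[f"raw_{lib}"] > 0)).sum()) for lib in LIBRARIES
    }
    unitags["total"] = int(is_unitag.sum())
    is_singleton = ~is_unitag
    singletons = {
        lib: int((is_singleton & (table[f"raw_{lib}"] > 0)).sum())
        for lib in LIBRARIES
    }
    singletons["total"] = int(is_singleton.sum())

    counts = pd.DataFrame(
        0.0, index=pd.Index(CLASS_ORDER, name="class"), columns=["W", "F"]
    )
    copies = counts.copy()
    for lib in LIBRARIES:
        detected = table[is_unitag & (table[f"raw_{lib}"] > 0)]
        classes = abundance_class(detected[f"norm_{lib}"].to_numpy())
        for cls in CLASS_ORDER:
            mask = classes == cls
            counts.loc[cls, lib] = int(mask.sum())
            copies.loc[cls, lib] = float(detected[f"norm_{lib}"].to_numpy()[mask].sum())

    counts["total"] = counts["W"] + counts["F"]
    grand = counts["total"].sum()
    counts["pct"] = [
        percentage(v, grand) if grand else 0.0 for v in counts["total"]
    ]
    copies["total"] = copies["W"] + copies["F"]
    copy_grand = copies["W"].sum() + copies["F"].sum()
    copies["pct"] = [
        percentage(v, copy_grand) if copy_grand else 0.0 for v in copies["total"]
    ]
    return LibrarySummary(sequenced, unitags, singletons, counts, copies)


def write_table(table: pd.DataFrame, path: Union[str, Path]) -> None:
    table.to_csv(path, sep="\t")


def read_table(path: Union[str, Path]) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="tag")
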