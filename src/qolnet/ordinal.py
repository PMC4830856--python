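"""Reading, validating and scoring ordinal questionnaire data.

The central container is :class:`OrdinalDataset`: an ``n_respondents x
n_items`` matrix of 0-based consecutive integer category codes, a list of
:class:`ItemSpec` describing each item (number of response categories,
reverse-coding flag, health domain), and an optional per-respondent group
label.  The SF-36 instrument — 36 items allocated to the eight health
domains PF, RP, BP, GH, VT, SF, RE and MH — ships as the default.

Domain scores follow the standard convention: per respondent, item codes
(reverse-coded items flipped as ``K - 1 - code``) are summed and the sum is
linearly rescaled to the 0–100 range attainable for that domain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .exceptions import DataError

logger = logging.getLogger(__name__)

_DOMAINS = (
    "Physical functioning",
    "Role limitations-physical",
    "Bodily pain",
    "General health",
    "Vitality",
    "Social functioning",
    "Role limitations-emotional",
    "Mental health",
)

# item id -> (n_categories, reverse_coded, domain); standard instrument layout
_SF36_ITEMS: tuple[tuple[str, int, bool, str], ...] = (
    ("1", 5, True, "General health"),
    ("2", 5, False, "none"),
    *[(f"3{c}", 3, False, "Physical functioning") for c in "abcdefghij"],
    *[(f"4{c}", 2, False, "Role limitations-physical") for c in "abcd"],
    *[(f"5{c}", 2, False, "Role limitations-emotional") for c in "abc"],
    ("6", 5, True, "Social functioning"),
    ("7", 6, True, "Bodily pain"),
    ("8", 5, True, "Bodily pain"),
    ("9a", 6, True, "Vitality"),
    ("9b", 6, False, "Mental health"),
    ("9c", 6, False, "Mental health"),
    ("9d", 6, True, "Mental health"),
    ("9e", 6, True, "Vitality"),
    ("9f", 6, False, "Mental health"),
    ("9g", 6, False, "Vitality"),
    ("9h", 6, True, "Mental health"),
    ("9i", 6, False, "Vitality"),
    ("10", 5, True, "Social functioning"),
    ("11a", 5, False, "General health"),
    ("11b", 5, True, "General health"),
    ("11c", 5, False, "General health"),
    ("11d", 5, True, "General health"),
)

#: Display labels of Table-3 style ("PF 03", "MH 24", ...), keyed by item id.
SF36_DISPLAY_LABELS: dict[str, str] = {}
_prefixes = {
    "General health": "GH", "Physical functioning": "PF",
    "Role limitations-physical": "RP", "Role limitations-emotional": "RE",
    "Social functioning": "SF", "Bodily pain": "BP", "Vitality": "VT",
    "Mental health": "MH", "none": "",
}
for _pos, (_iid, _, _, _dom) in enumerate(_SF36_ITEMS, start=1):
    _pref = _prefixes[_dom]
    SF36_DISPLAY_LABELS[_iid] = f"{_pref} {_pos:02d}".strip() if _pref else f"{_pos:02d}"


@dataclass(frozen=True)
class ItemSpec:
    """One questionnaire item: label, category count, coding, domain."""

    label: str
    n_categories: int
    reverse_coded: bool = False
    domain: str = "none"

    def __post_init__(self) -> None:
        if self.n_categories < 2:
            raise DataError(
                f"item {self.label!r}: n_categories must be >= 2, "
                f"got {self.n_categories}"
            )


@dataclass
class OrdinalDataset:
    """Integer-coded item responses with 0-based consecutive category codes."""

    values: np.ndarray
    items: list[ItemSpec]
    group: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if not np.issubdtype(self.values.dtype, np.integer):
            if np.any(self.values != np.round(self.values)):
                raise DataError("non-integer category codes in dataset")
            self.values = self.values.astype(np.int64)
        if self.values.ndim != 2:
            raise DataError("values must be a 2-D respondents x items matrix")
        if self.values.shape[0] < 1:
            raise DataError("dataset needs at least one respondent")
        if self.values.shape[1] != len(self.items):
            raise DataError(
                f"{self.values.shape[1]} columns but {len(self.items)} item specs"
            )
        labels = [it.label for it in self.items]
        if len(set(labels)) != len(labels):
            raise DataError("item labels must be unique")
        for j, it in enumerate(self.items):
            col = self.values[:, j]
            bad = (col < 0) | (col >= it.n_categories)
            if np.any(bad):
                row = int(np.nonzero(bad)[0][0])
                raise DataError(
                    f"code {col[row]} out of range [0, {it.n_categories - 1}] "
                    f"for item {it.label!r} at row {row}"
                )
        if self.group is not None:
            self.group = np.asarray(self.group)
            if self.group.shape[0] != self.values.shape[0]:
                raise DataError("group labels do not match number of respondents")

    @property
    def n_respondents(self) -> int:
        return self.values.shape[0]

    @property
    def n_items(self) -> int:
        return self.values.shape[1]

    @property
    def labels(self) -> list[str]:
        return [it.label for it in self.items]

    @property
    def n_categories(self) -> np.ndarray:
        return np.array([it.n_categories for it in self.items], dtype=np.int64)

    def split_groups(self) -> dict[str, "OrdinalDataset"]:
        """Split by group label into per-group datasets (groups dropped)."""
        if self.group is None:
            raise DataError("dataset has no group labels")
        out = {}
        for g in sorted({str(x) for x in self.group}):
            mask = np.asarray([str(x) == g for x in self.group])
            out[g] = OrdinalDataset(self.values[mask], list(self.items))
        return out

    def to_csv(self, path: str | Path, group_col: str = "group") -> None:
        frame = pd.DataFrame(self.values, columns=self.labels)
        if self.group is not None:
            frame[group_col] = self.group
        frame.to_csv(path, index=False)


@dataclass
class DomainScores:
    """Per-respondent domain scores on the 0–100 scale."""

    scores: np.ndarray
    domains: list[str]

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if np.any(self.scores < -1e-9) or np.any(self.scores > 100 + 1e-9):
            raise DataError("domain scores must lie in [0, 100]")

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.scores, columns=self.domains).to_csv(path, index=False)


def sf36_instrument(include_diagnostic_status: bool = False) -> list[ItemSpec]:
    """The default 36-item instrument (optionally plus a binary status item)."""
    items = [
        ItemSpec(label, ncat, rev, dom) for label, ncat, rev, dom in _SF36_ITEMS
    ]
    if include_diagnostic_status:
        items.append(ItemSpec("DS", 2, False, "none"))
    return items


def default_sf36_map() -> dict[str, list[str]]:
    """Default allocation of the 36 items to the eight health domains.

    Item 2 (health compared to one year ago) and the diagnostic-status
    variable belong to no domain and are excluded.
    """
    mapping: dict[str, list[str]] = {d: [] for d in _DOMAINS}
    for label, _, _, dom in _SF36_ITEMS:
        if dom != "none":
            mapping[dom].append(label)
    return mapping


def load_instrument(path: str | Path) -> list[ItemSpec]:
    """Read an instrument config (YAML list of label/n_categories/... entries)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not raw:
        raise DataError(f"empty instrument config: {path}")
    return [
        ItemSpec(
            label=str(entry["label"]),
            n_categories=int(entry["n_categories"]),
            reverse_coded=bool(entry.get("reverse_coded", False)),
            domain=str(entry.get("domain", "none")),
        )
        for entry in raw
    ]


def save_instrument(items: Sequence[ItemSpec], path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            [
                {
                    "label": it.label,
                    "n_categories": it.n_categories,
                    "reverse_coded": it.reverse_coded,
                    "domain": it.domain,
                }
                for it in items
            ],
            fh,
            sort_keys=False,
        )


def read_ordinal_csv(
    path: str | Path,
    instrument: Sequence[ItemSpec],
    group_col: str | None = None,
    origin: str | int = "auto",
) -> OrdinalDataset:
    """Read a respondents-by-items CSV and normalise codes to 0-based.

    Rows with any missing item response are dropped listwise (the count is
    logged).  Category-code origin per item: ``0`` or ``1`` force an offset,
    ``"auto"`` infers it — any observed 0 means 0-based, otherwise 1-based
    (the usual questionnaire convention).
    """
    frame = pd.read_csv(path)
    if frame.empty:
        raise DataError(f"empty input file: {path}")
    wanted = [it.label for it in instrument]
    known = set(wanted) | ({group_col} if group_col else set())
    for col in frame.columns:
        if str(col) not in known:
            raise DataError(f"unknown column {col!r} in {path}")
    missing = [lab for lab in wanted if lab not in frame.columns.astype(str).tolist()]
    if missing:
        raise DataError(f"missing item columns in {path}: {missing}")
    frame.columns = frame.columns.astype(str)

    group = None
    if group_col is not None:
        if group_col not in frame.columns:
            raise DataError(f"group column {group_col!r} not found in {path}")
        group_series = frame[group_col]
        frame = frame[wanted]
    else:
        frame = frame[wanted]
        group_series = None

    complete = frame.notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("dropped %d incomplete rows (listwise deletion)", n_dropped)
        frame = frame[complete]
        if group_series is not None:
            group_series = group_series[complete]
    if frame.empty:
        raise DataError("no complete rows left after listwise deletion")

    values = np.empty(frame.shape, dtype=np.int64)
    for j, it in enumerate(instrument):
        col = frame[it.label].to_numpy()
        as_int = np.asarray(col, dtype=float)
        if np.any(as_int != np.round(as_int)):
            raise DataError(f"non-integer codes in item {it.label!r}")
        col = as_int.astype(np.int64)
        if origin == "auto":
            off = 0 if (col == 0).any() else 1
        else:
            off = int(origin)
        recoded = col - off
        bad = (recoded < 0) | (recoded >= it.n_categories)
        if np.any(bad):
            row = int(np.nonzero(bad)[0][0])
            raise DataError(
                f"code {col[row]} outside declared range for "
                f"{it.n_categories}-category item {it.label!r} (row {row})"
            )
        values[:, j] = recoded
    if group_series is not None:
        group = group_series.to_numpy()
    return OrdinalDataset(values=values, items=list(instrument), group=group)


def score_domains(
    data: OrdinalDataset, mapping: Mapping[str, Sequence[str]] | None = None
) -> DomainScores:
    """Sum item codes per domain and rescale to 0–100.

    Reverse-coded items contribute ``K - 1 - code`` so that higher always
    means the same direction within a domain.  The transform maps the
    attainable range [0, sum(K_i - 1)] linearly onto [0, 100].
    """
    if mapping is None:
        mapping = {}
        for it in data.items:
            if it.domain != "none":
                mapping.setdefault(it.domain, []).append(it.label)
    idx = {it.label: j for j, it in enumerate(data.items)}
    domains = list(mapping)
    scores = np.empty((data.n_respondents, len(domains)))
    for d, dom in enumerate(domains):
        labels = list(mapping[dom])
        if not labels:
            raise DataError(f"domain {dom!r} has no items")
        cols = []
        for lab in labels:
            if lab not in idx:
                raise DataError(f"domain {dom!r}: item {lab!r} not in dataset")
            cols.append(idx[lab])
        raw = np.zeros(data.n_respondents)
        max_raw = 0
        for j in cols:
            it = data.items[j]
            code = data.values[:, j]
            if it.reverse_coded:
                code = it.n_categories - 1 - code
            raw = raw + code
            max_raw += it.n_categories - 1
        scores[:, d] = 100.0 * raw / max_raw
    return DomainScores(scores=scores, domains=domains)
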