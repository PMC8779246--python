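"""Domain types and I/O for ordinal symptom-rating data.

The raw input of every analysis in this package is a subjects x items matrix
of integer category scores (for the 18-item BPRS: 1 "not present" to
7 "very severe"), together with an item catalog assigning each item a short
code, a full name and a group label (whether the symptom maps onto a DSM-5
criterion for schizophrenia or not).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources as importlib_resources
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ItemCatalog",
    "OrdinalResponseMatrix",
    "ItemFrequencyTable",
    "DoseRecord",
    "bprs_catalog",
    "load_responses",
    "summarize_items",
    "summarize_counts",
    "flag_high_dose",
    "round_half_up",
    "reference_item_counts",
    "reference_cohort_counts",
]

MissingPolicy = Literal["reject-file", "drop-row"]


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round with ties away from zero at the given decimal, matching the
    rounding style of printed clinical tables (1.25 -> 1.3, not 1.2)."""
    factor = 10.0**decimals
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


def _read_packaged_json(name: str) -> dict:
    ref = importlib_resources.files("bprsnet.resources").joinpath(name)
    with ref.open("r", encoding="utf-8") as fh:
        return json.load(fh)


@dataclass(frozen=True)
class ItemCatalog:
    """Ordered catalog of rating-scale items.

    Each entry is a ``(code, name, group)`` triple; group labels partition the
    items (for the packaged BPRS catalog: 8 "DSM" and 10 "non-DSM" symptoms).
    """

    codes: tuple[str, ...]
    names: tuple[str, ...]
    groups: tuple[str, ...]
    K: int = 7

    def __post_init__(self) -> None:
        if len(self.codes) != len(set(self.codes)):
            raise ValueError("item codes must be unique")
        if not (len(self.codes) == len(self.names) == len(self.groups)):
            raise ValueError("codes, names and groups must have equal length")

    @property
    def p(self) -> int:
        return len(self.codes)

    def group_members(self, group: str) -> tuple[str, ...]:
        return tuple(c for c, g in zip(self.codes, self.groups) if g == group)

    def group_indicator(self, group: str) -> np.ndarray:
        """Boolean mask over catalog order for membership in ``group``."""
        return np.array([g == group for g in self.groups], dtype=bool)

    def name_of(self, code: str) -> str:
        return self.names[self.codes.index(code)]

    @classmethod
    def from_json(cls, path: str | Path) -> "ItemCatalog":
        with open(path, "r", encoding="utf-8") as fh:
            payload = json.load(fh)
        return cls._from_payload(payload)

    @classmethod
    def _from_payload(cls, payload: dict) -> "ItemCatalog":
        items = payload["items"]
        return cls(
            codes=tuple(it["code"] for it in items),
            names=tuple(it["name"] for it in items),
            groups=tuple(it["group"] for it in items),
            K=int(payload.get("K", 7)),
        )


def bprs_catalog() -> ItemCatalog:
    """The packaged 18-item BPRS catalog with its DSM / non-DSM split."""
    return ItemCatalog._from_payload(_read_packaged_json("bprs_catalog.json"))


@dataclass(frozen=True)
class OrdinalResponseMatrix:
    """n subjects x p items of integer category scores in 1..K."""

    values: np.ndarray
    item_codes: tuple[str, ...]
    K: int
    n_dropped: int = 0

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if not np.issubdtype(values.dtype, np.integer):
            raise ValueError("values must be integers")
        n, p = values.shape
        if n < 2 or p < 2:
            raise ValueError("need at least 2 subjects and 2 items")
        if p != len(self.item_codes):
            raise ValueError("item_codes length must match number of columns")
        if values.min() < 1 or values.max() > self.K:
            raise ValueError(f"all entries must lie in [1, {self.K}]")
        object.__setattr__(self, "values", values)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def column(self, code: str) -> np.ndarray:
        return self.values[:, self.item_codes.index(code)]

    def subset_rows(self, idx: np.ndarray) -> "OrdinalResponseMatrix":
        return OrdinalResponseMatrix(self.values[idx], self.item_codes, self.K)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, columns=list(self.item_codes)).to_csv(
            path, index=False
        )


@dataclass(frozen=True)
class ItemFrequencyTable:
    """Per-item response counts by category, with derived mean and SD.

    ``counts[i, k]`` is the number of subjects scoring category k+1 on item i;
    rows sum to the subject count n. Means and SDs reproduce the arithmetic of
    a published frequency table exactly when fed its printed counts.
    """

    counts: np.ndarray  # p x K integer matrix
    item_codes: tuple[str, ...]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 2 or counts.shape[0] != len(self.item_codes):
            raise ValueError("counts must be a p x K matrix matching item_codes")
        if counts.min() < 0:
            raise ValueError("counts must be nonnegative")
        if len(set(counts.sum(axis=1))) != 1:
            raise ValueError("counts must sum to the same n for every item")
        object.__setattr__(self, "counts", counts)

    @property
    def n(self) -> int:
        return int(self.counts[0].sum())

    @property
    def K(self) -> int:
        return self.counts.shape[1]

    @property
    def means(self) -> np.ndarray:
        cats = np.arange(1, self.K + 1)
        return (self.counts * cats).sum(axis=1) / self.n

    @property
    def sds(self) -> np.ndarray:
        """Sample standard deviation (n - 1 denominator)."""
        cats = np.arange(1, self.K + 1)
        mu = self.means[:, None]
        ss = (self.counts * (cats[None, :] - mu) ** 2).sum(axis=1)
        return np.sqrt(ss / (self.n - 1))

    @property
    def percentages(self) -> np.ndarray:
        """Category percentages rounded half-up to 1 decimal."""
        raw = 100.0 * self.counts / self.n
        vec = np.vectorize(lambda x: round_half_up(x, 1))
        return vec(raw)

    def rounded_mean(self, code: str) -> float:
        return round_half_up(float(self.means[self.item_codes.index(code)]), 1)

    def rounded_sd(self, code: str) -> float:
        return round_half_up(float(self.sds[self.item_codes.index(code)]), 1)

    def to_frame(self, catalog: ItemCatalog | None = None) -> pd.DataFrame:
        rows = {
            "code": list(self.item_codes),
            "mean": [round_half_up(m, 1) for m in self.means],
            "sd": [round_half_up(s, 1) for s in self.sds],
        }
        if catalog is not None:
            rows["item"] = [catalog.name_of(c) for c in self.item_codes]
        frame = pd.DataFrame(rows)
        for k in range(self.K):
            frame[f"count_{k + 1}"] = self.counts[:, k]
        cols = (["item"] if catalog is not None else []) + [
            "code",
            "mean",
            "sd",
            *[f"count_{k + 1}" for k in range(self.K)],
        ]
        return frame[cols]

    def to_tsv(self, path: str | Path, catalog: ItemCatalog | None = None) -> None:
        self.to_frame(catalog).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ItemFrequencyTable":
        frame = pd.read_csv(path, sep="\t")
        count_cols = sorted(
            (c for c in frame.columns if c.startswith("count_")),
            key=lambda c: int(c.split("_")[1]),
        )
        return cls(
            counts=frame[count_cols].to_numpy(dtype=np.int64),
            item_codes=tuple(frame["code"]),
        )


def load_responses(
    path: str | Path,
    catalog: ItemCatalog,
    K: int | None = None,
    policy: MissingPolicy = "reject-file",
) -> OrdinalResponseMatrix:
    """Read a subjects x items CSV of integer ratings.

    The header must contain every catalog code (order-insensitive; columns are
    reordered to catalog order). Non-integer cells are a hard error. Cells that
    are missing or outside [1, K] are a hard error under the default
    ``reject-file`` policy, or silently removed (with the count recorded on the
    returned matrix) under ``drop-row``.
    """
    K = catalog.K if K is None else K
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    for code in catalog.codes:
        if code not in frame.columns:
            raise ValueError(f"input file is missing required column '{code}'")
    unknown = [c for c in frame.columns if c not in catalog.codes]
    if unknown:
        raise ValueError(f"input file has unknown column(s): {unknown}")
    frame = frame[list(catalog.codes)]

    n, p = frame.shape
    values = np.zeros((n, p), dtype=np.int64)
    bad_rows: set[int] = set()
    for j, code in enumerate(catalog.codes):
        for i, cell in enumerate(frame[code].to_numpy()):
            text = cell.strip()
            if text == "":
                if policy == "reject-file":
                    raise ValueError(
                        f"missing value at row {i + 2}, column '{code}'"
                    )
                bad_rows.add(i)
                continue
            try:
                val = int(text)
            except ValueError as exc:
                raise ValueError(
                    f"non-integer value '{text}' at row {i + 2}, column '{code}'"
                ) from exc
            if not 1 <= val <= K:
                if policy == "reject-file":
                    raise ValueError(
                        f"value {val} outside [1, {K}] at row {i + 2}, "
                        f"column '{code}'"
                    )
                bad_rows.add(i)
                continue
            values[i, j] = val

    keep = np.array([i not in bad_rows for i in range(n)], dtype=bool)
    return OrdinalResponseMatrix(
        values=values[keep],
        item_codes=catalog.codes,
        K=K,
        n_dropped=len(bad_rows),
    )


def summarize_items(data: OrdinalResponseMatrix) -> ItemFrequencyTable:
    """Tabulate per-item category counts from raw responses."""
    counts = np.zeros((data.p, data.K), dtype=np.int64)
    for j in range(data.p):
        counts[j] = np.bincount(data.values[:, j], minlength=data.K + 1)[1:]
    return ItemFrequencyTable(counts=counts, item_codes=data.item_codes)


def summarize_counts(
    counts: np.ndarray | dict[str, Sequence[int]],
    item_codes: Iterable[str] | None = None,
) -> ItemFrequencyTable:
    """Build the summary directly from a pre-tabulated frequency table,
    e.g. the per-category counts printed in a publication."""
    if isinstance(counts, dict):
        item_codes = tuple(counts.keys())
        counts = np.array([counts[c] for c in item_codes], dtype=np.int64)
    else:
        if item_codes is None:
            raise ValueError("item_codes required when counts is an array")
        item_codes = tuple(item_codes)
    return ItemFrequencyTable(counts=np.asarray(counts), item_codes=item_codes)


@dataclass(frozen=True)
class DoseRecord:
    """Antipsychotic exposure: chlorpromazine-equivalent dose (mg/day) and the
    ratio of prescribed daily dose to defined daily dose (dimensionless)."""

    cpz_equivalent_mg: float
    pdd_ddd_ratio: float

    def __post_init__(self) -> None:
        if self.cpz_equivalent_mg < 0 or self.pdd_ddd_ratio < 0:
            raise ValueError("dose quantities must be nonnegative")


def flag_high_dose(
    rec: DoseRecord,
    cpz_threshold: float = 1000.0,
    ratio_threshold: float = 1.5,
) -> bool:
    """High-dose antipsychotic rule: chlorpromazine equivalent >= 1000 mg/day
    or prescribed/defined daily-dose ratio >= 1.5 (both bounds inclusive)."""
    return (
        rec.cpz_equivalent_mg >= cpz_threshold
        or rec.pdd_ddd_ratio >= ratio_threshold
    )


def reference_item_counts() -> ItemFrequencyTable:
    """Packaged per-category counts of the 18 BPRS items in the REAP-AP
    schizophrenia cohort (n = 1438)."""
    payload = _read_packaged_json("bprs_reference_counts.json")
    return summarize_counts(payload["counts"])


def reference_cohort_counts() -> tuple[dict[str, int], int]:
    """Packaged categorical counts describing the same cohort; returns
    (counts, n)."""
    payload = _read_packaged_json("cohort_reference.json")
    return dict(payload["counts"]), int(payload["n"])
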