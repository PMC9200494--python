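"""Prescription (transaction) dataset I/O and validation.

A prescription is the set of acupoints one clinical study's protocol uses;
a dataset is an ordered list of such sets. Two CSV dialects are accepted:

* delimited cell — one row per prescription, all codes in one cell
  separated by ``;`` (or the delimiter passed in);
* long format — one ``(id, code)`` pair per row, grouped by id.

JSON is a top-level list of ``{"id": ..., "acupoints": [...]}`` objects.
All raw names pass through registry standardization on read.
"""

from __future__ import annotations

import csv
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .registry import Registry, StandardizationError

__all__ = ["PrescriptionDataset", "DatasetError", "read_dataset", "write_dataset",
           "item_frequencies"]

logger = logging.getLogger(__name__)


class DatasetError(ValueError):
    """Malformed or unresolvable prescription data."""


@dataclass
class PrescriptionDataset:
    """Ordered collection of prescriptions (sets of canonical codes)."""

    prescriptions: list[frozenset[str]]
    source_ids: list[str] | None = None

    def __post_init__(self) -> None:
        if not self.prescriptions:
            raise DatasetError("dataset must contain at least one prescription")
        self.prescriptions = [frozenset(t) for t in self.prescriptions]
        if self.source_ids is not None and len(self.source_ids) != len(self.prescriptions):
            raise DatasetError("source_ids length mismatch")

    def __len__(self) -> int:
        return len(self.prescriptions)

    def __iter__(self):
        return iter(self.prescriptions)

    def validate(self, registry: Registry) -> None:
        for i, t in enumerate(self.prescriptions):
            for code in t:
                if code not in registry:
                    raise DatasetError(f"prescription {i}: unknown code {code!r}")

    def ids(self) -> list[str]:
        if self.source_ids is not None:
            return list(self.source_ids)
        return [f"P{i + 1}" for i in range(len(self))]


def item_frequencies(ds: PrescriptionDataset) -> dict[str, int]:
    """Number of prescriptions containing each code."""
    counts: dict[str, int] = {}
    for t in ds:
        for code in t:
            counts[code] = counts.get(code, 0) + 1
    return counts


def _standardize_row(
    tokens: Iterable[str], registry: Registry, row_label: str
) -> frozenset[str]:
    codes: list[str] = []
    for tok in tokens:
        tok = tok.strip()
        if not tok:
            continue
        try:
            codes.append(registry.standardize_code(tok))
        except StandardizationError:
            raise DatasetError(f"{row_label}: unresolvable acupoint {tok!r}") from None
    if len(codes) != len(set(codes)):
        dupes = sorted({c for c in codes if codes.count(c) > 1})
        warnings.warn(f"{row_label}: duplicate acupoints collapsed: {dupes}")
        logger.warning("%s: duplicate acupoints collapsed: %s", row_label, dupes)
    return frozenset(codes)


def read_dataset(
    path: str | Path,
    registry: Registry,
    format: str | None = None,
    delimiter: str = ";",
) -> PrescriptionDataset:
    """Read a prescription dataset from CSV or JSON.

    ``format`` defaults to the file suffix. Unresolvable names raise
    :class:`DatasetError` naming the row and token; duplicates within a
    prescription collapse with a warning.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "json":
        return _read_json(path, registry)
    if fmt == "csv":
        return _read_csv(path, registry, delimiter)
    raise DatasetError(f"unknown dataset format: {fmt!r}")


def _read_json(path: Path, registry: Registry) -> PrescriptionDataset:
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise DatasetError(f"{path}: invalid JSON: {exc}") from None
    if not isinstance(payload, list) or not payload:
        raise DatasetError(f"{path}: expected a nonempty JSON list of prescriptions")
    rows, ids = [], []
    for i, obj in enumerate(payload):
        if not isinstance(obj, dict) or "acupoints" not in obj:
            raise DatasetError(f"{path}: entry {i} lacks an 'acupoints' list")
        pts = obj["acupoints"]
        if not isinstance(pts, list) or not all(isinstance(p, str) for p in pts):
            raise DatasetError(f"{path}: entry {i}: 'acupoints' must be a list of strings")
        ids.append(str(obj.get("id", f"P{i + 1}")))
        rows.append(_standardize_row(pts, registry, f"entry {i}"))
    return PrescriptionDataset(rows, ids)


def _read_csv(path: Path, registry: Registry, delimiter: str) -> PrescriptionDataset:
    with open(path, newline="") as fh:
        raw_rows = [r for r in csv.reader(fh) if any(cell.strip() for cell in r)]
    if not raw_rows:
        raise DatasetError(f"{path}: empty file")
    # Long format: every row is exactly (id, code). Otherwise: one
    # prescription per row with codes in a single delimited cell (an
    # optional leading id cell is recognized when it fails to standardize
    # and the rest does).
    if all(len(r) == 2 for r in raw_rows) and not any(delimiter in r[1] for r in raw_rows):
        grouped: dict[str, list[str]] = {}
        for rid, code in raw_rows:
            grouped.setdefault(rid.strip(), []).append(code)
        rows = [
            _standardize_row(codes, registry, f"prescription {rid!r}")
            for rid, codes in grouped.items()
        ]
        return PrescriptionDataset(rows, list(grouped))
    rows, ids = [], []
    for lineno, r in enumerate(raw_rows, start=1):
        cells = [c for c in r if c.strip()]
        tokens = [t for cell in cells for t in cell.split(delimiter)]
        rows.append(_standardize_row(tokens, registry, f"row {lineno}"))
        ids.append(f"P{lineno}")
    return PrescriptionDataset(rows, ids)


def write_dataset(
    ds: PrescriptionDataset, path: str | Path, format: str | None = None
) -> None:
    """Write a dataset; JSON is the canonical round-trip format."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "json":
        payload = [
            {"id": rid, "acupoints": sorted(t)}
            for rid, t in zip(ds.ids(), ds.prescriptions)
        ]
        path.write_text(json.dumps(payload, indent=1) + "\n")
    elif fmt == "csv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            for t in ds.prescriptions:
                writer.writerow([";".join(sorted(t))])
    else:
        raise DatasetError(f"unknown dataset format: {fmt!r}")
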