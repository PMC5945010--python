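"""Manifest reading and corpus-cleaning filters.

The cleaning step mirrors common practice for crowdsourced image corpora:
remove files smaller than 10 kB (10 240 bytes; very low resolution or
broken downloads) and exact duplicates (spam reposts, advertisements posted
repeatedly). Together these typically account for a few percent of a raw
corpus. "Duplicate" means byte-identical content (SHA-256); among a
duplicate set the earliest-timestamped record is kept, ties broken by the
lexicographically smallest record id. The size filter runs first; with
byte-identity the order does not change the outcome, but it is fixed for
determinism.
"""

from __future__ import annotations

import csv
import hashlib
import logging
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Sequence

__all__ = [
    "ImageRecord",
    "FilterReport",
    "RowError",
    "load_manifest",
    "filter_corpus",
    "MANIFEST_COLUMNS",
]

logger = logging.getLogger(__name__)

MANIFEST_COLUMNS = ["record_id", "park", "timestamp", "filepath", "bytes"]


@dataclass(frozen=True)
class ImageRecord:
    """One manifest entry: an image file with its posting metadata."""

    record_id: str
    park: str
    timestamp: datetime
    filepath: str
    bytes: int


@dataclass(frozen=True)
class RowError:
    """A manifest row that could not be parsed."""

    line: int
    reason: str


@dataclass
class FilterReport:
    """Accounting of a corpus-cleaning pass.

    Invariant: ``n_input == n_retained + n_duplicates_removed +
    n_undersized_removed + n_unreadable_removed``.
    """

    n_input: int = 0
    n_duplicates_removed: int = 0
    n_undersized_removed: int = 0
    n_unreadable_removed: int = 0
    n_retained: int = 0
    removed_ids: list[str] = field(default_factory=list)
    removal_reasons: dict[str, str] = field(default_factory=dict)

    @property
    def removed_fraction(self) -> float:
        if self.n_input == 0:
            return 0.0
        return (self.n_input - self.n_retained) / self.n_input

    def reconciles(self) -> bool:
        return (
            self.n_input
            == self.n_retained
            + self.n_duplicates_removed
            + self.n_undersized_removed
            + self.n_unreadable_removed
        )


def _parse_timestamp(text: str) -> datetime:
    return datetime.fromisoformat(text.strip())


def load_manifest(path: str | Path) -> tuple[list[ImageRecord], list[RowError]]:
    """Read a manifest CSV into records, collecting per-row errors.

    The file must have the header ``record_id,park,timestamp,filepath,bytes``.
    Rows with a missing park, an unparseable timestamp or a non-integer byte
    count are reported in the error list and omitted from the output. A
    duplicated record id is fatal (the corpus would be ambiguous).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[ImageRecord] = []
    errors: list[RowError] = []
    seen: set[str] = set()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or list(reader.fieldnames) != MANIFEST_COLUMNS:
            raise ValueError(
                f"malformed manifest header {reader.fieldnames!r}; "
                f"expected {MANIFEST_COLUMNS!r}"
            )
        for lineno, row in enumerate(reader, start=2):
            rid = (row.get("record_id") or "").strip()
            if not rid:
                errors.append(RowError(lineno, "missing record_id"))
                continue
            if rid in seen:
                raise ValueError(f"duplicate record_id {rid!r} in manifest")
            park = (row.get("park") or "").strip()
            if not park:
                errors.append(RowError(lineno, f"{rid}: missing park"))
                continue
            try:
                ts = _parse_timestamp(row.get("timestamp") or "")
            except ValueError:
                errors.append(
                    RowError(lineno, f"{rid}: unparseable timestamp {row.get('timestamp')!r}")
                )
                continue
            try:
                nbytes = int(row.get("bytes") or "")
            except ValueError:
                errors.append(RowError(lineno, f"{rid}: non-integer bytes"))
                continue
            seen.add(rid)
            records.append(
                ImageRecord(rid, park, ts, (row.get("filepath") or "").strip(), nbytes)
            )
    return records, errors


def _content_hash(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def filter_corpus(
    records: Sequence[ImageRecord],
    min_bytes: int = 10240,
    image_root: str | Path | None = None,
) -> tuple[list[ImageRecord], FilterReport]:
    """Apply the size and duplicate filters to a corpus.

    Removes (1) every record whose file is smaller than ``min_bytes``
    (strict less-than), then (2) all but one record of each set of
    byte-identical files, keeping the earliest timestamp (ties: smallest
    record id). Files that cannot be read for hashing are removed with
    reason "unreadable" and counted separately. Deterministic given the
    input; the retained *set* is order-invariant.
    """
    root = Path(image_root) if image_root is not None else None

    def resolve(rec: ImageRecord) -> Path:
        p = Path(rec.filepath)
        return root / p if (root is not None and not p.is_absolute()) else p

    report = FilterReport(n_input=len(records))

    survivors: list[ImageRecord] = []
    for rec in records:
        if rec.bytes < min_bytes:
            report.n_undersized_removed += 1
            report.removed_ids.append(rec.record_id)
            report.removal_reasons[rec.record_id] = "undersized"
            logger.debug("removed %s: undersized (%d bytes)", rec.record_id, rec.bytes)
        else:
            survivors.append(rec)

    by_hash: dict[str, list[ImageRecord]] = {}
    unreadable: list[ImageRecord] = []
    for rec in survivors:
        try:
            digest = _content_hash(resolve(rec))
        except OSError:
            unreadable.append(rec)
            continue
        by_hash.setdefault(digest, []).append(rec)

    for rec in unreadable:
        report.n_unreadable_removed += 1
        report.removed_ids.append(rec.record_id)
        report.removal_reasons[rec.record_id] = "unreadable"
        logger.debug("removed %s: unreadable", rec.record_id)

    keep_ids: set[str] = set()
    for group in by_hash.values():
        keeper = min(group, key=lambda r: (r.timestamp, r.record_id))
        keep_ids.add(keeper.record_id)
        for rec in group:
            if rec.record_id != keeper.record_id:
                report.n_duplicates_removed += 1
                report.removed_ids.append(rec.record_id)
                report.removal_reasons[rec.record_id] = "duplicate"
                logger.debug("removed %s: duplicate of %s", rec.record_id, keeper.record_id)

    retained = [
        rec
        for rec in survivors
        if rec.record_id in keep_ids
    ]
    report.n_retained = len(retained)
    assert report.reconciles(), "filter accounting failed to reconcile"
    return retained, report
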