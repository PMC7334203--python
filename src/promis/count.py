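"""Tag counting: FASTQ -> per-sample scFv count matrix.

Re-implementation of the assay's digital readout. Per read, in order:

1. chastity filter — keep only reads whose Casava-1.8 header filter field is
   "N" (did not fail the instrument's purity check);
2. per-base quality filter — every base must meet the Phred threshold
   (Q30 by default);
3. tag extraction — the 8-nt scFv tag at read positions 35-42 (1-based);
4. tag assignment — exact dictionary lookup by default; optional unambiguous
   1-mismatch correction on panels with minimum pairwise distance >= 3.

Every read lands in exactly one accounting category (assigned to a tag,
chastity_failed, quality_failed, too_short, or unassigned), so per-sample
accounting always partitions the total — an invariant the tests enforce on
every input.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .panel import BarcodePanel, PanelError, hamming

__all__ = [
    "QCParams",
    "ReadRecord",
    "CountMatrix",
    "FastqParseError",
    "parse_fastq",
    "chastity_pass",
    "quality_pass",
    "extract_tag",
    "assign_tag",
    "demultiplex",
    "count_tags",
]

ACCOUNTING_COLUMNS = [
    "total_reads",
    "assigned",
    "chastity_failed",
    "quality_failed",
    "too_short",
    "unassigned",
]


class FastqParseError(ValueError):
    pass


@dataclass(frozen=True)
class QCParams:
    """Read-level quality control.

    ``min_phred`` is compared with >= by default; ``strict_over`` switches to
    the literal "over Q30" reading (> 30).  ``tag_region_only`` restricts the
    per-base check to the tag span instead of the whole read.
    """

    min_phred: int = 30
    strict_over: bool = False
    require_chastity_pass: bool = True
    tag_region_only: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.min_phred <= 60):
            raise ValueError("min_phred must be in [0, 60]")


@dataclass
class ReadRecord:
    """One FASTQ read with its parsed Casava-1.8 header fields.

    ``chastity`` is the filter field character ("N" pass / "Y" fail) or None
    when the header carries no filter block; ``index`` is the sample index
    sequence from the header, or None.
    """

    header: str
    sequence: str
    qualities: np.ndarray
    chastity: str | None = None
    index: str | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise FastqParseError(
                f"sequence/quality length mismatch in read {self.header!r}"
            )


def _parse_header(title: str) -> tuple[str | None, str | None]:
    """Extract (chastity_flag, index) from '<id> <read>:<Y|N>:<ctrl>:<index>'."""
    parts = title.split(" ", 1)
    if len(parts) < 2:
        return None, None
    fields = parts[1].split(":")
    if len(fields) < 2 or fields[1] not in ("N", "Y"):
        return None, None
    index = fields[3] if len(fields) >= 4 and fields[3] else None
    return fields[1], index


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def parse_fastq(path) -> Iterator[ReadRecord]:
    """Stream ReadRecords from a (optionally gzipped) Phred+33 FASTQ file.

    Truncated or malformed records raise :class:`FastqParseError` carrying the
    record position; sequences containing characters outside ACGTN are passed
    through (they simply fail tag assignment downstream).
    """
    with _open_text(path) as fh:
        n = 0
        try:
            for title, seq, qual in FastqGeneralIterator(fh):
                n += 1
                if len(seq) != len(qual):
                    raise FastqParseError(
                        f"{path}: record {n} ({title!r}): quality length "
                        f"{len(qual)} != sequence length {len(seq)}"
                    )
                chastity, index = _parse_header(title)
                yield ReadRecord(
                    header=title,
                    sequence=seq,
                    qualities=np.frombuffer(qual.encode(), dtype=np.uint8).astype(np.int16) - 33,
                    chastity=chastity,
                    index=index,
                )
        except ValueError as e:
            if isinstance(e, FastqParseError):
                raise
            raise FastqParseError(f"{path}: malformed FASTQ near record {n + 1}: {e}") from e


def chastity_pass(record: ReadRecord, missing_is_pass: bool = True) -> bool:
    """True iff the header filter field is "N" (read not filtered).

    A header with no filter field follows ``missing_is_pass`` (default: treat
    as pass); callers count these separately as a warning.
    """
    if record.chastity is None:
        return missing_is_pass
    return record.chastity == "N"


def quality_pass(
    record: ReadRecord, qc: QCParams, tag_slice: slice | None = None
) -> bool:
    """True iff every base meets the Phred threshold.

    Default comparator is >= min_phred; ``qc.strict_over`` requires strictly
    greater.  With ``qc.tag_region_only`` and a ``tag_slice``, only tag-span
    bases are checked.
    """
    q = record.qualities
    if qc.tag_region_only and tag_slice is not None:
        q = q[tag_slice]
    if q.size == 0:
        return False
    lo = int(q.min())
    return lo > qc.min_phred if qc.strict_over else lo >= qc.min_phred


def extract_tag(record: ReadRecord, structure) -> str | None:
    """Tag bases at 1-based positions tag_start..tag_end, or None if the read
    is shorter than tag_end (counted as too_short by the caller)."""
    if len(record.sequence) < structure.tag_end:
        return None
    return record.sequence[structure.tag_start - 1 : structure.tag_end]


class _TagAssigner:
    """Exact lookup, with optional unambiguous 1-mismatch correction.

    1-mismatch mode requires panel minimum pairwise distance >= 3, so every
    length-L string is within distance 1 of at most one panel tag and the
    correction can never be ambiguous.
    """

    def __init__(self, panel: BarcodePanel, max_mismatch: int = 0) -> None:
        if max_mismatch not in (0, 1):
            raise PanelError("max_mismatch must be 0 or 1")
        if max_mismatch == 1 and panel.min_hamming < 3:
            raise PanelError(
                f"1-mismatch assignment requires panel min_hamming >= 3 "
                f"(got {panel.min_hamming})"
            )
        self.exact = panel.tag_to_id
        self.max_mismatch = max_mismatch
        self.tags = [(t.tag, t.scfv_id) for t in panel.tags]
        self.tag_length = panel.structure.tag_length

    def __call__(self, tag: str) -> str | None:
        hit = self.exact.get(tag)
        if hit is not None or self.max_mismatch == 0:
            return hit
        if len(tag) != self.tag_length:
            return None
        best_id, best_d, ties = None, 2, 0
        for t, scfv in self.tags:
            d = sum(x != y for x, y in zip(tag, t))
            if d < best_d:
                best_id, best_d, ties = scfv, d, 1
            elif d == best_d:
                ties += 1
        return best_id if best_d <= 1 and ties == 1 else None


def assign_tag(tag: str, panel: BarcodePanel, max_mismatch: int = 0) -> str | None:
    """Assign an extracted tag to a panel scFv id, or None (unassigned).

    Exact dictionary lookup by default; ``max_mismatch=1`` assigns to the
    unique panel tag at Hamming distance <= 1 (ties or no candidate ->
    unassigned) and is only permitted on distance->=3 panels.
    """
    if len(tag) != panel.structure.tag_length:
        raise PanelError(
            f"tag length {len(tag)} != panel tag length {panel.structure.tag_length}"
        )
    return _TagAssigner(panel, max_mismatch)(tag)


def demultiplex(
    records: Iterable[ReadRecord],
    sample_sheet: pd.DataFrame,
    index_mismatch: int = 0,
) -> Iterator[tuple[str | None, ReadRecord]]:
    """Route reads to samples by their header index sequence.

    Yields ``(sample_id, record)``; ``sample_id`` is None for the
    undetermined pool.  ``index_mismatch=1`` allows unambiguous 1-mismatch
    matching and requires pairwise index distance >= 3.
    """
    if sample_sheet["index"].duplicated().any():
        raise PanelError("duplicate sample indexes in sheet")
    indexes = list(zip(sample_sheet["index"], sample_sheet["sample_id"]))
    if index_mismatch == 1:
        dists = [
            hamming(a, b)
            for i, (a, _) in enumerate(indexes)
            for (b, _) in indexes[i + 1 :]
        ]
        if dists and min(dists) < 3:
            raise PanelError(
                "1-mismatch demultiplexing requires pairwise index distance >= 3"
            )
    exact = dict(indexes)
    for rec in records:
        idx = rec.index
        hit = exact.get(idx) if idx is not None else None
        if hit is None and idx is not None and index_mismatch == 1:
            cands = [s for ix, s in indexes if len(ix) == len(idx) and hamming(ix, idx) <= 1]
            hit = cands[0] if len(cands) == 1 else None
        yield hit, rec


@dataclass
class CountMatrix:
    """samples x scfvs nonnegative integer counts with per-sample accounting.

    Invariant (audited by :meth:`check_conservation`): for every sample,
    assigned + chastity_failed + quality_failed + too_short + unassigned
    equals total_reads.
    """

    counts: pd.DataFrame  # index = sample_id, columns = scfv_id
    accounting: pd.DataFrame  # index = sample_id, columns = ACCOUNTING_COLUMNS
    orphan_tags: pd.DataFrame | None = None  # sample_id, tag, count

    def check_conservation(self) -> None:
        acc = self.accounting
        assigned = self.counts.sum(axis=1)
        if not (acc["assigned"] == assigned).all():
            raise AssertionError("accounting 'assigned' disagrees with row sums")
        parts = acc[["assigned", "chastity_failed", "quality_failed", "too_short", "unassigned"]]
        if not (parts.sum(axis=1) == acc["total_reads"]).all():
            raise AssertionError("read accounting does not partition total_reads")
        if (self.counts.to_numpy() < 0).any():
            raise AssertionError("negative counts")

    def to_tsv(self, path) -> None:
        merged = self.counts.join(self.accounting)
        merged.to_csv(path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, path) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col="sample_id")
        acc_cols = [c for c in ACCOUNTING_COLUMNS if c in df.columns]
        counts = df.drop(columns=acc_cols)
        accounting = df[acc_cols] if acc_cols else pd.DataFrame(index=df.index)
        return cls(counts=counts, accounting=accounting)


def count_tags(
    fastq_inputs: dict[str, str | Path] | str | Path,
    panel: BarcodePanel,
    sample_sheet: pd.DataFrame,
    qc: QCParams | None = None,
    max_mismatch: int = 0,
    orphan_top_n: int = 20,
) -> CountMatrix:
    """Count scFv tags per sample.

    ``fastq_inputs`` is either a mapping sample_id -> FASTQ path (already
    demultiplexed) or a single pooled FASTQ path, in which case reads are
    demultiplexed by header index against the sample sheet.  Filters apply in
    order chastity -> quality -> length -> assignment; each read increments
    exactly one accounting cell.  Totals are order-independent.
    """
    qc = qc or QCParams()
    scfv_ids = panel.scfv_ids
    assigner = _TagAssigner(panel, max_mismatch)
    structure = panel.structure
    tag_slice = slice(structure.tag_start - 1, structure.tag_end)
    samples = list(sample_sheet["sample_id"])
    counts = {s: dict.fromkeys(scfv_ids, 0) for s in samples}
    acc = {s: dict.fromkeys(ACCOUNTING_COLUMNS, 0) for s in samples}
    orphans: dict[str, dict[str, int]] = {s: {} for s in samples}

    def handle(sample: str, rec: ReadRecord) -> None:
        a = acc[sample]
        a["total_reads"] += 1
        if qc.require_chastity_pass and not chastity_pass(rec):
            a["chastity_failed"] += 1
            return
        if not quality_pass(rec, qc, tag_slice):
            a["quality_failed"] += 1
            return
        if len(rec.sequence) < structure.tag_end:
            a["too_short"] += 1
            return
        tag = rec.sequence[tag_slice]
        scfv = assigner(tag)
        if scfv is None:
            a["unassigned"] += 1
            orphans[sample][tag] = orphans[sample].get(tag, 0) + 1
        else:
            a["assigned"] += 1
            counts[sample][scfv] += 1

    if isinstance(fastq_inputs, dict):
        for sample, path in fastq_inputs.items():
            if sample not in acc:
                raise PanelError(f"FASTQ sample {sample!r} not in sample sheet")
            for rec in parse_fastq(path):
                handle(sample, rec)
    else:
        for sample, rec in demultiplex(parse_fastq(fastq_inputs), sample_sheet):
            if sample is not None:
                handle(sample, rec)

    counts_df = pd.DataFrame(
        [[counts[s][m] for m in scfv_ids] for s in samples],
        index=pd.Index(samples, name="sample_id"),
        columns=scfv_ids,
        dtype=np.int64,
    )
    acc_df = pd.DataFrame(
        [[acc[s][c] for c in ACCOUNTING_COLUMNS] for s in samples],
        index=pd.Index(samples, name="sample_id"),
        columns=ACCOUNTING_COLUMNS,
        dtype=np.int64,
    )
    orphan_rows = []
    for s in samples:
        top = sorted(orphans[s].items(), key=lambda kv: (-kv[1], kv[0]))[:orphan_top_n]
        orphan_rows.extend({"sample_id": s, "tag": t, "count": c} for t, c in top)
    cm = CountMatrix(
        counts=counts_df,
        accounting=acc_df,
        orphan_tags=pd.DataFrame(orphan_rows, columns=["sample_id", "tag", "count"]),
    )
    cm.check_conservation()
    return cm
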