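"""Barcode panel design and validation.

Each scFv antibody in the assay is conjugated 1:1 to a 68-nt oligonucleotide
carrying an 8-nt scFv-specific tag at positions 35-42 (1-based, inclusive).
Counting tag occurrences in sequencing reads counts antibody binding events.
This module defines the panel (scFv -> tag mapping), the read-structure
geometry shared by the simulator and the counter, and a generator that
produces panels with a guaranteed minimum pairwise Hamming distance so that
optional 1-mismatch tag correction is unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

NUCLEOTIDES = "ACGT"

__all__ = [
    "BarcodeTag",
    "ReadStructure",
    "BarcodePanel",
    "SampleIndex",
    "PanelReport",
    "PanelError",
    "FeasibilityError",
    "hamming",
    "generate_panel",
    "generate_sample_indexes",
    "validate_panel",
    "build_oligo",
    "read_panel_tsv",
    "write_panel_tsv",
    "read_sample_sheet",
    "write_sample_sheet",
]


class PanelError(ValueError):
    """Invalid panel, tag, or read-structure configuration."""


class FeasibilityError(PanelError):
    """Requested code set cannot be constructed (too many tags for the
    requested length/distance within the rejection budget)."""


def hamming(a: str, b: str) -> int:
    """Number of positions at which two equal-length strings differ."""
    if len(a) != len(b):
        raise PanelError(
            f"hamming distance undefined for unequal lengths ({len(a)} vs {len(b)})"
        )
    return sum(x != y for x, y in zip(a, b))


def _check_nucleotides(seq: str, what: str) -> None:
    if not seq or any(c not in NUCLEOTIDES for c in seq):
        raise PanelError(f"{what} must be a non-empty string over A/C/G/T, got {seq!r}")


@dataclass(frozen=True)
class ReadStructure:
    """Geometry of the barcode oligo as it appears in a sequencing read.

    Coordinates are 1-based inclusive, matching how positions are quoted in
    assay design documents ("position 35-42"); conversion to Python slices
    happens only inside this module and the counter.
    """

    oligo_length: int = 68
    tag_start: int = 35
    tag_end: int = 42
    scaffold_5p: str = ""
    scaffold_3p: str = ""

    def __post_init__(self) -> None:
        if not (1 <= self.tag_start <= self.tag_end <= self.oligo_length):
            raise PanelError(
                f"require 1 <= tag_start <= tag_end <= oligo_length, got "
                f"{self.tag_start}..{self.tag_end} in {self.oligo_length}"
            )
        if self.scaffold_5p and len(self.scaffold_5p) != self.tag_start - 1:
            raise PanelError(
                f"scaffold_5p length {len(self.scaffold_5p)} != tag_start-1 = {self.tag_start - 1}"
            )
        if self.scaffold_3p and len(self.scaffold_3p) != self.oligo_length - self.tag_end:
            raise PanelError(
                f"scaffold_3p length {len(self.scaffold_3p)} != oligo_length-tag_end = "
                f"{self.oligo_length - self.tag_end}"
            )
        for s, name in ((self.scaffold_5p, "scaffold_5p"), (self.scaffold_3p, "scaffold_3p")):
            if s:
                _check_nucleotides(s, name)

    @property
    def tag_length(self) -> int:
        return self.tag_end - self.tag_start + 1


@dataclass(frozen=True)
class BarcodeTag:
    scfv_id: str
    tag: str

    def __post_init__(self) -> None:
        _check_nucleotides(self.tag, f"tag for {self.scfv_id!r}")


@dataclass(frozen=True)
class SampleIndex:
    sample_id: str
    index: str

    def __post_init__(self) -> None:
        _check_nucleotides(self.index, f"index for {self.sample_id!r}")


@dataclass
class BarcodePanel:
    """Ordered scFv -> tag mapping plus the shared read-structure geometry."""

    structure: ReadStructure
    tags: list[BarcodeTag]

    def __post_init__(self) -> None:
        if not self.tags:
            raise PanelError("panel must contain at least one tag")
        L = self.structure.tag_length
        for t in self.tags:
            if len(t.tag) != L:
                raise PanelError(
                    f"tag {t.tag!r} ({t.scfv_id}) has length {len(t.tag)}, structure requires {L}"
                )
        ids = [t.scfv_id for t in self.tags]
        if len(set(ids)) != len(ids):
            raise PanelError("duplicate scfv_id in panel")

    def __len__(self) -> int:
        return len(self.tags)

    @property
    def scfv_ids(self) -> list[str]:
        return [t.scfv_id for t in self.tags]

    @property
    def tag_to_id(self) -> dict[str, str]:
        return {t.tag: t.scfv_id for t in self.tags}

    @property
    def min_hamming(self) -> int:
        """Smallest pairwise Hamming distance, by exhaustive comparison."""
        if len(self.tags) == 1:
            return self.structure.tag_length  # vacuous; no pair exists
        return min(
            hamming(a.tag, b.tag)
            for i, a in enumerate(self.tags)
            for b in self.tags[i + 1 :]
        )


@dataclass
class PanelReport:
    min_hamming: int
    duplicates: list[str] = field(default_factory=list)
    max_homopolymer: dict[str, int] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.duplicates


def _longest_run(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def validate_panel(panel: BarcodePanel) -> PanelReport:
    """Report-only audit: exhaustive min pairwise distance, duplicate tags,
    longest homopolymer run per tag."""
    seen: dict[str, str] = {}
    dups: list[str] = []
    for t in panel.tags:
        if t.tag in seen:
            dups.append(t.tag)
        seen[t.tag] = t.scfv_id
    return PanelReport(
        min_hamming=panel.min_hamming,
        duplicates=dups,
        max_homopolymer={t.scfv_id: _longest_run(t.tag) for t in panel.tags},
    )


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(NUCLEOTIDES[i] for i in rng.integers(0, 4, size=length))


def generate_panel(
    n_tags: int,
    tag_length: int = 8,
    min_hamming: int = 3,
    seed: int = 0,
    *,
    scfv_ids: Sequence[str] | None = None,
    structure: ReadStructure | None = None,
    max_rejections: int = 10_000,
) -> BarcodePanel:
    """Draw ``n_tags`` random tags pairwise at Hamming distance >= ``min_hamming``.

    Rejection sampling against the accepted set; deterministic for a fixed
    seed. The default min_hamming of 3 is the coding-theory requirement for
    unambiguous single-mismatch correction. Raises :class:`FeasibilityError`
    when ``max_rejections`` consecutive draws fail, which a brute-force
    enumeration confirms for genuinely infeasible requests (e.g. 5 tags of
    length 2 at distance >= 3).
    """
    if n_tags < 1:
        raise PanelError("n_tags must be >= 1")
    if min_hamming < 1:
        raise PanelError("min_hamming must be >= 1")
    if min_hamming > tag_length and n_tags > 1:
        # no two distinct tags of length L can differ in more than L positions
        raise FeasibilityError(
            f"min_hamming {min_hamming} exceeds tag_length {tag_length}: "
            f"no pair of tags can satisfy it"
        )
    if scfv_ids is not None and len(scfv_ids) != n_tags:
        raise PanelError("scfv_ids length must equal n_tags")

    rng = np.random.default_rng(seed)
    accepted: list[str] = []
    rejections = 0
    while len(accepted) < n_tags:
        cand = _random_seq(rng, tag_length)
        if all(hamming(cand, t) >= min_hamming for t in accepted):
            accepted.append(cand)
            rejections = 0
        else:
            rejections += 1
            if rejections >= max_rejections:
                raise FeasibilityError(
                    f"could not place tag {len(accepted) + 1}/{n_tags} at distance "
                    f">= {min_hamming} after {max_rejections} rejected draws"
                )

    if structure is None:
        base = ReadStructure()
        structure = ReadStructure(
            oligo_length=base.oligo_length,
            tag_start=base.tag_start,
            tag_end=base.tag_end,
            scaffold_5p=_random_seq(rng, base.tag_start - 1),
            scaffold_3p=_random_seq(rng, base.oligo_length - base.tag_end),
        )
    ids = list(scfv_ids) if scfv_ids is not None else [
        f"scFv({i + 1})-Srt" for i in range(n_tags)
    ]
    return BarcodePanel(structure=structure, tags=[
        BarcodeTag(scfv_id=i, tag=t) for i, t in zip(ids, accepted)
    ])


def generate_sample_indexes(
    sample_ids: Sequence[str],
    index_length: int = 8,
    min_hamming: int = 3,
    seed: int = 0,
) -> list[SampleIndex]:
    """Distinct sample indexes, pairwise distance >= min_hamming so that
    1-mismatch demultiplexing is unambiguous."""
    # reuse the tag generator; a different default seed stream keeps indexes
    # independent of any panel generated with the same seed
    pseudo = generate_panel(
        len(sample_ids), tag_length=index_length, min_hamming=min_hamming,
        seed=np.random.SeedSequence([seed, 0x5A17]).generate_state(1)[0] % (2**31),
        scfv_ids=list(sample_ids),
    )
    return [SampleIndex(sample_id=t.scfv_id, index=t.tag) for t in pseudo.tags]


def build_oligo(tag: BarcodeTag, structure: ReadStructure) -> str:
    """Full oligo sequence: 5' scaffold + tag + 3' scaffold.

    The tag occupies 1-based positions tag_start..tag_end of the result.
    """
    if len(tag.tag) != structure.tag_length:
        raise PanelError(
            f"tag length {len(tag.tag)} inconsistent with structure tag span "
            f"{structure.tag_length}"
        )
    if not structure.scaffold_5p or not structure.scaffold_3p:
        raise PanelError("structure must carry scaffold sequences to build an oligo")
    return structure.scaffold_5p + tag.tag + structure.scaffold_3p


# ---------------------------------------------------------------------------
# TSV round-trips. The panel file is diff-able plain text: a '#'-prefixed
# header block with the ReadStructure fields, then scfv_id/tag columns.

def write_panel_tsv(panel: BarcodePanel, path) -> None:
    s = panel.structure
    with open(path, "w") as fh:
        fh.write(f"#oligo_length\t{s.oligo_length}\n")
        fh.write(f"#tag_start\t{s.tag_start}\n")
        fh.write(f"#tag_end\t{s.tag_end}\n")
        fh.write(f"#scaffold_5p\t{s.scaffold_5p}\n")
        fh.write(f"#scaffold_3p\t{s.scaffold_3p}\n")
        fh.write("scfv_id\ttag\n")
        for t in panel.tags:
            fh.write(f"{t.scfv_id}\t{t.tag}\n")


def read_panel_tsv(path) -> BarcodePanel:
    meta: dict[str, str] = {}
    rows: list[tuple[str, str]] = []
    header_seen = False
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].partition("\t")
                meta[key] = val
            elif not header_seen:
                header_seen = True  # column header row
            else:
                scfv_id, _, tag = line.partition("\t")
                rows.append((scfv_id, tag))
    try:
        structure = ReadStructure(
            oligo_length=int(meta["oligo_length"]),
            tag_start=int(meta["tag_start"]),
            tag_end=int(meta["tag_end"]),
            scaffold_5p=meta.get("scaffold_5p", ""),
            scaffold_3p=meta.get("scaffold_3p", ""),
        )
    except KeyError as e:
        raise PanelError(f"panel file {path} missing header field {e}") from None
    return BarcodePanel(
        structure=structure,
        tags=[BarcodeTag(scfv_id=i, tag=t) for i, t in rows],
    )


def write_sample_sheet(rows, path) -> None:
    """rows: iterable of dicts with sample_id, index, group_label, replicate_id."""
    import pandas as pd

    df = pd.DataFrame(rows, columns=["sample_id", "index", "group_label", "replicate_id"])
    df.to_csv(path, sep="\t", index=False)


def read_sample_sheet(path):
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "index"}
    if not required <= set(df.columns):
        raise PanelError(f"sample sheet must have columns {sorted(required)}")
    if df["sample_id"].duplicated().any():
        raise PanelError("duplicate sample_id in sample sheet")
    if df["index"].duplicated().any():
        raise PanelError("duplicate sample index in sample sheet")
    return df
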