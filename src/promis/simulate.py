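"""Synthetic assay generator: ground truth through capture, PCR, sequencing.

The generative model mirrors the wet-lab chain of the bead-based barcoded-scFv
assay:

1. Each serum sample carries per-marker antigen abundances; control samples
   draw from a log-normal, cases are shifted by a per-marker log2 fold change.
2. With the antibody in excess, the number of barcode molecules captured on
   the beads is Poisson with mean proportional to the antigen amount.
3. Adapter PCR amplifies each captured molecule through a Galton-Watson
   branching process: every molecule duplicates independently each cycle with
   probability equal to the per-cycle efficiency (18 cycles by default).
4. Sequencing allocates a fixed read budget per sample multinomially over
   markers in proportion to post-PCR molecule counts, then corrupts reads with
   i.i.d. substitution errors, emits two-level per-base qualities, and flags a
   fraction of reads as chastity-filter failures.

Every intermediate truth is recorded in a ledger so the counting pipeline can
be audited read-for-read.  All randomness flows from one master seed through
hierarchically spawned per-sample streams: adding a sample never perturbs the
reads of another.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .panel import BarcodePanel, SampleIndex, build_oligo, generate_sample_indexes

__all__ = [
    "CohortDesign",
    "PCRParams",
    "SequencingParams",
    "DesignError",
    "simulate_abundances",
    "simulate_capture",
    "simulate_pcr",
    "simulate_reads",
    "simulate_counts",
    "default_sample_sheet",
]

CASE, CONTROL = "case", "control"


class DesignError(ValueError):
    """Invalid simulation design or parameters."""


@dataclass
class CohortDesign:
    """Specification of a synthetic case/control cohort.

    ``abundance_mu``/``abundance_sigma`` parameterize the natural-log scale of
    per-marker antigen abundance in controls (biological variability between
    individuals); ``effect_log2fc`` multiplies case abundances by
    ``2**effect`` per marker.  Defaults emulate the assay's study conditions:
    10 cases vs 10 controls, a 17-plex panel, marker means spanning three
    decades of captured-molecule scale, and sigma 0.5 (~53% between-subject CV).
    """

    n_case: int = 10
    n_control: int = 10
    n_markers: int = 17
    effect_log2fc: np.ndarray | Sequence[float] | float = 0.0
    abundance_mu: np.ndarray | Sequence[float] | None = None
    abundance_sigma: np.ndarray | Sequence[float] | float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_case < 1 or self.n_control < 1:
            raise DesignError("n_case and n_control must each be >= 1")
        if self.n_markers < 1:
            raise DesignError("n_markers must be >= 1")
        self.effect_log2fc = np.broadcast_to(
            np.asarray(self.effect_log2fc, dtype=float), (self.n_markers,)
        ).copy()
        if self.abundance_mu is None:
            # captured-molecule scale ~1e3..1e5 across the panel
            self.abundance_mu = np.linspace(np.log(1e3), np.log(1e5), self.n_markers)
        self.abundance_mu = np.broadcast_to(
            np.asarray(self.abundance_mu, dtype=float), (self.n_markers,)
        ).copy()
        self.abundance_sigma = np.broadcast_to(
            np.asarray(self.abundance_sigma, dtype=float), (self.n_markers,)
        ).copy()
        if np.any(self.abundance_sigma < 0):
            raise DesignError("abundance_sigma must be >= 0")

    @property
    def n_samples(self) -> int:
        return self.n_case + self.n_control

    @property
    def group_labels(self) -> list[str]:
        return [CASE] * self.n_case + [CONTROL] * self.n_control


@dataclass(frozen=True)
class PCRParams:
    """Branching-process amplification: ``cycles`` rounds, each molecule
    duplicating with probability ``efficiency`` per round.  Expected fold
    amplification is (1+efficiency)**cycles."""

    cycles: int = 18
    efficiency: float = 0.9
    normal_approx_threshold: int = 100_000

    def __post_init__(self) -> None:
        if self.cycles < 0:
            raise DesignError("cycles must be >= 0")
        if not (0.0 < self.efficiency <= 1.0):
            raise DesignError("efficiency must be in (0, 1]")


@dataclass(frozen=True)
class SequencingParams:
    """Read emission model.

    Substitutions are i.i.d. per base at ``sub_error_rate``.  Qualities are
    two-level: ``q_hi`` by default, ``q_lo`` at a background fraction
    ``q_lo_frac`` of bases and (with probability ``q_lo_at_error``) at
    substituted positions, so the per-base Q30 filter is exercised both ways.
    ``chastity_fail_rate`` of reads carry the "Y" filter flag in their header.
    """

    reads_per_sample: int = 100_000
    sub_error_rate: float = 0.001
    q_hi: int = 37
    q_lo: int = 12
    q_lo_frac: float = 0.02
    q_lo_at_error: float = 0.9
    chastity_fail_rate: float = 0.01
    read_length: int = 54

    def __post_init__(self) -> None:
        for name in ("sub_error_rate", "q_lo_frac", "q_lo_at_error", "chastity_fail_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise DesignError(f"{name} must be in [0, 1]")
        if self.reads_per_sample < 0:
            raise DesignError("reads_per_sample must be >= 0")


def _spawn_streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_abundances(
    design: CohortDesign,
) -> tuple[pd.DataFrame, list[str]]:
    """Per-sample, per-marker antigen abundances plus group labels.

    Controls: LogNormal(mu_k, sigma_k).  Cases: the same draw multiplied by
    2**effect_log2fc_k.  Sample order is cases first, then controls; rows are
    labelled S01..Snn.
    """
    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 1]))
    n = design.n_samples
    ln = rng.normal(
        loc=design.abundance_mu, scale=design.abundance_sigma, size=(n, design.n_markers)
    )
    ab = np.exp(ln)
    ab[: design.n_case] *= 2.0 ** design.effect_log2fc
    samples = [f"S{i + 1:02d}" for i in range(n)]
    return pd.DataFrame(ab, index=samples), design.group_labels


def simulate_capture(
    abundance: np.ndarray | pd.DataFrame,
    capture_scale: float = 1.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Captured barcode molecules ~ Poisson(capture_scale * abundance).

    Antibody excess makes expected capture proportional to antigen amount;
    independence across samples and markers.
    """
    ab = np.asarray(abundance, dtype=float)
    if np.any(ab < 0):
        raise DesignError("abundance must be nonnegative")
    if capture_scale < 0:
        raise DesignError("capture_scale must be >= 0")
    rng = rng or np.random.default_rng()
    return rng.poisson(capture_scale * ab).astype(np.int64)


def simulate_pcr(
    molecules: int | np.ndarray,
    params: PCRParams,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Amplify molecule counts through ``params.cycles`` Galton-Watson rounds.

    Each cycle adds Binomial(n, efficiency) new molecules per cell; above
    ``normal_approx_threshold`` molecules the binomial is replaced by its
    normal approximation (exact at efficiency 1, where the variance is 0).
    Returns an int64 array of post-PCR counts, shape-matching the input.
    """
    n = np.atleast_1d(np.asarray(molecules, dtype=np.int64))
    if np.any(n < 0):
        raise DesignError("molecule counts must be >= 0")
    rng = rng or np.random.default_rng()
    p = params.efficiency
    for _ in range(params.cycles):
        small = n <= params.normal_approx_threshold
        dup = np.zeros_like(n)
        if small.any():
            dup[small] = rng.binomial(n[small], p)
        big = ~small
        if big.any():
            mean = n[big] * p
            sd = np.sqrt(n[big] * p * (1.0 - p))
            dup[big] = np.maximum(0, np.rint(rng.normal(mean, sd))).astype(np.int64)
        n = n + dup
    out = n.astype(np.int64)
    if np.ndim(molecules) == 0:
        return out[0]
    return out.reshape(np.shape(molecules))


def _allocate_reads(
    post_pcr: np.ndarray, reads: int, rng: np.random.Generator
) -> np.ndarray:
    """Multinomial allocation of the sample's read budget over markers."""
    total = post_pcr.sum()
    if total == 0:
        return np.zeros_like(post_pcr)
    return rng.multinomial(reads, post_pcr / total)


_SUB_CHOICES = {b: [c for c in "ACGT" if c != b] for b in "ACGT"}


def _corrupt_read(
    seq: str, seqp: SequencingParams, rng: np.random.Generator
) -> tuple[str, str]:
    """Apply substitutions and emit the quality string for one read."""
    L = len(seq)
    qual = np.full(L, seqp.q_hi, dtype=np.int16)
    if seqp.q_lo_frac > 0:
        qual[rng.random(L) < seqp.q_lo_frac] = seqp.q_lo
    if seqp.sub_error_rate > 0:
        err_pos = np.nonzero(rng.random(L) < seqp.sub_error_rate)[0]
        if err_pos.size:
            s = list(seq)
            for i in err_pos:
                s[i] = _SUB_CHOICES[s[i]][rng.integers(3)]
                if rng.random() < seqp.q_lo_at_error:
                    qual[i] = seqp.q_lo
            seq = "".join(s)
    return seq, "".join(chr(q + 33) for q in qual)


def default_sample_sheet(
    design: CohortDesign, seed: int | None = None
) -> pd.DataFrame:
    """Sample sheet (sample_id, index, group_label, replicate_id) for a design."""
    seed = design.seed if seed is None else seed
    samples = [f"S{i + 1:02d}" for i in range(design.n_samples)]
    idx = generate_sample_indexes(samples, seed=seed)
    return pd.DataFrame(
        {
            "sample_id": samples,
            "index": [s.index for s in idx],
            "group_label": design.group_labels,
            "replicate_id": ["r1"] * design.n_samples,
        }
    )


def simulate_reads(
    post_pcr: pd.DataFrame,
    panel: BarcodePanel,
    seqp: SequencingParams,
    sample_sheet: pd.DataFrame,
    out_dir: str | Path,
    seed: int = 0,
    pooled: bool = False,
) -> pd.DataFrame:
    """Emit FASTQ reads for each sample and return the ground-truth ledger.

    ``post_pcr``: samples x markers molecule counts (index = sample_id,
    columns aligned with ``panel.scfv_ids``).  Reads start at oligo base 1
    (the Read-1 primer sits immediately upstream of the insert), so the tag
    occupies read positions tag_start..tag_end.  Headers are Casava-1.8
    style: ``@inst:run:fc:1:1:x:y 1:N:0:INDEX`` with "Y" marking chastity
    failures.  Output is gzip FASTQ, one file per sample (or one pooled file
    with ``pooled=True``); gzip mtime is pinned so identical inputs give
    byte-identical files.

    Returns a ledger DataFrame with one row per (sample, marker):
    post_pcr molecules and reads_emitted; per-sample reads sum exactly to
    ``seqp.reads_per_sample`` (0 for a sample with no molecules, reported
    via a zero row).
    """
    if seqp.read_length < panel.structure.tag_end:
        raise DesignError(
            f"read_length {seqp.read_length} < tag_end {panel.structure.tag_end}"
        )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scfv_ids = panel.scfv_ids
    templates = [
        build_oligo(t, panel.structure)[: seqp.read_length] for t in panel.tags
    ]
    sheet = sample_sheet.set_index("sample_id")
    streams = _spawn_streams(seed, len(post_pcr.index))

    ledger_rows = []
    pooled_fh = None
    if pooled:
        pooled_fh = gzip.GzipFile(
            filename="", mode="wb", fileobj=open(out_dir / "pooled.fastq.gz", "wb"), mtime=0
        )
    try:
        for si, sample_id in enumerate(post_pcr.index):
            rng = streams[si]
            index_seq = sheet.loc[sample_id, "index"]
            counts = post_pcr.loc[sample_id].to_numpy(dtype=np.int64)
            alloc = _allocate_reads(counts, seqp.reads_per_sample, rng)
            if pooled:
                fh = pooled_fh
            else:
                fh = gzip.GzipFile(
                    filename="",
                    mode="wb",
                    fileobj=open(out_dir / f"{sample_id}.fastq.gz", "wb"),
                    mtime=0,
                )
            try:
                read_no = 0
                for mi, n_reads in enumerate(alloc):
                    template = templates[mi]
                    for _ in range(int(n_reads)):
                        read_no += 1
                        seq, qual = _corrupt_read(template, seqp, rng)
                        fail = rng.random() < seqp.chastity_fail_rate
                        header = (
                            f"@SIM:1:FC1:1:1:{si + 1}:{read_no} "
                            f"1:{'Y' if fail else 'N'}:0:{index_seq}"
                        )
                        fh.write(f"{header}\n{seq}\n+\n{qual}\n".encode())
            finally:
                if not pooled:
                    fh.close()
            for mi, scfv in enumerate(scfv_ids):
                ledger_rows.append(
                    {
                        "sample_id": sample_id,
                        "scfv_id": scfv,
                        "post_pcr": int(counts[mi]),
                        "reads_emitted": int(alloc[mi]),
                    }
                )
    finally:
        if pooled_fh is not None:
            pooled_fh.close()
    return pd.DataFrame(ledger_rows)


def simulate_counts(
    design: CohortDesign,
    pcr: PCRParams | None = None,
    reads_per_sample: int = 100_000,
    capture_scale: float = 1.0,
    n_replicates: int = 1,
) -> tuple[pd.DataFrame, list[str]]:
    """Count-level fast path: abundance -> capture -> PCR -> read allocation.

    Produces the per-sample scFv read-count matrix that the full FASTQ route
    yields on an error-free channel (the counter's error-free oracle test
    establishes the equality), without materializing reads.  Used for
    statistical studies (power, null calibration, precision) where only the
    count matrix matters.  ``n_replicates`` > 1 splits each sample into that
    many technical replicates sharing the sample's true abundance (separate
    capture/PCR/sequencing noise), with ids ``<sample>_r<k>``.

    Returns (counts DataFrame, group labels aligned with its rows).
    """
    pcr = pcr or PCRParams()
    ab, labels = simulate_abundances(design)
    streams = _spawn_streams(
        int(np.random.SeedSequence([design.seed, 2]).generate_state(1)[0]),
        design.n_samples,
    )
    rows, index, out_labels = [], [], []
    for si, sample_id in enumerate(ab.index):
        rng = streams[si]
        for rep in range(n_replicates):
            captured = simulate_capture(ab.iloc[si].to_numpy(), capture_scale, rng)
            amplified = simulate_pcr(captured, pcr, rng)
            alloc = _allocate_reads(amplified, reads_per_sample, rng)
            rows.append(alloc)
            index.append(sample_id if n_replicates == 1 else f"{sample_id}_r{rep + 1}")
            out_labels.append(labels[si])
    counts = pd.DataFrame(np.asarray(rows), index=index)
    return counts, out_labels
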