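"""End-to-end orchestration: panel -> simulate -> count -> analyze.

One YAML config (or a :class:`RunConfig` built in Python) drives a full
deterministic run: the panel TSV, per-sample FASTQs, the ground-truth ledger,
the count matrix, and the analysis report are written to an output directory
together with a manifest of seeds and SHA-256 checksums.  Identical configs
produce byte-identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .analyze import AnalysisParams, run_study
from .count import QCParams, count_tags
from .panel import generate_panel, write_panel_tsv, write_sample_sheet
from .simulate import (
    CohortDesign,
    PCRParams,
    SequencingParams,
    default_sample_sheet,
    simulate_abundances,
    simulate_capture,
    simulate_pcr,
    simulate_reads,
)

__all__ = ["RunConfig", "run_end_to_end", "load_config"]


@dataclass
class RunConfig:
    design: CohortDesign = field(default_factory=CohortDesign)
    pcr: PCRParams = field(default_factory=PCRParams)
    sequencing: SequencingParams = field(default_factory=SequencingParams)
    qc: QCParams = field(default_factory=QCParams)
    analysis: AnalysisParams = field(default_factory=AnalysisParams)
    capture_scale: float = 1.0
    max_mismatch: int = 0
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kwargs = {}
        for key, typ in (
            ("design", CohortDesign),
            ("pcr", PCRParams),
            ("sequencing", SequencingParams),
            ("qc", QCParams),
            ("analysis", AnalysisParams),
        ):
            if key in d:
                kwargs[key] = typ(**d[key])
        for key in ("capture_scale", "max_mismatch", "seed"):
            if key in d:
                kwargs[key] = d[key]
        return cls(**kwargs)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh) or {})


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_end_to_end(config: RunConfig, out_dir) -> dict:
    """Run the full pipeline and write all artifacts under ``out_dir``.

    Returns a summary dict (also written as ``manifest.json``) with the AUC,
    PCA variance explained, per-stage accounting, seeds, and artifact
    checksums.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    design = config.design
    master = np.random.SeedSequence([config.seed, design.seed])
    sub_seeds = master.generate_state(3) % (2**31)

    panel = generate_panel(design.n_markers, seed=int(sub_seeds[0]))
    write_panel_tsv(panel, out / "panel.tsv")

    sheet = default_sample_sheet(design, seed=int(sub_seeds[1]))
    write_sample_sheet(sheet.to_dict("records"), out / "samples.tsv")

    abundance, labels = simulate_abundances(design)
    cap_rng = np.random.default_rng(int(sub_seeds[2]))
    captured = simulate_capture(abundance, config.capture_scale, cap_rng)
    post_pcr = simulate_pcr(captured, config.pcr, cap_rng)
    post_pcr_df = pd.DataFrame(post_pcr, index=abundance.index, columns=panel.scfv_ids)

    fastq_dir = out / "fastq"
    ledger = simulate_reads(
        post_pcr_df, panel, config.sequencing, sheet, fastq_dir,
        seed=int(sub_seeds[2]),
    )
    ledger = ledger.merge(
        pd.DataFrame(
            {
                "sample_id": np.repeat(abundance.index, design.n_markers),
                "scfv_id": np.tile(panel.scfv_ids, len(abundance)),
                "true_abundance": abundance.to_numpy().ravel(),
                "captured": captured.ravel(),
            }
        ),
        on=["sample_id", "scfv_id"],
    )[["sample_id", "scfv_id", "true_abundance", "captured", "post_pcr", "reads_emitted"]]
    ledger.to_csv(out / "ledger.tsv", sep="\t", index=False)

    fastqs = {s: fastq_dir / f"{s}.fastq.gz" for s in abundance.index}
    cm = count_tags(fastqs, panel, sheet, config.qc, config.max_mismatch)
    cm.to_tsv(out / "counts.tsv")
    if cm.orphan_tags is not None:
        cm.orphan_tags.to_csv(out / "orphan_tags.tsv", sep="\t", index=False)

    report = run_study(cm.counts, labels, config.analysis)
    report_dict = {
        "auc": report.classification.auc,
        "decision_values": report.classification.decision_values.to_dict(),
        "roc": {
            "fpr": report.classification.fpr.tolist(),
            "tpr": report.classification.tpr.tolist(),
        },
        "pca_variance_explained": report.pca.variance_explained.tolist(),
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report_dict, fh, indent=2)
    report.pca.scores.to_csv(out / "pca_scores.tsv", sep="\t")

    artifacts = sorted(
        p for p in out.rglob("*") if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "auc": report.classification.auc,
        "accounting": cm.accounting.sum().astype(int).to_dict(),
        "checksums": {str(p.relative_to(out)): _sha256(p) for p in artifacts},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
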