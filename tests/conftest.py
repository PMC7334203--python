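import numpy as np
import pandas as pd
import pytest

from promis.panel import BarcodePanel, BarcodeTag, ReadStructure, generate_panel
from promis.simulate import (
    CohortDesign,
    SequencingParams,
    default_sample_sheet,
    simulate_reads,
)


@pytest.fixture(scope="session")
def panel17():
    """A 17-plex panel with min pairwise Hamming distance >= 3."""
    return generate_panel(17, tag_length=8, min_hamming=3, seed=1)


@pytest.fixture
def tiny_structure():
    """Short geometry (tag at positions 3-6 of a 10-nt oligo) for hand-checkable reads."""
    return ReadStructure(
        oligo_length=10, tag_start=3, tag_end=6, scaffold_5p="CC", scaffold_3p="GGGG"
    )


@pytest.fixture
def tiny_panel(tiny_structure):
    return BarcodePanel(
        structure=tiny_structure,
        tags=[
            BarcodeTag("scFv(1)-Srt", "AAAA"),
            BarcodeTag("scFv(2)-Srt", "TTTT"),
            BarcodeTag("scFv(3)-Srt", "ACGT"),
        ],
    )


def simulate_small_experiment(
    tmp_path,
    panel,
    n_case=2,
    n_control=2,
    reads_per_sample=1500,
    seed=11,
    pooled=False,
    **seq_kwargs,
):
    """Small FASTQ-level experiment; returns (fastq_dir, ledger, sheet, design)."""
    design = CohortDesign(
        n_case=n_case, n_control=n_control, n_markers=len(panel), seed=seed
    )
    from promis.simulate import simulate_abundances, simulate_capture, simulate_pcr, PCRParams

    ab, _ = simulate_abundances(design)
    rng = np.random.default_rng(seed)
    captured = simulate_capture(ab, 0.05, rng)
    post = simulate_pcr(captured, PCRParams(cycles=6, efficiency=0.9), rng)
    post_df = pd.DataFrame(post, index=ab.index, columns=panel.scfv_ids)
    seqp = SequencingParams(reads_per_sample=reads_per_sample, read_length=54, **seq_kwargs)
    sheet = default_sample_sheet(design)
    out = tmp_path / "fastq"
    ledger = simulate_reads(post_df, panel, seqp, sheet, out, seed=seed, pooled=pooled)
    return out, ledger, sheet, design
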