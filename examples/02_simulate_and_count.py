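"""Simulate a small sequencing experiment and count tags from the FASTQs.

A 2-vs-2 cohort is pushed through the full generative chain (abundance ->
Poisson capture -> 18-cycle branching-process PCR -> multinomial read
emission with substitution errors and chastity flags), then the counting
pipeline reads the FASTQs back: chastity filter, per-base Q30 filter, tag
extraction at positions 35-42, exact tag assignment.
"""

import tempfile
from pathlib import Path

from promis import CohortDesign, RunConfig, SequencingParams, run_end_to_end

config = RunConfig(
    design=CohortDesign(n_case=2, n_control=2, n_markers=17, seed=0),
    sequencing=SequencingParams(reads_per_sample=5_000),
    seed=42,
)
with tempfile.TemporaryDirectory() as d:
    manifest = run_end_to_end(config, d)
    artifacts = sorted(p.name for p in Path(d).iterdir())

acc = manifest["accounting"]
print("artifacts written:", ", ".join(artifacts))
print(f"\ntotal reads:      {acc['total_reads']}")
print(f"assigned to tags: {acc['assigned']}")
print(f"chastity-failed:  {acc['chastity_failed']}   (instrument purity flag 'Y')")
print(f"quality-failed:   {acc['quality_failed']}   (some base below Q30)")
print(f"unassigned:       {acc['unassigned']}   (tag matches no panel barcode)")
print("\nEvery read lands in exactly one category - the accounting partition")
print("is exact by construction and audited on every run.")
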