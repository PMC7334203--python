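"""Counting pipeline: parsing, filters, tag assignment, demultiplexing,
conservation, and the error-free oracle against the simulator ledger."""

import gzip
import random

import numpy as np
import pandas as pd
import pytest

from conftest import simulate_small_experiment
from promis.count import (
    FastqParseError,
    QCParams,
    ReadRecord,
    assign_tag,
    chastity_pass,
    count_tags,
    demultiplex,
    extract_tag,
    parse_fastq,
    quality_pass,
)
from promis.panel import BarcodePanel, BarcodeTag, PanelError, ReadStructure


def _record(seq="ACGT", qual=None, header="M:1:F:1:1:1:1 1:N:0:AAAA"):
    q = np.asarray(qual if qual is not None else [40] * len(seq))
    chastity, index = None, None
    parts = header.split(" ", 1)
    if len(parts) == 2:
        f = parts[1].split(":")
        if len(f) >= 2 and f[1] in "NY":
            chastity = f[1]
            index = f[3] if len(f) >= 4 else None
    return ReadRecord(header=header, sequence=seq, qualities=q, chastity=chastity, index=index)


class TestParseFastq:
    def test_wellformed_two_records(self, tmp_path):
        p = tmp_path / "x.fastq"
        p.write_text(
            "@r1 1:N:0:AAAA\nACGT\n+\nIIII\n@r2 1:Y:0:AAAA\nTTTT\n+\n!!!!\n"
        )
        recs = list(parse_fastq(p))
        assert len(recs) == 2
        assert recs[0].sequence == "ACGT"
        assert recs[0].qualities.tolist() == [40, 40, 40, 40]
        assert recs[0].chastity == "N" and recs[1].chastity == "Y"
        assert recs[1].qualities.tolist() == [0, 0, 0, 0]

    def test_truncated_record_raises_with_position(self, tmp_path):
        p = tmp_path / "bad.fastq"
        p.write_text("@r1 1:N:0:AAAA\nACGT\n+\nII\n")
        with pytest.raises(FastqParseError):
            list(parse_fastq(p))

    def test_simulator_roundtrip(self, tmp_path, panel17):
        out, ledger, _, _ = simulate_small_experiment(
            tmp_path, panel17, reads_per_sample=1000,
            sub_error_rate=0.0, chastity_fail_rate=0.0, q_lo_frac=0.0,
        )
        fq = sorted(out.glob("*.fastq.gz"))[0]
        with gzip.open(fq, "rt") as fh:
            raw_seqs = fh.read().splitlines()[1::4]
        parsed = [r.sequence for r in parse_fastq(fq)]
        assert parsed == raw_seqs
        assert len(parsed) == 1000


class TestFilters:
    @pytest.mark.parametrize(
        "header,expected",
        [
            ("m 1:N:0:ACGTACGT", True),
            ("m 1:Y:0:ACGTACGT", False),
        ],
    )
    def test_chastity_flag(self, header, expected):
        assert chastity_pass(_record(header=header)) is expected

    def test_missing_filter_field_defaults_to_pass(self):
        assert chastity_pass(_record(header="bare-header")) is True
        assert chastity_pass(_record(header="bare-header"), missing_is_pass=False) is False

    def test_quality_all_above(self):
        assert quality_pass(_record(qual=[40, 40, 40, 40]), QCParams(min_phred=30))

    def test_single_low_base_rejects_read(self):
        assert not quality_pass(_record(qual=[40, 29, 40, 40]), QCParams(min_phred=30))

    def test_boundary_comparator_configurable(self):
        rec = _record(qual=[30, 30, 30, 30])
        assert quality_pass(rec, QCParams(min_phred=30))
        assert not quality_pass(rec, QCParams(min_phred=30, strict_over=True))

    def test_tag_region_only_scope(self):
        rec = _record(seq="ACGTACGT", qual=[2, 2, 40, 40, 40, 40, 2, 2])
        qc = QCParams(min_phred=30, tag_region_only=True)
        assert quality_pass(rec, qc, tag_slice=slice(2, 6))
        assert not quality_pass(rec, QCParams(min_phred=30), tag_slice=slice(2, 6))


class TestExtractTag:
    def test_positions_35_to_42(self, panel17):
        tag = panel17.tags[0].tag
        from promis.panel import build_oligo

        oligo = build_oligo(panel17.tags[0], panel17.structure)
        rec = _record(seq=oligo, qual=[40] * 68)
        assert extract_tag(rec, panel17.structure) == tag

    def test_too_short_read_signalled(self, panel17):
        rec = _record(seq="A" * 41, qual=[40] * 41)
        assert extract_tag(rec, panel17.structure) is None


class TestAssignTag:
    def test_exact_hit(self, panel17):
        t = panel17.tags[5]
        assert assign_tag(t.tag, panel17) == t.scfv_id

    def test_one_mismatch_corrects_uniquely(self, panel17):
        t = panel17.tags[3]
        mutated = ("A" if t.tag[0] != "A" else "C") + t.tag[1:]
        # brute-force: distance-3 panel guarantees a unique candidate
        dists = sorted(
            sum(a != b for a, b in zip(mutated, u.tag)) for u in panel17.tags
        )
        assert dists[0] == 1 and dists[1] >= 2
        assert assign_tag(mutated, panel17, max_mismatch=0) is None
        assert assign_tag(mutated, panel17, max_mismatch=1) == t.scfv_id

    def test_distance_two_stays_unassigned(self, panel17):
        t = panel17.tags[0].tag
        sub = {"A": "C", "C": "G", "G": "T", "T": "A"}
        mutated = sub[t[0]] + sub[t[1]] + t[2:]
        if all(sum(a != b for a, b in zip(mutated, u.tag)) >= 2 for u in panel17.tags):
            assert assign_tag(mutated, panel17, max_mismatch=1) is None

    def test_mismatch_mode_requires_distance_three_panel(self):
        p = BarcodePanel(
            structure=ReadStructure(oligo_length=16, tag_start=5, tag_end=12),
            tags=[BarcodeTag("a", "AAAAAAAA"), BarcodeTag("b", "AAAAAAAT")],
        )
        with pytest.raises(PanelError):
            assign_tag("AAAAAAAA", p, max_mismatch=1)

    def test_n_base_unassigned(self, panel17):
        bad = "N" + panel17.tags[0].tag[1:]
        assert assign_tag(bad, panel17, max_mismatch=0) is None


class TestDemultiplex:
    def test_routing_and_undetermined(self):
        sheet = pd.DataFrame(
            {"sample_id": ["S1", "S2"], "index": ["AAAAAAAA", "TTTTTTTT"]}
        )
        recs = [
            _record(header="m 1:N:0:AAAAAAAA"),
            _record(header="m 1:N:0:TTTTTTTT"),
            _record(header="m 1:N:0:GGGGGGGG"),
        ]
        routed = [s for s, _ in demultiplex(recs, sheet)]
        assert routed == ["S1", "S2", None]

    def test_duplicate_indexes_rejected(self):
        sheet = pd.DataFrame({"sample_id": ["S1", "S2"], "index": ["AAAA", "AAAA"]})
        with pytest.raises(PanelError):
            list(demultiplex([], sheet))

    def test_pooled_equals_per_sample_mode(self, tmp_path, panel17):
        kwargs = dict(reads_per_sample=800, seed=21)
        out_a, _, sheet, _ = simulate_small_experiment(tmp_path / "per", panel17, **kwargs)
        out_b, _, _, _ = simulate_small_experiment(
            tmp_path / "pool", panel17, pooled=True, **kwargs
        )
        fastqs = {s: out_a / f"{s}.fastq.gz" for s in sheet["sample_id"]}
        cm_per = count_tags(fastqs, panel17, sheet)
        cm_pool = count_tags(out_b / "pooled.fastq.gz", panel17, sheet)
        pd.testing.assert_frame_equal(cm_per.counts, cm_pool.counts)
        pd.testing.assert_frame_equal(cm_per.accounting, cm_pool.accounting)


def _ledger_pivot(ledger, scfv_ids):
    return (
        ledger.pivot(index="sample_id", columns="scfv_id", values="reads_emitted")
        .loc[:, scfv_ids]
        .astype(np.int64)
    )


class TestCountTags:
    def test_error_free_oracle_equals_ledger(self, tmp_path, panel17):
        out, ledger, sheet, _ = simulate_small_experiment(
            tmp_path, panel17, reads_per_sample=2000,
            sub_error_rate=0.0, chastity_fail_rate=0.0, q_lo_frac=0.0,
        )
        fastqs = {s: out / f"{s}.fastq.gz" for s in sheet["sample_id"]}
        cm = count_tags(fastqs, panel17, sheet)
        truth = _ledger_pivot(ledger, panel17.scfv_ids)
        pd.testing.assert_frame_equal(
            cm.counts, truth, check_names=False
        )
        assert (cm.accounting["unassigned"] == 0).all()

    def test_all_chastity_failed_gives_zero_rows(self, tmp_path, panel17):
        out, _, sheet, _ = simulate_small_experiment(
            tmp_path, panel17, reads_per_sample=500,
            sub_error_rate=0.0, chastity_fail_rate=1.0, q_lo_frac=0.0,
        )
        fastqs = {s: out / f"{s}.fastq.gz" for s in sheet["sample_id"]}
        cm = count_tags(fastqs, panel17, sheet)
        assert (cm.counts.to_numpy() == 0).all()
        assert (cm.accounting["chastity_failed"] == cm.accounting["total_reads"]).all()

    def test_conservation_partition_on_noisy_input(self, tmp_path, panel17):
        out, _, sheet, _ = simulate_small_experiment(
            tmp_path, panel17, reads_per_sample=1500,
            sub_error_rate=0.02, chastity_fail_rate=0.05,
        )
        fastqs = {s: out / f"{s}.fastq.gz" for s in sheet["sample_id"]}
        cm = count_tags(fastqs, panel17, sheet)
        cm.check_conservation()  # raises on violation
        parts = cm.accounting[
            ["assigned", "chastity_failed", "quality_failed", "too_short", "unassigned"]
        ].sum(axis=1)
        assert (parts == cm.accounting["total_reads"]).all()

    def test_stream_order_invariance(self, tmp_path, panel17):
        out, _, sheet, _ = simulate_small_experiment(
            tmp_path, panel17, reads_per_sample=600, sub_error_rate=0.01
        )
        sample = sheet["sample_id"].iloc[0]
        fq = out / f"{sample}.fastq.gz"
        with gzip.open(fq, "rt") as fh:
            lines = fh.read().splitlines()
        records = [lines[i : i + 4] for i in range(0, len(lines), 4)]
        random.Random(0).shuffle(records)
        shuffled = tmp_path / "shuffled.fastq"
        shuffled.write_text("\n".join("\n".join(r) for r in records) + "\n")
        one = sheet[sheet["sample_id"] == sample]
        cm_a = count_tags({sample: fq}, panel17, one)
        cm_b = count_tags({sample: shuffled}, panel17, one)
        pd.testing.assert_frame_equal(cm_a.counts, cm_b.counts)
        pd.testing.assert_frame_equal(cm_a.accounting, cm_b.accounting)

    def test_raising_min_phred_never_increases_counts(self, tmp_path, panel17):
        out, _, sheet, _ = simulate_small_experiment(
            tmp_path, panel17, reads_per_sample=1000, sub_error_rate=0.01
        )
        fastqs = {s: out / f"{s}.fastq.gz" for s in sheet["sample_id"]}
        prev = None
        for thr in (10, 30, 38):
            cm = count_tags(fastqs, panel17, sheet, QCParams(min_phred=thr))
            if prev is not None:
                assert (cm.counts.to_numpy() <= prev).all()
            prev = cm.counts.to_numpy()

    def test_sample_with_no_reads_gets_zero_row(self, tmp_path, panel17):
        out, _, sheet, _ = simulate_small_experiment(
            tmp_path, panel17, reads_per_sample=200
        )
        extra = pd.concat(
            [sheet, pd.DataFrame([{"sample_id": "S99", "index": "GGGGCCCC",
                                   "group_label": "control", "replicate_id": "r1"}])],
            ignore_index=True,
        )
        fastqs = {s: out / f"{s}.fastq.gz" for s in sheet["sample_id"]}
        cm = count_tags(fastqs, panel17, extra)
        assert cm.counts.loc["S99"].sum() == 0
        assert cm.accounting.loc["S99", "total_reads"] == 0

    def test_tsv_roundtrip(self, tmp_path, panel17):
        out, _, sheet, _ = simulate_small_experiment(tmp_path, panel17, reads_per_sample=400)
        fastqs = {s: out / f"{s}.fastq.gz" for s in sheet["sample_id"]}
        cm = count_tags(fastqs, panel17, sheet)
        path = tmp_path / "counts.tsv"
        cm.to_tsv(path)
        from promis.count import CountMatrix

        back = CountMatrix.from_tsv(path)
        pd.testing.assert_frame_equal(back.counts, cm.counts, check_names=False)
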