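"""Read QC, demultiplexing, tag scanning, junction calling and UMI dedup."""

import itertools

import numpy as np
import pytest

from tcrdiv import clonocall, simkit
from tcrdiv.clonocall import (AdapterLayout, IncoherentJunctionError,
                              JunctionCall, Repertoire, TagEntry, TagLibrary,
                              assess_productivity, build_repertoire,
                              build_tag_library, call_cdr3, dedup_umis,
                              demultiplex_and_parse_umi, find_conformation,
                              qc_filter, scan_tags)
from tcrdiv.simkit import GermlineSegment

from conftest import make_simple_pair


@pytest.fixture(scope="module")
def layout():
    return AdapterLayout(validation_barcode="ACTG",
                         library_id_map={"AACC": "S1", "GGTT": "S2"})


class TestQCFilter:
    def test_clean_250bp_pair_passes(self):
        ok, reason = qc_filter(make_simple_pair("A" * 250, "C" * 250, qual=30))
        assert ok and reason is None

    def test_single_q20_base_fails_strict_rule(self):
        pair = clonocall.ReadPair("r", "A" * 250, [30] * 249 + [20],
                                  "C" * 250, [30] * 250)
        ok, reason = qc_filter(pair)
        assert not ok and reason == "quality"

    def test_short_mate_fails_on_length(self):
        ok, reason = qc_filter(make_simple_pair("A" * 200, "C" * 250))
        assert not ok and reason == "length"

    def test_malformed_record_names_the_read(self):
        pair = clonocall.ReadPair("bad_read", "A" * 250, [30] * 10,
                                  "C" * 250, [30] * 250)
        with pytest.raises(ValueError, match="bad_read"):
            qc_filter(pair)


class TestDemux:
    def test_umi_concatenation_mate1_first(self, layout):
        pair = make_simple_pair("ACTG" + "AAAAAA" + "AACC" + "G" * 236,
                                "ACTG" + "CCCCCC" + "AACC" + "T" * 236)
        sample, umi12, trimmed, reason = demultiplex_and_parse_umi(pair, layout)
        assert (sample, umi12) == ("S1", "AAAAAACCCCCC")
        assert trimmed == "G" * 236 and reason is None

    def test_corrupted_validation_barcode_discarded(self, layout):
        pair = make_simple_pair("TTTG" + "AAAAAA" + "AACC" + "G" * 236,
                                "ACTG" + "CCCCCC" + "AACC" + "T" * 236)
        assert demultiplex_and_parse_umi(pair, layout)[3] == "invalid_barcode"

    def test_unknown_library_id_routed_to_undetermined(self, layout):
        pair = make_simple_pair("ACTG" + "AAAAAA" + "TTTT" + "G" * 236,
                                "ACTG" + "CCCCCC" + "TTTT" + "T" * 236)
        assert demultiplex_and_parse_umi(pair, layout)[3] == "unknown_library"

    def test_close_library_ids_rejected(self):
        with pytest.raises(ValueError, match="Hamming"):
            AdapterLayout(validation_barcode="ACTG",
                          library_id_map={"AAAA": "S1", "AAAT": "S2"})

    def test_simulated_pairs_assign_to_correct_sample(self, trb_segments):
        reps = {}
        truths = []
        for i, sid in enumerate(["S1", "S2", "S3"]):
            rep, truth = simkit.simulate_repertoire(
                simkit.RepertoireSpec(n_clonotypes=20, total_rearrangements=40,
                                      seed=20 + i),
                trb_segments, sample_id=sid)
            reps[sid] = rep
            truths.append(truth)
        layout = simkit.default_layout(list(reps))
        import pandas as pd

        reads, read_truth = simkit.simulate_reads(
            pd.concat(truths, ignore_index=True),
            simkit.ReadSimSpec(error_rate=0.0, seed=1), layout)
        truth_sample = dict(zip(read_truth.read_id, read_truth.sample_id))
        for pair in simkit.reads_as_pairs(reads):
            sample, _, _, _ = demultiplex_and_parse_umi(pair, layout)
            assert sample == truth_sample[pair.read_id]


class TestTagLibrary:
    def test_tags_cover_segments_and_are_20mers(self, trb_segments, trb_tags):
        assert all(len(e.tag) == 20 for e in trb_tags.entries)
        tagged = {e.element for e in trb_tags.entries}
        assert tagged == {s.name for s in trb_segments}
        # random toy references produce no shared tags
        assert not any(e.is_rtag for e in trb_tags.entries)

    def test_tag_offset_15bp_from_rss(self, trb_segments, trb_tags):
        segs = {s.name: s for s in trb_segments}
        for e in trb_tags.entries:
            seg = segs[e.element]
            if e.segment_class == "V" and e.flank == "coding":
                assert seg.sequence[seg.rss_position - 35:seg.rss_position - 15] == e.tag
            elif e.segment_class == "J" and e.flank == "coding":
                assert seg.sequence[seg.rss_position + 15:seg.rss_position + 35] == e.tag

    def test_tsv_roundtrip(self, trb_tags, tmp_path):
        trb_tags.to_tsv(tmp_path / "tags.tsv")
        back = TagLibrary.from_tsv(tmp_path / "tags.tsv")
        assert back.entries == trb_tags.entries


@pytest.fixture(scope="module")
def rtag_segments():
    """Two V segments sharing their coding-tag window but diverging upstream,
    plus a J: forces an rtag with alt-tag resolution."""
    rng = np.random.default_rng(77)
    bases = "ACGT"
    shared_55 = "".join(rng.choice(list(bases), size=55))
    segs = []
    for i, name in enumerate(("TRGV1", "TRGV2")):
        # distinct 35-mer head (divergence upstream of the tag), shared tail
        head = "".join(rng.choice(list(bases), size=35))
        coding = (head + shared_55)[:90]
        # keep frame-0 codons stop-free irrelevant here; not used for frames
        seq = coding + "".join(rng.choice(list(bases), size=40))
        segs.append(GermlineSegment(name=name, locus="TRG", segment_class="V",
                                    sequence=seq, rss_position=90, coding_frame=0))
    j = simkit.make_germline_reference(1, 0, 1, "TRG", seed=5)[-1]
    segs.append(j)
    return segs


class TestTagScanning:
    def test_v_and_j_tags_form_coding_conformation(self, trb_segments, trb_tags):
        v = next(s for s in trb_segments if s.segment_class == "V")
        j = next(s for s in trb_segments if s.segment_class == "J")
        read = v.sequence[:v.rss_position] + j.sequence[j.rss_position:]
        conf = find_conformation(scan_tags(read, trb_tags))
        assert conf is not None
        category, vh, jh = conf
        assert category == "coding"
        assert (vh.entry.element, jh.entry.element) == (v.name, j.name)

    def test_v_tag_alone_is_insufficient(self, trb_segments, trb_tags):
        v = next(s for s in trb_segments if s.segment_class == "V")
        assert find_conformation(scan_tags(v.sequence[:v.rss_position], trb_tags)) is None

    def test_signal_flank_tags_form_signal_conformation(self, trb_segments, trb_tags):
        v = next(s for s in trb_segments if s.segment_class == "V")
        j = next(s for s in trb_segments if s.segment_class == "J")
        read = j.sequence[:j.rss_position] + v.sequence[v.rss_position:]
        conf = find_conformation(scan_tags(read, trb_tags))
        assert conf is not None and conf[0] == "signal"

    def test_rtag_marked_and_resolved_via_alt_tag(self, rtag_segments):
        tags = build_tag_library(rtag_segments)
        rtags = [e for e in tags.entries if e.is_rtag]
        assert len(rtags) == 2  # one per sharing V segment
        assert all(e.alt_tag is not None for e in rtags)

        def brute_force_owner(read, vpos):
            # align the read around the tag against every V reference and
            # pick the segment with the strictly longest exact extension
            best, best_len = None, -1
            for seg in rtag_segments:
                if seg.segment_class != "V":
                    continue
                start = seg.rss_position - 35
                k = 0
                while (vpos - k - 1 >= 0 and start - k - 1 >= 0
                       and read[vpos - k - 1] == seg.sequence[start - k - 1]):
                    k += 1
                if k > best_len:
                    best, best_len = seg.name, k
                elif k == best_len:
                    best = None
            return best

        rng = np.random.default_rng(3)
        vsegs = [s for s in rtag_segments if s.segment_class == "V"]
        for i in range(100):
            v = vsegs[i % 2]
            read = v.sequence[:v.rss_position] + "".join(
                rng.choice(list("ACGT"), size=30))
            hits = [h for h in scan_tags(read, tags)
                    if h.entry.segment_class == "V" and h.entry.flank == "coding"]
            assert len(hits) == 1 and hits[0].via_rtag and not hits[0].ambiguous
            assert hits[0].entry.element == v.name
            assert brute_force_owner(read, hits[0].position) == v.name


@pytest.fixture(scope="module")
def toy_vj():
    """Hand-built V and J with frame 0 at both sides of the junction."""
    v = GermlineSegment(name="Vt", locus="TRG", segment_class="V",
                        sequence="ATG" + "GCT" * 29 + "A" * 40,
                        rss_position=90, coding_frame=0)
    j = GermlineSegment(name="Jt", locus="TRG", segment_class="J",
                        sequence="C" * 40 + "GGT" * 23 + "G",
                        rss_position=40, coding_frame=0)
    return v, j


class TestProductivity:
    def test_frame_preserving_junction_no_stop_is_productive(self, toy_vj):
        v, j = toy_vj
        assert assess_productivity(v, "GGGCCC", j) == (True, None)

    def test_one_base_shift_is_out_of_frame(self, toy_vj):
        v, j = toy_vj
        assert assess_productivity(v, "GGGC", j) == (False, "out-of-frame")

    def test_in_frame_stop_is_nonproductive(self, toy_vj):
        v, j = toy_vj
        assert assess_productivity(v, "TAAGGG", j) == (False, "stop")

    def test_missing_frame_annotation_is_config_error(self, toy_vj):
        v, j = toy_vj
        d = GermlineSegment(name="Dt", locus="TRB", segment_class="D",
                            sequence="A" * 30, rss_position=0, coding_frame=None)
        with pytest.raises(ValueError, match="coding_frame"):
            assess_productivity(d, "GGG", j)


class TestJunctionCalling:
    def test_no_edit_read_recovers_exact_truth_junction(self, trb_segments, trb_tags):
        v = next(s for s in trb_segments if s.segment_class == "V")
        j = next(s for s in trb_segments if s.segment_class == "J")
        insert = "ACGACT"
        read = v.sequence[:v.rss_position] + insert + j.sequence[j.rss_position:]
        _, vh, jh = find_conformation(scan_tags(read, trb_tags))
        call = call_cdr3(read, vh, jh, trb_tags, {s.name: s for s in trb_segments})
        assert call.cdr3_nt == insert
        assert (call.v_name, call.j_name) == (v.name, j.name)

    def test_divergence_before_cleavage_moves_boundary(self, trb_segments, trb_tags):
        v = next(s for s in trb_segments if s.segment_class == "V")
        j = next(s for s in trb_segments if s.segment_class == "J")
        # trim 2 germline bases from the V end; pick an insert that cannot
        # chance-match the trimmed reference bases
        trimmed = v.sequence[v.rss_position - 2:v.rss_position]
        first = "A" if trimmed[0] != "A" else "C"
        insert = first + "GGCCA"
        read = v.sequence[:v.rss_position - 2] + insert + j.sequence[j.rss_position:]
        _, vh, jh = find_conformation(scan_tags(read, trb_tags))
        call = call_cdr3(read, vh, jh, trb_tags, {s.name: s for s in trb_segments})
        assert call.cdr3_nt.startswith(insert[:1])
        assert call.v_end == v.rss_position - 2

    def test_simulated_junctions_match_truth_on_1000_reads(self, trb_segments, trb_tags):
        import pandas as pd

        rep, truth = simkit.simulate_repertoire(
            simkit.RepertoireSpec(n_clonotypes=300, total_rearrangements=1000, seed=8),
            trb_segments, sample_id="S1")
        layout = simkit.default_layout(["S1"])
        reads, read_truth = simkit.simulate_reads(
            truth, simkit.ReadSimSpec(pcr_duplication_mean=0.0, error_rate=0.0, seed=9),
            layout)
        assert len(reads) >= 1000
        calls, report = clonocall.process_read_pairs(
            simkit.reads_as_pairs(reads), layout, trb_tags, trb_segments)
        truth_junction = dict(zip(read_truth.read_id,
                                  zip(read_truth.v_call, read_truth.junction,
                                      read_truth.j_call)))
        assert report["bins"]["called_coding"] == len(reads)
        for c in calls:
            assert c.clonotype == truth_junction[c.read_id]


class TestDedup:
    def test_two_mismatch_umis_merge(self):
        assert dedup_umis(["AAAAAAAAAAAA", "AAAAAAAAAATT"])[0] == 1

    def test_distant_umis_stay_separate(self):
        assert dedup_umis(["AAAAAAAAAAAA", "TTTTTTTTTTTT"])[0] == 2

    def test_wrong_length_umi_rejected(self):
        with pytest.raises(ValueError, match="12"):
            dedup_umis(["AAAA"])

    def test_counts_equal_connected_components_oracle(self):
        def oracle(umis):
            uniq = list(dict.fromkeys(umis))
            seen, n = set(), 0
            adj = {u: [v for v in uniq if v != u
                       and sum(a != b for a, b in zip(u, v)) <= 2] for u in uniq}
            for u in uniq:
                if u in seen:
                    continue
                n += 1
                stack = [u]
                while stack:
                    x = stack.pop()
                    if x in seen:
                        continue
                    seen.add(x)
                    stack.extend(adj[x])
            return n

        rng = np.random.default_rng(0)
        for trial in range(50):
            k = int(rng.integers(1, 9))
            # low-cardinality alphabet makes near-collisions frequent
            umis = ["".join(rng.choice(["A", "C"], size=12)) for _ in range(k)]
            n, clusters = dedup_umis(umis)
            assert n == oracle(umis)
            assert n == len(set(clusters.values()))

    def test_adding_pcr_duplicates_never_changes_count(self, rng):
        umis = ["".join(rng.choice(list("ACGT"), size=12)) for _ in range(6)]
        base, _ = dedup_umis(umis)
        assert dedup_umis(umis + umis * 3)[0] == base


def _call(sample="S1", v="TRBV1", cdr3="AAA", j="TRBJ1", umi="AAAAAAAAAAAA",
          locus="TRB", productive=True, category="coding", read_id="r"):
    return JunctionCall(sample_id=sample, v_name=v, j_name=j, cdr3_nt=cdr3,
                        locus=locus, category=category, productive=productive,
                        umi12=umi, read_id=read_id)


class TestBuildRepertoire:
    def test_counts_by_clonotype(self):
        calls = [_call(umi="A" * 12, read_id="r1"),
                 _call(umi="C" * 12, read_id="r2"),
                 _call(umi="G" * 12, read_id="r3"),
                 _call(cdr3="CCC", umi="T" * 12, read_id="r4")]
        rep = build_repertoire(calls)
        assert rep.counts == {("TRBV1", "AAA", "TRBJ1"): 3,
                              ("TRBV1", "CCC", "TRBJ1"): 1}

    def test_delta_locus_and_nonproductive_and_signal_excluded(self):
        calls = [_call(),
                 _call(locus="TRD", v="TRDV1", umi="C" * 12),
                 _call(productive=False, cdr3="GGG", umi="G" * 12),
                 _call(category="signal", cdr3="", umi="T" * 12)]
        rep = build_repertoire(calls, sample_id="S1")
        assert rep.counts == {("TRBV1", "AAA", "TRBJ1"): 1}

    def test_mixed_samples_rejected(self):
        with pytest.raises(ValueError, match="sample"):
            build_repertoire([_call(sample="S1"), _call(sample="S2")])

    def test_airr_tsv_roundtrip(self, tmp_path):
        rep = build_repertoire([_call(umi="A" * 12), _call(umi="T" * 12),
                                _call(cdr3="CCC", umi="G" * 12)], sample_id="S1")
        rep.to_airr(tmp_path / "s1.tsv")
        back = Repertoire.from_airr(tmp_path / "s1.tsv", sample_id="S1")
        assert back.counts == rep.counts


class TestConservation:
    def test_every_pair_lands_in_exactly_one_bin(self, trb_segments, trb_tags):
        rep, truth = simkit.simulate_repertoire(
            simkit.RepertoireSpec(n_clonotypes=20, total_rearrangements=40, seed=30),
            trb_segments, sample_id="S1")
        layout = simkit.default_layout(["S1"])
        reads, _ = simkit.simulate_reads(truth, simkit.ReadSimSpec(seed=31), layout)
        pairs = simkit.reads_as_pairs(reads)
        # corrupt a few pairs in distinct ways
        p0 = pairs[0]
        pairs[0] = clonocall.ReadPair(p0.read_id, "T" * 250, [30] * 250,
                                      p0.seq2, list(p0.qual2))  # bad barcode
        p1 = pairs[1]
        pairs[1] = clonocall.ReadPair(p1.read_id, p1.seq1, [10] * 250,
                                      p1.seq2, list(p1.qual2))  # low quality
        p2 = pairs[2]
        pairs[2] = clonocall.ReadPair(p2.read_id, p2.seq1[:100], [40] * 100,
                                      p2.seq2, list(p2.qual2))  # short
        calls, report = clonocall.process_read_pairs(pairs, layout, trb_tags,
                                                     trb_segments)
        assert report["conserved"]
        assert sum(report["bins"].values()) == report["n_input"] == len(pairs)
        for bin_name in ("invalid_barcode", "qc_fail_quality", "qc_fail_length"):
            assert report["bins"][bin_name] >= 1
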