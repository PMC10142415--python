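"""Hash-read parsing, barcode correction, UMI collapse, and FASTQ counting."""

from __future__ import annotations

import itertools
from collections import Counter, defaultdict
from dataclasses import replace

import numpy as np
import pytest
from Bio import SeqIO
from hypothesis import given, settings, strategies as st

import nuhash as nh
from nuhash.counting import ParseStatus, WhitelistIndex, collapse_group


def ham(a, b):
    return sum(x != y for x, y in zip(a, b))


def mutate(seq, positions, base="N"):
    """Substitute at given positions with a base guaranteed to mismatch."""
    out = list(seq)
    for p in positions:
        out[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[p]]
    return "".join(out)


WHITELIST = ["ACGTACGTACGTACGT", "TTTTCCCCGGGGAAAA", "ACACACACACACACAC"]


def build_read(design, sample_idx=0, umi1="AAAAAAAA", umi2="CCCCCCCC",
               offset_pad="", anchor5=None):
    a5 = design.anchor5 if anchor5 is None else anchor5
    return (offset_pad + a5 + umi1 + design.barcodes[sample_idx].sequence
            + umi2 + design.anchor3)


class TestParseHashRead:
    def test_exact_read_is_valid(self, design):
        wl = WhitelistIndex(WHITELIST, tol=0)
        read = build_read(design)
        parsed = nh.parse_hash_read(read, WHITELIST[0], design, wl)
        assert parsed.status is ParseStatus.VALID
        assert parsed.sample_id == design.barcodes[0].sample_id
        assert parsed.umi == "AAAAAAAA" + "CCCCCCCC"
        assert parsed.corrected_cell_barcode == WHITELIST[0]

    def test_anchor_beyond_tolerance(self, design):
        wl = WhitelistIndex(WHITELIST)
        bad5 = mutate(design.anchor5, [0, 4, 8])  # 3 mismatches, tol 2
        read = build_read(design, anchor5=bad5)
        parsed = nh.parse_hash_read(read, WHITELIST[0], design, wl)
        assert parsed.status is ParseStatus.NO_ANCHOR

    @pytest.mark.parametrize("pad", ["", "G", "TG", "ATG"])
    def test_anchor_offset_window(self, design, pad):
        wl = WhitelistIndex(WHITELIST)
        read = build_read(design, offset_pad=pad)
        parsed = nh.parse_hash_read(read, WHITELIST[0], design, wl)
        assert parsed.status is ParseStatus.VALID

    def test_offset_beyond_window_fails(self, design):
        wl = WhitelistIndex(WHITELIST)
        read = build_read(design, offset_pad="ATTG")
        assert nh.parse_hash_read(read, WHITELIST[0], design, wl).status \
            is ParseStatus.NO_ANCHOR

    def test_hash_mismatch_within_tolerance_matches_neighborhood_oracle(self, design):
        """Hamming-1 barcode field maps to the sample whose distance-<=1
        neighborhood (enumerated exhaustively) contains it."""
        wl = WhitelistIndex(WHITELIST)
        bc = design.barcodes[1].sequence
        field = mutate(bc, [3])
        # oracle: enumerate every sequence within distance 1 of each barcode
        owners = []
        for b in design.barcodes:
            neighborhood = {b.sequence} | {
                b.sequence[:i] + x + b.sequence[i + 1:]
                for i in range(len(b.sequence)) for x in "ACGT"}
            if field in neighborhood:
                owners.append(b.sample_id)
        assert owners == [design.barcodes[1].sample_id]
        read = (design.anchor5 + "AAAAAAAA" + field + "CCCCCCCC"
                + design.anchor3)
        parsed = nh.parse_hash_read(read, WHITELIST[0], design, wl)
        assert parsed.status is ParseStatus.VALID
        assert parsed.sample_id == owners[0]

    def test_unknown_hash(self, design):
        wl = WhitelistIndex(WHITELIST)
        field = mutate(design.barcodes[0].sequence, [0, 1, 2])  # distance 3 > tol 1
        read = design.anchor5 + "A" * 8 + field + "C" * 8 + design.anchor3
        assert nh.parse_hash_read(read, WHITELIST[0], design, wl).status \
            is ParseStatus.UNKNOWN_HASH

    def test_status_order_anchor_before_cell(self, design):
        wl = WhitelistIndex(WHITELIST)
        bad5 = mutate(design.anchor5, [0, 4, 8])
        read = build_read(design, anchor5=bad5)
        parsed = nh.parse_hash_read(read, "G" * 16, design, wl)
        assert parsed.status is ParseStatus.NO_ANCHOR  # not unknown_cell


class TestCellCorrection:
    def test_exact_member_identity(self):
        assert nh.correct_cell_barcode(WHITELIST[0], WHITELIST, tol=1) == WHITELIST[0]

    def test_unique_neighbor_corrected(self):
        raw = mutate(WHITELIST[0], [5])
        # brute-force oracle over the whitelist
        hits = [w for w in WHITELIST if ham(w, raw) <= 1]
        assert hits == [WHITELIST[0]]
        assert nh.correct_cell_barcode(raw, WHITELIST, tol=1) == WHITELIST[0]

    def test_tie_is_ambiguous(self):
        wl = ["AAAA", "AATA"]
        raw = "AACA"  # distance 1 from both
        assert nh.correct_cell_barcode(raw, wl, tol=1) is None
        _, status = WhitelistIndex(wl, tol=1).correct(raw)
        assert status is ParseStatus.AMBIGUOUS_CELL

    def test_no_member_unknown(self):
        _, status = WhitelistIndex(WHITELIST, tol=1).correct("G" * 16)
        assert status is ParseStatus.UNKNOWN_CELL

    @given(st.integers(0, 2 ** 32 - 1))
    @settings(max_examples=50, derandomize=True)
    def test_wildcard_index_agrees_with_linear_scan(self, seed):
        rng = np.random.default_rng(seed)
        wl = ["".join("ACGT"[i] for i in rng.integers(0, 4, 8))
              for _ in range(20)]
        wl = list(dict.fromkeys(wl))
        raw = "".join("ACGT"[i] for i in rng.integers(0, 4, 8))
        fast = WhitelistIndex(wl, tol=1).correct(raw)
        dists = sorted((ham(w, raw), w) for w in wl)
        dmin = dists[0][0]
        nearest = [w for d, w in dists if d == dmin]
        if raw in wl:
            assert fast == (raw, None)
        elif dmin > 1:
            assert fast == (None, ParseStatus.UNKNOWN_CELL)
        elif len(nearest) == 1:
            assert fast == (nearest[0], None)
        else:
            assert fast == (None, ParseStatus.AMBIGUOUS_CELL)


def directional_reference(counts: dict[str, int]) -> int:
    """Independent all-pairs directional-network implementation."""
    order = sorted(counts, key=lambda u: (-counts[u], u))
    edges = defaultdict(list)
    for a, b in itertools.permutations(counts, 2):
        if ham(a, b) == 1 and counts[a] >= 2 * counts[b] - 1:
            edges[a].append(b)
    seen, n = set(), 0
    for u in order:
        if u in seen:
            continue
        n += 1
        stack = [u]
        seen.add(u)
        while stack:
            for v in edges[stack.pop()]:
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
    return n


class TestUmiCollapse:
    def test_identical_umis_count_once(self):
        counts = nh.collapse_umis([("C1", "S1", "AAAA")] * 5)
        assert counts == {("C1", "S1"): 1}

    def test_directional_absorbs_error_umi(self):
        triples = [("C1", "S1", "AAAA")] * 100 + [("C1", "S1", "AAAT")]
        assert directional_reference({"AAAA": 100, "AAAT": 1}) == 1
        assert nh.collapse_umis(triples) == {("C1", "S1"): 1}

    def test_distant_umis_not_merged(self):
        triples = [("C1", "S1", "AAAA")] * 3 + [("C1", "S1", "TTTT")] * 2
        assert nh.collapse_umis(triples) == {("C1", "S1"): 2}

    def test_exact_mode_keeps_neighbors(self):
        triples = [("C1", "S1", "AAAA")] * 100 + [("C1", "S1", "AAAT")]
        assert nh.collapse_umis(triples, method="exact") == {("C1", "S1"): 2}

    def test_balanced_neighbors_not_absorbed(self):
        # 2 >= 2*2 - 1 is false: equal-count neighbours stay separate
        assert collapse_group({"AAAA": 2, "AAAT": 2}) == 2
        assert collapse_group({"AAAA": 3, "AAAT": 2}) == 1

    @given(st.dictionaries(st.text(alphabet="AC", min_size=4, max_size=4),
                           st.integers(1, 30), min_size=1, max_size=12))
    @settings(max_examples=200, derandomize=True)
    def test_matches_directional_reference(self, counts):
        assert collapse_group(counts) == directional_reference(counts)


# ---------------------------------------------------------------------------
# FASTQ-level counting
# ---------------------------------------------------------------------------

def naive_count_hashes(sim, design):
    """Quadratic reference: independent FASTQ parser (Biopython), linear
    whitelist scans, all-pairs directional collapse."""
    reads = {}
    for key, path in (("r1", sim.fastq_r1), ("r2", sim.fastq_r2),
                      ("i", sim.fastq_index)):
        reads[key] = [(r.id, str(r.seq)) for r in SeqIO.parse(
            __import__("gzip").open(path, "rt"), "fastq")]
    whitelist = [l.strip() for l in open(sim.whitelist) if l.strip()]

    def correct_cell(raw):
        if raw in whitelist:
            return raw
        dists = sorted((ham(w, raw), w) for w in whitelist)
        if dists[0][0] > design.cell_mismatch_tol:
            return None
        nearest = [w for d, w in dists if d == dists[0][0]]
        return nearest[0] if len(nearest) == 1 else None

    def parse_one(seq):
        for off in range(4):
            window = seq[off:off + len(design.anchor5)]
            if (len(seq) - off >= design.layout_len
                    and len(window) == len(design.anchor5)
                    and ham(window, design.anchor5) <= design.anchor_mismatch_tol):
                pos = off + len(design.anchor5)
                umi1 = seq[pos:pos + design.umi1_len]
                bc = seq[pos + design.umi1_len:
                         pos + design.umi1_len + design.barcode_len]
                umi2 = seq[pos + design.umi1_len + design.barcode_len:
                           pos + design.umi1_len + design.barcode_len
                           + design.umi2_len]
                tail = pos + design.umi1_len + design.barcode_len + design.umi2_len
                if design.anchor3 and ham(
                        seq[tail:tail + len(design.anchor3)],
                        design.anchor3) > design.anchor_mismatch_tol:
                    return None
                dists = sorted((ham(b.sequence, bc), b.sample_id)
                               for b in design.barcodes)
                if dists[0][0] > design.hash_mismatch_tol:
                    return None
                nearest = [s for d, s in dists if d == dists[0][0]]
                return (nearest[0], umi1 + umi2) if len(nearest) == 1 else None
        return None

    rc = str.maketrans("ACGTN", "TGCAN")
    groups = defaultdict(Counter)
    for (n1, s1), (_, s2), (_, si) in zip(reads["r1"], reads["r2"], reads["i"]):
        hit = parse_one(s1) or parse_one(s2.translate(rc)[::-1])
        cell = correct_cell(si)
        if hit and cell:
            groups[(cell, hit[0])][hit[1]] += 1
    return {key: directional_reference(cnt) for key, cnt in groups.items()}


class TestCountHashes:
    def test_conservation_and_dedup_on_clean_run(self, clean_sim, clean_matrix):
        stats = clean_matrix.parse_stats
        assert stats["no_anchor"] == 0  # zero error rate
        assert sum(stats[s.value] for s in ParseStatus) == stats["total"]
        assert stats["total"] == int(clean_sim.truth.n_hash_reads.sum())
        # unique random 16-base UMIs: essentially no collapse expected
        assert clean_matrix.counts.sum() <= clean_matrix.raw_read_counts.sum()
        assert (clean_matrix.counts <= clean_matrix.raw_read_counts).all()

    def test_pcr_duplicates_collapse(self, design, tmp_path):
        """Duplicating every record doubles raw counts, not molecule counts."""
        import gzip as gz
        config = replace(nh.barnyard_config(10, 2, seed=3),
                         doublet_rate=0.0, ambient_fraction=0.0,
                         base_error_rate=0.0, hash_depth_mean=30.0)
        sim = nh.simulate_experiment(config, design, tmp_path / "base")
        single = nh.count_hashes(sim.fastq_r1, sim.fastq_r2, sim.fastq_index,
                                 sim.whitelist, design)
        dup_dir = tmp_path / "dup"
        dup_dir.mkdir()
        for src in (sim.fastq_r1, sim.fastq_r2, sim.fastq_index):
            records = []
            with gz.open(src, "rt") as fh:
                lines = fh.read().splitlines()
            for i in range(0, len(lines), 4):
                rec = lines[i:i + 4]
                records.append(rec)
                records.append([rec[0] + "_dup"] + rec[1:])
            with gz.open(dup_dir / src.name, "wt") as fh:
                fh.write("".join("\n".join(r) + "\n" for r in records))
        doubled = nh.count_hashes(dup_dir / sim.fastq_r1.name,
                                  dup_dir / sim.fastq_r2.name,
                                  dup_dir / sim.fastq_index.name,
                                  sim.whitelist, design)
        assert doubled.raw_read_counts.sum() == 2 * single.raw_read_counts.sum()
        assert doubled.counts.sum() == single.counts.sum()

    def test_matches_naive_reference_on_small_noisy_input(self, design, tmp_path):
        config = replace(nh.barnyard_config(8, 4, seed=7),
                         hash_depth_mean=12.0, ambient_fraction=0.2,
                         base_error_rate=0.01, doublet_rate=0.2)
        sim = nh.simulate_experiment(config, design, tmp_path)
        assert int(sim.truth.n_hash_reads.sum()) <= 500
        matrix = nh.count_hashes(sim.fastq_r1, sim.fastq_r2, sim.fastq_index,
                                 sim.whitelist, design)
        oracle = naive_count_hashes(sim, design)
        got = {(c, s): int(matrix.counts[i, j])
               for i, c in enumerate(matrix.cell_barcodes)
               for j, s in enumerate(matrix.sample_ids)
               if matrix.counts[i, j]}
        assert got == oracle

    def test_tolerance_monotonicity(self, design, tmp_path):
        """Loosening any mismatch tolerance never loses valid reads."""
        config = replace(nh.barnyard_config(30, 2, seed=5),
                         hash_depth_mean=20.0, base_error_rate=0.03)
        sim = nh.simulate_experiment(config, design, tmp_path)
        valid = {}
        for anchor_tol, cell_tol, hash_tol in [(0, 0, 0), (1, 1, 1), (2, 1, 1)]:
            d = design.with_tolerances(hash_tol=hash_tol, cell_tol=cell_tol,
                                       anchor_tol=anchor_tol)
            m = nh.count_hashes(sim.fastq_r1, sim.fastq_r2, sim.fastq_index,
                                sim.whitelist, d)
            valid[(anchor_tol, cell_tol, hash_tol)] = m.parse_stats["valid"]
        assert valid[(0, 0, 0)] <= valid[(1, 1, 1)] <= valid[(2, 1, 1)]

    def test_desynchronized_streams_hard_error(self, clean_sim, design, tmp_path):
        import gzip as gz
        truncated = tmp_path / "r2_short.fastq.gz"
        with gz.open(clean_sim.fastq_r2, "rt") as fh:
            lines = fh.read().splitlines()
        with gz.open(truncated, "wt") as fh:
            fh.write("\n".join(lines[:-4]) + "\n")
        with pytest.raises(ValueError, match="desynchronized"):
            nh.count_hashes(clean_sim.fastq_r1, truncated,
                            clean_sim.fastq_index, clean_sim.whitelist, design)

    def test_matrix_round_trips_through_tsv(self, clean_matrix, tmp_path):
        clean_matrix.write_dir(tmp_path)
        back = nh.HashCountMatrix.read_tsv(tmp_path / "hash_counts.tsv")
        assert back.cell_barcodes == clean_matrix.cell_barcodes
        assert back.sample_ids == clean_matrix.sample_ids
        assert (back.counts == clean_matrix.counts).all()
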