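import itertools

import numpy as np
import pytest
from scipy import sparse

import spatialcite as sc
from spatialcite.chip import hamming
from spatialcite.demux import (
    BarcodeMatcher,
    DemuxRecord,
    PixelMatrix,
    Status,
    TranscriptReference,
    count_umi_classes,
    dedup_umis,
    qc_per_pixel,
    qc_summary,
)
from spatialcite.simulate import _assemble_read2


def _sub(seq: str, pos: int) -> str:
    """Substitute the base at pos with a different one."""
    repl = {"A": "C", "C": "G", "G": "T", "T": "A"}
    return seq[:pos] + repl[seq[pos]] + seq[pos + 1 :]


def _read2(design, row, col, umi="ACGTACGTAC"):
    row_seq = dict(design.row_barcodes)[f"A{row}"]
    col_seq = dict(design.col_barcodes)[f"B{col}"]
    return _assemble_read2(design, umi, row_seq, col_seq)


class TestExtractSpatial:
    def test_exact_read_decodes(self, design20):
        seq = _read2(design20, 3, 7)
        pixel, umi, status = sc.extract_spatial(seq, None, design20)
        assert status is Status.OK
        assert pixel == sc.PixelAddress(3, 7)
        assert umi == "ACGTACGTAC"

    def test_single_mismatch_in_row_barcode_corrected(self, design20):
        # brute-force check: the mutated segment is still uniquely nearest
        # to A3 because all row barcodes are pairwise Hamming >= 3 apart
        seq = _read2(design20, 3, 7)
        aseg = design20.segment("barcode_a")
        mutated = seq[: aseg.offset] + _sub(seq[aseg.offset :], 0)
        mut_bc = mutated[aseg.offset : aseg.end]
        dists = sorted(hamming(mut_bc, s) for _, s in design20.row_barcodes)
        assert dists[0] == 1 and dists[1] >= 2
        pixel, _, status = sc.extract_spatial(mutated, None, design20)
        assert status is Status.OK and pixel == sc.PixelAddress(3, 7)

    def test_two_mismatches_in_row_barcode_rejected(self, design20):
        seq = _read2(design20, 3, 7)
        aseg = design20.segment("barcode_a")
        bc = seq[aseg.offset : aseg.end]
        bc = _sub(_sub(bc, 0), 1)
        # only reject if genuinely no row barcode within distance 1
        if min(hamming(bc, s) for _, s in design20.row_barcodes) > 1:
            mutated = seq[: aseg.offset] + bc + seq[aseg.end :]
            pixel, _, status = sc.extract_spatial(mutated, None, design20)
            assert status is Status.NO_ROW_BARCODE and pixel is None

    def test_two_mismatches_in_col_barcode_rejected(self, design20):
        seq = _read2(design20, 3, 7)
        bseg = design20.segment("barcode_b")
        bc = _sub(_sub(seq[bseg.offset : bseg.end], 0), 1)
        if min(hamming(bc, s) for _, s in design20.col_barcodes) > 1:
            mutated = seq[: bseg.offset] + bc + seq[bseg.end :]
            _, _, status = sc.extract_spatial(mutated, None, design20)
            assert status is Status.NO_COL_BARCODE

    def test_short_read_is_low_quality(self, design20):
        _, _, status = sc.extract_spatial("ACGT", None, design20)
        assert status is Status.LOW_QUALITY

    def test_broken_linker_is_low_quality(self, design20):
        seq = _read2(design20, 3, 7)
        lseg = design20.segment("linker")
        broken = (
            seq[: lseg.offset]
            + _sub(_sub(_sub(seq[lseg.offset : lseg.end], 0), 1), 2)
            + seq[lseg.end :]
        )
        _, _, status = sc.extract_spatial(broken, None, design20)
        assert status is Status.LOW_QUALITY

    def test_low_quality_bases_count_as_mismatches(self, design20):
        seq = _read2(design20, 3, 7)
        aseg = design20.segment("barcode_a")
        quals = [40] * len(seq)
        # one untrusted base: still a unique match within distance 1
        quals[aseg.offset] = 2
        pixel, _, status = sc.extract_spatial(seq, quals, design20)
        assert status is Status.OK and pixel == sc.PixelAddress(3, 7)
        # two untrusted bases exceed the correction budget
        quals[aseg.offset + 1] = 2
        _, _, status = sc.extract_spatial(seq, quals, design20)
        assert status is Status.NO_ROW_BARCODE

    def test_tie_between_barcodes_is_ambiguous(self):
        matcher = BarcodeMatcher(["AAAA", "AATT"], max_mismatch=1)
        hit, outcome = matcher.match("AAAT")  # distance 1 from both
        assert hit is None and outcome == "ambiguous"


class TestAssignADT:
    def test_exact_tag(self, panel):
        tag = panel.entries[3].sequence
        feature, status = sc.assign_adt(tag + "A" * 20, panel)
        assert status is Status.OK and feature == panel.entries[3].name

    def test_single_error_corrected(self, panel):
        tag = _sub(panel.entries[3].sequence, 4)
        dists = sorted(hamming(tag, e.sequence) for e in panel.entries)
        assert dists[0] == 1 and dists[1] >= 2
        feature, status = sc.assign_adt(tag + "AAAA", panel)
        assert status is Status.OK and feature == panel.entries[3].name

    def test_poly_a_read_has_no_feature(self, panel):
        feature, status = sc.assign_adt("A" * 40, panel)
        assert feature is None and status is Status.NO_FEATURE


@pytest.fixture(scope="module")
def reference():
    rng = np.random.default_rng(42)
    nuc = np.array(list("ACGT"))
    seqs = {g: "".join(nuc[rng.integers(0, 4, 300)]) for g in ("GENE1", "GENE2")}
    # GENE3 shares an exact 60-base block with GENE2
    seqs["GENE3"] = seqs["GENE2"][:60] + "".join(nuc[rng.integers(0, 4, 240)])
    return TranscriptReference(seqs)


class TestAssignTranscript:

    def test_verbatim_read_maps(self, reference):
        read = reference.gene_seqs["GENE1"][100:150]
        gene, status = sc.assign_transcript(read, reference)
        assert status is Status.OK and gene == "GENE1"

    def test_shared_block_is_ambiguous(self, reference):
        read = reference.gene_seqs["GENE2"][5:55]  # inside the shared block
        gene, status = sc.assign_transcript(read, reference)
        assert status is Status.AMBIGUOUS_FEATURE and gene is None

    def test_random_read_has_no_feature(self, reference):
        rng = np.random.default_rng(7)
        nuc = np.array(list("ACGT"))
        read = "".join(nuc[rng.integers(0, 4, 50)])
        # brute-force oracle: no 30-mer of the read occurs in any transcript
        hit = any(
            read[i : i + 30] in ref
            for ref in reference.gene_seqs.values()
            for i in range(len(read) - 29)
        )
        assert not hit
        gene, status = sc.assign_transcript(read, reference)
        assert status is Status.NO_FEATURE and gene is None

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            TranscriptReference({})


def _directional_components_bruteforce(umis):
    """Quadratic all-pairs oracle for the directional merge rule."""
    from collections import Counter

    counts = Counter(umis)
    unique = list(counts)
    n = len(unique)
    adj = {i: set() for i in range(n)}
    for i, j in itertools.combinations(range(n), 2):
        u, v = unique[i], unique[j]
        if hamming(u, v) <= 1:
            hi, lo = max(counts[u], counts[v]), min(counts[u], counts[v])
            if hi >= 2 * lo - 1:
                adj[i].add(j)
                adj[j].add(i)
    seen, comps = set(), 0
    for i in range(n):
        if i in seen:
            continue
        comps += 1
        stack = [i]
        while stack:
            k = stack.pop()
            if k not in seen:
                seen.add(k)
                stack.extend(adj[k] - seen)
    return comps


class TestUmiDedup:
    def test_identical_umis_collapse_to_one(self):
        assert count_umi_classes(["ACGTAC"] * 5, "exact") == 1
        assert count_umi_classes(["ACGTAC"] * 5, "directional") == 1

    def test_distinct_umis_stay_separate_in_exact_mode(self):
        umis = ["AAAAAA", "CCAAAA", "GGGGAA"]
        assert all(
            hamming(a, b) >= 2 for a, b in itertools.combinations(umis, 2)
        )
        assert count_umi_classes(umis, "exact") == 3

    def test_directional_merges_error_offspring(self):
        # abundant parent absorbs a singleton one substitution away
        umis = ["AAAAAA"] * 5 + ["AAAAAT"]
        assert count_umi_classes(umis, "directional") == 1
        assert count_umi_classes(umis, "exact") == 2

    @pytest.mark.parametrize("trial", range(20))
    def test_directional_matches_bruteforce_oracle(self, trial):
        rng = np.random.default_rng(1000 + trial)
        n = int(rng.integers(2, 201))
        # short UMIs over a reduced alphabet force frequent adjacency
        nuc = np.array(list("ACGT"))
        umis = ["".join(nuc[rng.integers(0, 2 + trial % 3, 4)]) for _ in range(n)]
        assert count_umi_classes(umis, "directional") == _directional_components_bruteforce(umis)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            count_umi_classes(["AAAA"], "cluster")


def _rec(row, col, umi, feature):
    return DemuxRecord("r", sc.PixelAddress(row, col), umi, feature, Status.OK)


class TestDedupMatrix:
    def test_counts_are_umi_classes_per_group(self):
        records = [
            _rec(1, 1, "AAAA", "CD3"),
            _rec(1, 1, "AAAA", "CD3"),  # duplicate
            _rec(1, 1, "CCCC", "CD3"),
            _rec(2, 2, "AAAA", "CD4"),
        ]
        mat = dedup_umis(records, "protein", feature_order=["CD3", "CD4"])
        assert mat.total_umis() == 3
        dense = mat.dense()
        assert dense[0, 0] == 2 and dense[1, 1] == 1

    def test_record_order_does_not_matter(self, rng):
        records = [
            _rec(int(r) + 1, int(c) + 1, "".join("ACGT"[b] for b in rng.integers(0, 4, 6)), f)
            for r, c, f in zip(
                rng.integers(0, 5, 300), rng.integers(0, 5, 300),
                rng.choice(["X", "Y", "Z"], 300),
            )
        ]
        m1 = dedup_umis(records, "protein")
        shuffled = [records[i] for i in rng.permutation(len(records))]
        m2 = dedup_umis(shuffled, "protein")
        assert m1.feature_index == m2.feature_index
        assert m1.pixel_index == m2.pixel_index
        assert (m1.counts != m2.counts).nnz == 0

    def test_rejects_non_ok_records(self):
        bad = DemuxRecord("r", None, "AAAA", None, Status.NO_FEATURE)
        with pytest.raises(ValueError):
            dedup_umis([bad], "protein")


class TestQC:
    def test_features_and_umis_per_pixel(self):
        mat = PixelMatrix(
            sparse.csr_matrix(np.array([[2, 0, 1]])),
            [sc.PixelAddress(1, 1)],
            ["A", "B", "C"],
            "protein",
        )
        qc = qc_per_pixel(mat)
        assert qc.loc[0, "n_features_detected"] == 2
        assert qc.loc[0, "total_umi"] == 3

    def test_empty_matrix_gives_empty_table(self):
        mat = PixelMatrix(sparse.csr_matrix((0, 3), dtype=np.int64), [], ["A", "B", "C"], "protein")
        assert len(qc_per_pixel(mat)) == 0
        assert qc_summary(mat)["n_pixels"] == 0


class TestRunConservation:
    def test_status_tallies_cover_all_reads(self, clean_sim, clean_demux):
        for modality in ("protein", "rna"):
            mat, summary = clean_demux[modality]
            assert sum(summary["status_counts"].values()) == summary["n_reads"]
            assert summary["n_reads"] == clean_sim.n_reads[modality]
            # deduplicated molecules never exceed decoded reads
            assert mat.total_umis() <= summary["n_ok"]
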