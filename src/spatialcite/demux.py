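"""Read decoding, UMI deduplication, and pixel x feature counting.

Each read pair is decoded into (pixel address, UMI, feature): Read 2
carries the UMI and both spatial barcodes at fixed offsets, Read 1
carries the feature evidence — an antibody tag for the ADT library or a
transcript fragment for the cDNA library. Reads sharing a UMI within one
(pixel, feature) group are PCR duplicates and collapse to one molecule.
"""

from __future__ import annotations

import json
from collections import Counter, defaultdict
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Iterator

import numpy as np
from scipy import sparse

from .chip import ADTPanel, ChipDesign, PixelAddress

_ENC = np.zeros(128, dtype=np.uint8)
for _i, _b in enumerate(b"ACGTN"):
    _ENC[_b] = _i


class Status(str, Enum):
    OK = "OK"
    NO_ROW_BARCODE = "NO_ROW_BARCODE"
    NO_COL_BARCODE = "NO_COL_BARCODE"
    AMBIGUOUS_BARCODE = "AMBIGUOUS_BARCODE"
    NO_FEATURE = "NO_FEATURE"
    AMBIGUOUS_FEATURE = "AMBIGUOUS_FEATURE"
    LOW_QUALITY = "LOW_QUALITY"


@dataclass
class DemuxRecord:
    """Per-read decode outcome; pixel and feature are set iff status is OK."""

    read_id: str
    pixel: PixelAddress | None
    umi: str
    feature: str | None
    status: Status


@dataclass
class PixelMatrix:
    """Sparse pixel x feature UMI count matrix with spatial coordinates."""

    counts: sparse.csr_matrix
    pixel_index: list[PixelAddress]
    feature_index: list[str]
    modality: str  # "protein" | "rna"

    def __post_init__(self) -> None:
        assert self.counts.shape == (len(self.pixel_index), len(self.feature_index))
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("negative count")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def total_umis(self) -> int:
        return int(self.counts.sum())

    def dense(self) -> np.ndarray:
        return np.asarray(self.counts.todense())


class BarcodeMatcher:
    """Matches a fixed-length segment against a barcode whitelist.

    Exact hits resolve immediately; otherwise a unique whitelist entry
    within ``max_mismatch`` substitutions is accepted and ties are
    ambiguous. Bases below ``min_phred`` are untrusted and count as
    mismatches against every barcode.
    """

    def __init__(self, sequences: list[str], max_mismatch: int = 1, min_phred: int = 10):
        self.sequences = sequences
        self.length = len(sequences[0])
        self.max_mismatch = max_mismatch
        self.min_phred = min_phred
        self._exact = {s: i for i, s in enumerate(sequences)}
        self._mat = np.vstack(
            [_ENC[np.frombuffer(s.encode(), dtype=np.uint8)] for s in sequences]
        )

    def match(self, segment: str, quals: list[int] | None = None) -> tuple[int | None, str]:
        """Return (whitelist index | None, outcome) with outcome in
        {"ok", "none", "ambiguous"}."""
        lowq = None
        if quals is not None:
            lowq = np.asarray(quals) < self.min_phred
            if not lowq.any():
                lowq = None
        if lowq is None:
            hit = self._exact.get(segment)
            if hit is not None:
                return hit, "ok"
        if self.max_mismatch == 0 and lowq is None:
            return None, "none"
        enc = _ENC[np.frombuffer(segment.encode(), dtype=np.uint8)]
        mism = self._mat != enc
        if lowq is not None:
            mism |= lowq
        dists = mism.sum(axis=1)
        best = int(dists.min())
        if best > self.max_mismatch:
            return None, "none"
        hits = np.flatnonzero(dists == best)
        if len(hits) > 1:
            return None, "ambiguous"
        return int(hits[0]), "ok"


def extract_spatial(
    seq: str,
    quals: list[int] | None,
    design: ChipDesign,
    row_matcher: BarcodeMatcher | None = None,
    col_matcher: BarcodeMatcher | None = None,
    max_mismatch: int = 1,
    max_linker_mismatch: int = 2,
) -> tuple[PixelAddress | None, str, Status]:
    """Decode Read 2 into (pixel address, UMI, status).

    Matchers may be passed in to amortize whitelist encoding over a run.
    Reads shorter than the layout, or with a ligation linker more than
    ``max_linker_mismatch`` substitutions away from the expected sequence
    (a chimeric-ligation guard), are LOW_QUALITY.
    """
    if len(seq) < design.read2_min_length:
        return None, "", Status.LOW_QUALITY
    seq = seq.upper()
    if row_matcher is None:
        row_matcher = BarcodeMatcher([s for _, s in design.row_barcodes], max_mismatch)
    if col_matcher is None:
        col_matcher = BarcodeMatcher([s for _, s in design.col_barcodes], max_mismatch)

    useg = design.segment("umi")
    umi = seq[useg.offset : useg.end]

    try:
        lseg = design.segment("linker")
    except KeyError:
        lseg = None
    if lseg is not None:
        linker = seq[lseg.offset : lseg.end]
        if sum(a != b for a, b in zip(linker, design.linker)) > max_linker_mismatch:
            return None, umi, Status.LOW_QUALITY

    aseg = design.segment("barcode_a")
    bseg = design.segment("barcode_b")
    qa = quals[aseg.offset : aseg.end] if quals is not None else None
    qb = quals[bseg.offset : bseg.end] if quals is not None else None
    row_hit, row_out = row_matcher.match(seq[aseg.offset : aseg.end], qa)
    col_hit, col_out = col_matcher.match(seq[bseg.offset : bseg.end], qb)

    if row_out == "none":
        return None, umi, Status.NO_ROW_BARCODE
    if col_out == "none":
        return None, umi, Status.NO_COL_BARCODE
    if row_out == "ambiguous" or col_out == "ambiguous":
        return None, umi, Status.AMBIGUOUS_BARCODE
    return PixelAddress(row_hit + 1, col_hit + 1), umi, Status.OK


def assign_adt(
    seq: str,
    panel: ADTPanel,
    matcher: BarcodeMatcher | None = None,
    tag_offset: int = 0,
    max_mismatch: int = 1,
) -> tuple[str | None, Status]:
    """Match the antibody tag at the start of Read 1 against the panel."""
    if matcher is None:
        matcher = BarcodeMatcher([e.sequence for e in panel.entries], max_mismatch)
    segment = seq[tag_offset : tag_offset + panel.tag_length].upper()
    if len(segment) < panel.tag_length:
        return None, Status.NO_FEATURE
    hit, outcome = matcher.match(segment)
    if outcome == "ok":
        return panel.entries[hit].name, Status.OK
    if outcome == "ambiguous":
        return None, Status.AMBIGUOUS_FEATURE
    return None, Status.NO_FEATURE


class TranscriptReference:
    """Exact-substring transcript assigner for desk-scale references.

    A read maps to a gene when at least ``min_match`` consecutive bases
    occur verbatim in that gene's transcript sequence; hits to more than
    one gene are ambiguous. K-mer seeding (default k=21) prefilters
    candidate genes before substring verification. This is a deliberately
    simple stand-in for a splice-aware aligner, adequate for synthetic
    references; externally produced per-read gene assignments can be
    loaded with :func:`load_gene_assignments`.
    """

    def __init__(self, gene_seqs: dict[str, str], k: int = 21, min_match: int = 30):
        if not gene_seqs:
            raise ValueError("empty reference")
        self.gene_seqs = {g: s.upper() for g, s in gene_seqs.items()}
        self.k = k
        self.min_match = min_match
        self._index: dict[str, set[str]] = defaultdict(set)
        for gene, s in self.gene_seqs.items():
            for i in range(len(s) - k + 1):
                self._index[s[i : i + k]].add(gene)

    @classmethod
    def from_fasta(cls, path: str, **kw) -> "TranscriptReference":
        from Bio import SeqIO

        seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}
        return cls(seqs, **kw)

    def assign(self, seq: str) -> tuple[str | None, Status]:
        seq = seq.upper()
        if len(seq) < self.min_match:
            return None, Status.NO_FEATURE
        candidates: set[str] = set()
        for i in range(0, len(seq) - self.k + 1):
            candidates |= self._index.get(seq[i : i + self.k], set())
        hits = set()
        for gene in candidates:
            ref = self.gene_seqs[gene]
            if any(
                seq[i : i + self.min_match] in ref
                for i in range(len(seq) - self.min_match + 1)
            ):
                hits.add(gene)
        if not hits:
            return None, Status.NO_FEATURE
        if len(hits) > 1:
            return None, Status.AMBIGUOUS_FEATURE
        return hits.pop(), Status.OK


def assign_transcript(seq: str, reference: TranscriptReference) -> tuple[str | None, Status]:
    return reference.assign(seq)


def load_gene_assignments(path: str) -> dict[str, str]:
    """Load externally produced per-read gene assignments (TSV: read_id, gene)."""
    out = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 2 and parts[0] != "read_id":
                out[parts[0]] = parts[1]
    return out


# ---------------------------------------------------------------------------
# UMI deduplication


def _umi_components_directional(umis: list[str]) -> int:
    """Connected components under the directional-adjacency merge rule:
    u,v join when Hamming(u,v) <= 1 and the more abundant one has
    count >= 2 * count(other) - 1."""
    counts = Counter(umis)
    unique = list(counts)
    n = len(unique)
    if n <= 1:
        return n
    idx = {u: i for i, u in enumerate(unique)}
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj

    # bucket by single-position wildcard: any two UMIs sharing a bucket
    # differ at most at that one position
    buckets: dict[str, list[int]] = defaultdict(list)
    for u, i in idx.items():
        for p in range(len(u)):
            buckets[u[:p] + "." + u[p + 1 :]].append(i)
    for members in buckets.values():
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                i, j = members[a], members[b]
                ci, cj = counts[unique[i]], counts[unique[j]]
                hi, lo = max(ci, cj), min(ci, cj)
                if hi >= 2 * lo - 1:
                    union(i, j)
    return len({find(i) for i in range(n)})


def count_umi_classes(umis: list[str], mode: str = "exact") -> int:
    """Number of distinct molecules among the UMIs of one (pixel, feature)
    group. ``exact`` collapses identical UMIs only; ``directional``
    additionally merges likely sequencing-error offspring."""
    if mode == "exact":
        return len(set(umis))
    if mode == "directional":
        return _umi_components_directional(umis)
    raise ValueError(f"unknown umi mode {mode!r}")


def dedup_umis(
    records: Iterable[DemuxRecord],
    modality: str,
    mode: str = "exact",
    design: ChipDesign | None = None,
    feature_order: list[str] | None = None,
) -> PixelMatrix:
    """Collapse OK records to a pixel x feature molecule-count matrix.

    The result is order-independent: pixels sort by (row, col) and
    features follow ``feature_order`` when given (e.g. panel order),
    else lexicographic. When ``design`` is given, every chip pixel gets a
    row so matrices from different modalities are co-indexed.
    """
    groups: dict[tuple[PixelAddress, str], list[str]] = defaultdict(list)
    for rec in records:
        if rec.status is not Status.OK:
            raise ValueError("dedup_umis expects only OK records")
        groups[(rec.pixel, rec.feature)].append(rec.umi)

    if design is not None:
        pixels = design.addresses()
    else:
        pixels = sorted({p for p, _ in groups}, key=lambda a: (a.row, a.col))
    if feature_order is not None:
        features = list(feature_order)
    else:
        features = sorted({f for _, f in groups})
    prow = {p: i for i, p in enumerate(pixels)}
    fcol = {f: j for j, f in enumerate(features)}

    rows, cols, data = [], [], []
    for (pix, feat), umis in groups.items():
        if feat not in fcol or pix not in prow:
            continue
        rows.append(prow[pix])
        cols.append(fcol[feat])
        data.append(count_umi_classes(umis, mode))
    counts = sparse.csr_matrix(
        (data, (rows, cols)), shape=(len(pixels), len(features)), dtype=np.int64
    )
    counts.sort_indices()
    return PixelMatrix(counts, pixels, features, modality)


def qc_per_pixel(matrix: PixelMatrix):
    """Per-pixel QC table: features detected and total UMIs per pixel."""
    import pandas as pd

    dense = matrix.counts
    n_feat = np.asarray((dense > 0).sum(axis=1)).ravel()
    total = np.asarray(dense.sum(axis=1)).ravel()
    return pd.DataFrame(
        {
            "pixel": [p.label for p in matrix.pixel_index],
            "row": [p.row for p in matrix.pixel_index],
            "col": [p.col for p in matrix.pixel_index],
            "n_features_detected": n_feat.astype(int),
            "total_umi": total.astype(int),
        }
    )


def qc_summary(matrix: PixelMatrix) -> dict:
    qc = qc_per_pixel(matrix)
    if len(qc) == 0:
        return {"n_pixels": 0, "mean_features_per_pixel": 0.0, "mean_umi_per_pixel": 0.0}
    return {
        "n_pixels": int(len(qc)),
        "mean_features_per_pixel": float(qc["n_features_detected"].mean()),
        "mean_umi_per_pixel": float(qc["total_umi"].mean()),
    }


# ---------------------------------------------------------------------------
# FASTQ driver


def _open_maybe_gzip(path: str):
    import gzip

    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def read_pairs(r1_path: str, r2_path: str) -> Iterator[tuple[str, str, str, str, str]]:
    """Yield (read_id, seq1, seq2, qual1, qual2) from a FASTQ pair."""
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    with _open_maybe_gzip(r1_path) as f1, _open_maybe_gzip(r2_path) as f2:
        for (t1, s1, q1), (t2, s2, q2) in zip(
            FastqGeneralIterator(f1), FastqGeneralIterator(f2), strict=True
        ):
            yield t1.split()[0], s1, s2, q1, q2


def demux_fastq(
    r1_path: str,
    r2_path: str,
    design: ChipDesign,
    modality: str,
    panel: ADTPanel | None = None,
    reference: TranscriptReference | None = None,
    gene_assignments: dict[str, str] | None = None,
    max_mismatch: int = 1,
    umi_mode: str = "exact",
    use_quality: bool = True,
    keep_records: bool = False,
) -> tuple[PixelMatrix, dict, list[DemuxRecord]]:
    """Decode a paired FASTQ library into a deduplicated count matrix.

    Returns (matrix, summary, rejected_records). The summary tallies every
    read by status, so the tallies always sum to the input read count.
    """
    if modality == "protein" and panel is None:
        raise ValueError("protein modality requires an ADT panel")
    if modality == "rna" and reference is None and gene_assignments is None:
        raise ValueError("rna modality requires a reference or gene assignments")

    row_m = BarcodeMatcher([s for _, s in design.row_barcodes], max_mismatch)
    col_m = BarcodeMatcher([s for _, s in design.col_barcodes], max_mismatch)
    tag_m = (
        BarcodeMatcher([e.sequence for e in panel.entries], max_mismatch)
        if panel is not None
        else None
    )

    tallies: Counter = Counter()
    ok_records: list[DemuxRecord] = []
    rejected: list[DemuxRecord] = []
    n_reads = 0
    for read_id, s1, s2, q1, q2 in read_pairs(r1_path, r2_path):
        n_reads += 1
        quals = [ord(c) - 33 for c in q2] if use_quality else None
        pixel, umi, status = extract_spatial(
            s2, quals, design, row_m, col_m, max_mismatch
        )
        feature = None
        if status is Status.OK:
            if modality == "protein":
                feature, status = assign_adt(s1, panel, tag_m, max_mismatch=max_mismatch)
            elif gene_assignments is not None:
                feature = gene_assignments.get(read_id)
                status = Status.OK if feature is not None else Status.NO_FEATURE
            else:
                feature, status = reference.assign(s1)
        rec = DemuxRecord(read_id, pixel if status is Status.OK else pixel, umi, feature, status)
        tallies[status.value] += 1
        if status is Status.OK:
            ok_records.append(rec)
        elif keep_records:
            rejected.append(rec)

    if modality == "protein":
        feature_order = panel.names
    elif reference is not None:
        feature_order = sorted(reference.gene_seqs)
    elif gene_assignments is not None:
        feature_order = sorted(set(gene_assignments.values()))
    else:
        feature_order = None
    matrix = dedup_umis(ok_records, modality, umi_mode, design, feature_order)
    summary = {
        "n_reads": n_reads,
        "status_counts": dict(tallies),
        "n_ok": tallies.get("OK", 0),
        "total_umis": matrix.total_umis(),
        "umi_mode": umi_mode,
        "max_mismatch": max_mismatch,
        "modality": modality,
    }
    assert sum(tallies.values()) == n_reads
    return matrix, summary, rejected


def write_summary(summary: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
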