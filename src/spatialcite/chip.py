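"""Chip geometry, spatial barcode sets, and read layout.

A DBiT (deterministic barcoding in tissue) chip delivers two orthogonal
sets of DNA barcodes over a tissue section: row barcodes A1..An in a
first microfluidic flow, then column barcodes B1..Bm in a perpendicular
flow. Their in-situ ligation defines a grid of tissue pixels, each
carrying the spatial address code AiBj. Read 2 of both sequencing
libraries carries the UMI and both spatial barcodes in fixed segments;
this module owns that layout and the pixel -> micron coordinate map.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass, field

import yaml

NUCLEOTIDES = "ACGT"

#: Default ligation-linker sequence joining barcode B to barcode A on Read 2.
DEFAULT_LINKER = "GTGGCCGATGTTTCG"

#: Seed for the bundled stand-in barcode/tag sequence sets. The published
#: sets live in vendor supplementary files; the bundled ones are generated
#: random sequences with the same combinatorial guarantees.
_BUNDLED_SEED = 20220330


class ChipDesignError(ValueError):
    """Raised when a chip design or panel violates a structural invariant."""


@dataclass(frozen=True)
class Segment:
    """One fixed-offset segment of Read 2."""

    name: str  # one of: umi, barcode_b, linker, barcode_a
    offset: int
    length: int

    @property
    def end(self) -> int:
        return self.offset + self.length


@dataclass(frozen=True)
class PixelAddress:
    """1-based grid address: row i (barcode A), column j (barcode B)."""

    row: int
    col: int

    @property
    def label(self) -> str:
        return f"A{self.row}B{self.col}"


@dataclass
class ChipDesign:
    """Barcode sets plus Read-2 layout and physical pixel geometry.

    ``row_barcodes``/``col_barcodes`` are ordered (label, sequence) pairs;
    position k in the list is grid index k+1. ``pixel_pitch_um`` is the
    center-to-center pixel spacing, ``pixel_size_um`` the channel width.
    """

    row_barcodes: list[tuple[str, str]]
    col_barcodes: list[tuple[str, str]]
    umi_length: int = 10
    linker: str = DEFAULT_LINKER
    pixel_pitch_um: float = 25.0
    pixel_size_um: float = 25.0
    read2_layout: list[Segment] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.row_barcodes or not self.col_barcodes:
            raise ChipDesignError("barcode sets must be non-empty")
        for name, bcs in (("row", self.row_barcodes), ("column", self.col_barcodes)):
            lengths = {len(s) for _, s in bcs}
            if len(lengths) != 1:
                raise ChipDesignError(f"inconsistent barcode length in {name} set")
            seqs = [s for _, s in bcs]
            if len(set(seqs)) != len(seqs):
                raise ChipDesignError(f"degenerate barcode set: duplicate {name} sequence")
            labels = [l for l, _ in bcs]
            if len(set(labels)) != len(labels):
                raise ChipDesignError(f"duplicate {name} barcode label")
        if len(self.row_barcodes[0][1]) != len(self.col_barcodes[0][1]):
            raise ChipDesignError("inconsistent barcode length between row and column sets")
        if not self.read2_layout:
            self.read2_layout = default_read2_layout(
                self.umi_length, self.barcode_length, len(self.linker)
            )
        self._validate_layout()

    def _validate_layout(self) -> None:
        segs = sorted(self.read2_layout, key=lambda s: s.offset)
        names = [s.name for s in segs]
        for required in ("umi", "barcode_b", "barcode_a"):
            if required not in names:
                raise ChipDesignError(f"read2 layout missing segment {required!r}")
        for a, b in itertools.pairwise(segs):
            if a.end > b.offset:
                raise ChipDesignError(f"read2 segments {a.name} and {b.name} overlap")
        by_name = {s.name: s for s in segs}
        if by_name["umi"].length != self.umi_length:
            raise ChipDesignError("umi segment length disagrees with umi_length")
        for seg_name in ("barcode_a", "barcode_b"):
            if by_name[seg_name].length != self.barcode_length:
                raise ChipDesignError(f"{seg_name} segment length disagrees with barcode_length")

    # -- derived properties -------------------------------------------------

    @property
    def barcode_length(self) -> int:
        return len(self.row_barcodes[0][1])

    @property
    def n_rows(self) -> int:
        return len(self.row_barcodes)

    @property
    def n_cols(self) -> int:
        return len(self.col_barcodes)

    @property
    def read2_min_length(self) -> int:
        return max(s.end for s in self.read2_layout)

    def segment(self, name: str) -> Segment:
        for s in self.read2_layout:
            if s.name == name:
                return s
        raise KeyError(name)

    def addresses(self) -> list[PixelAddress]:
        """All n*m representable pixel addresses, row-major."""
        return [
            PixelAddress(i, j)
            for i in range(1, self.n_rows + 1)
            for j in range(1, self.n_cols + 1)
        ]

    def address_to_labels(self, addr: PixelAddress) -> tuple[str, str]:
        self._check_bounds(addr)
        return self.row_barcodes[addr.row - 1][0], self.col_barcodes[addr.col - 1][0]

    def labels_to_address(self, row_label: str, col_label: str) -> PixelAddress:
        rows = {l: i for i, (l, _) in enumerate(self.row_barcodes, start=1)}
        cols = {l: j for j, (l, _) in enumerate(self.col_barcodes, start=1)}
        return PixelAddress(rows[row_label], cols[col_label])

    def _check_bounds(self, addr: PixelAddress) -> None:
        if not (1 <= addr.row <= self.n_rows and 1 <= addr.col <= self.n_cols):
            raise ChipDesignError(
                f"address {addr.label} outside {self.n_rows}x{self.n_cols} chip"
            )

    def min_pairwise_hamming(self) -> int:
        """Smallest pairwise Hamming distance within either barcode set."""
        return min(
            _min_set_hamming([s for _, s in self.row_barcodes]),
            _min_set_hamming([s for _, s in self.col_barcodes]),
        )


@dataclass(frozen=True)
class ADTEntry:
    name: str
    sequence: str
    is_isotype_control: bool = False


@dataclass
class ADTPanel:
    """Antibody name <-> DNA tag dictionary, with isotype-control flags."""

    entries: list[ADTEntry]
    species: str = ""

    def __post_init__(self) -> None:
        if not self.entries:
            raise ChipDesignError("empty ADT panel")
        lengths = {len(e.sequence) for e in self.entries}
        if len(lengths) != 1:
            raise ChipDesignError("inconsistent tag length in ADT panel")
        seqs = [e.sequence for e in self.entries]
        if len(set(seqs)) != len(seqs):
            raise ChipDesignError("degenerate ADT panel: duplicate tag sequence")
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise ChipDesignError("duplicate antibody name in panel")

    @property
    def tag_length(self) -> int:
        return len(self.entries[0].sequence)

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    @property
    def n_isotype_controls(self) -> int:
        return sum(e.is_isotype_control for e in self.entries)

    def __len__(self) -> int:
        return len(self.entries)


# ---------------------------------------------------------------------------
# construction helpers


def default_read2_layout(umi_length: int, barcode_length: int, linker_length: int) -> list[Segment]:
    """UMI | barcode B | ligation linker | barcode A, packed from offset 0.

    Barcode B (carrying the UMI) is ligated on top of barcode A, so it is
    sequenced first on Read 2; the linker sits between the two barcodes.
    """
    segs = []
    off = 0
    for name, length in (
        ("umi", umi_length),
        ("barcode_b", barcode_length),
        ("linker", linker_length),
        ("barcode_a", barcode_length),
    ):
        segs.append(Segment(name, off, length))
        off += length
    return segs


def _min_set_hamming(seqs: list[str]) -> int:
    if len(seqs) < 2:
        return len(seqs[0]) if seqs else 0
    return min(hamming(a, b) for a, b in itertools.combinations(seqs, 2))


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance needs equal-length sequences")
    return sum(x != y for x, y in zip(a, b))


def random_barcode_set(
    n: int, length: int, rng: random.Random, min_distance: int = 3, avoid: set[str] | None = None
) -> list[str]:
    """Greedily sample ``n`` sequences with pairwise Hamming >= min_distance.

    ``avoid`` lets a caller keep a second set disjoint from the first. A
    min distance of 3 makes single-mismatch correction unambiguous.
    """
    chosen: list[str] = []
    avoid = avoid or set()
    attempts = 0
    while len(chosen) < n:
        attempts += 1
        if attempts > 200_000:
            raise ChipDesignError("cannot satisfy barcode distance constraint")
        cand = "".join(rng.choice(NUCLEOTIDES) for _ in range(length))
        if cand in avoid:
            continue
        if all(hamming(cand, c) >= min_distance for c in chosen):
            chosen.append(cand)
    return chosen


def default_chip_design(
    n_rows: int = 50,
    n_cols: int = 50,
    barcode_length: int = 8,
    umi_length: int = 10,
    pixel_pitch_um: float = 25.0,
    pixel_size_um: float = 25.0,
    seed: int = _BUNDLED_SEED,
) -> ChipDesign:
    """The bundled 50x50 chip with generated stand-in barcode sequences.

    Sequences are random, length 8, filtered to pairwise Hamming >= 3
    within each set, and deterministic for a given seed.
    """
    rng = random.Random(seed)
    rows = random_barcode_set(n_rows, barcode_length, rng)
    cols = random_barcode_set(n_cols, barcode_length, rng, avoid=set(rows))
    return ChipDesign(
        row_barcodes=[(f"A{i}", s) for i, s in enumerate(rows, 1)],
        col_barcodes=[(f"B{j}", s) for j, s in enumerate(cols, 1)],
        umi_length=umi_length,
        pixel_pitch_um=pixel_pitch_um,
        pixel_size_um=pixel_size_um,
    )


# canonical immune markers used to name the leading panel entries; the
# remainder get systematic names. Tag sequences are generated stand-ins.
_MARKER_NAMES = [
    "CD3", "CD4", "CD8a", "CD19", "CD20", "CD21", "CD23", "CD9", "CD11b",
    "CD11c", "CD14", "CD16", "CD25", "CD27", "CD28", "CD32", "CD38", "CD44",
    "CD45", "CD45RA", "CD45RO", "CD56", "CD62L", "CD69", "CD90", "CD103",
    "CD127", "CD138", "CD171", "PD-1", "PD-L1", "CD223", "TIGIT", "CXCR6",
    "ICOS", "CTLA-4", "IgM", "IgD", "IgG1", "Notch3", "Mac2", "HLA-DR",
    "B220", "F4-80", "Ly6G", "Ly6C", "NK1.1", "TCRb", "CD150", "CD86",
]


def builtin_panel(species: str, seed: int = _BUNDLED_SEED) -> ADTPanel:
    """Bundled ADT panel fixture: 273 antibodies (human) or 189 (mouse),
    each including 9 isotype controls, mirroring the commercial cocktail
    sizes. Names mix canonical markers with systematic fillers; tag
    sequences are generated 15-mers with pairwise Hamming >= 3.
    """
    sizes = {"human": 273, "mouse": 189}
    if species not in sizes:
        raise ChipDesignError(f"unknown panel species {species!r}")
    total = sizes[species]
    n_iso = 9
    n_specific = total - n_iso
    names = list(_MARKER_NAMES[:n_specific])
    k = 1
    while len(names) < n_specific:
        names.append(f"ADT{k:03d}")
        k += 1
    iso_names = [f"IsotypeCtrl{i}" for i in range(1, n_iso + 1)]
    rng = random.Random(seed + hash(species) % 10_000)
    seqs = random_barcode_set(total, 15, rng)
    entries = [ADTEntry(n, s, False) for n, s in zip(names, seqs[:n_specific])]
    entries += [ADTEntry(n, s, True) for n, s in zip(iso_names, seqs[n_specific:])]
    return ADTPanel(entries=entries, species=species)


def small_panel(n: int = 40, tag_length: int = 15, seed: int = _BUNDLED_SEED) -> ADTPanel:
    """A compact panel for simulation and desk-scale runs."""
    rng = random.Random(seed + 7)
    seqs = random_barcode_set(n, tag_length, rng)
    names = (_MARKER_NAMES + [f"ADT{k:03d}" for k in range(1, n + 1)])[:n]
    return ADTPanel(entries=[ADTEntry(nm, sq, False) for nm, sq in zip(names, seqs)])


# ---------------------------------------------------------------------------
# file IO


def load_chip_design(path: str) -> ChipDesign:
    """Load and validate a chip design from YAML.

    Expected keys: ``row_barcodes``/``col_barcodes`` (lists of
    ``{label, sequence}``), optional ``umi_length``, ``linker``,
    ``pixel_pitch_um``, ``pixel_size_um``, ``read2_layout`` (list of
    ``{name, offset, length}``). Any invariant violation raises
    :class:`ChipDesignError`.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ChipDesignError(f"cannot parse chip design file {path}")
    try:
        rows = [(d["label"], d["sequence"].upper()) for d in cfg["row_barcodes"]]
        cols = [(d["label"], d["sequence"].upper()) for d in cfg["col_barcodes"]]
    except (KeyError, TypeError) as exc:
        raise ChipDesignError(f"malformed chip design file {path}: {exc}") from exc
    kwargs = {}
    for key in ("umi_length", "linker", "pixel_pitch_um", "pixel_size_um"):
        if key in cfg:
            kwargs[key] = cfg[key]
    if "read2_layout" in cfg:
        kwargs["read2_layout"] = [
            Segment(d["name"], int(d["offset"]), int(d["length"])) for d in cfg["read2_layout"]
        ]
    return ChipDesign(row_barcodes=rows, col_barcodes=cols, **kwargs)


def save_chip_design(design: ChipDesign, path: str) -> None:
    cfg = {
        "row_barcodes": [{"label": l, "sequence": s} for l, s in design.row_barcodes],
        "col_barcodes": [{"label": l, "sequence": s} for l, s in design.col_barcodes],
        "umi_length": design.umi_length,
        "linker": design.linker,
        "pixel_pitch_um": design.pixel_pitch_um,
        "pixel_size_um": design.pixel_size_um,
        "read2_layout": [
            {"name": s.name, "offset": s.offset, "length": s.length}
            for s in design.read2_layout
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def load_adt_panel(path: str, species: str = "") -> ADTPanel:
    """Load a panel from TSV with columns: name, sequence[, isotype]."""
    entries = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {c: i for i, c in enumerate(header)}
        if "name" not in idx or "sequence" not in idx:
            raise ChipDesignError(f"panel file {path} needs 'name' and 'sequence' columns")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2 or not parts[0]:
                continue
            iso = False
            if "isotype" in idx and len(parts) > idx["isotype"]:
                iso = parts[idx["isotype"]].strip().lower() in ("1", "true", "yes")
            entries.append(ADTEntry(parts[idx["name"]], parts[idx["sequence"]].upper(), iso))
    return ADTPanel(entries=entries, species=species)


def save_adt_panel(panel: ADTPanel, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("name\tsequence\tisotype\n")
        for e in panel.entries:
            fh.write(f"{e.name}\t{e.sequence}\t{int(e.is_isotype_control)}\n")


def pixel_to_micron(addr: PixelAddress, design: ChipDesign) -> tuple[float, float]:
    """Affine grid -> physical map with origin at the center of pixel (1,1).

    x runs along columns (barcode B), y along rows (barcode A):
    x = (col-1) * pitch, y = (row-1) * pitch.
    """
    design._check_bounds(addr)
    pitch = float(design.pixel_pitch_um)
    return (addr.col - 1) * pitch, (addr.row - 1) * pitch
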