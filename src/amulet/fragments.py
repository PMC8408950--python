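"""Reading, filtering and deduplicating paired-end snATAC fragments.

Two input dialects are supported: coordinate-sorted, barcode-tagged BAM/SAM
alignments and 10x-style 5-column fragments files.  Both are reduced to the
same primitive, a :class:`ValidFragment` — one deduplicated, quality-filtered
fragment interval assigned to a nucleus barcode — emitted in (chrom, start)
order.  Fragment intervals are 0-based half-open, computed from the leftmost
mate's start and the template length; no Tn5 +4/-5 shift is applied because
overlap counting is insensitive to a uniform shift.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "HUMAN_AUTOSOMES",
    "BarcodeTable",
    "FilterConfig",
    "FragmentSet",
    "ValidFragment",
    "dedupe_coordinate",
    "read_singlecell_csv",
    "stream_bam_fragments",
    "stream_fragment_file",
]

#: Default autosome list (human, UCSC naming).  Overridable via FilterConfig.
HUMAN_AUTOSOMES: tuple[str, ...] = tuple(f"chr{i}" for i in range(1, 23))


class ValidFragment(NamedTuple):
    """One retained paired-end fragment: 0-based half-open interval + barcode."""

    chrom: str
    start: int
    end: int
    barcode: str


@dataclass(frozen=True)
class FilterConfig:
    """Read-pair filters applied while streaming alignments.

    ``min_mapq_exclusive`` rejects mapping quality <= the value (default 30);
    ``max_insert`` rejects fragments longer than the value (default 900 bp,
    about six nucleosomes).  ``dedupe_mode`` selects which duplicate handling
    applies: the aligner's duplicate flag, coordinate-based collapsing, or
    both.
    """

    min_mapq_exclusive: int = 30
    max_insert: int = 900
    autosomes: tuple[str, ...] = HUMAN_AUTOSOMES
    dedupe_mode: str = "both"  # {"flag", "coordinate", "both"}
    barcode_tag: str = "CB"

    def __post_init__(self) -> None:
        if self.min_mapq_exclusive < 0:
            raise ValueError("min_mapq_exclusive must be >= 0")
        if self.max_insert <= 0:
            raise ValueError("max_insert must be > 0")
        if self.dedupe_mode not in {"flag", "coordinate", "both"}:
            raise ValueError(f"unknown dedupe_mode {self.dedupe_mode!r}")


@dataclass
class BarcodeTable:
    """Per-barcode cell calls plus a running tally of valid read pairs."""

    barcodes: list[str]
    is_cell: np.ndarray  # bool, aligned with barcodes
    valid_pair_count: np.ndarray = field(default=None)  # type: ignore[assignment]
    _index: dict[str, int] = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if len(set(self.barcodes)) != len(self.barcodes):
            raise ValueError("barcodes must be unique")
        self.is_cell = np.asarray(self.is_cell, dtype=bool)
        if self.valid_pair_count is None:
            self.valid_pair_count = np.zeros(len(self.barcodes), dtype=np.int64)
        self._index = {b: i for i, b in enumerate(self.barcodes)}

    @property
    def cell_barcodes(self) -> list[str]:
        return [b for b, c in zip(self.barcodes, self.is_cell) if c]

    @property
    def n_cells(self) -> int:
        return int(self.is_cell.sum())

    def index_of(self, barcode: str) -> int:
        return self._index[barcode]

    def is_cell_barcode(self, barcode: str) -> bool:
        i = self._index.get(barcode)
        return i is not None and bool(self.is_cell[i])

    def count_pair(self, barcode: str) -> None:
        self.valid_pair_count[self._index[barcode]] += 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "barcode": self.barcodes,
                "is__cell_barcode": self.is_cell.astype(int),
                "valid_pair_count": self.valid_pair_count,
            }
        )


def read_singlecell_csv(
    path: str | Path, cell_column: str = "is__cell_barcode"
) -> BarcodeTable:
    """Load a Cell Ranger ``singlecell.csv``-dialect table.

    Column 1 holds the barcode; ``cell_column`` holds the 0/1 cell call.
    """
    df = pd.read_csv(path)
    if cell_column not in df.columns:
        raise ValueError(f"{path}: missing cell-call column {cell_column!r}")
    barcodes = df.iloc[:, 0].astype(str).tolist()
    return BarcodeTable(barcodes=barcodes, is_cell=df[cell_column].to_numpy(dtype=bool))


def stream_bam_fragments(
    bam_path: str | Path,
    barcodes: BarcodeTable,
    cfg: FilterConfig = FilterConfig(),
    diagnostics: dict | None = None,
) -> Iterator[ValidFragment]:
    """Stream retained fragments from a coordinate-sorted BAM/SAM file.

    A read pair is retained iff it is paired, both mates mapped, the record is
    neither secondary nor supplementary, not duplicate-flagged (when
    ``cfg.dedupe_mode`` includes the flag), both mates map to the same
    chromosome, mapping quality exceeds ``cfg.min_mapq_exclusive``, the
    fragment (|TLEN|) is at most ``cfg.max_insert`` long, the chromosome is an
    autosome, and the barcode tag names a called cell.  Each pair is processed
    once, from its leftmost mate (TLEN > 0), and contributes the interval
    ``[pos, pos + TLEN)``.  ``barcodes.valid_pair_count`` is incremented per
    emitted fragment.  Records without the barcode tag are skipped and tallied
    in ``diagnostics['missing_barcode_tag']``.
    """
    import pysam

    use_flag_dedupe = cfg.dedupe_mode in {"flag", "both"}
    autosomes = set(cfg.autosomes)
    diag = diagnostics if diagnostics is not None else {}
    diag.setdefault("missing_barcode_tag", 0)
    diag.setdefault("emitted", 0)

    last: tuple[int, int] | None = None
    with pysam.AlignmentFile(str(bam_path), require_index=False) as af:
        so = af.header.get("HD", {}).get("SO")
        if so is not None and so != "coordinate":
            raise ValueError(f"{bam_path}: input not coordinate-sorted (SO={so})")
        for rec in af:
            if rec.is_unmapped:
                continue
            key = (rec.reference_id, rec.reference_start)
            if last is not None and key < last:
                raise ValueError(f"{bam_path}: alignments are not coordinate-sorted")
            last = key
            if not rec.is_paired or rec.mate_is_unmapped:
                continue
            if rec.is_secondary or rec.is_supplementary:
                continue
            if use_flag_dedupe and rec.is_duplicate:
                continue
            if rec.reference_id != rec.next_reference_id:
                continue
            if rec.mapping_quality <= cfg.min_mapq_exclusive:
                continue
            tlen = rec.template_length
            if tlen <= 0:  # process each pair once, from the leftmost mate
                continue
            if tlen > cfg.max_insert:
                continue
            chrom = rec.reference_name
            if chrom not in autosomes:
                continue
            try:
                bc = rec.get_tag(cfg.barcode_tag)
            except KeyError:
                diag["missing_barcode_tag"] += 1
                continue
            if not barcodes.is_cell_barcode(bc):
                continue
            barcodes.count_pair(bc)
            diag["emitted"] += 1
            yield ValidFragment(chrom, rec.reference_start, rec.reference_start + tlen, bc)


def _open_text(path: str | Path):
    p = str(path)
    if p.endswith(".gz"):
        return gzip.open(p, "rt")
    return open(p, "rt")


def stream_fragment_file(
    path: str | Path,
    barcodes: BarcodeTable,
    cfg: FilterConfig = FilterConfig(),
) -> Iterator[ValidFragment]:
    """Stream retained fragments from a 10x-style fragments TSV.

    Expects 5 columns (chrom, start, end, barcode, duplicate count), 0-based
    half-open, position-sorted; ``#`` comment lines are ignored.  The
    duplicate count is collapsed to a single fragment.  Autosome, length and
    cell-call filters apply; MAPQ and flag filters do not exist in this
    dialect.
    """
    autosomes = set(cfg.autosomes)
    last: tuple[str, int] | None = None
    last_chrom_rank: dict[str, int] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 5:
                raise ValueError(f"{path}:{lineno}: expected 5 columns, got {len(parts)}")
            chrom, s, e, bc = parts[0], parts[1], parts[2], parts[3]
            try:
                start, end = int(s), int(e)
                int(parts[4])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed numeric field") from exc
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end")
            if chrom not in last_chrom_rank:
                last_chrom_rank[chrom] = len(last_chrom_rank)
            key = (last_chrom_rank[chrom], start)
            if last is not None and key < last:
                raise ValueError(f"{path}:{lineno}: fragments file is not position-sorted")
            last = key
            if chrom not in autosomes:
                continue
            if end - start > cfg.max_insert:
                continue
            if not barcodes.is_cell_barcode(bc):
                continue
            barcodes.count_pair(bc)
            yield ValidFragment(chrom, start, end, bc)


def dedupe_coordinate(fragments: Iterable[ValidFragment]) -> Iterator[ValidFragment]:
    """Collapse coordinate duplicates: one fragment per (chrom, start, end, barcode).

    Input must be sorted by (chrom, start); order is preserved.  Memory stays
    bounded because only fragments sharing the current (chrom, start) need to
    be remembered.
    """
    cur_key: tuple[str, int] | None = None
    seen: set[tuple[int, str]] = set()
    for frag in fragments:
        key = (frag.chrom, frag.start)
        if key != cur_key:
            cur_key = key
            seen.clear()
        tail = (frag.end, frag.barcode)
        if tail in seen:
            continue
        seen.add(tail)
        yield frag


class FragmentSet:
    """Column-oriented container of ValidFragments for vectorised processing.

    Stores chromosome and barcode as integer codes alongside their name
    tables; this is the representation the sweep and the synthetic generator
    operate on directly, so multi-million-fragment samples never materialise
    Python objects.
    """

    def __init__(
        self,
        chrom_codes: np.ndarray,
        starts: np.ndarray,
        ends: np.ndarray,
        barcode_codes: np.ndarray,
        chrom_names: list[str],
        barcode_names: list[str],
    ) -> None:
        n = len(starts)
        if not (len(chrom_codes) == len(ends) == len(barcode_codes) == n):
            raise ValueError("column length mismatch")
        self.chrom_codes = np.asarray(chrom_codes, dtype=np.int32)
        self.starts = np.asarray(starts, dtype=np.int64)
        self.ends = np.asarray(ends, dtype=np.int64)
        self.barcode_codes = np.asarray(barcode_codes, dtype=np.int32)
        self.chrom_names = list(chrom_names)
        self.barcode_names = list(barcode_names)

    def __len__(self) -> int:
        return len(self.starts)

    @classmethod
    def from_fragments(
        cls, fragments: Iterable[ValidFragment], barcode_names: list[str] | None = None
    ) -> "FragmentSet":
        chroms: list[str] = []
        chrom_idx: dict[str, int] = {}
        bc_names = list(barcode_names) if barcode_names is not None else []
        bc_idx = {b: i for i, b in enumerate(bc_names)}
        grow_bc = barcode_names is None
        cc, ss, ee, bb = [], [], [], []
        for f in fragments:
            ci = chrom_idx.get(f.chrom)
            if ci is None:
                ci = chrom_idx[f.chrom] = len(chroms)
                chroms.append(f.chrom)
            bi = bc_idx.get(f.barcode)
            if bi is None:
                if not grow_bc:
                    raise KeyError(f"barcode {f.barcode!r} not in barcode table")
                bi = bc_idx[f.barcode] = len(bc_names)
                bc_names.append(f.barcode)
            cc.append(ci)
            ss.append(f.start)
            ee.append(f.end)
            bb.append(bi)
        return cls(
            np.array(cc, dtype=np.int32),
            np.array(ss, dtype=np.int64),
            np.array(ee, dtype=np.int64),
            np.array(bb, dtype=np.int32),
            chroms,
            bc_names,
        )

    def iter_fragments(self) -> Iterator[ValidFragment]:
        for ci, s, e, bi in zip(self.chrom_codes, self.starts, self.ends, self.barcode_codes):
            yield ValidFragment(self.chrom_names[ci], int(s), int(e), self.barcode_names[bi])

    def sort(self) -> "FragmentSet":
        """Return a copy sorted by (chrom code, start, end, barcode)."""
        order = np.lexsort((self.barcode_codes, self.ends, self.starts, self.chrom_codes))
        return FragmentSet(
            self.chrom_codes[order],
            self.starts[order],
            self.ends[order],
            self.barcode_codes[order],
            self.chrom_names,
            self.barcode_names,
        )
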