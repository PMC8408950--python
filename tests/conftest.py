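"""Shared fixtures: tiny in-memory samples and programmatic SAM/TSV writers."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pytest

from amulet.fragments import BarcodeTable, FilterConfig, ValidFragment


@pytest.fixture
def barcode_table():
    return BarcodeTable(
        barcodes=["AAA-1", "CCC-1", "GGG-1", "TTT-1"],
        is_cell=np.array([True, True, True, False]),
    )


@pytest.fixture
def filter_cfg():
    return FilterConfig()


def write_sam(
    path: Path,
    pairs: list[dict],
    chroms: dict[str, int] | None = None,
    sort_order: str = "coordinate",
) -> Path:
    """Write a SAM file of read pairs.

    Each pair dict: chrom, start (0-based), tlen, barcode (or None), and
    optional mapq (default 60), flags overrides (duplicate, secondary,
    mate_unmapped, mate_chrom), read_len (default 50).
    """
    import pysam

    chroms = chroms or {f"chr{i}": 10_000_000 for i in (1, 2, 23)}
    header = {
        "HD": {"VN": "1.6", "SO": sort_order},
        "SQ": [{"SN": name, "LN": ln} for name, ln in chroms.items()],
    }
    names = list(chroms)
    records = []
    for i, p in enumerate(pairs):
        chrom = p["chrom"]
        start = p["start"]
        tlen = p["tlen"]
        read_len = p.get("read_len", 50)
        mapq = p.get("mapq", 60)
        mate_chrom = p.get("mate_chrom", chrom)
        mate_start = p.get("mate_start", start + tlen - read_len)

        a = pysam.AlignedSegment()
        a.query_name = f"pair{i}"
        a.query_sequence = "A" * read_len
        a.query_qualities = pysam.qualitystring_to_array("I" * read_len)
        a.reference_id = names.index(chrom)
        a.reference_start = start
        a.cigarstring = f"{read_len}M"
        a.mapping_quality = mapq
        a.flag = 0x1 | 0x20 | 0x40  # paired, mate reverse, first in pair
        if p.get("duplicate"):
            a.flag |= 0x400
        if p.get("secondary"):
            a.flag |= 0x100
        if p.get("mate_unmapped"):
            a.flag |= 0x8
        a.next_reference_id = names.index(mate_chrom)
        a.next_reference_start = mate_start
        a.template_length = tlen
        if p.get("barcode") is not None:
            a.set_tag("CB", p["barcode"])

        b = pysam.AlignedSegment()
        b.query_name = f"pair{i}"
        b.query_sequence = "A" * read_len
        b.query_qualities = pysam.qualitystring_to_array("I" * read_len)
        b.reference_id = names.index(mate_chrom)
        b.reference_start = mate_start
        b.cigarstring = f"{read_len}M"
        b.mapping_quality = mapq
        b.flag = 0x1 | 0x10 | 0x80  # paired, reverse, second in pair
        if p.get("duplicate"):
            b.flag |= 0x400
        b.next_reference_id = names.index(chrom)
        b.next_reference_start = start
        b.template_length = -tlen
        if p.get("barcode") is not None:
            b.set_tag("CB", p["barcode"])

        if not p.get("mate_unmapped"):
            records.append(b)
        records.append(a)

    records.sort(key=lambda r: (r.reference_id, r.reference_start))
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for r in records:
            out.write(r)
    return path


def write_fragments_tsv(path: Path, fragments: list[tuple], dup: int = 1) -> Path:
    """Write 10x-style fragments TSV from (chrom, start, end, barcode) tuples."""
    rows = sorted(fragments, key=lambda f: (f[0], f[1]))
    with open(path, "w") as fh:
        for chrom, start, end, bc in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{bc}\t{dup}\n")
    return path


def brute_force_sites(
    fragments: list[ValidFragment], threshold: int = 2
) -> set[tuple[str, str, int, int, int]]:
    """Per-base depth oracle: (barcode, chrom, start, end, max_depth) tuples
    of maximal runs with depth > threshold."""
    by_group: dict[tuple[str, str], list[ValidFragment]] = {}
    for f in fragments:
        by_group.setdefault((f.barcode, f.chrom), []).append(f)
    out: set[tuple[str, str, int, int, int]] = set()
    for (bc, chrom), frags in by_group.items():
        hi = max(f.end for f in frags) + 1
        depth = np.zeros(hi, dtype=np.int64)
        for f in frags:
            depth[f.start : f.end] += 1
        above = depth > threshold
        # maximal runs of True
        padded = np.concatenate([[False], above, [False]])
        diff = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(diff == 1)
        ends = np.flatnonzero(diff == -1)
        for s, e in zip(starts, ends):
            out.add((bc, chrom, int(s), int(e), int(depth[s:e].max())))
    return out
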