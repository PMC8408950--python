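"""Per-nucleus overlap-depth sweep.

For every nucleus, finds each maximal genomic subinterval covered by more
than ``threshold`` (default 2) distinct fragments.  Breakpoints get +1 at a
fragment start and -1 at its end; visiting them in sorted order and keeping a
cumulative sum yields the overlap depth between consecutive breakpoints.  At
equal positions ends are processed before starts, so abutting half-open
fragments never count as overlapping.

The implementation is array-based: all (barcode, chromosome) groups are swept
in one pass over a single sorted breakpoint array.  Because every group's
deltas sum to zero, a global cumulative sum restarts at zero at each group
boundary by construction, so no per-group bookkeeping is needed.
"""

from __future__ import annotations

from typing import Iterable, NamedTuple

import numpy as np

from amulet.fragments import FragmentSet, ValidFragment

__all__ = ["OverlapSite", "SiteSet", "count_sites_per_nucleus", "sweep_overlap_sites", "sweep_site_set"]


class OverlapSite(NamedTuple):
    """Maximal subinterval of one nucleus covered by > threshold fragments."""

    chrom: str
    start: int
    end: int
    barcode: str
    max_depth: int


class SiteSet:
    """Array-of-columns container for overlap sites (mirrors FragmentSet)."""

    def __init__(
        self,
        chrom_codes: np.ndarray,
        starts: np.ndarray,
        ends: np.ndarray,
        barcode_codes: np.ndarray,
        max_depths: np.ndarray,
        chrom_names: list[str],
        barcode_names: list[str],
    ) -> None:
        self.chrom_codes = chrom_codes
        self.starts = starts
        self.ends = ends
        self.barcode_codes = barcode_codes
        self.max_depths = max_depths
        self.chrom_names = list(chrom_names)
        self.barcode_names = list(barcode_names)

    def __len__(self) -> int:
        return len(self.starts)

    def to_sites(self) -> list[OverlapSite]:
        return [
            OverlapSite(self.chrom_names[c], int(s), int(e), self.barcode_names[b], int(d))
            for c, s, e, b, d in zip(
                self.chrom_codes, self.starts, self.ends, self.barcode_codes, self.max_depths
            )
        ]

    def subset(self, mask: np.ndarray) -> "SiteSet":
        return SiteSet(
            self.chrom_codes[mask],
            self.starts[mask],
            self.ends[mask],
            self.barcode_codes[mask],
            self.max_depths[mask],
            self.chrom_names,
            self.barcode_names,
        )


def _check_sorted(fs: FragmentSet) -> None:
    cc, ss = fs.chrom_codes, fs.starts
    if len(cc) < 2:
        return
    changes = np.flatnonzero(np.diff(cc) != 0)
    # each chromosome code must form a single contiguous block
    block_codes = np.concatenate(([cc[0]], cc[changes + 1]))
    if len(np.unique(block_codes)) != len(block_codes):
        raise ValueError("fragments are not sorted: chromosome blocks are interleaved")
    same = np.diff(cc) == 0
    if np.any((np.diff(ss) < 0) & same):
        raise ValueError("fragments are not sorted by (chrom, start)")


def sweep_site_set(fragments: FragmentSet, threshold: int = 2, check_sorted: bool = True) -> SiteSet:
    """Vectorised sweep over all (barcode, chromosome) groups at once."""
    if check_sorted:
        _check_sorted(fragments)
    n = len(fragments)
    n_chrom = max(len(fragments.chrom_names), 1)
    if n == 0:
        empty_i = np.empty(0, dtype=np.int64)
        return SiteSet(
            empty_i.astype(np.int32), empty_i, empty_i, empty_i.astype(np.int32),
            empty_i, fragments.chrom_names, fragments.barcode_names,
        )

    group = fragments.barcode_codes.astype(np.int64) * n_chrom + fragments.chrom_codes
    pos = np.concatenate([fragments.starts, fragments.ends])
    delta = np.concatenate(
        [np.ones(n, dtype=np.int32), -np.ones(n, dtype=np.int32)]
    )
    grp2 = np.concatenate([group, group])

    max_pos = int(pos.max()) + 1
    max_grp = int(group.max()) + 1
    # pack (group, pos, is_start) into one int64 key when it fits; ends sort
    # before starts at equal positions so abutting fragments do not overlap
    pos_bits = int(max_pos).bit_length() + 1
    grp_bits = int(max_grp).bit_length()
    if pos_bits + grp_bits + 1 <= 62:
        key = (grp2 << (pos_bits + 1)) | (pos << 1) | (delta > 0).astype(np.int64)
        order = np.argsort(key, kind="stable")
    else:
        order = np.lexsort((delta, pos, grp2))

    pos_s = pos[order]
    depth = np.cumsum(delta[order])
    grp_s = grp2[order]

    # interval i spans [pos_s[i], pos_s[i+1]) at depth depth[i]; depth is 0 at
    # every group's last breakpoint, so cross-group intervals never qualify
    s_arr = pos_s[:-1]
    e_arr = pos_s[1:]
    d_arr = depth[:-1]
    g_arr = grp_s[:-1]
    qual = (d_arr > threshold) & (e_arr > s_arr)
    if not np.any(qual):
        empty_i = np.empty(0, dtype=np.int64)
        return SiteSet(
            empty_i.astype(np.int32), empty_i, empty_i, empty_i.astype(np.int32),
            empty_i, fragments.chrom_names, fragments.barcode_names,
        )
    sq, eq, dq, gq = s_arr[qual], e_arr[qual], d_arr[qual], g_arr[qual]

    # merge touching qualifying intervals (depth dips at a single point do not
    # split a site; positive-width dips do)
    new_site = np.ones(len(sq), dtype=bool)
    new_site[1:] = (gq[1:] != gq[:-1]) | (sq[1:] != eq[:-1])
    first = np.flatnonzero(new_site)
    last = np.concatenate([first[1:] - 1, [len(sq) - 1]])
    site_start = sq[first]
    site_end = eq[last]
    site_depth = np.maximum.reduceat(dq, first)
    site_grp = gq[first]
    return SiteSet(
        (site_grp % n_chrom).astype(np.int32),
        site_start.astype(np.int64),
        site_end.astype(np.int64),
        (site_grp // n_chrom).astype(np.int32),
        site_depth.astype(np.int64),
        fragments.chrom_names,
        fragments.barcode_names,
    )


def sweep_overlap_sites(
    fragments: FragmentSet | Iterable[ValidFragment], threshold: int = 2
) -> list[OverlapSite]:
    """Find all per-nucleus subintervals with more than ``threshold`` overlaps.

    ``fragments`` must be sorted by (chrom, start) and deduplicated.  Returns
    sites for all nuclei; a clean diploid nucleus (at most two fragments per
    locus) yields none at the default threshold.
    """
    if not isinstance(fragments, FragmentSet):
        fragments = FragmentSet.from_fragments(fragments)
    return sweep_site_set(fragments, threshold=threshold).to_sites()


def count_sites_per_nucleus(
    sites: Iterable[OverlapSite] | SiteSet, barcodes: Iterable[str] | None = None
) -> dict[str, int]:
    """Count overlap sites per barcode.

    ``barcodes``, when given, lists every cell barcode that must appear in the
    result (mapped to 0 when it has no sites).
    """
    counts: dict[str, int] = {b: 0 for b in barcodes} if barcodes is not None else {}
    if isinstance(sites, SiteSet):
        bc = np.bincount(sites.barcode_codes, minlength=len(sites.barcode_names))
        for code in np.flatnonzero(bc):
            name = sites.barcode_names[code]
            counts[name] = counts.get(name, 0) + int(bc[code])
        return counts
    for site in sites:
        counts[site.barcode] = counts.get(site.barcode, 0) + 1
    return counts
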