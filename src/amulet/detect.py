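"""Multiplet calling from per-nucleus overlap sites.

Pipeline: drop sites overlapping exclusion regions (simple repeats,
segmental duplications, RepeatMasker, blacklists), merge the surviving sites
across nuclei (>= 1 bp overlap), build a binary merged-region x nucleus
matrix, flag residual repetitive regions from the row sums and remove them,
then call multiplets from the column sums.  Both tests use the Poisson upper
tail with the respective mean row/column sum as the expectation, corrected
with Benjamini-Hochberg; calls are made at adjusted q < 0.01 by default.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from amulet.fragments import BarcodeTable, FragmentSet
from amulet.overlap import OverlapSite, SiteSet, sweep_site_set

__all__ = [
    "DetectionResult",
    "OverlapMatrix",
    "RegionSet",
    "bh_adjust",
    "build_matrix",
    "detect_multiplets",
    "filter_sites",
    "infer_repetitive",
    "load_region_beds",
    "merge_sites",
    "poisson_upper_tail",
    "run_detection",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# exclusion regions
# ---------------------------------------------------------------------------


class RegionSet:
    """Genomic intervals (0-based half-open) supporting fast overlap queries.

    Input intervals may overlap each other; they are merged internally per
    chromosome, which preserves overlap semantics while making each query a
    single binary search.
    """

    def __init__(self, intervals: Iterable[tuple[str, int, int]] = ()) -> None:
        self.intervals: list[tuple[str, int, int]] = list(intervals)
        self._merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in self.intervals:
            if start >= end:
                raise ValueError(f"degenerate interval {chrom}:{start}-{end}")
            by_chrom.setdefault(chrom, []).append((start, end))
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            starts, ends = [], []
            cur_s, cur_e = ivs[0]
            for s, e in ivs[1:]:
                if s < cur_e:  # strict: touching intervals share no base
                    cur_e = max(cur_e, e)
                else:
                    starts.append(cur_s)
                    ends.append(cur_e)
                    cur_s, cur_e = s, e
            starts.append(cur_s)
            ends.append(cur_e)
            self._merged[chrom] = (np.array(starts), np.array(ends))

    def __len__(self) -> int:
        return len(self.intervals)

    def overlaps(self, chrom: str, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        """Vectorised: does each query share >= 1 bp with any interval?"""
        starts = np.asarray(starts)
        ends = np.asarray(ends)
        if chrom not in self._merged:
            return np.zeros(len(starts), dtype=bool)
        ms, me = self._merged[chrom]
        # candidate = last merged interval starting at or before query end - 1
        idx = np.searchsorted(ms, ends - 1, side="right") - 1
        hit = idx >= 0
        hit[hit] = me[idx[hit]] > starts[hit]
        return hit

    def overlaps_one(self, chrom: str, start: int, end: int) -> bool:
        return bool(self.overlaps(chrom, np.array([start]), np.array([end]))[0])


def load_region_beds(paths: Sequence[str | Path]) -> RegionSet:
    """Union of intervals from BED3+ files (0-based half-open)."""
    intervals: list[tuple[str, int, int]] = []
    for path in paths:
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3:
                    raise ValueError(f"{path}:{lineno}: BED line has fewer than 3 columns")
                try:
                    start, end = int(parts[1]), int(parts[2])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: non-integer BED coordinates") from exc
                intervals.append((parts[0], start, end))
    return RegionSet(intervals)


def filter_sites(
    sites: list[OverlapSite] | SiteSet, excl: RegionSet
) -> list[OverlapSite] | SiteSet:
    """Remove every site sharing at least one base with an exclusion interval."""
    if isinstance(sites, SiteSet):
        keep = np.ones(len(sites), dtype=bool)
        for code, chrom in enumerate(sites.chrom_names):
            mask = sites.chrom_codes == code
            if not mask.any():
                continue
            keep[mask] = ~excl.overlaps(chrom, sites.starts[mask], sites.ends[mask])
        return sites.subset(keep)
    return [s for s in sites if not excl.overlaps_one(s.chrom, s.start, s.end)]


# ---------------------------------------------------------------------------
# merging and matrix construction
# ---------------------------------------------------------------------------


def merge_sites(sites: list[OverlapSite] | SiteSet) -> list[tuple[str, int, int]]:
    """Merge sites from all nuclei that overlap by >= 1 bp (transitively).

    Returns sorted, pairwise non-overlapping regions.
    """
    if isinstance(sites, SiteSet):
        items = zip(sites.chrom_codes, sites.starts, sites.ends)
        names = sites.chrom_names
        triples = sorted((int(c), int(s), int(e)) for c, s, e in items)
        keyed = [(names[c], s, e) for c, s, e in triples]
    else:
        keyed = sorted((s.chrom, s.start, s.end) for s in sites)
    merged: list[tuple[str, int, int]] = []
    for chrom, start, end in keyed:
        if merged and merged[-1][0] == chrom and start < merged[-1][2]:
            prev = merged[-1]
            merged[-1] = (chrom, prev[1], max(prev[2], end))
        else:
            merged.append((chrom, start, end))
    return merged


@dataclass
class OverlapMatrix:
    """Binary merged-region x nucleus matrix of >threshold overlap occurrences."""

    regions: list[tuple[str, int, int]]
    barcodes: list[str]
    M: sp.csr_matrix = field(repr=False)  # type: ignore[assignment]

    @property
    def row_sums(self) -> np.ndarray:
        return np.asarray(self.M.sum(axis=1)).ravel()

    @property
    def col_sums(self) -> np.ndarray:
        return np.asarray(self.M.sum(axis=0)).ravel()

    def drop_rows(self, mask: np.ndarray) -> "OverlapMatrix":
        keep = ~np.asarray(mask, dtype=bool)
        return OverlapMatrix(
            regions=[r for r, k in zip(self.regions, keep) if k],
            barcodes=self.barcodes,
            M=self.M[keep],
        )


def build_matrix(
    merged: list[tuple[str, int, int]],
    sites: list[OverlapSite] | SiteSet,
    barcodes: Sequence[str],
) -> OverlapMatrix:
    """Binary matrix M[r, b] = 1 iff any site of nucleus b overlaps region r."""
    barcodes = list(barcodes)
    bc_index = {b: i for i, b in enumerate(barcodes)}
    n_regions = len(merged)

    # per-chromosome sorted region starts for site -> region assignment
    region_rows: list[int] = []
    region_cols: list[int] = []
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom in {r[0] for r in merged}:
        idx = np.array([i for i, r in enumerate(merged) if r[0] == chrom])
        starts = np.array([merged[i][1] for i in idx])
        ends = np.array([merged[i][2] for i in idx])
        by_chrom[chrom] = (starts, ends, idx)

    def assign(chrom: str, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        if chrom not in by_chrom:
            raise AssertionError(f"site on {chrom} overlaps no merged region")
        ms, me, idx = by_chrom[chrom]
        j = np.searchsorted(ms, starts, side="right") - 1
        ok = (j >= 0) & (me[np.clip(j, 0, None)] > starts)
        if not np.all(ok):
            raise AssertionError("site overlaps no merged region (construction bug)")
        return idx[j]

    if isinstance(sites, SiteSet):
        code_to_col = np.full(len(sites.barcode_names), -1, dtype=np.int64)
        for code, name in enumerate(sites.barcode_names):
            col = bc_index.get(name)
            if col is not None:
                code_to_col[code] = col
        for code, chrom in enumerate(sites.chrom_names):
            mask = sites.chrom_codes == code
            if not mask.any():
                continue
            rows = assign(chrom, sites.starts[mask], sites.ends[mask])
            cols_arr = code_to_col[sites.barcode_codes[mask]]
            if np.any(cols_arr < 0):
                raise KeyError("site barcode missing from barcode list")
            region_rows.extend(rows.tolist())
            region_cols.extend(cols_arr.tolist())
    else:
        for s in sites:
            row = assign(s.chrom, np.array([s.start]), np.array([s.end]))[0]
            region_rows.append(int(row))
            region_cols.append(bc_index[s.barcode])

    data = np.ones(len(region_rows), dtype=np.int8)
    M = sp.coo_matrix(
        (data, (region_rows, region_cols)), shape=(n_regions, len(barcodes))
    ).tocsr()
    M.data[:] = 1  # binary: multiple sites of one nucleus in one region count once
    return OverlapMatrix(regions=list(merged), barcodes=barcodes, M=M)


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------


def poisson_upper_tail(k, lam):
    """P(X >= k) for X ~ Poisson(lam); inclusive upper tail, 1 - CDF(k - 1).

    Accepts scalars or arrays; k must be >= 0 and lam > 0.
    """
    k_arr = np.asarray(k)
    lam_arr = np.asarray(lam, dtype=float)
    if np.any(k_arr < 0):
        raise ValueError("k must be non-negative")
    if np.any(lam_arr <= 0):
        raise ValueError("lambda must be positive (degenerate expectation)")
    p = stats.poisson.sf(k_arr - 1, lam_arr)
    if np.isscalar(k) and np.isscalar(lam):
        return float(p)
    return p


def bh_adjust(pvals: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, input order preserved.

    q_(i) = min_{j >= i} m * p_(j) / j over the sorted p-values, capped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def infer_repetitive(
    M: OverlapMatrix, fdr: float = 0.01
) -> tuple[pd.DataFrame, OverlapMatrix]:
    """Flag residual repetitive regions from row sums and drop them.

    A region observed with >threshold reads in significantly more nuclei than
    the mean row sum predicts (Poisson upper tail, BH across regions,
    q < ``fdr``) is considered repetitive and removed from the matrix.
    """
    n_regions = len(M.regions)
    cols = ["chrom", "start", "end", "n_nuclei", "lambda_row", "p", "q", "flagged"]
    if n_regions == 0:
        return pd.DataFrame(columns=cols), M
    row_sums = M.row_sums
    lam = float(row_sums.mean())
    if lam <= 0:
        calls = pd.DataFrame(
            {
                "chrom": [r[0] for r in M.regions],
                "start": [r[1] for r in M.regions],
                "end": [r[2] for r in M.regions],
                "n_nuclei": row_sums,
                "lambda_row": lam,
                "p": 1.0,
                "q": 1.0,
                "flagged": False,
            }
        )
        return calls, M
    p = poisson_upper_tail(row_sums, lam)
    q = bh_adjust(p)
    flagged = q < fdr
    calls = pd.DataFrame(
        {
            "chrom": [r[0] for r in M.regions],
            "start": [r[1] for r in M.regions],
            "end": [r[2] for r in M.regions],
            "n_nuclei": row_sums,
            "lambda_row": lam,
            "p": p,
            "q": q,
            "flagged": flagged,
        }
    )
    reduced = M.drop_rows(flagged) if flagged.any() else M
    return calls, reduced


def detect_multiplets(
    M_reduced: OverlapMatrix, fdr: float = 0.01, include_zero: bool = True
) -> pd.DataFrame:
    """Call multiplets from column sums of the repetitive-filtered matrix.

    The expectation is the mean column sum recomputed on the reduced matrix;
    the BH family spans all cell barcodes (k = 0 nuclei get p = 1) unless
    ``include_zero`` is False, in which case only nuclei with k > 0 are
    tested.  ``is_multiplet`` is q < ``fdr``.
    """
    cols = ["barcode", "k", "lambda", "p", "q", "is_multiplet"]
    if len(M_reduced.barcodes) == 0:
        return pd.DataFrame(columns=cols)
    k = M_reduced.col_sums.astype(np.int64)
    lam = float(k.mean()) if len(M_reduced.regions) else 0.0
    if lam <= 0:
        warnings.warn("all column sums are zero; no multiplet calls made", stacklevel=2)
        return pd.DataFrame(
            {
                "barcode": M_reduced.barcodes,
                "k": k,
                "lambda": lam,
                "p": 1.0,
                "q": 1.0,
                "is_multiplet": False,
            }
        )
    calls = pd.DataFrame({"barcode": M_reduced.barcodes, "k": k, "lambda": lam})
    if include_zero:
        calls["p"] = poisson_upper_tail(k, lam)
        calls["q"] = bh_adjust(calls["p"].to_numpy())
    else:
        calls["p"] = 1.0
        calls["q"] = 1.0
        tested = k > 0
        p_tested = poisson_upper_tail(k[tested], lam)
        calls.loc[tested, "p"] = p_tested
        calls.loc[tested, "q"] = bh_adjust(p_tested)
    calls["is_multiplet"] = calls["q"] < fdr
    return calls


# ---------------------------------------------------------------------------
# end-to-end driver
# ---------------------------------------------------------------------------


@dataclass
class DetectionResult:
    calls: pd.DataFrame
    repetitive: pd.DataFrame
    merged_regions: list[tuple[str, int, int]]
    matrix: OverlapMatrix
    stage_counts: dict[str, int]

    @property
    def multiplet_barcodes(self) -> list[str]:
        return self.calls.loc[self.calls["is_multiplet"], "barcode"].tolist()


def run_detection(
    fragments: FragmentSet,
    barcode_table: BarcodeTable,
    exclusions: RegionSet | None = None,
    threshold: int = 2,
    fdr: float = 0.01,
    include_zero: bool = True,
    check_sorted: bool = False,
) -> DetectionResult:
    """Run sweep -> exclusion filter -> merge -> matrix -> row test -> column test.

    ``fragments`` must already be filtered/deduplicated (see amulet.fragments);
    only barcodes marked as cells in ``barcode_table`` are called.
    """
    cell_barcodes = barcode_table.cell_barcodes
    sites = sweep_site_set(fragments, threshold=threshold, check_sorted=check_sorted)
    n_raw = len(sites)
    if exclusions is not None and len(exclusions):
        sites = filter_sites(sites, exclusions)
    n_kept = len(sites)
    merged = merge_sites(sites)
    matrix = build_matrix(merged, sites, cell_barcodes)
    repetitive, reduced = infer_repetitive(matrix, fdr=fdr)
    calls = detect_multiplets(reduced, fdr=fdr, include_zero=include_zero)
    stage_counts = {
        "fragments": len(fragments),
        "sites": n_raw,
        "sites_after_exclusion": n_kept,
        "merged_regions": len(merged),
        "repetitive_regions": int(repetitive["flagged"].sum()) if len(repetitive) else 0,
        "cell_barcodes": len(cell_barcodes),
        "multiplets": int(calls["is_multiplet"].sum()) if len(calls) else 0,
    }
    logger.info("detection stage counts: %s", stage_counts)
    return DetectionResult(
        calls=calls,
        repetitive=repetitive,
        merged_regions=merged,
        matrix=reduced,
        stage_counts=stage_counts,
    )
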