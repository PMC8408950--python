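"""Synthetic snATAC samples with known multiplet truth.

The generative model follows the diploid counting principle the detector
relies on: each singlet nucleus contributes 0, 1 or 2 distinct fragments per
accessible peak (one per open allele), so no clean singlet ever shows more
than two overlapping fragments at a locus.  On top of that the generator can
add uniform noise reads over open chromatin, per-nucleus technical artifact
pileups (a depth-independent background of >2-read loci), repeat-element
hotspots shared across most nuclei (signal for repetitive-region inference),
and PCR duplicates.  Artificial multiplets are injected by the barcode
remapping protocol: 5% of nuclei are selected, paired (optionally re-paired
until heterotypic or homotypic), all reads of the second constituent are
reassigned to the first constituent's barcode, and the second barcode is
dropped from the cell list — yielding multiplets equal to 2.5% of the
population.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from amulet.fragments import BarcodeTable, FragmentSet

__all__ = [
    "CellTypeSpec",
    "MultipletTruth",
    "SyntheticSample",
    "SyntheticSpec",
    "evaluate_calls",
    "inject_artificial_multiplets",
    "make_synthetic_sample",
]


@dataclass(frozen=True)
class CellTypeSpec:
    name: str
    proportion: float
    marker_peak_idx: np.ndarray  # indices into SyntheticSpec peak table
    shared_peak_idx: np.ndarray


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic sample; see :meth:`toy` for a ready config."""

    n_nuclei: int
    cell_types: tuple[CellTypeSpec, ...]
    depth_per_nucleus: float  # median valid read pairs per nucleus
    noise_rate: float  # fraction of depth placed uniformly over shared peaks
    n_repeat_hotspots: int
    duplicate_rate: float
    seed: int
    chrom_names: tuple[str, ...]
    chrom_sizes: tuple[int, ...]
    peak_chrom: np.ndarray  # codes into chrom_names
    peak_start: np.ndarray
    peak_end: np.ndarray
    hotspot_chrom: np.ndarray
    hotspot_start: np.ndarray
    hotspot_end: np.ndarray
    allele_open_prob: float | None = None  # derived from depth when None
    artifact_rate: float = 0.0  # mean per-nucleus count of private >2 pileups
    hotspot_cell_frac: float = 0.85
    fragment_length_mean: float = 200.0
    fragment_length_sd: float = 25.0

    def __post_init__(self) -> None:
        total = sum(ct.proportion for ct in self.cell_types)
        if abs(total - 1.0) > 1e-8:
            raise ValueError(f"cell type proportions must sum to 1 (got {total})")
        for rate in (self.noise_rate, self.duplicate_rate, self.hotspot_cell_frac):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.allele_open_prob is not None and not 0.0 <= self.allele_open_prob <= 1.0:
            raise ValueError("allele_open_prob must lie in [0, 1]")
        if self.n_nuclei <= 0 or self.depth_per_nucleus <= 0:
            raise ValueError("n_nuclei and depth_per_nucleus must be positive")

    @property
    def n_peaks(self) -> int:
        return len(self.peak_start)

    def peak_regions(self) -> list[tuple[str, int, int]]:
        return [
            (self.chrom_names[c], int(s), int(e))
            for c, s, e in zip(self.peak_chrom, self.peak_start, self.peak_end)
        ]

    def hotspot_regions(self) -> list[tuple[str, int, int]]:
        return [
            (self.chrom_names[c], int(s), int(e))
            for c, s, e in zip(self.hotspot_chrom, self.hotspot_start, self.hotspot_end)
        ]

    @classmethod
    def toy(
        cls,
        n_nuclei: int = 400,
        depth: float = 25_000,
        n_cell_types: int = 4,
        n_peaks: int = 60_000,
        markers_per_type: int = 500,
        peak_width: int = 800,
        peak_spacing: int = 1_000,
        n_repeat_hotspots: int = 10,
        noise_rate: float = 0.01,
        artifact_rate: float = 3.0,
        duplicate_rate: float = 0.05,
        seed: int = 0,
        n_chroms: int = 2,
    ) -> "SyntheticSpec":
        """Small fictitious genome: peaks tiled on ``n_chroms`` chromosomes with
        a peak-free reserve at each chromosome end for repeat hotspots."""
        per_chrom = int(np.ceil(n_peaks / n_chroms))
        reserve = 200_000
        chrom_names = tuple(f"chr{i + 1}" for i in range(n_chroms))
        chrom_sizes = tuple(
            1_000 + per_chrom * peak_spacing + reserve for _ in range(n_chroms)
        )
        pc, ps = [], []
        for c in range(n_chroms):
            k = min(per_chrom, n_peaks - c * per_chrom)
            pc.append(np.full(k, c, dtype=np.int32))
            ps.append(1_000 + np.arange(k, dtype=np.int64) * peak_spacing)
        peak_chrom = np.concatenate(pc)
        peak_start = np.concatenate(ps)
        peak_end = peak_start + peak_width
        hs_chrom = np.arange(n_repeat_hotspots, dtype=np.int32) % n_chroms
        hs_rank = np.arange(n_repeat_hotspots) // n_chroms
        hs_start = np.array(
            [
                chrom_sizes[c] - reserve + 50_000 + r * 2_000
                for c, r in zip(hs_chrom, hs_rank)
            ],
            dtype=np.int64,
        )
        hs_end = hs_start + 300

        rng = np.random.default_rng(seed)
        marker_pool = rng.permutation(len(peak_start))
        types = []
        used = 0
        for t in range(n_cell_types):
            markers = np.sort(marker_pool[used : used + markers_per_type])
            used += markers_per_type
            types.append((f"type{chr(ord('A') + t)}", markers))
        all_markers = np.sort(marker_pool[:used])
        shared = np.setdiff1d(np.arange(len(peak_start)), all_markers)
        prop = 1.0 / n_cell_types
        cell_types = tuple(
            CellTypeSpec(
                name=name,
                proportion=prop if t < n_cell_types - 1 else 1.0 - prop * (n_cell_types - 1),
                marker_peak_idx=markers,
                shared_peak_idx=shared,
            )
            for t, (name, markers) in enumerate(types)
        )
        return cls(
            n_nuclei=n_nuclei,
            cell_types=cell_types,
            depth_per_nucleus=depth,
            noise_rate=noise_rate,
            n_repeat_hotspots=n_repeat_hotspots,
            duplicate_rate=duplicate_rate,
            seed=seed,
            chrom_names=chrom_names,
            chrom_sizes=chrom_sizes,
            peak_chrom=peak_chrom,
            peak_start=peak_start,
            peak_end=peak_end,
            hotspot_chrom=hs_chrom,
            hotspot_start=hs_start,
            hotspot_end=hs_end,
            artifact_rate=artifact_rate,
        )


@dataclass(frozen=True)
class MultipletTruth:
    """Ground truth for one injected artificial multiplet."""

    multiplet_barcode: str
    constituent_barcodes: tuple[str, ...]
    mode: str  # actual composition: "heterotypic" or "homotypic"
    constituent_types: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.constituent_barcodes) < 2:
            raise ValueError("a multiplet needs at least 2 constituents")


@dataclass
class SyntheticSample:
    """In-memory synthetic sample: fragments + cell calls + truth sidecars."""

    spec: SyntheticSpec
    fragments: FragmentSet  # deduplicated
    dup_counts: np.ndarray  # per unique fragment, >= 1
    barcode_table: BarcodeTable
    labels: dict[str, str]  # barcode -> cell type
    peak_counts: sp.csr_matrix  # peaks x all barcodes, on-peak fragments only
    truth: list[MultipletTruth] = field(default_factory=list)

    @property
    def barcodes(self) -> list[str]:
        return self.barcode_table.barcodes

    def inject(
        self, select_fraction: float = 0.05, mode: str = "any", seed: int = 0
    ) -> "SyntheticSample":
        """Return a copy with artificial multiplets injected by barcode remapping."""
        cells = self.barcode_table.cell_barcodes
        truth = inject_artificial_multiplets(
            cells, self.labels, select_fraction=select_fraction, mode=mode, seed=seed
        )
        bc_index = {b: i for i, b in enumerate(self.fragments.barcode_names)}
        remap = np.arange(len(self.fragments.barcode_names), dtype=np.int32)
        removed: set[str] = set()
        for t in truth:
            first, rest = t.constituent_barcodes[0], t.constituent_barcodes[1:]
            for b in rest:
                remap[bc_index[b]] = bc_index[first]
                removed.add(b)
        frags = FragmentSet(
            self.fragments.chrom_codes,
            self.fragments.starts,
            self.fragments.ends,
            remap[self.fragments.barcode_codes],
            self.fragments.chrom_names,
            self.fragments.barcode_names,
        )
        is_cell = self.barcode_table.is_cell.copy()
        vpc = self.barcode_table.valid_pair_count.copy()
        for t in truth:
            fi = self.barcode_table.index_of(t.constituent_barcodes[0])
            for b in t.constituent_barcodes[1:]:
                si = self.barcode_table.index_of(b)
                is_cell[si] = False
                vpc[fi] += vpc[si]
                vpc[si] = 0
        table = BarcodeTable(
            barcodes=list(self.barcode_table.barcodes),
            is_cell=is_cell,
            valid_pair_count=vpc,
        )
        # sum each removed constituent's count column into the multiplet column
        n_bc = len(self.barcode_table.barcodes)
        col_target = np.arange(n_bc, dtype=np.int64)
        for t in truth:
            fi = self.barcode_table.index_of(t.constituent_barcodes[0])
            for b in t.constituent_barcodes[1:]:
                col_target[self.barcode_table.index_of(b)] = fi
        S = sp.coo_matrix(
            (np.ones(n_bc, dtype=self.peak_counts.dtype), (np.arange(n_bc), col_target)),
            shape=(n_bc, n_bc),
        ).tocsr()
        counts = (self.peak_counts @ S).tocsr()
        return SyntheticSample(
            spec=self.spec,
            fragments=frags,
            dup_counts=self.dup_counts,
            barcode_table=table,
            labels=dict(self.labels),
            peak_counts=counts.tocsr(),
            truth=list(self.truth) + truth,
        )

    # -- writers (plain-text formats the CLI consumes unmodified) ----------

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fragments": outdir / "fragments.tsv",
            "singlecell": outdir / "singlecell.csv",
            "peaks": outdir / "peaks.bed",
            "clusters": outdir / "clusters.tsv",
            "truth": outdir / "truth.tsv",
            "hotspots": outdir / "hotspots.bed",
            "matrix": outdir / "matrix.mtx",
            "barcodes": outdir / "barcodes.tsv",
        }
        with open(paths["fragments"], "w") as fh:
            dup = self.dup_counts
            # dup_counts follow the original (unsorted) fragment order; re-sort
            sort_order = np.lexsort(
                (
                    self.fragments.barcode_codes,
                    self.fragments.ends,
                    self.fragments.starts,
                    self.fragments.chrom_codes,
                )
            )
            cc = self.fragments.chrom_codes[sort_order]
            ss = self.fragments.starts[sort_order]
            ee = self.fragments.ends[sort_order]
            bb = self.fragments.barcode_codes[sort_order]
            dd = dup[sort_order]
            names = self.fragments.chrom_names
            bnames = self.fragments.barcode_names
            for c, s, e, b, d in zip(cc, ss, ee, bb, dd):
                fh.write(f"{names[c]}\t{s}\t{e}\t{bnames[b]}\t{d}\n")
        self.barcode_table.to_frame().to_csv(paths["singlecell"], index=False)
        with open(paths["peaks"], "w") as fh:
            for chrom, s, e in self.spec.peak_regions():
                fh.write(f"{chrom}\t{s}\t{e}\n")
        with open(paths["hotspots"], "w") as fh:
            for chrom, s, e in self.spec.hotspot_regions():
                fh.write(f"{chrom}\t{s}\t{e}\n")
        pd.DataFrame(
            {"barcode": list(self.labels), "cell_type": list(self.labels.values())}
        ).to_csv(paths["clusters"], sep="\t", index=False)
        truth_rows = [
            {
                "multiplet_barcode": t.multiplet_barcode,
                "constituent_barcodes": ",".join(t.constituent_barcodes),
                "mode": t.mode,
                "constituent_types": ",".join(t.constituent_types),
            }
            for t in self.truth
        ]
        pd.DataFrame(
            truth_rows,
            columns=["multiplet_barcode", "constituent_barcodes", "mode", "constituent_types"],
        ).to_csv(paths["truth"], sep="\t", index=False)
        from scipy.io import mmwrite

        mmwrite(str(paths["matrix"]), self.peak_counts)
        with open(paths["barcodes"], "w") as fh:
            for b in self.barcodes:
                fh.write(b + "\n")
        return paths


def _expand_counts(cell_idx: np.ndarray, peak_idx: np.ndarray, counts: np.ndarray):
    rep = counts.astype(np.int64)
    return np.repeat(cell_idx, rep), np.repeat(peak_idx, rep)


def make_synthetic_sample(spec: SyntheticSpec, outdir: str | Path | None = None) -> SyntheticSample:
    """Generate one synthetic sample; optionally write its files to ``outdir``.

    Fully reproducible from ``spec.seed``: random streams for type assignment,
    alleles, jitter, noise, artifacts, hotspots and duplicates are split from
    one master generator so each purpose has an independent stream.
    """
    rng = np.random.default_rng(spec.seed)
    (r_assign, r_alleles, r_pos, r_noise, r_art, r_hot, r_dup, r_len) = rng.spawn(8)

    n = spec.n_nuclei
    barcodes = [f"BC{i:05d}-1" for i in range(n)]

    # cell type assignment by largest-remainder rounding, then shuffled
    props = np.array([ct.proportion for ct in spec.cell_types])
    base = np.floor(props * n).astype(int)
    rem = n - base.sum()
    frac_order = np.argsort(-(props * n - base))
    base[frac_order[:rem]] += 1
    type_of = np.repeat(np.arange(len(spec.cell_types)), base)
    type_of = type_of[r_assign.permutation(n)]

    depth = float(spec.depth_per_nucleus)
    cell_parts: list[np.ndarray] = []
    peak_parts: list[np.ndarray] = []

    # diploid fragments: 0/1/2 per accessible peak per nucleus
    for t, ct in enumerate(spec.cell_types):
        cells_t = np.flatnonzero(type_of == t)
        if len(cells_t) == 0:
            continue
        acc = np.concatenate([ct.marker_peak_idx, ct.shared_peak_idx])
        if spec.allele_open_prob is not None:
            p_open = spec.allele_open_prob
        else:
            p_open = min(0.95, depth * (1.0 - spec.noise_rate) / (2.0 * len(acc)))
        alleles = r_alleles.binomial(2, p_open, size=(len(cells_t), len(acc))).astype(np.int8)
        nz_cell, nz_peak = np.nonzero(alleles)
        ci, pi = _expand_counts(
            cells_t[nz_cell], acc[nz_peak], alleles[nz_cell, nz_peak]
        )
        cell_parts.append(ci.astype(np.int32))
        peak_parts.append(pi.astype(np.int32))

    # noise reads: uniform over shared peaks
    shared = spec.cell_types[0].shared_peak_idx
    if spec.noise_rate > 0 and len(shared):
        n_noise = r_noise.poisson(spec.noise_rate * depth, size=n)
        total = int(n_noise.sum())
        if total:
            cell_parts.append(np.repeat(np.arange(n, dtype=np.int32), n_noise))
            peak_parts.append(
                shared[r_noise.integers(0, len(shared), size=total)].astype(np.int32)
            )

    cell_idx = np.concatenate(cell_parts) if cell_parts else np.empty(0, dtype=np.int32)
    peak_idx = np.concatenate(peak_parts) if peak_parts else np.empty(0, dtype=np.int32)

    # on-peak fragment coordinates: jittered within the peak
    m = len(cell_idx)
    widths = (spec.peak_end - spec.peak_start)[peak_idx]
    lengths = np.clip(
        np.rint(r_len.normal(spec.fragment_length_mean, spec.fragment_length_sd, size=m)),
        50,
        np.minimum(widths - 1, 500),
    ).astype(np.int64)
    offsets = np.floor(r_pos.random(m) * (widths - lengths + 1)).astype(np.int64)
    starts = spec.peak_start[peak_idx] + offsets
    ends = starts + lengths
    chroms = spec.peak_chrom[peak_idx].astype(np.int32)

    frag_cell = [cell_idx]
    frag_chrom = [chroms]
    frag_start = [starts]
    frag_end = [ends]
    count_cell = cell_idx  # on-peak fragments feed the peak-count matrix
    count_peak = peak_idx

    # technical artifact pileups: per nucleus, Poisson(artifact_rate) loci with
    # 3 mutually overlapping fragments at a uniform random genome position
    if spec.artifact_rate > 0:
        n_art = r_art.poisson(spec.artifact_rate, size=n)
        total = int(n_art.sum())
        if total:
            art_cell = np.repeat(np.arange(n, dtype=np.int32), n_art)
            sizes = np.array(spec.chrom_sizes, dtype=np.float64)
            probs = sizes / sizes.sum()
            art_chrom = r_art.choice(len(sizes), size=total, p=probs).astype(np.int32)
            span = 250
            art_pos = np.floor(
                r_art.random(total) * (sizes[art_chrom] - span - 100)
            ).astype(np.int64)
            for copy in range(3):
                jit = r_art.integers(0, 40, size=total)
                s = art_pos + jit
                frag_cell.append(art_cell)
                frag_chrom.append(art_chrom)
                frag_start.append(s)
                frag_end.append(s + span - copy)  # distinct coords after dedup

    # repeat hotspots: most nuclei pile >2 overlapping fragments at the locus
    if spec.n_repeat_hotspots > 0:
        for h in range(spec.n_repeat_hotspots):
            has = r_hot.random(n) < spec.hotspot_cell_frac
            cells_h = np.flatnonzero(has)
            reps = 3 + r_hot.poisson(0.7, size=len(cells_h))
            hc = np.repeat(cells_h.astype(np.int32), reps)
            k = len(hc)
            s = spec.hotspot_start[h] + r_hot.integers(0, 50, size=k)
            lo = 180 + r_hot.integers(0, 60, size=k)
            frag_cell.append(hc)
            frag_chrom.append(np.full(k, spec.hotspot_chrom[h], dtype=np.int32))
            frag_start.append(s.astype(np.int64))
            frag_end.append((s + lo).astype(np.int64))

    all_cell = np.concatenate(frag_cell)
    all_chrom = np.concatenate(frag_chrom)
    all_start = np.concatenate(frag_start)
    all_end = np.concatenate(frag_end)

    dup = np.ones(len(all_cell), dtype=np.int32)
    if spec.duplicate_rate > 0:
        dup += (r_dup.random(len(all_cell)) < spec.duplicate_rate).astype(np.int32)

    fragments = FragmentSet(
        all_chrom, all_start, all_end, all_cell, list(spec.chrom_names), barcodes
    )
    counts = sp.coo_matrix(
        (
            np.ones(len(count_cell), dtype=np.int32),
            (count_peak, count_cell),
        ),
        shape=(spec.n_peaks, n),
    ).tocsr()
    table = BarcodeTable(
        barcodes=barcodes,
        is_cell=np.ones(n, dtype=bool),
        valid_pair_count=np.bincount(all_cell, minlength=n).astype(np.int64),
    )
    labels = {barcodes[i]: spec.cell_types[type_of[i]].name for i in range(n)}
    sample = SyntheticSample(
        spec=spec,
        fragments=fragments,
        dup_counts=dup,
        barcode_table=table,
        labels=labels,
        peak_counts=counts,
    )
    if outdir is not None:
        sample.write(outdir)
    return sample


def inject_artificial_multiplets(
    barcodes: Sequence[str],
    cluster_labels: Mapping[str, str] | None,
    select_fraction: float = 0.05,
    mode: str = "any",
    seed: int = 0,
    max_attempts: int = 10_000,
) -> list[MultipletTruth]:
    """Select nuclei and pair them into artificial multiplets.

    ``floor(select_fraction * N)`` nuclei (rounded down to even) are drawn
    without replacement and paired, yielding multiplets equal to half that
    number — 2.5% of the population at the default 5% selection.  In
    ``heterotypic``/``homotypic`` mode, a candidate partner is re-drawn until
    the pair satisfies the constraint per ``cluster_labels``.  The first
    constituent's barcode becomes the multiplet barcode.
    """
    if mode not in {"any", "heterotypic", "homotypic"}:
        raise ValueError(f"unknown mode {mode!r}")
    if mode != "any" and cluster_labels is None:
        raise ValueError(f"{mode} mode requires cluster labels")
    n = len(barcodes)
    n_sel = int(select_fraction * n)
    n_sel -= n_sel % 2
    if n_sel < 2:
        raise ValueError("select_fraction * N must select at least 2 nuclei")
    n_pairs = n_sel // 2

    rng = np.random.default_rng(seed)
    order = rng.permutation(n).tolist()
    used: set[int] = set()
    truth: list[MultipletTruth] = []
    pos = 0

    def next_unused(start: int) -> int | None:
        i = start
        while i < len(order):
            if order[i] not in used:
                return i
            i += 1
        return None

    attempts = 0
    while len(truth) < n_pairs:
        ia = next_unused(pos)
        if ia is None:
            raise RuntimeError("ran out of nuclei while pairing multiplets")
        a = order[ia]
        used.add(a)
        pos = ia + 1
        b = None
        j = pos
        while True:
            ib = next_unused(j)
            if ib is None:
                raise RuntimeError(
                    f"could not form a {mode} pair; clusters may be too small"
                )
            cand = order[ib]
            la = cluster_labels[barcodes[a]] if cluster_labels else None
            lb = cluster_labels[barcodes[cand]] if cluster_labels else None
            ok = (
                mode == "any"
                or (mode == "heterotypic" and la != lb)
                or (mode == "homotypic" and la == lb)
            )
            attempts += 1
            if attempts > max_attempts * n_pairs:
                raise RuntimeError(f"exceeded pairing attempts for mode {mode!r}")
            if ok:
                b = cand
                used.add(b)
                break
            j = ib + 1
        la = cluster_labels[barcodes[a]] if cluster_labels else "NA"
        lb = cluster_labels[barcodes[b]] if cluster_labels else "NA"
        actual = "heterotypic" if la != lb else "homotypic"
        truth.append(
            MultipletTruth(
                multiplet_barcode=barcodes[a],
                constituent_barcodes=(barcodes[a], barcodes[b]),
                mode=actual if cluster_labels else mode,
                constituent_types=(la, lb),
            )
        )
    return truth


def evaluate_calls(
    truth: Sequence[MultipletTruth],
    calls: Sequence[str] | pd.DataFrame,
) -> dict[str, float | int | None]:
    """Recall and worst-case precision of multiplet calls against truth.

    ``calls`` may be a list of called barcodes or a detection DataFrame with
    ``barcode``/``is_multiplet`` columns.  Precision is a lower bound: every
    call that is not an injected multiplet counts as a false positive even
    though it may be a genuine one.
    """
    if isinstance(calls, pd.DataFrame):
        called = set(calls.loc[calls["is_multiplet"], "barcode"])
    else:
        called = set(calls)
    true_bcs = {t.multiplet_barcode for t in truth}
    hits = len(called & true_bcs)
    return {
        "n_true": len(true_bcs),
        "n_called": len(called),
        "n_hit": hits,
        "recall": (hits / len(true_bcs)) if true_bcs else None,
        "precision_lower_bound": (hits / len(called)) if called else None,
    }
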