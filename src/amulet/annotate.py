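"""Cell-type-of-origin annotation for detected multiplets.

Marker peaks are found per cell type by one-vs-rest logistic regression on
normalised accessibility (likelihood-ratio test against the intercept-only
model, Bonferroni-adjusted, top 100 kept for types with >= 150 cells).  Cells
are embedded with truncated SVD of the term-frequency-scaled peak matrix, raw
counts at marker peaks are smoothed by averaging over each cell's k nearest
neighbours (self included), and each smoothed value is converted to a score
in (0, 1] via the empirical CDF over all cells.  A multiplet's per-type score
is the mean over that type's markers; its Euclidean distance to the singlet
mean profile of its most-associated type feeds a 1-D Gaussian mixture (1-3
components by BIC).  Members of the largest-mean component are heterotypic
(annotated with the top-2 types), the rest homotypic (top-1).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

__all__ = [
    "AssociationProfiles",
    "MarkerPeakSet",
    "PeakCountMatrix",
    "annotate_multiplets",
    "association_scores",
    "classify_and_annotate",
    "find_marker_peaks",
    "knn_aggregate",
    "read_peak_count_matrix",
    "singlet_mean_profiles",
    "svd_embedding",
]

logger = logging.getLogger(__name__)


@dataclass
class PeakCountMatrix:
    """Sparse peak x barcode count matrix with its sidecar labels."""

    peaks: list[tuple[str, int, int]]
    barcodes: list[str]
    counts: sp.csr_matrix  # peaks x barcodes, non-negative ints

    def __post_init__(self) -> None:
        if self.counts.shape != (len(self.peaks), len(self.barcodes)):
            raise ValueError("count matrix shape does not match sidecars")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be non-negative")

    def subset_barcodes(self, keep: Sequence[str]) -> "PeakCountMatrix":
        idx = {b: i for i, b in enumerate(self.barcodes)}
        cols = [idx[b] for b in keep]
        return PeakCountMatrix(self.peaks, list(keep), self.counts[:, cols].tocsr())


def read_peak_count_matrix(
    mtx_path: str | Path, peaks_bed: str | Path, barcodes_tsv: str | Path
) -> PeakCountMatrix:
    """Load a Matrix Market triplet matrix with peak/barcode sidecar files."""
    from scipy.io import mmread

    counts = sp.csr_matrix(mmread(str(mtx_path)))
    peaks: list[tuple[str, int, int]] = []
    with open(peaks_bed) as fh:
        for line in fh:
            if not line.strip():
                continue
            c, s, e = line.split("\t")[:3]
            peaks.append((c, int(s), int(e)))
    with open(barcodes_tsv) as fh:
        barcodes = [line.strip() for line in fh if line.strip()]
    return PeakCountMatrix(peaks=peaks, barcodes=barcodes, counts=counts)


@dataclass
class MarkerPeakSet:
    """Top marker peaks per eligible cell type.

    ``tables`` maps cell type -> DataFrame(peak_index, adjusted_p, avg_logFC)
    sorted by (adjusted_p asc, |avg_logFC| desc).
    """

    tables: dict[str, pd.DataFrame]

    @property
    def cell_types(self) -> list[str]:
        return list(self.tables)

    def peak_indices(self, cell_type: str) -> np.ndarray:
        return self.tables[cell_type]["peak_index"].to_numpy()

    @property
    def all_peak_indices(self) -> np.ndarray:
        """Concatenated marker peak indices, grouped by cell type."""
        return np.concatenate([self.peak_indices(t) for t in self.tables])

    def type_slices(self) -> dict[str, slice]:
        out: dict[str, slice] = {}
        start = 0
        for t in self.tables:
            k = len(self.tables[t])
            out[t] = slice(start, start + k)
            start += k
        return out


def _normalise_accessibility(counts: sp.csr_matrix) -> sp.csr_matrix:
    """log1p of depth-normalised counts (per-cell term frequency x 1e4)."""
    c = counts.tocsc().astype(np.float64)
    depth = np.asarray(c.sum(axis=0)).ravel()
    depth[depth == 0] = 1.0
    scale = sp.diags(1e4 / depth)
    x = (c @ scale).tocsr()
    x.data = np.log1p(x.data)
    return x


def _logistic_lrt(x: np.ndarray, y: np.ndarray, max_iter: int = 30) -> np.ndarray:
    """Vectorised single-predictor logistic regression LRT p-values.

    ``x`` is (n_peaks, n_cells), ``y`` the binary group label.  For each peak,
    fits logit(P(y=1)) = b0 + b1 * x by Newton iterations and tests against
    the intercept-only model with a 1-df likelihood-ratio chi-square.
    Perfectly separating peaks do not converge in coefficients but their
    deviance does, which is all the test needs.
    """
    n_peaks, n_cells = x.shape
    ybar = y.mean()
    ll_null = n_cells * (ybar * np.log(ybar) + (1 - ybar) * np.log1p(-ybar))
    b0 = np.full(n_peaks, np.log(ybar / (1 - ybar)))
    b1 = np.zeros(n_peaks)
    yv = y[None, :]
    for _ in range(max_iter):
        eta = b0[:, None] + b1[:, None] * x
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
        w = np.maximum(mu * (1 - mu), 1e-10)
        r = yv - mu
        # 2x2 normal equations per peak
        sw = w.sum(axis=1)
        swx = (w * x).sum(axis=1)
        swxx = (w * x * x).sum(axis=1)
        g0 = r.sum(axis=1)
        g1 = (r * x).sum(axis=1)
        det = sw * swxx - swx * swx
        det = np.where(np.abs(det) < 1e-12, 1e-12, det)
        db0 = (swxx * g0 - swx * g1) / det
        db1 = (sw * g1 - swx * g0) / det
        step = np.clip(np.stack([db0, db1]), -5, 5)
        b0 += step[0]
        b1 += step[1]
        if np.max(np.abs(step)) < 1e-8:
            break
    eta = b0[:, None] + b1[:, None] * x
    # log-likelihood via log(sigmoid); stable formulation
    ll_fit = (yv * eta - np.logaddexp(0.0, eta)).sum(axis=1)
    lr = np.maximum(2.0 * (ll_fit - ll_null), 0.0)
    return stats.chi2.sf(lr, df=1)


def find_marker_peaks(
    counts: PeakCountMatrix,
    labels: Mapping[str, str],
    top_n: int = 100,
    min_cells: int = 150,
    chunk_size: int = 2048,
) -> MarkerPeakSet:
    """One-vs-rest marker peaks per cell type with >= ``min_cells`` members.

    P-values come from a logistic-regression likelihood-ratio test on
    normalised accessibility, Bonferroni-adjusted over peaks; the top
    ``top_n`` positive-fold-change peaks are kept, ranked by adjusted p then
    |avg logFC|.
    """
    lab = np.array([labels[b] for b in counts.barcodes])
    types, n_per = np.unique(lab, return_counts=True)
    eligible = [t for t, c in zip(types, n_per) if c >= min_cells]
    if len(eligible) < 2:
        raise ValueError(
            f"need >= 2 cell types with >= {min_cells} cells; got {len(eligible)}"
        )
    x_norm = _normalise_accessibility(counts.counts)
    n_peaks = len(counts.peaks)
    tables: dict[str, pd.DataFrame] = {}
    for t in eligible:
        y = (lab == t).astype(np.float64)
        pvals = np.empty(n_peaks)
        for lo in range(0, n_peaks, chunk_size):
            hi = min(lo + chunk_size, n_peaks)
            block = np.asarray(x_norm[lo:hi].todense())
            pvals[lo:hi] = _logistic_lrt(block, y)
        adj = np.minimum(pvals * n_peaks, 1.0)
        mean_in = np.asarray(counts.counts[:, y.astype(bool)].mean(axis=1)).ravel()
        mean_out = np.asarray(counts.counts[:, ~y.astype(bool)].mean(axis=1)).ravel()
        logfc = np.log((mean_in + 1e-3) / (mean_out + 1e-3))
        df = pd.DataFrame(
            {"peak_index": np.arange(n_peaks), "adjusted_p": adj, "avg_logFC": logfc}
        )
        df = df[df["avg_logFC"] > 0]
        df["abs_fc"] = df["avg_logFC"].abs()
        df = df.sort_values(
            ["adjusted_p", "abs_fc"], ascending=[True, False], kind="stable"
        ).drop(columns="abs_fc")
        tables[t] = df.head(top_n).reset_index(drop=True)
    return MarkerPeakSet(tables=tables)


def svd_embedding(
    counts: PeakCountMatrix | sp.spmatrix,
    n_components: int = 50,
    tf_scale: bool = True,
    random_state: int = 0,
) -> np.ndarray:
    """Embed cells in the top singular space of the (scaled) count matrix.

    Returns an (n_cells, n_components) coordinate matrix (U * S of the cells x
    peaks view).  ``n_components`` is reduced with a warning when it reaches
    the matrix rank limit.  Deterministic for a fixed ``random_state``.
    """
    from sklearn.decomposition import TruncatedSVD

    mat = counts.counts if isinstance(counts, PeakCountMatrix) else counts
    cells = sp.csr_matrix(mat).T.astype(np.float64)  # cells x peaks
    if tf_scale:
        depth = np.asarray(cells.sum(axis=1)).ravel()
        depth[depth == 0] = 1.0
        cells = sp.diags(1.0 / depth) @ cells
    limit = min(cells.shape) - 1
    if n_components > limit:
        warnings.warn(
            f"n_components={n_components} >= min(dim); reduced to {limit}",
            stacklevel=2,
        )
        n_components = limit
    svd = TruncatedSVD(n_components=n_components, random_state=random_state)
    return svd.fit_transform(cells)


def knn_aggregate(
    counts: PeakCountMatrix | sp.spmatrix,
    embedding: np.ndarray,
    peaks: MarkerPeakSet | np.ndarray,
    k: int = 15,
    include_self: bool = True,
) -> np.ndarray:
    """Average raw counts at marker peaks over each cell's k nearest neighbours.

    Neighbours are Euclidean in ``embedding``; the cell itself is part of the
    average when ``include_self`` (so k = 0 returns the raw counts).  Returns
    a dense (n_cells, n_marker_peaks) array ordered like
    ``peaks.all_peak_indices``.
    """
    from sklearn.neighbors import NearestNeighbors

    mat = counts.counts if isinstance(counts, PeakCountMatrix) else counts
    peak_idx = peaks.all_peak_indices if isinstance(peaks, MarkerPeakSet) else peaks
    marker = np.asarray(mat[peak_idx, :].todense(), dtype=np.float64).T  # cells x markers
    n_cells = marker.shape[0]
    if k >= n_cells:
        raise ValueError("k must be smaller than the number of cells")
    if k == 0:
        return marker.copy()
    nn = NearestNeighbors(n_neighbors=k + 1).fit(embedding)
    _, idx = nn.kneighbors(embedding)
    if not include_self:
        # drop each cell's own index from its neighbour list; when exact ties
        # hide it, drop the first (closest) column instead
        out_idx = np.empty((n_cells, k), dtype=idx.dtype)
        for i in range(n_cells):
            row = idx[i][idx[i] != i][:k]
            if len(row) < k:
                row = idx[i][1 : k + 1]
            out_idx[i] = row
        idx = out_idx
    return marker[idx].mean(axis=1)


@dataclass
class AssociationProfiles:
    """Per-cell ecdf scores at marker peaks plus per-type summary scores."""

    barcodes: list[str]
    peak_scores: np.ndarray  # cells x marker peaks, in (0, 1]
    type_scores: pd.DataFrame  # cells x cell types (mean over the type's markers)
    marker_peaks: MarkerPeakSet = field(repr=False)


def association_scores(
    aggregated: np.ndarray, peaks: MarkerPeakSet, barcodes: Sequence[str]
) -> AssociationProfiles:
    """Empirical-CDF score of each cell's aggregated signal at each marker peak.

    The ecdf is taken over all cells, so the cell with the maximum value at a
    peak scores exactly 1; a constant peak gives every cell 1 (degenerate but
    harmless).  Per-type summaries are the mean over the type's marker peaks.
    """
    n_cells, n_marker = aggregated.shape
    scores = np.empty_like(aggregated)
    for j in range(n_marker):
        col = aggregated[:, j]
        order = np.sort(col)
        scores[:, j] = np.searchsorted(order, col, side="right") / n_cells
    summaries = {
        t: scores[:, sl].mean(axis=1) for t, sl in peaks.type_slices().items()
    }
    return AssociationProfiles(
        barcodes=list(barcodes),
        peak_scores=scores,
        type_scores=pd.DataFrame(summaries, index=list(barcodes)),
        marker_peaks=peaks,
    )


def singlet_mean_profiles(
    profiles: AssociationProfiles,
    labels: Mapping[str, str],
    multiplet_barcodes: Sequence[str],
) -> pd.DataFrame:
    """Mean marker-peak score vector over each type's non-multiplet cells."""
    mset = set(multiplet_barcodes)
    bc_index = {b: i for i, b in enumerate(profiles.barcodes)}
    out: dict[str, np.ndarray] = {}
    for t in profiles.marker_peaks.cell_types:
        rows = [
            bc_index[b]
            for b in profiles.barcodes
            if b not in mset and labels.get(b) == t
        ]
        if not rows:
            raise ValueError(f"no singlet cells for type {t!r}")
        out[t] = profiles.peak_scores[rows].mean(axis=0)
    return pd.DataFrame(out).T


def _fit_distance_mixture(
    distances: np.ndarray, max_components: int = 3, random_state: int = 0
):
    from sklearn.mixture import GaussianMixture

    x = distances.reshape(-1, 1)
    best = None
    best_bic = np.inf
    limit = min(max_components, len(np.unique(distances)), len(distances))
    for c in range(1, max(limit, 1) + 1):
        # a tight minority component next to a broad one is easy for EM to
        # miss from k-means inits; many random restarts find the global fit
        gm = GaussianMixture(
            n_components=c,
            random_state=random_state,
            n_init=30,
            init_params="random_from_data",
            reg_covar=1e-8,
        ).fit(x)
        bic = gm.bic(x)
        if bic < best_bic:
            best, best_bic = gm, bic
    return best


def classify_and_annotate(
    profiles: AssociationProfiles,
    labels: Mapping[str, str],
    multiplet_barcodes: Sequence[str],
    random_state: int = 0,
) -> pd.DataFrame:
    """Classify multiplets homotypic/heterotypic and assign origin types.

    Singlet profiles (mean marker-peak score vectors over each type's
    non-multiplet cells) anchor the classification: each multiplet's Euclidean
    distance to the singlet profile of its top-scoring type is fitted with a
    1-D Gaussian mixture (1-3 components by BIC); the largest-mean component
    is heterotypic.  Heterotypic multiplets get the top-2 per-type scores as
    origins, homotypic the top-1.
    """
    mset = set(multiplet_barcodes)
    if not mset:
        raise ValueError("no multiplets to annotate")
    bc_index = {b: i for i, b in enumerate(profiles.barcodes)}
    missing = mset - set(bc_index)
    if missing:
        raise KeyError(f"multiplet barcodes absent from profiles: {sorted(missing)[:5]}")

    singlet_df = singlet_mean_profiles(profiles, labels, multiplet_barcodes)
    singlet_profiles = {t: singlet_df.loc[t].to_numpy() for t in singlet_df.index}

    type_names = list(profiles.type_scores.columns)
    records = []
    distances = np.empty(len(mset))
    ordered = list(multiplet_barcodes)
    for i, b in enumerate(ordered):
        row = profiles.type_scores.loc[b].to_numpy()
        rank = np.argsort(-row, kind="stable")
        top1 = type_names[rank[0]]
        top2 = type_names[rank[1]] if len(rank) > 1 else None
        d = float(
            np.linalg.norm(profiles.peak_scores[bc_index[b]] - singlet_profiles[top1])
        )
        distances[i] = d
        records.append({"barcode": b, "top1": top1, "top2": top2, "distance": d})

    if len(ordered) == 1:
        warnings.warn("single multiplet: mixture fit skipped, classified homotypic", stacklevel=2)
        het = np.array([False])
    else:
        gm = _fit_distance_mixture(distances, random_state=random_state)
        if gm.n_components == 1:
            warnings.warn(
                "distance mixture collapsed to one component; all classified homotypic",
                stacklevel=2,
            )
            het = np.zeros(len(ordered), dtype=bool)
        else:
            # the nearest component is the homotypic anchor, the farthest the
            # heterotypic one; the cut between them is their spread-weighted
            # midpoint, so a tight homotypic cluster next to a broad
            # heterotypic spread is split where the clusters actually divide
            means = gm.means_.ravel()
            sds = np.sqrt(gm.covariances_.reshape(len(means)))
            # floor the spreads so a near-degenerate singleton component
            # cannot drag the cut onto its own mean
            sds = np.maximum(sds, 0.05 * float(distances.std()))
            lo, hi = int(np.argmin(means)), int(np.argmax(means))
            cut = (means[lo] * sds[hi] + means[hi] * sds[lo]) / (sds[lo] + sds[hi])
            het = distances > cut

    out = []
    for rec, is_het in zip(records, het):
        out.append(
            {
                "barcode": rec["barcode"],
                "type_class": "heterotypic" if is_het else "homotypic",
                "origin1": rec["top1"],
                "origin2": rec["top2"] if is_het else "",
                "distance_to_top_singlet": rec["distance"],
            }
        )
    return pd.DataFrame(out)


def annotate_multiplets(
    counts: PeakCountMatrix,
    labels: Mapping[str, str],
    multiplet_barcodes: Sequence[str],
    k: int = 15,
    n_components: int = 50,
    top_markers: int = 100,
    min_cells: int = 150,
    random_state: int = 0,
) -> tuple[pd.DataFrame, MarkerPeakSet, AssociationProfiles]:
    """Full origin-annotation pipeline on a peak count matrix."""
    markers = find_marker_peaks(counts, labels, top_n=top_markers, min_cells=min_cells)
    embedding = svd_embedding(counts, n_components=n_components, random_state=random_state)
    aggregated = knn_aggregate(counts, embedding, markers, k=k)
    profiles = association_scores(aggregated, markers, counts.barcodes)
    calls = classify_and_annotate(
        profiles, labels, multiplet_barcodes, random_state=random_state
    )
    logger.info(
        "annotated %d multiplets (%d heterotypic)",
        len(calls),
        int((calls["type_class"] == "heterotypic").sum()),
    )
    return calls, markers, profiles
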