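"""Beta diversity as multivariate dispersion around group centroids.

The chain is: modified Gower dissimilarities between trap-level samples
(log-transformed abundances, so an order-of-magnitude change in abundance
weighs the same as a presence/absence change) -> principal-coordinates
embedding that retains negative-eigenvalue ("imaginary") axes -> Euclidean
distance from every trap to the centroid of its spatial group, with the
standard signed squared-distance correction on the imaginary axes
(betadisper-style).  Dispersion is computed at four nested spatial scales
from one per-season embedding.

The PCoA here deliberately keeps the negative-eigenvalue axes: for a
non-Euclidean dissimilarity the identity

    d_ij^2 = ||x_i - x_j||^2(real axes) - ||y_i - y_j||^2(imaginary axes)

holds exactly, and dropping the imaginary part would bias every centroid
distance downward.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from scipy.spatial.distance import pdist, squareform
from skbio.stats.distance import DistanceMatrix

from .community import CommunityMatrix, TrapTable, build_community_matrix
from .errors import UndefinedPairError, ValidationError

logger = logging.getLogger(__name__)

#: The four spatial scales, mapping scale name -> metadata columns whose
#: combination defines a group.
SCALES: Mapping[str, tuple[str, ...]] = {
    "transect": ("transect",),
    "distance_category": ("distance_m",),
    "distance_by_transect": ("transect", "distance_m"),
    "sample_point": ("transect", "distance_m", "sample_point"),
}


def modified_gower(cm: CommunityMatrix, log_base: float = 10.0) -> DistanceMatrix:
    """Pairwise modified Gower dissimilarity between samples.

    Each count x is transformed to log_base(x) + 1 for x > 0 and 0 for
    absence; the dissimilarity of two samples is the mean absolute
    difference of transformed values over the species that are not absent
    from both.  With base 10 a tenfold abundance change contributes exactly
    as much as a gain/loss of one species.
    """
    if log_base <= 1:
        raise ValidationError("log_base must be > 1")
    C = cm.counts.to_numpy(dtype=float)
    if C.shape[0] < 2:
        raise ValidationError("need at least 2 samples for a dissimilarity matrix")
    X = np.where(C > 0, np.log(np.where(C > 0, C, 1.0)) / np.log(log_base) + 1.0, 0.0)
    L1 = squareform(pdist(X, metric="cityblock"))
    present = C > 0
    r = present.sum(axis=1)
    shared_absent_free = r[:, None] + r[None, :] - (present @ present.T)  # |union of present species|
    bad = (shared_absent_free == 0) & ~np.eye(len(r), dtype=bool)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise UndefinedPairError(
            f"samples {cm.sample_ids[i]!r} and {cm.sample_ids[j]!r} share no "
            "non-absent species; dissimilarity undefined (empty samples?)"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        D = np.where(shared_absent_free > 0, L1 / np.maximum(shared_absent_free, 1), 0.0)
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix((D + D.T) / 2.0, ids=cm.sample_ids)


@dataclass
class OrdinationEmbedding:
    """Principal-coordinates embedding keeping both eigenvalue signs.

    ``real`` holds coordinates on positive-eigenvalue axes, ``imag`` on
    negative-eigenvalue axes (scaled by sqrt(|eigenvalue|)); ``eigvals`` are
    all retained eigenvalues, positive ones descending then negative ones by
    magnitude descending.
    """

    ids: list[str]
    real: np.ndarray
    imag: np.ndarray
    eigvals: np.ndarray

    @property
    def n_samples(self) -> int:
        return len(self.ids)

    def squared_distance(self, i: int, j: int) -> float:
        """Signed reconstruction of the squared input dissimilarity."""
        dp = float(((self.real[i] - self.real[j]) ** 2).sum())
        dm = float(((self.imag[i] - self.imag[j]) ** 2).sum())
        return dp - dm


def pcoa(D: DistanceMatrix | np.ndarray, ids: Sequence[str] | None = None,
         rel_tol: float = 1e-10) -> OrdinationEmbedding:
    """Principal coordinates of a dissimilarity matrix, negative axes kept.

    Gower-centres -D^2/2 and eigendecomposes it; eigenvalues with magnitude
    below ``rel_tol`` times the largest magnitude are treated as zero.
    """
    if isinstance(D, DistanceMatrix):
        ids = list(D.ids)
        A = D.data.astype(float)
    else:
        A = np.asarray(D, dtype=float)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValidationError("dissimilarity matrix must be square")
        if not np.allclose(A, A.T, atol=1e-12):
            raise ValidationError("dissimilarity matrix must be symmetric")
        ids = list(ids) if ids is not None else [str(i) for i in range(A.shape[0])]
    n = A.shape[0]
    G = -0.5 * A ** 2
    G = G - G.mean(axis=0, keepdims=True) - G.mean(axis=1, keepdims=True) + G.mean()
    w, V = eigh((G + G.T) / 2.0)
    scale = max(np.abs(w).max(), np.finfo(float).tiny)
    tol = rel_tol * scale
    pos = w > tol
    neg = w < -tol
    order_pos = np.argsort(-w[pos])
    order_neg = np.argsort(w[neg])  # most negative first
    real = V[:, pos][:, order_pos] * np.sqrt(w[pos][order_pos])
    imag = V[:, neg][:, order_neg] * np.sqrt(-w[neg][order_neg])
    eigvals = np.concatenate([w[pos][order_pos], w[neg][order_neg]])
    return OrdinationEmbedding(ids, real, imag, eigvals)


@dataclass
class DispersionResult:
    """Per-sample distances to group centroids at one spatial scale."""

    scale: str
    season: str | None
    table: pd.DataFrame  # columns: sample, group, distance, clamped
    n_excluded_empty: int = 0

    @property
    def n_clamped(self) -> int:
        return int(self.table["clamped"].sum())

    @property
    def mean_distance(self) -> float:
        return float(self.table["distance"].mean())


def dispersion(embedding: OrdinationEmbedding, grouping: Mapping[str, object],
               scale: str = "custom", season: str | None = None) -> DispersionResult:
    """Distance from every sample to the centroid of its group.

    Squared distances on real axes minus squared distances on imaginary
    axes, clamped at zero (clamp events are counted in the output and
    logged).  Singleton groups yield distance 0.
    """
    missing = [s for s in embedding.ids if s not in grouping]
    if missing:
        raise ValidationError(f"samples missing from grouping: {missing[:5]}")
    groups = pd.Series([grouping[s] for s in embedding.ids], index=embedding.ids)
    dist = np.empty(embedding.n_samples)
    clamped = np.zeros(embedding.n_samples, dtype=bool)
    idx = {s: i for i, s in enumerate(embedding.ids)}
    for g, members in groups.groupby(groups):
        rows = np.array([idx[s] for s in members.index])
        cr = embedding.real[rows].mean(axis=0)
        ci = embedding.imag[rows].mean(axis=0) if embedding.imag.shape[1] else None
        d2 = ((embedding.real[rows] - cr) ** 2).sum(axis=1)
        if ci is not None:
            d2 = d2 - ((embedding.imag[rows] - ci) ** 2).sum(axis=1)
        clamped[rows] = d2 < 0
        dist[rows] = np.sqrt(np.clip(d2, 0.0, None))
    n_clamped = int(clamped.sum())
    if n_clamped:
        logger.info("dispersion scale=%s: %d negative squared distances clamped to 0",
                    scale, n_clamped)
    table = pd.DataFrame(
        {"sample": embedding.ids,
         "group": [str(grouping[s]) for s in embedding.ids],
         "distance": dist, "clamped": clamped}
    )
    return DispersionResult(scale, season, table)


def multiscale_dispersion(table: TrapTable, season: str,
                          log_base: float = 10.0) -> list[DispersionResult]:
    """Four-scale dispersion of one season's trap-level communities.

    All four scales are measured in a single per-season principal-coordinate
    space of trap samples.  Empty traps (no captures) are excluded before
    the dissimilarity step — their modified Gower distance is undefined —
    and the exclusion count is reported on every result.
    """
    cm = build_community_matrix(table, level="trap", season_filter=season)
    occupied = cm.counts.sum(axis=1) > 0
    n_empty = int((~occupied).sum())
    if n_empty:
        logger.info("season %s: excluding %d empty trap(s) from ordination", season, n_empty)
        cm = CommunityMatrix(cm.counts.loc[occupied],
                             cm.metadata.loc[occupied], cm.level, cm.zero_species_dropped)
    emb = pcoa(modified_gower(cm, log_base=log_base))
    results = []
    for scale, cols in SCALES.items():
        keys = cm.metadata[list(cols)].astype(str).agg("/".join, axis=1)
        res = dispersion(emb, keys.to_dict(), scale=scale, season=season)
        res.n_excluded_empty = n_empty
        results.append(res)
    return results


def dispersion_long_table(results: Sequence[DispersionResult],
                          metadata: pd.DataFrame | None = None) -> pd.DataFrame:
    """Stack DispersionResults into one long table (model-ready export)."""
    frames = []
    for r in results:
        t = r.table.copy()
        t["scale"] = r.scale
        t["season"] = r.season
        frames.append(t)
    out = pd.concat(frames, ignore_index=True)
    if metadata is not None:
        out = out.merge(metadata.reset_index(names="sample"), on="sample", how="left")
    return out
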