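"""Geometry of dissimilarity space: Gower centering, principal coordinates,
and centroid-distance identities.

Bray-Curtis is a semimetric, so the implied sample cloud lives in a space with
both real and imaginary axes (negative PCoA eigenvalues).  Every centroid
computation here follows the signed convention of distance-based MANOVA:
squared distances are (positive-axis part) - (negative-axis part), and any
negative squared result is clipped to zero with a warning while the raw value
is kept for diagnostics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .community import DissimilarityMatrix

__all__ = [
    "GowerMatrix",
    "PCoAResult",
    "ClipDiagnostics",
    "clip_diagnostics",
    "gower_center",
    "pcoa",
    "centroid_sq_distance",
    "distances_to_own_centroid",
]


class ClipDiagnostics:
    """Records negative squared centroid distances that were clipped to zero."""

    def __init__(self) -> None:
        self.events: list[float] = []

    def record(self, raw: float) -> None:
        self.events.append(float(raw))

    @property
    def count(self) -> int:
        return len(self.events)

    @property
    def worst(self) -> float:
        return min(self.events) if self.events else 0.0

    def reset(self) -> None:
        self.events.clear()


#: module-level diagnostic stream for clipped negative squared distances
clip_diagnostics = ClipDiagnostics()


@dataclass
class GowerMatrix:
    """G = -1/2 J A J with A_ij = d_ij^2 and J = I - (1/N) 11'.

    Row and column sums are zero; trace(G) is the total sum of squares
    (1/N) sum_{i<j} d_ij^2.
    """

    sample_ids: list
    G: np.ndarray

    def __post_init__(self) -> None:
        G = np.asarray(self.G, dtype=float)
        n = len(self.sample_ids)
        if G.shape != (n, n):
            raise ValueError("Gower matrix shape does not match sample count")
        scale = max(1.0, np.abs(G).max(initial=0.0))
        if np.abs(G.sum(axis=0)).max(initial=0.0) > 1e-10 * scale * n:
            raise ValueError("Gower matrix columns do not sum to zero")
        self.G = G
        self.sample_ids = list(self.sample_ids)

    @property
    def total_ss(self) -> float:
        return float(np.trace(self.G))


@dataclass
class PCoAResult:
    """Principal coordinates: real axes (positive eigenvalues) and imaginary
    axes (negative eigenvalues), each scaled by sqrt(|lambda|)."""

    sample_ids: list
    eigenvalues: np.ndarray        # descending, negligible ones dropped
    coords_pos: np.ndarray         # n x p, axes for positive eigenvalues
    coords_neg: np.ndarray         # n x q, axes for negative eigenvalues

    def to_dataframe(self):
        """Coordinates as a DataFrame (axes PCo1.. for real, iPCo1.. for
        imaginary), ready for CSV export and ordination plotting."""
        import pandas as pd

        cols = {f"PCo{k + 1}": self.coords_pos[:, k]
                for k in range(self.coords_pos.shape[1])}
        cols.update({f"iPCo{k + 1}": self.coords_neg[:, k]
                     for k in range(self.coords_neg.shape[1])})
        return pd.DataFrame(cols, index=self.sample_ids)

    def reconstructed_sq_distances(self) -> np.ndarray:
        """Signed squared distances: positive-axis part minus negative-axis part."""
        def sq(coords: np.ndarray) -> np.ndarray:
            if coords.shape[1] == 0:
                n = coords.shape[0]
                return np.zeros((n, n))
            sq_norm = (coords**2).sum(axis=1)
            d2 = sq_norm[:, None] + sq_norm[None, :] - 2.0 * coords @ coords.T
            return np.clip(d2, 0.0, None)

        return sq(self.coords_pos) - sq(self.coords_neg)


def gower_center(D: DissimilarityMatrix) -> GowerMatrix:
    A = D.values.astype(float) ** 2
    n = A.shape[0]
    # J A J expanded: avoids building J explicitly
    row_mean = A.mean(axis=1, keepdims=True)
    col_mean = A.mean(axis=0, keepdims=True)
    grand = A.mean()
    G = -0.5 * (A - row_mean - col_mean + grand)
    G = (G + G.T) / 2.0
    return GowerMatrix(D.sample_ids, G)


def pcoa(G: GowerMatrix, cutoff: float = 1e-9) -> PCoAResult:
    """Eigendecomposition of the Gower matrix.

    Axes with |lambda| below ``cutoff * max|lambda|`` are treated as
    numerical noise and dropped.
    """
    lam, vec = scipy.linalg.eigh(G.G)
    order = np.argsort(lam)[::-1]
    lam, vec = lam[order], vec[:, order]
    max_abs = np.abs(lam).max(initial=0.0)
    keep = np.abs(lam) > cutoff * max_abs if max_abs > 0 else np.zeros_like(lam, bool)
    lam, vec = lam[keep], vec[:, keep]
    coords = vec * np.sqrt(np.abs(lam))[None, :]
    pos = lam > 0
    return PCoAResult(
        sample_ids=list(G.sample_ids),
        eigenvalues=lam,
        coords_pos=coords[:, pos],
        coords_neg=coords[:, ~pos],
    )


def _clip_sq(raw: float, diagnostics: ClipDiagnostics | None) -> float:
    if raw < 0.0:
        (diagnostics or clip_diagnostics).record(raw)
        if raw < -1e-12:
            warnings.warn(
                f"negative squared centroid distance {raw:.3e} clipped to 0 "
                "(semimetric dissimilarity)",
                RuntimeWarning,
                stacklevel=3,
            )
        return 0.0
    return float(raw)


def centroid_sq_distance(
    D: DissimilarityMatrix,
    setA,
    setB,
    diagnostics: ClipDiagnostics | None = None,
) -> float:
    """Squared distance between the centroids of two sample sets.

    Works directly from the dissimilarities via the identity

        ||c_A - c_B||^2 = S(A,B)/(nA nB) - S(A,A)/(2 nA^2) - S(B,B)/(2 nB^2)

    where S(X,Y) is the full double sum of d_ij^2 over X x Y.  The identity
    holds in the (signed) PCoA embedding; for semimetric input the result can
    be negative and is clipped to zero (raw value recorded in diagnostics).
    """
    A = np.asarray(list(setA), dtype=int)
    B = np.asarray(list(setB), dtype=int)
    if A.size == 0 or B.size == 0:
        raise ValueError("centroid_sq_distance: empty sample set")
    d2 = D.values**2
    sAB = d2[np.ix_(A, B)].sum()
    sAA = d2[np.ix_(A, A)].sum()
    sBB = d2[np.ix_(B, B)].sum()
    raw = sAB / (A.size * B.size) - sAA / (2.0 * A.size**2) - sBB / (2.0 * B.size**2)
    return _clip_sq(raw, diagnostics)


def distances_to_own_centroid(
    D: DissimilarityMatrix,
    groups,
    diagnostics: ClipDiagnostics | None = None,
) -> np.ndarray:
    """Distance of every sample to its own group centroid (PERMDISP z_i).

    Computed in the signed PCoA embedding: z_i^2 = ||x_i - c||^2 on the real
    axes minus the same on the imaginary axes; negative z_i^2 clips to 0.
    Singleton groups give z = 0.
    """
    groups = np.asarray([str(g) for g in groups], dtype=object)
    if groups.shape[0] != D.n_samples:
        raise ValueError("one group label per sample required")
    res = pcoa(gower_center(D))
    z = np.zeros(D.n_samples)
    for g in np.unique(groups):
        idx = np.flatnonzero(groups == g)
        if idx.size == 1:
            z[idx[0]] = 0.0
            continue
        for coords, sign in ((res.coords_pos, +1.0), (res.coords_neg, -1.0)):
            if coords.shape[1] == 0:
                continue
            c = coords[idx].mean(axis=0)
            z[idx] += sign * ((coords[idx] - c) ** 2).sum(axis=1)
    for i in range(z.size):
        z[i] = _clip_sq(z[i], diagnostics)
    return np.sqrt(z)
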