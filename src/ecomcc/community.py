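"""Community abundance matrices: data model, CSV I/O, filtering, pooling,
the fourth-root transform and Bray-Curtis dissimilarity.

The central object is :class:`CommunityMatrix`, a samples x taxa table of
non-negative abundances (individuals per standard sample area) together with
per-sample metadata (site, plot, time, replicate).  All downstream analyses
operate on the :class:`DissimilarityMatrix` produced by :func:`bray_curtis`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from ._utils import time_sort_key

__all__ = [
    "CommunityMatrix",
    "DissimilarityMatrix",
    "CommunityFormatError",
    "CommunityValidationError",
    "read_community_csv",
    "write_community_csv",
    "filter_and_aggregate",
    "pool_replicates",
    "fourth_root_transform",
    "bray_curtis",
]

METADATA_COLUMNS = ("site", "plot", "time", "replicate")


class CommunityFormatError(ValueError):
    """Malformed input file (duplicates, bad header, unparsable cells)."""


class CommunityValidationError(ValueError):
    """Structurally valid input violating a domain invariant."""


@dataclass
class CommunityMatrix:
    """Samples x taxa abundance table with per-sample metadata.

    Parameters
    ----------
    abundance:
        DataFrame indexed by sample id, one column per taxon, non-negative
        real entries (counts per standard sample area; reals admitted so that
        pooled or standardized data validate).
    metadata:
        DataFrame indexed by sample id with columns site, plot, time,
        replicate.  (site, plot, time, replicate) tuples must be unique.
    """

    abundance: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        ab, md = self.abundance, self.metadata
        if ab.index.has_duplicates:
            dup = ab.index[ab.index.duplicated()][0]
            raise CommunityFormatError(f"duplicate sample label: {dup!r}")
        if ab.columns.has_duplicates:
            dup = ab.columns[ab.columns.duplicated()][0]
            raise CommunityFormatError(f"duplicate taxon label: {dup!r}")
        vals = ab.to_numpy(dtype=float)
        if np.isnan(vals).any():
            i, j = np.argwhere(np.isnan(vals))[0]
            raise CommunityValidationError(
                f"missing abundance for sample {ab.index[i]!r}, taxon {ab.columns[j]!r}"
            )
        if (vals < 0).any():
            i, j = np.argwhere(vals < 0)[0]
            raise CommunityValidationError(
                f"negative abundance at sample {ab.index[i]!r}, taxon {ab.columns[j]!r}"
            )
        missing = [c for c in METADATA_COLUMNS if c not in md.columns]
        if missing:
            raise CommunityValidationError(f"metadata missing column(s): {missing}")
        if not ab.index.equals(md.index):
            extra = set(ab.index).symmetric_difference(md.index)
            raise CommunityValidationError(
                f"metadata does not cover exactly the samples; mismatch: {sorted(map(str, extra))[:5]}"
            )
        if md[list(METADATA_COLUMNS)].isna().any().any():
            raise CommunityValidationError("missing metadata value")
        keys = md[list(METADATA_COLUMNS)].astype(str)
        if keys.duplicated().any():
            dup = keys[keys.duplicated()].iloc[0].tolist()
            raise CommunityValidationError(
                f"duplicate (site, plot, time, replicate) tuple: {dup}"
            )
        self.abundance = ab.astype(float)
        self.metadata = md

    # -- convenience accessors -------------------------------------------------
    @property
    def sample_ids(self) -> list:
        return list(self.abundance.index)

    @property
    def taxa_ids(self) -> list:
        return list(self.abundance.columns)

    @property
    def n_samples(self) -> int:
        return self.abundance.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.abundance.shape[1]

    def time_order(self) -> list:
        """Distinct time labels in analysis order (numeric when parseable)."""
        return sorted(set(self.metadata["time"]), key=time_sort_key)

    def copy(self) -> "CommunityMatrix":
        return CommunityMatrix(self.abundance.copy(), self.metadata.copy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CommunityMatrix):
            return NotImplemented
        return (
            self.abundance.equals(other.abundance)
            and self.metadata[list(METADATA_COLUMNS)]
            .astype(str)
            .equals(other.metadata[list(METADATA_COLUMNS)].astype(str))
        )


@dataclass
class DissimilarityMatrix:
    """Square symmetric pairwise dissimilarity matrix with sample labels.

    ``kind='bray-curtis'`` declares the [0, 1] range; ``kind='general'``
    only requires non-negativity.
    """

    sample_ids: list
    values: np.ndarray
    kind: str = "bray-curtis"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if v.shape != (n, n):
            raise CommunityValidationError(
                f"dissimilarity matrix shape {v.shape} does not match {n} samples"
            )
        if len(set(map(str, self.sample_ids))) != n:
            raise CommunityValidationError("duplicate sample labels")
        if not np.allclose(v, v.T, atol=1e-12, rtol=0.0):
            raise CommunityValidationError("dissimilarity matrix is not symmetric")
        if np.abs(np.diag(v)).max(initial=0.0) > 1e-12:
            raise CommunityValidationError("dissimilarity diagonal is not zero")
        if (v < -1e-12).any():
            raise CommunityValidationError("negative dissimilarity")
        if self.kind == "bray-curtis" and (v > 1 + 1e-12).any():
            raise CommunityValidationError("Bray-Curtis dissimilarity above 1")
        v = (v + v.T) / 2.0
        np.fill_diagonal(v, 0.0)
        self.values = np.clip(v, 0.0, None)
        self.sample_ids = list(self.sample_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def index_of(self, labels) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.array([pos[lab] for lab in labels], dtype=int)
        except KeyError as exc:
            raise KeyError(f"unknown sample label: {exc.args[0]!r}") from None

    def subset(self, labels) -> "DissimilarityMatrix":
        idx = self.index_of(labels)
        return DissimilarityMatrix(
            [self.sample_ids[i] for i in idx], self.values[np.ix_(idx, idx)], self.kind
        )

    def to_csv(self, path) -> None:
        pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids).to_csv(
            path, index_label="sample_id"
        )

    @classmethod
    def from_csv(cls, path, kind: str = "bray-curtis") -> "DissimilarityMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(list(df.index), df.to_numpy(dtype=float), kind)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_community_csv(path, orientation: str = "samples", metadata_path=None) -> CommunityMatrix:
    """Read a community table from delimited text.

    ``orientation='samples'`` (default): one row per sample, first column the
    sample id; metadata either embedded as reserved columns
    (site/plot/time/replicate) or in a companion CSV keyed on sample_id.
    ``orientation='taxa'``: one row per taxon, columns are samples; metadata
    must come from the companion file.
    """
    if orientation not in ("samples", "taxa"):
        raise ValueError(f"unknown orientation: {orientation!r}")
    df = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
    if orientation == "taxa":
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)

    meta_cols = [c for c in METADATA_COLUMNS if c in df.columns]
    if metadata_path is not None:
        md = pd.read_csv(metadata_path, index_col=0, dtype=str, keep_default_na=False)
        md.index = md.index.astype(str)
        missing = set(df.index) - set(md.index)
        if missing:
            raise CommunityValidationError(
                f"metadata file missing sample_id(s): {sorted(missing)[:5]}"
            )
        md = md.loc[df.index]
        ab = df.drop(columns=meta_cols)
    elif len(meta_cols) == len(METADATA_COLUMNS):
        md = df[list(METADATA_COLUMNS)].copy()
        ab = df.drop(columns=list(METADATA_COLUMNS))
    else:
        raise CommunityValidationError(
            "no companion metadata file and embedded metadata columns "
            f"{sorted(set(METADATA_COLUMNS) - set(meta_cols))} are absent"
        )

    def parse_cell(x: str, row, col) -> float:
        if x.strip() == "":
            raise CommunityFormatError(f"blank abundance cell at sample {row!r}, taxon {col!r}")
        try:
            return float(x)  # locale-independent: dot decimal separator only
        except ValueError:
            raise CommunityFormatError(
                f"unparsable abundance {x!r} at sample {row!r}, taxon {col!r}"
            ) from None

    parsed = pd.DataFrame(
        [[parse_cell(ab.iat[i, j], ab.index[i], ab.columns[j]) for j in range(ab.shape[1])]
         for i in range(ab.shape[0])],
        index=ab.index,
        columns=ab.columns,
        dtype=float,
    )
    return CommunityMatrix(parsed, md)


def write_community_csv(M: CommunityMatrix, path, metadata_path=None) -> None:
    """Write a community table; metadata embedded unless a separate path is given."""
    if metadata_path is None:
        out = pd.concat([M.metadata[list(METADATA_COLUMNS)], M.abundance], axis=1)
        out.to_csv(path, index_label="sample_id")
    else:
        M.abundance.to_csv(path, index_label="sample_id")
        M.metadata[list(METADATA_COLUMNS)].to_csv(metadata_path, index_label="sample_id")


# ---------------------------------------------------------------------------
# Taxon filtering / pooling / transform
# ---------------------------------------------------------------------------

def filter_and_aggregate(M: CommunityMatrix, drop=(), merge=None) -> CommunityMatrix:
    """Drop taxa and/or merge taxa (summing abundances) under new labels.

    ``merge`` maps old taxon label -> new label; all old taxa mapped to the
    same new label are summed column-wise.  A taxon may not be both dropped
    and merged.
    """
    merge = dict(merge or {})
    drop = set(drop)
    known = set(M.taxa_ids)
    unknown = (drop | set(merge)) - known
    if unknown:
        raise KeyError(f"unknown taxon label(s): {sorted(map(str, unknown))}")
    both = drop & set(merge)
    if both:
        raise ValueError(f"taxa in both drop and merge: {sorted(map(str, both))}")

    ab = M.abundance.drop(columns=list(drop))
    if merge:
        new_cols = {}
        order = []
        for t in ab.columns:
            target = merge.get(t, t)
            if target not in new_cols:
                new_cols[target] = ab[t].to_numpy(dtype=float).copy()
                order.append(target)
            else:
                new_cols[target] = new_cols[target] + ab[t].to_numpy(dtype=float)
        ab = pd.DataFrame({t: new_cols[t] for t in order}, index=ab.index)
    return CommunityMatrix(ab, M.metadata.copy())


def pool_replicates(M: CommunityMatrix, keys=("site", "plot", "time")) -> CommunityMatrix:
    """Sum abundances over samples sharing the key tuple (e.g. pooling cores).

    New sample ids are derived deterministically from the key tuple and the
    replicate label is set to ``"pooled"``.
    """
    keys = list(keys)
    if not set(keys) <= {"site", "plot", "time"}:
        raise ValueError(f"pooling keys must be among site/plot/time, got {keys}")
    if M.n_samples == 0:
        raise CommunityValidationError("cannot pool an empty matrix")

    md = M.metadata
    group_keys = md[keys].astype(str)
    rows, metas, ids = [], [], []
    seen = {}
    for sid in M.sample_ids:
        tup = tuple(group_keys.loc[sid])
        if tup not in seen:
            seen[tup] = len(rows)
            rows.append(M.abundance.loc[sid].to_numpy(dtype=float).copy())
            meta = {c: md.loc[sid, c] for c in METADATA_COLUMNS}
            for c in ("site", "plot", "time"):
                if c not in keys:
                    meta[c] = "pooled"
            meta["replicate"] = "pooled"
            metas.append(meta)
            ids.append("_".join(tup))
        else:
            rows[seen[tup]] += M.abundance.loc[sid].to_numpy(dtype=float)
    ab = pd.DataFrame(np.array(rows), index=ids, columns=M.taxa_ids)
    md_out = pd.DataFrame(metas, index=ids)
    return CommunityMatrix(ab, md_out)


def fourth_root_transform(M: CommunityMatrix) -> CommunityMatrix:
    """y -> y**(1/4): severe down-weighting of numerically dominant taxa so the
    whole community, not just the dominants, drives the resemblance measure."""
    vals = M.abundance.to_numpy(dtype=float)
    if (vals < 0).any():
        raise CommunityValidationError("negative abundance under fourth-root transform")
    ab = pd.DataFrame(vals ** 0.25, index=M.abundance.index, columns=M.abundance.columns)
    return CommunityMatrix(ab, M.metadata.copy())


# ---------------------------------------------------------------------------
# Bray-Curtis
# ---------------------------------------------------------------------------

def bray_curtis(M: CommunityMatrix) -> DissimilarityMatrix:
    """Bray-Curtis dissimilarity d_ij = sum_k |y_ik - y_jk| / sum_k (y_ik + y_jk).

    A pair of all-zero samples has an undefined ratio; by convention two empty
    samples are treated as identical (d = 0) and a warning is emitted.
    """
    if M.n_samples < 2:
        raise CommunityValidationError("Bray-Curtis needs at least 2 samples")
    X = M.abundance.to_numpy(dtype=float)
    num = squareform(pdist(X, metric="cityblock"))
    s = X.sum(axis=1)
    den = s[:, None] + s[None, :]
    degenerate = den == 0.0
    np.fill_diagonal(degenerate, False)
    if degenerate.any():
        warnings.warn(
            "all-zero sample pair(s) under Bray-Curtis; defining d = 0 for "
            f"{int(degenerate.sum() // 2)} pair(s)",
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(den > 0.0, num / np.where(den > 0.0, den, 1.0), 0.0)
    np.fill_diagonal(d, 0.0)
    return DissimilarityMatrix(M.sample_ids, np.clip(d, 0.0, 1.0), kind="bray-curtis")
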