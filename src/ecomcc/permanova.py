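"""Distance-based permutational ANOVA and dispersion tests.

Implements the pseudo-F partitioning of a dissimilarity matrix for a one-way
fixed design and a two-way crossed mixed model (fixed x random), with

* Type III sums of squares via hat-matrix projections of the Gower matrix,
* pseudo-F denominators from mixed-model expected mean squares,
* p-values by permutation (whole-sample-unit label permutation for the
  one-way design, Freedman-Lane permutation of residuals under the reduced
  model for the two-way design), switching to exhaustive enumeration when the
  permutation space is no larger than the requested number of permutations,
* method-of-moments components of variation, and
* PERMDISP (homogeneity of multivariate dispersions) on distances to group
  centroids in the signed PCoA embedding.

Everywhere the p-value convention is (1 + #{stat_perm >= stat_obs})/(1 + B)
for sampled permutations, and the exact proportion under enumeration.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
from sympy.utilities.iterables import multiset_permutations

from ._utils import spawn_seed
from .community import DissimilarityMatrix
from .geometry import gower_center, pcoa

__all__ = [
    "PermanovaResult",
    "PairwiseResult",
    "PermdispResult",
    "permanova_oneway",
    "permanova_twoway_mixed",
    "pairwise_fixed",
    "components_of_variation",
    "permdisp",
]

_EPS = 1e-12


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------

@dataclass
class PermanovaResult:
    """Term table of a distance-based permutational ANOVA.

    ``terms`` has one row per model term plus 'Residual' and 'Total', with
    columns df, SS, MS, pseudo_F, p_perm, n_unique_perms.  ``design`` carries
    the layout needed to derive components of variation.
    """

    terms: pd.DataFrame
    scheme: str
    seed: int | None
    design: dict
    components: pd.DataFrame | None = None

    def to_json(self) -> str:
        payload = {
            "scheme": self.scheme,
            "seed": self.seed,
            "design": self.design,
            "terms": json.loads(self.terms.to_json(orient="index")),
        }
        if self.components is not None:
            payload["components"] = json.loads(self.components.to_json(orient="index"))
        return json.dumps(payload, indent=2)

    def term(self, name: str) -> pd.Series:
        return self.terms.loc[name]


@dataclass
class PairwiseResult:
    """One pairwise comparison: t = sqrt(pseudo-F) on the two-level subset."""

    pair: tuple
    t: float
    p_perm: float
    n_unique_perms: int


@dataclass
class PermdispResult:
    """Test of homogeneity of multivariate dispersions."""

    group_means: pd.Series
    F: float
    p_perm: float
    n_unique_perms: int
    seed: int | None
    distances: np.ndarray = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# Shared helpers
# ---------------------------------------------------------------------------

def _as_labels(x, n: int, what: str) -> np.ndarray:
    lab = np.asarray([str(v) for v in x], dtype=object)
    if lab.shape[0] != n:
        raise ValueError(f"{what}: expected one label per sample ({n}), got {lab.shape[0]}")
    return lab


def _safe_F(num_ms: float, den_ms: float) -> float:
    if den_ms <= _EPS:
        return 0.0 if num_ms <= _EPS else math.inf
    return num_ms / den_ms


def _p_from_perms(f_obs: float, f_perm: np.ndarray, exhaustive: bool) -> float:
    tol = 1e-9 * (1.0 + abs(f_obs))
    ge = int(np.count_nonzero(f_perm >= f_obs - tol))
    if exhaustive:
        return ge / f_perm.size
    return (1 + ge) / (1 + f_perm.size)


def _hat(X: np.ndarray) -> np.ndarray:
    # orthonormal-basis projector: numerically tighter than X pinv(X)
    Q = scipy.linalg.orth(X)
    return Q @ Q.T


def _sum_to_zero(labels: np.ndarray) -> tuple[np.ndarray, list]:
    """Sum-to-zero (effects) coding: one column per non-reference level."""
    levels = sorted(set(labels))
    a = len(levels)
    X = np.zeros((labels.shape[0], a - 1))
    for j, lev in enumerate(levels[:-1]):
        X[labels == lev, j] = 1.0
    X[labels == levels[-1], :] = -1.0
    return X, levels


# ---------------------------------------------------------------------------
# One-way PERMANOVA
# ---------------------------------------------------------------------------

def _oneway_stats(d2: np.ndarray, onehot: np.ndarray, sizes: np.ndarray):
    """(SS_among, SS_within, SS_total) from squared dissimilarities.

    SS_total = (1/N) sum_{i<j} d2; SS_within = sum_g S(g,g)/(2 n_g).
    Equals the hat-matrix trace formulation tr(HGH) / tr((I-H)G(I-H)).
    """
    n = d2.shape[0]
    ss_total = d2.sum() / (2.0 * n)
    quad = np.einsum("gi,ij,gj->g", onehot, d2, onehot)
    ss_within = (quad / (2.0 * sizes)).sum()
    return ss_total - ss_within, ss_within, ss_total


def permanova_oneway(
    D: DissimilarityMatrix,
    factor,
    n_perm: int = 9999,
    seed: int | None = 0,
) -> PermanovaResult:
    """One-way fixed-effect PERMANOVA with unrestricted permutation of raw data.

    Group labels are permuted as whole sample units; when the number of
    distinct label arrangements is at most ``n_perm`` the permutation space is
    enumerated exhaustively and the exact p-value reported.
    """
    n = D.n_samples
    labels = _as_labels(factor, n, "factor")
    levels = sorted(set(labels))
    a = len(levels)
    if a < 2:
        raise ValueError("one-way PERMANOVA needs at least 2 groups")
    if n - a == 0:
        raise ValueError("no residual degrees of freedom (every group is a singleton)")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")

    d2 = D.values.astype(float) ** 2
    onehot = np.stack([(labels == lev).astype(float) for lev in levels])
    sizes = onehot.sum(axis=1)
    ss_among, ss_within, ss_total = _oneway_stats(d2, onehot, sizes)
    df_a, df_res = a - 1, n - a

    degenerate = ss_total <= _EPS
    if degenerate:
        f_obs, p = 0.0, 1.0
        n_used = 0
    else:
        f_obs = _safe_F(ss_among / df_a, ss_within / df_res)
        counts = np.array([int(c) for c in sizes])
        n_distinct = math.factorial(n)
        for c in counts:
            n_distinct //= math.factorial(c)
        if n_distinct <= n_perm:
            f_perm = np.empty(n_distinct)
            base = np.concatenate([[g] * c for g, c in enumerate(counts)])
            for k, arrangement in enumerate(multiset_permutations(list(base))):
                arr = np.asarray(arrangement)
                oh = np.stack([(arr == g).astype(float) for g in range(a)])
                sa, sw, _ = _oneway_stats(d2, oh, sizes)
                f_perm[k] = _safe_F(sa / df_a, sw / df_res)
            p = _p_from_perms(f_obs, f_perm, exhaustive=True)
            n_used = n_distinct
        else:
            rng = np.random.default_rng(spawn_seed(seed or 0, "oneway"))
            perms = np.array([rng.permutation(n) for _ in range(n_perm)])
            # permuted one-hot per group: onehot[g][perms] has shape (P, n)
            quads = np.zeros((n_perm, a))
            for g in range(a):
                V = onehot[g][perms]
                quads[:, g] = np.einsum("pi,ij,pj->p", V, d2, V)
            ss_w = (quads / (2.0 * sizes[None, :])).sum(axis=1)
            ss_a = ss_total - ss_w
            with np.errstate(divide="ignore", invalid="ignore"):
                f_perm = np.where(
                    ss_w / df_res <= _EPS,
                    np.where(ss_a / df_a <= _EPS, 0.0, np.inf),
                    (ss_a / df_a) / (ss_w / df_res),
                )
            p = _p_from_perms(f_obs, f_perm, exhaustive=False)
            n_used = n_perm

    name = "Factor"
    terms = pd.DataFrame(
        {
            "df": [df_a, df_res, n - 1],
            "SS": [ss_among, ss_within, ss_total],
            "MS": [ss_among / df_a, ss_within / df_res, np.nan],
            "pseudo_F": [f_obs, np.nan, np.nan],
            "p_perm": [p, np.nan, np.nan],
            "n_unique_perms": [n_used, 0, 0],
        },
        index=[name, "Residual", "Total"],
    )
    balanced = len(set(sizes)) == 1
    design = {
        "type": "oneway",
        "a": a,
        "N": n,
        "n": int(sizes[0]) if balanced else None,
        "balanced": balanced,
        "levels": levels,
    }
    result = PermanovaResult(
        terms=terms, scheme="unrestricted permutation of raw data", seed=seed, design=design
    )
    if balanced:
        result.components = components_of_variation(result)
    return result


# ---------------------------------------------------------------------------
# Two-way crossed mixed model
# ---------------------------------------------------------------------------

def _twoway_matrices(fixed_labels: np.ndarray, random_labels: np.ndarray):
    XA, levels_a = _sum_to_zero(fixed_labels)
    XB, levels_b = _sum_to_zero(random_labels)
    XAB = np.einsum("ni,nj->nij", XA, XB).reshape(XA.shape[0], -1)
    X0 = np.ones((XA.shape[0], 1))
    return X0, XA, XB, XAB, levels_a, levels_b


def permanova_twoway_mixed(
    D: DissimilarityMatrix,
    fixed,
    random,
    n_perm: int = 9999,
    seed: int | None = 0,
    ems: str = "restricted",
    fixed_name: str = "Fixed",
    random_name: str = "Random",
) -> PermanovaResult:
    """Two-way crossed PERMANOVA: one fixed and one random factor.

    Type III sums of squares; pseudo-F denominators follow the mixed-model
    expected mean squares: the fixed main effect is tested over the
    interaction MS, the random main effect and the interaction over the
    residual MS (``ems='unrestricted'`` tests both main effects over the
    interaction MS).  P-values use permutation of residuals under the reduced
    model: for each term the Gower matrix is residualized by the hat matrix of
    the model without that term, its rows/columns co-permuted, and the term's
    pseudo-F recomputed.
    """
    if ems not in ("restricted", "unrestricted"):
        raise ValueError("ems must be 'restricted' or 'unrestricted'")
    n = D.n_samples
    fa = _as_labels(fixed, n, "fixed")
    rb = _as_labels(random, n, "random")
    if len(set(fa)) < 2 or len(set(rb)) < 2:
        raise ValueError("both factors need at least 2 levels")
    part_f = {lev: frozenset(np.flatnonzero(fa == lev)) for lev in set(fa)}
    part_r = {lev: frozenset(np.flatnonzero(rb == lev)) for lev in set(rb)}
    if set(part_f.values()) == set(part_r.values()):
        raise ValueError("fixed and random factors are aliased (identical partitions)")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")

    X0, XA, XB, XAB, levels_a, levels_b = _twoway_matrices(fa, rb)
    a, b = len(levels_a), len(levels_b)
    df = {
        "A": a - 1,
        "B": b - 1,
        "AB": (a - 1) * (b - 1),
        "Residual": n - a * b,
    }
    if df["Residual"] <= 0:
        raise ValueError("no residual degrees of freedom (need replication within cells)")

    Hf = _hat(np.hstack([X0, XA, XB, XAB]))
    Hr = {
        "A": _hat(np.hstack([X0, XB, XAB])),
        "B": _hat(np.hstack([X0, XA, XAB])),
        "AB": _hat(np.hstack([X0, XA, XB])),
    }
    G = gower_center(D).G
    R = np.eye(n) - Hf
    M = {t: Hf - Hr[t] for t in ("A", "B", "AB")}

    ss = {t: float(np.sum(M[t] * G)) for t in ("A", "B", "AB")}
    ss["Residual"] = float(np.sum(R * G))
    ss_total = float(np.trace(G))
    ms = {t: ss[t] / df[t] for t in ss}

    den_name = {"A": "AB", "B": "AB" if ems == "unrestricted" else "Residual", "AB": "Residual"}
    f_obs = {t: _safe_F(ms[t], ms[den_name[t]]) for t in ("A", "B", "AB")}

    degenerate = ss_total <= _EPS
    p = {}
    n_used = {}
    if degenerate:
        for t in ("A", "B", "AB"):
            f_obs[t], p[t], n_used[t] = 0.0, 1.0, 0
    else:
        n_space = math.factorial(n)
        exhaustive = n_space <= n_perm
        den_tol = 1e-10 * max(ss_total, _EPS)  # scale-aware degeneracy cutoff
        for t in ("A", "B", "AB"):
            G_res = (np.eye(n) - Hr[t]) @ G @ (np.eye(n) - Hr[t])
            Mt = M[t]
            Md = M[den_name[t]] if den_name[t] != "Residual" else R
            df_t, df_d = df[t], df[den_name[t]]
            if exhaustive:
                perm_iter = itertools.permutations(range(n))
                total = n_space
            else:
                rng = np.random.default_rng(spawn_seed(seed or 0, "twoway", t))
                perm_iter = (rng.permutation(n) for _ in range(n_perm))
                total = n_perm
            f_perm = np.empty(total)
            for k, sigma in enumerate(perm_iter):
                sigma = np.asarray(sigma)
                Gp = G_res[np.ix_(sigma, sigma)]
                num = np.sum(Mt * Gp) / df_t
                den = np.sum(Md * Gp) / df_d
                # permuted residualized traces may be negative or (for some
                # structurally degenerate permutations of small designs)
                # exactly zero; keep the signed ratio, with x/0 -> signed inf
                # and 0/0 -> 0, so the null ordering is well defined
                if abs(den) <= den_tol:
                    if abs(num) <= den_tol:
                        f_perm[k] = 0.0
                    else:
                        f_perm[k] = math.inf if num > 0 else -math.inf
                else:
                    f_perm[k] = num / den
            p[t] = _p_from_perms(f_obs[t], f_perm, exhaustive=exhaustive)
            n_used[t] = total

    order = [fixed_name, random_name, f"{fixed_name}x{random_name}", "Residual", "Total"]
    key = {fixed_name: "A", random_name: "B", f"{fixed_name}x{random_name}": "AB"}
    terms = pd.DataFrame(
        {
            "df": [df[key[t]] if t in key else (df["Residual"] if t == "Residual" else n - 1)
                   for t in order],
            "SS": [ss[key[t]] if t in key else (ss["Residual"] if t == "Residual" else ss_total)
                   for t in order],
            "MS": [ms[key[t]] if t in key else (ms["Residual"] if t == "Residual" else np.nan)
                   for t in order],
            "pseudo_F": [f_obs[key[t]] if t in key else np.nan for t in order],
            "p_perm": [p[key[t]] if t in key else np.nan for t in order],
            "n_unique_perms": [n_used[key[t]] if t in key else 0 for t in order],
        },
        index=order,
    )

    cell_sizes = pd.crosstab(pd.Series(fa), pd.Series(rb)).to_numpy()
    balanced = cell_sizes.min() == cell_sizes.max()
    design = {
        "type": "twoway_mixed",
        "a": a,
        "b": b,
        "n": int(cell_sizes[0, 0]) if balanced else None,
        "N": n,
        "balanced": bool(balanced),
        "ems": ems,
        "fixed_name": fixed_name,
        "random_name": random_name,
        "levels_fixed": levels_a,
        "levels_random": levels_b,
    }
    result = PermanovaResult(
        terms=terms,
        scheme="permutation of residuals under a reduced model (Type III SS)",
        seed=seed,
        design=design,
    )
    if balanced:
        result.components = components_of_variation(result)
    return result


# ---------------------------------------------------------------------------
# Pairwise comparisons
# ---------------------------------------------------------------------------

def pairwise_fixed(
    D: DissimilarityMatrix,
    fixed,
    random=None,
    pair: tuple = (),
    n_perm: int = 9999,
    seed: int | None = 0,
    ems: str = "restricted",
) -> PairwiseResult:
    """Pairwise comparison between two levels of the fixed factor.

    The full design is re-run on the subset of samples at the two levels;
    t = sqrt(pseudo-F) and the p-value uses the same permutation scheme as the
    parent design restricted to the subset.
    """
    n = D.n_samples
    fa = _as_labels(fixed, n, "fixed")
    lev1, lev2 = (str(p) for p in pair)
    for lev in (lev1, lev2):
        if lev not in set(fa):
            raise ValueError(f"level {lev!r} not present in the fixed factor")
    keep = np.flatnonzero((fa == lev1) | (fa == lev2))
    Dsub = D.subset([D.sample_ids[i] for i in keep])
    fsub = fa[keep]

    if random is None:
        res = permanova_oneway(Dsub, fsub, n_perm=n_perm, seed=seed)
        row = res.terms.iloc[0]
    else:
        rsub = _as_labels(random, n, "random")[keep]
        for lev in (lev1, lev2):
            if len(set(rsub[fsub == lev])) < 2:
                raise ValueError(
                    f"level {lev!r} has all samples in one cell of the random factor"
                )
        res = permanova_twoway_mixed(
            Dsub, fsub, rsub, n_perm=n_perm, seed=seed, ems=ems
        )
        row = res.terms.iloc[0]
    f_val = float(row["pseudo_F"])
    return PairwiseResult(
        pair=(lev1, lev2),
        t=math.sqrt(max(0.0, f_val)),
        p_perm=float(row["p_perm"]),
        n_unique_perms=int(row["n_unique_perms"]),
    )


# ---------------------------------------------------------------------------
# Components of variation
# ---------------------------------------------------------------------------

def components_of_variation(result: PermanovaResult) -> pd.DataFrame:
    """Method-of-moments variance components by equating MS to EMS.

    Balanced designs only.  Negative estimates are reported as 0 (raw value
    retained); percentages are over the sum of non-negative estimates plus the
    residual.
    """
    design = result.design
    if not design.get("balanced"):
        raise ValueError("components of variation require a balanced design")
    terms = result.terms
    raw = {}
    if design["type"] == "oneway":
        n_rep = design["n"]
        ms_a = terms.iloc[0]["MS"]
        ms_res = terms.loc["Residual", "MS"]
        raw[terms.index[0]] = (ms_a - ms_res) / n_rep
        raw["Residual"] = ms_res
    elif design["type"] == "twoway_mixed":
        a, b, n_rep = design["a"], design["b"], design["n"]
        fixed_name = design["fixed_name"]
        random_name = design["random_name"]
        inter_name = f"{fixed_name}x{random_name}"
        ms_a = terms.loc[fixed_name, "MS"]
        ms_b = terms.loc[random_name, "MS"]
        ms_ab = terms.loc[inter_name, "MS"]
        ms_res = terms.loc["Residual", "MS"]
        raw[fixed_name] = (ms_a - ms_ab) / (n_rep * b)
        if design.get("ems") == "unrestricted":
            raw[random_name] = (ms_b - ms_ab) / (n_rep * a)
        else:
            raw[random_name] = (ms_b - ms_res) / (n_rep * a)
        raw[inter_name] = (ms_ab - ms_res) / n_rep
        raw["Residual"] = ms_res
    else:
        raise ValueError(f"unsupported design type {design['type']!r}")

    est = {t: max(0.0, v) for t, v in raw.items()}
    total = sum(est.values())
    pct = {t: (100.0 * v / total if total > 0 else np.nan) for t, v in est.items()}
    return pd.DataFrame(
        {"estimate_raw": raw, "estimate": est, "percent": pct}
    )


# ---------------------------------------------------------------------------
# PERMDISP
# ---------------------------------------------------------------------------

def _dispersion_distances(coords_pos, coords_neg, onehot, sizes):
    """z (per sample) for P permuted one-hot group matrices at once.

    onehot: (a, P, n) boolean membership after permutation.
    Returns z with shape (P, n).
    """
    a, P, n = onehot.shape
    zsq = np.zeros((P, n))
    for coords, sign in ((coords_pos, 1.0), (coords_neg, -1.0)):
        if coords.shape[1] == 0:
            continue
        sq_norm = (coords**2).sum(axis=1)          # (n,)
        for g in range(a):
            V = onehot[g].astype(float)            # (P, n)
            C = (V @ coords) / sizes[g]            # (P, p)
            cross = coords @ C.T                   # (n, P)
            c_norm = (C**2).sum(axis=1)            # (P,)
            contrib = sq_norm[None, :] - 2.0 * cross.T + c_norm[:, None]
            zsq += sign * contrib * V
    return np.sqrt(np.clip(zsq, 0.0, None))


def _anova_F_on_z(z, onehot, sizes):
    """Classical one-way ANOVA F on z, vectorized over permutations (axis 0)."""
    P, n = z.shape
    a = onehot.shape[0]
    grand = z.mean(axis=1)
    ss_b = np.zeros(P)
    ss_w = np.zeros(P)
    for g in range(a):
        V = onehot[g].astype(float)
        m_g = (V * z).sum(axis=1) / sizes[g]
        ss_b += sizes[g] * (m_g - grand) ** 2
        ss_w += (V * (z - m_g[:, None]) ** 2).sum(axis=1)
    df_b, df_w = a - 1, n - a
    ms_b, ms_w = ss_b / df_b, ss_w / df_w
    return np.where(ms_w <= _EPS, np.where(ms_b <= _EPS, 0.0, np.inf), ms_b / np.where(ms_w <= _EPS, 1.0, ms_w))


def permdisp(
    D: DissimilarityMatrix,
    groups,
    n_perm: int = 9999,
    seed: int | None = 0,
) -> PermdispResult:
    """PERMDISP: permutation test of homogeneity of multivariate dispersions.

    Distances of samples to their own group centroid (signed PCoA
    convention) are compared across groups by a classical one-way ANOVA F;
    significance by permuting group labels and recomputing the distances.
    """
    n = D.n_samples
    labels = _as_labels(groups, n, "groups")
    levels = sorted(set(labels))
    a = len(levels)
    if a < 2:
        raise ValueError("PERMDISP needs at least 2 groups")
    sizes = np.array([np.count_nonzero(labels == lev) for lev in levels], dtype=float)
    if sizes.min() < 2:
        small = levels[int(np.argmin(sizes))]
        raise ValueError(f"PERMDISP group {small!r} has fewer than 2 samples")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")

    res = pcoa(gower_center(D))
    onehot_obs = np.stack([(labels == lev) for lev in levels])[:, None, :]
    z_obs = _dispersion_distances(res.coords_pos, res.coords_neg, onehot_obs, sizes)[0]
    f_obs = float(_anova_F_on_z(z_obs[None, :], onehot_obs, sizes)[0])

    n_distinct = math.factorial(n)
    for c in sizes.astype(int):
        n_distinct //= math.factorial(int(c))
    if n_distinct <= n_perm:
        base = np.concatenate([[g] * int(c) for g, c in enumerate(sizes.astype(int))])
        arrangements = np.array(list(multiset_permutations(list(base))))
        onehot = np.stack([(arrangements == g) for g in range(a)])
        exhaustive, n_used = True, n_distinct
    else:
        rng = np.random.default_rng(spawn_seed(seed or 0, "permdisp"))
        perms = np.array([rng.permutation(n) for _ in range(n_perm)])
        onehot = np.stack([(labels == lev) for lev in levels])[:, perms]  # (a, P, n)
        exhaustive, n_used = False, n_perm
    z_perm = _dispersion_distances(res.coords_pos, res.coords_neg, onehot, sizes)
    f_perm = _anova_F_on_z(z_perm, onehot, sizes)
    p = _p_from_perms(f_obs, f_perm, exhaustive=exhaustive)

    means = pd.Series(
        {lev: float(z_obs[labels == lev].mean()) for lev in levels}, name="mean_distance"
    )
    return PermdispResult(
        group_means=means, F=f_obs, p_perm=p, n_unique_perms=n_used, seed=seed,
        distances=z_obs,
    )
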