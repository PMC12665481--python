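"""Community-diversity statistics, implemented from first principles.

Everything downstream of an ASV count table lives here: rarefaction,
observed richness, unweighted UniFrac, principal coordinates analysis,
Ward hierarchical clustering, PERMANOVA (distance-based linear model with
permutation test), a pairwise-complete Spearman correlation matrix, and a
single-predictor ANOVA F-test.

These statistics are the analytical core of the package and are written
out explicitly (Gower double-centering, Lance-Williams recurrence,
McArdle-Anderson sums of squares) rather than delegated; established
libraries supply only primitives (rank transforms, eigendecompositions,
hypergeometric sampling) and serve as independent cross-checks in tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import dendropy
import numpy as np
import pandas as pd
from scipy import linalg, stats

__all__ = [
    "AsvTable", "DistanceMatrix", "rarefy", "observed_richness",
    "unifrac_unweighted", "pcoa", "ward_hac", "cut_tree", "permanova",
    "spearman_matrix", "anova_lm",
]


@dataclass
class AsvTable:
    """Counts (samples x ASVs) with sample and ASV identifiers."""

    counts: np.ndarray
    sample_ids: list
    asv_ids: list

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (samples x ASVs)")
        if self.counts.shape != (len(self.sample_ids), len(self.asv_ids)):
            raise ValueError("counts shape does not match id lists")
        if np.any(self.counts < 0) or not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)) or np.any(self.counts < 0):
                raise ValueError("counts must be non-negative integers")
            self.counts = self.counts.astype(np.int64)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if len(set(self.asv_ids)) != len(self.asv_ids):
            raise ValueError("duplicate ASV ids")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, orientation: str = "asv_rows") -> "AsvTable":
        """Build from a DataFrame; ``orientation`` names what the rows are."""
        if orientation == "asv_rows":
            df = df.T
        elif orientation != "sample_rows":
            raise ValueError("orientation must be 'asv_rows' or 'sample_rows'")
        return cls(df.to_numpy(), list(df.index), list(df.columns))

    def to_frame(self, orientation: str = "asv_rows") -> pd.DataFrame:
        df = pd.DataFrame(self.counts, index=self.sample_ids, columns=self.asv_ids)
        return df.T if orientation == "asv_rows" else df

    @property
    def depths(self) -> np.ndarray:
        return self.counts.sum(axis=1)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with a zero diagonal."""

    data: np.ndarray
    ids: list

    def __post_init__(self):
        self.data = np.asarray(self.data, float)
        n = len(self.ids)
        if self.data.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.data, self.data.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.data), 0.0, atol=1e-12):
            raise ValueError("distance matrix must have a zero diagonal")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.ids, columns=self.ids)


def rarefy(table: AsvTable, depth: int, seed: int) -> AsvTable:
    """Subsample every sample without replacement to exactly ``depth`` reads.

    Samples whose total is below ``depth`` are dropped; ASVs left with zero
    total are removed.  Sampling is multivariate hypergeometric (equivalent
    to drawing reads without replacement).
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    keep = table.depths >= depth
    if not np.any(keep):
        raise ValueError(f"all samples fall below rarefaction depth {depth}")
    rng = np.random.default_rng(seed)
    rows = []
    for i in np.flatnonzero(keep):
        counts = table.counts[i]
        if counts.sum() == depth:
            rows.append(counts.copy())
        else:
            rows.append(rng.multivariate_hypergeometric(counts, depth))
    new = np.vstack(rows)
    nz = new.sum(axis=0) > 0
    return AsvTable(new[:, nz],
                    [s for s, k in zip(table.sample_ids, keep) if k],
                    [a for a, k in zip(table.asv_ids, nz) if k])


def observed_richness(table: AsvTable) -> pd.Series:
    """Number of ASVs with count > 0, per sample."""
    return pd.Series((table.counts > 0).sum(axis=1), index=table.sample_ids,
                     name="observed_asvs")


def _tree_edges(tree: dendropy.Tree, asv_ids: Sequence[str]):
    """Branch lengths and per-edge leaf-descendant membership.

    Returns (lengths[n_edges], membership[n_edges, n_asvs] boolean) where
    membership[e, a] is True when leaf ``a`` lies below edge ``e``.  The
    root edge is excluded (it is shared by every profile).
    """
    idx = {name: j for j, name in enumerate(asv_ids)}
    leaves = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    missing = [a for a in asv_ids if a not in leaves]
    if missing:
        raise ValueError(f"ASV(s) absent from tree: {missing[:5]}")
    lengths, member = [], []
    below: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            vec = np.zeros(len(asv_ids), bool)
            j = idx.get(node.taxon.label)
            if j is not None:
                vec[j] = True
        else:
            vec = np.zeros(len(asv_ids), bool)
            for ch in node.child_nodes():
                vec |= below[id(ch)]
        below[id(node)] = vec
        if node.parent_node is not None:
            lengths.append(node.edge.length or 0.0)
            member.append(vec)
    return np.asarray(lengths, float), np.asarray(member, bool)


def unifrac_unweighted(table: AsvTable, tree: dendropy.Tree) -> DistanceMatrix:
    """Unweighted UniFrac: unshared branch length over total observed length.

    For each pair of samples, a branch counts as observed when at least one
    leaf below it is present (count > 0) in either sample; the distance is
    the summed length of branches observed in exactly one sample divided by
    the summed length observed in at least one.
    """
    lengths, member = _tree_edges(tree, table.asv_ids)
    presence = table.counts > 0                       # samples x ASVs
    # edge_in[s, e]: sample s has at least one present leaf below edge e
    edge_in = presence @ member.T.astype(np.int64) > 0
    n = len(table.sample_ids)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            either = edge_in[i] | edge_in[j]
            unshared = edge_in[i] ^ edge_in[j]
            total = lengths[either].sum()
            D[i, j] = D[j, i] = (lengths[unshared].sum() / total) if total > 0 else 0.0
    return DistanceMatrix(D, list(table.sample_ids))


@dataclass
class PcoaResult:
    coordinates: np.ndarray      # n x n_positive_axes
    eigenvalues: np.ndarray      # all eigenvalues, descending
    proportion_explained: np.ndarray   # over positive eigenvalues
    ids: list

    def to_frame(self) -> pd.DataFrame:
        cols = [f"PCo{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.ids, columns=cols)


def _gower_center(D: np.ndarray) -> np.ndarray:
    """B = -1/2 J D^2 J with J the centering matrix."""
    A = -0.5 * D ** 2
    row = A.mean(axis=1, keepdims=True)
    col = A.mean(axis=0, keepdims=True)
    return A - row - col + A.mean()

def pcoa(D: Union[DistanceMatrix, np.ndarray], ids: Optional[list] = None) -> PcoaResult:
    """Principal coordinates analysis via Gower double-centering.

    Coordinates are eigenvectors scaled by sqrt(eigenvalue), for positive
    eigenvalues only; negative eigenvalues (non-Euclidean distances) are
    reported but yield no axes.
    """
    if isinstance(D, DistanceMatrix):
        ids = D.ids
        D = D.data
    D = np.asarray(D, float)
    if ids is None:
        ids = list(range(D.shape[0]))
    B = _gower_center(D)
    evals, evecs = linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(1e-12, 1e-10 * max(abs(evals[0]), 1.0))
    pos = evals > tol
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    prop = evals[pos] / evals[pos].sum() if pos.any() else np.array([])
    return PcoaResult(coords, evals, prop, list(ids))


def ward_hac(D: Union[DistanceMatrix, np.ndarray]) -> np.ndarray:
    """Ward clustering of a distance matrix (ward.D2 dialect).

    Runs the Lance-Williams recurrence on squared distances; the merge
    height is the (unsquared) Ward distance, so the output matches a
    scipy-style linkage matrix ``Z`` with rows (i, j, height, size).
    Ties break deterministically on the lowest index pair.
    """
    if isinstance(D, DistanceMatrix):
        D = D.data
    D = np.asarray(D, float)
    n = D.shape[0]
    d2 = D.astype(float) ** 2
    active = list(range(n))               # cluster labels, scipy convention
    sizes = {i: 1 for i in range(n)}
    cur = {i: i for i in range(n)}        # position -> label
    d2 = d2.copy()
    Z = np.zeros((n - 1, 4))
    pos = list(range(n))                  # active row/col positions in d2
    for step in range(n - 1):
        # find minimal pair among active positions, lowest-index tie-break
        best = None
        for ai in range(len(pos)):
            for aj in range(ai + 1, len(pos)):
                v = d2[pos[ai], pos[aj]]
                if best is None or v < best[0] - 1e-15:
                    best = (v, ai, aj)
        v, ai, aj = best
        pi, pj = pos[ai], pos[aj]
        li, lj = cur[pi], cur[pj]
        ni, nj = sizes[li], sizes[lj]
        Z[step] = [min(li, lj), max(li, lj), np.sqrt(max(v, 0.0)), ni + nj]
        # Lance-Williams (Ward) update of d2 against all other clusters
        for ak in range(len(pos)):
            pk = pos[ak]
            if pk in (pi, pj):
                continue
            nk = sizes[cur[pk]]
            new = ((ni + nk) * d2[pi, pk] + (nj + nk) * d2[pj, pk]
                   - nk * v) / (ni + nj + nk)
            d2[pi, pk] = d2[pk, pi] = new
        new_label = n + step
        sizes[new_label] = ni + nj
        cur[pi] = new_label
        pos.pop(aj)
    return Z


def cut_tree(Z: np.ndarray, k: int) -> np.ndarray:
    """Flat cluster assignment (0..k-1) from a linkage matrix at k clusters."""
    n = Z.shape[0] + 1
    members = {i: [i] for i in range(n)}
    for step in range(n - 1 - (k - 1)):
        i, j = int(Z[step, 0]), int(Z[step, 1])
        members[n + step] = members.pop(i) + members.pop(j)
    labels = np.zeros(n, int)
    for lab, (_, mem) in enumerate(sorted(members.items())):
        labels[mem] = lab
    return labels


def _design_matrix(X) -> np.ndarray:
    """Predictor columns -> design matrix with intercept; categoricals one-hot."""
    df = pd.DataFrame(X)
    cols = [np.ones(len(df))]
    for c in df.columns:
        col = df[c]
        if pd.api.types.is_numeric_dtype(col):
            x = col.to_numpy(float)
            if np.ptp(x) == 0:
                raise ValueError(f"no variance in predictor {c!r}")
            cols.append(x)
        else:
            levels = pd.unique(col)
            if len(levels) < 2:
                raise ValueError(f"no variance in predictor {c!r}")
            for lev in levels[1:]:
                cols.append((col == lev).to_numpy(float))
    return np.column_stack(cols)


def _hat(X: np.ndarray) -> np.ndarray:
    Q, _ = np.linalg.qr(X)
    return Q @ Q.T


def permanova(D: Union[DistanceMatrix, np.ndarray], X, n_perm: int = 999,
              seed: int = 0) -> dict:
    """Distance-based multivariate ANOVA (one model term block).

    Partitions the total sum of squares of the Gower-centered distance
    matrix by the hat matrix of the design built from ``X`` (continuous or
    categorical columns, intercept added).  The p-value is
    (1 + #{F_perm >= F_obs}) / (1 + n_perm) under random row permutations
    of the predictors.
    """
    if isinstance(D, DistanceMatrix):
        D = D.data
    D = np.asarray(D, float)
    n = D.shape[0]
    Xd = _design_matrix(X)
    if Xd.shape[0] != n:
        raise ValueError("predictor rows do not align with the distance matrix")
    G = _gower_center(D)
    df_model = np.linalg.matrix_rank(Xd) - 1
    if df_model < 1:
        raise ValueError("no variance in predictor")
    df_resid = n - df_model - 1
    ss_total = np.trace(G)

    if Xd.shape[1] == 2:
        # single continuous predictor: tr(H G) reduces to a quadratic form
        # in the centered predictor (the intercept term vanishes because G
        # is double-centered), so permutations are cheap dot products
        xc = Xd[:, 1] - Xd[:, 1].mean()
        Gx_norm = xc @ xc

        def f_and_r2(x):
            ss_model = float(x @ G @ x) / Gx_norm
            ss_resid = ss_total - ss_model
            F = (ss_model / df_model) / (ss_resid / df_resid)
            return F, ss_model / ss_total

        F_obs, r2 = f_and_r2(xc)
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            F_p, _ = f_and_r2(xc[rng.permutation(n)])
            if F_p >= F_obs:
                count += 1
    else:
        def f_and_r2(Xmat):
            H = _hat(Xmat)
            ss_model = float(np.sum(H * G))     # tr(H G), H symmetric
            ss_resid = ss_total - ss_model
            F = (ss_model / df_model) / (ss_resid / df_resid)
            return F, ss_model / ss_total

        F_obs, r2 = f_and_r2(Xd)
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            F_p, _ = f_and_r2(Xd[perm])
            if F_p >= F_obs:
                count += 1
    return {
        "R2": r2, "pseudo_F": F_obs, "p": (1 + count) / (1 + n_perm),
        "df_model": df_model, "df_resid": df_resid,
        "SS_model": r2 * ss_total, "SS_total": ss_total,
    }


def permanova_terms(D, X: pd.DataFrame, n_perm: int = 999, seed: int = 0) -> pd.DataFrame:
    """Sequential (Type I) PERMANOVA over the columns of ``X`` in order.

    Each term's SS is the increment in explained SS when the term is added
    after the preceding ones; permutations shuffle raw observations.
    """
    if isinstance(D, DistanceMatrix):
        Dm = D.data
    else:
        Dm = np.asarray(D, float)
    n = Dm.shape[0]
    G = _gower_center(Dm)
    ss_total = np.trace(G)
    terms = list(X.columns)

    def seq_ss(Xdf):
        out, prev = [], float(np.sum(_hat(np.ones((n, 1))) * G))
        for j in range(len(terms)):
            Xd = _design_matrix(Xdf[terms[: j + 1]])
            cur = float(np.sum(_hat(Xd) * G))
            out.append(cur - prev)
            prev = cur
        return np.array(out), prev

    ss_terms, ss_model_tot = seq_ss(X)
    df_terms = []
    prev_rank = 1
    for j in range(len(terms)):
        r = np.linalg.matrix_rank(_design_matrix(X[terms[: j + 1]]))
        df_terms.append(r - prev_rank)
        prev_rank = r
    df_terms = np.array(df_terms)
    df_resid = n - prev_rank
    ss_resid = ss_total - ss_model_tot
    F_obs = (ss_terms / df_terms) / (ss_resid / df_resid)

    rng = np.random.default_rng(seed)
    counts = np.zeros(len(terms))
    for _ in range(n_perm):
        perm = rng.permutation(n)
        Xp = X.iloc[perm].reset_index(drop=True)
        ss_p, tot_p = seq_ss(Xp)
        F_p = (ss_p / df_terms) / ((ss_total - tot_p) / df_resid)
        counts += F_p >= F_obs
    return pd.DataFrame({
        "term": terms, "df": df_terms, "SS": ss_terms,
        "R2": ss_terms / ss_total, "pseudo_F": F_obs,
        "p": (1 + counts) / (1 + n_perm),
    }).set_index("term")


def spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rho: Pearson correlation of average ranks."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx ** 2).sum() * (ry ** 2).sum())
    if denom == 0:
        return np.nan
    return float((rx * ry).sum() / denom)


def _spearman_p(rho: float, n: int) -> float:
    """Two-sided p from the t approximation with n-2 df."""
    if n < 3 or np.isnan(rho) or abs(rho) >= 1.0:
        return 0.0 if abs(rho) >= 1.0 and n >= 3 else np.nan
    t = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
    return float(2 * stats.t.sf(abs(t), df=n - 2))


def spearman_matrix(variables: pd.DataFrame) -> dict:
    """Pairwise-complete Spearman correlation matrix.

    Returns dict of DataFrames ``rho``, ``p``, ``n``; entries with fewer
    than 3 complete pairs are null.
    """
    cols = list(variables.columns)
    k = len(cols)
    rho = np.full((k, k), np.nan)
    pmat = np.full((k, k), np.nan)
    nmat = np.zeros((k, k), int)
    arr = variables.to_numpy(float)
    for i in range(k):
        for j in range(i, k):
            mask = ~(np.isnan(arr[:, i]) | np.isnan(arr[:, j]))
            n = int(mask.sum())
            nmat[i, j] = nmat[j, i] = n
            if n < 3:
                continue
            r = spearman_rho(arr[mask, i], arr[mask, j])
            rho[i, j] = rho[j, i] = r
            pmat[i, j] = pmat[j, i] = _spearman_p(r, n) if i != j else 0.0
    return {
        "rho": pd.DataFrame(rho, index=cols, columns=cols),
        "p": pd.DataFrame(pmat, index=cols, columns=cols),
        "n": pd.DataFrame(nmat, index=cols, columns=cols),
    }


def anova_lm(y, x) -> dict:
    """Single-predictor OLS F-test (F = MS_model / MS_residual, df (1, n-2))."""
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    mask = ~(np.isnan(x) | np.isnan(y))
    x, y = x[mask], y[mask]
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.ptp(x) == 0:
        raise ValueError("no variance in predictor")
    xc = x - x.mean()
    beta = (xc * y).sum() / (xc ** 2).sum()
    yhat = y.mean() + beta * xc
    ss_model = ((yhat - y.mean()) ** 2).sum()
    ss_resid = ((y - yhat) ** 2).sum()
    ss_total = ss_model + ss_resid
    if ss_resid == 0:
        return {"F": np.inf, "p": 0.0, "R2": 1.0, "n": n}
    F = ss_model / (ss_resid / (n - 2))
    p = float(stats.f.sf(F, 1, n - 2))
    return {"F": float(F), "p": p, "R2": float(ss_model / ss_total), "n": n}
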