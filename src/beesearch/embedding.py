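"""Low-dimensional embedding of heat maps and group separation.

Flattened per-bee heat maps (342 tile fractions) form the predictor X;
the binary group indicator forms Y.  A SIMPLS partial-least-squares
regression reduces X to a few scores per bee; each group's scores are
wrapped in a minimum-volume enclosing ellipsoid; the ellipsoid surfaces
are resampled and a linear soft-margin SVM fits the separating
hyperplane (separatrix) between two sets of groups.  Signed distances
of bees to the separatrix order the groups.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from beesearch.features import Grid
from beesearch.stats import MesResult, cohen_u3_mes


def group_indicator(groups: pd.Series | list) -> pd.DataFrame:
    """Binary (bees × groups) indicator matrix Y, one column per group
    in first-appearance order."""
    s = pd.Series(groups)
    labels = list(dict.fromkeys(s))
    Y = pd.DataFrame(0.0, index=s.index, columns=labels)
    for g in labels:
        Y.loc[s == g, g] = 1.0
    return Y


@dataclass
class PLSModel:
    """A fitted SIMPLS partial-least-squares regression.

    ``scores`` are the per-bee component coordinates (unit-norm columns),
    ``x_loadings`` the X loadings P (the "support vectors", renderable as
    heat maps), ``variance_explained`` the fraction of X variance per
    component with ``cumulative_variance`` its running sum.
    """

    n_components: int
    scores: np.ndarray  # (bees, A)
    x_loadings: np.ndarray  # (features, A)
    x_weights: np.ndarray  # (features, A); X0 @ x_weights = scores
    y_loadings: np.ndarray  # (targets, A)
    variance_explained: np.ndarray  # per component, fraction of X variance
    cumulative_variance: np.ndarray
    x_mean: np.ndarray
    y_mean: np.ndarray
    feature_names: list[str] | None = None
    group_names: list[str] | None = None

    @property
    def support_vectors(self) -> np.ndarray:
        return self.x_loadings

    @property
    def coef(self) -> np.ndarray:
        """Regression coefficients B with Ŷ = (X − x̄) B + ȳ."""
        return self.x_weights @ self.y_loadings.T

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, float) - self.x_mean) @ self.coef + self.y_mean

    def reconstruct_x(self) -> np.ndarray:
        """X̂ = scores · loadingsᵀ + mean (rank-A approximation of X)."""
        return self.scores @ self.x_loadings.T + self.x_mean


def fit_pls(X, Y, n_components: int = 3) -> PLSModel:
    """SIMPLS partial least squares on column-centered X and Y (no
    scaling).

    If more components than the rank of centered X are requested, the
    count is reduced with a warning-free truncation (deflation leaves
    nothing to extract).
    """
    feature_names = list(X.columns) if isinstance(X, pd.DataFrame) else None
    group_names = list(Y.columns) if isinstance(Y, pd.DataFrame) else None
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must have the same number of rows")
    n, p = X.shape
    q = Y.shape[1]
    x_mean = X.mean(axis=0)
    y_mean = Y.mean(axis=0)
    X0 = X - x_mean
    Y0 = Y - y_mean
    ssx = float(np.sum(X0 * X0))
    rank = np.linalg.matrix_rank(X0)
    A = min(n_components, rank) if rank > 0 else 0

    T = np.zeros((n, A))
    P = np.zeros((p, A))
    W = np.zeros((p, A))
    Q = np.zeros((q, A))
    V = np.zeros((p, A))
    S = X0.T @ Y0
    for a in range(A):
        # dominant left singular vector of the deflated covariance
        U, sv, _ = np.linalg.svd(S, full_matrices=False)
        r = U[:, 0]
        t = X0 @ r
        nt = np.linalg.norm(t)
        if nt == 0:
            A = a
            break
        t /= nt
        r /= nt
        T[:, a] = t
        W[:, a] = r
        P[:, a] = X0.T @ t
        Q[:, a] = Y0.T @ t
        v = P[:, a].copy()
        if a > 0:
            v -= V[:, :a] @ (V[:, :a].T @ P[:, a])
        nv = np.linalg.norm(v)
        if nv == 0:
            A = a + 1
            break
        v /= nv
        V[:, a] = v
        S = S - np.outer(v, v @ S)
    T, P, W, Q = T[:, :A], P[:, :A], W[:, :A], Q[:, :A]
    var = np.einsum("ij,ij->j", P, P) / ssx if ssx > 0 else np.zeros(A)
    return PLSModel(
        n_components=A,
        scores=T,
        x_loadings=P,
        x_weights=W,
        y_loadings=Q,
        variance_explained=var,
        cumulative_variance=np.cumsum(var),
        x_mean=x_mean,
        y_mean=y_mean,
        feature_names=feature_names,
        group_names=group_names,
    )


@dataclass
class Ellipsoid:
    """{z : (z − c)ᵀ A (z − c) ≤ 1} with A symmetric positive definite."""

    center: np.ndarray
    shape: np.ndarray
    degenerate: bool = False

    def mahalanobis_sq(self, points: np.ndarray) -> np.ndarray:
        d = np.atleast_2d(points) - self.center
        return np.einsum("ij,jk,ik->i", d, self.shape, d)

    def contains(self, points: np.ndarray, tol: float = 1e-6) -> np.ndarray:
        return self.mahalanobis_sq(points) <= 1.0 + tol


def min_volume_ellipsoid(points: np.ndarray, tolerance: float = 1e-6) -> Ellipsoid:
    """Minimum-volume enclosing ellipsoid via Khachiyan's iterative
    algorithm.

    Degenerate point sets (fewer points than dimension + 1, collinear or
    coplanar clouds) fall back to a ridge-regularized shape matrix and
    are flagged.
    """
    P = np.atleast_2d(np.asarray(points, float))
    n, d = P.shape
    if n == 1 or np.allclose(P, P[0]):
        # single (repeated) point: tiny ball at the point, flagged
        return Ellipsoid(P[0].copy(), np.eye(d) * 1e12, degenerate=True)

    Qm = np.column_stack([P, np.ones(n)]).T  # (d+1, n)
    u = np.full(n, 1.0 / n)
    max_iter = 1000
    degenerate = False
    for _ in range(max_iter):
        Xm = Qm @ np.diag(u) @ Qm.T
        try:
            M = np.einsum("ij,ji->i", Qm.T, np.linalg.solve(Xm, Qm))
        except np.linalg.LinAlgError:
            degenerate = True
            M = np.einsum("ij,ji->i", Qm.T, np.linalg.pinv(Xm) @ Qm)
        j = int(np.argmax(M))
        maximum = M[j]
        if maximum <= d + 1 + tolerance * (d + 1):
            break
        step = (maximum - d - 1.0) / ((d + 1.0) * (maximum - 1.0))
        u *= 1.0 - step
        u[j] += step

    c = P.T @ u
    cov = P.T @ np.diag(u) @ P - np.outer(c, c)
    try:
        A = np.linalg.inv(cov) / d
        if np.linalg.cond(cov) > 1e12:
            degenerate = True
            A = np.linalg.inv(cov + np.eye(d) * 1e-9) / d
    except np.linalg.LinAlgError:
        degenerate = True
        A = np.linalg.inv(cov + np.eye(d) * 1e-9) / d
    A = 0.5 * (A + A.T)
    e = Ellipsoid(c, A, degenerate=degenerate)
    # guarantee containment: inflate to the farthest generating point
    m = float(np.max(e.mahalanobis_sq(P)))
    if m > 1.0:
        e.shape = e.shape / m
    return e


def sample_ellipsoid_surface(e: Ellipsoid, n: int = 441) -> np.ndarray:
    """Deterministic surface sample of a 3-D ellipsoid.

    A 21 × 21 azimuth × inclination grid on the unit sphere (poles kept
    once each, pole duplicates replaced by extra equator points so the
    count is exactly n) is mapped through the ellipsoid transform.
    """
    d = len(e.center)
    if d != 3:
        raise ValueError("surface sampling is defined for 3-D ellipsoids")
    g = int(round(np.sqrt(n)))
    if g * g != n:
        g = max(2, int(np.sqrt(n)))  # nearest grid below; padded back to n
    incl = np.linspace(0.0, np.pi, g)
    azim = np.linspace(0.0, 2.0 * np.pi, g + 1)[:-1]
    ii, aa = np.meshgrid(incl[1:-1], azim, indexing="ij")
    pts = [np.array([[0.0, 0.0, 1.0], [0.0, 0.0, -1.0]])]  # poles, once each
    pts.append(
        np.column_stack(
            [np.sin(ii.ravel()) * np.cos(aa.ravel()), np.sin(ii.ravel()) * np.sin(aa.ravel()), np.cos(ii.ravel())]
        )
    )
    base = np.vstack(pts)
    missing = n - len(base)
    if missing > 0:
        # pad along the equator at azimuths that cannot collide with the grid
        extra_az = np.arange(missing) * (2.0 * np.pi / missing) + np.pi / (2 * g * missing)
        base = np.vstack(
            [base, np.column_stack([np.cos(extra_az), np.sin(extra_az), np.zeros(missing)])]
        )
    elif missing < 0:
        base = base[:n]
    # map unit sphere -> ellipsoid surface: z = c + A^{-1/2} s
    w, V = np.linalg.eigh(e.shape)
    w = np.clip(w, 1e-300, None)
    A_inv_half = V @ np.diag(1.0 / np.sqrt(w)) @ V.T
    return e.center + base @ A_inv_half.T


@dataclass
class Separatrix:
    """A separating hyperplane in score space: unit normal and offset,
    with signed distance(z) = normal·z − offset."""

    normal: np.ndarray
    offset: float
    side_of_group: dict[str, int] = field(default_factory=dict)

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        return np.atleast_2d(points) @ self.normal - self.offset


def fit_separatrix_points(points: np.ndarray, labels: np.ndarray, C: float = 1.0) -> Separatrix:
    """Linear soft-margin SVM hyperplane through labeled points
    (labels ±1; balanced class weights, fixed C, deterministic solver)."""
    clf = SVC(kernel="linear", C=C, class_weight="balanced")
    clf.fit(np.asarray(points, float), np.asarray(labels))
    w = np.array(clf.coef_[0])
    b = float(clf.intercept_[0])
    nrm = float(np.linalg.norm(w))
    return Separatrix(w / nrm, -b / nrm)


def fit_separatrix(
    side1: list[Ellipsoid],
    side2: list[Ellipsoid],
    n_surface: int = 441,
    C: float = 1.0,
    side1_labels: list[str] | None = None,
    side2_labels: list[str] | None = None,
) -> Separatrix:
    """Linear soft-margin SVM separatrix between two sets of group
    ellipsoids, trained on their pooled resampled surfaces (balanced
    class weights, fixed C)."""
    if not side1 or not side2:
        raise ValueError("both sides need at least one ellipsoid")
    P1 = np.vstack([sample_ellipsoid_surface(e, n_surface) for e in side1])
    P2 = np.vstack([sample_ellipsoid_surface(e, n_surface) for e in side2])
    Xs = np.vstack([P1, P2])
    ys = np.concatenate([-np.ones(len(P1)), np.ones(len(P2))])
    sep = fit_separatrix_points(Xs, ys, C=C)
    sides: dict[str, int] = {}
    for labels, sign in ((side1_labels, -1), (side2_labels, 1)):
        for lab in labels or []:
            sides[lab] = sign
    sep.side_of_group = sides
    return sep


def signed_distances(
    s: Separatrix, scores: np.ndarray, groups: pd.Series | list
) -> tuple[pd.DataFrame, dict[tuple[str, str], MesResult]]:
    """Signed distance of each bee's score to the separatrix, plus all
    pairwise Cohen's-U3 results on the per-group distance distributions."""
    groups = pd.Series(list(groups), name="group")
    dist = s.signed_distance(np.asarray(scores, float))
    df = pd.DataFrame({"group": groups.values, "distance": dist})
    labels = list(dict.fromkeys(groups))
    pairwise: dict[tuple[str, str], MesResult] = {}
    for a, b in itertools.combinations(labels, 2):
        pairwise[(a, b)] = cohen_u3_mes(
            df.loc[df["group"] == a, "distance"], df.loc[df["group"] == b, "distance"]
        )
    return df, pairwise


def support_vector_heatmap(vector: np.ndarray, grid: Grid = Grid()) -> np.ndarray:
    """Render a tile-space loading vector (e.g. a PLS support vector, or a
    separatrix normal pulled back through the loadings) as a grid matrix
    normalized to [−1, +1] by its maximum absolute value."""
    v = np.asarray(vector, float)
    if v.size != grid.n_tiles:
        raise ValueError(f"vector length {v.size} does not match the {grid.n_tiles}-tile grid")
    m = np.abs(v).max()
    out = v if m == 0 else v / m
    return out.reshape(grid.n_rows, grid.n_cols)


def separatrix_in_tile_space(s: Separatrix, model: PLSModel) -> np.ndarray:
    """Pull the separatrix normal back to tile space via the PLS loadings."""
    return model.x_loadings @ s.normal
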