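"""Unsupervised codebook learning from whitened TF-patches.

The dictionary is learned in two stages: (1) PCA whitening of the
flattened TF-patches, keeping the fewest components explaining 99% of
the training-set variance, so whitened dimensions are uncorrelated with
unit variance; (2) spherical k-means, which constrains centroids to the
unit sphere and assigns each sample to the codeword with the largest
absolute dot product.  One sweep of the algorithm is

    s_j^(i) = D(j)' x^(i)   if j == argmax_l |D(l)' x^(i)|, else 0
    D      := X S' + D                       (damped additive update)
    D(j)   := D(j) / ||D(j)||_2              (renormalization)

iterated until the assigned-index vector stops changing (or max_iter).
Centroids are initialized from a standard Normal and normalized.  Note
the additive update means a cluster that receives no samples keeps its
previous centroid rather than collapsing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .frontend import RawPatchSet


@dataclass
class WhiteningTransform:
    """PCA whitening learned on training patches.

    ``projection`` (n x p) combines the PCA rotation with per-component
    inverse-standard-deviation scaling, so applying the transform to the
    fit set yields zero mean and unit variance per retained dimension.
    """

    mean: np.ndarray  # (p,)
    projection: np.ndarray  # (n, p)
    n_components: int
    explained_variance_fraction: float

    @property
    def input_dim(self) -> int:
        return self.mean.size


@dataclass
class PatchMatrix:
    """Whitened patches, one per column (the X of the learning stage)."""

    X: np.ndarray  # (n, m)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def m(self) -> int:
        return self.X.shape[1]


@dataclass
class Codebook:
    """Learned dictionary of k unit-norm codewords (columns of D)."""

    D: np.ndarray  # (n, k)
    seed: int | None = None
    iterations_run: int = 0

    @property
    def n(self) -> int:
        return self.D.shape[0]

    @property
    def k(self) -> int:
        return self.D.shape[1]


@dataclass
class AssignmentMatrix:
    """Sparse code vectors: at most one non-zero per sample.

    ``indices[i]`` is the winning codeword for sample i and
    ``values[i]`` the signed dot product D(j)' x^(i) stored there.
    """

    indices: np.ndarray  # (m,) int
    values: np.ndarray  # (m,) float
    k: int

    @property
    def m(self) -> int:
        return self.indices.size

    def to_dense(self) -> np.ndarray:
        S = np.zeros((self.k, self.m))
        S[self.indices, np.arange(self.m)] = self.values
        return S


def _as_columns(patches) -> np.ndarray:
    if isinstance(patches, RawPatchSet):
        return patches.patches
    return np.asarray(patches, dtype=np.float64)


def fit_whitening(raw_patches, variance_keep: float = 0.99) -> WhiteningTransform:
    """Fit PCA whitening on training patches (columns = patches).

    Keeps the fewest components whose cumulative explained-variance
    fraction reaches ``variance_keep``; each kept component is scaled to
    unit variance on the fit set.
    """
    P = _as_columns(raw_patches)
    if not (0.0 < variance_keep <= 1.0):
        raise ValueError("variance_keep must lie in (0, 1]")
    if P.ndim != 2 or P.shape[1] < 2:
        raise ValueError("need at least 2 patches to fit whitening")
    if not np.all(np.isfinite(P)):
        raise ValueError("patches contain non-finite values")
    total_var = float(np.var(P, axis=1).sum())
    if total_var <= 1e-300:
        raise ValueError("patches have zero variance; whitening is undefined")
    if variance_keep == 1.0:
        pca = PCA(svd_solver="full")
    else:
        pca = PCA(n_components=variance_keep, svd_solver="full")
    pca.fit(P.T)
    if variance_keep == 1.0:
        keep = int(np.sum(pca.explained_variance_ > 1e-12 * pca.explained_variance_[0]))
    else:
        keep = pca.n_components_
    components = pca.components_[:keep]
    variances = pca.explained_variance_[:keep]
    projection = components / np.sqrt(variances)[:, None]
    evf = float(pca.explained_variance_ratio_[:keep].sum())
    return WhiteningTransform(
        mean=pca.mean_.copy(),
        projection=projection,
        n_components=keep,
        explained_variance_fraction=evf,
    )


def apply_whitening(transform: WhiteningTransform, raw) -> PatchMatrix:
    """Whiten patches (columns) with training-time parameters."""
    P = _as_columns(raw)
    if P.ndim == 1:
        P = P[:, None]
    if P.shape[0] != transform.input_dim:
        raise ValueError(
            f"patch length {P.shape[0]} != whitening input dim {transform.input_dim}"
        )
    X = transform.projection @ (P - transform.mean[:, None])
    return PatchMatrix(X=X)


def _assign(D: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    scores = D.T @ X  # (k, m)
    idx = np.argmax(np.abs(scores), axis=0)  # ties -> lowest index
    vals = scores[idx, np.arange(X.shape[1])]
    return idx, vals


def assign_codes(codebook: Codebook, X: PatchMatrix | np.ndarray) -> AssignmentMatrix:
    """Assign each whitened patch to its best-matching codeword.

    The winner is argmax over codewords of |D(l)' x|, ties broken by
    lowest index; the stored value is the signed dot product.
    """
    Xa = X.X if isinstance(X, PatchMatrix) else np.asarray(X, dtype=np.float64)
    if Xa.shape[0] != codebook.n:
        raise ValueError(f"dimension mismatch: X has {Xa.shape[0]} dims, codebook {codebook.n}")
    idx, vals = _assign(codebook.D, Xa)
    return AssignmentMatrix(indices=idx, values=vals, k=codebook.k)


def spherical_kmeans(
    X: PatchMatrix | np.ndarray,
    k: int,
    max_iter: int = 100,
    tol: float = 0.0,
    seed: int = 0,
    check_invariants: bool = False,
    reseed_empty: bool = False,
) -> tuple[Codebook, AssignmentMatrix]:
    """Learn a k-codeword dictionary by spherical k-means.

    Parameters
    ----------
    X : whitened patches, one per column.  k may exceed both the
        dimensionality and the sample count (over-complete codebooks).
    tol : optional centroid-movement stopping criterion (max column L2
        movement).  When 0 (default) the loop stops as soon as the
        assigned-index vector repeats; when positive, the movement
        criterion alone governs, letting the damped update iterate to
        its fixed point even after assignments stabilize.
    reseed_empty : if True, clusters that receive no samples are
        re-drawn from a Normal; by default the damped update leaves them
        unchanged, which is what the printed update rule does.
    """
    Xa = X.X if isinstance(X, PatchMatrix) else np.asarray(X, dtype=np.float64)
    if Xa.ndim != 2 or Xa.shape[1] == 0:
        raise ValueError("X must be a non-empty 2-D matrix of column samples")
    if k <= 0:
        raise ValueError("k must be >= 1")
    if not np.all(np.isfinite(Xa)):
        raise ValueError("X contains non-finite values")
    n, m = Xa.shape
    rng = np.random.default_rng(seed)
    D = rng.standard_normal((n, k))
    D /= np.linalg.norm(D, axis=0, keepdims=True)

    prev_idx = None
    iterations = 0
    for iterations in range(1, max_iter + 1):
        idx, vals = _assign(D, Xa)
        if tol == 0 and prev_idx is not None and np.array_equal(idx, prev_idx):
            iterations -= 1  # this sweep changed nothing
            break
        prev_idx = idx
        # D := X S' + D   (scatter-add the scaled samples into winners)
        update = np.zeros((k, n))
        np.add.at(update, idx, (Xa * vals).T)
        D_new = D + update.T
        norms = np.linalg.norm(D_new, axis=0)
        empty = ~np.isin(np.arange(k), idx)
        if reseed_empty and empty.any():
            D_new[:, empty] = rng.standard_normal((n, int(empty.sum())))
            norms = np.linalg.norm(D_new, axis=0)
        degenerate = norms < 1e-300
        if degenerate.any():  # pathological cancellation; keep previous direction
            D_new[:, degenerate] = D[:, degenerate]
            norms = np.linalg.norm(D_new, axis=0)
        moved = D_new / norms - D
        D = D_new / norms
        if check_invariants:
            assert np.allclose(np.linalg.norm(D, axis=0), 1.0, atol=1e-6)
        if tol > 0 and float(np.linalg.norm(moved, axis=0).max()) < tol:
            break

    idx, vals = _assign(D, Xa)
    codebook = Codebook(D=D, seed=seed, iterations_run=iterations)
    return codebook, AssignmentMatrix(indices=idx, values=vals, k=k)


def subsample_patches(patches: np.ndarray, cap: int, seed: int = 0) -> np.ndarray:
    """Randomly subsample patch columns to at most ``cap`` (seeded).

    Codebook learning cost scales with the patch count; the study-scale
    default cap is 250 000 columns.
    """
    m = patches.shape[1]
    if m <= cap:
        return patches
    rng = np.random.default_rng(seed)
    cols = np.sort(rng.choice(m, size=cap, replace=False))
    return patches[:, cols]
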