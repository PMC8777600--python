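"""Multiway PCA of stacks of 2T2D correlation maps.

The three-way array (samples x nu1 x nu2) is unfolded row-major into an
n x p^2 matrix, preprocessed, and decomposed by SVD — for an unfolded array
this is definitionally ordinary PCA of the unfolded matrix. Preprocessing
follows the chemometric convention used with correlation maps:

1. *normalization* — each sample row is divided by its Euclidean (Frobenius)
   norm, removing the concentration scale that 2T2D maps inherit from the
   raw absorbances;
2. *autoscaling with a scale offset* — each column (wavelength pair) is
   mean-centered and divided by (standard deviation + offset), the additive
   offset (default 1e-5) guarding near-constant columns against noise
   blow-up.

Model quality is summarised by the explained variance per component, the
calibration error RMSEC(k), and the venetian-blinds cross-validation error
RMSECV(k): samples are assigned to folds in a regular blocked pattern
(consecutive ``per_blind`` samples per blind, blinds dealt round-robin over
``n_splits`` folds), preprocessing and decomposition are refit on each
training fold, and the held-out rows are reconstructed from k components.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cos2t2d import CorrelationMap, MapStack
from .spectral import GridMismatchError, WavelengthGrid

__all__ = [
    "InsufficientSamplesError",
    "RankError",
    "FoldError",
    "PreprocessParams",
    "MPCAModel",
    "CVResult",
    "unfold",
    "refold",
    "preprocess",
    "apply_preprocess",
    "fit_mpca",
    "fit_stack",
    "venetian_blind_assignment",
    "cross_validate",
    "project",
]


class InsufficientSamplesError(ValueError):
    """Too few samples for the requested operation."""


class RankError(ValueError):
    """Requested more components than the data can support."""


class FoldError(ValueError):
    """A cross-validation training fold is too small."""


@dataclass
class PreprocessParams:
    """Frozen preprocessing state, reusable to project new samples.

    ``row_norms`` are the training rows' Euclidean norms (diagnostic only:
    projection normalizes each new row by its *own* norm); ``col_means`` and
    ``col_scales`` (= std + offset) are applied as stored.
    """

    row_norms: np.ndarray
    col_means: np.ndarray
    col_scales: np.ndarray
    offset: float
    zero_norm_rows: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.offset <= 0:
            raise ValueError("scale offset must be positive")
        if np.any(self.col_scales < self.offset):
            raise ValueError("column scales cannot fall below the offset")
        if not self.col_means.shape == self.col_scales.shape:
            raise ValueError("column parameter lengths disagree")


@dataclass
class MPCAModel:
    """A fitted multiway PCA model."""

    n_components: int
    loadings: np.ndarray  # (k, p^2), rows orthonormal
    scores: np.ndarray  # (n, k)
    singular_values: np.ndarray  # all computed singular values of X
    explained_variance_pct: np.ndarray  # (k,)
    rmsec_per_k: np.ndarray  # (k,), RMSEC for 1..k components
    preprocess: PreprocessParams | None = None
    grid: WavelengthGrid | None = None

    @property
    def cumulative_variance_pct(self) -> np.ndarray:
        return np.cumsum(self.explained_variance_pct)

    def loading_map(self, component: int) -> np.ndarray:
        """Refold one loading vector to its p x p wavelength-pair map."""
        if self.grid is None:
            raise ValueError("model has no grid; cannot refold loadings")
        p = self.grid.n_points
        return self.loadings[component].reshape(p, p)


@dataclass
class CVResult:
    """Venetian-blinds cross-validation summary."""

    n_splits: int
    samples_per_blind: int
    assignment: np.ndarray  # fold index per sample
    rmsecv_per_k: np.ndarray  # (k_max,)


def unfold(stack: MapStack) -> np.ndarray:
    """Unfold an (n, p, p) map stack into an n x p^2 matrix, row-major in
    (nu1, nu2)."""
    return stack.as_array().reshape(len(stack), -1)


def refold(X: np.ndarray, grid: WavelengthGrid) -> np.ndarray:
    """Inverse of :func:`unfold`: an (n, p^2) matrix back to (n, p, p)."""
    X = np.asarray(X)
    p = grid.n_points
    if X.ndim != 2 or X.shape[1] != p * p:
        raise ValueError(f"cannot refold shape {X.shape} onto a {p}x{p} grid")
    return X.reshape(X.shape[0], p, p)


def preprocess(X: np.ndarray, offset: float = 1e-5) -> tuple[np.ndarray, PreprocessParams]:
    """Row-normalize then autoscale columns with an additive scale offset.

    Rows with zero norm are left unchanged and flagged in the returned
    parameters. Column standard deviations use the n-1 denominator.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise InsufficientSamplesError(
            "preprocessing needs a 2-D matrix with at least two samples"
        )
    norms = np.linalg.norm(X, axis=1)
    zero_rows = tuple(int(i) for i in np.nonzero(norms == 0)[0])
    safe = np.where(norms == 0, 1.0, norms)
    Xn = X / safe[:, None]
    means = Xn.mean(axis=0)
    scales = Xn.std(axis=0, ddof=1) + offset
    Xp = (Xn - means) / scales
    return Xp, PreprocessParams(norms, means, scales, offset, zero_rows)


def apply_preprocess(X: np.ndarray, params: PreprocessParams) -> np.ndarray:
    """Preprocess new rows with stored column parameters.

    Each new row is normalized by its own Euclidean norm (the stored rule),
    then centered/scaled with the training column statistics.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    norms = np.linalg.norm(X, axis=1)
    safe = np.where(norms == 0, 1.0, norms)
    return (X / safe[:, None] - params.col_means) / params.col_scales


def _svd_with_sign_convention(Xp: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Economy SVD with each right-singular vector flipped so its
    largest-magnitude element is positive (SVD signs are arbitrary)."""
    U, S, Vt = np.linalg.svd(Xp, full_matrices=False)
    for i in range(Vt.shape[0]):
        j = int(np.argmax(np.abs(Vt[i])))
        if Vt[i, j] < 0:
            Vt[i] *= -1.0
            U[:, i] *= -1.0
    return U, S, Vt


def fit_mpca(
    Xp: np.ndarray,
    k_max: int,
    preprocess_params: PreprocessParams | None = None,
    grid: WavelengthGrid | None = None,
) -> MPCAModel:
    """PCA by SVD of a preprocessed unfolded matrix.

    Scores are U * S (so their Gram matrix is diagonal); explained variance
    per component is sigma_i^2 over the total sum of squared singular
    values; RMSEC(k) = sqrt(sum of squared residuals / (n p^2)) for the
    rank-k reconstruction.
    """
    Xp = np.asarray(Xp, dtype=float)
    n, m = Xp.shape
    if not 1 <= k_max <= min(n - 1, m):
        raise RankError(
            f"k_max must lie in [1, min(n-1, p^2)] = [1, {min(n - 1, m)}], got {k_max}"
        )
    U, S, Vt = _svd_with_sign_convention(Xp)
    total_ss = float(np.sum(S**2))
    scores = U[:, :k_max] * S[:k_max]
    loadings = Vt[:k_max]
    if total_ss > 0:
        explained = 100.0 * S[:k_max] ** 2 / total_ss
    else:
        explained = np.zeros(k_max)
    rmsec = np.empty(k_max)
    for k in range(1, k_max + 1):
        resid = Xp - scores[:, :k] @ loadings[:k]
        rmsec[k - 1] = np.sqrt(np.sum(resid**2) / (n * m))
    return MPCAModel(
        n_components=k_max,
        loadings=loadings,
        scores=scores,
        singular_values=S,
        explained_variance_pct=explained,
        rmsec_per_k=rmsec,
        preprocess=preprocess_params,
        grid=grid,
    )


def fit_stack(stack: MapStack, k_max: int, offset: float = 1e-5) -> MPCAModel:
    """Unfold, preprocess and decompose a correlation-map stack."""
    X = unfold(stack)
    Xp, params = preprocess(X, offset)
    return fit_mpca(Xp, k_max, preprocess_params=params, grid=stack.grid)


def venetian_blind_assignment(
    n: int, n_splits: int = 10, per_blind: int = 2, order: str = "blocked"
) -> np.ndarray:
    """Fold index per sample for venetian-blinds cross-validation.

    ``blocked`` deals consecutive runs of ``per_blind`` samples round-robin
    over the folds (sample i -> floor(i / per_blind) mod n_splits);
    ``interleave`` deals single samples (i mod n_splits).
    """
    i = np.arange(n)
    if order == "blocked":
        return (i // per_blind) % n_splits
    if order == "interleave":
        return i % n_splits
    raise ValueError(f"unknown cv order {order!r}; expected 'blocked' or 'interleave'")


def cross_validate(
    X: np.ndarray,
    k_max: int,
    n_splits: int = 10,
    per_blind: int = 2,
    order: str = "blocked",
    offset: float = 1e-5,
) -> CVResult:
    """Venetian-blinds RMSECV on a raw (unfolded, unpreprocessed) matrix.

    For each fold, preprocessing parameters and the decomposition are refit
    on the retained samples only; the held-out rows are preprocessed with
    those parameters and reconstructed from 1..k_max components. RMSECV(k)
    pools squared residuals over all held-out rows:
    sqrt(sum resid^2 / (n p^2)).
    """
    X = np.asarray(X, dtype=float)
    n, m = X.shape
    if n < n_splits:
        raise InsufficientSamplesError(
            f"need at least n_splits={n_splits} samples, got {n}"
        )
    assignment = venetian_blind_assignment(n, n_splits, per_blind, order)
    press = np.zeros(k_max)
    for fold in range(n_splits):
        held = assignment == fold
        if not np.any(held):
            continue
        train = X[~held]
        if train.shape[0] < 2:
            raise FoldError(f"training fold {fold} has fewer than two samples")
        if k_max > min(train.shape[0] - 1, m):
            raise RankError(
                f"k_max={k_max} exceeds the rank available in training fold {fold}"
            )
        Xp_train, params = preprocess(train, offset)
        _, _, Vt = _svd_with_sign_convention(Xp_train)
        Xp_held = apply_preprocess(X[held], params)
        for k in range(1, k_max + 1):
            recon = (Xp_held @ Vt[:k].T) @ Vt[:k]
            press[k - 1] += float(np.sum((Xp_held - recon) ** 2))
    rmsecv = np.sqrt(press / (n * m))
    return CVResult(n_splits, per_blind, assignment, rmsecv)


def project(model: MPCAModel, new_maps: MapStack) -> np.ndarray:
    """Score new correlation maps in a fitted model's component space."""
    if model.preprocess is None:
        raise ValueError("model carries no preprocessing parameters")
    if model.grid is not None and new_maps.grid != model.grid:
        raise GridMismatchError("new maps are not on the model's wavelength grid")
    Xp = apply_preprocess(unfold(new_maps), model.preprocess)
    return Xp @ model.loadings.T
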