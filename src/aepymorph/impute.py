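"""Iterative-PCA (EM) imputation of missing measurements.

The algorithm alternates a truncated-SVD reconstruction of the scaled,
centred data matrix with replacement of the missing cells by their fitted
values, keeping observed cells fixed, until the imputed values converge.
The regularized variant shrinks each retained singular value toward a
residual-variance estimate (the mean of the discarded eigenvalues), which
damps the overfitting the plain EM iteration is prone to when many cells
are missing.  The number of components is chosen by k-fold cross-validation
on held-out observed cells, minimising the mean squared error of prediction
(MSEP) in scaled space.

All functions accept either a :class:`~aepymorph.datamodel.Dataset` or a
plain DataFrame with NaN marking missing cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import Dataset

MODES = ("EM", "regularized")


@dataclass(frozen=True)
class ScalingParams:
    """Observed-cell mean and sample standard deviation per measurement."""

    mean: pd.Series
    sd: pd.Series

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return (X - self.mean) / self.sd

    def inverse(self, Z: pd.DataFrame) -> pd.DataFrame:
        return Z * self.sd + self.mean


@dataclass
class ImputationResult:
    completed: pd.DataFrame        # specimens x codes, mm
    imputed_mask: pd.DataFrame     # True where a cell was imputed
    ncp: int
    cv_errors: dict[int, float]    # candidate ncp -> MSEP (empty if ncp fixed)
    iterations: int
    converged: bool
    mode: str
    trace: list[float]             # total squared reconstruction error per iter


def _as_frame(data) -> pd.DataFrame:
    if isinstance(data, Dataset):
        return data.matrix()
    return pd.DataFrame(data).astype(float)


def fit_scaling(data) -> ScalingParams:
    """Per-code mean and sample sd (n-1) over observed cells only.

    Codes observed fewer than twice or with zero variance are rejected:
    unit-variance scaling is undefined for them.
    """
    X = _as_frame(data)
    counts = X.notna().sum()
    starved = counts[counts < 2]
    if len(starved):
        raise ValueError(
            f"codes observed fewer than twice: {', '.join(starved.index)}"
        )
    mean = X.mean()
    sd = X.std(ddof=1)
    flat = sd[sd <= 0]
    if len(flat):
        raise ValueError(f"zero observed variance in codes: {', '.join(flat.index)}")
    return ScalingParams(mean=mean, sd=sd)


def _low_rank_fit(Z: np.ndarray, ncp: int, mode: str) -> np.ndarray:
    """Rank-ncp reconstruction of the centred matrix Z (rows recentred by
    the caller); regularized mode shrinks the singular values."""
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    if mode == "regularized":
        ev = s**2
        discarded = ev[ncp:]
        sigma2 = discarded.mean() if discarded.size else 0.0
        s_fit = np.where(s[:ncp] > 0, (ev[:ncp] - sigma2) / np.where(s[:ncp] > 0, s[:ncp], 1.0), 0.0)
        s_fit = np.clip(s_fit, 0.0, None)
    else:
        s_fit = s[:ncp]
    return (U[:, :ncp] * s_fit) @ Vt[:ncp]


def impute_iterative_pca(
    data,
    ncp: int,
    mode: str = "regularized",
    tol: float = 1e-6,
    max_iter: int = 500,
    scaling: ScalingParams | None = None,
) -> ImputationResult:
    """Complete a partially observed matrix by iterative PCA.

    Missing cells start at the column mean (zero in scaled space); each
    iteration recentres, reconstructs at rank ``ncp`` and refreshes the
    missing cells from the fit.  Convergence is declared when the largest
    absolute change on any imputed cell (scaled units) drops below ``tol``.
    Observed cells are returned bit-identical to the input.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    X = _as_frame(data)
    n, p = X.shape
    limit = min(n, p) - 1
    if not 1 <= ncp <= limit:
        raise ValueError(f"ncp must be in [1, {limit}], got {ncp}")

    scaling = scaling or fit_scaling(X)
    Z = scaling.transform(X).to_numpy()
    mask = np.isnan(Z)

    if not mask.any():
        return ImputationResult(
            completed=X.copy(), imputed_mask=pd.DataFrame(mask, index=X.index, columns=X.columns),
            ncp=ncp, cv_errors={}, iterations=1, converged=True, mode=mode,
            trace=[0.0],
        )

    Z[mask] = 0.0  # column means in scaled space
    converged = False
    trace: list[float] = []
    iterations = 0
    for iterations in range(1, max_iter + 1):
        mu = Z.mean(axis=0)
        fit = _low_rank_fit(Z - mu, ncp, mode) + mu
        trace.append(float(((Z - fit) ** 2).sum()))
        new_vals = fit[mask]
        delta = np.abs(new_vals - Z[mask]).max()
        Z[mask] = new_vals
        if delta < tol:
            converged = True
            break

    completed = scaling.inverse(pd.DataFrame(Z, index=X.index, columns=X.columns))
    completed = completed.where(pd.DataFrame(mask, index=X.index, columns=X.columns), X)
    return ImputationResult(
        completed=completed,
        imputed_mask=pd.DataFrame(mask, index=X.index, columns=X.columns),
        ncp=ncp, cv_errors={}, iterations=iterations, converged=converged,
        mode=mode, trace=trace,
    )


def default_candidates(n: int, p: int) -> list[int]:
    upper = min(8, p - 2, n - 2)
    return list(range(1, max(upper, 1) + 1))


def select_ncp_cv(
    data,
    candidates: list[int] | None = None,
    folds: int = 5,
    mode: str = "regularized",
    seed: int = 0,
    tol: float = 1e-4,
    max_iter: int = 500,
    max_retries: int = 20,
) -> tuple[int, dict[int, float]]:
    """Choose the number of components by k-fold CV on observed cells.

    Observed cells are randomly partitioned into ``folds`` groups; each
    group is masked in turn, the matrix re-imputed with every candidate
    rank, and squared prediction error accumulated on the held-out cells in
    scaled space.  Returns the MSEP-minimising candidate (ties break toward
    the smaller rank) and the full error map.

    The default convergence tolerance is looser than the final imputation's:
    CV only ranks candidate ranks, which stabilises well before the imputed
    values themselves do.
    """
    X = _as_frame(data)
    n, p = X.shape
    if candidates is None:
        candidates = default_candidates(n, p)
    if not candidates:
        raise ValueError("no candidate ranks")
    scaling = fit_scaling(X)
    observed = np.argwhere(X.notna().to_numpy())
    if len(observed) < folds:
        raise ValueError("fewer observed cells than folds")

    rng = np.random.default_rng(seed)
    fold_of = _draw_folds(X, observed, folds, rng, max_retries)

    sq_err = {c: 0.0 for c in candidates}
    n_held = {c: 0 for c in candidates}
    Z_true = scaling.transform(X).to_numpy()
    for f in range(folds):
        held = observed[fold_of == f]
        arr = X.to_numpy(copy=True)
        arr[held[:, 0], held[:, 1]] = np.nan
        Xf = pd.DataFrame(arr, index=X.index, columns=X.columns)
        for c in candidates:
            res = impute_iterative_pca(
                Xf, ncp=c, mode=mode, tol=tol, max_iter=max_iter, scaling=scaling
            )
            Zc = scaling.transform(res.completed).to_numpy()
            err = Zc[held[:, 0], held[:, 1]] - Z_true[held[:, 0], held[:, 1]]
            sq_err[c] += float((err**2).sum())
            n_held[c] += len(held)

    cv_errors = {c: sq_err[c] / n_held[c] for c in candidates}
    best = min(cv_errors, key=lambda c: (cv_errors[c], c))
    return best, cv_errors


def _draw_folds(X, observed, folds, rng, max_retries) -> np.ndarray:
    """Assign observed cells to folds such that masking any single fold
    leaves every column with at least two observed training cells."""
    notna = X.notna().to_numpy()
    col_counts = notna.sum(axis=0)
    for _ in range(max_retries):
        fold_of = rng.integers(0, folds, size=len(observed))
        ok = True
        for f in range(folds):
            held = observed[fold_of == f]
            lost = np.bincount(held[:, 1], minlength=X.shape[1])
            if ((col_counts - lost) < 2).any():
                ok = False
                break
        if ok:
            return fold_of
    raise ValueError(
        "could not partition observed cells into folds without starving a "
        "column; reduce folds or drop sparse columns"
    )
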