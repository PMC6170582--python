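"""PCA and finite Gaussian-mixture clustering with BIC model selection.

Mixtures are fitted by EM over six covariance parameterisations, named by
the mclust convention (volume-shape-orientation):

====== ==========================================
EII    spherical, equal volume across components
VII    spherical, varying volume
EEI    diagonal, equal volume and shape
VVI    diagonal, varying volume and shape
EEE    ellipsoidal, shared covariance
VVV    ellipsoidal, fully free per component
====== ==========================================

BIC follows the mclust sign convention, BIC = 2 log L - m log n, and is
maximised; a selection is called *stable* when the best model beats the
best model with a different number of components by more than a
configurable margin (default 2).  EM is initialised from a Ward
agglomeration cut at K, with additional randomly initialised restarts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.special import logsumexp

FAMILIES = ("EII", "VII", "EEI", "VVI", "EEE", "VVV")

_RIDGE_COND = 1e10
_RIDGE_EPS = 1e-6


@dataclass
class PcaResult:
    loadings: pd.DataFrame            # codes x components
    scores: pd.DataFrame              # specimens x components
    explained_fraction: np.ndarray

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def pca(matrix: pd.DataFrame) -> PcaResult:
    """Centred SVD of a completed matrix.

    Sign convention: within each component the largest-magnitude loading is
    made positive, so results are deterministic across SVD backends.
    """
    X = pd.DataFrame(matrix).astype(float)
    if X.isna().any().any():
        raise ValueError("PCA input must have no missing cells")
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 specimens")
    centred = X - X.mean()
    U, s, Vt = np.linalg.svd(centred.to_numpy(), full_matrices=False)
    if not np.any(s > 0):
        raise ValueError("matrix has rank 0")
    ncomp = int(np.sum(s > s[0] * 1e-12))
    U, s, Vt = U[:, :ncomp], s[:ncomp], Vt[:ncomp]
    # deterministic sign: flip so the largest-|loading| entry is positive
    flip = np.sign(Vt[np.arange(ncomp), np.abs(Vt).argmax(axis=1)])
    flip[flip == 0] = 1.0
    Vt = Vt * flip[:, None]
    U = U * flip[None, :]
    comp_names = [f"PC{i + 1}" for i in range(ncomp)]
    explained = s**2 / (s**2).sum()
    return PcaResult(
        loadings=pd.DataFrame(Vt.T, index=X.columns, columns=comp_names),
        scores=pd.DataFrame(U * s, index=X.index, columns=comp_names),
        explained_fraction=explained,
    )


def n_mixture_params(family: str, K: int, d: int) -> int:
    """Free parameters: K-1 weights, K*d means, plus covariance terms."""
    cov = {
        "EII": 1,
        "VII": K,
        "EEI": d,
        "VVI": K * d,
        "EEE": d * (d + 1) // 2,
        "VVV": K * d * (d + 1) // 2,
    }[family]
    return (K - 1) + K * d + cov


@dataclass
class MixtureModel:
    family: str
    K: int
    weights: np.ndarray               # (K,)
    means: np.ndarray                 # (K, d)
    covariances: np.ndarray           # (K, d, d)
    loglik: float
    bic: float
    n_params: int
    loglik_trace: list[float] = field(default_factory=list, repr=False)
    converged: bool = True

    @property
    def d(self) -> int:
        return self.means.shape[1]


@dataclass
class Assignment:
    """Posterior cluster memberships for a set of specimens."""

    responsibilities: pd.DataFrame    # specimens x components
    labels: pd.Series                 # argmax component (int)
    uncertainty: pd.Series            # 1 - max posterior


class _EmptyComponent(Exception):
    pass


def _regularize(cov: np.ndarray) -> np.ndarray:
    diag = np.diagonal(cov)
    mean_diag = float(diag.mean()) if diag.size else 0.0
    if mean_diag <= 0:
        raise _EmptyComponent("degenerate covariance")
    ev = np.linalg.eigvalsh(cov)
    if ev[0] <= 0 or ev[-1] / max(ev[0], 1e-300) > _RIDGE_COND:
        cov = cov + np.eye(cov.shape[0]) * _RIDGE_EPS * mean_diag
    return cov


def _log_gauss(X: np.ndarray, mu: np.ndarray, cov: np.ndarray) -> np.ndarray:
    d = X.shape[1]
    cov = _regularize(cov)
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise _EmptyComponent("singular covariance") from exc
    diff = X - mu
    sol = np.linalg.solve(chol, diff.T)
    maha = (sol**2).sum(axis=0)
    logdet = 2.0 * np.log(np.diagonal(chol)).sum()
    return -0.5 * (d * np.log(2.0 * np.pi) + logdet + maha)


def _m_step_cov(family, X, resp, means, nk):
    n, d = X.shape
    K = means.shape[0]
    W = np.empty((K, d, d))
    for k in range(K):
        diff = X - means[k]
        W[k] = (resp[:, k][:, None] * diff).T @ diff
    covs = np.empty((K, d, d))
    if family == "VVV":
        for k in range(K):
            covs[k] = W[k] / nk[k]
    elif family == "EEE":
        covs[:] = W.sum(axis=0) / n
    elif family == "VVI":
        for k in range(K):
            covs[k] = np.diag(np.diagonal(W[k]) / nk[k])
    elif family == "EEI":
        covs[:] = np.diag(np.diagonal(W.sum(axis=0)) / n)
    elif family == "VII":
        for k in range(K):
            covs[k] = np.eye(d) * (np.trace(W[k]) / (nk[k] * d))
    elif family == "EII":
        covs[:] = np.eye(d) * (np.trace(W.sum(axis=0)) / (n * d))
    else:
        raise ValueError(f"unknown covariance family {family!r}")
    return covs


def _hierarchical_labels(X: np.ndarray, K: int) -> np.ndarray:
    if K == 1:
        return np.zeros(len(X), dtype=int)
    Z = linkage(X, method="ward")
    return fcluster(Z, t=K, criterion="maxclust") - 1


def _resp_from_labels(labels: np.ndarray, K: int) -> np.ndarray:
    resp = np.zeros((len(labels), K))
    resp[np.arange(len(labels)), labels] = 1.0
    return resp


def _em(X, K, family, resp, tol, max_iter):
    n, d = X.shape
    trace: list[float] = []
    loglik = -np.inf
    converged = False
    for _ in range(max_iter):
        nk = resp.sum(axis=0)
        if np.any(nk < 1e-8):
            raise _EmptyComponent("component lost all responsibility")
        weights = nk / n
        means = (resp.T @ X) / nk[:, None]
        covs = _m_step_cov(family, X, resp, means, nk)
        log_dens = np.empty((n, K))
        for k in range(K):
            log_dens[:, k] = np.log(weights[k]) + _log_gauss(X, means[k], covs[k])
        norm = logsumexp(log_dens, axis=1)
        new_loglik = float(norm.sum())
        trace.append(new_loglik)
        resp = np.exp(log_dens - norm[:, None])
        if np.isfinite(loglik) and abs(new_loglik - loglik) < tol * (1 + abs(new_loglik)):
            loglik = new_loglik
            converged = True
            break
        loglik = new_loglik
    return weights, means, covs, loglik, trace, converged, resp


def fit_gmm(
    scores,
    K: int,
    family: str,
    init: str = "hierarchical",
    n_restarts: int = 3,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> MixtureModel:
    """Fit a K-component Gaussian mixture of the given covariance family.

    The first start cuts a Ward agglomeration at K (``init='random'`` skips
    it); remaining restarts use random hard assignments.  The best restart
    by log-likelihood wins.  An EM run that empties a component is retried
    with a fresh random start (bounded), then treated as failed.
    """
    X = pd.DataFrame(scores).astype(float)
    arr = X.to_numpy()
    if arr.ndim == 1:
        arr = arr[:, None]
    n, d = arr.shape
    if n <= K:
        raise ValueError(f"need more specimens ({n}) than components ({K})")
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; choose from {FAMILIES}")

    rng = np.random.default_rng(seed)
    starts = []
    if init == "hierarchical":
        starts.append(_hierarchical_labels(arr, K))
    extra = max(n_restarts - len(starts), 0)
    for _ in range(extra + 4):  # a few spares to absorb failed runs
        labels = rng.integers(0, K, size=n)
        for k in range(K):       # guarantee non-empty start
            if not np.any(labels == k):
                labels[rng.integers(n)] = k
        starts.append(labels)

    best = None
    successes = 0
    for labels in starts:
        if successes >= max(n_restarts, 1):
            break
        try:
            w, m, c, ll, trace, conv, resp = _em(
                arr, K, family, _resp_from_labels(labels, K), tol, max_iter
            )
        except _EmptyComponent:
            continue
        successes += 1
        if best is None or ll > best[3]:
            best = (w, m, c, ll, trace, conv)
    if best is None:
        raise RuntimeError(
            f"all EM starts failed for K={K}, family={family} "
            "(components kept emptying)"
        )
    w, m, c, ll, trace, conv = best[0], best[1], best[2], best[3], best[4], best[5]
    n_params = n_mixture_params(family, K, d)
    return MixtureModel(
        family=family, K=K, weights=w, means=m, covariances=c,
        loglik=ll, bic=2.0 * ll - n_params * np.log(n),
        n_params=n_params, loglik_trace=trace, converged=conv,
    )


def classify(model: MixtureModel, scores) -> Assignment:
    """Posterior responsibilities via Bayes' rule; uncertainty = 1 - max."""
    X = pd.DataFrame(scores).astype(float)
    arr = X.to_numpy()
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.shape[1] != model.d:
        raise ValueError(
            f"scores have {arr.shape[1]} dimensions, model was fitted on {model.d}"
        )
    K = model.K
    log_dens = np.empty((len(arr), K))
    for k in range(K):
        log_dens[:, k] = np.log(model.weights[k]) + _log_gauss(
            arr, model.means[k], model.covariances[k]
        )
    norm = logsumexp(log_dens, axis=1)
    resp = np.exp(log_dens - norm[:, None])
    resp_df = pd.DataFrame(resp, index=X.index, columns=range(K))
    labels = pd.Series(resp.argmax(axis=1), index=X.index, name="label")
    uncertainty = pd.Series(1.0 - resp.max(axis=1), index=X.index, name="uncertainty")
    return Assignment(responsibilities=resp_df, labels=labels, uncertainty=uncertainty)


@dataclass
class ModelSelection:
    model: MixtureModel
    bic_table: pd.DataFrame           # index K, columns family
    stable: bool
    margin: float                     # best BIC minus best different-K BIC


def select_model(
    scores,
    K_range=range(1, 7),
    families=FAMILIES,
    stability_delta: float = 2.0,
    seed: int = 0,
    n_restarts: int = 3,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> ModelSelection:
    """Fit every (K, family) pair and keep the highest-BIC model.

    Exact BIC ties break toward smaller K, then fewer parameters.  The
    result is stable when the winner beats the best model with a different
    K by more than ``stability_delta``.
    """
    K_list = sorted(set(int(k) for k in K_range))
    fam_list = [f for f in families]
    if not K_list or not fam_list:
        raise ValueError("empty K_range or families grid")
    fits: list[MixtureModel] = []
    bic = pd.DataFrame(np.nan, index=K_list, columns=fam_list)
    for K in K_list:
        for fam in fam_list:
            try:
                m = fit_gmm(
                    scores, K, fam, seed=seed + 7919 * K,
                    n_restarts=n_restarts, tol=tol, max_iter=max_iter,
                )
            except (RuntimeError, ValueError):
                continue
            fits.append(m)
            bic.loc[K, fam] = m.bic
    if not fits:
        raise RuntimeError("every (K, family) fit failed")
    best = max(fits, key=lambda m: (m.bic, -m.K, -m.n_params))
    others = [m.bic for m in fits if m.K != best.K]
    margin = best.bic - max(others) if others else np.inf
    return ModelSelection(
        model=best, bic_table=bic, stable=bool(margin > stability_delta),
        margin=float(margin),
    )


@dataclass
class SteppedResult:
    n_pcs_used: int
    model: MixtureModel
    selection: ModelSelection
    stable: bool
    per_step: list[ModelSelection] = field(default_factory=list, repr=False)


def stepped_pc_selection(
    pca_result: PcaResult,
    K_range=range(1, 7),
    families=FAMILIES,
    max_pcs: int | None = None,
    stability_delta: float = 2.0,
    seed: int = 0,
    **fit_kwargs,
) -> SteppedResult:
    """Introduce principal components one at a time until BIC resolves a
    stable cluster structure; the first stable step wins.

    A step terminates the search only when it is stable *and* resolves a
    distinct pattern (K >= 2): a confidently unimodal low-dimensional view
    must not stop the search when clusters separate on a later component.
    If no step qualifies, the step with the largest stability margin is
    returned, flagged unstable (this includes genuinely structureless data,
    where K = 1 wins at every step).
    """
    avail = pca_result.n_components
    max_pcs = avail if max_pcs is None else min(max_pcs, avail)
    if max_pcs < 1:
        raise ValueError("no principal components available")
    steps: list[ModelSelection] = []
    for m in range(1, max_pcs + 1):
        sel = select_model(
            pca_result.scores.iloc[:, :m], K_range=K_range, families=families,
            stability_delta=stability_delta, seed=seed, **fit_kwargs,
        )
        steps.append(sel)
        if sel.stable and sel.model.K >= 2:
            return SteppedResult(m, sel.model, sel, True, steps)
    best_idx = int(np.argmax([s.margin for s in steps]))
    sel = steps[best_idx]
    return SteppedResult(best_idx + 1, sel.model, sel, False, steps)
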