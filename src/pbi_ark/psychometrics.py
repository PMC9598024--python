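"""Subscale derivation and reliability for needs-questionnaire items.

Exploratory factor analysis on the recoded importance (PNQ) matrix:
principal-component extraction from the Pearson correlation matrix of
listwise-complete rows, Kaiser retention (eigenvalue strictly greater
than 1), and varimax rotation with Kaiser row-normalisation.  Items are
assigned to the factor carrying their highest absolute rotated loading,
with explicit content-based overrides and factor-merging supported for
solutions where several factors map onto one content-defined subscale.
Internal consistency is Cronbach's alpha with listwise deletion.

Principal-component extraction is the default because eigenvalues of the
correlation matrix are the natural retention quantity under the Kaiser
rule; iterated principal-axis factoring is available as an alternative
extraction for sensitivity checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .instrument import N_ITEMS, Population, SubscaleMap

__all__ = [
    "FactorSolution",
    "AssignmentResult",
    "ReliabilityResult",
    "ExploratoryFactorAnalysis",
    "NoFactorsRetainedError",
    "LoadingTieError",
    "efa_varimax",
    "efa_from_correlation",
    "varimax",
    "assign_items",
    "loading_table",
    "cronbach_alpha",
    "tucker_congruence",
]


class NoFactorsRetainedError(ValueError):
    """No correlation-matrix eigenvalue exceeded 1; nothing to rotate."""

    def __init__(self, eigenvalues: np.ndarray):
        self.eigenvalues = np.asarray(eigenvalues)
        super().__init__(
            "no eigenvalue exceeds 1 under the Kaiser rule "
            f"(largest: {self.eigenvalues.max():.4f})"
        )


class LoadingTieError(ValueError):
    """Two factors tie exactly for an item's highest absolute loading."""


@dataclass(frozen=True)
class FactorSolution:
    """A rotated principal-component solution on an item correlation matrix."""

    n_used: int
    eigenvalues: np.ndarray          # all p eigenvalues, descending
    n_retained: int
    loadings: np.ndarray             # (p, n_retained), varimax-rotated
    variance_explained_pct: float
    rotation_matrix: np.ndarray      # (n_retained, n_retained), orthonormal
    item_ids: tuple[int, ...]

    @property
    def communalities(self) -> np.ndarray:
        return (self.loadings ** 2).sum(axis=1)


@dataclass(frozen=True)
class ItemAssignment:
    item_id: int
    subscale: str
    winning_factor: int              # 0-based column of the loading matrix
    winning_loading: float
    secondary_loadings: tuple[tuple[int, float], ...]  # |loading| >= 0.3, non-winning
    override: bool
    override_reason: Optional[str] = None


@dataclass(frozen=True)
class AssignmentResult:
    subscales: Mapping[str, frozenset[int]]
    items: tuple[ItemAssignment, ...]

    def to_subscale_map(self, population: Union[Population, str]) -> SubscaleMap:
        population = Population(population) if isinstance(population, str) else population
        return SubscaleMap(population, dict(self.subscales))


@dataclass(frozen=True)
class ReliabilityResult:
    scale: str
    k: int
    n_used: int
    alpha: float


# ---------------------------------------------------------------------------
# Extraction and rotation


def varimax(
    loadings: np.ndarray,
    kaiser_normalize: bool = True,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> tuple[np.ndarray, np.ndarray]:
    """Varimax rotation; returns (rotated loadings, rotation matrix).

    Kaiser row-normalisation divides each item row by its communality
    before rotating and restores it afterwards, so low-communality items
    do not dominate the criterion.  Each rotated factor is reflected so
    its largest-magnitude loading is positive.
    """
    L = np.asarray(loadings, dtype=float)
    p, k = L.shape
    if k < 2:
        R = np.eye(k)
        return _reflect(L.copy()), R
    h = np.sqrt((L ** 2).sum(axis=1)) if kaiser_normalize else np.ones(p)
    h = np.where(h == 0, 1.0, h)
    A = L / h[:, None]
    R = np.eye(k)
    d_old = 0.0
    for _ in range(max_iter):
        B = A @ R
        grad = A.T @ (B ** 3 - B @ np.diag((B ** 2).sum(axis=0)) / p)
        u, s, vt = np.linalg.svd(grad)
        R = u @ vt
        d_new = s.sum()
        if d_new <= d_old * (1.0 + tol):
            break
        d_old = d_new
    rotated = (A @ R) * h[:, None]
    rotated, signs = _reflect(rotated, return_signs=True)
    return rotated, R * signs[None, :]


def _reflect(L: np.ndarray, return_signs: bool = False):
    signs = np.ones(L.shape[1])
    for j in range(L.shape[1]):
        i = np.argmax(np.abs(L[:, j]))
        if L[i, j] < 0:
            signs[j] = -1.0
            L[:, j] = -L[:, j]
    return (L, signs) if return_signs else L


def _principal_axis(R: np.ndarray, n_factors: int, max_iter: int = 100, tol: float = 1e-4) -> np.ndarray:
    """Iterated principal-axis loadings (alternative extraction)."""
    Rw = R.copy()
    comm = 1.0 - 1.0 / np.diag(np.linalg.inv(R))  # SMC start
    for _ in range(max_iter):
        np.fill_diagonal(Rw, comm)
        vals, vecs = np.linalg.eigh(Rw)
        order = np.argsort(vals)[::-1][:n_factors]
        L = vecs[:, order] * np.sqrt(np.clip(vals[order], 0, None))
        new_comm = (L ** 2).sum(axis=1)
        if np.max(np.abs(new_comm - comm)) < tol:
            comm = new_comm
            break
        comm = new_comm
    return L


class ExploratoryFactorAnalysis(BaseEstimator, TransformerMixin):
    """Kaiser-retained, varimax-rotated factor analysis of an item matrix.

    Parameters
    ----------
    extraction:
        ``"principal_component"`` (default) or ``"principal_axis"``.
    rotation_tol, rotation_max_iter:
        Varimax convergence settings.

    Fitted attributes: ``eigenvalues_``, ``n_retained_``, ``loadings_``
    (items x retained factors, rotated), ``variance_explained_pct_``,
    ``rotation_matrix_``, ``n_used_`` (rows after listwise deletion),
    ``solution_`` (the full :class:`FactorSolution`).

    ``transform`` projects (complete) rows onto the rotated components via
    correlation-weighted regression scores, so the estimator composes with
    sklearn pipelines; the validation pipeline itself only uses ``fit``.
    """

    def __init__(
        self,
        extraction: str = "principal_component",
        rotation_tol: float = 1e-6,
        rotation_max_iter: int = 200,
    ):
        self.extraction = extraction
        self.rotation_tol = rotation_tol
        self.rotation_max_iter = rotation_max_iter

    def fit(self, X, y=None, item_ids: Optional[Sequence[int]] = None) -> "ExploratoryFactorAnalysis":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] < 2:
            raise ValueError("X must be a 2-D matrix with at least 2 items")
        complete = ~np.isnan(X).any(axis=1)
        Xc = X[complete]
        p = X.shape[1]
        if Xc.shape[0] < p + 1:
            raise ValueError(
                f"only {Xc.shape[0]} listwise-complete rows for {p} items; "
                f"need at least {p + 1}"
            )
        sd = Xc.std(axis=0, ddof=1)
        zero_var = np.flatnonzero(sd == 0)
        if zero_var.size:
            ids = item_ids or tuple(range(1, p + 1))
            raise ValueError(
                f"zero-variance item(s): {[ids[j] for j in zero_var]}"
            )
        R = np.corrcoef(Xc, rowvar=False)
        self._fit_correlation(R, n_used=Xc.shape[0], item_ids=item_ids)
        self._mean_ = Xc.mean(axis=0)
        self._sd_ = sd
        return self

    def _fit_correlation(self, R: np.ndarray, n_used: int, item_ids: Optional[Sequence[int]] = None):
        p = R.shape[0]
        item_ids = tuple(item_ids) if item_ids is not None else tuple(range(1, p + 1))
        vals, vecs = np.linalg.eigh(R)
        order = np.argsort(vals)[::-1]
        vals, vecs = vals[order], vecs[:, order]
        retained = vals > 1.0  # strictly greater: equality does not retain
        m = int(retained.sum())
        if m == 0:
            raise NoFactorsRetainedError(vals)
        if self.extraction == "principal_component":
            L = vecs[:, :m] * np.sqrt(vals[:m])
        elif self.extraction == "principal_axis":
            L = _principal_axis(R, m)
        else:
            raise ValueError(f"unknown extraction {self.extraction!r}")
        rotated, Rot = varimax(
            L, kaiser_normalize=True, tol=self.rotation_tol, max_iter=self.rotation_max_iter
        )
        self.eigenvalues_ = vals
        self.n_retained_ = m
        self.loadings_ = rotated
        self.rotation_matrix_ = Rot
        self.variance_explained_pct_ = float(100.0 * vals[:m].sum() / p)
        self.n_used_ = n_used
        self.item_ids_ = item_ids
        self._correlation_ = R
        self.solution_ = FactorSolution(
            n_used=n_used,
            eigenvalues=vals,
            n_retained=m,
            loadings=rotated,
            variance_explained_pct=self.variance_explained_pct_,
            rotation_matrix=Rot,
            item_ids=item_ids,
        )
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "loadings_"):
            raise RuntimeError("not fitted")
        X = np.asarray(X, dtype=float)
        Z = (X - self._mean_) / self._sd_
        W = np.linalg.solve(self._correlation_, self.loadings_)
        return Z @ W


def efa_varimax(
    X, item_ids: Optional[Sequence[int]] = None, extraction: str = "principal_component"
) -> FactorSolution:
    """Fit the default EFA on a respondents-by-items importance matrix."""
    est = ExploratoryFactorAnalysis(extraction=extraction)
    return est.fit(X, item_ids=item_ids).solution_


def efa_from_correlation(
    R: np.ndarray, n_used: int, item_ids: Optional[Sequence[int]] = None
) -> FactorSolution:
    """Fit directly on a (population) correlation matrix; used for analytic checks."""
    est = ExploratoryFactorAnalysis()
    est._fit_correlation(np.asarray(R, dtype=float), n_used=n_used, item_ids=item_ids)
    return est.solution_


# ---------------------------------------------------------------------------
# Item assignment


def assign_items(
    solution: FactorSolution,
    overrides: Iterable[tuple[int, str, str]] = (),
    factor_subscales: Optional[Mapping[int, str]] = None,
    secondary_threshold: float = 0.3,
) -> AssignmentResult:
    """Assign each item to the factor with its highest absolute loading.

    ``factor_subscales`` maps 0-based factor columns to subscale names and
    supports merging several factors into one content-defined subscale
    (the adolescent solution merges five factors into three subscales);
    by default each factor becomes its own subscale ``factor_1..factor_m``.
    ``overrides`` are ``(item_id, subscale_name, reason)`` triples applied
    last and recorded on the result.  An exact tie in absolute loading
    without an override raises :class:`LoadingTieError`.
    """
    L = solution.loadings
    m = solution.n_retained
    if m < 1:
        raise ValueError("solution has no retained factors")
    if factor_subscales is None:
        factor_subscales = {j: f"factor_{j + 1}" for j in range(m)}
    else:
        unknown = set(factor_subscales) - set(range(m))
        if unknown:
            raise ValueError(f"factor_subscales names unknown factor columns {sorted(unknown)}")
        if set(factor_subscales) != set(range(m)):
            raise ValueError("factor_subscales must cover every retained factor")
    override_by_item = {}
    for item_id, target, reason in overrides:
        if item_id not in solution.item_ids:
            raise ValueError(f"override names unknown item {item_id}")
        override_by_item[item_id] = (target, reason)

    assignments = []
    subscales: dict[str, set[int]] = {}
    for row, item_id in enumerate(solution.item_ids):
        absrow = np.abs(L[row])
        winner = int(np.argmax(absrow))
        ties = np.flatnonzero(absrow == absrow[winner])
        secondary = tuple(
            (int(j), float(L[row, j]))
            for j in np.argsort(-absrow)
            if j != winner and absrow[j] >= secondary_threshold
        )
        if item_id in override_by_item:
            target, reason = override_by_item[item_id]
            assignment = ItemAssignment(
                item_id, target, winner, float(L[row, winner]), secondary, True, reason
            )
        else:
            if ties.size > 1:
                raise LoadingTieError(
                    f"item {item_id}: factors {sorted(int(t) + 1 for t in ties)} tie at "
                    f"|loading| = {absrow[winner]:.6f}; supply an explicit override"
                )
            assignment = ItemAssignment(
                item_id, factor_subscales[winner], winner, float(L[row, winner]), secondary, False
            )
        assignments.append(assignment)
        subscales.setdefault(assignment.subscale, set()).add(item_id)
    return AssignmentResult(
        subscales={k: frozenset(v) for k, v in subscales.items()},
        items=tuple(assignments),
    )


def loading_table(solution: FactorSolution, threshold: float = 0.3) -> pd.DataFrame:
    """Display table of rotated loadings: |loading| < threshold blanked,
    per-item winning loading marked with ``*`` (the printed-table bold).
    """
    if not 0 <= threshold < 1:
        raise ValueError(f"threshold must be in [0, 1), got {threshold}")
    L = solution.loadings
    cols = [f"factor_{j + 1}" for j in range(solution.n_retained)]
    rows = []
    for row, item_id in enumerate(solution.item_ids):
        winner = int(np.argmax(np.abs(L[row])))
        cells = []
        for j in range(solution.n_retained):
            v = L[row, j]
            if abs(v) < threshold:
                cells.append("")
            else:
                mark = "*" if j == winner else ""
                cells.append(f"{v:.3f}{mark}")
        rows.append([item_id] + cells)
    return pd.DataFrame(rows, columns=["item_id"] + cols)


# ---------------------------------------------------------------------------
# Reliability


def cronbach_alpha(X, scale: str = "scale") -> ReliabilityResult:
    """Cronbach's alpha with listwise deletion and n-1 variances.

    alpha = k/(k-1) * (1 - sum(item variances) / variance(item sum)).
    Requires k >= 2 items and >= 3 listwise-complete rows; raises on zero
    total variance.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("alpha needs a 2-D matrix with k >= 2 items")
    complete = ~np.isnan(X).any(axis=1)
    Xc = X[complete]
    n, k = Xc.shape
    if n < 3:
        raise ValueError(f"only {n} listwise-complete rows; need >= 3")
    total = Xc.sum(axis=1)
    var_total = total.var(ddof=1)
    if var_total == 0:
        raise ValueError("zero variance of the item sum; alpha undefined")
    alpha = k / (k - 1) * (1.0 - Xc.var(axis=0, ddof=1).sum() / var_total)
    return ReliabilityResult(scale=scale, k=k, n_used=n, alpha=float(alpha))


def tucker_congruence(a: np.ndarray, b: np.ndarray) -> float:
    """Tucker congruence (cosine) between two loading columns, sign-free."""
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    denom = np.sqrt((a ** 2).sum() * (b ** 2).sum())
    if denom == 0:
        return float("nan")
    return float(abs((a * b).sum()) / denom)
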