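"""Principal components with oblique (direct oblimin) rotation, and
metric selection for the combined regression model.

To pick one metric per task for the combined model, the behavioral
measures are submitted to a principal component analysis of their
correlation matrix with three components, rotated obliquely (direct
oblimin, gamma = 0, i.e. quartimin) so that correlated components are
allowed — error measures from the same task are strongly related.  Each
rotated component is attributed to the task whose measures carry most
of its absolute pattern-loading mass, and the highest-loading measure
of each task on its component is selected.

The rotation is computed with the standard gradient-projection
algorithm for oblique rotation (Jennrich 2002; Bernaards & Jennrich
2005), with Kaiser normalization of the loading rows.  Oblique rotation
leaves communalities — hence uniquenesses — unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd


@dataclass
class PCAReport:
    """Rotated pattern loadings (measures x components), component
    correlation matrix, and per-measure uniqueness."""

    pattern: pd.DataFrame
    phi: np.ndarray
    uniqueness: pd.Series
    eigenvalues: np.ndarray


def _quartimin(L: np.ndarray) -> tuple[float, np.ndarray]:
    """Direct oblimin criterion at gamma = 0 and its gradient."""
    L2 = L**2
    k = L.shape[1]
    N = np.ones((k, k)) - np.eye(k)
    X = L2 @ N
    return float(np.sum(L2 * X) / 4.0), L * X


def _gpa_oblique(
    A: np.ndarray,
    T0: np.ndarray | None = None,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray]:
    """Gradient-projection minimization of the quartimin criterion over
    oblique rotations of ``A``, from the start ``T0`` (identity by
    default).  Returns (pattern, phi)."""
    k = A.shape[1]
    T = np.eye(k) if T0 is None else T0.copy()
    al = 1.0
    L = A @ np.linalg.inv(T).T
    f, Gq = _quartimin(L)
    G = -(L.T @ Gq @ np.linalg.inv(T)).T  # d f / d T for oblique rotation

    ft, Tt = f, T
    for _ in range(max_iter):
        Gp = G - T @ np.diag(np.sum(T * G, axis=0))
        s = np.sqrt(np.sum(Gp**2))
        if s < tol:
            break
        al *= 2.0
        for _ in range(20):
            X = T - al * Gp
            Tt = X @ np.diag(1.0 / np.sqrt(np.sum(X**2, axis=0)))
            L = A @ np.linalg.inv(Tt).T
            ft, Gq = _quartimin(L)
            if ft < f - 0.5 * s**2 * al:
                break
            al /= 2.0
        T = Tt
        f = ft
        G = -(L.T @ Gq @ np.linalg.inv(T)).T
    phi = T.T @ T
    pattern = A @ np.linalg.inv(T).T
    return pattern, phi


def _rotate_best(A: np.ndarray, n_starts: int = 5) -> tuple[np.ndarray, np.ndarray]:
    """Run the gradient projection from the identity plus ``n_starts``
    deterministic random oblique starts and keep the solution with the
    lowest quartimin criterion (the criterion is not convex and the
    identity start occasionally lands in a local minimum)."""
    k = A.shape[1]
    starts: list[np.ndarray | None] = [None]
    rng = np.random.default_rng(0)
    for _ in range(n_starts):
        X = rng.normal(size=(k, k))
        starts.append(X @ np.diag(1.0 / np.sqrt(np.sum(X**2, axis=0))))
    best = None
    for T0 in starts:
        pattern, phi = _gpa_oblique(A, T0=T0)
        f, _ = _quartimin(pattern)
        if best is None or f < best[0]:
            best = (f, pattern, phi)
    return best[1], best[2]


def pca_oblimin(measure_matrix: pd.DataFrame, n_components: int = 3) -> PCAReport:
    """Correlation-matrix PCA of the measures followed by direct
    oblimin rotation of the top ``n_components`` component loadings.

    ``measure_matrix`` holds one row per participant and one column per
    behavioral measure; rows with missing values are dropped listwise.
    Raises if there are fewer rows than measures or the correlation
    matrix is not positive definite.
    """
    X = measure_matrix.dropna()
    n, p = X.shape
    if p < n_components:
        raise ValueError(f"need at least {n_components} measures, got {p}")
    if n <= p:
        raise ValueError(f"need more rows ({n}) than measures ({p})")
    R = np.corrcoef(X.to_numpy(dtype=float), rowvar=False)
    evals, evecs = np.linalg.eigh(R)
    if evals.min() <= 1e-10:
        raise ValueError("correlation matrix is not positive definite")
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    A = evecs[:, :n_components] * np.sqrt(evals[:n_components])

    communality = np.sum(A**2, axis=1)
    # Kaiser normalization: rotate unit-communality rows, then restore
    h = np.sqrt(communality)
    pattern_n, phi = _rotate_best(A / h[:, None])
    pattern = pattern_n * h[:, None]

    # orient each component so its dominant loadings are positive
    signs = np.sign(np.sum(pattern**3, axis=0))
    signs[signs == 0] = 1.0
    pattern = pattern * signs
    phi = phi * np.outer(signs, signs)

    cols = [f"RC{i + 1}" for i in range(n_components)]
    return PCAReport(
        pattern=pd.DataFrame(pattern, index=X.columns, columns=cols),
        phi=phi,
        uniqueness=pd.Series(1.0 - communality, index=X.columns, name="uniqueness"),
        eigenvalues=evals,
    )


def attribute_components(
    report: PCAReport, task_of_measure: Mapping[str, str]
) -> dict[str, str]:
    """Map each rotated component to the task carrying the majority of
    its absolute pattern-loading mass.  Raises if the resulting map is
    not one component per task."""
    tasks = sorted(set(task_of_measure.values()))
    comp_task: dict[str, str] = {}
    for comp in report.pattern.columns:
        mass: dict[str, float] = {t: 0.0 for t in tasks}
        for measure, loading in report.pattern[comp].items():
            mass[task_of_measure[measure]] += abs(float(loading))
        comp_task[comp] = max(mass, key=mass.get)
    if sorted(comp_task.values()) != tasks:
        raise ValueError(
            f"components not attributable to unique tasks: {comp_task}"
        )
    return comp_task


def select_combined_metrics(
    report: PCAReport, task_of_measure: Mapping[str, str]
) -> dict[str, str]:
    """Pick, per task, the measure with the largest absolute pattern
    loading on the component attributed to that task."""
    comp_task = attribute_components(report, task_of_measure)
    selected: dict[str, str] = {}
    for comp, task in comp_task.items():
        measures = [m for m, t in task_of_measure.items() if t == task]
        loadings = report.pattern.loc[measures, comp].abs()
        selected[task] = str(loadings.idxmax())
    return selected
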