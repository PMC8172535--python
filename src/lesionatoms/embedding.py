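"""Low-dimensional lesion embedding: NMF into lesion atoms.

``log1p``-transformed lesion loads are factorized as ``X ~ H @ W`` with
``H >= 0`` (patients x atoms scores) and ``W >= 0`` (atoms x parcels
basis), minimizing squared Frobenius error with multiplicative updates
from a deterministic SVD-based non-negative (NNDSVD) initialization.
Basis rows are L2-normalized (the scale is moved into the scores) so that
downstream regression coefficients are comparable across runs; the
per-iteration reconstruction-error trace is recorded and is non-increasing
by construction of the updates.

Cross-cohort use: a basis fitted on one cohort is applied to another via
non-negative least squares (:func:`project_scores`), and two fitted bases
are aligned atom-by-atom with an assignment-problem matcher
(:func:`match_atoms`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment, nnls

from .parcellation import LesionLoadMatrix

__all__ = ["AtomDecomposition", "fit_nmf", "project_scores", "match_atoms"]

_EPS = 1e-12


@dataclass
class AtomDecomposition:
    """Fitted NMF: non-negative basis (atoms x parcels) and scores."""

    basis: np.ndarray = field(repr=False)
    scores: np.ndarray = field(repr=False)
    n_atoms: int = 0
    fit_metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(self.basis < 0) or np.any(self.scores < 0):
            raise ValueError("basis and scores must be non-negative")
        norms = np.linalg.norm(self.basis, axis=1)
        nonzero = norms > 0
        if not np.allclose(norms[nonzero], 1.0, atol=1e-8):
            raise ValueError("basis rows must be L2-normalized")


def _nndsvd(x: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic non-negative initialization from the truncated SVD."""
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    h = np.zeros((x.shape[0], k))
    w = np.zeros((k, x.shape[1]))
    h[:, 0] = np.sqrt(s[0]) * np.abs(u[:, 0])
    w[0] = np.sqrt(s[0]) * np.abs(vt[0])
    for j in range(1, k):
        uj, vj = u[:, j], vt[j]
        up, un = np.clip(uj, 0, None), np.clip(-uj, 0, None)
        vp, vn = np.clip(vj, 0, None), np.clip(-vj, 0, None)
        np_norm, nn_norm = np.linalg.norm(up) * np.linalg.norm(vp), \
            np.linalg.norm(un) * np.linalg.norm(vn)
        if np_norm >= nn_norm:
            sigma, uu, vv = np_norm, up, vp
        else:
            sigma, uu, vv = nn_norm, un, vn
        if sigma > 0:
            h[:, j] = np.sqrt(s[j] * sigma) * uu / np.linalg.norm(uu)
            w[j] = np.sqrt(s[j] * sigma) * vv / np.linalg.norm(vv)
    # fill structural zeros with the matrix mean so multiplicative updates
    # can move them (zeros are absorbing states of the updates)
    fill = x.mean()
    h[h <= 0] = fill
    w[w <= 0] = fill
    return h, w


def fit_nmf(loads: LesionLoadMatrix | np.ndarray, n_atoms: int = 10,
            seed: int = 0, max_iter: int = 500,
            tol: float = 1e-6) -> AtomDecomposition:
    """Factorize log1p lesion loads into non-negative lesion atoms.

    Parameters
    ----------
    loads : LesionLoadMatrix or array
        Non-negative patients x parcels matrix (raw voxel counts; the
        log1p transform is applied internally).
    n_atoms : int
        Number of atoms; must not exceed min(patients, parcels).
    seed : int
        Recorded in metadata; the fit itself is deterministic (SVD-based
        initialization, multiplicative updates).
    max_iter, tol : int, float
        Update iterations stop when the relative decrease of the
        Frobenius error falls below ``tol``.
    """
    values = loads.values if isinstance(loads, LesionLoadMatrix) else \
        np.asarray(loads, dtype=float)
    if np.any(values < 0):
        raise ValueError("lesion loads must be non-negative")
    n, p = values.shape
    if not 1 <= n_atoms <= min(n, p):
        raise ValueError(
            f"n_atoms={n_atoms} must lie in [1, min(patients, parcels)"
            f"={min(n, p)}]")

    x = np.log1p(values.astype(float))
    zero_cols = ~x.any(axis=0)
    h, w = _nndsvd(x, n_atoms)
    w[:, zero_cols] = 0.0  # absorbing: unobserved parcels stay out of atoms

    errors = [float(np.linalg.norm(x - h @ w))]
    for it in range(max_iter):
        # multiplicative Frobenius updates (monotone non-increasing error)
        h *= (x @ w.T) / (h @ (w @ w.T) + _EPS)
        w *= (h.T @ x) / ((h.T @ h) @ w + _EPS)
        err = float(np.linalg.norm(x - h @ w))
        errors.append(err)
        if errors[-2] - err < tol * errors[0]:
            break

    norms = np.linalg.norm(w, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    w = w / safe[:, None]
    h = h * safe[None, :]
    w[w < _EPS] = 0.0
    h[h < _EPS] = 0.0
    return AtomDecomposition(
        basis=w, scores=h, n_atoms=n_atoms,
        fit_metadata={
            "seed": seed,
            "n_iterations": len(errors) - 1,
            "final_reconstruction_error": errors[-1],
            "error_trace": errors,
            "relative_error": errors[-1] / (np.linalg.norm(x) + _EPS),
        })


def project_scores(loads: LesionLoadMatrix | np.ndarray,
                   basis: np.ndarray) -> np.ndarray:
    """Project a cohort onto a fitted basis via per-patient NNLS.

    Solves ``min_s || log1p(load_row) - s @ basis ||`` s.t. ``s >= 0`` for
    each patient, allowing a basis estimated on one cohort to embed
    another.
    """
    values = loads.values if isinstance(loads, LesionLoadMatrix) else \
        np.asarray(loads, dtype=float)
    basis = np.asarray(basis, dtype=float)
    if values.shape[1] != basis.shape[1]:
        raise ValueError(
            f"loads have {values.shape[1]} parcels but basis has "
            f"{basis.shape[1]}")
    x = np.log1p(values.astype(float))
    a = basis.T  # parcels x atoms
    scores = np.empty((values.shape[0], basis.shape[0]))
    for i in range(values.shape[0]):
        scores[i], _ = nnls(a, x[i])
    return scores


def match_atoms(basis_a: np.ndarray,
                basis_b: np.ndarray) -> dict[str, np.ndarray]:
    """Optimal one-to-one pairing of atoms across two bases.

    Maximizes the total Pearson correlation between paired basis rows
    (Hungarian assignment).  Returns ``pairing`` (atom ``i`` of A pairs
    with ``pairing[i]`` of B) and the per-pair correlations.
    """
    basis_a = np.asarray(basis_a, dtype=float)
    basis_b = np.asarray(basis_b, dtype=float)
    if basis_a.shape != basis_b.shape:
        raise ValueError("bases must have identical shape")
    k = basis_a.shape[0]
    corr = np.empty((k, k))
    for i in range(k):
        for j in range(k):
            ai = basis_a[i] - basis_a[i].mean()
            bj = basis_b[j] - basis_b[j].mean()
            denom = np.linalg.norm(ai) * np.linalg.norm(bj)
            corr[i, j] = (ai @ bj) / denom if denom > 0 else 0.0
    rows, cols = linear_sum_assignment(-corr)
    pairing = np.empty(k, dtype=int)
    pairing[rows] = cols
    return {"pairing": pairing, "matched_correlations": corr[rows, cols]}
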