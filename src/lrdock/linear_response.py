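"""Receptor flexibility by linear response.

Linear response approximates the mean deformation of a receptor under small
external forces from the equilibrium fluctuations of the *unperturbed*
receptor: with the 3N x 3N covariance of atomic fluctuations truncated to
its top-M eigenpairs (eigenvalues lambda in A^2, orthonormal eigenvectors V),
the displacement from the relaxed structure r_o at static equilibrium is

    dr = beta * V * diag(lambda) * V^T * f(r_o + dr),

where f are the per-atom external forces (kJ mol^-1 A^-1) on the deformed
structure and beta = 1/(k_b T) in mol/kJ. The product is evaluated as three
matrix-vector products; the 3N x 3N matrix is never materialized. A damped
fixed-point iteration moves smoothly toward the static-equilibrium
deformation.

The truncation exploits the "important subspace" of protein dynamics: most
positional fluctuation lives in a small number of collective modes, so small
M suffices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .chem_io import K_BOLTZMANN
from .errors import ShapeError, ValidationError


@dataclass
class ResponseModel:
    """Truncated covariance eigenmodel of a receptor.

    r_o : flat 3N relaxed coordinates (A); V : 3N x M orthonormal eigenvector
    matrix; lambdas : M eigenvalues (A^2), descending; beta : 1/(k_b T)
    (mol/kJ).
    """

    r_o: np.ndarray
    V: np.ndarray
    lambdas: np.ndarray
    beta: float
    captured_fraction: float | None = None

    def __post_init__(self):
        self.r_o = np.asarray(self.r_o, dtype=float).reshape(-1)
        self.V = np.asarray(self.V, dtype=float)
        self.lambdas = np.asarray(self.lambdas, dtype=float).reshape(-1)
        n3 = self.r_o.size
        if self.V.ndim != 2 or self.V.shape[0] != n3:
            raise ShapeError(f"eigenvector matrix must be {n3} x M")
        if self.V.shape[1] != self.lambdas.size:
            raise ShapeError("eigenvalue count does not match eigenvector columns")
        if self.V.shape[1] > n3:
            raise ShapeError("more modes than degrees of freedom")
        if np.any(self.lambdas < 0):
            raise ValidationError("eigenvalues must be non-negative")
        if np.any(np.diff(self.lambdas) > 1e-12):
            raise ValidationError("eigenvalues must be sorted descending")
        gram = self.V.T @ self.V
        if np.abs(gram - np.eye(self.M)).max() > 1e-8:
            raise ValidationError("eigenvector columns are not orthonormal")
        if self.beta <= 0:
            raise ValidationError("beta must be positive")

    @property
    def N(self) -> int:
        return self.r_o.size // 3

    @property
    def M(self) -> int:
        return self.V.shape[1]

    @staticmethod
    def beta_from_temperature(temperature: float) -> float:
        if temperature <= 0:
            raise ValidationError("temperature must be positive")
        return 1.0 / (K_BOLTZMANN * temperature)


@dataclass
class RelaxationSettings:
    """Damped fixed-point iteration parameters.

    mixing alpha in (0, 1] (1 = undamped); tolerance is the max-norm change
    (A) declaring convergence.
    """
    alpha: float = 0.2
    tolerance: float = 1e-4
    max_iterations: int = 500

    def __post_init__(self):
        if not (0.0 < self.alpha <= 1.0):
            raise ValidationError("mixing alpha must be in (0, 1]")
        if self.tolerance <= 0:
            raise ValidationError("tolerance must be positive")


@dataclass
class RelaxationResult:
    coordinates: np.ndarray        # 3N deformed coordinates
    deformation: np.ndarray        # 3N displacement from r_o
    trace: list = field(default_factory=list)  # per-iteration max change (A)
    converged: bool = True

    @property
    def iterations(self) -> int:
        return len(self.trace)


def displacement(model: ResponseModel, forces: np.ndarray) -> np.ndarray:
    """dr = beta V diag(lambda) V^T f, as three matrix-vector products."""
    f = np.asarray(forces, dtype=float).reshape(-1)
    if f.size != model.r_o.size:
        raise ShapeError(f"forces have length {f.size}, expected {model.r_o.size}")
    return model.beta * (model.V @ (model.lambdas * (model.V.T @ f)))


def relax_to_equilibrium(model: ResponseModel, force_function,
                         settings: RelaxationSettings | None = None) -> RelaxationResult:
    """Iterate dr <- (1-alpha) dr + alpha * displacement(model, f(r_o + dr)).

    Starts from dr = 0; stops when the max-norm change drops below the
    tolerance or after max_iterations (the result is then flagged, not
    raised). The per-iteration max-change trace is always returned.
    """
    settings = settings or RelaxationSettings()
    dr = np.zeros_like(model.r_o)
    trace: list[float] = []
    converged = False
    for _ in range(settings.max_iterations):
        f = np.asarray(force_function(model.r_o + dr), dtype=float).reshape(-1)
        if not np.all(np.isfinite(f)):
            raise ValidationError("non-finite force during relaxation")
        target = displacement(model, f)
        new_dr = (1.0 - settings.alpha) * dr + settings.alpha * target
        change = float(np.abs(new_dr - dr).max())
        trace.append(change)
        dr = new_dr
        if change < settings.tolerance:
            converged = True
            break
    if not converged:
        warnings.warn("relaxation did not converge within max_iterations",
                      RuntimeWarning, stacklevel=2)
    return RelaxationResult(coordinates=model.r_o + dr, deformation=dr,
                            trace=trace, converged=converged)


# ---------------------------------------------------------------------------
# model building from an ensemble

def _as_frames(ensemble: np.ndarray) -> np.ndarray:
    arr = np.asarray(ensemble, dtype=float)
    if arr.ndim == 3:
        arr = arr.reshape(arr.shape[0], -1)
    if arr.ndim != 2 or arr.shape[1] % 3 != 0:
        raise ShapeError("ensemble must be (F, 3N) or (F, N, 3)")
    return arr


def kabsch_rotation(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Optimal rotation aligning centered P onto centered Q (N x 3 each)."""
    H = P.T @ Q
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    return Vt.T @ D @ U.T


def superpose_frames(frames: np.ndarray) -> np.ndarray:
    """Kabsch-superpose every frame onto the first (removes rigid motion)."""
    frames = _as_frames(frames)
    F, n3 = frames.shape
    n = n3 // 3
    ref = frames[0].reshape(n, 3)
    ref_c = ref - ref.mean(axis=0)
    out = np.empty_like(frames)
    for k in range(F):
        X = frames[k].reshape(n, 3)
        Xc = X - X.mean(axis=0)
        R = kabsch_rotation(Xc, ref_c)
        out[k] = (Xc @ R.T + ref.mean(axis=0)).reshape(-1)
    return out


def closest_to_average(ensemble: np.ndarray, superpose: bool = False) -> int:
    """Index of the frame with minimal RMSD to the ensemble mean (ties ->
    lowest index)."""
    frames = _as_frames(ensemble)
    if superpose:
        frames = superpose_frames(frames)
    mean = frames.mean(axis=0)
    rmsd = np.sqrt(np.mean((frames - mean) ** 2, axis=1))
    return int(np.argmin(rmsd))


def build_response_model(ensemble: np.ndarray, M: int,
                         temperature: float = 300.0,
                         superpose: bool = True) -> ResponseModel:
    """Truncated eigenmodel of the atomic-fluctuation covariance.

    Frames are optionally Kabsch-superposed onto the first (default on, so
    rigid-body motion does not dominate the spectrum). The covariance uses
    plain Cartesian coordinates and 1/F normalization. For F - 1 < 3N the
    eigenpairs come from the F x F Gram matrix, avoiding the dense 3N x 3N
    problem. r_o is the closest-to-average frame; the captured-fluctuation
    fraction sum(lambda_1..M)/trace(C) is stored on the model.
    """
    frames = _as_frames(ensemble)
    F, n3 = frames.shape
    if F < 2:
        raise ValidationError("need at least two frames")
    if M < 1 or M > min(n3, F - 1):
        raise ShapeError(f"M must be in [1, min(3N, F-1)] = "
                         f"[1, {min(n3, F - 1)}]")
    if superpose:
        frames = superpose_frames(frames)
    mean = frames.mean(axis=0)
    X = frames - mean
    total_var = float(np.sum(X * X) / F)  # trace of the covariance
    if total_var == 0.0:
        warnings.warn("zero-variance ensemble; all eigenvalues are zero",
                      RuntimeWarning, stacklevel=2)
        V = np.eye(n3)[:, :M]
        lambdas = np.zeros(M)
        captured = 0.0
    elif F - 1 < n3:
        # Gram trick: XX^T/F shares nonzero eigenvalues with X^T X / F
        G = X @ X.T / F
        w, U = np.linalg.eigh(G)
        order = np.argsort(w)[::-1][:M]
        lambdas = np.maximum(w[order], 0.0)
        V = np.zeros((n3, M))
        for k, (lam, col) in enumerate(zip(lambdas, order)):
            if lam > 0:
                v = X.T @ U[:, col]
                V[:, k] = v / np.linalg.norm(v)
            else:
                # degenerate null direction: arbitrary unit vector orthogonal
                # to the previous columns
                v = np.zeros(n3)
                v[k] = 1.0
                v -= V[:, :k] @ (V[:, :k].T @ v)
                V[:, k] = v / np.linalg.norm(v)
        captured = float(lambdas.sum() / total_var)
    else:
        C = X.T @ X / F
        w, U = np.linalg.eigh(C)
        order = np.argsort(w)[::-1][:M]
        lambdas = np.maximum(w[order], 0.0)
        V = U[:, order]
        captured = float(lambdas.sum() / total_var)
    r_o = frames[closest_to_average(frames)]
    model = ResponseModel(r_o=r_o, V=V, lambdas=lambdas,
                          beta=ResponseModel.beta_from_temperature(temperature),
                          captured_fraction=captured)
    return model
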