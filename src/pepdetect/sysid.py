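"""Output-only (stochastic) subspace identification of innovation-form models.

The signal is modeled as the output of a linear innovation-form state space

    x_{T+1} = A x_T + K e_T
    y_T     = C x_T + e_T

with e_T zero-mean white noise and K the steady-state Kalman gain.  With no
measured input, identification is covariance-driven: sample output
covariances fill a block-Hankel matrix whose CVA-weighted SVD yields the
observability range; A follows from shift invariance, C from the first
block row, and K from the forward Riccati fixed point on the estimated
covariance sequence (with a one-step residual-regression fallback).

Raw (A, C, K) are only defined up to a similarity transform, so every
realization is canonicalized to a real modal (block-diagonal) form with a
fixed eigenvalue ordering and per-mode scaling before its entries are used
as features.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import linalg, signal

from .preprocess import DegenerateInputError

logger = logging.getLogger(__name__)

DEFAULT_HORIZON = 20


class ConditioningError(ValueError):
    """Eigen-structure too ill-conditioned to canonicalize."""


@dataclass
class StateSpaceRealization:
    """Innovation-form model (A, C, K) with innovation variance."""

    A: np.ndarray                 # (m, m)
    C: np.ndarray                 # (1, m)
    K: np.ndarray                 # (m, 1)
    innovation_variance: float = 1.0
    riccati_converged: bool = True
    stabilized: bool = False
    canonical: bool = False

    def __post_init__(self) -> None:
        self.A = np.atleast_2d(np.asarray(self.A, dtype=float))
        self.C = np.asarray(self.C, dtype=float).reshape(1, -1)
        self.K = np.asarray(self.K, dtype=float).reshape(-1, 1)
        m = self.A.shape[0]
        if self.A.shape != (m, m) or self.C.shape != (1, m) or self.K.shape != (m, 1):
            raise ValueError(
                f"inconsistent shapes: A {self.A.shape}, C {self.C.shape}, K {self.K.shape}"
            )
        if self.innovation_variance < 0:
            raise ValueError("innovation_variance must be >= 0")

    @property
    def order(self) -> int:
        return self.A.shape[0]

    def poles(self) -> np.ndarray:
        return np.linalg.eigvals(self.A)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "A": self.A.tolist(),
            "C": self.C.ravel().tolist(),
            "K": self.K.ravel().tolist(),
            "order": self.order,
            "innovation_variance": self.innovation_variance,
            "riccati_converged": self.riccati_converged,
            "stabilized": self.stabilized,
            "canonical": self.canonical,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "StateSpaceRealization":
        p = Path(text_or_path) if not str(text_or_path).lstrip().startswith("{") else None
        text = p.read_text() if p is not None and p.exists() else str(text_or_path)
        d = json.loads(text)
        return cls(
            A=np.array(d["A"]),
            C=np.array(d["C"]),
            K=np.array(d["K"]),
            innovation_variance=d["innovation_variance"],
            riccati_converged=d["riccati_converged"],
            stabilized=d["stabilized"],
            canonical=d["canonical"],
        )


# ---------------------------------------------------------------------------
# Identification
# ---------------------------------------------------------------------------

def _sample_covariances(y: np.ndarray, max_lag: int) -> np.ndarray:
    n = len(y)
    return np.array([y[l:] @ y[: n - l] / (n - l) for l in range(max_lag + 1)])


def identify(
    samples: np.ndarray,
    order: int,
    horizon: int = DEFAULT_HORIZON,
    weighting: str = "cva",
    canonical: bool = True,
) -> StateSpaceRealization:
    """Covariance-driven stochastic subspace identification.

    Parameters
    ----------
    samples : 1-D signal (mean is removed internally).
    order : model order m (5 offline, 3 in the streaming detector).
    horizon : number of block rows of the covariance Hankel matrix.
    weighting : "cva" (canonical variate weighting, default) or "none".
    canonical : return the modal canonical form (required for features).
    """
    y = np.asarray(samples, dtype=float).ravel()
    if not np.all(np.isfinite(y)):
        raise DegenerateInputError("samples contain non-finite values")
    if len(y) < 2 * horizon + 10 * order:
        raise DegenerateInputError(
            f"need at least {2 * horizon + 10 * order} samples for order {order}, "
            f"horizon {horizon}; got {len(y)}"
        )
    y = y - y.mean()
    if np.std(y) < 1e-12 * max(1.0, np.max(np.abs(y)) if len(y) else 1.0) or np.std(y) == 0:
        raise DegenerateInputError("constant signal carries no dynamics")

    h = horizon
    lam = _sample_covariances(y, 2 * h)
    H = linalg.hankel(lam[1 : h + 1], lam[h : 2 * h])

    if weighting == "cva":
        # whiten by the Toeplitz covariance of past/future stacks; a
        # symmetric inverse square root with an eigenvalue floor keeps the
        # weighting usable for heavily oversampled narrowband signals whose
        # Toeplitz matrix is numerically rank-deficient
        T = linalg.toeplitz(lam[:h])
        w, Q = linalg.eigh(T)
        floor = max(w.max(), abs(lam[0])) * 1e-10
        w = np.clip(w, floor, None)
        Tisq = (Q * w**-0.5) @ Q.T
        Tsq = (Q * w**0.5) @ Q.T
        Hw = Tisq @ H @ Tisq
        U, s, Vt = linalg.svd(Hw)
        U = Tsq @ U[:, :order]
        Vt = (Tsq @ Vt[:order].T).T
    else:
        U, s, Vt = linalg.svd(H)
        U, Vt = U[:, :order], Vt[:order]

    sq = np.sqrt(s[:order])
    Obs = U * sq                      # extended observability, h x m
    Ctr = sq[:, None] * Vt            # controllability-like factor, m x h
    C = Obs[0:1, :].copy()
    A = linalg.lstsq(Obs[:-1], Obs[1:])[0]
    G = Ctr[:, 0:1].copy()            # G = E[x_{t+1} y_t]
    K, sigma2, converged = _kalman_gain(A, C, G, lam[0])
    if not converged:
        K, sigma2 = _innovation_regression(y, A, C)
        logger.warning(
            "Riccati fixed point did not converge; Kalman gain from "
            "one-step residual regression"
        )
    real = StateSpaceRealization(
        A=A, C=C, K=K, innovation_variance=sigma2, riccati_converged=converged
    )
    return canonicalize(real) if canonical else real


def _kalman_gain(
    A: np.ndarray, C: np.ndarray, G: np.ndarray, lam0: float,
    max_iter: int = 20000, tol: float = 1e-12,
) -> tuple[np.ndarray, float, bool]:
    """Forward Riccati fixed point for the stochastic realization problem:
    P = A P A' + (G - A P C')(lam0 - C P C')^-1 (G - A P C')'."""
    m = A.shape[0]
    P = np.zeros((m, m))
    scale = max(1.0, abs(lam0))
    for _ in range(max_iter):
        denom = lam0 - (C @ P @ C.T).item()
        if denom <= 0:
            return np.zeros((m, 1)), lam0, False
        M = G - A @ P @ C.T
        Pn = A @ P @ A.T + (M @ M.T) / denom
        if np.max(np.abs(Pn - P)) < tol * scale:
            denom = lam0 - (C @ Pn @ C.T).item()
            if denom <= 0:
                return np.zeros((m, 1)), lam0, False
            K = (G - A @ Pn @ C.T) / denom
            return K, denom, True
        P = Pn
    return np.zeros((m, 1)), lam0, False


def _innovation_regression(
    y: np.ndarray, A: np.ndarray, C: np.ndarray
) -> tuple[np.ndarray, float]:
    """Fallback K: run a naive observer, regress state updates on residuals."""
    m = A.shape[0]
    # one-step Kalman filter with K as free parameter is nonlinear; instead use
    # the steady-state filter for K=0 residuals as innovations estimate
    n = len(y)
    x = np.zeros(m)
    X = np.zeros((n, m))
    E = np.zeros(n)
    K = np.zeros((m, 1))
    for _ in range(3):  # few fixed-point sweeps over the filter
        x = np.zeros(m)
        for t in range(n):
            X[t] = x
            E[t] = y[t] - (C @ x).item()
            x = A @ x + K.ravel() * E[t]
        denom = (E @ E).item()
        if denom == 0:
            break
        # X[t+1] = A X[t] + K e_t  =>  regress residual state on innovation
        R = X[1:] - X[:-1] @ A.T
        K_new = (R.T @ E[:-1] / (E[:-1] @ E[:-1]).item()).reshape(m, 1)
        if np.max(np.abs(K_new - K)) < 1e-10:
            K = K_new
            break
        K = K_new
    sigma2 = float(np.var(E)) if n else 0.0
    return K, sigma2


# ---------------------------------------------------------------------------
# Simulation and spectra
# ---------------------------------------------------------------------------

def simulate(
    realization: StateSpaceRealization,
    n_samples: int,
    innovation_series: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    x0: np.ndarray | None = None,
) -> np.ndarray:
    """Forward recursion y_T = C x_T + e_T, x_{T+1} = A x_T + K e_T, x_0 = 0."""
    m = realization.order
    if innovation_series is None:
        rng = rng or np.random.default_rng()
        innovation_series = rng.standard_normal(n_samples) * np.sqrt(
            realization.innovation_variance
        )
    e = np.asarray(innovation_series, dtype=float).ravel()[:n_samples]
    if len(e) < n_samples:
        raise ValueError("innovation series shorter than n_samples")
    rho = np.max(np.abs(realization.poles()))
    if rho >= 1.0 and n_samples > 10000:
        raise OverflowError(
            f"spectral radius {rho:.3f} >= 1: long simulation would overflow"
        )
    sys = signal.dlti(
        realization.A, realization.K, realization.C, np.ones((1, 1)), dt=1.0
    )
    x0 = np.zeros(m) if x0 is None else np.asarray(x0, dtype=float)
    _, y, _ = signal.dlsim(sys, e[:, None], x0=x0)
    return y.ravel()


def analytic_spectrum(
    realization: StateSpaceRealization, freqs: np.ndarray, fs: float
) -> np.ndarray:
    """Output power spectral density of the innovation form:
    S(f) = sigma^2 |C (zI - A)^-1 K + 1|^2, z = exp(2 pi i f / fs)."""
    m = realization.order
    z = np.exp(2j * np.pi * np.asarray(freqs, dtype=float) / fs)
    S = np.empty(len(z))
    I = np.eye(m)
    for i, zz in enumerate(z):
        H = (realization.C @ np.linalg.solve(zz * I - realization.A, realization.K))[0, 0]
        S[i] = realization.innovation_variance * abs(H + 1.0) ** 2
    return S


# ---------------------------------------------------------------------------
# Canonicalization
# ---------------------------------------------------------------------------

def _pair_eigenvalues(ev: np.ndarray, V: np.ndarray, tol: float):
    """Group eigenvalues into real values and complex-conjugate pairs."""
    used = np.zeros(len(ev), dtype=bool)
    groups = []
    for i, lam in enumerate(ev):
        if used[i]:
            continue
        if abs(lam.imag) <= tol * max(1.0, abs(lam)):
            groups.append(("real", i, None))
            used[i] = True
        else:
            # find the conjugate partner
            cand = [
                j for j in range(len(ev))
                if not used[j] and j != i
                and abs(ev[j] - np.conj(lam)) <= 100 * tol * max(1.0, abs(lam))
            ]
            if not cand:
                raise ConditioningError(
                    "complex eigenvalue without conjugate partner; "
                    "matrix too ill-conditioned to canonicalize"
                )
            j = min(cand, key=lambda j: abs(ev[j] - np.conj(lam)))
            used[i] = used[j] = True
            # keep the positive-imaginary member
            k = i if ev[i].imag > 0 else j
            groups.append(("pair", k, j if k == i else i))
    return groups


def canonicalize(
    realization: StateSpaceRealization, ordering: str = "frequency"
) -> StateSpaceRealization:
    """Map a realization to its real modal canonical form.

    Modes are sorted by |angle| ascending then modulus descending
    (ordering="frequency", the default — mode frequencies are the most
    stable ordering statistic across noisy re-estimates) or by modulus
    descending then |angle| ascending (ordering="modulus");
    each real eigenvalue contributes a 1x1 block, each complex pair a 2x2
    rotation-scaled block [[a, b], [-b, a]] (b > 0).  Within each mode the
    remaining similarity freedom (scale, and rotation for pairs) is pinned
    by rotating C's block to (|c|, 0) and balancing |C| against |K|, with
    C's leading entry made positive.  Any pole with modulus >= 1 is
    reflected to 1/|modulus| (flagged on the result).

    Two realizations related by an invertible state transform therefore map
    to the same canonical matrices, which makes concatenated (A, C, K)
    entries usable as features.
    """
    A, C, K = realization.A, realization.C, realization.K
    m = realization.order
    ev, V = np.linalg.eig(A)
    if np.linalg.cond(V) > 1e10:
        raise ConditioningError(
            f"eigenvector matrix condition {np.linalg.cond(V):.2e} too high "
            "(defective or near-defective A)"
        )
    tol = 1e-9
    groups = _pair_eigenvalues(ev, V, tol)

    def sort_key(g):
        lam = ev[g[1]]
        if ordering == "frequency":
            return (round(abs(np.angle(lam)), 9), -round(abs(lam), 9))
        return (-round(abs(lam), 9), round(abs(np.angle(lam)), 9))

    groups = sorted(groups, key=sort_key)

    stabilized = False
    blocks: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    for kind, i, j in groups:
        lam = ev[i]
        r = abs(lam)
        if r >= 1.0:
            lam = lam / (r * r)  # reflect to 1/|lam|, same angle
            stabilized = True
        if kind == "real":
            v = V[:, i]
            # rotate the (possibly complex-phase) eigenvector to be real
            p = np.argmax(np.abs(v))
            v = np.real(v * np.exp(-1j * np.angle(v[p])))
            nv = np.linalg.norm(v)
            if nv == 0:
                raise ConditioningError("zero eigenvector")
            cols.append((v / nv)[:, None])
            blocks.append(np.array([[lam.real]]))
        else:
            v = V[:, i]  # positive-imag eigenvalue's eigenvector
            P, Q = np.real(v), np.imag(v)
            B = np.column_stack([P, Q])
            # normalize the 2-column block to unit Frobenius scale
            B = B / np.linalg.norm(B)
            cols.append(B)
            a, b = lam.real, abs(lam.imag)
            blocks.append(np.array([[a, b], [-b, a]]))
    T = np.hstack(cols)
    if np.linalg.cond(T) > 1e10:
        raise ConditioningError("modal transform ill-conditioned")
    Ti = np.linalg.inv(T)
    Cm = (C @ T).ravel()
    Km = (Ti @ K).ravel()

    # per-block scale/rotation pinning
    Ac = np.zeros((m, m))
    Cc = np.zeros(m)
    Kc = np.zeros(m)
    idx = 0
    ztol = 1e-9 * max(1.0, np.max(np.abs(Cm)), np.max(np.abs(Km)))
    for blk in blocks:
        w = blk.shape[0]
        Ac[idx : idx + w, idx : idx + w] = blk
        if w == 1:
            c, k = Cm[idx], Km[idx]
            if abs(c) > ztol and abs(k) > ztol:
                s = np.sign(c) * np.sqrt(abs(k) / abs(c))
            elif abs(c) > ztol:
                s = 1.0 / c
            elif abs(k) > ztol:
                s = np.sign(k) * abs(k)
            else:
                s = 1.0
            Cc[idx] = c * s
            Kc[idx] = k / s
        else:
            cb = Cm[idx : idx + 2]
            kb = Km[idx : idx + 2]
            nc, nk = np.linalg.norm(cb), np.linalg.norm(kb)
            if nc > ztol:
                # rotation sending cb to (|cb|, 0); R commutes with the block
                ct, st = cb[0] / nc, -cb[1] / nc
            elif nk > ztol:
                # pin by K instead: send R^T kb to (|kb|, 0)
                ct, st = kb[0] / nk, -kb[1] / nk
            else:
                ct, st = 1.0, 0.0
            R = np.array([[ct, st], [-st, ct]])
            cb = cb @ R
            kb = R.T @ kb
            nc, nk = np.linalg.norm(cb), np.linalg.norm(kb)
            if nc > ztol and nk > ztol:
                rho = np.sqrt(nk / nc)
            elif nc > ztol:
                rho = 1.0 / nc
            elif nk > ztol:
                rho = nk
            else:
                rho = 1.0
            Cc[idx : idx + 2] = cb * rho
            Kc[idx : idx + 2] = kb / rho
        idx += w

    out = replace(
        realization,
        A=Ac,
        C=Cc.reshape(1, -1),
        K=Kc.reshape(-1, 1),
        stabilized=realization.stabilized or stabilized,
        canonical=True,
    )
    if stabilized:
        logger.warning("unstable pole(s) reflected inside the unit circle")
    return out
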