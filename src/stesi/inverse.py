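"""Linear distributed inverse solvers: minimum-norm (MNE) and sLORETA.

Both minimize ||Y - L X||_F^2 + lambda ||X||_F^2; sLORETA additionally
standardizes each source row by the square root of the corresponding
diagonal entry of the resolution operator, which restores exact
localization of single dipoles in the noiseless case.

The regularization weight is made unitless by scaling it with the mean
sensor-space eigenvalue trace(L L^T)/Ne, so a given lambda transfers
across head models; the "auto" rule sets lambda = 1/SNR_linear from an
assumed sensor SNR in dB, the common minimum-norm heuristic.  Noise is
assumed white (sigma^2 I); a whitener hook accepts a measured covariance.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

__all__ = ["InverseConfig", "InverseSolution", "mne_solve", "sloreta_solve"]


@dataclass
class InverseConfig:
    method: str = "mne"                  # "mne" | "sloreta"
    lambda_: float | str = "auto"        # unitless weight or "auto"
    snr_assumed_db: float = 5.0          # used by the auto rule
    noise_cov: np.ndarray | None = None  # optional whitening covariance

    def resolve_lambda(self) -> float:
        if self.lambda_ == "auto":
            return 1.0 / 10 ** (self.snr_assumed_db / 10.0)
        lam = float(self.lambda_)
        if lam < 0:
            raise ValueError("lambda_ must be non-negative")
        return lam


@dataclass
class InverseSolution:
    X_hat: np.ndarray
    method: str
    config: dict
    t_solve: float = 0.0
    flagged_sources: list = field(default_factory=list)


def _whiten(L, Y, cfg):
    if cfg.noise_cov is None:
        return L, Y
    W = np.linalg.cholesky(np.linalg.inv(cfg.noise_cov))
    return W.T @ L, W.T @ Y


def _mne_kernel(L: np.ndarray, lam: float) -> np.ndarray:
    """K = L^T (L L^T + lam * (tr(L L^T)/Ne) I)^-1."""
    ne = L.shape[0]
    gram = L @ L.T
    lam_tilde = lam * np.trace(gram) / ne
    try:
        return L.T @ scipy.linalg.solve(gram + lam_tilde * np.eye(ne), np.eye(ne),
                                        assume_a="pos")
    except scipy.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular sensor covariance; use lambda_ > 0") from exc


def mne_solve(L: np.ndarray, Y: np.ndarray, cfg: InverseConfig | None = None
              ) -> InverseSolution:
    """Regularized minimum-norm estimate X = K Y."""
    cfg = cfg or InverseConfig(method="mne")
    if L.shape[0] != Y.shape[0]:
        raise ValueError("leadfield and EEG row counts differ")
    lam = cfg.resolve_lambda()
    t0 = time.perf_counter()
    Lw, Yw = _whiten(L, Y, cfg)
    K = _mne_kernel(Lw, lam)
    X = K @ Yw
    return InverseSolution(X_hat=X, method="mne",
                           config={"lambda": lam, "snr_assumed_db": cfg.snr_assumed_db},
                           t_solve=time.perf_counter() - t0)


def sloreta_solve(L: np.ndarray, Y: np.ndarray, cfg: InverseConfig | None = None
                  ) -> InverseSolution:
    """Standardized minimum-norm estimate.

    With K the minimum-norm kernel and S = diag(K L) the resolution
    diagonal, each row of the MNE solution is divided by sqrt(S_j).
    S_j > 0 holds for lambda > 0 and any non-null leadfield column; a null
    column is excluded (row zeroed) and reported in ``flagged_sources``.
    """
    cfg = cfg or InverseConfig(method="sloreta")
    if L.shape[0] != Y.shape[0]:
        raise ValueError("leadfield and EEG row counts differ")
    lam = cfg.resolve_lambda()
    if lam <= 0:
        raise ValueError("sLORETA requires lambda > 0")
    t0 = time.perf_counter()
    Lw, Yw = _whiten(L, Y, cfg)
    K = _mne_kernel(Lw, lam)
    S = np.einsum("je,ej->j", K, Lw)
    flagged = np.flatnonzero(S <= 0).tolist()
    scale = np.zeros_like(S)
    ok = S > 0
    scale[ok] = 1.0 / np.sqrt(S[ok])
    X = (K @ Yw) * scale[:, None]
    return InverseSolution(X_hat=X, method="sloreta",
                           config={"lambda": lam, "snr_assumed_db": cfg.snr_assumed_db},
                           t_solve=time.perf_counter() - t0,
                           flagged_sources=flagged)
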