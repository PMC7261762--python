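"""Single-tensor diffusion tensor imaging fit and its four scalar metrics.

The tensor is estimated by weighted log-linear least squares: an ordinary
LLS pass on log-signals, then one reweighted pass with weights equal to the
squared predicted signals (adequate at the SNR of this package's phantoms).
ADC/FA/AD/RD follow from the eigen-decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .acquisition import B_D_SCALE, AcquisitionScheme, VoxelSignal
from .errors import ValidationError

_COND_LIMIT = 1.0e8
_LOG_FLOOR = 1.0e-12


@dataclass
class DtiFit:
    """Eigenvalues (descending, um^2/ms) and derived scalars of one voxel."""

    eigenvalues: np.ndarray   # (3,) lambda1 >= lambda2 >= lambda3
    eigenvectors: np.ndarray  # (3, 3), columns match eigenvalues
    s0: float
    quality: str = "ok"

    @property
    def adc(self) -> float:
        return float(np.mean(self.eigenvalues))

    @property
    def ad(self) -> float:
        return float(self.eigenvalues[0])

    @property
    def rd(self) -> float:
        return float(np.mean(self.eigenvalues[1:]))

    @property
    def fa(self) -> float:
        ev = self.eigenvalues
        md = ev.mean()
        denom = np.sqrt(np.sum(ev**2))
        if denom == 0:
            return 0.0
        return float(np.sqrt(1.5 * np.sum((ev - md) ** 2)) / denom)

    @property
    def principal_direction(self) -> np.ndarray:
        return self.eigenvectors[:, 0]


def _design_matrix(scheme: AcquisitionScheme) -> np.ndarray:
    """Rows [1, -b(gx^2, gy^2, gz^2, 2 gx gy, 2 gx gz, 2 gy gz)] for
    ln S = ln S0 - b g' D g (b scaled so D is in um^2/ms)."""
    g = scheme.directions
    b = scheme.bvalues * B_D_SCALE
    cols = np.column_stack([
        g[:, 0] ** 2, g[:, 1] ** 2, g[:, 2] ** 2,
        2 * g[:, 0] * g[:, 1], 2 * g[:, 0] * g[:, 2], 2 * g[:, 1] * g[:, 2],
    ])
    return np.column_stack([np.ones(scheme.K), -b[:, None] * cols])


def _check_design(X: np.ndarray):
    cond = np.linalg.cond(X)
    if not np.isfinite(cond) or cond > _COND_LIMIT:
        raise ValidationError(
            f"rank-deficient DTI design (condition number {cond:.3g}); "
            "need >= 6 non-collinear weighted directions plus a b = 0 entry"
        )


def _tensor_from_coefs(coefs: np.ndarray):
    d = coefs[1:]
    D = np.array([
        [d[0], d[3], d[4]],
        [d[3], d[1], d[5]],
        [d[4], d[5], d[2]],
    ])
    evals, evecs = np.linalg.eigh(D)
    order = np.argsort(evals)[::-1]
    return evals[order], evecs[:, order], float(np.exp(coefs[0]))


def fit_dti_coefficients(signals: np.ndarray, scheme: AcquisitionScheme) -> np.ndarray:
    """Vectorized WLLS solve. ``signals`` is (n, K); returns (n, 7) coefficient
    rows [ln S0, Dxx, Dyy, Dzz, Dxy, Dxz, Dyz]."""
    X = _design_matrix(scheme)
    _check_design(X)
    logs = np.log(np.clip(signals, _LOG_FLOOR, None))
    beta = np.linalg.lstsq(X, logs.T, rcond=None)[0].T  # OLS pass
    pred = beta @ X.T
    w = np.exp(2 * np.clip(pred, np.log(_LOG_FLOOR), 50))  # squared predicted signal
    out = np.empty_like(beta)
    for i in range(signals.shape[0]):
        Xw = X * w[i, :, None]
        out[i] = np.linalg.solve(X.T @ Xw, Xw.T @ logs[i])
    return out


def fit_dti(signal: VoxelSignal, scheme: AcquisitionScheme) -> DtiFit:
    """Fit one voxel; negative eigenvalues are clamped to zero with a
    ``"clamped"`` quality flag."""
    coefs = fit_dti_coefficients(signal.values[None, :], scheme)[0]
    evals, evecs, s0 = _tensor_from_coefs(coefs)
    quality = "ok"
    if np.any(evals < 0):
        evals = np.clip(evals, 0, None)
        quality = "clamped"
    return DtiFit(eigenvalues=evals, eigenvectors=evecs, s0=s0, quality=quality)


def fit_dti_table(signals: np.ndarray, scheme: AcquisitionScheme) -> np.ndarray:
    """Fit many voxels at once; returns (n, 4) columns [adc, fa, ad, rd]."""
    coefs = fit_dti_coefficients(np.asarray(signals, dtype=float), scheme)
    d = coefs[:, 1:]
    D = np.empty((len(d), 3, 3))
    D[:, 0, 0], D[:, 1, 1], D[:, 2, 2] = d[:, 0], d[:, 1], d[:, 2]
    D[:, 0, 1] = D[:, 1, 0] = d[:, 3]
    D[:, 0, 2] = D[:, 2, 0] = d[:, 4]
    D[:, 1, 2] = D[:, 2, 1] = d[:, 5]
    evals = np.linalg.eigvalsh(D)[:, ::-1]
    evals = np.clip(evals, 0, None)
    adc = evals.mean(axis=1)
    ad = evals[:, 0]
    rd = evals[:, 1:].mean(axis=1)
    denom = np.sqrt(np.sum(evals**2, axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5 * np.sum((evals - adc[:, None]) ** 2, axis=1)) / denom
    fa = np.where(denom > 0, fa, 0.0)
    return np.column_stack([adc, fa, ad, rd])
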