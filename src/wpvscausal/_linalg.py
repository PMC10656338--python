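"""Symmetric-matrix helpers used by the score predictor.

All fractional matrix powers are taken through the symmetric
eigendecomposition; eigenvalues below ``EIG_FLOOR`` are clipped up to the
floor so that near-singular within-covariance estimates remain usable.
"""

from __future__ import annotations

import numpy as np

EIG_FLOOR = 1e-8


def sym_power(mat: np.ndarray, power: float, floor: float = EIG_FLOOR) -> np.ndarray:
    """Real power of a symmetric PSD matrix via eigendecomposition.

    Eigenvalues in (-floor, floor) are clipped to ``floor`` before the power
    is applied, which keeps negative powers finite for PSD-up-to-rounding
    inputs.  Raises if an eigenvalue is materially negative (< -1e-6 times
    the largest eigenvalue scale).
    """
    mat = np.asarray(mat, dtype=float)
    vals, vecs = np.linalg.eigh((mat + mat.T) / 2.0)
    scale = max(abs(vals[-1]), 1.0)
    if vals[0] < -1e-6 * scale:
        raise np.linalg.LinAlgError(
            f"matrix is not PSD (min eigenvalue {vals[0]:.3g})"
        )
    vals = np.clip(vals, floor, None)
    return (vecs * vals**power) @ vecs.T


def nearest_psd(mat: np.ndarray, floor: float = 0.0) -> tuple[np.ndarray, bool]:
    """Eigenvalue-clip a symmetric matrix to PSD.

    Returns the repaired matrix and a flag telling whether any eigenvalue
    actually had to be raised.
    """
    mat = np.asarray(mat, dtype=float)
    sym = (mat + mat.T) / 2.0
    vals, vecs = np.linalg.eigh(sym)
    if vals[0] >= floor:
        return sym, False
    vals = np.clip(vals, floor, None)
    return (vecs * vals) @ vecs.T, True
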