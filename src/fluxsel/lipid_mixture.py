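"""Palmitate/LPC synthesis mixture model.

Newly synthesized palmitate (16 carbons) is the eight-fold convolution of
the two-carbon acetyl MID; pre-existing palmitate carries the natural
isotope distribution.  The LPC MID is the convolution of the palmitate
mixture with the measured glycerophosphocholine backbone MID, and the
fraction alpha of newly synthesized palmitate is linear in the model, so
it is estimated by closed-form least squares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import binom

from .emu_engine import convolve, validate_mid

__all__ = [
    "NATURAL_13C_ABUNDANCE",
    "natural_mid",
    "palmitate_new",
    "convolution_matrix",
    "mixture_mid",
    "fit_alpha",
    "MixtureFit",
]

NATURAL_13C_ABUNDANCE = 0.0107


def natural_mid(n_carbons: int, p13: float = NATURAL_13C_ABUNDANCE) -> np.ndarray:
    """Binomial natural-abundance MID of an n-carbon fragment."""
    if n_carbons < 0:
        raise ValueError("carbon count must be non-negative")
    if not 0.0 <= p13 <= 1.0:
        raise ValueError("isotope fraction must lie in [0, 1]")
    return binom.pmf(np.arange(n_carbons + 1), n_carbons, p13)


def palmitate_new(x_ac: np.ndarray) -> np.ndarray:
    """MID of palmitate built from eight acetyl units: 8-fold convolution."""
    x_ac = np.asarray(x_ac, float)
    if x_ac.shape != (3,):
        raise ValueError("acetyl MID must have 3 entries (2 carbons)")
    out = x_ac
    for _ in range(7):
        out = convolve(out, x_ac)
    return out


def convolution_matrix(x_g3pc: np.ndarray, n_pmt: int) -> np.ndarray:
    """Matrix C with C @ x_pmt = convolve(x_g3pc, x_pmt)."""
    x_g3pc = np.asarray(x_g3pc, float)
    C = np.zeros((len(x_g3pc) + n_pmt - 1, n_pmt))
    for j in range(n_pmt):
        C[j: j + len(x_g3pc), j] = x_g3pc
    return C


def mixture_mid(alpha: float, x_ac: np.ndarray, x_g3pc: np.ndarray,
                p13: float = NATURAL_13C_ABUNDANCE) -> np.ndarray:
    """Modeled LPC MID at mixture coefficient alpha."""
    x_new = palmitate_new(x_ac)
    x_old = natural_mid(16, p13)
    x_pmt = alpha * x_new + (1.0 - alpha) * x_old
    return convolve(np.asarray(x_g3pc, float), x_pmt)


@dataclass
class MixtureFit:
    alpha: float
    alpha_unconstrained: float
    clipped: bool
    fitted_lpc: np.ndarray
    residual: float  # sum of squared residuals

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "alpha_unconstrained": self.alpha_unconstrained,
            "clipped": self.clipped,
            "fitted_lpc": self.fitted_lpc.tolist(),
            "residual": self.residual,
        }


def fit_alpha(
    x_lpc_obs: np.ndarray,
    x_ac: np.ndarray,
    x_g3pc: np.ndarray,
    p13: float = NATURAL_13C_ABUNDANCE,
) -> MixtureFit:
    """Closed-form least-squares estimate of the new-palmitate fraction.

    The model is linear in alpha:
        x_lpc(alpha) = C(x_g3pc) (alpha x_new + (1 - alpha) x_old)
    The unconstrained solution is clipped to [0, 1] with a flag.
    """
    x_lpc_obs = np.asarray(x_lpc_obs, float)
    x_g3pc = np.asarray(x_g3pc, float)
    x_new = palmitate_new(x_ac)
    x_old = natural_mid(16, p13)
    C = convolution_matrix(x_g3pc, 17)
    if x_lpc_obs.shape != (C.shape[0],):
        raise ValueError(
            f"observed LPC MID must have {C.shape[0]} entries "
            f"(len(g3pc) + 16), got {len(x_lpc_obs)}")
    base = C @ x_old
    direction = C @ (x_new - x_old)
    denom = float(direction @ direction)
    if denom < 1e-24:
        raise ValueError("alpha not identifiable: new and pre-existing "
                         "palmitate MIDs coincide")
    alpha_u = float(direction @ (x_lpc_obs - base)) / denom
    alpha = min(1.0, max(0.0, alpha_u))
    fitted = base + alpha * direction
    resid = float(np.sum((x_lpc_obs - fitted) ** 2))
    return MixtureFit(
        alpha=alpha, alpha_unconstrained=alpha_u,
        clipped=not (0.0 <= alpha_u <= 1.0),
        fitted_lpc=fitted, residual=resid,
    )
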