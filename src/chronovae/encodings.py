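"""Covariate encodings: sinusoidal time embedding and one-hot categories.

Time is embedded with transformer-style sinusoids so that the decoder can
interpolate cellular profiles at arbitrary real-valued days, not only the
days that were sequenced. The embedding dimension d yields d/2
(sin, cos) pairs with geometrically spaced frequencies; the fastest
component has period exactly ``min_wavelength`` days.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["TimeEncodingConfig", "sinusoidal_encode", "encode_categories"]


@dataclass(frozen=True)
class TimeEncodingConfig:
    """Configuration of the sinusoidal time embedding.

    Parameters
    ----------
    d : even embedding dimension (default 50, i.e. 25 frequency pairs).
    min_wavelength : period in days of the fastest sinusoid. The default
        grid explores {1, 2*pi}.
    """

    d: int = 50
    min_wavelength: float = 1.0

    def __post_init__(self):
        if self.d < 2 or self.d % 2 != 0:
            raise ValueError(f"embedding dimension must be even and >= 2, got {self.d}")
        if not self.min_wavelength > 0:
            raise ValueError("min_wavelength must be positive")

    def frequencies(self) -> np.ndarray:
        """Angular frequencies w_j = (2*pi/min_wavelength) / 10000^(2(j-1)/d)."""
        j = np.arange(self.d // 2)
        return (2.0 * np.pi / self.min_wavelength) / np.power(10000.0, 2.0 * j / self.d)


def sinusoidal_encode(t, cfg: TimeEncodingConfig = TimeEncodingConfig()) -> np.ndarray:
    """Embed time(s) ``t`` (days) as interleaved (sin, cos) pairs.

    Accepts a scalar (returns shape ``(d,)``) or a 1-D array of times
    (returns shape ``(n, d)``). The squared norm of every encoding is d/2.
    """
    t = np.asarray(t, dtype=np.float64)
    if not np.all(np.isfinite(t)):
        raise ValueError("time values must be finite")
    scalar = t.ndim == 0
    t2 = np.atleast_1d(t)[:, None]
    w = cfg.frequencies()[None, :]
    out = np.empty((t2.shape[0], cfg.d))
    out[:, 0::2] = np.sin(w * t2)
    out[:, 1::2] = np.cos(w * t2)
    return out[0] if scalar else out


def encode_categories(labels, levels) -> np.ndarray:
    """One-hot encode ``labels`` against an ordered list of ``levels``.

    Raises if any label is not a known level (listing the known levels),
    so unseen conditions fail loudly rather than silently zeroing out.
    """
    levels = list(levels)
    index = {lv: i for i, lv in enumerate(levels)}
    labels = np.asarray(labels, dtype=object).ravel()
    unknown = sorted({str(l) for l in labels if l not in index})
    if unknown:
        raise ValueError(f"unknown label(s) {unknown}; known levels: {levels}")
    out = np.zeros((labels.shape[0], len(levels)))
    for i, lab in enumerate(labels):
        out[i, index[lab]] = 1.0
    return out
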