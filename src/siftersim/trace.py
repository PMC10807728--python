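"""Shared time-trace container for dipolar signals."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["DipolarTrace"]


@dataclass
class DipolarTrace:
    """A dipolar signal sampled on the SIFTER time axis t = tau1 - tau2.

    ``t_us`` must be strictly increasing.  For fixed-total-time experiments
    (SIFTER/SIDRE) the metadata carries ``tau0`` and |t| <= tau0 holds; Hahn
    decays use the same container with ``t_us`` meaning the inter-pulse delay.
    """

    t_us: np.ndarray
    amplitude: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.t_us, dtype=float)
        a = np.asarray(self.amplitude, dtype=float)
        if t.ndim != 1 or t.shape != a.shape:
            raise ValueError("t grid and amplitude must be matching 1-D arrays")
        if t.size >= 2 and np.any(np.diff(t) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if not np.all(np.isfinite(a)):
            raise ValueError("amplitude must be finite")
        tau0 = self.metadata.get("tau0")
        if tau0 is not None and t.size and np.max(np.abs(t)) > float(tau0) + 1e-9:
            raise ValueError("|t| exceeds tau0 recorded in metadata")
        self.t_us = t
        self.amplitude = a

    @property
    def tau0(self) -> float | None:
        v = self.metadata.get("tau0")
        return None if v is None else float(v)

    def copy_with(self, amplitude: np.ndarray, **meta) -> "DipolarTrace":
        md = dict(self.metadata)
        md.update(meta)
        return DipolarTrace(self.t_us.copy(), np.asarray(amplitude, dtype=float), md)
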