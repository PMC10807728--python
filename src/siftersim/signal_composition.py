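"""Assembly of full SIFTER / SIDRE signals from their building blocks.

A SIFTER trace at fixed total evolution time 2*tau0 is sampled on the time
axis t = tau1 - tau2 with tau1 = (tau0+t)/2, tau2 = (tau0-t)/2.  The
composed signals combine

* the intramolecular form factor F(t) and the fixed-sum constant
  K = <cos(w_dd (tau1+tau2))> = F(tau0) (dipolar_model);
* the relaxation surfaces Bt(tau1)Bt(tau2) and BS(tau1,tau2)
  (relaxation_models);
* the coherence-transfer factor D*tau1*tau2 with D the summed second moment
  of the intermolecular dipolar frequencies (ensemble_mc or explicit).

Monoradical:   V = BS + D tau1 tau2 * Bt Bt.

Biradical, modulation depth lambda in [0, 1):
    V = (1-lambda) * V_nm + lambda * V_mod
    V_mod = F(t) * (BS + Bt Bt)/2 + F(tau1) F(tau2) D tau1 tau2 * Bt Bt
    V_nm  = BS + D tau1 tau2 * Bt Bt
            + lambda/(2(1-lambda)) * K * (BS - Bt Bt)

The K bookkeeping follows from the pathway split of the intramolecular
modulation: the no-transfer (cos.cos) pathway relaxes with BS and the
transfer (sin.sin) pathway with Bt.Bt, so the constant part enters as
+K (BS - Bt Bt)/2.  The composed form is verified (numerically, in tests)
to be identical to the direct sum
    F(t) BS + Fs(tau1,tau2) [Bt Bt - BS] + F(tau1)F(tau2) D tau1 tau2 Bt Bt
with Fs = (F(t) - K)/2 the sine-product kernel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dipolar_model import (DipolarParameters, DistanceDistribution,
                            fixed_sum_cosine, powder_form_factor)
from .relaxation_models import SidreSurfaceParams, evaluate_bs, evaluate_bt
from .trace import DipolarTrace

__all__ = [
    "CompositionParams",
    "DipolarTrace",
    "transfer_factor",
    "compose_monoradical",
    "artefact_term",
    "compose_biradical",
    "divide_by_sidre",
    "main_term_background",
]

BS_FLOOR = 1e-6


@dataclass(frozen=True)
class CompositionParams:
    """Scalars entering the composed biradical signal."""

    lam: float       # modulation depth, in [0, 1)
    D: float         # summed second moment, rad^2/us^2
    tau0: float      # us
    K: float = 0.0   # fixed-sum cosine <cos(w_dd tau0)>

    def __post_init__(self) -> None:
        if not (0.0 <= self.lam < 1.0):
            raise ValueError("modulation depth must satisfy 0 <= lambda < 1")
        if self.D < 0:
            raise ValueError("second moment D must be non-negative")
        if self.tau0 <= 0:
            raise ValueError("tau0 must be positive")


def _tau_split(tau0: float, t_grid) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    t = np.asarray(t_grid, dtype=float)
    if np.any(np.abs(t) > tau0 + 1e-12):
        raise ValueError("|t| must not exceed tau0")
    return t, np.clip((tau0 + t) / 2, 0, None), np.clip((tau0 - t) / 2, 0, None)


def transfer_factor(D: float, tau1_us, tau2_us):
    """Coherence-transfer factor D tau1 tau2 = D/4 (tau0^2 - t^2)."""
    t1 = np.asarray(tau1_us, dtype=float)
    t2 = np.asarray(tau2_us, dtype=float)
    if np.any(t1 < 0) or np.any(t2 < 0):
        raise ValueError("delays must be non-negative")
    out = D * t1 * t2
    return out if out.ndim else float(out)


def _relaxation_surfaces(bt, bs, tau1, tau2):
    if bt is None and bs is None:
        one = np.ones_like(tau1)
        return one, one
    btbt = evaluate_bt(bt, tau1) * evaluate_bt(bt, tau2)
    bs_v = evaluate_bs(bs, tau1, tau2)
    return btbt, bs_v


def compose_monoradical(bt, bs: SidreSurfaceParams | None, D: float,
                        tau0: float, t_grid) -> DipolarTrace:
    """Monoradical SIFTER V = BS + D tau1 tau2 * Bt Bt along the t grid."""
    t, tau1, tau2 = _tau_split(tau0, t_grid)
    btbt, bs_v = _relaxation_surfaces(bt, bs, tau1, tau2)
    amp = bs_v + transfer_factor(D, tau1, tau2) * btbt
    return DipolarTrace(t, amp, {"sequence": "sifter", "kind": "mono",
                                 "tau0": float(tau0), "D": float(D)})


def artefact_term(f_tau1, f_tau2, D: float, tau1_us, tau2_us):
    """Intermolecular coherence-transfer artefact A = F(tau1) F(tau2) D tau1 tau2."""
    return np.asarray(f_tau1, float) * np.asarray(f_tau2, float) \
        * transfer_factor(D, tau1_us, tau2_us)


def compose_biradical(dist: DistanceDistribution,
                      bt, bs: SidreSurfaceParams | None,
                      params: CompositionParams,
                      t_grid,
                      dipolar: DipolarParameters | None = None,
                      n_theta: int = 401,
                      return_breakdown: bool = False):
    """Full biradical SIFTER trace; optionally with the per-term breakdown.

    The form factor, artefact factors and the fixed-sum constant K are
    computed from ``dist`` (K passed in ``params`` is ignored in favour of
    the consistent quadrature value).  Breakdown keys:
    ``v_nm`` (unmodulated part incl. K term, unscaled), ``v_mod``
    (modulated part, unscaled), ``main`` (F(t)(BS+BtBt)/2), ``artefact``,
    ``k_term`` (lambda K (BS-BtBt)/2, as it appears in (1-lambda) V_nm),
    ``btbt``, ``bs``, ``f``, ``K``, ``eq_direct`` (direct pathway sum used
    by the internal consistency check).
    """
    lam, D, tau0 = params.lam, params.D, params.tau0
    t, tau1, tau2 = _tau_split(tau0, t_grid)
    btbt, bs_v = _relaxation_surfaces(bt, bs, tau1, tau2)
    f_t = powder_form_factor(dist, t, dipolar, n_theta)
    f_t1 = powder_form_factor(dist, tau1, dipolar, n_theta)
    f_t2 = powder_form_factor(dist, tau2, dipolar, n_theta)
    K = fixed_sum_cosine(dist, tau0, dipolar, n_theta)

    dtt = transfer_factor(D, tau1, tau2)
    art = f_t1 * f_t2 * dtt * btbt
    main = f_t * 0.5 * (bs_v + btbt)
    v_mod = main + art
    k_term = 0.5 * lam * K * (bs_v - btbt)          # = (1-lam) * [lam/(2(1-lam)) K (BS-BtBt)]
    v_nm_scaled = (1.0 - lam) * (bs_v + dtt * btbt) + k_term
    amp = v_nm_scaled + lam * v_mod

    trace = DipolarTrace(t, amp, {"sequence": "sifter", "kind": "bi",
                                  "tau0": float(tau0), "lambda": lam,
                                  "D": float(D), "K": float(K)})
    if not return_breakdown:
        return trace
    fs = 0.5 * (f_t - K)
    eq_direct = (1.0 - lam) * (bs_v + dtt * btbt) \
        + lam * (f_t * bs_v + fs * (btbt - bs_v) + f_t1 * f_t2 * dtt * btbt)
    breakdown = {
        "v_nm": np.where(lam < 1.0, v_nm_scaled / (1.0 - lam), np.nan),
        "v_nm_scaled": v_nm_scaled,
        "v_mod": v_mod,
        "main": main,
        "artefact": art,
        "k_term": k_term,
        "btbt": btbt,
        "bs": bs_v,
        "f": f_t,
        "f_tau1": f_t1,
        "f_tau2": f_t2,
        "K": K,
        "eq_direct": eq_direct,
    }
    return trace, breakdown


def divide_by_sidre(trace: DipolarTrace, bs: SidreSurfaceParams,
                    floor: float = BS_FLOOR) -> DipolarTrace:
    """Pointwise quotient trace / BS(tau1, tau2); sub-floor points are masked.

    Masked points are set to NaN and counted in metadata (``n_masked``);
    they are never interpolated.
    """
    tau0 = trace.tau0
    if tau0 is None:
        raise ValueError("trace needs tau0 metadata for the BS surface")
    _, tau1, tau2 = _tau_split(tau0, trace.t_us)
    bs_v = evaluate_bs(bs, tau1, tau2)
    bad = bs_v < floor
    amp = np.where(bad, np.nan, trace.amplitude / np.where(bad, 1.0, bs_v))
    out = trace.copy_with(np.zeros_like(amp), divided_by="sidre",
                          n_masked=int(bad.sum()))
    out.amplitude = amp  # bypass finite check for deliberately masked points
    return out


def main_term_background(bt, bs: SidreSurfaceParams, tau0: float, t_grid) -> np.ndarray:
    """Background of the main dipolar term: (BS + Bt Bt)/2 along the trace."""
    _, tau1, tau2 = _tau_split(tau0, t_grid)
    btbt, bs_v = _relaxation_surfaces(bt, bs, tau1, tau2)
    return 0.5 * (bs_v + btbt)
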