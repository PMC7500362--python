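"""Carbonic anhydrase activity from ¹⁸O unlabeling of ¹³CO₂.

CA catalyzes CO₂ hydration, and each hydration/dehydration cycle can swap
one CO₂ oxygen with water oxygen.  After a spike of doubly-labeled ¹³C¹⁸O₂
(injected as H¹³C¹⁸O₃⁻), the ¹⁸O content of the ¹³CO₂ pool

    α(t) = (2·C₄₉ + C₄₇) / (C₄₉ + C₄₇ + C₄₅)      ∈ [0, 2]

(the mean number of ¹⁸O atoms per ¹³CO₂ molecule, from the m/z 45/47/49
channels) decays exponentially, α = a₁·e^(−θt), with θ the ¹⁸O–water
exchange rate constant — the activity readout.  Working on the ¹³C mass
channels sidesteps the m/z 44 background from ambient ¹²CO₂.

α is invariant to isotope-blind consumption of the CO₂ pool (all three
isotopologues scaled equally), so CO₂ fixation does not bias θ; the
``total_13C`` series (Σ) is reported to audit that consumption.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .calibrate import CalibrationModel, signal_to_concentration
from .errors import AnalysisError
from .registry import GasRegistry
from .trace import TraceSet

__all__ = ["CAResult", "isotopic_enrichment", "fit_unlabeling", "ca_assay"]

ISOTOPOLOGUES = ("13C18O2", "13C18O16O", "13CO2")  # m/z 49, 47, 45


@dataclass
class CAResult:
    """α(t), the fitted exponential, and the total-¹³C audit series."""

    time: np.ndarray
    alpha: np.ndarray
    mask: np.ndarray
    a1: float
    theta: float  # s⁻¹
    fit_window: tuple[float, float]
    residual_rms: float
    total_13C: np.ndarray


def isotopic_enrichment(
    C49: np.ndarray, C47: np.ndarray, C45: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Mean ¹⁸O atoms per ¹³CO₂ molecule: α = (2·C₄₉ + C₄₇)/(C₄₉+C₄₇+C₄₅).

    Returns ``(alpha, mask)``; all-zero points are masked (undefined).
    Under binomial scrambling at atom enrichment p, α = 2p exactly.
    """
    C49 = np.asarray(C49, float)
    C47 = np.asarray(C47, float)
    C45 = np.asarray(C45, float)
    total = C49 + C47 + C45
    mask = total > 0
    alpha = np.full(total.shape, np.nan)
    np.divide(2.0 * C49 + C47, total, out=alpha, where=mask)
    return alpha, mask


def fit_unlabeling(
    time: np.ndarray,
    alpha: np.ndarray,
    window: tuple[float, float],
) -> tuple[float, float, dict]:
    """Nonlinear least-squares fit of α = a₁·e^(−θt) on a time window.

    A log-linear regression initializes (a₁, θ); θ is constrained ≥ 0.
    Non-positive α inside the window are trimmed with a warning entry in
    the diagnostics; fewer than 5 usable points is an error.  θ is
    invariant to time-origin shifts (a₁ absorbs them); the reported a₁ is
    referenced to the first fitted point (``t_ref`` in the diagnostics).

    Returns ``(a1, theta, diagnostics)`` with diagnostics carrying the
    residual RMS, point count and any trimming note.
    """
    time = np.asarray(time, float)
    alpha = np.asarray(alpha, float)
    sel = (time >= window[0]) & (time <= window[1]) & np.isfinite(alpha)
    trimmed = int((sel & ~(alpha > 0)).sum())
    sel &= alpha > 0
    n = int(sel.sum())
    if n < 5:
        raise AnalysisError(
            f"fit window {window}: need >= 5 positive points, got {n}"
        )
    t, a = time[sel], alpha[sel]
    # log-linear initializer; shift the origin for conditioning
    t0 = t[0]
    slope, intercept = np.polyfit(t - t0, np.log(a), 1)
    theta0 = max(-slope, 0.0)
    a10 = float(np.exp(intercept))

    def model(tt, a1, theta):
        return a1 * np.exp(-theta * (tt - t0))

    popt, _ = curve_fit(
        model, t, a, p0=[a10, max(theta0, 1e-12)],
        bounds=([0.0, 0.0], [np.inf, np.inf]), maxfev=10000,
    )
    a1, theta = float(popt[0]), float(popt[1])  # a1 referenced to window start
    resid = a - model(t, *popt)
    diagnostics = {
        "t_ref": float(t0),
        "residual_rms": float(np.sqrt(np.mean(resid**2))),
        "n": n,
        "trimmed_nonpositive": trimmed,
    }
    return a1, theta, diagnostics


def ca_assay(
    trace: TraceSet,
    cal: CalibrationModel,
    registry: GasRegistry,
    *,
    injection_label: str = "injection",
    mixing_lag: float = 10.0,
    fit_end: float | None = None,
    recombination_gamma: float = 0.0,
) -> CAResult:
    """Full CA assay: channels 45/47/49 → α(t) → exponential unlabeling fit.

    The fit window defaults to ``[injection + mixing_lag, end of trace]``
    (or ``fit_end``, e.g. the end of the dark period).  When ¹⁸O₂ labeling
    runs concurrently the ion source can recombine ¹⁸O with C¹⁶O₂ into
    spurious m/z 47 signal; ``recombination_gamma`` > 0 subtracts the
    linear cross-term ``γ·S(mz36)·S(mz45)`` from the m/z 47 channel before
    the analysis (γ estimated from a biology-free control; off by default).
    """
    for mz in (45, 47, 49):
        if mz not in trace.channels:
            raise AnalysisError(f"CA assay requires channel mz{mz}")
    try:
        t_inj = trace.event_time(injection_label)
    except KeyError as exc:
        raise AnalysisError(str(exc)) from exc

    work = trace
    if recombination_gamma > 0:
        if 36 not in trace.channels:
            raise AnalysisError("recombination correction needs channel mz36")
        channels = dict(trace.channels)
        channels[47] = channels[47] - recombination_gamma * trace.channel(36) * trace.channel(45)
        work = trace.with_channels(channels)

    conc = signal_to_concentration(work, cal, registry, list(ISOTOPOLOGUES))
    C49, C47, C45 = conc["13C18O2"], conc["13C18O16O"], conc["13CO2"]
    alpha, mask = isotopic_enrichment(C49, C47, C45)
    window = (t_inj + mixing_lag, fit_end if fit_end is not None else float(trace.time[-1]))
    a1, theta, diag = fit_unlabeling(trace.time, alpha, window)
    a1 = a1 * np.exp(theta * (diag["t_ref"] - t_inj))  # amplitude at injection
    return CAResult(
        time=trace.time,
        alpha=alpha,
        mask=mask,
        a1=a1,
        theta=theta,
        fit_window=window,
        residual_rms=diag["residual_rms"],
        total_13C=C49 + C47 + C45,
    )
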