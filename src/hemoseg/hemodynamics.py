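"""Perfusion quantification: concentration conversion, AIF, rCBV/rCBF/MTT/TTP.

The T2* signal drop during bolus passage relates to contrast concentration by
``S(t) = S0 exp(-k TE C(t))``, so ``C(t) = -(k/TE) ln(S(t)/S0)``.  With an
arterial input function C_a(t) taken from the artery cluster, indicator
dilution theory gives

    rCBV = integral of C over the first pass / integral of C_a,
    C(t) = rCBF * dt * (C_a (*) R)(t)  with residue function R,
    rCBF = max_t of the deconvolved rCBF*R(t) curve,
    MTT  = rCBV / rCBF (central volume theorem),
    TTP  = argmax_t C(t).

Deconvolution inverts the lower-triangular Toeplitz convolution matrix of the
AIF by truncated SVD.  All quantities are relative (k = 1); configurable
multipliers map them to conventional units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

DEFAULT_SVD_TRUNCATION = 0.20


@dataclass
class ConcentrationCurve:
    """Contrast-agent concentration samples on a uniform time grid."""

    values: np.ndarray
    times: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.values.shape != self.times.shape or self.values.ndim != 1:
            raise ValueError("values and times must be matching 1D arrays")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])


@dataclass
class AIF:
    """Arterial input function with its first-pass integration window."""

    curve: ConcentrationCurve
    first_pass_window: tuple[float, float]   # (t_start, t_end) seconds
    fitted: bool = True                      # False -> raw-average fallback
    gamma_params: tuple | None = None        # (A, t0, r, beta) when fitted


def detect_baseline_window(signal: np.ndarray, threshold: float = 0.05) -> int:
    """Number of leading pre-bolus frames.

    The bolus arrival is taken as the first frame where the signal drop from
    the running baseline exceeds ``threshold`` of the maximal drop; frames
    before it form the baseline window.
    """
    signal = np.asarray(signal, dtype=float)
    s0_guess = signal[: max(3, len(signal) // 10)].mean()
    drop = s0_guess - signal
    max_drop = drop.max()
    if max_drop <= 0:
        return len(signal)
    above = np.nonzero(drop > threshold * max_drop)[0]
    return int(above[0]) if above.size else len(signal)


def signal_to_concentration(signal: np.ndarray, te: float,
                            baseline_frames: int | None = None,
                            times: np.ndarray | None = None,
                            k: float = 1.0,
                            floor_fraction: float = 1e-3) -> ConcentrationCurve:
    """C(t) = -(k/TE) ln(S(t)/S0) with S0 the mean over the baseline window."""
    signal = np.asarray(signal, dtype=float)
    if times is None:
        times = np.arange(len(signal), dtype=float)
    if baseline_frames is None:
        baseline_frames = detect_baseline_window(signal)
    baseline_frames = max(1, min(baseline_frames, len(signal)))
    s0 = signal[:baseline_frames].mean()
    if s0 <= 0:
        raise ValueError("nonpositive baseline signal")
    floor = floor_fraction * s0
    if np.any(signal <= 0):
        warnings.warn("nonpositive signal values clamped before log conversion")
    safe = np.clip(signal, floor, None)
    values = -(k / te) * np.log(safe / s0)
    return ConcentrationCurve(values=values, times=np.asarray(times, float))


def concentration_to_signal(concentration: np.ndarray, s0: float, te: float,
                            k: float = 1.0) -> np.ndarray:
    """Inverse conversion S(t) = S0 exp(-k TE C(t))."""
    if s0 <= 0:
        raise ValueError("baseline signal must be positive")
    return s0 * np.exp(-k * te * np.asarray(concentration, dtype=float))


def gamma_variate(t, amplitude, t0, r, beta):
    """First-pass bolus shape A (t - t0)^r exp(-(t - t0)/beta) for t > t0."""
    t = np.asarray(t, dtype=float)
    shifted = np.clip(t - t0, 0.0, None)
    with np.errstate(invalid="ignore"):
        out = amplitude * shifted ** r * np.exp(-shifted / beta)
    return np.where(t > t0, out, 0.0)


def estimate_aif(concentrations: np.ndarray, times: np.ndarray) -> AIF:
    """Average artery-voxel curves and fit a gamma variate over the first pass.

    ``concentrations`` is (n_voxels, M) or (M,).  The fit suppresses
    recirculation; the first-pass window runs from bolus arrival to the
    post-peak return below 10% of the fitted peak.  On fit failure the raw
    averaged curve with the full acquisition window is returned, flagged.
    """
    concentrations = np.atleast_2d(np.asarray(concentrations, dtype=float))
    times = np.asarray(times, dtype=float)
    mean_curve = concentrations.mean(axis=0)
    peak_idx = int(np.argmax(mean_curve))
    peak = mean_curve[peak_idx]
    try:
        if peak <= 0:
            raise RuntimeError("no positive peak")
        t_peak = times[peak_idx]
        onset_guess = times[detect_baseline_window(
            -mean_curve + mean_curve.max())] if peak_idx > 0 else times[0]
        p0 = (peak / max((t_peak - onset_guess), 1e-3) ** 3 * np.exp(3),
              max(onset_guess - 1.0, 0.0), 3.0, max((t_peak - onset_guess) / 3, 0.5))
        popt, _ = curve_fit(gamma_variate, times, mean_curve, p0=p0,
                            bounds=([0, 0, 0.5, 0.05],
                                    [np.inf, times[-1], 20, times[-1]]),
                            maxfev=20000)
        fitted_vals = gamma_variate(times, *popt)
        fpeak_idx = int(np.argmax(fitted_vals))
        fpeak = fitted_vals[fpeak_idx]
        after = np.nonzero(fitted_vals[fpeak_idx:] < 0.1 * fpeak)[0]
        t_end = times[fpeak_idx + after[0]] if after.size else times[-1]
        window = (float(popt[1]), float(t_end))
        return AIF(curve=ConcentrationCurve(fitted_vals, times),
                   first_pass_window=window, fitted=True,
                   gamma_params=tuple(popt))
    except (RuntimeError, ValueError):
        warnings.warn("gamma-variate AIF fit failed; using the raw averaged curve")
        return AIF(curve=ConcentrationCurve(mean_curve, times),
                   first_pass_window=(float(times[0]), float(times[-1])),
                   fitted=False)


def first_pass_window(curve: ConcentrationCurve,
                      return_fraction: float = 0.1) -> tuple[float, float]:
    """Window from bolus arrival to the post-peak drop below a peak fraction."""
    vals = curve.values
    peak_idx = int(np.argmax(vals))
    peak = vals[peak_idx]
    if peak <= 0:
        return float(curve.times[0]), float(curve.times[-1])
    before = np.nonzero(vals[:peak_idx + 1] < return_fraction * peak)[0]
    t_start = curve.times[before[-1]] if before.size else curve.times[0]
    after = np.nonzero(vals[peak_idx:] < return_fraction * peak)[0]
    t_end = curve.times[peak_idx + after[0]] if after.size else curve.times[-1]
    return float(t_start), float(t_end)


def _window_area(curve: ConcentrationCurve, window: tuple[float, float]) -> float:
    t0, t1 = window
    sel = (curve.times >= t0) & (curve.times <= t1)
    if sel.sum() < 2:
        sel = np.ones_like(sel, dtype=bool)
    return float(np.trapezoid(curve.values[sel], curve.times[sel]))


def compute_rcbv(curve: ConcentrationCurve, aif: AIF,
                 return_fraction: float = 0.02) -> float:
    """First-pass area of the tissue curve over the first-pass area of the AIF.

    Both curves are integrated over a common bolus window derived from the
    AIF (arrival to the post-peak return below ``return_fraction`` of its
    peak); a shared window keeps the area ratio unbiased for tissue curves
    smeared by their transit time.
    """
    window = first_pass_window(aif.curve, return_fraction)
    aif_area = _window_area(aif.curve, window)
    if aif_area == 0:
        raise ValueError("zero AIF first-pass area")
    return _window_area(curve, window) / aif_area


def svd_deconvolve(curve: ConcentrationCurve, aif: AIF,
                   truncation_fraction: float = DEFAULT_SVD_TRUNCATION
                   ) -> np.ndarray:
    """Recover the flow-scaled residue series rCBF*R(t) by truncated SVD.

    Solves C = A x where A is the lower-triangular Toeplitz matrix of the
    AIF scaled by dt; singular values below ``truncation_fraction * sigma_max``
    are zeroed before inversion.
    """
    a = aif.curve.values
    dt = curve.dt
    m = len(curve.values)
    A = np.zeros((m, m))
    for i in range(m):
        A[i, : i + 1] = a[i::-1][: i + 1] * dt
    U, s, Vt = np.linalg.svd(A)
    keep = s >= truncation_fraction * s[0]
    if not keep.any():
        raise ValueError("all singular values truncated")
    s_inv = np.where(keep, 1.0 / np.where(keep, s, 1.0), 0.0)
    return Vt.T @ (s_inv * (U.T @ curve.values))


def compute_rcbf(residue_series: np.ndarray) -> float:
    """Flow = maximum of the deconvolved rCBF*R(t) series."""
    return float(np.max(residue_series))


def compute_mtt(rcbv: float, rcbf: float, scale: float = 1.0) -> float:
    """Central volume theorem MTT = scale * rCBV / rCBF (scale=60 for per-minute flow)."""
    if rcbf <= 0:
        raise ValueError("rcbf must be positive")
    return scale * rcbv / rcbf


def compute_ttp(curve: ConcentrationCurve) -> float:
    """Time of the concentration maximum (earliest frame on ties)."""
    return float(curve.times[int(np.argmax(curve.values))])


@dataclass
class HemodynamicMaps:
    """Per-voxel (per-column) hemodynamic parameters."""

    rcbv: np.ndarray
    rcbf: np.ndarray
    mtt: np.ndarray
    ttp: np.ndarray


def compute_hemodynamic_maps(values: np.ndarray, times: np.ndarray, te: float,
                             labels: np.ndarray, artery_class: int,
                             aif_mode: str = "global",
                             artery_classes: "list[int] | None" = None,
                             truncation_fraction: float = DEFAULT_SVD_TRUNCATION,
                             baseline_frames: int | None = None,
                             flow_scale: float = 60.0) -> tuple[HemodynamicMaps, AIF]:
    """Voxelwise rCBV/rCBF/MTT/TTP for a signal matrix with tissue labels.

    ``aif_mode``:

    * ``"global"`` — one AIF from the artery class is used for every voxel.
    * ``"local"`` — ``artery_classes`` lists every arterial cluster (the
      normal artery plus any delayed/dispersed artery); each tissue class is
      deconvolved against the arterial input whose time-to-peak is closest
      to its own.  Impaired tissue thereby uses the delayed artery's input,
      which removes most of the delay/dispersion bias of the global AIF.

    ``flow_scale`` converts MTT to seconds when flow is per-minute.
    """
    values = np.asarray(values, dtype=float)
    m, n = values.shape
    labels = np.asarray(labels, dtype=int)
    concentrations = np.stack([
        signal_to_concentration(values[:, j], te, baseline_frames, times).values
        for j in range(n)], axis=0)                      # (N, M)
    artery_sel = labels == artery_class
    if not artery_sel.any():
        raise ValueError("no artery-labeled voxels")
    global_aif = estimate_aif(concentrations[artery_sel], times)
    class_aifs = {}
    if aif_mode == "local":
        if not artery_classes:
            artery_classes = [artery_class]
        arterial_aifs = {}
        for c in artery_classes:
            if not (labels == c).any():
                raise ValueError(f"arterial class {c} has no voxels")
            arterial_aifs[c] = estimate_aif(concentrations[labels == c], times)
        aif_ttps = {c: compute_ttp(a.curve) for c, a in arterial_aifs.items()}
        for c in np.unique(labels):
            class_ttp = compute_ttp(ConcentrationCurve(
                concentrations[labels == c].mean(axis=0), times))
            nearest = min(aif_ttps, key=lambda a: abs(aif_ttps[a] - class_ttp))
            class_aifs[c] = arterial_aifs[nearest]
    elif aif_mode != "global":
        raise ValueError(f"unknown aif_mode {aif_mode!r}")
    rcbv = np.empty(n)
    rcbf = np.empty(n)
    mtt = np.full(n, np.nan)
    ttp = np.empty(n)
    for j in range(n):
        curve = ConcentrationCurve(concentrations[j], times)
        aif = class_aifs.get(labels[j], global_aif)
        rcbv[j] = compute_rcbv(curve, aif)
        residue = svd_deconvolve(curve, aif, truncation_fraction)
        rcbf[j] = compute_rcbf(residue)
        if rcbf[j] > 0:
            mtt[j] = compute_mtt(rcbv[j], rcbf[j], scale=flow_scale)
        ttp[j] = compute_ttp(curve)
    return HemodynamicMaps(rcbv=rcbv, rcbf=rcbf, mtt=mtt, ttp=ttp), global_aif


def tissue_statistics(maps: HemodynamicMaps, labels: np.ndarray,
                      class_names: dict[int, str] | None = None) -> pd.DataFrame:
    """Per-class mean and SD of TTP, rCBV, rCBF, MTT (one row per class)."""
    labels = np.asarray(labels, dtype=int)
    rows = []
    for c in np.unique(labels):
        sel = labels == c
        if not sel.any():
            warnings.warn(f"class {c} empty; omitted")
            continue
        row = {"class": class_names.get(c, str(c)) if class_names else str(c),
               "n_voxels": int(sel.sum())}
        for name, arr in (("ttp", maps.ttp), ("rcbv", maps.rcbv),
                          ("rcbf", maps.rcbf), ("mtt", maps.mtt)):
            vals = arr[sel]
            vals = vals[np.isfinite(vals)]
            row[f"{name}_mean"] = float(vals.mean()) if vals.size else np.nan
            row[f"{name}_sd"] = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows)
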