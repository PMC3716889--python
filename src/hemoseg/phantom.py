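"""Monte Carlo phantom simulator for hypothetical tissue compartments.

Each tissue class is a multivariate Gaussian over the M time points: a mean
signal-time curve built from the bolus forward model

    C(t) = rCBF * dt * (AIF (*) R_eff)(t),
    R_eff(t) = exp(-(t - t_delay)/MTT) for t >= t_delay (0 before),
               convolved with the exponential transport kernel
               (1/b) exp(-t/b) dt when the dispersion b > 0,
    S(t) = S0 exp(-TE * C(t)),

plus a temporal covariance describing intra-class variability.  The
covariance combines low-rank physiological terms — baseline-level jitter
along the flat direction, bolus-depth jitter along the class's own
signal-drop direction, and arrival-time jitter along the temporal
derivative — with an AR(1) noise floor sigma^2 rho^|i-j|.  Delayed/
dispersed variants of artery, GM and WM (dArtery, dGM, dWM) reuse the normal
kinetic parameters with an added (t_delay, b) impairment.

Phantom pixel counts follow the seven-compartment reference design
(artery 551, GM 1741, WM 1636, vein+sinus 610, sinus 80, CSF+cp 412,
artifact 175); benchmarks may scale all counts down by a common factor to
trade Monte Carlo size for runtime.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .hemodynamics import concentration_to_signal, gamma_variate
from .segment import segment_matrix

# --- canonical acquisition/design defaults -------------------------------
DEFAULT_M = 65            # analysis frames
DEFAULT_TR = 1.0          # s
DEFAULT_TE = 0.06         # s (60 ms echo time)
DEFAULT_S0 = 1000.0       # baseline signal, arbitrary units
AIF_ONSET = 10.0          # s, bolus arrival in the artery
AIF_SHAPE_R = 3.0         # gamma-variate shape
AIF_SCALE_BETA = 1.5      # s, gamma-variate scale
ARTERY_PEAK_CONC = 10.0   # concentration units at the artery peak
                          # (45% signal drop at TE = 60 ms)

# intra-class variability; the AR(1) floor is in signal units.  Classes with
# heterogeneous composition (venous sinuses, CSF spaces with choroid plexus)
# carry a per-class ``jitter`` multiplier on these three terms.
BASELINE_JITTER = 0.05    # relative SD of the voxel-wise baseline level (coil
                          # sensitivity / proton density / T2*)
AMPLITUDE_JITTER = 0.08   # relative SD of the bolus depth across a class
ARRIVAL_JITTER = 0.3      # s, SD of per-voxel bolus arrival within a class
NOISE_FLOOR_SD = 25.0     # signal units, AR(1) floor
NOISE_FLOOR_RHO = 0.5


@dataclass
class TissueSpec:
    """One tissue class of the phantom mixture."""

    name: str
    n_pixels: int
    mean_curve: np.ndarray           # signal units, length M
    covariance: np.ndarray           # M x M SPD, signal units^2
    impairment: tuple[float, float] | None = None   # (t_delay, b) seconds
    kinetics: dict = field(default_factory=dict)    # rcbf/mtt/arrival/b

    def __post_init__(self):
        if self.n_pixels < 1:
            raise ValueError("n_pixels must be >= 1")
        if np.any(np.asarray(self.mean_curve) <= 0):
            raise ValueError("mean curve must be positive")


@dataclass
class PhantomConfig:
    """Full description of one simulated dynamic image set."""

    tissues: list[TissueSpec]
    tr: float = DEFAULT_TR
    te: float = DEFAULT_TE
    s0: float = DEFAULT_S0
    snr: float | None = None
    seed: int = 0

    @property
    def n_frames(self) -> int:
        lengths = {len(t.mean_curve) for t in self.tissues}
        if len(lengths) != 1:
            raise ValueError("tissue curves have inconsistent lengths")
        return lengths.pop()


def canonical_aif(times: np.ndarray, peak: float = ARTERY_PEAK_CONC,
                  onset: float = AIF_ONSET) -> np.ndarray:
    """Gamma-variate arterial input, normalized to the given peak value."""
    raw = gamma_variate(times, 1.0, onset, AIF_SHAPE_R, AIF_SCALE_BETA)
    m = raw.max()
    return raw * (peak / m) if m > 0 else raw


def effective_residue(t_grid: np.ndarray, mtt: float, t_delay: float = 0.0,
                      b: float = 0.0) -> np.ndarray:
    """Delayed, dispersed residue function on a uniform grid.

    Base residue exp(-t/MTT), shifted to start at ``t_delay``; a dispersion
    ``b > 0`` convolves it with the unit-area transport kernel
    (1/b) exp(-t/b) dt.
    """
    if mtt <= 0:
        raise ValueError("mtt must be positive")
    if t_delay < 0 or b < 0:
        raise ValueError("t_delay and b must be nonnegative")
    t = np.asarray(t_grid, dtype=float)
    shifted = t - t_delay
    residue = np.where(shifted >= 0, np.exp(-np.clip(shifted, 0, None) / mtt), 0.0)
    if b > 0:
        dt = float(t[1] - t[0])
        kernel = (1.0 / b) * np.exp(-t / b) * dt
        residue = np.convolve(residue, kernel)[: len(t)]
    return residue


def simulate_impaired_curve(aif: np.ndarray, rcbf: float, mtt: float,
                            t_delay: float, b: float, dt: float) -> np.ndarray:
    """Tissue concentration C = rCBF * dt * (AIF (*) R_eff) on the AIF grid."""
    t = np.arange(len(aif)) * dt
    residue = effective_residue(t, mtt, t_delay, b)
    return rcbf * dt * np.convolve(aif, residue)[: len(aif)]


# (rcbf, mtt s, arrival s, dispersion s, relative baseline, jitter scale)
# per class; rcbf in relative flow units with a global concentration scale
# fixed by the artery peak.  Baselines reflect T2*-EPI contrast (CSF bright,
# WM darker than GM, flow-enhanced artery bright); the draining sinus carries
# the deepest, latest bolus; mixed compartments (CSF families, accessory
# veins) are the most heterogeneous (``jitter`` multiplier).
_KINETICS = {
    "artery":      dict(rcbf=350.0, mtt=1.5, arrival=0.0, b=0.0,
                        baseline=1.35, jitter=1.0),
    "GM":          dict(rcbf=50.0, mtt=4.0, arrival=1.0, b=0.5,
                        baseline=1.00, jitter=1.0),
    "WM":          dict(rcbf=22.1, mtt=4.13, arrival=2.0, b=1.0,
                        baseline=0.62, jitter=1.0),
    "vein+sinus":  dict(rcbf=120.0, mtt=5.5, arrival=3.0, b=1.5,
                        baseline=0.85, jitter=2.0),
    "sinus":       dict(rcbf=250.0, mtt=8.0, arrival=7.5, b=2.5,
                        baseline=1.25, jitter=1.0),
    "CSF+cp":      dict(rcbf=40.0, mtt=8.0, arrival=3.0, b=3.0,
                        baseline=1.38, jitter=2.0),
    "CSF":         dict(rcbf=30.0, mtt=8.0, arrival=4.0, b=3.0,
                        baseline=1.56, jitter=5.5),
    "vein+noise":  dict(rcbf=110.0, mtt=6.0, arrival=3.2, b=2.5,
                        baseline=0.76, jitter=6.0),
}
ARTIFACT_BASELINE = 2.15
ARTIFACT_GHOST_FRACTION = 0.10

_PIXEL_COUNTS = {
    "artery": 551, "GM": 1741, "WM": 1636, "vein+sinus": 610,
    "sinus": 80, "CSF+cp": 412, "artifact": 175, "CSF": 350,
    "vein+noise": 300,
}

# order in which classes enter K-class designs
_CLASS_ORDER = ["artery", "GM", "WM", "vein+sinus", "sinus", "CSF+cp",
                "artifact", "CSF", "vein+noise"]


def _class_covariance(mean_curve: np.ndarray, s0: float, tr: float,
                      noise_scale: float = 1.0,
                      jitter_scale: float = 1.0) -> np.ndarray:
    """Low-rank physiological variability plus an AR(1) floor.

    Voxel-wise baseline-level jitter shifts the whole curve (rank-1 along the
    flat direction); partial-volume jitter scales the bolus depth (rank-1
    along the drop); arrival jitter acts along the temporal derivative; an
    AR(1) floor keeps the covariance full rank.
    """
    m = len(mean_curve)
    flat = np.full(m, s0)                        # baseline-level direction
    drop = mean_curve - s0                       # bolus-depth direction
    slope = np.gradient(mean_curve, tr)          # arrival-shift direction
    idx = np.arange(m)
    ar1 = (noise_scale * NOISE_FLOOR_SD) ** 2 * NOISE_FLOOR_RHO ** np.abs(
        idx[:, None] - idx[None, :])
    cov = (jitter_scale ** 2 * (BASELINE_JITTER ** 2 * np.outer(flat, flat)
                                + AMPLITUDE_JITTER ** 2 * np.outer(drop, drop)
                                + ARRIVAL_JITTER ** 2 * np.outer(slope, slope))
           + ar1)
    return cov


def _build_spec(name: str, n_pixels: int, times: np.ndarray, aif: np.ndarray,
                s0: float, te: float, tr: float,
                extra_delay: float = 0.0, extra_b: float = 0.0,
                impairment: tuple[float, float] | None = None) -> TissueSpec:
    kin = _KINETICS[name]
    dt = float(times[1] - times[0])
    conc = simulate_impaired_curve(aif, kin["rcbf"] * _conc_scale(dt, len(times)),
                                   kin["mtt"], kin["arrival"] + extra_delay,
                                   kin["b"] + extra_b, dt)
    s0_class = kin["baseline"] * s0
    mean_curve = concentration_to_signal(conc, s0_class, te)
    noise_scale = 1.75 if name == "vein+noise" else 1.0
    cov = _class_covariance(mean_curve, s0_class, tr, noise_scale,
                            jitter_scale=kin.get("jitter", 1.0))
    return TissueSpec(name=name if impairment is None else "d" + name,
                      n_pixels=n_pixels, mean_curve=mean_curve, covariance=cov,
                      impairment=impairment,
                      kinetics=dict(kin, extra_delay=extra_delay, extra_b=extra_b))


_CONC_SCALE_CACHE: dict[tuple, float] = {}


def _conc_scale(tr: float = DEFAULT_TR, m: int = DEFAULT_M) -> float:
    """Global flow-to-concentration factor: pins the artery peak concentration."""
    key = (tr, m)
    if key not in _CONC_SCALE_CACHE:
        times = np.arange(m) * tr
        aif = canonical_aif(times)
        kin = _KINETICS["artery"]
        raw = simulate_impaired_curve(aif, kin["rcbf"], kin["mtt"],
                                      kin["arrival"], kin["b"], tr)
        _CONC_SCALE_CACHE[key] = ARTERY_PEAK_CONC / raw.max()
    return _CONC_SCALE_CACHE[key]


def canonical_tissue_library(M: int = DEFAULT_M, tr: float = DEFAULT_TR,
                             s0: float = DEFAULT_S0, te: float = DEFAULT_TE,
                             scale: float = 1.0) -> list[TissueSpec]:
    """The seven-compartment reference design with its stated pixel counts.

    ``scale`` multiplies every pixel count (minimum 20 per class), allowing
    smaller Monte Carlo problems with the same class geometry.
    """
    if M < 40:
        raise ValueError("need at least 40 frames for the bolus design")
    return extended_tissue_library(7, M=M, tr=tr, s0=s0, te=te, scale=scale)


def extended_tissue_library(n_classes: int, M: int = DEFAULT_M,
                            tr: float = DEFAULT_TR, s0: float = DEFAULT_S0,
                            te: float = DEFAULT_TE,
                            scale: float = 1.0) -> list[TissueSpec]:
    """First ``n_classes`` compartments of the canonical order (4..9 supported).

    Classes 8 and 9 (CSF separate from CSF+cp, and a noisier vein variant)
    extend the seven-compartment design for the larger model orders.
    """
    if not (2 <= n_classes <= len(_CLASS_ORDER)):
        raise ValueError(f"n_classes must be in 2..{len(_CLASS_ORDER)}")
    times = np.arange(M) * tr
    aif = canonical_aif(times)
    specs = []
    for name in _CLASS_ORDER[:n_classes]:
        n_pix = max(20, int(round(_PIXEL_COUNTS[name] * scale)))
        if name == "artifact":
            # Nyquist-ghost residue of the arterial bolus: dark baseline with
            # a positive, artery-timed deflection (ghosts mirror the signal
            # drop with opposite sign in the ghosted half-FOV)
            s0_art = ARTIFACT_BASELINE * s0
            kin = _KINETICS["artery"]
            art_conc = simulate_impaired_curve(
                aif, kin["rcbf"] * _conc_scale(tr, M), kin["mtt"],
                kin["arrival"], kin["b"], float(times[1] - times[0]))
            art_drop = 1.0 - concentration_to_signal(art_conc, 1.0, te)
            bump = art_drop / max(art_drop.max(), 1e-12)
            mean_curve = s0_art * (1.0 + ARTIFACT_GHOST_FRACTION * bump)
            drift = np.linspace(-1.0, 1.0, M) * 0.04 * s0_art
            idx = np.arange(M)
            flat = np.full(M, s0_art)
            cov = (BASELINE_JITTER ** 2 * np.outer(flat, flat)
                   + np.outer(drift, drift) + NOISE_FLOOR_SD ** 2
                   * NOISE_FLOOR_RHO ** np.abs(idx[:, None] - idx[None, :]))
            specs.append(TissueSpec(name=name, n_pixels=n_pix,
                                    mean_curve=mean_curve, covariance=cov))
        else:
            specs.append(_build_spec(name, n_pix, times, aif, s0, te, tr))
    return specs


def round_half_down(x: float) -> int:
    """round() that sends exact halves down (551*50% -> 275)."""
    return int(math.ceil(x - 0.5))


def apply_abnormal_fraction(specs: list[TissueSpec], fraction: float,
                            impairment: tuple[float, float],
                            s0: float = DEFAULT_S0, te: float = DEFAULT_TE,
                            tr: float = DEFAULT_TR) -> list[TissueSpec]:
    """Split artery/GM/WM into normal and delayed/dispersed compartments.

    The impaired classes dArtery/dGM/dWM get ``round(fraction * n)`` pixels
    (halves round down) and reuse the normal kinetics with the extra
    ``(t_delay, b)``; the normal classes keep the remainder.  ``fraction`` = 1
    removes the normal classes entirely.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    t_delay, b = impairment
    m = len(specs[0].mean_curve)
    times = np.arange(m) * tr
    aif = canonical_aif(times)
    normal, impaired = [], []
    for spec in specs:
        if spec.name in ("artery", "GM", "WM"):
            n_abn = round_half_down(spec.n_pixels * fraction)
            n_abn = min(max(n_abn, 1), spec.n_pixels)
            d_spec = _build_spec(spec.name, n_abn, times, aif, s0, te, tr,
                                 extra_delay=t_delay, extra_b=b,
                                 impairment=(t_delay, b))
            impaired.append(d_spec)
            if spec.n_pixels - n_abn > 0:
                normal.append(replace(spec, n_pixels=spec.n_pixels - n_abn))
        else:
            normal.append(spec)
    return normal + impaired


def generate_phantom(config: PhantomConfig,
                     rng: np.random.Generator | None = None
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Sample the phantom signal matrix and its ground-truth labels.

    Each class contributes ``n_pixels`` columns drawn from its multivariate
    Gaussian; columns are shuffled with the (recoverable) truth labels.
    """
    rng = rng or np.random.default_rng(config.seed)
    m = config.n_frames
    blocks, labels = [], []
    for k, spec in enumerate(config.tissues):
        L = np.linalg.cholesky(spec.covariance
                               + 1e-10 * np.trace(spec.covariance) / m * np.eye(m))
        z = rng.standard_normal((m, spec.n_pixels))
        blocks.append(spec.mean_curve[:, None] + L @ z)
        labels.append(np.full(spec.n_pixels, k))
    values = np.concatenate(blocks, axis=1)
    labels = np.concatenate(labels)
    if config.snr is not None:
        values = add_noise(values, config.snr, rng)
    perm = rng.permutation(values.shape[1])
    return values[:, perm], labels[perm]


def add_noise(values: np.ndarray, snr: float,
              rng: np.random.Generator | int = 0,
              baseline_frames: int = 8) -> np.ndarray:
    """Add i.i.d. Gaussian noise with sigma = (mean baseline signal) / SNR."""
    if snr <= 0:
        raise ValueError("snr must be positive")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    values = np.asarray(values, dtype=float)
    sigma = values[:baseline_frames].mean() / snr
    return values + sigma * rng.standard_normal(values.shape)


@dataclass
class SimulationResult:
    """Matched classification rates for one segmentation run."""

    per_cluster_rates: np.ndarray    # r_i per truth class, in [0, 1]
    overall_rate: float              # R, percent
    confusion: np.ndarray            # truth x predicted counts
    matching: np.ndarray             # predicted class matched to each truth class (-1 none)


def classification_rate(truth: np.ndarray, predicted: np.ndarray,
                        pixel_weighted: bool = False) -> SimulationResult:
    """Per-cluster agreement rates after maximum-agreement one-to-one matching.

    Predicted clusters are matched to truth clusters by the Hungarian
    algorithm on the confusion matrix; r_i = m_i / N_i and the overall rate
    R is the unweighted cluster average in percent (a pixel-weighted variant
    is available).  Unmatched truth classes score 0.
    """
    truth = np.asarray(truth, dtype=int)
    predicted = np.asarray(predicted, dtype=int)
    if truth.shape != predicted.shape:
        raise ValueError("label vectors must have equal length")
    t_classes = np.unique(truth)
    p_classes = np.unique(predicted)
    conf = np.zeros((t_classes.size, p_classes.size), dtype=int)
    t_idx = np.searchsorted(t_classes, truth)
    p_idx = np.searchsorted(p_classes, predicted)
    np.add.at(conf, (t_idx, p_idx), 1)
    rows, cols = linear_sum_assignment(conf, maximize=True)
    matching = np.full(t_classes.size, -1)
    matching[rows] = cols
    sizes = conf.sum(axis=1)
    agreements = np.zeros(t_classes.size)
    agreements[rows] = conf[rows, cols]
    rates = agreements / sizes
    if pixel_weighted:
        overall = 100.0 * agreements.sum() / sizes.sum()
    else:
        overall = 100.0 * rates.mean()
    return SimulationResult(per_cluster_rates=rates, overall_rate=float(overall),
                            confusion=conf, matching=matching)


# ------------------------- benchmark drivers -----------------------------

def run_single(config: PhantomConfig, K: int, seed: int,
               initializer: str = "hc", var_threshold: float = 0.99,
               **segment_kwargs) -> SimulationResult:
    """Generate one phantom, segment it and score the classification rate."""
    rng = np.random.default_rng(seed)
    values, truth = generate_phantom(config, rng)
    labels = segment_matrix(values, K, initializer=initializer,
                            seed=seed, var_threshold=var_threshold,
                            **segment_kwargs).labels
    return classification_rate(truth, labels)


def run_init_benchmark(k_values=range(4, 10), noise_levels=(None, 70, 40),
                       initializer: str = "hc", reps: int = 100, seed: int = 0,
                       scale: float = 1.0, M: int = DEFAULT_M) -> pd.DataFrame:
    """Initialization benchmark: K-class phantoms across noise levels.

    Returns one row per (K, noise) condition with the mean and SD of the
    overall classification rate over ``reps`` seeded repetitions.
    """
    ss = np.random.SeedSequence(seed)
    rows = []
    for K in k_values:
        specs = extended_tissue_library(K, M=M, scale=scale)
        for snr in noise_levels:
            config = PhantomConfig(tissues=specs, snr=snr)
            rates = _run_reps(config, K, reps, ss, initializer)
            rows.append(_summary_row({"K": K, "snr": snr}, rates, initializer))
    return pd.DataFrame(rows)


def run_delay_dispersion_benchmark(delays=(0, 1, 2, 3, 4, 5),
                                   dispersions=(0, 1, 2, 3, 4, 5),
                                   fraction: float = 0.25,
                                   snr: float | None = 70,
                                   reps: int = 50, seed: int = 0,
                                   scale: float = 1.0,
                                   M: int = DEFAULT_M) -> pd.DataFrame:
    """Delay/dispersion benchmark on 9-class (6 normal + 3 impaired) phantoms.

    The (0, 0) cell is skipped: with no impairment the abnormal compartments
    coincide with their normal counterparts.
    """
    base = extended_tissue_library(6, M=M, scale=scale)
    ss = np.random.SeedSequence(seed)
    rows = []
    for b in dispersions:
        for t_delay in delays:
            if b == 0 and t_delay == 0:
                continue
            specs = apply_abnormal_fraction(base, fraction, (t_delay, b))
            config = PhantomConfig(tissues=specs, snr=snr)
            rates = _run_reps(config, len(specs), reps, ss, "hc")
            rows.append(_summary_row(
                {"b": b, "t_delay": t_delay, "fraction": fraction, "snr": snr},
                rates, "hc"))
    return pd.DataFrame(rows)


def _run_reps(config: PhantomConfig, K: int, reps: int,
              ss: np.random.SeedSequence, initializer: str) -> np.ndarray:
    rates = []
    for child in ss.spawn(reps):
        seed = int(child.generate_state(1)[0] % (2 ** 31))
        rates.append(run_single(config, K, seed, initializer).overall_rate)
    return np.asarray(rates)


def _summary_row(condition: dict, rates: np.ndarray, initializer: str) -> dict:
    row = dict(condition)
    row.update(initializer=initializer, reps=len(rates),
               mean_rate=float(np.mean(rates)),
               sd_rate=float(np.std(rates, ddof=1)) if len(rates) > 1 else 0.0)
    return row


def design_run_count(n_cluster_counts: int = 6, n_noise_levels: int = 3,
                     reps: int = 1000, n_delays: int = 0, n_dispersions: int = 0,
                     n_fractions: int = 0) -> int:
    """Enumerate the total number of simulated image sets in a design."""
    if n_delays or n_dispersions or n_fractions:
        return n_delays * n_dispersions * n_fractions * n_noise_levels * reps
    return n_cluster_counts * n_noise_levels * reps
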