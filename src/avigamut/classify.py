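"""Rule-based assignment of colour-production mechanisms from spectral shape.

Plumage colours arise from a handful of mechanisms with recognisable
reflectance signatures:

* melanin — flat or monotonically rising curves without a clear maximum
  (blacks, greys, browns, rufous); unpigmented white is folded in here;
* carotenoid — an absorption trough near 450 nm with fine structure and
  high long-wavelength reflectance, or a sigmoid curve with a long-
  wavelength "shoulder" (yellows, reds);
* psittacofulvin — carotenoid-like spectra in parrots (Psittaciformes),
  which replace carotenoids with endogenous psittacofulvins;
* structural — bell-shaped curves with discrete maxima, or multi-peaked
  iridescent spectra (blues, violets, UV);
* carotenoid + structure / psittacofulvin + structure — a 450 nm trough
  with fine structure, a peak between 500 and 600 nm, and another trough
  at longer wavelengths (greens).

The field assigns these categories by expert inspection of spectral shape;
this module operationalises the same criteria with named numeric
thresholds.  The defaults are calibrated to separate the parametric
spectral families of :mod:`avigamut.simulate` cleanly and are configurable
for real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, savgol_filter
from scipy.stats import spearmanr

from .spectra import GRID, ReflectanceSpectrum, SpectrumSet

MECHANISMS = (
    "melanin",
    "carotenoid",
    "psittacofulvin",
    "structural",
    "carotenoid_structural",
    "psittacofulvin_structural",
)

#: taxonomic orders whose carotenoid-shaped spectra are psittacofulvin-based
PARROT_ORDERS = frozenset({"psittaciformes"})


@dataclass
class ClassifierConfig:
    """Numeric thresholds for the shape rules (units noted per field)."""

    trough_window: tuple[float, float] = (400.0, 510.0)   # nm, the ~450 trough
    mid_peak_window: tuple[float, float] = (500.0, 600.0)  # nm, combo peak
    long_window: tuple[float, float] = (650.0, 700.0)      # nm, long-wave level
    short_window: tuple[float, float] = (300.0, 350.0)     # nm, UV level
    major_prominence_frac: float = 0.20   # of spectral range: a "discrete maximum"
    major_prominence_min: float = 3.0     # %R absolute floor for a discrete maximum
    minor_prominence: float = 0.4         # %R: fine-structure bumps in the trough
    fine_prominence_max: float = 6.0      # %R: fine structure is small; a larger
                                          # peak in the trough window is a real
                                          # (structural) maximum
    trough_depth_frac: float = 0.10       # of long-wave reflectance
    plateau_slope: float = 0.15           # %/nm: derivative below this = plateau
    plateau_from: float = 640.0           # nm: where the shoulder plateau is judged
    rise_slope: float = 0.30              # %/nm: max derivative for a real rise
    sigmoid_contrast: float = 3.0         # long/short reflectance ratio
    plateau_level_frac: float = 0.75      # long mean vs max for trough carotenoids
    monotonicity_min: float = 0.40        # Spearman rho for sigmoid shapes
    uv_ratio_min: float = 1.5             # UV peak vs long-wave mean
    uv_argmax_nm: float = 350.0           # UV-truncated bell: global max below
    long_fall_frac: float = 0.60          # combo: long mean below this x mid peak
    combo_guard_nm: float = 490.0         # combo: no discrete maximum below this
                                          # (a short-wave bell means iridescence)
    smooth_window: int = 7                # points (odd), local-polynomial smoother
    smooth_order: int = 3


DEFAULT_CONFIG = ClassifierConfig()


def smooth_spectrum(spectrum: ReflectanceSpectrum, window: int = 11,
                    order: int = 3) -> ReflectanceSpectrum:
    """Savitzky-Golay smoothing on the common grid, clamped to [0, 100]."""
    if window % 2 == 0 or window <= order:
        raise ValueError("window must be odd and greater than order")
    if window >= spectrum.wavelengths.size:
        raise ValueError("window must be shorter than the grid")
    r = savgol_filter(spectrum.reflectance, window, order)
    return replace(spectrum, reflectance=np.clip(r, 0.0, 100.0))


def _window_mask(wl: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    return (wl >= window[0]) & (wl <= window[1])


@dataclass
class SpectralFeatures:
    """Deterministic shape descriptors of one smoothed spectrum."""

    monotonicity: float            # Spearman rho of reflectance vs wavelength
    flatness: float                # (max - min) / mean
    peaks: list[tuple[float, float, float]]  # (wavelength, value, prominence)
    trough450_value: float         # min reflectance in the trough window
    trough450_wl: float
    fine_structure450: int         # small local maxima inside the trough window
    shoulder: bool                 # steep rise then long-wave plateau
    long_trough: bool              # interior minimum above 600 nm
    uv_peak_ratio: float           # short-wave level / long-wave level
    argmax_wl: float               # wavelength of the global maximum
    long_mean: float
    short_mean: float
    smax: float
    smin: float
    config: ClassifierConfig = field(default_factory=ClassifierConfig, repr=False)


def spectral_features(spectrum: ReflectanceSpectrum,
                      config: ClassifierConfig = DEFAULT_CONFIG,
                      presmoothed: bool = False) -> SpectralFeatures:
    """Extract the shape features the mechanism rules consume.

    The spectrum must be on the common grid; it is smoothed first unless
    ``presmoothed``.  Identical input gives identical features.
    """
    if not presmoothed:
        spectrum = smooth_spectrum(spectrum, config.smooth_window,
                                   config.smooth_order)
    wl, r = spectrum.wavelengths, spectrum.reflectance
    smax, smin, mean = float(r.max()), float(r.min()), float(r.mean())
    rng_ = smax - smin

    if rng_ < 1e-9:
        mono = 0.0
    else:
        mono = float(spearmanr(wl, r).statistic)
        if np.isnan(mono):
            mono = 0.0
    flatness = rng_ / mean if mean > 0 else 0.0

    # all interior local maxima with their prominences
    pk_idx, props = find_peaks(r, prominence=1e-6)
    peaks = [(float(wl[i]), float(r[i]), float(p))
             for i, p in zip(pk_idx, props["prominences"])]

    long_mean = float(r[_window_mask(wl, config.long_window)].mean())
    short_mean = float(r[_window_mask(wl, config.short_window)].mean())

    tmask = _window_mask(wl, config.trough_window)
    t_i = int(np.argmin(np.where(tmask, r, np.inf)))
    trough_val, trough_wl = float(r[t_i]), float(wl[t_i])

    fine = sum(
        1 for (pwl, pval, prom) in peaks
        if config.trough_window[0] <= pwl <= config.trough_window[1]
        and config.minor_prominence <= prom <= config.fine_prominence_max
        and pval <= 0.6 * smax
    )

    deriv = np.gradient(r, wl)
    tail = wl >= config.plateau_from
    # plateau slope from a least-squares line over the tail: robust to
    # spectrally correlated noise, unlike a pointwise max derivative
    tail_slope = float(np.polyfit(wl[tail], r[tail], 1)[0])
    shoulder = bool(
        deriv.max() >= config.rise_slope
        and abs(tail_slope) < config.plateau_slope
    )

    lt_mask = (wl > 600.0) & (wl < wl[-1])
    long_trough = any(
        600.0 < wl[i] < wl[-1]
        for i in find_peaks(-r, prominence=config.minor_prominence)[0]
    ) if lt_mask.any() else False

    uv_ratio = short_mean / long_mean if long_mean > 1e-9 else np.inf

    return SpectralFeatures(
        monotonicity=mono, flatness=flatness, peaks=peaks,
        trough450_value=trough_val, trough450_wl=trough_wl,
        fine_structure450=fine, shoulder=shoulder, long_trough=long_trough,
        uv_peak_ratio=uv_ratio, argmax_wl=float(wl[int(np.argmax(r))]),
        long_mean=long_mean, short_mean=short_mean,
        smax=smax, smin=smin, config=config,
    )


def _is_parrot(order: str) -> bool:
    return order.strip().lower() in PARROT_ORDERS


def classify_mechanism(features: SpectralFeatures, order: str = "unknown") -> str:
    """Assign exactly one mechanism label from shape features.

    Rule precedence: pigment+structure combinations fire before the single
    carotenoid and structural rules; melanin (including white) is the
    fall-through.  Carotenoid-shaped spectra in Psittaciformes are labelled
    psittacofulvin; if the order is unknown the carotenoid label is kept.
    """
    cfg = features.config
    rng_ = features.smax - features.smin
    major = max(cfg.major_prominence_frac * rng_, cfg.major_prominence_min)

    major_peaks = [(pwl, pval, prom) for (pwl, pval, prom) in features.peaks
                   if prom >= major and rng_ > 1e-9]
    parrot = _is_parrot(order)

    # (1) pigment + structure: 450 trough with fine structure, a 500-600 nm
    # peak, and depressed reflectance beyond it
    mid = [(pwl, pval, prom) for (pwl, pval, prom) in major_peaks
           if cfg.mid_peak_window[0] <= pwl <= cfg.mid_peak_window[1]]
    short_bell = any(pwl < cfg.combo_guard_nm for (pwl, _, _) in major_peaks)
    if mid and features.fine_structure450 >= 1 and not short_bell:
        peak_val = max(pval for (_, pval, _) in mid)
        if (features.trough450_value <= cfg.long_fall_frac * peak_val
                and features.long_mean <= cfg.long_fall_frac * peak_val):
            return "psittacofulvin_structural" if parrot else "carotenoid_structural"

    # (2) carotenoid-type: trough + fine structure + high long-wave plateau,
    # or a sigmoid rise with a long-wave shoulder
    trough_deep = (
        features.long_mean > 0
        and features.long_mean - features.trough450_value
        >= cfg.trough_depth_frac * features.long_mean
    )
    carotenoid_a = (
        trough_deep
        and features.fine_structure450 >= 1
        and features.long_mean >= cfg.plateau_level_frac * features.smax
        and features.short_mean > 0
        and features.long_mean / features.short_mean >= cfg.sigmoid_contrast
    )
    # a sigmoid has no discrete interior maximum; a bell (even one peaking
    # beyond 600 nm in iridescent spectra) is not a carotenoid shoulder
    carotenoid_b = (
        features.shoulder
        and features.monotonicity >= cfg.monotonicity_min
        and features.short_mean > 0
        and features.long_mean / features.short_mean >= cfg.sigmoid_contrast
        and not any(pwl < 620.0 for (pwl, _, _) in major_peaks)
    )
    if carotenoid_a or carotenoid_b:
        return "psittacofulvin" if parrot else "carotenoid"

    # (3) structural: a discrete interior maximum that is not a carotenoid
    # plateau, or a dominant UV/short-wave peak truncated at the grid edge
    if major_peaks and features.long_mean < cfg.plateau_level_frac * features.smax:
        return "structural"
    if (features.uv_peak_ratio >= cfg.uv_ratio_min
            and features.argmax_wl <= cfg.uv_argmax_nm):
        return "structural"

    # (5) melanin: flat or monotonically rising, incl. white
    return "melanin"


def classify_spectrum(spectrum: ReflectanceSpectrum,
                      config: ClassifierConfig = DEFAULT_CONFIG) -> str:
    return classify_mechanism(spectral_features(spectrum, config),
                              spectrum.order)


def classify_set(sset: SpectrumSet,
                 config: ClassifierConfig = DEFAULT_CONFIG
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Label every spectrum and tabulate mechanism shares.

    Returns ``(labelled, shares)``: the per-spectrum metadata table with a
    ``mechanism`` column, and a share table with percentage of spectra per
    mechanism (rows for all six mechanisms, summing to 100 for non-empty
    input).  Order-independent: permuting the input permutes rows only.
    """
    labelled = sset.meta_frame()
    labelled["mechanism"] = [classify_spectrum(s, config) for s in sset]
    counts = labelled["mechanism"].value_counts()
    n = len(labelled)
    shares = pd.DataFrame(
        {
            "mechanism": MECHANISMS,
            "n": [int(counts.get(m, 0)) for m in MECHANISMS],
        }
    )
    shares["share_pct"] = 100.0 * shares["n"] / n if n else 0.0
    return labelled, shares
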