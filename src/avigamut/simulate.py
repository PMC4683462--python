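"""Synthetic avifaunas: parametric reflectance spectra with known mechanisms.

Museum-grade spectral libraries of whole avifaunas are rarely deposited, so
every pipeline stage here is exercised on generated data with ground truth.
Each colour-production mechanism is a parametric spectral family:

* melanin — flat or monotonically rising (linear or saturating) curves;
* white — flat high-reflectance curves (classified with melanin);
* carotenoid / psittacofulvin — logistic rise to a long-wave plateau with
  optional fine-structure absorption dips near 430/465 nm;
* structural — Gaussian bells (UV-blue range), optionally iridescent with
  a second bell;
* carotenoid_structural / psittacofulvin_structural — a 500-600 nm bell
  with a 450 nm trough carrying fine structure and depressed long-wave
  reflectance with a slight far-red tail.

Noise is spectrally correlated (smoothed white noise, ~25 nm correlation
length): real reflectance noise is smooth, and independent per-wavelength
noise would destroy shape classification unrealistically.

An avifauna is organised as orders of unequal size, each with its own
mechanism frequency vector; sexual dichromatism is modelled as female
substitution of ornamental (non-melanin) patches by melanin/white,
reproducing the male-biased periphery of colour space.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .spectra import GRID, ReflectanceSpectrum, SpectrumSet

FAMILIES = (
    "melanin",
    "white",
    "carotenoid",
    "structural",
    "carotenoid_structural",
)

#: default specimen-to-specimen noise standard deviation, %reflectance
DEFAULT_NOISE_SD = 1.5

#: correlation length of the noise, expressed in 5 nm grid steps (~25 nm)
NOISE_SMOOTH_STEPS = 5.0


@dataclass
class SpectralFamilyParams:
    """Parameters of one synthetic spectrum's noise-free shape."""

    family: str
    baseline: float                     # %R
    amplitude: float                    # %R above baseline
    center_or_inflection: float = 500.0  # nm (bell centre / logistic midpoint)
    width_or_slope: float = 40.0         # nm (bell sigma / logistic width / tau)
    fine_structure: bool = False
    fs_depth: float = 2.2                # %R, absorption-dip depth
    second_peak: float | None = None     # nm, iridescent second bell
    second_amplitude: float = 0.0        # %R
    tail_amplitude: float = 0.0          # %R, far-red tail (combo family)
    saturating: bool = False             # melanin: saturating vs linear rise
    noise_sd: float = DEFAULT_NOISE_SD


def _gauss(wl: np.ndarray, centre: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - centre) / sigma) ** 2)


def _logistic(wl: np.ndarray, centre: float, width: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-(wl - centre) / width))


def clean_curve(params: SpectralFamilyParams) -> np.ndarray:
    """The noise-free reflectance curve of a family, clipped to [0, 100]."""
    wl = GRID
    p = params
    if p.family in ("melanin", "white"):
        if p.family == "white" or p.amplitude == 0:
            r = np.full_like(wl, p.baseline)
        elif p.saturating:
            r = p.baseline + p.amplitude * (
                1.0 - np.exp(-(wl - wl[0]) / p.width_or_slope)
            )
        else:
            r = p.baseline + p.amplitude * (wl - wl[0]) / (wl[-1] - wl[0])
    elif p.family == "carotenoid":
        r = p.baseline + p.amplitude * _logistic(
            wl, p.center_or_inflection, p.width_or_slope
        )
    elif p.family == "structural":
        r = p.baseline + p.amplitude * _gauss(
            wl, p.center_or_inflection, p.width_or_slope
        )
        if p.second_peak is not None:
            r = r + p.second_amplitude * _gauss(wl, p.second_peak,
                                                p.width_or_slope)
    elif p.family == "carotenoid_structural":
        r = (
            p.baseline
            + p.amplitude * _gauss(wl, p.center_or_inflection,
                                   p.width_or_slope)
            + p.tail_amplitude * _logistic(wl, 670.0, 12.0)
        )
    else:
        raise ValueError(f"unknown spectral family {params.family!r}")
    if p.fine_structure:
        # two absorption dips flanking ~447 nm create the small local
        # maximum ("fine structure") characteristic of carotenoid troughs
        r = r - p.fs_depth * (_gauss(wl, 425.0, 11.0) + _gauss(wl, 470.0, 11.0))
    return np.clip(r, 0.0, 100.0)


def correlated_noise(rng: np.random.Generator, sd: float,
                     n: int = 1) -> np.ndarray:
    """(n, 81) smooth noise with per-row standard deviation ``sd``."""
    eps = rng.standard_normal((n, GRID.size))
    smooth = gaussian_filter1d(eps, NOISE_SMOOTH_STEPS, axis=-1,
                               mode="nearest")
    scale = smooth.std(axis=-1, keepdims=True)
    scale[scale < 1e-12] = 1.0
    return sd * smooth / scale


def gen_spectrum(params: SpectralFamilyParams, rng: np.random.Generator,
                 **meta) -> ReflectanceSpectrum:
    """One synthetic spectrum: clean family curve plus correlated noise."""
    r = clean_curve(params)
    if params.noise_sd > 0:
        r = np.clip(r + correlated_noise(rng, params.noise_sd)[0], 0.0, 100.0)
    return ReflectanceSpectrum(GRID.copy(), r, **meta)


def draw_family_params(family: str, rng: np.random.Generator,
                       noise_sd: float = DEFAULT_NOISE_SD
                       ) -> SpectralFamilyParams:
    """Draw shape parameters from the family's prior.

    The priors are calibrated once so that noise-free curves carry their
    family-defining features (trough depth, peak prominence, plateau
    contrast) clearly above the classifier's default thresholds.
    """
    u = rng.uniform
    if family == "white":
        return SpectralFamilyParams("white", baseline=u(55, 85), amplitude=0.0,
                                    noise_sd=noise_sd)
    if family == "melanin":
        baseline = u(5, 35)
        return SpectralFamilyParams(
            "melanin", baseline=baseline, amplitude=u(0, 1.2 * baseline),
            width_or_slope=u(120, 250), saturating=bool(rng.random() < 0.5),
            noise_sd=noise_sd,
        )
    if family == "carotenoid":
        return SpectralFamilyParams(
            "carotenoid", baseline=u(4, 8), amplitude=u(35, 65),
            center_or_inflection=u(490, 530), width_or_slope=u(12, 22),
            fine_structure=bool(rng.random() < 0.6), fs_depth=u(2.2, 3.6),
            noise_sd=noise_sd,
        )
    if family == "structural":
        amp = u(25, 60)
        second = rng.random() < 0.25
        centre = u(320, 480)
        return SpectralFamilyParams(
            "structural", baseline=u(2, 8), amplitude=amp,
            center_or_inflection=centre, width_or_slope=u(25, 55),
            second_peak=centre + u(170, 230) if second else None,
            second_amplitude=amp * u(0.35, 0.6) if second else 0.0,
            noise_sd=noise_sd,
        )
    if family == "carotenoid_structural":
        return SpectralFamilyParams(
            "carotenoid_structural", baseline=u(4, 8), amplitude=u(35, 60),
            center_or_inflection=u(555, 590), width_or_slope=u(22, 30),
            fine_structure=True, fs_depth=u(2.2, 3.6),
            tail_amplitude=u(3, 8), noise_sd=noise_sd,
        )
    raise ValueError(f"unknown spectral family {family!r}")


def true_mechanism(family: str, order_is_parrot: bool) -> str:
    """Map a generating family to the mechanism label ground truth."""
    if family == "white":
        return "melanin"
    if family == "carotenoid":
        return "psittacofulvin" if order_is_parrot else "carotenoid"
    if family == "carotenoid_structural":
        return ("psittacofulvin_structural" if order_is_parrot
                else "carotenoid_structural")
    return family


@dataclass
class OrderSpec:
    """One taxonomic order: size, mechanism frequencies, parrot flag."""

    name: str
    n_species: int
    mechanism_freqs: dict[str, float]   # over melanin/carotenoid/structural/
                                        # carotenoid_structural base families
    is_parrot_like: bool = False


@dataclass
class AvifaunaConfig:
    """Design of a synthetic avifauna."""

    orders: list[OrderSpec] = field(default_factory=lambda: default_orders())
    n_specimens_per_sex: int = 3
    n_patches: int = 17
    dichromatism: float = 0.4     # P(female version of an ornamental patch
                                  # is replaced by melanin/white)
    white_within_melanin: float = 0.15
    share_sex_params: bool = True
    noise_sd: float = DEFAULT_NOISE_SD
    seed: int = 1

    @property
    def n_species(self) -> int:
        return sum(o.n_species for o in self.orders)

    def __post_init__(self) -> None:
        for o in self.orders:
            total = sum(o.mechanism_freqs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"mechanism frequencies of {o.name} sum to {total}, not 1"
                )


def default_orders() -> list[OrderSpec]:
    """Four orders of very different sizes, melanin-dominant overall, with a
    small parrot-like order carrying disproportionate structural and
    psittacofulvin colour."""
    return [
        OrderSpec("Passeriformes", 30, {
            "melanin": 0.66, "carotenoid": 0.14, "structural": 0.14,
            "carotenoid_structural": 0.06,
        }),
        OrderSpec("Columbiformes", 15, {
            "melanin": 0.80, "carotenoid": 0.08, "structural": 0.10,
            "carotenoid_structural": 0.02,
        }),
        OrderSpec("Charadriiformes", 10, {
            "melanin": 0.92, "carotenoid": 0.04, "structural": 0.04,
            "carotenoid_structural": 0.00,
        }),
        OrderSpec("Psittaciformes", 5, {
            "melanin": 0.40, "carotenoid": 0.25, "structural": 0.15,
            "carotenoid_structural": 0.20,
        }, is_parrot_like=True),
    ]


def default_config(**overrides) -> AvifaunaConfig:
    return AvifaunaConfig(**overrides)


def gen_avifauna(config: AvifaunaConfig) -> tuple[SpectrumSet, pd.DataFrame]:
    """Generate a full avifauna and its ground-truth table.

    Returns the spectra (species x sex x specimen x patch, all on the
    common grid) and a truth table with one row per spectrum recording the
    generating family and the mechanism label the classifier should
    recover.  Deterministic for a fixed config (seed included).
    """
    rng = np.random.default_rng(config.seed)
    base_families = ("melanin", "carotenoid", "structural",
                     "carotenoid_structural")
    sset = SpectrumSet(provenance=f"synthetic avifauna seed={config.seed}")
    truth_rows = []
    patches = [f"patch_{i:02d}" for i in range(1, config.n_patches + 1)]

    for order in config.orders:
        freqs = np.array([order.mechanism_freqs.get(f, 0.0)
                          for f in base_families])
        for si in range(order.n_species):
            species = f"{order.name}_sp{si:03d}"
            for patch in patches:
                fam = base_families[rng.choice(len(base_families), p=freqs)]
                if fam == "melanin" and rng.random() < config.white_within_melanin:
                    fam = "white"
                male_params = draw_family_params(fam, rng, config.noise_sd)
                if config.share_sex_params:
                    female_params = replace(male_params)
                else:
                    female_params = draw_family_params(fam, rng,
                                                       config.noise_sd)
                female_fam = fam
                if (fam not in ("melanin", "white")
                        and rng.random() < config.dichromatism):
                    female_fam = ("white" if rng.random() < 0.3 else "melanin")
                    female_params = draw_family_params(female_fam, rng,
                                                       config.noise_sd)
                for sex, params, sfam in (("male", male_params, fam),
                                          ("female", female_params,
                                           female_fam)):
                    clean = clean_curve(params)
                    noise = correlated_noise(rng, config.noise_sd,
                                             config.n_specimens_per_sex)
                    for k in range(config.n_specimens_per_sex):
                        specimen = f"{species}_{sex[0]}{k + 1}"
                        r = np.clip(clean + noise[k], 0.0, 100.0)
                        sset.spectra.append(ReflectanceSpectrum(
                            GRID.copy(), r, species=species, order=order.name,
                            sex=sex, specimen_id=specimen, patch=patch,
                        ))
                        truth_rows.append({
                            "species": species, "order": order.name,
                            "sex": sex, "specimen_id": specimen,
                            "patch": patch, "family": sfam,
                            "mechanism": true_mechanism(
                                sfam, order.is_parrot_like),
                        })
    return sset, pd.DataFrame(truth_rows)
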