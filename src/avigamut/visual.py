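"""Avian visual modelling: cone quantum catches and tetrahedral coordinates.

The model is purely geometric: reflectance x irradiance x cone sensitivity
summed over the 5 nm grid, relative to the catch from a perfect reflector,
gives a quantum catch per cone (so white sits at the achromatic point); the
four catches normalised to sum to one are a point on the usml simplex; an
affine map
embeds the simplex as a regular tetrahedron of circumradius 0.75 centred on
the achromatic point, oriented with the longwave (L) vertex at the apex
(0, 0, 0.75).  No receptor noise, chromatic adaptation or log transform is
applied.

Cone sensitivities come either from a Govardovskii A1 alpha-band template
evaluated at configurable peak wavelengths (defaults: UV-type 372/456/544/609
nm, violet-type 419/478/542/607 nm -- widely used averages for UVS and VS
birds) or bit-for-bit from a user-supplied CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spectra import GRID, ReflectanceSpectrum, SpectrumSet

#: default cone peak sensitivities (u/v, s, m, l) in nm
U_TYPE_LMAX = (372.0, 456.0, 544.0, 609.0)
V_TYPE_LMAX = (419.0, 478.0, 542.0, 607.0)

CONE_NAMES = ("u", "s", "m", "l")


class GridError(ValueError):
    """Raised when a spectrum and a sensitivity set disagree on the grid."""


class DegenerateSpectrumError(ValueError):
    """Raised for an all-zero quantum catch (black has no chromaticity)."""


def cone_template(lambda_max: float, grid: np.ndarray | None = None) -> np.ndarray:
    """Govardovskii A1 visual-pigment alpha-band template, unit peak.

    Standard published constants; the beta band is omitted (its contribution
    is small above 350 nm and user-supplied curves may include it).
    """
    if grid is None:
        grid = GRID
    grid = np.asarray(grid, dtype=float)
    if not (grid[0] <= lambda_max <= grid[-1]):
        raise ValueError(f"lambda_max {lambda_max} nm outside grid "
                         f"{grid[0]:g}-{grid[-1]:g} nm")
    x = lambda_max / grid
    a = 0.8795 + 0.0459 * np.exp(-((lambda_max - 300.0) ** 2) / 11940.0)
    s = 1.0 / (
        np.exp(69.7 * (a - x))
        + np.exp(28.0 * (0.922 - x))
        + np.exp(-14.9 * (1.104 - x))
        + 0.674
    )
    return s / s.max()


@dataclass
class SensitivitySet:
    """Four cone sensitivity curves on the common grid.

    ``curves`` has shape (4, 81), rows ordered (u_or_v, s, m, l), each
    non-negative with unit peak.  ``type_tag`` is "U", "V" or "custom".
    """

    grid: np.ndarray
    curves: np.ndarray
    type_tag: str = "custom"
    lambda_max: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.curves = np.asarray(self.curves, dtype=float)
        if self.curves.shape != (4, self.grid.size):
            raise ValueError("curves must be a (4, n_grid) array")
        if np.any(self.curves < 0):
            raise ValueError("sensitivities must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"wavelength_nm": self.grid})
        for name, row in zip(CONE_NAMES, self.curves):
            df[name] = row
        return df

    def to_csv(self, path) -> None:
        # 17 significant digits: files round-trip bit-for-bit
        self.to_frame().to_csv(path, index=False, float_format="%.17g")


def build_sensitivity_set(
    visual_system: str = "U",
    lambda_max: tuple[float, float, float, float] | None = None,
    path=None,
) -> SensitivitySet:
    """Build cone sensitivities from a template type, λmax list, or CSV file.

    Exactly one source is used, with precedence file > lambda_max > type.
    A file written by :meth:`SensitivitySet.to_csv` round-trips exactly.
    """
    if path is not None:
        # round_trip parsing: supplied curves override templates bit-for-bit
        df = pd.read_csv(path, float_precision="round_trip")
        missing = [c for c in ("wavelength_nm", *CONE_NAMES) if c not in df.columns]
        if missing:
            raise ValueError(f"sensitivity file missing columns {missing}")
        return SensitivitySet(
            df["wavelength_nm"].to_numpy(float),
            np.vstack([df[c].to_numpy(float) for c in CONE_NAMES]),
            type_tag="custom",
        )
    if lambda_max is None:
        vs = visual_system.upper()
        if vs == "U":
            lambda_max = U_TYPE_LMAX
        elif vs == "V":
            lambda_max = V_TYPE_LMAX
        else:
            raise ValueError(f"unknown visual system {visual_system!r}")
        tag = vs
    else:
        tag = "custom"
    curves = np.vstack([cone_template(lm) for lm in lambda_max])
    return SensitivitySet(GRID.copy(), curves, type_tag=tag,
                          lambda_max=tuple(float(v) for v in lambda_max))


def quantum_catches(
    spectrum: ReflectanceSpectrum,
    sens: SensitivitySet,
    irradiance: np.ndarray | None = None,
) -> np.ndarray:
    """Cone quantum catches on the 5 nm grid, normalised to a perfect
    reflector.

    Q_i = sum_lambda R * I * C_i / sum_lambda I * C_i, with reflectance as a
    proportion (percent / 100) and ``irradiance=None`` meaning the ideal
    flat spectrum I(lambda) = 1.  The denominator is each cone's catch from
    a 100% ("white standard") reflector under the same illuminant, so a
    flat spectrum stimulates all four cones equally and maps to the
    achromatic point -- the convention that puts unsaturated grey, white
    and melanin colours at the centre of the tetrahedron.  Rectangle-rule
    summation; any constant bin width cancels in the ratio.
    """
    if spectrum.wavelengths.size != sens.grid.size or not np.array_equal(
        spectrum.wavelengths, sens.grid
    ):
        raise GridError("spectrum and sensitivity set are on different grids")
    r = spectrum.reflectance / 100.0
    if irradiance is None:
        weighted = r
        denom = sens.curves.sum(axis=1)
    else:
        irradiance = np.asarray(irradiance, dtype=float)
        if irradiance.shape != r.shape:
            raise GridError("irradiance not on the common grid")
        weighted = r * irradiance
        denom = sens.curves @ irradiance
    return (sens.curves @ weighted) / denom


def relative_catches(q: np.ndarray) -> np.ndarray:
    """Normalise catches to the usml simplex: f_i = Q_i / sum(Q)."""
    q = np.asarray(q, dtype=float)
    total = q.sum()
    if total <= 0:
        raise DegenerateSpectrumError(
            "all-zero quantum catch: an all-black spectrum has no chromaticity"
        )
    return q / total


# simplex -> tetrahedron affine map, L vertex at the apex (0, 0, 0.75)
_SQRT32 = np.sqrt(1.5)
_SQRT8 = 2.0 * np.sqrt(2.0)


def tetra_coords(f: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Map relative catches (u, s, m, l) to tetrahedral coordinates.

    x = ((1 - 2s - m - l)/2) * sqrt(3/2)
    y = (-1 + 3m + l) / (2*sqrt(2))
    z = l - 1/4

    The four single-cone vertices form a regular tetrahedron of edge
    sqrt(3/2) and circumradius 0.75 centred on the achromatic point, with
    the l vertex at (0, 0, 0.75).
    """
    f = np.asarray(f, dtype=float)
    if f.min() < -tol or abs(f.sum() - 1.0) > max(tol, 1e-9):
        raise ValueError(f"relative catches {f} are off the simplex")
    u, s, m, l = f
    return np.array(
        [
            0.5 * (1.0 - 2.0 * s - m - l) * _SQRT32,
            (-1.0 + 3.0 * m + l) / _SQRT8,
            l - 0.25,
        ]
    )


def tetra_vertices() -> np.ndarray:
    """Coordinates of the four single-cone vertices (rows u, s, m, l)."""
    return np.vstack([tetra_coords(f) for f in np.eye(4)])


#: convex-hull volume of the full tetrahedron, (sqrt(3/2))^3 / (6*sqrt(2))
TETRA_VOLUME = (np.sqrt(1.5) ** 3) / (6.0 * np.sqrt(2.0))


def model_set(
    sset: SpectrumSet,
    sens: SensitivitySet,
    irradiance: np.ndarray | None = None,
) -> pd.DataFrame:
    """Vectorised pipeline spectrum -> quantum catch -> tetra point.

    Returns a DataFrame with metadata columns plus x, y, z.  Spectra must be
    on the common grid.  All-zero catches raise, matching
    :func:`relative_catches`.
    """
    if len(sset) == 0:
        return pd.DataFrame(
            columns=["species", "order", "sex", "specimen_id", "patch",
                     "x", "y", "z"]
        )
    refl = sset.reflectance_matrix() / 100.0
    if refl.shape[1] != sens.grid.size:
        raise GridError("spectra and sensitivity set are on different grids")
    if irradiance is None:
        denom = sens.curves.sum(axis=1)
    else:
        refl = refl * np.asarray(irradiance, dtype=float)[None, :]
        denom = sens.curves @ np.asarray(irradiance, dtype=float)
    q = (refl @ sens.curves.T) / denom[None, :]   # (n, 4)
    totals = q.sum(axis=1)
    if np.any(totals <= 0):
        raise DegenerateSpectrumError("set contains an all-zero spectrum")
    f = q / totals[:, None]
    u, s, m, l = f.T
    df = sset.meta_frame()
    df["x"] = 0.5 * (1.0 - 2.0 * s - m - l) * _SQRT32
    df["y"] = (-1.0 + 3.0 * m + l) / _SQRT8
    df["z"] = l - 0.25
    return df


def aggregate_species_sex(points: pd.DataFrame) -> pd.DataFrame:
    """Average specimen points within each (species, sex, patch) group.

    The species x sex x patch mean colour is the analysis unit; specimens
    are replicates.  Convexity keeps every mean inside the tetrahedron.
    Non-grouping metadata (order) is carried via first value per group.
    """
    if points.empty:
        return points.copy()
    grouped = points.groupby(["species", "sex", "patch"], sort=False).agg(
        order=("order", "first"), x=("x", "mean"), y=("y", "mean"),
        z=("z", "mean"),
    )
    return grouped.reset_index()[["species", "order", "sex", "patch", "x", "y", "z"]]
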