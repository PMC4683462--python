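"""Reading, validation and resampling of plumage reflectance spectra.

All downstream analysis happens on a common wavelength grid of 300-700 nm in
5 nm steps (81 points).  Spectra arrive either as "long" tables (one row per
wavelength per spectrum) or "wide" tables (one column per spectrum), are
linearly interpolated onto the grid, and carry their museum-style metadata
(species, taxonomic order, sex, specimen, plumage patch) through the whole
pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: the common analysis grid: 300, 305, ..., 700 nm
GRID = np.arange(300.0, 700.0 + 1e-9, 5.0)

#: recognised sex codes; anything else is flagged by validate_set
SEXES = ("male", "female", "unknown")

#: default list of standardized plumage patch labels (configurable)
DEFAULT_PATCHES = tuple(f"patch_{i:02d}" for i in range(1, 18))


class CoverageError(ValueError):
    """Raised when a spectrum does not cover the 300-700 nm analysis range."""


class FormatError(ValueError):
    """Raised when an input table lacks required columns or structure."""


@dataclass
class ReflectanceSpectrum:
    """A single reflectance measurement of one plumage patch.

    Reflectance is in percent (0-100).  Small negative values from
    instrument noise are tolerated on input and clamped at resampling.
    """

    wavelengths: np.ndarray
    reflectance: np.ndarray
    species: str = "unknown"
    order: str = "unknown"
    sex: str = "unknown"
    specimen_id: str = "unknown"
    patch: str = "unknown"

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        if self.wavelengths.shape != self.reflectance.shape:
            raise ValueError("wavelengths and reflectance must have equal length")
        if self.wavelengths.size < 2:
            raise ValueError("a spectrum needs at least two samples")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")

    @property
    def on_grid(self) -> bool:
        return self.wavelengths.size == GRID.size and np.array_equal(
            self.wavelengths, GRID
        )

    def key(self) -> tuple[str, str, str, str]:
        return (self.species, self.sex, self.specimen_id, self.patch)


@dataclass
class SpectrumSet:
    """An ordered collection of spectra plus free-text provenance.

    ``dropped`` records spectra that could not be parsed (one message each);
    replicate scans of the same specimen-patch are allowed.
    """

    spectra: list[ReflectanceSpectrum] = field(default_factory=list)
    provenance: str = ""
    dropped: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self):
        return iter(self.spectra)

    def reflectance_matrix(self) -> np.ndarray:
        """Stack all (on-grid) spectra into an (n, 81) matrix of percent."""
        return np.vstack([s.reflectance for s in self.spectra])

    def meta_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "species": [s.species for s in self.spectra],
                "order": [s.order for s in self.spectra],
                "sex": [s.sex for s in self.spectra],
                "specimen_id": [s.specimen_id for s in self.spectra],
                "patch": [s.patch for s in self.spectra],
            }
        )


@dataclass
class ValidationReport:
    off_grid: list[tuple[str, str, str, str]] = field(default_factory=list)
    out_of_range: list[tuple[str, str, str, str]] = field(default_factory=list)
    unknown_sex: list[tuple[str, str, str, str]] = field(default_factory=list)
    unknown_order: list[tuple[str, str, str, str]] = field(default_factory=list)
    duplicates: list[tuple[str, str, str, str]] = field(default_factory=list)

    @property
    def is_clean(self) -> bool:
        return not (
            self.off_grid
            or self.out_of_range
            or self.unknown_sex
            or self.unknown_order
            or self.duplicates
        )


LONG_COLUMNS = ("wavelength_nm", "reflectance_pct", "species", "order", "sex",
                "specimen_id", "patch")
META_COLUMNS = LONG_COLUMNS[2:]


def read_spectra(path, format: str = "long") -> SpectrumSet:
    """Read a delimited text file of reflectance spectra.

    ``format="long"``: columns wavelength_nm, reflectance_pct plus metadata
    columns (missing metadata filled with "unknown").  ``format="wide"``:
    first column wavelength_nm; every other column is one spectrum whose
    header encodes ``species|order|sex|specimen_id|patch``.

    Spectra with non-numeric reflectance are dropped and listed in
    ``SpectrumSet.dropped``.
    """
    df = pd.read_csv(path)
    if format == "long":
        return _read_long(df, str(path))
    if format == "wide":
        return _read_wide(df, str(path))
    raise ValueError(f"unknown format {format!r}")


def _read_long(df: pd.DataFrame, source: str) -> SpectrumSet:
    if "wavelength_nm" not in df.columns:
        raise FormatError(f"{source}: missing wavelength_nm column")
    if "reflectance_pct" not in df.columns:
        raise FormatError(f"{source}: missing reflectance_pct column")
    for col in META_COLUMNS:
        if col not in df.columns:
            df[col] = "unknown"
        df[col] = df[col].fillna("unknown").astype(str)
    out = SpectrumSet(provenance=f"long CSV {source}")
    refl = pd.to_numeric(df["reflectance_pct"], errors="coerce")
    for key, group in df.groupby(list(META_COLUMNS), sort=False):
        r = refl.loc[group.index]
        if r.isna().any():
            out.dropped.append(f"{'|'.join(key)}: non-numeric reflectance")
            continue
        g = group.sort_values("wavelength_nm")
        out.spectra.append(
            ReflectanceSpectrum(
                g["wavelength_nm"].to_numpy(float),
                r.loc[g.index].to_numpy(float),
                **dict(zip(META_COLUMNS, key)),
            )
        )
    return out


def _read_wide(df: pd.DataFrame, source: str) -> SpectrumSet:
    if "wavelength_nm" not in df.columns:
        raise FormatError(f"{source}: missing wavelength_nm column")
    wl = df["wavelength_nm"].to_numpy(float)
    out = SpectrumSet(provenance=f"wide CSV {source}")
    for col in df.columns:
        if col == "wavelength_nm":
            continue
        parts = col.split("|")
        meta = dict(zip(META_COLUMNS, parts + ["unknown"] * (5 - len(parts))))
        r = pd.to_numeric(df[col], errors="coerce")
        if r.isna().any():
            out.dropped.append(f"{col}: non-numeric reflectance")
            continue
        out.spectra.append(ReflectanceSpectrum(wl, r.to_numpy(float), **meta))
    return out


def resample(spectrum: ReflectanceSpectrum) -> ReflectanceSpectrum:
    """Linearly interpolate onto the 5 nm grid, clamping to [0, 100].

    Raises :class:`CoverageError` if the input does not span 300-700 nm.
    Idempotent: resampling an already-gridded spectrum reproduces it (up to
    the clamp).
    """
    wl = spectrum.wavelengths
    if wl[0] > GRID[0] or wl[-1] < GRID[-1]:
        raise CoverageError(
            f"spectrum {spectrum.key()} covers {wl[0]:g}-{wl[-1]:g} nm, "
            "needs 300-700 nm"
        )
    r = np.interp(GRID, wl, spectrum.reflectance)
    r = np.clip(r, 0.0, 100.0)
    return replace(spectrum, wavelengths=GRID.copy(), reflectance=r)


def resample_set(sset: SpectrumSet) -> SpectrumSet:
    return SpectrumSet(
        [resample(s) for s in sset], provenance=sset.provenance,
        dropped=list(sset.dropped),
    )


def average_replicates(sset: SpectrumSet) -> SpectrumSet:
    """Average replicate scans of the same (species, sex, specimen, patch).

    Replicates are collapsed at the reflectance level before visual
    modelling; spectra must already share the common grid.  Order of first
    appearance is preserved.
    """
    groups: dict[tuple, list[ReflectanceSpectrum]] = {}
    for s in sset:
        groups.setdefault(s.key(), []).append(s)
    out = SpectrumSet(provenance=sset.provenance, dropped=list(sset.dropped))
    for members in groups.values():
        first = members[0]
        if len(members) == 1:
            out.spectra.append(first)
        else:
            mean_r = np.mean([m.reflectance for m in members], axis=0)
            out.spectra.append(replace(first, reflectance=mean_r))
    return out


def validate_set(sset: SpectrumSet) -> ValidationReport:
    """Report (never fix) structural problems in a spectrum set."""
    report = ValidationReport()
    seen: dict[tuple, int] = {}
    for s in sset:
        k = s.key()
        if not s.on_grid:
            report.off_grid.append(k)
        elif np.any(s.reflectance < 0) or np.any(s.reflectance > 100):
            report.out_of_range.append(k)
        if s.sex not in SEXES:
            report.unknown_sex.append(k)
        if s.order == "unknown":
            report.unknown_order.append(k)
        seen[k] = seen.get(k, 0) + 1
    report.duplicates = [k for k, n in seen.items() if n > 1]
    return report


def write_long_csv(sset: SpectrumSet, path) -> None:
    """Write a set in the long-CSV dialect read by :func:`read_spectra`."""
    rows = []
    for s in sset:
        rows.append(
            pd.DataFrame(
                {
                    "wavelength_nm": s.wavelengths,
                    "reflectance_pct": s.reflectance,
                    "species": s.species,
                    "order": s.order,
                    "sex": s.sex,
                    "specimen_id": s.specimen_id,
                    "patch": s.patch,
                }
            )
        )
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)
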