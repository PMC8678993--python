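"""Band and massif quantification of FT-IR hyperspectral maps.

Each biochemical parameter is the baseline-corrected integrated absorbance
of one absorption band (or spectral massif), or the ratio of two such
integrals.  The baseline is "trapezoidal": a straight line through the mean
absorbance in short anchor sub-windows at the two edges of the integration
window, subtracted before integrating with the trapezoid rule.  A linear
(more generally affine-in-wavenumber) spectrum therefore integrates to
exactly zero.

The default parameter registry covers the standard brain-tissue band set:
amide I (1658 cm^-1) and its beta-sheet component (1635 cm^-1), the lipid
C-H stretching massif (2800-3000 cm^-1) with its 2924/2955 cm^-1
sub-bands, phosphate/nucleic-acid bands (1080, 1240 cm^-1), the
CH2/CH3-bending massif of lipids and cholesterol (1360-1480 cm^-1) and the
carbonyl ester band (1740 cm^-1) — 6 absolute parameters and 11 ratios.
Window limits and anchor widths are defaults and fully overridable via a
YAML registry file.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping

import numpy as np

from .io import SpectralMap


class DomainError(ValueError):
    """Integration window falls outside the spectral axis."""


class ResolutionError(ValueError):
    """Too few channels inside the integration window."""


@dataclass(frozen=True)
class BandDefinition:
    """Quantification recipe for one band or massif.

    ``window`` is a closed interval [lo, hi] in cm^-1; ``anchor_halfwidth``
    is the half-width (cm^-1) of the edge sub-windows whose mean absorbance
    anchors the baseline; ``mode`` selects integrated area (AU*cm^-1) or
    baseline-corrected peak height (AU).
    """

    name: str
    window: tuple[float, float]
    anchor_halfwidth: float = 8.0
    mode: str = "area"

    def __post_init__(self) -> None:
        lo, hi = self.window
        if not lo < hi:
            raise ValueError(f"band {self.name!r}: window lo must be < hi")
        if self.anchor_halfwidth < 0:
            raise ValueError(f"band {self.name!r}: anchor half-width must be >= 0")
        if self.mode not in ("area", "height"):
            raise ValueError(f"band {self.name!r}: mode must be 'area' or 'height'")


@dataclass(frozen=True)
class ParameterSpec:
    """A named biochemical parameter: one band, or a ratio of two bands."""

    name: str
    numerator: BandDefinition
    denominator: BandDefinition | None = None

    @property
    def is_ratio(self) -> bool:
        return self.denominator is not None


@dataclass
class ChemicalMap:
    """2-D image of a parameter over a tissue section.

    Invalid pixels (ratio denominator below the floor, or masked out) carry
    value 0.0 and ``valid == False``; they are never NaN/Inf.
    """

    values: np.ndarray
    name: str
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.values.shape != self.valid.shape:
            raise ValueError("values and validity mask shapes differ")


def _baseline_anchors(
    wn: np.ndarray, ab: np.ndarray, edge: float, halfwidth: float
) -> tuple[float, np.ndarray]:
    """Mean wavenumber and mean absorbance in the anchor window around an edge.

    Returns (x, y) where y has the leading shape of ``ab`` (anything x
    channels).  Falls back to linear interpolation at the edge when no
    channel lies inside the anchor window.  Using the mean *wavenumber* of
    the anchor channels (not the nominal edge) as the abscissa makes the
    subtraction exactly annihilate affine spectra.
    """
    sel = (wn >= edge - halfwidth) & (wn <= edge + halfwidth)
    if not sel.any():
        y = np.apply_along_axis(lambda s: np.interp(edge, wn, s), -1, ab)
        return float(edge), y
    return float(wn[sel].mean()), ab[..., sel].mean(axis=-1)


def _corrected_window(
    ab: np.ndarray, wn: np.ndarray, band: BandDefinition
) -> tuple[np.ndarray, np.ndarray]:
    """Baseline-corrected absorbance restricted to the band window.

    ``ab`` may be a single spectrum (channels,) or a cube (..., channels).
    Returns (corrected, window_wavenumbers).
    """
    lo, hi = band.window
    if lo < wn[0] or hi > wn[-1]:
        raise DomainError(
            f"band {band.name!r}: window [{lo}, {hi}] outside axis "
            f"[{wn[0]}, {wn[-1]}]"
        )
    sel = (wn >= lo) & (wn <= hi)
    if sel.sum() < 2:
        raise ResolutionError(
            f"band {band.name!r}: only {int(sel.sum())} channel(s) in window"
        )
    xlo, ylo = _baseline_anchors(wn, ab, lo, band.anchor_halfwidth)
    xhi, yhi = _baseline_anchors(wn, ab, hi, band.anchor_halfwidth)
    w = wn[sel]
    if xhi == xlo:  # degenerate anchors: flat baseline
        baseline = np.broadcast_to(ylo[..., None], ab[..., sel].shape)
    else:
        slope = (yhi - ylo) / (xhi - xlo)
        baseline = ylo[..., None] + slope[..., None] * (w - xlo)
    return ab[..., sel] - baseline, w


def integrate_band(
    spectrum: np.ndarray, wavenumbers: np.ndarray, band: BandDefinition
) -> float:
    """Baseline-corrected integral (or peak height) of one spectrum.

    Area mode returns the trapezoid-rule integral of (spectrum - baseline)
    over the window in AU*cm^-1; it may be negative and is not clipped.
    Height mode returns max(spectrum - baseline) within the window, in AU.
    """
    spectrum = np.asarray(spectrum, dtype=float)
    wavenumbers = np.asarray(wavenumbers, dtype=float)
    corr, w = _corrected_window(spectrum, wavenumbers, band)
    if band.mode == "height":
        return float(corr.max())
    return float(np.trapezoid(corr, w))


def integrate_cube(
    cube: np.ndarray, wavenumbers: np.ndarray, band: BandDefinition
) -> np.ndarray:
    """Vectorized :func:`integrate_band` over a (rows, cols, channels) cube."""
    corr, w = _corrected_window(np.asarray(cube, dtype=float), wavenumbers, band)
    if band.mode == "height":
        return corr.max(axis=-1)
    return np.trapezoid(corr, w, axis=-1)


def compute_parameter(
    smap: SpectralMap,
    spec: ParameterSpec,
    denominator_floor: float = 1e-3,
    clip_negative: bool = False,
) -> ChemicalMap:
    """Per-pixel chemical map of one parameter.

    Ratio pixels whose denominator magnitude falls below
    ``denominator_floor`` (AU*cm^-1) are marked invalid and set to 0; they
    are excluded from all downstream statistics rather than silently kept.
    Negative corrected areas are retained unless ``clip_negative`` is set
    (silent clipping would bias group means).
    """
    num = integrate_cube(smap.absorbance, smap.wavenumbers, spec.numerator)
    valid = np.ones(num.shape, dtype=bool)
    if spec.denominator is not None:
        den = integrate_cube(smap.absorbance, smap.wavenumbers, spec.denominator)
        valid &= np.abs(den) >= denominator_floor
        values = np.zeros_like(num)
        np.divide(num, den, out=values, where=valid)
    else:
        values = num
    if clip_negative:
        values = np.clip(values, 0.0, None)
    values = np.where(valid, values, 0.0)
    return ChemicalMap(values, spec.name, valid)


def tissue_mask(
    smap: SpectralMap,
    threshold: float,
    band: BandDefinition | None = None,
) -> np.ndarray:
    """Boolean tissue footprint: amide-I integrated area >= threshold."""
    if threshold < 0:
        raise ValueError("tissue threshold must be >= 0")
    if band is None:
        band = default_bands()["amide_I"]
    area = integrate_cube(smap.absorbance, smap.wavenumbers, band)
    mask = area >= threshold
    if not mask.any():
        warnings.warn("tissue threshold above global maximum: empty tissue mask")
    return mask


# ---------------------------------------------------------------------------
# default registry

#: (name, window) of the default band set.  Single bands use a +-24 cm^-1
#: window around the nominal center; the amide-I sub-bands use +-8 cm^-1 so
#: the 1635/1658 windows stay disjoint; massifs use their conventional ranges.
_DEFAULT_BAND_WINDOWS: tuple[tuple[str, tuple[float, float]], ...] = (
    ("amide_I", (1650.0, 1666.0)),          # 1658 cm^-1, alpha-helix C=O
    ("beta_1635", (1627.0, 1643.0)),        # beta-sheet amide-I component
    ("lipid_massif", (2800.0, 3000.0)),     # C-H stretching massif
    ("ch2_2924", (2900.0, 2948.0)),         # asym CH2 stretch
    ("ch3_2955", (2931.0, 2979.0)),         # asym CH3 stretch
    ("phosphate_1080", (1056.0, 1104.0)),   # PO2-/carbohydrate
    ("phosphate_1240", (1216.0, 1264.0)),   # PO2- asym / nucleic acids
    ("chol_massif", (1360.0, 1480.0)),      # CH2/CH3 bending, cholesterol
    ("ester_1740", (1716.0, 1764.0)),       # C=O ester / carbonyl
)


#: The narrow amide-I sub-bands use half-size anchors: +-8 cm^-1 anchors on
#: a +-8 cm^-1 window would reach into the neighbouring sub-band's flank and
#: leak its amplitude into the baseline.
_NARROW_ANCHORS = {"amide_I": 4.0, "beta_1635": 4.0}


def default_bands(anchor_halfwidth: float = 8.0) -> dict[str, BandDefinition]:
    return {
        name: BandDefinition(
            name, window,
            anchor_halfwidth=min(anchor_halfwidth, _NARROW_ANCHORS.get(name, anchor_halfwidth)),
        )
        for name, window in _DEFAULT_BAND_WINDOWS
    }


#: parameter name -> (numerator band, denominator band or None)
_DEFAULT_PARAMETERS: tuple[tuple[str, str, str | None], ...] = (
    ("1658", "amide_I", None),
    ("2800-3000", "lipid_massif", None),
    ("1080", "phosphate_1080", None),
    ("1240", "phosphate_1240", None),
    ("1360-1480", "chol_massif", None),
    ("1740", "ester_1740", None),
    ("1635/1658", "beta_1635", "amide_I"),
    ("2924/2955", "ch2_2924", "ch3_2955"),
    ("2800-3000/1658", "lipid_massif", "amide_I"),
    ("1080/1658", "phosphate_1080", "amide_I"),
    ("1240/1658", "phosphate_1240", "amide_I"),
    ("1740/1658", "ester_1740", "amide_I"),
    ("1360-1480/1658", "chol_massif", "amide_I"),
    ("1080/2800-3000", "phosphate_1080", "lipid_massif"),
    ("1240/2800-3000", "phosphate_1240", "lipid_massif"),
    ("1740/2800-3000", "ester_1740", "lipid_massif"),
    ("1360-1480/2800-3000", "chol_massif", "lipid_massif"),
)


def default_registry(anchor_halfwidth: float = 8.0) -> dict[str, ParameterSpec]:
    """The 17 default biochemical parameters (6 absolute + 11 ratios)."""
    bands = default_bands(anchor_halfwidth)
    return {
        name: ParameterSpec(name, bands[num], bands[den] if den else None)
        for name, num, den in _DEFAULT_PARAMETERS
    }


def get_parameter(name: str, registry: Mapping[str, ParameterSpec] | None = None) -> ParameterSpec:
    registry = registry if registry is not None else default_registry()
    try:
        return registry[name]
    except KeyError:
        raise KeyError(
            f"unknown parameter {name!r}; known: {sorted(registry)}"
        ) from None


def registry_from_yaml(path: str | Path) -> dict[str, ParameterSpec]:
    """Load a parameter registry from a YAML file.

    Schema::

        bands:
          amide_I: {window: [1650, 1666], anchor_halfwidth: 8, mode: area}
        parameters:
          "1658": {numerator: amide_I}
          "1635/1658": {numerator: beta_1635, denominator: amide_I}

    Bands not listed fall back to the defaults, so a file may override just
    the integration limits it knows better (e.g. instrument-specific ones).
    """
    import yaml

    cfg = yaml.safe_load(Path(path).read_text())
    bands = default_bands()
    for name, b in (cfg.get("bands") or {}).items():
        bands[name] = BandDefinition(
            name,
            tuple(float(x) for x in b["window"]),
            anchor_halfwidth=float(b.get("anchor_halfwidth", 8.0)),
            mode=b.get("mode", "area"),
        )
    params = cfg.get("parameters")
    if not params:
        return {
            name: ParameterSpec(name, bands[num], bands[den] if den else None)
            for name, num, den in _DEFAULT_PARAMETERS
        }
    registry = {}
    for name, p in params.items():
        den = p.get("denominator")
        registry[name] = ParameterSpec(name, bands[p["numerator"]], bands[den] if den else None)
    return registry
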