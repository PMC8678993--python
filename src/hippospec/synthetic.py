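"""Synthetic FT-IR tissue phantoms and seizure logs with known ground truth.

A phantom is a layered section of the hippocampal formation rendered as a
hyperspectral cube: horizontal stripes for the molecular (MO), granular
(GR), pyramidal (PY) and multiform (MU) layers inside a background margin.
Each layer's noiseless spectrum is a sum of Gaussian absorption bands at
the standard brain-tissue wavenumbers (amide I/II, the beta-sheet
component, phosphate and carbonyl bands, the C-H stretching and
CH2/CH3-bending massifs).  Group x layer biochemical anomalies are planted
as multiplicative factors on band amplitudes, so every downstream estimate
can be checked against a closed-form truncated-Gaussian area.

On top of the deterministic composition the generator adds, per pixel,
i.i.d. Gaussian absorbance noise and a low-order polynomial baseline
drift, and, per animal, lognormal band-amplitude scatter plus a global
section-thickness factor — the minimal ingredients needed for the group
comparison to face realistic between-animal variability.

Synthetic seizure logs plant severity tiers: daily clonic/tonic intensity
(integer scales, clonic 0-5, tonic 0-3) and durations drawn around
tier-specific means over a 21-day stimulation protocol, with independent
clonic and tonic tier assignments per animal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .bands import BandDefinition, ParameterSpec, default_registry
from .io import LAYERS, LayerMask, SeizureLog, SpectralMap

SQRT2PI = math.sqrt(2.0 * math.pi)


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class BandModel:
    """One Gaussian (optionally Lorentzian) absorption component."""

    center: float  # cm^-1
    width: float  # standard deviation (Gaussian) / HWHM (Lorentzian), cm^-1
    amplitude: float  # AU
    shape: str = "gaussian"

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ConfigurationError(f"band at {self.center}: width must be > 0")
        if self.amplitude < 0:
            raise ConfigurationError(f"band at {self.center}: amplitude must be >= 0")
        if self.shape not in ("gaussian", "lorentzian"):
            raise ConfigurationError(f"band at {self.center}: unknown shape {self.shape!r}")

    def evaluate(self, wn: np.ndarray) -> np.ndarray:
        x = (wn - self.center) / self.width
        if self.shape == "gaussian":
            return self.amplitude * np.exp(-0.5 * x * x)
        return self.amplitude / (1.0 + x * x)

    def area(self, lo: float | None = None, hi: float | None = None) -> float:
        """Closed-form area, truncated to [lo, hi] when given."""
        if self.shape == "gaussian":
            full = self.amplitude * self.width * SQRT2PI
            if lo is None and hi is None:
                return full
            a = -np.inf if lo is None else (lo - self.center) / self.width
            b = np.inf if hi is None else (hi - self.center) / self.width
            from scipy.stats import norm

            return full * float(norm.cdf(b) - norm.cdf(a))
        full = self.amplitude * self.width * math.pi
        if lo is None and hi is None:
            return full
        a = -math.inf if lo is None else (lo - self.center) / self.width
        b = math.inf if hi is None else (hi - self.center) / self.width
        return self.amplitude * self.width * (math.atan(b) - math.atan(a))


@dataclass(frozen=True)
class EffectEntry:
    """Multiplicative anomaly on a band amplitude for one group x layer.

    ``band`` is either a single model-band center or a (lo, hi) wavenumber
    range (a massif: the factor applies to every component band whose
    center falls inside the range).
    """

    group: str
    layer: str
    band: float | tuple[float, float]
    factor: float

    def __post_init__(self) -> None:
        if self.factor <= 0:
            raise ConfigurationError("effect factors must be > 0")
        if self.group not in ("N", "K"):
            raise ConfigurationError(f"unknown group {self.group!r}")
        if self.layer not in LAYERS:
            raise ConfigurationError(f"unknown layer {self.layer!r}")

    def applies(self, group: str, layer: str, center: float) -> bool:
        if group != self.group or layer != self.layer:
            return False
        if isinstance(self.band, tuple):
            lo, hi = self.band
            return lo <= center <= hi
        return math.isclose(center, self.band)


@dataclass(frozen=True)
class EffectMap:
    entries: tuple[EffectEntry, ...] = ()

    def factor(self, group: str, layer: str, center: float) -> float:
        f = 1.0
        for e in self.entries:
            if e.applies(group, layer, center):
                f *= e.factor
        return f


def default_effects(magnitude: float = 0.15) -> EffectMap:
    """The significant group-K anomalies reported for this model, as factors.

    Directions: raised beta-sheet component (1635) in MO; raised 1080 in
    GR+PY; lowered 1240 in MU+MO; raised carbonyl 1740 in all layers;
    lowered CH2/CH3-bending massif (1360-1480) in all layers; raised lipid
    C-H massif in PY.  The magnitude is a free parameter (the study reports
    significance, not effect sizes); default +-15%.
    """
    up, down = 1.0 + magnitude, 1.0 - magnitude
    entries = [
        EffectEntry("K", "MO", 1635.0, up),
        EffectEntry("K", "GR", 1080.0, up),
        EffectEntry("K", "PY", 1080.0, up),
        EffectEntry("K", "MU", 1240.0, down),
        EffectEntry("K", "MO", 1240.0, down),
        EffectEntry("K", "PY", (2800.0, 3000.0), up),
    ]
    for layer in LAYERS:
        entries.append(EffectEntry("K", layer, 1740.0, up))
        entries.append(EffectEntry("K", layer, (1360.0, 1480.0), down))
    return EffectMap(tuple(entries))


def null_effects() -> EffectMap:
    return EffectMap(())


# ---------------------------------------------------------------------------
# layer composition

#: Base band amplitudes (AU) per layer, reflecting the broad compositional
#: contrasts of hippocampal cytoarchitecture: cell-body layers (GR, PY)
#: richer in nucleic acids/protein, neuropil layers (MU, MO) in lipid.
#: (center, width sigma) -> {layer: amplitude}.  The amide-I sub-bands are
#: kept narrow (sigma 2.5) so the +-8 cm^-1 quantification windows resolve
#: them; real protein bands are far broader, a deliberate idealization.
_BASE_COMPOSITION: tuple[tuple[float, float, dict[str, float]], ...] = (
    (1080.0, 10.0, {"GR": 0.45, "PY": 0.40, "MU": 0.30, "MO": 0.28}),
    (1240.0, 12.0, {"GR": 0.35, "PY": 0.32, "MU": 0.26, "MO": 0.24}),
    (1400.0, 15.0, {"GR": 0.25, "PY": 0.28, "MU": 0.30, "MO": 0.26}),
    (1455.0, 12.0, {"GR": 0.20, "PY": 0.22, "MU": 0.24, "MO": 0.21}),
    (1545.0, 12.0, {"GR": 0.55, "PY": 0.60, "MU": 0.50, "MO": 0.48}),  # amide II
    (1635.0, 2.5, {"GR": 0.30, "PY": 0.32, "MU": 0.28, "MO": 0.26}),
    (1658.0, 2.5, {"GR": 0.95, "PY": 1.00, "MU": 0.85, "MO": 0.80}),
    (1740.0, 8.0, {"GR": 0.12, "PY": 0.13, "MU": 0.12, "MO": 0.11}),
    (2850.0, 10.0, {"GR": 0.40, "PY": 0.45, "MU": 0.50, "MO": 0.42}),
    (2924.0, 10.0, {"GR": 0.55, "PY": 0.60, "MU": 0.65, "MO": 0.55}),
    (2955.0, 8.0, {"GR": 0.35, "PY": 0.38, "MU": 0.40, "MO": 0.35}),
    (3290.0, 60.0, {"GR": 0.70, "PY": 0.75, "MU": 0.65, "MO": 0.62}),  # amide A
)


def layer_bands(
    layer: str,
    group: str = "N",
    effects: EffectMap | None = None,
    band_scale: dict[float, float] | None = None,
    global_scale: float = 1.0,
    shape: str = "gaussian",
    composition: tuple[tuple[float, float, dict[str, float]], ...] | None = None,
) -> list[BandModel]:
    """Band models for one layer with effects and per-animal scatter applied."""
    effects = effects or null_effects()
    out = []
    for center, width, amps in (composition or _BASE_COMPOSITION):
        a = amps[layer] * global_scale * effects.factor(group, layer, center)
        if band_scale:
            a *= band_scale.get((layer, center), band_scale.get(center, 1.0))
        out.append(BandModel(center, width, a, shape=shape))
    return out


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, spectral axis and noise model of one phantom section.

    Layers are horizontal stripes; ``layer_fractions`` splits the tissue
    rows (image rows minus the background margin) top to bottom.  The
    default geometry guarantees, after 1-pixel border erosion, at least
    120/150/300/300 pixels for GR/PY/MU/MO.
    """

    shape: tuple[int, int] = (48, 50)
    margin: int = 2
    layer_fractions: tuple[tuple[str, float], ...] = (
        ("MO", 13 / 44),
        ("GR", 8 / 44),
        ("PY", 8 / 44),
        ("MU", 15 / 44),
    )
    wn_start: float = 900.0
    wn_stop: float = 4000.0
    wn_step: float = 4.0
    noise_sigma: float = 0.005  # AU, additive i.i.d. Gaussian
    drift_order: int = 2  # per-pixel polynomial baseline drift
    drift_scale: float = 0.01  # AU, sd of drift coefficients
    animal_sigma: float = 0.05  # lognormal per-band amplitude scatter
    thickness_sigma: float = 0.05  # lognormal global section-thickness scatter
    band_shape: str = "gaussian"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.wn_step <= 0:
            raise ConfigurationError("wavenumber step must be > 0")
        if self.wn_stop <= self.wn_start:
            raise ConfigurationError("wavenumber stop must exceed start")
        if self.margin < 0 or min(self.shape) <= 2 * self.margin:
            raise ConfigurationError("image too small for the background margin")

    @property
    def wavenumbers(self) -> np.ndarray:
        n = int(round((self.wn_stop - self.wn_start) / self.wn_step)) + 1
        return self.wn_start + self.wn_step * np.arange(n)

    def layer_rows(self) -> dict[str, tuple[int, int]]:
        """Row span [start, stop) of each layer stripe."""
        tissue_rows = self.shape[0] - 2 * self.margin
        spans: dict[str, tuple[int, int]] = {}
        start = self.margin
        fracs = list(self.layer_fractions)
        total = sum(f for _, f in fracs)
        for i, (layer, frac) in enumerate(fracs):
            if i == len(fracs) - 1:
                stop = self.margin + tissue_rows
            else:
                stop = start + int(round(frac / total * tissue_rows))
            if stop <= start:
                raise ConfigurationError(f"layer {layer!r} has zero pixels")
            spans[layer] = (start, stop)
            start = stop
        return spans


def build_mask(config: PhantomConfig) -> LayerMask:
    labels = np.zeros(config.shape, dtype=int)
    legend = {0: "background"}
    c0, c1 = config.margin, config.shape[1] - config.margin
    for idx, (layer, (r0, r1)) in enumerate(config.layer_rows().items(), start=1):
        labels[r0:r1, c0:c1] = idx
        legend[idx] = layer
    return LayerMask(labels, legend)


def ground_truth_table(
    config: PhantomConfig,
    effects: EffectMap,
    group: str,
    registry: dict[str, ParameterSpec] | None = None,
    band_scale: dict[float, float] | None = None,
    global_scale: float = 1.0,
    composition: tuple[tuple[float, float, dict[str, float]], ...] | None = None,
) -> pd.DataFrame:
    """Noiseless parameter values per layer, from closed-form band areas.

    A parameter's band integral is the sum of truncated areas of the model
    components whose centers fall inside its integration window (no
    baseline, no cross-talk) — the analytic reference the measured maps are
    compared against.
    """
    registry = registry or default_registry()

    def band_area(band: BandDefinition, models: Sequence[BandModel]) -> float:
        lo, hi = band.window
        return sum(m.area(lo, hi) for m in models if lo <= m.center <= hi)

    rows = []
    for layer in LAYERS:
        models = layer_bands(
            layer, group, effects, band_scale=band_scale, global_scale=global_scale,
            shape=config.band_shape, composition=composition,
        )
        for name, spec in registry.items():
            v = band_area(spec.numerator, models)
            if spec.denominator is not None:
                den = band_area(spec.denominator, models)
                v = v / den if den != 0 else np.nan
            rows.append({"layer": layer, "parameter": name, "value": v})
    return pd.DataFrame(rows)


def make_phantom(
    config: PhantomConfig,
    effects: EffectMap | None = None,
    group: str = "N",
    animal_id: str = "",
    rng: np.random.Generator | None = None,
    composition: tuple[tuple[float, float, dict[str, float]], ...] | None = None,
) -> tuple[SpectralMap, LayerMask, pd.DataFrame]:
    """Generate one phantom section: cube, mask and its ground-truth table.

    The returned ground truth reflects the *realized* composition of this
    animal (planted effects times the drawn per-band scatter), so planted
    multiplicative effects appear exactly as ratios of ground-truth values.
    """
    if group not in ("N", "K"):
        raise ConfigurationError(f"group must be 'N' or 'K', got {group!r}")
    effects = effects or null_effects()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    wn = config.wavenumbers
    mask = build_mask(config)

    table = composition or _BASE_COMPOSITION
    centers = [c for c, _, _ in table]
    # biological between-animal scatter, independent per layer and band:
    # layer compositions are not rigidly coupled across the formation
    band_scale = {
        (layer, c): (
            float(np.exp(rng.normal(0.0, config.animal_sigma)))
            if config.animal_sigma > 0 else 1.0
        )
        for layer in LAYERS
        for c in centers
    }
    thickness = float(np.exp(rng.normal(0.0, config.thickness_sigma))) if config.thickness_sigma > 0 else 1.0

    cube = np.zeros(config.shape + (wn.size,), dtype=float)
    for layer in LAYERS:
        spectrum = np.zeros_like(wn)
        for m in layer_bands(
            layer, group, effects, band_scale, thickness, config.band_shape, table
        ):
            spectrum += m.evaluate(wn)
        cube[mask.layer_pixels(layer)] = spectrum

    if config.drift_order >= 0 and config.drift_scale > 0:
        x = (wn - wn.mean()) / ((wn[-1] - wn[0]) / 2.0)  # [-1, 1]
        coeffs = rng.normal(0.0, config.drift_scale, size=config.shape + (config.drift_order + 1,))
        drift = np.zeros_like(cube)
        xp = np.ones_like(wn)
        for p in range(config.drift_order + 1):
            drift += coeffs[..., p:p + 1] * xp
            xp = xp * x
        cube += drift
    if config.noise_sigma > 0:
        cube += rng.normal(0.0, config.noise_sigma, size=cube.shape)

    smap = SpectralMap(cube, wn, animal_id=animal_id, group=group)
    gt = ground_truth_table(
        config, effects, group, band_scale=band_scale, global_scale=thickness,
        composition=composition,
    )
    gt.insert(0, "animal_id", animal_id)
    return smap, mask, gt


# ---------------------------------------------------------------------------
# seizure logs


@dataclass(frozen=True)
class TierSpec:
    """One planted severity tier of a seizure type."""

    n: int
    intensity_mean: float
    intensity_sd: float
    duration_mean: float  # s per day
    duration_sd: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ConfigurationError("tier size must be >= 1")
        for sd in (self.intensity_sd, self.duration_sd):
            if sd < 0:
                raise ConfigurationError("tier dispersions must be >= 0")


@dataclass(frozen=True)
class SeizureSimConfig:
    """Planted clonic/tonic severity tiers over a daily stimulation protocol.

    Tiers are ordered most to least severe.  Tonic intensities live on the
    0-3 extension scale; clonic intensities on a 0-``clonic_scale_max``
    limbic-seizure scale.  Clonic and tonic tier memberships are assigned
    independently (a permutation decouples them).
    """

    days: int = 21
    clonic_tiers: tuple[TierSpec, ...] = (
        TierSpec(5, 4.0, 0.7, 120.0, 25.0),   # severe (CS-like)
        TierSpec(5, 2.0, 0.7, 45.0, 12.0),    # intermediate (ICS-like)
        TierSpec(6, 0.3, 0.5, 5.0, 3.0),      # light (LCS-like)
    )
    tonic_tiers: tuple[TierSpec, ...] = (
        TierSpec(8, 2.2, 0.5, 30.0, 8.0),     # severe (TS-like)
        TierSpec(8, 0.5, 0.5, 5.0, 2.0),      # light (LTS-like)
    )
    clonic_scale_max: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.days < 1:
            raise ConfigurationError("days must be >= 1")
        if sum(t.n for t in self.clonic_tiers) != sum(t.n for t in self.tonic_tiers):
            raise ConfigurationError("clonic and tonic tiers must cover the same animals")

    @classmethod
    def for_cohort(cls, n: int, **kwargs) -> "SeizureSimConfig":
        """Default tier means/dispersions rescaled to an n-animal cohort."""
        base = cls(**kwargs) if kwargs else cls()

        def resize(tiers: tuple[TierSpec, ...]) -> tuple[TierSpec, ...]:
            k = min(len(tiers), n)
            sizes = [n // k + (1 if i < n % k else 0) for i in range(k)]
            from dataclasses import replace as _replace

            return tuple(_replace(t, n=s) for t, s in zip(tiers[:k], sizes))

        from dataclasses import replace as _replace

        return _replace(base, clonic_tiers=resize(base.clonic_tiers),
                        tonic_tiers=resize(base.tonic_tiers))


def _draw_daily(
    rng: np.random.Generator, tier: TierSpec, days: int, scale_max: int
) -> tuple[np.ndarray, np.ndarray]:
    intensity = np.rint(rng.normal(tier.intensity_mean, tier.intensity_sd, days)) if tier.intensity_sd > 0 else np.full(days, round(tier.intensity_mean), dtype=float)
    intensity = np.clip(intensity, 0, scale_max).astype(int)
    duration = rng.normal(tier.duration_mean, tier.duration_sd, days) if tier.duration_sd > 0 else np.full(days, tier.duration_mean)
    duration = np.clip(duration, 0.0, None)
    duration[intensity == 0] = 0.0  # no seizure, no duration
    return intensity, duration


def make_seizure_logs(
    config: SeizureSimConfig,
    animal_ids: Sequence[str] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[SeizureLog], pd.DataFrame]:
    """Generate per-animal logs plus the planted tier assignments.

    Returns (logs, assignments) where assignments has columns animal_id,
    clonic_tier, tonic_tier (0 = most severe tier).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = sum(t.n for t in config.clonic_tiers)
    if animal_ids is None:
        animal_ids = [f"K{i + 1:02d}" for i in range(n)]
    if len(animal_ids) != n:
        raise ConfigurationError(f"{len(animal_ids)} ids for {n} configured animals")

    clonic_tier = np.repeat(np.arange(len(config.clonic_tiers)), [t.n for t in config.clonic_tiers])
    tonic_tier = np.repeat(np.arange(len(config.tonic_tiers)), [t.n for t in config.tonic_tiers])
    tonic_tier = tonic_tier[rng.permutation(n)]  # decouple the two assignments

    logs = []
    for i, aid in enumerate(animal_ids):
        ci, cd = _draw_daily(rng, config.clonic_tiers[clonic_tier[i]], config.days, config.clonic_scale_max)
        ti, td = _draw_daily(rng, config.tonic_tiers[tonic_tier[i]], config.days, 3)
        rec = pd.DataFrame(
            {
                "day": np.arange(1, config.days + 1),
                "clonic_intensity": ci,
                "clonic_duration_s": cd,
                "tonic_intensity": ti,
                "tonic_duration_s": td,
            }
        )
        logs.append(SeizureLog(str(aid), rec, n_days=config.days))
    assignments = pd.DataFrame(
        {"animal_id": list(animal_ids), "clonic_tier": clonic_tier, "tonic_tier": tonic_tier}
    )
    return logs, assignments
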