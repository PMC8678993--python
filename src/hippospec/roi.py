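"""Layer-wise pixel extraction, per-animal aggregation and group comparison.

Pixels are pooled per cellular layer after eroding the layer region
(border exclusion), averaged to one value per animal x layer x parameter,
quality-controlled against minimum pixel counts, and compared between
groups/subgroups with the two-sided Mann-Whitney U test at alpha = 0.05.
Raw p-values decide significance (per-comparison 5% level);
Benjamini-Hochberg adjusted p-values are reported alongside for
transparency but do not drive the default flag.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

from .bands import ChemicalMap
from .io import LayerMask

#: Default minimum pixel counts per layer (granular, pyramidal, and the
#: "several hundred" for multiform/molecular interpreted as 300).
DEFAULT_PIXEL_MINIMA = {"GR": 120, "PY": 150, "MU": 300, "MO": 300}

#: 4-connected structuring element used for border-exclusion erosion.
_CROSS = ndimage.generate_binary_structure(2, 1)


class QCError(ValueError):
    pass


@dataclass
class LayerSummary:
    animal_id: str
    group: str
    layer: str
    parameter: str
    mean: float
    n_pixels: int
    qc_pass: bool


@dataclass
class ComparisonResult:
    parameter: str
    layer: str
    group1: str
    group2: str
    n1: int
    n2: int
    u: float
    p: float
    direction: str  # "up" / "down" / "none": group1's median vs group2's
    significant: bool


def extract_layer_pixels(
    cmap: ChemicalMap, mask: LayerMask, layer: str, erosion: int = 1
) -> np.ndarray:
    """Valid parameter values in one layer after border erosion.

    The layer region is morphologically eroded ``erosion`` times with a
    4-connected cross (image borders count as outside), mirroring the
    manual practice of avoiding pixels at layer borders; only pixels that
    survive erosion *and* are valid in the chemical map are returned.
    """
    if erosion < 0:
        raise ValueError("erosion radius must be >= 0")
    region = mask.layer_pixels(layer)  # raises KeyError if layer unknown
    if not region.any():
        raise QCError(f"layer {layer!r} has no pixels in the mask")
    if region.shape != cmap.values.shape:
        raise ValueError("mask and chemical map shapes differ")
    if erosion > 0:
        region = ndimage.binary_erosion(
            region, structure=_CROSS, iterations=erosion, border_value=0
        )
    return cmap.values[region & cmap.valid]


def summarize_animal(
    values: np.ndarray, minimum: int = 1
) -> tuple[float, int, bool]:
    """Per-animal mean with pixel count and QC flag (count >= minimum)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise QCError("no pixels to summarize")
    return float(values.mean()), int(values.size), bool(values.size >= minimum)


def summarize_layers(
    cmaps: dict[str, ChemicalMap],
    mask: LayerMask,
    animal_id: str,
    group: str,
    erosion: int = 1,
    pixel_minima: dict[str, int] | None = None,
) -> list[LayerSummary]:
    """All layer x parameter summaries for one animal's chemical maps."""
    minima = pixel_minima or DEFAULT_PIXEL_MINIMA
    out = []
    for layer in minima:
        for name, cmap in cmaps.items():
            values = extract_layer_pixels(cmap, mask, layer, erosion=erosion)
            if values.size == 0:
                out.append(LayerSummary(animal_id, group, layer, name, float("nan"), 0, False))
                continue
            mean, n, ok = summarize_animal(values, minimum=minima[layer])
            out.append(LayerSummary(animal_id, group, layer, name, mean, n, ok))
    return out


def summaries_frame(summaries: list[LayerSummary]) -> pd.DataFrame:
    return pd.DataFrame([vars(s) for s in summaries])


def mann_whitney(
    x: np.ndarray,
    y: np.ndarray,
    alternative: str = "two-sided",
    alpha: float = 0.05,
    parameter: str = "",
    layer: str = "",
    group1: str = "",
    group2: str = "",
) -> ComparisonResult:
    """Mann-Whitney U comparison of two per-animal value sets.

    Exact p by enumeration of rank assignments when both samples have at
    most 9 observations and there are no ties; otherwise the normal
    approximation with tie and continuity corrections.  When every value
    in both samples is identical the test is degenerate: p = 1, direction
    "none".
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must contain at least one value")
    pooled = np.concatenate([x, y])
    if np.unique(pooled).size == 1:
        return ComparisonResult(
            parameter, layer, group1, group2, x.size, y.size,
            x.size * y.size / 2.0, 1.0, "none", False,
        )
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (x.size <= 9 and y.size <= 9 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    mx, my = float(np.median(x)), float(np.median(y))
    direction = "up" if mx > my else ("down" if mx < my else "none")
    p = float(min(res.pvalue, 1.0))
    return ComparisonResult(
        parameter, layer, group1, group2, x.size, y.size,
        float(res.statistic), p, direction, p < alpha,
    )


#: Subgroup comparison pairs per grouping scheme.
GROUPING_PAIRS = {
    "group": [("K", "N")],
    "clonic": [("CS", "N"), ("LCS", "N"), ("CS", "LCS")],
    "tonic": [("TS", "N"), ("LTS", "N"), ("TS", "LTS")],
}


def run_comparisons(
    summaries: pd.DataFrame,
    pairs: list[tuple[str, str]] | None = None,
    alpha: float = 0.05,
    group_column: str = "group",
    drop_qc_failures: bool = True,
) -> pd.DataFrame:
    """One Mann-Whitney comparison per parameter x layer x group pair.

    ``summaries`` must carry columns animal_id, layer, parameter, mean and
    the grouping column.  Animals failing pixel-count QC are excluded when
    ``drop_qc_failures`` (the default).  A Benjamini-Hochberg adjusted
    p-value column (``p_bh``) is appended over all rows of the table.
    """
    if pairs is None:
        labels = sorted(summaries[group_column].dropna().unique())
        pairs = list(itertools.combinations(labels, 2))
    if not pairs:
        raise ValueError("no group pairs to compare")
    known = set(summaries[group_column].dropna().unique())
    for g1, g2 in pairs:
        for g in (g1, g2):
            if g not in known:
                raise KeyError(f"unknown group label {g!r}; present: {sorted(known)}")
    df = summaries
    if drop_qc_failures and "qc_pass" in df.columns:
        df = df[df["qc_pass"]]
    rows = []
    for (parameter, layer), sub in df.groupby(["parameter", "layer"], sort=False):
        for g1, g2 in pairs:
            x = sub.loc[sub[group_column] == g1, "mean"].to_numpy()
            y = sub.loc[sub[group_column] == g2, "mean"].to_numpy()
            if x.size == 0 or y.size == 0:
                continue
            rows.append(vars(mann_whitney(
                x, y, alpha=alpha, parameter=parameter, layer=layer,
                group1=g1, group2=g2,
            )))
    result = pd.DataFrame(rows)
    if not result.empty:
        result["p_bh"] = multipletests(result["p"], method="fdr_bh")[1]
    return result
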