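"""End-to-end study orchestration: simulate or ingest, quantify, compare.

The full chain mirrors the study design: hyperspectral maps of 16
stimulated (K) and 10 control (N) animals are quantified into 17
biochemical parameters, averaged per animal and cellular layer, and
compared K vs N; stimulated animals are additionally subgrouped by Ward
clustering of their seizure logs (clonic k=3 -> CS/ICS/LCS, tonic k=2 ->
TS/LTS) and the severe/light subgroups are compared against controls.
A single seed fans out to per-stage substreams so any stage can be rerun
in isolation; all thresholds live in the run configuration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import bands, cluster, io, roi, synthetic


class StageError(RuntimeError):
    """An orchestration stage failed; the message names the stage."""


@dataclass
class RunConfig:
    manifest: str
    outdir: str = "run"
    registry: str | None = None  # YAML parameter registry; None = defaults
    erosion: int = 1
    pixel_minima: dict = field(default_factory=lambda: dict(roi.DEFAULT_PIXEL_MINIMA))
    alpha: float = 0.05
    denominator_floor: float = 1e-3
    k_clonic: int = 3
    k_tonic: int = 2
    standardize: bool = True
    linkage: str = "ward.d"
    n_days: int = 21
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        return cls(**yaml.safe_load(Path(path).read_text()))


def _registry(config: RunConfig):
    if config.registry:
        return bands.registry_from_yaml(config.registry)
    return bands.default_registry()


# ---------------------------------------------------------------------------
# simulation


def simulate_study(
    outdir: str | Path,
    seed: int = 0,
    n_k: int = 16,
    n_n: int = 10,
    phantom: synthetic.PhantomConfig | None = None,
    seizures: synthetic.SeizureSimConfig | None = None,
    effects: synthetic.EffectMap | None = None,
) -> Path:
    """Generate a full phantom study on disk; returns the manifest path.

    Control (N) animals receive all-zero seizure logs: they were never
    stimulated, and a zero record keeps the log table rectangular.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    phantom = phantom or synthetic.PhantomConfig()
    if effects is None:
        effects = synthetic.default_effects()
    ss = np.random.SeedSequence(seed)
    map_rng, log_rng = (np.random.default_rng(c) for c in ss.spawn(2))

    k_ids = [f"K{i + 1:02d}" for i in range(n_k)]
    n_ids = [f"N{i + 1:02d}" for i in range(n_n)]
    rows, gts = [], []
    for aid in k_ids + n_ids:
        group = "K" if aid.startswith("K") else "N"
        smap, mask, gt = synthetic.make_phantom(
            phantom, effects, group, animal_id=aid, rng=map_rng
        )
        io.write_map(smap, outdir / f"{aid}.h5")
        io.write_mask(mask, outdir / f"{aid}.mask.txt")
        gts.append(gt)
        rows.append(
            {"animal_id": aid, "group": group, "map": f"{aid}.h5",
             "mask": f"{aid}.mask.txt", "log": "logs.csv"}
        )

    seizures = seizures or synthetic.SeizureSimConfig.for_cohort(n_k)
    if sum(t.n for t in seizures.clonic_tiers) != n_k:
        raise synthetic.ConfigurationError("seizure tiers must cover the K animals")
    logs, tiers = synthetic.make_seizure_logs(seizures, animal_ids=k_ids, rng=log_rng)
    zero = pd.DataFrame(
        {"day": np.arange(1, seizures.days + 1), "clonic_intensity": 0,
         "clonic_duration_s": 0.0, "tonic_intensity": 0, "tonic_duration_s": 0.0}
    )
    logs = logs + [io.SeizureLog(aid, zero.copy(), n_days=seizures.days) for aid in n_ids]
    io.write_logs(logs, outdir / "logs.csv")
    tiers.to_csv(outdir / "ground_truth_tiers.csv", index=False)
    pd.concat(gts, ignore_index=True).to_csv(
        outdir / "ground_truth_parameters.tsv", sep="\t", index=False
    )
    manifest = io.StudyManifest(pd.DataFrame(rows))
    path = outdir / "manifest.csv"
    io.write_manifest(manifest, path)
    return path


# ---------------------------------------------------------------------------
# quantification + summarization


def quantify_animal(
    smap: io.SpectralMap,
    registry: dict[str, bands.ParameterSpec],
    denominator_floor: float = 1e-3,
) -> dict[str, bands.ChemicalMap]:
    return {
        name: bands.compute_parameter(smap, spec, denominator_floor=denominator_floor)
        for name, spec in registry.items()
    }


def summarize_study(
    animals: list[tuple[str, str, io.SpectralMap, io.LayerMask]],
    registry: dict[str, bands.ParameterSpec],
    erosion: int = 1,
    pixel_minima: dict[str, int] | None = None,
    denominator_floor: float = 1e-3,
) -> pd.DataFrame:
    """Per-animal x layer x parameter means for a loaded cohort."""
    summaries: list[roi.LayerSummary] = []
    for animal_id, group, smap, mask in animals:
        cmaps = quantify_animal(smap, registry, denominator_floor)
        summaries.extend(
            roi.summarize_layers(cmaps, mask, animal_id, group, erosion, pixel_minima)
        )
    return roi.summaries_frame(summaries)


def load_study(
    manifest_path: str | Path, n_days: int = 21
) -> tuple[list[tuple[str, str, io.SpectralMap, io.LayerMask]], list[io.SeizureLog]]:
    manifest = io.read_manifest(manifest_path)
    animals = []
    log_paths = {}
    for _, row in manifest.entries.iterrows():
        aid = str(row["animal_id"])
        try:
            smap = io.read_map(io.resolve_path(manifest_path, row["map"]))
            mask = io.read_mask(io.resolve_path(manifest_path, row["mask"]))
        except (OSError, io.FormatError) as exc:
            raise StageError(f"ingest: animal {aid}: {exc}") from exc
        if mask.labels.shape != smap.shape:
            raise StageError(f"ingest: animal {aid}: mask/map shape mismatch")
        animals.append((aid, str(row["group"]), smap, mask))
        log_paths[aid] = io.resolve_path(manifest_path, row["log"])
    logs: list[io.SeizureLog] = []
    seen = set()
    for aid, p in log_paths.items():
        if p in seen:
            continue
        seen.add(p)
        logs.extend(io.read_logs(p, n_days=n_days))
    by_id = {log.animal_id: log for log in logs}
    ordered = [by_id[a] for a in manifest.animals() if a in by_id]
    return animals, ordered


# ---------------------------------------------------------------------------
# full run


def run_study(config: RunConfig) -> dict:
    """Execute the full pipeline and write the result bundle to disk.

    Outputs under ``config.outdir``: the per-animal summary table, K-vs-N
    and subgroup comparison tables (TSV), subgroup assignments (CSV),
    clonic/tonic dendrograms (merge-list TSV + Newick) and a JSON run
    report with all configuration values and QC exclusions.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    registry = _registry(config)

    try:
        animals, logs = load_study(config.manifest, n_days=config.n_days)
    except (io.FormatError, io.ValidationError) as exc:
        raise StageError(f"ingest: {exc}") from exc

    try:
        summaries = summarize_study(
            animals, registry, config.erosion, config.pixel_minima,
            config.denominator_floor,
        )
    except Exception as exc:
        raise StageError(f"quantify: {exc}") from exc
    summaries.to_csv(outdir / "summaries.tsv", sep="\t", index=False)

    try:
        comparisons = roi.run_comparisons(
            summaries, roi.GROUPING_PAIRS["group"], alpha=config.alpha
        )
    except Exception as exc:
        raise StageError(f"compare: {exc}") from exc
    comparisons.to_csv(outdir / "comparisons_group.tsv", sep="\t", index=False)

    groups = dict(zip(
        (a for a, _, _, _ in animals), (g for _, g, _, _ in animals)
    ))
    k_logs = [log for log in logs if groups.get(log.animal_id) == "K"]
    result = {"summaries": summaries, "comparisons": {"group": comparisons}}
    subgroup_tables = {}
    if k_logs:
        try:
            assignment, dend_c, dend_t = cluster.assign_subgroups(
                k_logs, config.k_clonic, config.k_tonic,
                standardize=config.standardize, dialect=config.linkage,
            )
        except Exception as exc:
            raise StageError(f"cluster: {exc}") from exc
        assignment.to_csv(outdir / "subgroups.csv", index=False)
        for name, dend in (("clonic", dend_c), ("tonic", dend_t)):
            dend.to_frame().to_csv(outdir / f"dendrogram_{name}.tsv", sep="\t", index=False)
            (outdir / f"dendrogram_{name}.nwk").write_text(dend.to_newick())
        result["subgroups"] = assignment
        result["dendrograms"] = {"clonic": dend_c, "tonic": dend_t}

        label_map = {
            "clonic": dict(zip(assignment["animal_id"], assignment["clonic_label"])),
            "tonic": dict(zip(assignment["animal_id"], assignment["tonic_label"])),
        }
        ks = {"clonic": config.k_clonic, "tonic": config.k_tonic}
        for scheme in ("clonic", "tonic"):
            col = summaries["animal_id"].map(
                lambda a: label_map[scheme].get(a, "N" if groups.get(a) == "N" else None)
            )
            sub = summaries.assign(subgroup=col).dropna(subset=["subgroup"])
            # severe vs N, light vs N, severe vs light; intermediate tiers
            # are left out of the pairwise comparisons by design
            order = cluster.label_order(scheme, ks[scheme])
            pairs = [(order[0], "N"), (order[-1], "N"), (order[0], order[-1])]
            table = roi.run_comparisons(
                sub, pairs, alpha=config.alpha, group_column="subgroup",
            )
            table.to_csv(outdir / f"comparisons_{scheme}.tsv", sep="\t", index=False)
            subgroup_tables[scheme] = table
        result["comparisons"].update(subgroup_tables)

    excluded = summaries.loc[~summaries["qc_pass"], ["animal_id", "layer", "parameter", "n_pixels"]]
    report = {
        "config": asdict(config),
        "n_animals": len(animals),
        "group_counts": pd.Series(list(groups.values())).value_counts().to_dict(),
        "n_parameters": len(registry),
        "qc_excluded": excluded.to_dict(orient="records"),
        "n_comparisons": {k: len(v) for k, v in result["comparisons"].items()},
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=2))
    result["report"] = report
    return result


# ---------------------------------------------------------------------------
# in-memory phantom study (no disk round trip; used by simulations/tests)


def run_phantom_comparison(
    seed: int,
    n_k: int = 16,
    n_n: int = 10,
    effects: synthetic.EffectMap | None = None,
    phantom: synthetic.PhantomConfig | None = None,
    erosion: int = 1,
    alpha: float = 0.05,
    registry: dict[str, bands.ParameterSpec] | None = None,
    pixel_minima: dict[str, int] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a K-vs-N phantom cohort in memory and compare the groups.

    Returns (comparison table, expected direction table).  The expected
    direction of each parameter x layer is derived from the scatter-free
    ground truth of the planted effect map: "up"/"down" when the K and N
    closed-form values differ by more than 0.1%, "none" otherwise.
    """
    phantom = phantom or synthetic.PhantomConfig()
    if effects is None:
        effects = synthetic.default_effects()
    registry = registry or bands.default_registry()
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    animals = []
    for i in range(n_k + n_n):
        group = "K" if i < n_k else "N"
        aid = f"{group}{i + 1:02d}"
        smap, mask, _ = synthetic.make_phantom(phantom, effects, group, aid, rng)
        animals.append((aid, group, smap, mask))
    summaries = summarize_study(animals, registry, erosion=erosion, pixel_minima=pixel_minima)
    comparisons = roi.run_comparisons(summaries, [("K", "N")], alpha=alpha)

    gt_k = synthetic.ground_truth_table(phantom, effects, "K", registry)
    gt_n = synthetic.ground_truth_table(phantom, effects, "N", registry)
    merged = gt_k.merge(gt_n, on=["layer", "parameter"], suffixes=("_k", "_n"))
    rel = merged["value_k"] / merged["value_n"] - 1.0
    merged["expected_direction"] = np.select(
        [rel > 1e-3, rel < -1e-3], ["up", "down"], default="none"
    )
    return comparisons, merged[["layer", "parameter", "expected_direction"]]
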