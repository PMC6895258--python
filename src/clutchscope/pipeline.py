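"""End-to-end orchestration: configuration, staged analysis and the
condition-comparison report.

A run consumes either simulated preset nuclei or per-cell localization files,
applies QC gating, Voronoi density analysis and the clutch-seeded co-structure
analysis, and emits a JSON report in which every number traces back to a stage
output.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np

from . import clutch as clutchmod
from . import costructure as cs
from . import synthdata
from .locdata_io import LocalizationTable, NuclearMask, clip_to_mask, select_slice
from .voronoi_density import compare_distributions, density_distribution, tessellate

__all__ = ["RunConfig", "validate_config", "run_pipeline", "analyze_cell"]

#: every known key with its default; defaults follow the source analysis
CONFIG_DEFAULTS: dict[str, Any] = {
    "conditions": {"control": {"preset": "control", "n_cells": 4, "condition": "control"},
                   "tsa": {"preset": "tsa", "n_cells": 5, "condition": "treated"}},
    "seed": 0,
    "eps": clutchmod.DEFAULT_EPS,
    "min_size": clutchmod.DEFAULT_MIN_SIZE,
    "island_link": clutchmod.DEFAULT_ISLAND_LINK,
    "enforce_qc": True,
    "dr": cs.DEFAULT_DR,
    "r_max": cs.DEFAULT_RMAX,
    "association_radius": cs.ASSOCIATION_RADIUS,
    "nnd_radius": 70.0,
    "nnd_bin": 20.0,
    "slice_center": 0.0,
    "slice_thickness": 120.0,
    "fine_pixel": 20.0,
    "coarse_pixel": 160.0,
    "transition_alpha": 1e-4,
    "transition_min_radius": 30.0,
    "output_dir": None,
}


@dataclass
class RunConfig:
    values: dict[str, Any]

    def __getattr__(self, key):
        try:
            return self.values[key]
        except KeyError as exc:  # pragma: no cover - programming error
            raise AttributeError(key) from exc

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.values, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def validate_config(config: dict[str, Any] | None = None) -> RunConfig:
    """Fill defaults, reject unknown keys and enforce cross-field constraints."""
    config = dict(config or {})
    unknown = set(config) - set(CONFIG_DEFAULTS)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    merged = {**CONFIG_DEFAULTS, **config}
    if merged["dr"] <= 0 or merged["r_max"] <= 0:
        raise ValueError("dr and r_max must be positive")
    ratio = merged["r_max"] / merged["dr"]
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError("r_max must be an integer multiple of dr")
    if not merged["fine_pixel"] < merged["coarse_pixel"]:
        raise ValueError("fine_pixel must be smaller than coarse_pixel")
    for name, spec in merged["conditions"].items():
        if spec.get("condition", "control") not in clutchmod.QC_THRESHOLDS:
            raise ValueError(f"condition {name!r}: unknown QC condition label")
    return RunConfig(merged)


def analyze_cell(h2b: LocalizationTable, dna: LocalizationTable, mask: NuclearMask,
                 config: RunConfig, condition: str = "control",
                 cell_index: int = 0) -> dict[str, Any]:
    """All per-cell stages: slice, clip, QC, Voronoi density, co-structure."""
    if h2b.has("z"):
        h2b = select_slice(h2b, config.slice_center, config.slice_thickness)
    if dna.has("z"):
        dna = select_slice(dna, config.slice_center, config.slice_thickness)
    h2b = clip_to_mask(h2b, mask)
    dna = clip_to_mask(dna, mask)

    clutches = clutchmod.segment_clutches(h2b, eps=config.eps, min_size=config.min_size)
    islands = clutchmod.group_islands(clutches, xy=h2b.xy, link=config.island_link)

    report = clutchmod.QCReport(
        occupancy=clutchmod.occupancy(h2b, mask, config.fine_pixel, config.coarse_pixel),
        clustered_area=clutchmod.clustered_area_percent(clutches, h2b, mask,
                                                        config.fine_pixel),
        clusters_per_island=islands.clusters_per_island,
        nyquist=max(clutchmod.nyquist_metric(dna, mask, config.slice_thickness,
                                             config.fine_pixel)),
    )
    clutchmod.qc_gate(report, condition=condition)

    vmap = tessellate(dna, mask, dimension=2)

    out: dict[str, Any] = {
        "cell": cell_index,
        "qc": {"occupancy": report.occupancy,
               "clustered_area": report.clustered_area,
               "clusters_per_island": report.clusters_per_island,
               "nyquist": report.nyquist,
               "passed": report.passed,
               "failures": report.failures},
        "n_clutches": len(clutches),
        "voronoi_map": vmap,
    }
    if len(clutches) >= 4:
        polygons = cs.clutch_voronoi(clutches, mask)
        cs.assign_dna(dna, polygons)
        profiles = cs.radial_profiles(polygons, dna, dr=config.dr,
                                      r_max=config.r_max, cell=cell_index)
        frac, _ = cs.associated_fraction(profiles, r=config.association_radius)
        out["profiles"] = profiles
        out["clutches"] = clutches
        out["associated_fraction"] = frac
        out["coloc_clutch_fraction"] = cs.colocalized_clutch_fraction(
            profiles, r=config.association_radius)
        out["nnd_same_island"] = cs.nnd(clutches, same_island_only=True)
    return out


def run_pipeline(config: RunConfig | dict | None = None) -> dict[str, Any]:
    """Run the full synthetic-condition comparison and build the report."""
    if not isinstance(config, RunConfig):
        config = validate_config(config)
    rng = np.random.default_rng(config.seed)
    report: dict[str, Any] = {"config_hash": config.hash(), "seed": config.seed,
                              "conditions": {}}
    condition_results: dict[str, list[dict]] = {}
    for name, spec in config.conditions.items():
        nuc_model, dna_model = synthdata.condition_presets(spec["preset"])
        cells = []
        for i in range(spec["n_cells"]):
            sim = synthdata.simulate_nucleus(nuc_model, dna_model,
                                             synthdata.AcquisitionModel(),
                                             seed=int(rng.integers(2 ** 31)))
            cells.append(analyze_cell(sim["h2b"], sim["dna"], sim["mask"], config,
                                      condition=spec.get("condition", "control"),
                                      cell_index=i))
        condition_results[name] = cells

    for name, cells in condition_results.items():
        if config.enforce_qc:
            passed = [c for c in cells if c["qc"]["passed"]]
            excluded = [c["cell"] for c in cells if not c["qc"]["passed"]]
        else:
            passed, excluded = list(cells), []
        fracs = [c["associated_fraction"] for c in passed if "associated_fraction" in c]
        profiles = [p for c in passed for p in c.get("profiles", [])]
        entry: dict[str, Any] = {
            "n_cells": len(cells),
            "n_passed": len(passed),
            "excluded_cells": excluded,
            "qc": [c["qc"] for c in cells],
            "associated_fraction_mean": float(np.mean(fracs)) if fracs else math.nan,
            "associated_fraction_sd": float(np.std(fracs)) if fracs else math.nan,
        }
        if profiles:
            matrix = cs.similarity_matrix(profiles)
            entry["transition_radius"] = cs.transition_radius(
                matrix, alpha=config.transition_alpha,
                min_radius=config.transition_min_radius)
            nnd_curve = cs.density_vs_nnd(
                [(c["profiles"], c["nnd_same_island"]) for c in passed
                 if "profiles" in c and len(c["nnd_same_island"])],
                r=config.nnd_radius, bin_width=config.nnd_bin)
            entry["density_vs_nnd"] = nnd_curve.to_dict(orient="list")
        report["conditions"][name] = entry

    names = list(condition_results)
    if len(names) == 2:
        dists = []
        for n in names:
            cells = condition_results[n]
            kept = ([c for c in cells if c["qc"]["passed"]]
                    if config.enforce_qc else cells) or cells
            dists.append(density_distribution([c["voronoi_map"] for c in kept]))
        D, p = compare_distributions(dists[0], dists[1])
        report["voronoi_comparison"] = {"ks_D": D, "ks_p": p,
                                        "conditions": names}

    if config.output_dir:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report
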