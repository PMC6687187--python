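"""Seeded scenario presets and the synthetic ABC test set.

Four representative growth scenarios (birth rate 1 throughout):

* ``neutral_homogeneous``   — u=10, driver at t=4 with s=0, a=1, ~100k cells
* ``selective_homogeneous`` — u=10, driver at t=8 with s=3, a=1, ~80k cells
* ``neutral_boundary``      — u=10, driver at t=4 with s=0, a=0.025
* ``selective_boundary``    — u=10, driver at t=8 with s=2, a=0.025

The nominal population sizes are reached through the grid-boundary stop
rule (2D grid extent 400) plus the cell cap; ``run_scenario`` accepts a
smaller ``max_cells`` for quick, reduced-size runs of the same scenarios.
"""

from __future__ import annotations

import hashlib
import json
import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import engine, io, phylogeny, sampling, sequencing, summaries
from .params import SimulationParams

__version__ = "0.1.0"


@dataclass
class ScenarioPreset:
    name: str
    params: SimulationParams
    n_punches: int = 6
    depth: float = 100.0
    min_alt: int = 5
    n_single_cells: int = 10
    n_single_cells_large: int = 400
    n_cells_per_bulk: int = 4


def _preset(name, t, s, a, max_cells) -> ScenarioPreset:
    return ScenarioPreset(
        name=name,
        params=SimulationParams(
            dims=2, grid_extent=400, b=1.0, d=0.0, u=10.0,
            a=a, t_driver=t, s=s, max_cells=max_cells,
        ),
    )


REPRESENTATIVE = {
    "neutral_homogeneous": _preset("neutral_homogeneous", t=4.0, s=0.0, a=1.0, max_cells=100_000),
    "selective_homogeneous": _preset("selective_homogeneous", t=8.0, s=3.0, a=1.0, max_cells=80_000),
    "neutral_boundary": _preset("neutral_boundary", t=4.0, s=0.0, a=0.025, max_cells=100_000),
    "selective_boundary": _preset("selective_boundary", t=8.0, s=2.0, a=0.025, max_cells=100_000),
}


def make_test_set(seed: int = 0) -> pd.DataFrame:
    """The 34-target synthetic test set for inference benchmarking:
    13 homogeneous no-death targets, 11 homogeneous with cell death and
    10 boundary-driven, with parameters drawn from the inference priors
    (death and boundary draws kept inside simulable sub-ranges)."""
    rng = np.random.default_rng(seed)
    rows = []

    def draw(set_name, n, death, boundary):
        for _ in range(n):
            rows.append(
                {
                    "set": set_name,
                    "u": round(float(rng.uniform(1, 50)), 1),
                    "t_driver": round(float(rng.uniform(2, 10)), 2),
                    "s": round(float(rng.uniform(0, 1)), 2),
                    "d": round(float(rng.uniform(0.1, 0.6)), 2) if death else 0.0,
                    "a": round(float(rng.uniform(0.01, 0.2)), 3) if boundary else 1.0,
                    "b": 1.0,
                }
            )

    draw("homogeneous_no_death", 13, death=False, boundary=False)
    draw("homogeneous_death", 11, death=True, boundary=False)
    draw("boundary_driven", 10, death=False, boundary=True)
    df = pd.DataFrame(rows)
    df.insert(0, "target_id", [f"T{i + 1:02d}" for i in range(len(df))])
    return df


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]


def run_scenario(preset, seed: int, out_dir=None, max_cells: int | None = None) -> dict:
    """Simulate a preset end to end: grow, sample (punches, needles, whole
    tumour, single cells), sequence, summarise, and optionally write every
    artifact plus a manifest capturing the exact configuration and seed."""
    if isinstance(preset, str):
        preset = REPRESENTATIVE[preset]
    cfg = preset.params.to_dict()
    cfg["seed"] = int(seed)
    if max_cells is not None:
        cfg["max_cells"] = int(max_cells)
    params = SimulationParams.from_dict(cfg)
    state = engine.run_with_restarts(params)
    rng = np.random.default_rng(seed + 1)

    bulks = sampling.default_multiregion_design(state, n_punches=preset.n_punches)
    spectra = {
        b.sample_id: sequencing.sequence_bulk(
            b, Z=preset.depth, min_alt=preset.min_alt, rng=rng
        )
        for b in bulks
    }
    n_sc = min(preset.n_single_cells, state.n_cells)
    sc_ids = sampling.sample_single_cells_random(state, n_sc, rng=rng)
    matrix = sequencing.sequence_single_cells_wgs(state, sc_ids)
    tree = phylogeny.build_tree(matrix) if n_sc >= 2 else None

    stats = {}
    for sid, spec in spectra.items():
        try:
            cum = summaries.cumulative_spectrum(spec)
            res = summaries.auc_neutrality_test(cum, rng=rng, n_resamples=200)
            stats[sid] = {
                "n_mutations": len(spec),
                "u_hat": res.u_hat,
                "auc": res.auc,
                "p_value": res.p_value,
                "neutral": res.neutral,
            }
        except summaries.InsufficientSpectrumError:
            stats[sid] = {"n_mutations": len(spec)}

    bundle = {
        "state": state,
        "bulks": bulks,
        "spectra": spectra,
        "single_cell_ids": sc_ids,
        "genotype_matrix": matrix,
        "tree": tree,
        "summary_stats": stats,
        "manifest": {
            "package": "latticetumour",
            "version": __version__,
            "scenario": preset.name,
            "seed": int(seed),
            "config": cfg,
            "config_hash": _config_hash(cfg),
            "n_cells_final": state.n_cells,
            "t_final": state.t,
            "extinct": state.extinct,
            "driver_skipped": state.driver_skipped,
        },
    }

    if out_dir is not None:
        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        state.occupancy_frame().to_csv(out / "occupancy.tsv", sep="\t", index=False)
        state.lineage.to_frame().to_csv(out / "lineage.tsv", sep="\t", index=False)
        engine.growth_curves(state).to_csv(out / "growth_curves.tsv", sep="\t", index=False)
        sampling.sample_manifest(bulks).to_csv(out / "samples.tsv", sep="\t", index=False)
        for sid, spec in spectra.items():
            io.write_mutation_table(spec, out / f"mutations_{sid}.tsv")
        if tree is not None:
            phylogeny.write_newick(tree, out / "single_cell_tree.nwk")
        pd.DataFrame(stats).T.rename_axis("sample_id").reset_index().to_csv(
            out / "summary_stats.tsv", sep="\t", index=False
        )
        with open(out / "manifest.json", "w") as fh:
            json.dump(bundle["manifest"], fh, indent=2, sort_keys=True)
    return bundle
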