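"""End-to-end pipeline: align → fields → 2D descriptors → PLS → contours.

A :class:`PipelineConfig` (schema-validated, unknown keys rejected) fully
determines a run; the run directory receives the aligned structures, the
fitted statistics (Table-style JSON), contour cube files and a provenance
manifest, so every artifact is reproducible from the manifest alone.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict

from . import __version__
from .alignment import align_set
from .chem_io import Molecule, prepare_all, read_activities, read_ligands, write_ligands
from .contours import contour_levels, export_cube, stdev_coeff_map
from .descriptors2d import descriptor_table
from .fields import (
    COMFA_KINDS,
    COMSIA_KINDS,
    BlockScaler,
    ProbeSpec,
    compute_field_tables,
    make_grid,
)
from .pls import PLSQSAR
from .synthetic import CORE_SMARTS, SeriesSpec, generate_series, split_set


class AlignmentOptions(BaseModel):
    model_config = ConfigDict(extra="forbid")
    template_id: Optional[str] = None   # default: most potent molecule
    core_smarts: Optional[str] = None   # default: MCS search


class GridOptions(BaseModel):
    model_config = ConfigDict(extra="forbid")
    spacing: float = 2.0
    margin: float = 4.0


class ProbeOptions(BaseModel):
    model_config = ConfigDict(extra="forbid")
    charge: float = 1.0
    radius: float = 1.0
    alpha: float = 0.3
    energy_cutoff: float = 30.0

    def to_spec(self) -> ProbeSpec:
        return ProbeSpec(
            charge=self.charge,
            radius=self.radius,
            alpha=self.alpha,
            energy_cutoff=self.energy_cutoff,
        )


class PLSOptions(BaseModel):
    model_config = ConfigDict(extra="forbid")
    max_components: int = 10


class ContourOptions(BaseModel):
    model_config = ConfigDict(extra="forbid")
    favored_pct: float = 80.0
    disfavored_pct: float = 20.0


class PipelineConfig(BaseModel):
    """The single YAML-loadable configuration driving ``run_pipeline``."""

    model_config = ConfigDict(extra="forbid")

    ligands: Optional[str] = None          # SDF path; None → synthetic series
    activities: Optional[str] = None       # CSV path (id,value,scale)
    fields: Literal["comfa", "comsia", "both"] = "comsia"
    use_2d_descriptors: bool = True
    n_test: Optional[int] = None           # None → synthetic spec's split
    seed: int = 7
    alignment: AlignmentOptions = AlignmentOptions()
    grid: GridOptions = GridOptions()
    probe: ProbeOptions = ProbeOptions()
    pls: PLSOptions = PLSOptions()
    contours: ContourOptions = ContourOptions()


@dataclass
class PipelineResult:
    stats: dict
    model: PLSQSAR
    block: object
    grid: object
    maps: dict
    train_ids: list[str]
    test_ids: list[str]
    aligned: list[Molecule]


def _field_kinds(choice: str) -> tuple[str, ...]:
    return {
        "comfa": COMFA_KINDS,
        "comsia": COMSIA_KINDS,
        "both": COMFA_KINDS + COMSIA_KINDS,
    }[choice]


def run_pipeline(
    config: PipelineConfig, outdir: str | Path | None = None
) -> PipelineResult:
    stage = "input"
    try:
        core_smarts = config.alignment.core_smarts
        if config.ligands is None:
            stage = "simulate"
            spec = SeriesSpec(seed=config.seed)
            mols, activities, _ = generate_series(spec)
            n_test = config.n_test if config.n_test is not None else spec.n_test
            if core_smarts is None:
                core_smarts = CORE_SMARTS  # the generator's own scaffold core
        else:
            mols = read_ligands(config.ligands)
            if config.activities is not None:
                act = read_activities(config.activities)
                lookup = dict(zip(act["id"], act["pKi"]))
                for m in mols:
                    m.activity = lookup.get(m.id, m.activity)
            activities = pd.DataFrame(
                {"id": [m.id for m in mols], "value": [m.activity for m in mols],
                 "scale": "pKi"}
            )
            n_test = config.n_test if config.n_test is not None else max(len(mols) // 6, 1)

        stage = "align"
        template = config.alignment.template_id
        if template is None:
            template = activities.loc[activities["value"].idxmax(), "id"]
        aligned, rmsd_report = align_set(mols, template, core_smarts=core_smarts)

        stage = "prepare"
        prepared = prepare_all(aligned)
        for m, a in zip(prepared, aligned):
            m.activity = a.activity

        stage = "split"
        train_ids, test_ids = split_set(activities, n_test, seed=config.seed + 1)
        by_id = {m.id: m for m in prepared}
        train = [by_id[i] for i in train_ids]
        test = [by_id[i] for i in test_ids]
        y_train = np.array([m.activity for m in train])
        y_test = np.array([m.activity for m in test])

        stage = "fields"
        kinds = _field_kinds(config.fields)
        grid = make_grid(prepared, config.grid.spacing, config.grid.margin)
        probe = config.probe.to_spec()
        tables_train = compute_field_tables(train, grid, probe, kinds)
        tables_test = compute_field_tables(test, grid, probe, kinds)

        stage = "descriptors"
        extra_train = extra_test = None
        if config.use_2d_descriptors:
            extra_train = descriptor_table(train)
            extra_test = descriptor_table(test)

        stage = "fit"
        scaler = BlockScaler()
        block_train = scaler.fit_transform(tables_train, extra_train)
        block_test = scaler.transform(tables_test, extra_test)
        model = PLSQSAR(max_components=config.pls.max_components)
        model.fit(block_train, y_train)
        stats = model.stats(block_test, y_test).to_dict()
        stats["n_train"] = len(train_ids)
        stats["n_test"] = len(test_ids)

        stage = "contours"
        maps = {}
        for b in block_train.blocks:
            if b.grid is None or b.cols.stop == b.cols.start:
                continue
            cmap = stdev_coeff_map(model, block_train, b.name)
            if np.any(cmap.values != 0):
                contour_levels(
                    cmap, config.contours.favored_pct, config.contours.disfavored_pct
                )
            maps[b.name] = cmap
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    result = PipelineResult(
        stats=stats, model=model, block=block_train, grid=grid, maps=maps,
        train_ids=train_ids, test_ids=test_ids, aligned=prepared,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_ligands(prepared, outdir / "aligned.sdf")
        rmsd_report.to_csv(outdir / "core_rmsd.csv", index=False)
        (outdir / "stats.json").write_text(json.dumps(stats, indent=2, sort_keys=True) + "\n")
        for name, cmap in maps.items():
            export_cube(cmap, outdir / f"{name}.cube", mol=by_id[template])
        manifest = {
            "fieldqsar_version": __version__,
            "python": platform.python_version(),
            "seed": config.seed,
            "config": config.model_dump(),
            "template_id": str(template),
            "train_ids": train_ids,
            "test_ids": test_ids,
        }
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
    return result
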