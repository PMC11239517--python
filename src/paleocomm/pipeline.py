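"""End-to-end orchestration: read -> retrodeform -> jackknife -> analyses.

A run is driven by a YAML manifest listing the census CSVs plus per-run
options, and writes a bundle of CSV/JSON artifacts.  All randomness is
drawn from named streams spawned from one master seed, so re-running the
same configuration reproduces every table bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .composition import (EffacedTreatment, bray_curtis_matrix,
                          combine_tables, composition_table,
                          hierarchical_cluster, jackknife_composition_table,
                          nmds, relative_abundance)
from .io import SurfaceMap, derive_geometry, read_surface_map, retrodeform
from .jackknife import JackknifeConfig, generate_jackknife_samples
from .succession import (assign_stages, regress_w_covariates, stage_table,
                         surface_abc, surface_covariates,
                         w_jackknife_distribution)
from .tiering import (community_dvs, morphogroup_dvs, tiering_table,
                      tiering_succession_association)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    manifest: str | Path
    out_dir: str | Path = "paleocomm_out"
    level: str = "species"
    treatment: EffacedTreatment = field(default_factory=EffacedTreatment)
    jackknife_fraction: float = 0.66
    jackknife_samples: int = 1000
    alpha: float = 0.05
    tier_high: float = 0.70
    tier_low: float = 0.40
    morphogroup_min_n: int = 31
    retrodeform_min_discs: int = 10
    nmds_samples_per_surface: int = 100  # replicates entering the ordination
    nmds_restarts: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if not self.tier_low < self.tier_high:
            raise ValueError("tier thresholds must be ordered")


class StageFailure(RuntimeError):
    """Raised when a pipeline stage fails; names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def load_manifest(path: str | Path) -> list[dict]:
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    entries = doc["surfaces"] if isinstance(doc, dict) else doc
    for e in entries:
        e.setdefault("jackknife", True)
        e["file"] = str((path.parent / e["file"]).resolve())
    return entries


def _load_surfaces(entries: Sequence[dict],
                   cfg: PipelineConfig) -> list[tuple[SurfaceMap, dict]]:
    out = []
    for e in entries:
        extent = tuple(e["extent"]) if "extent" in e else None
        s = read_surface_map(e["file"], surface_id=e["surface_id"],
                             extent=extent, area_m2=e.get("area_m2"))
        s = derive_geometry(s)
        if e.get("retrodeform", True):
            s = retrodeform(s, n_min=cfg.retrodeform_min_discs)
        out.append((s, e))
    return out


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage and write the report bundle under ``cfg.out_dir``.

    Returns a dict of the in-memory results keyed by stage name.  Any
    stage failure aborts with a stage-named error; artifacts written so
    far stay on disk next to a ``FAILED`` marker naming the stage.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    ss = np.random.SeedSequence(cfg.seed)
    seeds = {name: int(s.generate_state(1)[0] % (2**31))
             for name, s in zip(
                 ("jackknife", "nmds", "treatment"), ss.spawn(3))}

    stage = "read"
    try:
        entries = load_manifest(cfg.manifest)
        loaded = _load_surfaces(entries, cfg)
        surfaces = [s for s, _ in loaded]
        results["surfaces"] = surfaces

        treatment = cfg.treatment
        if treatment.mode == "proportional_relabel" \
                and treatment.relabel_seed is None:
            treatment = dataclasses.replace(treatment,
                                            relabel_seed=seeds["treatment"])

        stage = "jackknife"
        jk_cfg = JackknifeConfig(fraction=cfg.jackknife_fraction,
                                 n_samples=cfg.jackknife_samples,
                                 seed=seeds["jackknife"])
        jackknifed = {}
        for s, e in loaded:
            if e.get("jackknife", True):
                jackknifed[s.surface_id] = generate_jackknife_samples(s, jk_cfg)
        results["jackknife"] = jackknifed

        stage = "composition"
        surf_comp = composition_table(surfaces, cfg.level, treatment)
        surf_comp.to_csv(out / "composition_surface.csv")
        jk_tables = [
            jackknife_composition_table(s, jackknifed[s.surface_id],
                                        cfg.level, treatment)
            for s in surfaces if s.surface_id in jackknifed
        ]
        jk_comp = combine_tables(jk_tables)
        jk_comp.to_csv(out / "composition_jackknife.csv")
        bray_curtis_matrix(relative_abundance(surf_comp)).to_csv(
            out / "distance_surface.csv")
        results["composition"] = surf_comp

        stage = "clustering"
        clust = hierarchical_cluster(surf_comp)
        (out / "dendrogram.nwk").write_text(clust.to_newick() + "\n")
        results["clustering"] = clust

        stage = "nmds"
        rng = np.random.default_rng(seeds["nmds"])
        keep = []
        for sid, grp in jk_comp.groupby(level=0, sort=False):
            take = min(cfg.nmds_samples_per_surface, len(grp))
            keep.append(grp.iloc[
                np.sort(rng.choice(len(grp), size=take, replace=False))])
        nmds_input = pd.concat(keep)
        nmds_input = nmds_input[nmds_input.sum(axis=1) > 0]
        ord2 = nmds(nmds_input, k=2, seed=seeds["nmds"],
                    n_restarts=cfg.nmds_restarts)
        coords = ord2.coordinates.copy()
        coords["stress"] = ord2.stress
        coords.to_csv(out / "nmds_coords.csv")
        results["nmds"] = ord2

        stage = "succession"
        dists = {
            s.surface_id: w_jackknife_distribution(
                s, jackknifed[s.surface_id], cfg.level, treatment)
            for s in surfaces if s.surface_id in jackknifed
        }
        pd.DataFrame({sid: pd.Series(d.values) for sid, d in dists.items()}) \
            .to_csv(out / "w_distributions.csv", index=False)
        full_w = {
            s.surface_id: surface_abc(s, cfg.level, treatment).W
            for s in surfaces if s.surface_id not in jackknifed
        }
        assignments = assign_stages(dists, full_w, alpha=cfg.alpha)
        stages_df = stage_table(assignments)
        stages_df.to_csv(out / "stages.csv", index=False)
        results["stages"] = stages_df

        stage = "regressions"
        cov = surface_covariates(surfaces)
        reg_in = stages_df.set_index("surface_id").join(cov)
        jack_only = reg_in.loc[reg_in.index.isin(dists)]
        regs = regress_w_covariates(jack_only)
        pd.DataFrame([dataclasses.asdict(r) for r in regs.values()]) \
            .to_csv(out / "w_regressions.csv", index=False)
        results["regressions"] = regs

        stage = "tiering"
        tier_results, per_taxon = [], []
        for s in surfaces:
            try:
                r = community_dvs(s, cfg.level, treatment=treatment)
            except ValueError as err:
                logger.warning("tiering skipped: %s", err)
                continue
            tier_results.append(r)
            pt = r.per_taxon.copy()
            pt.insert(0, "surface_id", s.surface_id)
            per_taxon.append(pt)
        tier_df = tiering_table(tier_results)
        tier_df.to_csv(out / "tiering_surface.csv")
        pd.concat(per_taxon).to_csv(out / "tiering_taxon.csv", index=False)
        morpho = []
        for s in surfaces:
            try:
                r = morphogroup_dvs(s, min_n=cfg.morphogroup_min_n,
                                    treatment=treatment)
                morpho.append(r)
            except ValueError as err:
                logger.info("morphogroup tiering: %s", err)
        if morpho:
            tiering_table(morpho).to_csv(out / "morphogroup_tiering.csv")
        results["tiering"] = tier_df

        stage = "associations"
        assoc_in = tier_df.join(stages_df.set_index("surface_id")["mean_w"])
        try:
            regs2, corrs = tiering_succession_association(assoc_in)
            rows = [dataclasses.asdict(r) for r in regs2.values()]
            rows += [dataclasses.asdict(c) for c in corrs.values()]
            pd.DataFrame(rows).to_csv(out / "associations.csv", index=False)
            results["associations"] = (regs2, corrs)
        except ValueError as err:
            logger.warning("association stage skipped: %s", err)

        stage = "log"
        log = {
            "package_version": __version__,
            "seed": cfg.seed,
            "stream_seeds": seeds,
            "level": cfg.level,
            "treatment": cfg.treatment.mode,
            "n_surfaces": len(surfaces),
            "n_jackknifed": len(jackknifed),
            "nmds_stress": results["nmds"].stress,
        }
        (out / "run_log.json").write_text(json.dumps(log, indent=1))
        echo = dataclasses.asdict(cfg)
        echo["manifest"] = str(cfg.manifest)
        echo["out_dir"] = str(cfg.out_dir)
        echo["treatment"] = cfg.treatment.mode
        (out / "config_echo.yaml").write_text(yaml.safe_dump(echo))
    except StageFailure:
        raise
    except Exception as err:  # noqa: BLE001 - re-raise with stage context
        (out / "FAILED").write_text(f"{stage}: {err}\n")
        raise StageFailure(stage, err) from err
    return results
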