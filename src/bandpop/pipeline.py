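"""End-to-end orchestration: matrix -> efficiency -> diversity -> tree -> AMOVA.

A run is described by a :class:`PipelineConfig` that either points at an
input band matrix (plus primer-system and metadata tables) or embeds a
simulation block, never both.  The output directory receives the four
summary tables (per-primer amplification, marker efficiency, diversity
with the Shannon partition, AMOVA including per-subspecies by-country
runs), the bootstrap-annotated Newick tree, the Dice distance matrix and
a run log; any stage failure removes partial outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .amova import amova_by_country, amova_oneway, squared_euclidean
from .diversity import group_diversity
from .efficiency import efficiency_report
from .matrix import (
    BandMatrix,
    BandMatrixError,
    SampleMetadata,
    read_band_matrix,
    read_metadata,
)
from .phylo import bootstrap_support, dissimilarity_matrix, write_newick
from .simulate import SimulationConfig, simulate_band_matrix

__all__ = ["PipelineConfig", "run_pipeline"]

OUTPUT_FILES = (
    "table1.tsv",
    "table2.tsv",
    "table3.tsv",
    "table4.tsv",
    "tree.nwk",
    "distances.tsv",
    "run_log.json",
)


@dataclass(frozen=True)
class PipelineConfig:
    """Inputs, grouping choices and stochastic-stage settings for one run.

    Exactly one of ``inputs`` (paths ``matrix``, ``primer_systems``,
    ``metadata``) and ``simulate`` must be given.  ``seed`` drives both
    bootstrap and permutation stages.
    """

    out_dir: str | Path
    inputs: dict | None = None
    simulate: SimulationConfig | None = None
    grouping: str = "subspecies"
    pic_mode: str = "pattern"
    freq_method: str = "sqrt"
    bootstrap_reps: int = 1000
    amova_permutations: int = 999
    seed: int = 0

    def __post_init__(self):
        if (self.inputs is None) == (self.simulate is None):
            raise ValueError(
                "config must provide exactly one of an inputs block or a simulate block"
            )
        if self.inputs is not None:
            missing = {"matrix", "primer_systems", "metadata"} - set(self.inputs)
            if missing:
                raise ValueError(f"inputs block missing paths: {sorted(missing)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        sim = raw.pop("simulate", None)
        if sim is not None:
            sim = SimulationConfig(**sim)
        return cls(simulate=sim, **raw)


def _load(cfg: PipelineConfig) -> tuple[BandMatrix, SampleMetadata]:
    if cfg.simulate is not None:
        m, md, _ = simulate_band_matrix(cfg.simulate)
        return m, md
    m = read_band_matrix(cfg.inputs["matrix"], cfg.inputs["primer_systems"])
    md = read_metadata(cfg.inputs["metadata"])
    md.check_covers(m)
    return m, md


def run_pipeline(cfg: PipelineConfig) -> dict[str, Path]:
    """Run every stage and write the report bundle; returns output paths.

    Deterministic given the config (including its seed): running twice
    produces byte-identical files.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "load"
    try:
        m, md = _load(cfg)
        groups = md.group_map(cfg.grouping)

        def emit(name: str, frame: pd.DataFrame, index: bool) -> Path:
            p = out / name
            frame.to_csv(p, sep="\t", index=index, float_format="%.6g")
            written.append(p)
            return p

        stage = "efficiency"
        eff = efficiency_report(m, pic_mode=cfg.pic_mode)
        emit("table1.tsv", eff.primer_frame(), index=False)
        emit("table2.tsv", eff.per_system, index=True)

        stage = "diversity"
        div = group_diversity(m, groups, method=cfg.freq_method)
        t3 = div.per_group.copy()
        partition = pd.DataFrame(
            {
                "n": [np.nan] * 4,
                "na": [np.nan] * 4,
                "ne": [np.nan] * 4,
                "he": [np.nan] * 4,
                "shannon": [div.it_total, div.is_within, div.is_over_it, div.s_prime],
            },
            index=["It", "Is", "Is/It", "S'"],
        )
        emit("table3.tsv", pd.concat([t3, partition]), index=True)

        stage = "distance/tree"
        d = dissimilarity_matrix(m)
        emit("distances.tsv", d.to_data_frame(), index=True)
        tree = bootstrap_support(m, n_reps=cfg.bootstrap_reps, seed=cfg.seed)
        tree_path = out / "tree.nwk"
        write_newick(tree, tree_path)
        written.append(tree_path)

        stage = "amova"
        d2 = squared_euclidean(m)
        res = amova_oneway(
            d2, groups, n_perm=cfg.amova_permutations, seed=cfg.seed
        )
        frames = [res.to_frame().assign(analysis=cfg.grouping)]
        by_country = {}
        t = md.table
        for subsp in t["subspecies"].unique():
            if t.loc[t["subspecies"] == subsp, "country"].nunique() < 2:
                continue
            r = amova_by_country(
                m, md, subsp, n_perm=cfg.amova_permutations, seed=cfg.seed
            )
            by_country[subsp] = r
            frames.append(r.to_frame().assign(analysis=f"{subsp}:countries"))
        emit("table4.tsv", pd.concat(frames, ignore_index=True), index=False)

        stage = "log"
        log = {
            "bandpop_version": __version__,
            "numpy_version": np.__version__,
            "pandas_version": pd.__version__,
            "seed": cfg.seed,
            "grouping": cfg.grouping,
            "pic_mode": cfg.pic_mode,
            "freq_method": cfg.freq_method,
            "bootstrap_reps": cfg.bootstrap_reps,
            "amova_permutations": cfg.amova_permutations,
            "n_samples": m.n_samples,
            "n_bands": m.n_bands,
            "n_primers": len(m.primers),
            "systems": list(m.systems),
            "amova_group_sizes": res.group_sizes,
            "simulated": cfg.simulate is not None,
        }
        log_path = out / "run_log.json"
        log_path.write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")
        written.append(log_path)
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise BandMatrixError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return {p.name: p for p in written}
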