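"""End-to-end analysis pipeline: dataset -> networks, centralities, ANOVA tables.

Outputs are text-first (TSV) so every artifact is diffable and
deterministically reproducible under a fixed seed; plots are optional
derivatives rendered from the same tables.  All files are written atomically
(write to a temporary file, then rename), so a failed run never leaves a
partially written artifact.

Output layout under the run directory::

    run_config.json                      provenance: config, seed, versions
    observations.csv                     the analyzed dataset (if simulated)
    networks/{G}_{PHASE}_ppd{D}.edges.tsv   from/to/weight edge list
    networks/{G}_{PHASE}_ppd{D}.nodes.tsv   code/size node table
    heatmaps/{G}_{PHASE}_ppd{D}.tsv         6x6 transition-weight matrix
    centrality/{G}_{PHASE}_ppd{D}.tsv       per-node raw + z centralities
    anova.tsv                            response x phase mixed-ANOVA table
    plots/...                            optional PNG renderings
"""

from __future__ import annotations

import json
import os
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .centrality import centrality_table
from .ethogram import GROUPS, Dataset, read_observations, write_observations
from .simulate import SimConfig, default_config, simulate_dataset
from .stats import mixed_anova, response_table
from .transitions import NODE_ORDER, PHASES, build_group_network

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

#: Responses reported in the summary ANOVA table, per phase.
ANOVA_RESPONSES = ("HG", "LW", "SUP", "HG/L", "L", "transitions")

_FLOAT_FMT = "%.10g"


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and context."""


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run.

    ``input_path`` points at an observation CSV to analyze; when it is None a
    dataset is simulated from ``sim_config`` (default presets with
    ``seed``).  The full configuration is serialized into the output
    directory for provenance.
    """

    out_dir: Path
    input_path: Path | None = None
    sim_config: SimConfig | None = None
    seed: int = 0
    l_policy: str = "bridge"
    betweenness_mode: str = "binary"
    plots: bool = False

    def resolved_sim_config(self) -> SimConfig:
        return self.sim_config if self.sim_config is not None else default_config(self.seed)


def _atomic_write_text(path: Path, text: str) -> None:
    tmp = path.with_name(path.name + ".tmp")
    tmp.write_text(text, encoding="utf-8")
    os.replace(tmp, path)


def _write_tsv(path: Path, frame: pd.DataFrame, index: bool = False) -> None:
    _atomic_write_text(path, frame.to_csv(sep="\t", index=index, float_format=_FLOAT_FMT))


def _slug(group: str, phase: str, ppd: int) -> str:
    return f"{group}_{phase}_ppd{ppd}"


def _provenance(config: RunConfig) -> dict:
    sim = None
    if config.input_path is None:
        sc = config.resolved_sim_config()
        sim = {
            "n_dams_per_group": sc.n_dams_per_group,
            "ppd_range": list(sc.ppd_range),
            "seed": sc.seed,
            "profiles": {
                f"{g}_{p}": {
                    "fragmentation": prof.fragmentation,
                    "day_drift": prof.day_drift,
                    "initial_dist": prof.initial_dist.tolist(),
                    "switch_kernel": prof.switch_kernel.tolist(),
                }
                for (g, p), prof in sorted(sc.profiles.items())
            },
        }
    return {
        "maternet_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "python_version": platform.python_version(),
        "seed": config.seed,
        "input": str(config.input_path) if config.input_path else None,
        "l_policy": config.l_policy,
        "betweenness_mode": config.betweenness_mode,
        "plots": config.plots,
        "simulation": sim,
    }


def _network_frames(net) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    w = net.weights
    edge_rows = [
        {"from": NODE_ORDER[i], "to": NODE_ORDER[j], "weight": w[i, j]}
        for i in range(len(NODE_ORDER))
        for j in range(len(NODE_ORDER))
        if w[i, j] > 0
    ]
    edges = pd.DataFrame(edge_rows, columns=["from", "to", "weight"])
    nodes = pd.DataFrame({"code": NODE_ORDER, "size": net.node_sizes})
    heat = pd.DataFrame(w, index=pd.Index(NODE_ORDER, name="from"), columns=NODE_ORDER)
    return edges, nodes, heat


def _anova_frame(dataset: Dataset) -> pd.DataFrame:
    rows = []
    for phase in PHASES:
        for response in ANOVA_RESPONSES:
            table = response_table(dataset, response, phase)
            anova = mixed_anova(table)
            row = {"phase": phase, "response": response}
            for factor in ("day", "housing", "interaction"):
                eff = anova[factor]
                row[f"{factor}_F"] = eff["F"]
                row[f"{factor}_df1"] = int(eff["df1"])
                row[f"{factor}_df2"] = int(eff["df2"])
                row[f"{factor}_p"] = eff["p"]
                row[f"{factor}_sig"] = "*" if eff["p"] < 0.05 else ""
            rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis and return a manifest of written artifacts.

    Stages: load or simulate the dataset; build one behavior network per
    (group, phase, ppd); export edge/node/heat-map/centrality tables; fit
    the mixed ANOVA per response and phase; optionally render plots.
    """
    out = Path(config.out_dir)

    # Stage 1: obtain and validate the dataset before creating any output.
    try:
        if config.input_path is not None:
            dataset = read_observations(config.input_path)
        else:
            dataset = simulate_dataset(config.resolved_sim_config())
    except Exception as exc:
        raise PipelineError(f"stage=load: {exc}") from exc
    if len(dataset) == 0:
        raise PipelineError("stage=load: dataset is empty")
    groups = [g for g in GROUPS if dataset.dam_ids(g)]
    ppds = dataset.ppds()

    out.mkdir(parents=True, exist_ok=True)
    for sub in ("networks", "heatmaps", "centrality"):
        (out / sub).mkdir(exist_ok=True)

    manifest: dict = {"out_dir": str(out), "networks": [], "files": []}

    _atomic_write_text(out / "run_config.json",
                       json.dumps(_provenance(config), indent=2) + "\n")
    manifest["files"].append("run_config.json")

    if config.input_path is None:
        write_observations(dataset, out / "observations.csv")
        manifest["files"].append("observations.csv")

    # Stage 2: networks, heat maps, centralities.
    for group in groups:
        for phase in PHASES:
            for ppd in ppds:
                ctx = f"group={group}, phase={phase}, ppd={ppd}"
                try:
                    net = build_group_network(
                        dataset, group, phase, ppd, l_policy=config.l_policy
                    )
                    edges, nodes, heat = _network_frames(net)
                    cent = centrality_table(net, mode=config.betweenness_mode)
                except Exception as exc:
                    raise PipelineError(f"stage=network ({ctx}): {exc}") from exc
                slug = _slug(group, phase, ppd)
                _write_tsv(out / "networks" / f"{slug}.edges.tsv", edges)
                _write_tsv(out / "networks" / f"{slug}.nodes.tsv", nodes)
                _write_tsv(out / "heatmaps" / f"{slug}.tsv", heat, index=True)
                _write_tsv(out / "centrality" / f"{slug}.tsv", cent)
                manifest["networks"].append(slug)

    # Stage 3: group statistics.
    try:
        anova = _anova_frame(dataset)
    except Exception as exc:
        raise PipelineError(f"stage=anova: {exc}") from exc
    _write_tsv(out / "anova.tsv", anova)
    manifest["files"].append("anova.tsv")

    if config.plots:
        try:
            from .plots import render_run_plots

            render_run_plots(dataset, out, config)
        except Exception as exc:
            raise PipelineError(f"stage=plots: {exc}") from exc
        manifest["files"].append("plots/")

    return manifest
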