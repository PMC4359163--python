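"""End-to-end orchestration: deconvolve -> infer links -> network -> MIS.

The pipeline is configured by a single mapping (typically loaded from
YAML), runs each stage with logging and row counts, and writes
deterministic artifacts plus a JSON run manifest.  Absent input paths are
filled in from the synthetic generators under the run's seed, so a demo
run needs no external data.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import response as rd
from .boolnet import BooleanNetwork, read_network
from .deconvolution import DeconvolutionConfig, deconvolve_contributions
from .links import InferenceConfig, LinkInferrer, links_to_network, write_links
from .mis import (
    KNOCK_DOWN,
    OVER_EXPRESS,
    InterventionSet,
    MISQuery,
    classify_mis,
    mis_unroll,
)
from .synthetic import (
    PAPERLIKE_CATEGORIES,
    PAPERLIKE_DISPLAY_NAMES,
    MixtureDesign,
    default_planted_design,
    generate_mixture_dataset,
    generate_response_dataset,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineError", "RunManifest", "run_pipeline", "report", "load_config"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending input."""


@dataclass
class RunManifest:
    """Provenance record of one pipeline run."""

    config: dict[str, Any]
    seed: int
    stages: dict[str, dict[str, Any]] = field(default_factory=dict)

    def record(self, stage: str, wall_time: float, **counts: Any) -> None:
        self.stages[stage] = {"wall_time_s": round(wall_time, 4), **counts}

    def to_json(self) -> str:
        return json.dumps(
            {"config": self.config, "seed": self.seed, "stages": self.stages},
            indent=2,
            sort_keys=True,
            default=str,
        )

    def write(self, path) -> None:
        Path(path).write_text(self.to_json() + "\n", encoding="utf-8")


_DEFAULTS: dict[str, Any] = {
    "seed": 0,
    "out_dir": "temnet-run",
    "receptor_table": None,
    "cytokine_table": None,
    "composition_table": None,
    "bulk_table": None,
    "network_file": None,
    "roots": ["TIE2", "VEGFR1"],
    "k_max": 3,
    "inference": {},
    "deconvolution": {},
}


def load_config(path=None, overrides: Mapping[str, Any] | None = None) -> dict[str, Any]:
    """Merge YAML config (optional) and overrides onto the defaults."""
    import yaml

    config = {k: (dict(v) if isinstance(v, dict) else v) for k, v in _DEFAULTS.items()}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if not isinstance(loaded, dict):
            raise PipelineError(f"config {path} must be a mapping")
        config.update(loaded)
    for key, value in (overrides or {}).items():
        if value is not None:
            config[key] = value
    return config


def _stage(manifest: RunManifest, name: str):
    class _Timer:
        def __enter__(self):
            self.start = time.perf_counter()
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            self.elapsed = time.perf_counter() - self.start
            return False

    return _Timer()


def _resolve_roots(network: BooleanNetwork, wanted: list[str]) -> list[str]:
    if all(node in network.nodes for node in wanted):
        return list(wanted)
    fallback = sorted(n for n in network.nodes if n not in network.inputs and "_AND_" not in n)
    if len(fallback) < 2:
        raise PipelineError("network has fewer than two non-input nodes to use as roots")
    logger.info("configured roots %s absent; falling back to %s", wanted, fallback[:2])
    return fallback[:2]


def _mis_candidates(network: BooleanNetwork, roots: list[str]):
    """Therapeutic candidate policy: ligand inputs up, root receptors down."""
    ligands = [n for n in network.nodes if n in network.inputs]
    allowed = {n: (OVER_EXPRESS,) for n in ligands}
    for root in roots:
        allowed[root] = (KNOCK_DOWN,)
    return tuple(ligands + [r for r in roots if r not in ligands]), allowed


def _ancestor_closure(network: BooleanNetwork, roots: list[str]) -> BooleanNetwork:
    """Restrict to the regulator closure of the roots.

    Exact for networks whose removed part is purely downstream of the kept
    part (the readout layer of a link-built network); used to keep
    exhaustive fixed-point scans small.
    """
    keep: set[str] = set()
    frontier = list(roots)
    while frontier:
        node = frontier.pop()
        if node in keep:
            continue
        keep.add(node)
        frontier.extend(network.regulators(node))
    nodes = tuple(n for n in network.nodes if n in keep)
    functions = {n: network.functions[n] for n in nodes}
    clamps = {n: v for n, v in network.clamps.items() if n in keep}
    return BooleanNetwork(nodes, functions, clamps, dict(network.metadata))


def run_pipeline(config: Mapping[str, Any]) -> RunManifest:
    """Execute the full chain and write artifacts into ``out_dir``.

    Stages: load-or-generate inputs, per-cytokine deconvolution, link
    inference, network assembly (or a curated equation file), fixed
    points, MIS for both phenotype constraints (all roots high =
    promoting, all low = dampening), classified report.  Deterministic
    given config and seed.
    """
    config = dict(config)
    seed = int(config.get("seed", 0))
    out_dir = Path(config.get("out_dir", "temnet-run"))
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config, seed=seed)

    # -- inputs ------------------------------------------------------------
    with _stage(manifest, "inputs") as timer:
        if config.get("receptor_table") and config.get("cytokine_table"):
            receptor_table = rd.read_response_table(config["receptor_table"], rd.RECEPTOR)
            cytokine_table = rd.read_response_table(config["cytokine_table"], rd.CYTOKINE)
            truth = None
        else:
            design = default_planted_design(seed=seed)
            receptor_table, cytokine_table, truth = generate_response_dataset(design)
            rd.write_response_table(receptor_table, out_dir / "receptor_responses.tsv")
            rd.write_response_table(cytokine_table, out_dir / "cytokine_responses.tsv")
    manifest.record(
        "inputs",
        timer.elapsed,
        receptor_rows=len(receptor_table.data),
        cytokine_rows=len(cytokine_table.data),
        synthetic=truth is not None,
    )

    # -- deconvolution -----------------------------------------------------
    with _stage(manifest, "deconvolution") as timer:
        deconv_config = DeconvolutionConfig(**config.get("deconvolution", {}))
        if config.get("composition_table") and config.get("bulk_table"):
            comp_frame = pd.read_csv(config["composition_table"], sep="\t")
            bulk_frame = pd.read_csv(config["bulk_table"], sep="\t")
            merged = bulk_frame.merge(comp_frame, on="replicate")
            compositions = merged[["Na", "Nb", "Nc"]].to_numpy(dtype=float)
            measurements = merged["value"].to_numpy(dtype=float)
        else:
            measurements, compositions, _ = generate_mixture_dataset(MixtureDesign(seed=seed))
        contribution = deconvolve_contributions(measurements, compositions, deconv_config)
        contrib_frame = pd.DataFrame(
            {
                "population": ["DN", "SP", "DP"],
                "contribution_percent": list(contribution.as_array()),
                "clamped": [p in contribution.clamped for p in ("DN", "SP", "DP")],
                "iqr": list(contribution.spread),
            }
        )
        contrib_frame.to_csv(out_dir / "population_contributions.tsv", sep="\t", index=False)
        (out_dir / "deconvolution_summary.json").write_text(
            json.dumps(
                {
                    "n_systems_solved": contribution.n_systems_solved,
                    "clamped": sorted(contribution.clamped),
                },
                indent=2,
            )
            + "\n",
            encoding="utf-8",
        )
    manifest.record(
        "deconvolution",
        timer.elapsed,
        n_replicates=len(measurements),
        n_systems_solved=contribution.n_systems_solved,
        clamped=sorted(contribution.clamped),
    )

    # -- link inference ----------------------------------------------------
    with _stage(manifest, "links") as timer:
        inference_config = InferenceConfig(**config.get("inference", {}))
        inferrer = LinkInferrer(
            reproducibility_fraction=inference_config.reproducibility_fraction,
            amplitude_quantiles=inference_config.amplitude_quantiles,
            coherence_min_treatments=inference_config.coherence_min_treatments,
            require_both_amplitude=inference_config.require_both_amplitude,
            coherence_requires_amplitude=inference_config.coherence_requires_amplitude,
        )
        inferrer.fit(receptor_table, cytokine_table)
        write_links(inferrer.links_, out_dir / "retained_links.tsv")
    manifest.record(
        "links",
        timer.elapsed,
        n_candidates=len(inferrer.candidates_),
        n_retained=len(inferrer.links_),
    )

    # -- network -----------------------------------------------------------
    with _stage(manifest, "network") as timer:
        if config.get("network_file"):
            network = read_network(config["network_file"])
        else:
            if not inferrer.links_:
                raise PipelineError("no retained links and no curated network file")
            network = links_to_network(inferrer.links_)
        network.write(out_dir / "network.bnet")
        network.write_dot(out_dir / "network.dot")
    manifest.record("network", timer.elapsed, n_nodes=network.n_nodes)

    # -- fixed points ------------------------------------------------------
    with _stage(manifest, "fixed_points") as timer:
        roots = _resolve_roots(network, list(config.get("roots", [])))
        core = network if network.n_nodes <= 20 else _ancestor_closure(network, roots)
        fps = core.fixed_points()
        fp_frame = pd.DataFrame(fps)
        fp_frame.to_csv(out_dir / "fixed_points.tsv", sep="\t", index=False)
    manifest.record(
        "fixed_points", timer.elapsed, n_fixed_points=len(fps), core_nodes=core.n_nodes, roots=roots
    )

    # -- MIS ---------------------------------------------------------------
    with _stage(manifest, "mis") as timer:
        candidates, allowed = _mis_candidates(core, roots)
        k_max = int(config.get("k_max", 3))
        results: dict[str, list[InterventionSet]] = {}
        for label, polarity in (("promoting", 1), ("dampening", 0)):
            query = MISQuery(
                network=core,
                constraint={root: polarity for root in roots},
                k_max=k_max,
                candidate_nodes=candidates,
                allowed_polarities=allowed,
            )
            results[label] = mis_unroll(query)
        (out_dir / "mis.json").write_text(
            json.dumps(
                {
                    label: [
                        [{"node": iv.node, "polarity": iv.polarity} for iv in sorted(s)]
                        for s in sets
                    ]
                    for label, sets in results.items()
                },
                indent=2,
            )
            + "\n",
            encoding="utf-8",
        )
        categories = config.get("node_categories") or PAPERLIKE_CATEGORIES
        rows = []
        for label, sets in results.items():
            for row in classify_mis(sets, categories, PAPERLIKE_DISPLAY_NAMES):
                rows.append({"transition": label, **row})
        mis_frame = pd.DataFrame(rows)
        mis_frame.to_csv(out_dir / "mis_report.tsv", sep="\t", index=False)
    manifest.record(
        "mis",
        timer.elapsed,
        n_promoting=len(results["promoting"]),
        n_dampening=len(results["dampening"]),
        k_max=k_max,
    )

    manifest.write(out_dir / "manifest.json")
    return manifest


def report(manifest: RunManifest, out_dir=None) -> str:
    """Render a Markdown summary of a completed run from its artifacts."""
    out_dir = Path(out_dir or manifest.config.get("out_dir", "temnet-run"))
    lines = ["# temnet run summary", ""]
    lines.append(f"Seed: {manifest.seed}")
    lines.append("")
    links_stage = manifest.stages.get("links", {})
    lines.append(
        f"Retained {links_stage.get('n_retained', 0)} of "
        f"{links_stage.get('n_candidates', 0)} candidate links."
    )
    deconv = manifest.stages.get("deconvolution", {})
    if deconv:
        clamped = deconv.get("clamped") or []
        note = f" (clamped to floor: {', '.join(clamped)})" if clamped else ""
        lines.append(
            f"Deconvolution solved {deconv.get('n_systems_solved', 0)} replicate-triple "
            f"systems{note}."
        )
    fps = manifest.stages.get("fixed_points", {})
    if fps:
        lines.append(
            f"Fixed points: {fps.get('n_fixed_points', 0)} on the {fps.get('core_nodes')}-node "
            f"core (roots: {', '.join(fps.get('roots', []))})."
        )
    mis_stage = manifest.stages.get("mis", {})
    if mis_stage:
        lines.append("")
        lines.append("## Minimal intervention sets")
        lines.append("")
        n_promoting = mis_stage.get("n_promoting", 0)
        n_dampening = mis_stage.get("n_dampening", 0)
        k_max = mis_stage.get("k_max", 3)
        if n_promoting + n_dampening == 0:
            lines.append(f"No intervention set of size <= {k_max} found.")
        else:
            lines.append(
                f"{n_promoting} promoting and {n_dampening} dampening set(s) of size <= {k_max}."
            )
            mis_path = out_dir / "mis_report.tsv"
            if mis_path.exists():
                table = pd.read_csv(mis_path, sep="\t")
                lines.append("")
                lines.append("| " + " | ".join(table.columns) + " |")
                lines.append("|" + "---|" * len(table.columns))
                for _, row in table.iterrows():
                    lines.append("| " + " | ".join(str(v) for v in row) + " |")
    text = "\n".join(lines) + "\n"
    (out_dir / "report.md").write_text(text, encoding="utf-8")
    return text
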