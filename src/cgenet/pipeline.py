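"""End-to-end orchestration: expression -> networks -> communities ->
contrasts -> renders, with a reproducibility manifest.

One config drives the whole analysis. Defaults mirror the standard protocol:
edge threshold alpha = 0.05, FDR level q = 0.35, resolution gamma = 1, each
drug group contrasted against the same-gene, same-age saline baseline.
Re-running an identical config produces byte-identical artifacts; the
manifest records parameters, seeds, per-stage SHA-256 checksums and package
versions so a run can be audited or resumed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib
import networkx
import numpy
import pandas
import scipy
import yaml

from . import __version__
from .community import CommunityPartition, detect_communities, write_partition
from .compare import DEFAULT_Q, DifferenceMap, compare_networks, write_difference_map
from .errors import CgenetError
from .expression import ExpressionTable, GroupKey, load_expression, write_expression
from .network import (
    DEFAULT_ALPHA,
    CorrelationNetwork,
    ThresholdedNetwork,
    pearson_network,
    threshold_network,
    write_matrix,
)
from .registry import RegionRegistry, default_region_registry
from .simulate import SimulationDesign, default_design, design_from_dict, simulate_expression
from .viz import render_difference_map, render_network

logger = logging.getLogger(__name__)

BASELINE_TREATMENT = "saline"
#: typical subjects-per-group range; outside it a validation warning is logged
EXPECTED_N = (6, 7)


@dataclass(frozen=True)
class PipelineConfig:
    input_table: Path | None = None
    design: SimulationDesign | None = None
    alpha: float = DEFAULT_ALPHA
    q_level: float = DEFAULT_Q
    fdr_method: str = "bh"
    gamma: float = 1.0
    seed: int = 0
    restarts: int = 20
    positive_only: bool = False
    allow_missing: bool = False
    render: bool = True
    contrasts: tuple[tuple[GroupKey, GroupKey], ...] | None = None
    output_dir: Path = Path("cge_out")

    def __post_init__(self) -> None:
        if (self.input_table is None) == (self.design is None):
            raise CgenetError(
                "config needs exactly one of input_table or simulation design"
            )


@dataclass
class PipelineResult:
    networks: dict[GroupKey, CorrelationNetwork]
    thresholded: dict[GroupKey, ThresholdedNetwork]
    partitions: dict[GroupKey, CommunityPartition]
    differences: dict[tuple[GroupKey, GroupKey], DifferenceMap]
    manifest_path: Path
    artifacts: dict[str, str] = field(default_factory=dict)


def default_contrasts(
    groups: list[GroupKey], baseline: str = BASELINE_TREATMENT
) -> tuple[tuple[GroupKey, GroupKey], ...]:
    """Each non-baseline group vs the matched (gene, age) baseline group."""
    present = set(groups)
    out = []
    for g in groups:
        if g.treatment == baseline:
            continue
        base = GroupKey(g.gene, g.age, baseline)
        if base in present:
            out.append((g, base))
    return tuple(out)


def _validate_contrasts(
    contrasts: tuple[tuple[GroupKey, GroupKey], ...], groups: list[GroupKey]
) -> None:
    present = set(groups)
    for a, b in contrasts:
        if a not in present or b not in present:
            raise CgenetError(f"contrast ({a}, {b}) references absent group")
        if a.gene != b.gene or a.age != b.age:
            raise CgenetError(
                f"contrast ({a.label()}, {b.label()}) must match gene and age"
            )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(
    config: PipelineConfig, registry: RegionRegistry | None = None
) -> PipelineResult:
    registry = registry or default_region_registry()
    out = Path(config.output_dir)
    for sub in ("nets", "partitions", "diffs", "renders"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    def record(path: Path) -> None:
        artifacts[str(path.relative_to(out))] = _sha256(path)

    if config.design is not None:
        logger.info("stage simulate: %d groups", len(config.design.groups))
        table = simulate_expression(config.design, registry)
        record(write_expression(table, out / "expression.tsv"))
    else:
        logger.info("stage load: %s", config.input_table)
        table = load_expression(config.input_table, registry)

    groups = table.groups()
    for key, n in table.subject_counts().items():
        if not EXPECTED_N[0] <= n <= EXPECTED_N[1]:
            logger.warning("group %s has n=%d (typical range %s)",
                           key, n, EXPECTED_N)

    networks: dict[GroupKey, CorrelationNetwork] = {}
    thresholded: dict[GroupKey, ThresholdedNetwork] = {}
    partitions: dict[GroupKey, CommunityPartition] = {}
    for g in groups:
        try:
            net = pearson_network(
                table, g, registry, allow_missing=config.allow_missing
            )
        except CgenetError as exc:
            raise CgenetError(f"stage network, group {g.label()}: {exc}") from exc
        thr = threshold_network(net, config.alpha)
        part = detect_communities(
            thr, gamma=config.gamma, seed=config.seed,
            restarts=config.restarts, positive_only=config.positive_only,
        )
        networks[g], thresholded[g], partitions[g] = net, thr, part
        label = g.label()
        record(write_matrix(net.r, out / "nets" / f"{label}_r.csv"))
        record(write_matrix(net.p, out / "nets" / f"{label}_p.csv"))
        record(write_matrix(thr.w, out / "nets" / f"{label}_thresholded.csv"))
        record(write_partition(part, out / "partitions" / f"{label}.tsv"))
        if config.render:
            record(render_network(thr, part, registry,
                                  out / "renders" / f"{label}.svg"))

    contrasts = config.contrasts
    if contrasts is None:
        contrasts = default_contrasts(groups)
    _validate_contrasts(contrasts, groups)

    differences: dict[tuple[GroupKey, GroupKey], DifferenceMap] = {}
    for a, b in contrasts:
        diff = compare_networks(
            networks[a], networks[b], thresholded[a], thresholded[b],
            q_level=config.q_level, method=config.fdr_method,
        )
        differences[(a, b)] = diff
        name = f"{a.label()}__vs__{b.label()}"
        record(write_difference_map(diff, out / "diffs" / f"{name}.tsv"))
        if config.render:
            record(render_difference_map(diff, registry,
                                         out / "renders" / f"{name}.svg"))

    manifest = {
        "cgenet_version": __version__,
        "library_versions": {
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "pandas": pandas.__version__,
            "networkx": networkx.__version__,
            "matplotlib": matplotlib.__version__,
        },
        "parameters": {
            "alpha": config.alpha,
            "q_level": config.q_level,
            "fdr_method": config.fdr_method,
            "gamma": config.gamma,
            "seed": config.seed,
            "restarts": config.restarts,
            "positive_only": config.positive_only,
            "tail": "two-sided",
        },
        "groups": {g.label(): networks[g].n for g in groups},
        "contrasts": [[a.label(), b.label()] for a, b in contrasts],
        "checksums": dict(sorted(artifacts.items())),
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return PipelineResult(
        networks=networks, thresholded=thresholded, partitions=partitions,
        differences=differences, manifest_path=manifest_path,
        artifacts=artifacts,
    )


def config_from_yaml(
    path: str | Path, registry: RegionRegistry | None = None
) -> PipelineConfig:
    """Parse a pipeline config file (schema in the package docs)."""
    registry = registry or default_region_registry()
    raw = yaml.safe_load(Path(path).read_text())
    seed = int(raw.get("seed", 0))
    inp = raw.get("input", {})
    input_table = Path(inp["table"]) if "table" in inp else None
    design = None
    if "simulate" in inp:
        sim = inp["simulate"]
        if sim.get("design") == "default":
            design = default_design(
                seed=seed, n_subjects=int(sim.get("n_subjects", 7)),
                registry=registry,
            )
        else:
            design = design_from_dict(sim["design"], registry, seed=seed)
    contrasts = None
    if isinstance(raw.get("contrasts"), list):
        contrasts = tuple(
            (GroupKey(**a), GroupKey(**b)) for a, b in raw["contrasts"]
        )
    return PipelineConfig(
        input_table=input_table,
        design=design,
        alpha=float(raw.get("alpha", DEFAULT_ALPHA)),
        q_level=float(raw.get("q_level", DEFAULT_Q)),
        fdr_method=str(raw.get("fdr_method", "bh")),
        gamma=float(raw.get("gamma", 1.0)),
        seed=seed,
        restarts=int(raw.get("restarts", 20)),
        positive_only=bool(raw.get("positive_only", False)),
        allow_missing=bool(raw.get("allow_missing", False)),
        render=bool(raw.get("render", True)),
        contrasts=contrasts,
        output_dir=Path(raw.get("output_dir", "cge_out")),
    )
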