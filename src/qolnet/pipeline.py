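"""Full analysis pipeline: per-group networks, centrality, comparison, layout.

The pipeline mirrors a two-sample questionnaire study design:

* item-level networks for each group and for the combined sample, with the
  binary group indicator appended as an extra node in the combined network
  (polychoric input; the binary indicator is a 2-category ordinal item);
* domain-level networks per group and combined (domain scores are
  quasi-continuous, so Pearson correlations feed the glasso there; the
  binary indicator enters the combined domain matrix as a point-biserial
  Pearson column);
* closeness centrality per network;
* permutation comparison tests, weighted and unweighted, at each level;
* Fruchterman-Reingold layout coordinates per network (coordinates are
  exported; rendering is left to downstream tools).

Every produced file is listed in the run report with a SHA-256 checksum,
and the report body is deterministic for a fixed config and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from . import __version__
from .centrality import closeness
from .comparison import compare_networks
from .exceptions import DataError
from .ggm import DEFAULT_GAMMA, DEFAULT_PATH_LENGTH, DEFAULT_PATH_RATIO, NetworkModel, select_network
from .ordinal import ItemSpec, OrdinalDataset, read_ordinal_csv, score_domains, sf36_instrument
from .polychoric import pearson_matrix, polychoric_matrix
from .synthetic import SyntheticSpec, make_two_groups

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a pipeline run needs; the seed is always recorded."""

    data_csv: str | None = None
    group_col: str = "group"
    instrument: str = "sf36"  # "sf36" or a path to an instrument YAML
    synthetic: SyntheticSpec | None = None
    levels: tuple[str, ...] = ("item", "domain")
    include_combined: bool = True
    gamma: float = DEFAULT_GAMMA
    path_length: int = DEFAULT_PATH_LENGTH
    path_ratio: float = DEFAULT_PATH_RATIO
    n_permutations: int = 1000
    seed: int = 0
    out_dir: str = "qolnet_run"
    layout_iterations: int = 500

    def __post_init__(self) -> None:
        if not self.levels:
            raise DataError("at least one analysis level is required")
        for lv in self.levels:
            if lv not in ("item", "domain"):
                raise DataError(f"unknown analysis level {lv!r}")
        if self.data_csv is None and self.synthetic is None:
            raise DataError("config needs either data_csv or a synthetic spec")


@dataclass
class RunReport:
    """Metadata, file inventory (with checksums) and results of one run."""

    config: dict
    version: str
    networks: dict
    comparisons: dict
    files: dict
    warnings: list
    stage_seconds: dict

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


def fr_layout(
    weights: np.ndarray,
    seed: int = 0,
    labels: list[str] | None = None,
    iterations: int = 500,
) -> dict[str, tuple[float, float]]:
    """Force-directed (Fruchterman-Reingold) coordinates with |w| attraction.

    Strongly connected nodes end up closer together; the seed fixes the
    random initialisation so coordinates are reproducible.
    """
    weights = np.asarray(weights, dtype=float)
    p = weights.shape[0]
    labels = list(labels) if labels is not None else [f"v{i}" for i in range(p)]
    g = nx.Graph()
    g.add_nodes_from(labels)
    for i in range(p):
        for j in range(i + 1, p):
            if weights[i, j] != 0:
                g.add_edge(labels[i], labels[j], weight=abs(weights[i, j]))
    pos = nx.spring_layout(g, weight="weight", iterations=iterations, seed=seed)
    return {lab: (float(xy[0]), float(xy[1])) for lab, xy in pos.items()}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_groups(config: RunConfig) -> tuple[OrdinalDataset, OrdinalDataset, list[str]]:
    if config.synthetic is not None:
        data_a, data_b, _ = make_two_groups(config.synthetic)
        return data_a, data_b, ["A", "B"]
    if config.instrument == "sf36":
        instrument = sf36_instrument()
    else:
        from .ordinal import load_instrument

        instrument = load_instrument(config.instrument)
    data = read_ordinal_csv(config.data_csv, instrument, group_col=config.group_col)
    if data.group is None:
        raise DataError("pipeline needs a group column for the two-sample design")
    groups = data.split_groups()
    if len(groups) != 2:
        raise DataError(
            f"exactly two groups required, found {sorted(groups)} in "
            f"column {config.group_col!r}"
        )
    names = sorted(groups)
    return groups[names[0]], groups[names[1]], names


def _combined_dataset(
    data_a: OrdinalDataset, data_b: OrdinalDataset, node: str = "DS"
) -> OrdinalDataset:
    """Pool both groups and append the binary group indicator as an item."""
    values = np.vstack([data_a.values, data_b.values])
    indicator = np.concatenate(
        [np.zeros(data_a.n_respondents, np.int64), np.ones(data_b.n_respondents, np.int64)]
    )
    items = list(data_a.items) + [ItemSpec(node, 2, False, "none")]
    return OrdinalDataset(
        values=np.column_stack([values, indicator]), items=items
    )


def _write_network(
    net: NetworkModel, name: str, out: Path, seed: int, layout_iterations: int
) -> tuple[dict, list[Path]]:
    files = []
    net.weights_to_csv(out / f"{name}_weights.csv")
    net.edges_to_tsv(out / f"{name}_edges.tsv")
    net.to_graphml(out / f"{name}_network.graphml")
    net.metadata_to_json(out / f"{name}_metadata.json")
    files += [
        out / f"{name}_weights.csv", out / f"{name}_edges.tsv",
        out / f"{name}_network.graphml", out / f"{name}_metadata.json",
    ]
    table = closeness(net.weights, labels=net.labels, network=name)
    table.to_tsv(out / f"{name}_centrality.tsv")
    files.append(out / f"{name}_centrality.tsv")
    coords = fr_layout(
        net.weights, seed=seed, labels=net.labels, iterations=layout_iterations
    )
    with open(out / f"{name}_layout.csv", "w") as fh:
        fh.write("label,x,y\n")
        for lab in net.labels:
            x, y = coords[lab]
            fh.write(f"{lab},{x:.10g},{y:.10g}\n")
    files.append(out / f"{name}_layout.csv")
    return net.metadata(), files


def run_pipeline(config: RunConfig) -> RunReport:
    """Run the full two-sample network analysis described by the config."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.perf_counter()
    stage_seconds: dict[str, float] = {}
    warnings_log: list[str] = []
    networks: dict[str, dict] = {}
    comparisons: dict[str, dict] = {}
    produced: list[Path] = []

    data_a, data_b, names = _load_groups(config)
    stage_seconds["load"] = round(time.perf_counter() - t_start, 3)

    domains = [it.domain for it in data_a.items]

    def item_network(data: OrdinalDataset, doms: list[str]) -> NetworkModel:
        r = polychoric_matrix(data)
        return select_network(
            r, gamma=config.gamma, labels=data.labels, domains=doms,
        )

    if "item" in config.levels:
        t0 = time.perf_counter()
        runs = {
            f"item_{names[0]}": (data_a, domains),
            f"item_{names[1]}": (data_b, domains),
        }
        if config.include_combined:
            combined = _combined_dataset(data_a, data_b)
            runs["item_combined"] = (combined, domains + ["none"])
        for name, (data, doms) in runs.items():
            net = item_network(data, doms)
            meta, files = _write_network(
                net, name, out, config.seed, config.layout_iterations
            )
            networks[name] = meta
            produced += files
        stage_seconds["item_networks"] = round(time.perf_counter() - t0, 3)

        t0 = time.perf_counter()
        item_cmp = compare_networks(
            data_a, data_b, n_permutations=config.n_permutations,
            gamma=config.gamma, seed=config.seed,
        )
        for mode, res in item_cmp.items():
            path = out / f"comparison_item_{mode}.json"
            res.to_json(path)
            produced.append(path)
            comparisons[f"item_{mode}"] = {
                "t_obs": res.t_obs, "p_value": res.p_value, "mode": mode,
                "n_permutations": res.n_permutations,
            }
        stage_seconds["item_comparison"] = round(time.perf_counter() - t0, 3)

    if "domain" in config.levels:
        t0 = time.perf_counter()
        has_domains = any(d != "none" for d in domains)
        if not has_domains:
            raise DataError("domain-level analysis requires items with domains")
        scores_a = score_domains(data_a)
        scores_b = score_domains(data_b)
        runs_d: dict[str, np.ndarray] = {
            f"domain_{names[0]}": scores_a.scores,
            f"domain_{names[1]}": scores_b.scores,
        }
        labels_d = scores_a.domains
        if config.include_combined:
            pooled = np.vstack([scores_a.scores, scores_b.scores])
            indicator = np.concatenate(
                [np.zeros(scores_a.scores.shape[0]), np.ones(scores_b.scores.shape[0])]
            )
            runs_d["domain_combined"] = np.column_stack([pooled, indicator])
        for name, mat in runs_d.items():
            labs = labels_d + (["DS"] if mat.shape[1] > len(labels_d) else [])
            r = pearson_matrix(mat, labels=labs)
            net = select_network(r, gamma=config.gamma, labels=labs, domains=labs)
            meta, files = _write_network(
                net, name, out, config.seed, config.layout_iterations
            )
            networks[name] = meta
            produced += files
        stage_seconds["domain_networks"] = round(time.perf_counter() - t0, 3)

        t0 = time.perf_counter()
        dom_cmp = compare_networks(
            scores_a.scores, scores_b.scores, n_permutations=config.n_permutations,
            gamma=config.gamma, seed=config.seed, estimator="pearson",
        )
        for mode, res in dom_cmp.items():
            path = out / f"comparison_domain_{mode}.json"
            res.to_json(path)
            produced.append(path)
            comparisons[f"domain_{mode}"] = {
                "t_obs": res.t_obs, "p_value": res.p_value, "mode": mode,
                "n_permutations": res.n_permutations,
            }
        stage_seconds["domain_comparison"] = round(time.perf_counter() - t0, 3)

    files = {str(pth.relative_to(out)): _sha256(pth) for pth in produced}
    config_echo = {
        k: (asdict(v) if isinstance(v, SyntheticSpec) else v)
        for k, v in asdict(config).items()
    }
    report = RunReport(
        config=config_echo,
        version=__version__,
        networks=networks,
        comparisons=comparisons,
        files=files,
        warnings=warnings_log,
        stage_seconds=stage_seconds,
    )
    report.to_json(out / "report.json")
    logger.info("pipeline finished: %d files in %s", len(files) + 1, out)
    return report
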