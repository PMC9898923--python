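"""End-to-end orchestration: read -> binarize -> summarize -> learn -> query.

``run_pipeline`` executes the full analysis described by a ``RunConfig``
and writes a deterministic report bundle:

* ``summary.json``    cohort summary (counts, shares, mean +/- SD sIgE)
* ``table1.tsv``      the same per-component table as TSV
* ``age_profile.tsv`` per-band sensitization frequencies (long format)
* ``net.json``        the learned network (nodes, edges, CPTs)
* ``net.dot``         Graphviz export of the learned DAG
* ``cpd_results.json``all requested conditional-probability queries
* ``run_config.yaml`` the resolved configuration actually used
* ``run.log``         structured log (timestamp-free, for reproducibility)

Identical config + seed produce byte-identical artifacts.  Any stage error
aborts the run with the stage name and removes partial outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from .bayesnet import BayesNet, fit_cpds
from .cohort import (
    AgeBands,
    DEFAULT_CHILD_CUTOFF,
    DEFAULT_CUTPOINTS,
    DEFAULT_THRESHOLD,
    binarize,
    cohort_summary,
    filter_sensitized,
    group_frequency_table,
)
from .inference import query
from .learn import learn_structure_chowliu, learn_structure_hc
from .panel_io import export_dag_dot, read_panel

logger = logging.getLogger(__name__)

#: Default query set: each component's reported neighbourhood pattern, in
#: presence and absence form, plus the marginal for the unaffected root
#: Der p 21.  ``(target assignment, evidence assignment)`` pairs.
DEFAULT_QUERIES: tuple[tuple[dict, dict], ...] = (
    ({"Der p 23": 1}, {"Der p 1": 1, "Der p 5": 1, "Der p 7": 1}),
    ({"Der p 23": 0}, {"Der p 1": 0, "Der p 5": 0, "Der p 7": 0}),
    ({"Der f 1": 1}, {"Der f 2": 1, "Der p 1": 1, "Der p 23": 1}),
    ({"Der p 10": 1}, {"Der f 1": 1, "Der f 2": 1, "Der p 20": 1, "Der p 23": 1}),
    ({"Der p 10": 0}, {"Der f 1": 1, "Der f 2": 1, "Der p 20": 1, "Der p 23": 1}),
    ({"Der p 10": 0}, {"Der f 1": 0, "Der f 2": 0, "Der p 20": 0, "Der p 23": 0}),
    ({"Der f 2": 1}, {"Der p 1": 1, "Der p 21": 1, "Der p 23": 1, "Der p 7": 1}),
    ({"Der f 2": 1}, {"Der p 1": 0, "Der p 21": 0, "Der p 23": 0, "Der p 7": 0}),
    ({"Der p 2": 1}, {"Der f 2": 1, "Der p 1": 1}),
    ({"Der p 11": 1}, {"Der f 2": 1}),
    ({"Der f 2": 1}, {"Der p 11": 0}),
    ({"Der p 20": 1}, {"Der f 2": 0, "Der p 1": 0, "Der p 23": 0, "Der p 5": 0}),
    ({"Der p 1": 1}, {"Der p 21": 1, "Der p 5": 1, "Der p 7": 1}),
    ({"Der p 1": 0}, {"Der p 21": 0, "Der p 5": 0, "Der p 7": 0}),
    ({"Der p 21": 1}, {}),
    ({"Der p 5": 1}, {"Der p 21": 1}),
    ({"Der p 5": 0}, {"Der p 21": 0}),
    ({"Der p 7": 0}, {"Der p 21": 0, "Der p 5": 0}),
)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Serializable description of one end-to-end run."""

    input: str
    outdir: str
    threshold: float = DEFAULT_THRESHOLD
    child_cutoff: float = DEFAULT_CHILD_CUTOFF
    bands: tuple[float, ...] = DEFAULT_CUTPOINTS
    method: str = "hc"  # "hc" | "chowliu"
    root: str | None = "Der p 23"
    root_constraint: bool = True
    alpha: float = 1.0
    max_parents: int = 4
    seed: int = 0
    delimiter: str | None = None
    queries: Sequence[tuple[Mapping[str, int], Mapping[str, int]]] = field(
        default_factory=lambda: [(dict(t), dict(e)) for t, e in DEFAULT_QUERIES]
    )
    log_level: str = "INFO"

    def to_yaml(self, path: str | Path) -> None:
        doc = asdict(self)
        doc["bands"] = list(self.bands)
        doc["queries"] = [{"target": dict(t), "evidence": dict(e)} for t, e in self.queries]
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=True), encoding="utf-8")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        if "bands" in doc:
            doc["bands"] = tuple(doc["bands"])
        if "queries" in doc:
            doc["queries"] = [
                (dict(q["target"]), dict(q["evidence"])) for q in doc["queries"]
            ]
        return cls(**doc)


def _write_json(path: Path, payload) -> None:
    path.write_text(
        json.dumps(payload, indent=2, sort_keys=True, allow_nan=False) + "\n",
        encoding="utf-8",
    )


def _summary_tsv(summary_dict: dict, path: Path) -> None:
    cols = [
        "n", "share", "mean_sige", "sd_sige",
        "n_children", "share_children", "mean_sige_children", "sd_sige_children",
        "n_adults", "share_adults", "mean_sige_adults", "sd_sige_adults",
    ]
    lines = ["component\t" + "\t".join(cols)]
    for comp, row in summary_dict["per_component"].items():
        cells = []
        for c in cols:
            v = row.get(c)
            if v is None:
                cells.append("NA")
            elif isinstance(v, float):
                cells.append(f"{v:.2f}")
            else:
                cells.append(str(v))
        lines.append(comp + "\t" + "\t".join(cells))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def _age_profile_tsv(profile, path: Path) -> None:
    lines = ["band\tn_band\tcomponent\tpct_within_band\tpct_of_sensitized"]
    for band in profile.pct_within_band.index:
        n_band = int(profile.band_sizes[band])
        for comp in profile.pct_within_band.columns:
            within = profile.pct_within_band.loc[band, comp]
            total = profile.pct_of_sample.loc[band, comp]
            within_s = "NA" if within != within else f"{within:.2f}"
            lines.append(f"{band}\t{n_band}\t{comp}\t{within_s}\t{total:.2f}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def learn_network(matrix, config: RunConfig) -> BayesNet:
    """Structure learning + CPD fitting as configured."""
    root = config.root if config.root_constraint else None
    if config.method == "hc":
        dag = learn_structure_hc(
            matrix, root=root, max_parents=config.max_parents, seed=config.seed
        )
    elif config.method == "chowliu":
        if config.root is None:
            raise ValueError("chowliu requires a root node")
        dag = learn_structure_chowliu(matrix, root=config.root)
    else:
        raise ValueError(f"unknown method {config.method!r}")
    return fit_cpds(dag, matrix, alpha=config.alpha)


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute the full pipeline; return the artifact paths."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    created: list[Path] = []

    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    pkg_logger = logging.getLogger("mitebn")
    old_level = pkg_logger.level
    pkg_logger.addHandler(handler)
    pkg_logger.setLevel(config.log_level)
    created.append(log_path)

    stage = "setup"
    try:
        stage = "read"
        table = read_panel(config.input, delimiter=config.delimiter)
        logger.info("read %d patients from %s", table.n, config.input)

        stage = "binarize"
        matrix = filter_sensitized(binarize(table, config.threshold))
        logger.info("sensitized patients: %d", matrix.n)
        if matrix.n == 0:
            raise ValueError("no sensitized patients above threshold")

        stage = "summarize"
        summary = cohort_summary(
            table, matrix, threshold=config.threshold, child_cutoff=config.child_cutoff
        )
        summary_dict = summary.to_dict()
        _write_json(outdir / "summary.json", summary_dict)
        created.append(outdir / "summary.json")
        _summary_tsv(summary_dict, outdir / "table1.tsv")
        created.append(outdir / "table1.tsv")
        profile = group_frequency_table(matrix, AgeBands(config.bands))
        _age_profile_tsv(profile, outdir / "age_profile.tsv")
        created.append(outdir / "age_profile.tsv")

        stage = "learn"
        net = learn_network(matrix, config)
        net.save(outdir / "net.json")
        created.append(outdir / "net.json")
        export_dag_dot(net, outdir / "net.dot")
        created.append(outdir / "net.dot")
        logger.info("learned %d edges with method=%s", len(net.dag.edges), config.method)

        stage = "query"
        results = [query(net, dict(t), dict(e)).to_dict() for t, e in config.queries]
        _write_json(outdir / "cpd_results.json", results)
        created.append(outdir / "cpd_results.json")

        stage = "archive"
        config.to_yaml(outdir / "run_config.yaml")
        created.append(outdir / "run_config.yaml")
    except Exception as exc:
        pkg_logger.removeHandler(handler)
        handler.close()
        pkg_logger.setLevel(old_level)
        for p in created:
            p.unlink(missing_ok=True)
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    pkg_logger.removeHandler(handler)
    handler.close()
    pkg_logger.setLevel(old_level)
    return {p.name: p for p in created}
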