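"""End-to-end pipeline orchestration and the machine-readable run report."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .centrality import CENTRALITY_INDICES, centrality_table
from .community import spinglass_partition
from .data import ItemCatalog, OrdinalResponseMatrix, load_responses
from .layout import fr_layout
from .network import estimate_network
from .polychoric import polychoric_matrix
from .resampling import (
    DEFAULT_DROP_GRID,
    FitConfig,
    case_drop_stability,
    group_centrality_permutation,
    nonparametric_bootstrap,
)

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "validate_report"]

logger = logging.getLogger("bprsnet")


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of one run; everything randomized takes its seed here."""

    # network estimation
    gamma_ebic: float = 0.5
    n_lambda: int = 100
    lambda_min_ratio: float = 0.01
    closeness_variant: str = "reciprocal-total"
    # community detection
    gamma_spin: float = 0.5
    spins: int = 17
    t_start: float = 1.0
    t_stop: float = 0.01
    cooling: float = 0.99
    restarts: int = 10
    # optional inference stages
    run_stability: bool = False
    stability_grid: tuple[float, ...] = DEFAULT_DROP_GRID
    stability_B: int = 100
    run_bootstrap: bool = False
    bootstrap_B: int = 1000
    run_permutation: bool = False
    permutation_R: int = 100_000
    permutation_mode: str = "auto"
    # I/O
    missing_policy: str = "reject-file"
    top_k_edges: int = 10
    seed: int = 2016

    def fit_config(self) -> FitConfig:
        return FitConfig(
            gamma_ebic=self.gamma_ebic,
            n_lambda=self.n_lambda,
            lambda_min_ratio=self.lambda_min_ratio,
            closeness_variant=self.closeness_variant,
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            payload = json.load(fh)
        if "stability_grid" in payload:
            payload["stability_grid"] = tuple(payload["stability_grid"])
        return cls(**payload)


@dataclass(frozen=True)
class RunReport:
    """Everything a run computed, recomputable from inputs + config + seeds."""

    payload: dict
    timings_sec: dict = field(default_factory=dict)

    def to_dict(self, include_timings: bool = True) -> dict:
        out = dict(self.payload)
        if include_timings:
            out["timings_sec"] = self.timings_sec
        return out

    def to_json(self, path: str | Path | None = None, include_timings: bool = True) -> str:
        text = json.dumps(self.to_dict(include_timings), indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text


def validate_report(report: dict) -> None:
    """Check a report dict against the shipped schema (required keys and
    scalar types/bounds; a lightweight structural check)."""
    from importlib import resources as importlib_resources

    ref = importlib_resources.files("bprsnet.resources").joinpath(
        "report_schema.json"
    )
    schema = json.loads(ref.read_text(encoding="utf-8"))
    for key in schema["required"]:
        if key not in report:
            raise ValueError(f"report is missing required field '{key}'")
    typemap = {"object": dict, "integer": int, "number": (int, float),
               "boolean": bool, "array": list, "string": str}
    for key, sub in schema["properties"].items():
        if key not in report:
            continue
        expected = typemap[sub["type"]]
        if not isinstance(report[key], expected):
            raise ValueError(f"report field '{key}' has wrong type")
        if isinstance(report[key], (int, float)) and not isinstance(report[key], bool):
            if "minimum" in sub and report[key] < sub["minimum"]:
                raise ValueError(f"report field '{key}' below minimum")
            if "maximum" in sub and report[key] > sub["maximum"]:
                raise ValueError(f"report field '{key}' above maximum")


def run_pipeline(
    input_path: str | Path | OrdinalResponseMatrix,
    catalog: ItemCatalog | None = None,
    config: PipelineConfig | None = None,
    outdir: str | Path | None = None,
) -> RunReport:
    """Run data -> polychoric -> network -> centrality -> communities ->
    (optional) stability / bootstrap / permutation, writing artifacts to
    ``outdir`` when given. A stage failure removes partial artifacts and
    raises an error naming the stage."""
    config = config or PipelineConfig()
    timings: dict[str, float] = {}
    written: list[Path] = []
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    def _stage(name):
        class _Timer:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                logger.info("stage %s started", name)
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self_inner.t0, 4)
                if exc_type is None:
                    logger.info("stage %s finished in %.2fs", name, timings[name])
                else:
                    logger.error("stage %s failed: %s", name, exc)
                    for path in written:
                        path.unlink(missing_ok=True)
                    raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
                return False

        return _Timer()

    def _write(name: str, writer) -> None:
        if outdir is None:
            return
        path = outdir / name
        writer(path)
        written.append(path)

    with _stage("load"):
        if isinstance(input_path, OrdinalResponseMatrix):
            data = input_path
        else:
            if catalog is None:
                raise ValueError("a catalog is required to load a CSV")
            data = load_responses(
                input_path, catalog, policy=config.missing_policy
            )

    with _stage("polychoric"):
        poly = polychoric_matrix(data)
        _write("polychoric.tsv", poly.to_tsv)

    with _stage("network"):
        net = estimate_network(
            poly.correlation,
            n=data.n,
            item_codes=data.item_codes,
            gamma_ebic=config.gamma_ebic,
            n_lambda=config.n_lambda,
            lambda_min_ratio=config.lambda_min_ratio,
        )
        _write("weights.tsv", net.to_weight_tsv)
        _write("edges.tsv", net.to_edge_tsv)

    with _stage("centrality"):
        cent = centrality_table(net, config.closeness_variant)
        _write("centrality.csv", cent.to_csv)

    with _stage("communities"):
        partition = spinglass_partition(
            net,
            gamma_spin=config.gamma_spin,
            spins=config.spins,
            t_start=config.t_start,
            t_stop=config.t_stop,
            cooling=config.cooling,
            seed=config.seed,
            restarts=config.restarts,
        )
        if outdir is not None:
            import pandas as pd

            _write(
                "partition.csv",
                lambda p_: pd.DataFrame(
                    {"node": list(net.item_codes), "community": partition.labels}
                ).to_csv(p_, index=False),
            )

    with _stage("layout"):
        layout = fr_layout(net, seed=config.seed)
        _write("layout.tsv", layout.to_tsv)

    edge_frame = net.edge_list().head(config.top_k_edges)
    payload: dict = {
        "config": {
            **asdict(config),
            "stability_grid": list(config.stability_grid),
        },
        "versions": {"bprsnet": __version__},
        "n_subjects": data.n,
        "n_items": data.p,
        "n_dropped_rows": data.n_dropped,
        "possible_edges": net.possible_edges,
        "edge_count": net.edge_count,
        "edge_fraction_pct": round(100.0 * net.edge_fraction, 1),
        "selected_lambda": net.lam,
        "pd_adjusted": poly.pd_adjusted,
        "top_edges": [
            {
                "node_i": r.node_i,
                "node_j": r.node_j,
                "weight": round(float(r.weight), 6),
            }
            for r in edge_frame.itertuples()
        ],
        "centrality": {
            index: {
                code: round(float(v), 6)
                for code, v in zip(net.item_codes, cent.raw(index))
            }
            for index in CENTRALITY_INDICES
        },
        "partition": partition.summary(),
    }

    if config.run_stability:
        with _stage("stability"):
            stab = case_drop_stability(
                data,
                config.fit_config(),
                grid=config.stability_grid,
                B_per=config.stability_B,
                seed=config.seed,
            )
            payload["stability"] = stab.to_dict()

    if config.run_bootstrap:
        with _stage("bootstrap"):
            boot = nonparametric_bootstrap(
                data, config.fit_config(), B=config.bootstrap_B, seed=config.seed
            )
            payload["bootstrap"] = {
                "B": boot.B,
                "n_failed": boot.n_failed,
                "seed": boot.seed,
                "edge_ci": {
                    f"{net.item_codes[i]}-{net.item_codes[j]}": [
                        round(v, 6) for v in boot.edge_interval(i, j)
                    ]
                    for (i, j), w in zip(boot.pairs, boot.edge_point)
                    if w != 0
                },
            }

    if config.run_permutation:
        with _stage("permutation"):
            if catalog is None or "DSM" not in catalog.groups:
                raise ValueError("permutation test needs a catalog with groups")
            payload["permutation"] = {
                index: group_centrality_permutation(
                    cent.raw(index),
                    catalog,
                    R=config.permutation_R,
                    mode=config.permutation_mode,
                    seed=config.seed,
                ).to_dict()
                for index in CENTRALITY_INDICES
            }

    report = RunReport(payload=payload, timings_sec=timings)
    validate_report(report.to_dict())
    if outdir is not None:
        report.to_json(outdir / "report.json")
    return report
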