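"""End-to-end orchestration: simulate or load data, select DE genes, scan
sites, run the enrichment test, and write all result tables.

Every output file carries a commented header with the master seed and a
configuration hash; a run is byte-identical when repeated with the same
configuration and seed. On any stage failure, partial outputs are removed
and a stage-tagged error is raised.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from . import io as seio
from .diffexp import ExpressionMatrix, select_de
from .enrichment import TargetEnrichment, TargetEnrichmentResults
from .records import MatureMiRNA, UTRPool
from .simulate import SyntheticConfig, generate_two_mirna_scenario
from .sites import scan_pool

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message is tagged with the stage name."""


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    ``mode`` is ``"simulate"`` (generate a synthetic dataset, then analyse
    it) or ``"real-input"`` (consume the given FASTA/TSV paths). Exactly the
    inputs of the active mode are required.
    """

    out_dir: str | Path = "results"
    mode: str = "simulate"
    # real-input paths
    utr_fasta: str | Path | None = None
    mirna_tsv: str | Path | None = None
    expression_tsv: str | Path | None = None
    groups_tsv: str | Path | None = None
    # diffexp parameters
    fc_threshold: float = 2.0
    p_threshold: float = 0.05
    use_adjusted: bool = False
    # enrichment parameters
    B: int = 1000
    null_mode: str = "windows"
    fallback: str = "error"
    tie_mode: str = "strict"
    # master seed (simulation and resampling)
    seed: int = 0
    simulate: SyntheticConfig = field(default_factory=SyntheticConfig)
    write_null_dump: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "real-input"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.fc_threshold <= 0 or self.p_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if self.mode == "real-input":
            missing = [
                name
                for name, p in (
                    ("utr_fasta", self.utr_fasta),
                    ("mirna_tsv", self.mirna_tsv),
                    ("expression_tsv", self.expression_tsv),
                    ("groups_tsv", self.groups_tsv),
                )
                if p is None
            ]
            if missing:
                raise ValueError(f"real-input mode requires paths: {missing}")

    def meta(self) -> dict[str, Any]:
        cfg = dataclasses.asdict(self)
        cfg.pop("out_dir")
        return {"seed": self.seed, "config_hash": seio.config_hash(cfg)}


@dataclass
class PipelineResult:
    """Outputs of a pipeline run (paths plus in-memory objects)."""

    de_table: pd.DataFrame
    enrichment: TargetEnrichmentResults
    paths: dict[str, Path]
    log_lines: list[str]


def _stage(name: str):
    def wrap(exc: Exception) -> PipelineError:
        return PipelineError(f"[{name}] {exc}")

    return wrap


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full analysis; returns the result bundle.

    Stages: data (simulate or load) -> diffexp -> sites -> enrichment ->
    write. The background passed to the enrichment null is exactly the
    non-DE complement of the selected gene sets.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = config.meta()
    written: list[Path] = []
    log: list[str] = [f"seedenrich pipeline, mode={config.mode}, seed={config.seed}",
                      f"config_hash={meta['config_hash']}"]

    def _write(name: str, fn) -> Path:
        path = out_dir / name
        fn(path)
        written.append(path)
        return path

    try:
        paths: dict[str, Path] = {}
        # ---- stage: data -------------------------------------------------
        try:
            if config.mode == "simulate":
                sim = dataclasses.replace(config.simulate, rng_seed=config.seed)
                pool, mirnas, matrix, truth = generate_two_mirna_scenario(sim)
                paths["utr_fasta"] = _write(
                    "utrs.fasta", lambda p: seio.write_utr_fasta(pool, p)
                )
                paths["mirna_tsv"] = _write(
                    "mirnas.tsv", lambda p: seio.write_mirna_tsv(mirnas, p)
                )
                paths["expression_tsv"] = _write(
                    "expression.tsv", lambda p: seio.write_expression_tsv(matrix, p)
                )
                paths["groups_tsv"] = _write(
                    "groups.tsv", lambda p: seio.write_groups_tsv(matrix, p)
                )
                paths["truth_calls"] = _write(
                    "truth_calls.tsv",
                    lambda p: truth.calls.to_csv(p, sep="\t", header=True),
                )
                paths["truth_sites"] = _write(
                    "truth_sites.tsv",
                    lambda p: truth.sites.to_csv(p, sep="\t", index=False),
                )
            else:
                pool = seio.read_utr_fasta(config.utr_fasta)
                mirnas = seio.read_mirna_tsv(config.mirna_tsv)
                matrix = seio.read_expression_tsv(
                    config.expression_tsv, config.groups_tsv
                )
            log.append(f"genes in pool: {len(pool)}; miRNAs: {len(mirnas)}")
        except PipelineError:
            raise
        except Exception as exc:
            raise _stage("data")(exc) from exc

        # ---- stage: diffexp ----------------------------------------------
        try:
            de_table = select_de(
                matrix,
                fc_threshold=config.fc_threshold,
                p_threshold=config.p_threshold,
                use_adjusted=config.use_adjusted,
            )
            n_up = int((de_table["call"] == "up").sum())
            n_down = int((de_table["call"] == "down").sum())
            log.append(f"DE calls: up={n_up} down={n_down} "
                       f"non_de={len(de_table) - n_up - n_down}")
            paths["de_table"] = _write(
                "de_table.tsv", lambda p: seio.write_de_table(de_table, p, meta)
            )
        except PipelineError:
            raise
        except Exception as exc:
            raise _stage("diffexp")(exc) from exc

        # ---- stage: sites -------------------------------------------------
        try:
            sites = scan_pool(pool, mirnas)
            log.append(f"canonical sites found: {len(sites)}")
            paths["sites"] = _write(
                "sites.tsv", lambda p: seio.write_sites_tsv(sites, p, meta)
            )
        except PipelineError:
            raise
        except Exception as exc:
            raise _stage("sites")(exc) from exc

        # ---- stage: enrichment ---------------------------------------------
        try:
            if n_up == 0 or n_down == 0:
                raise ValueError(
                    "empty gene set: no genes called "
                    + ("up" if n_up == 0 else "down")
                )
            model = TargetEnrichment.from_diffexp(
                de_table,
                pool,
                mirnas,
                B=config.B,
                mode=config.null_mode,
                fallback=config.fallback,
                tie_mode=config.tie_mode,
            )
            set_ids = {g for s in model.gene_sets for g in s.gene_ids}
            assert set_ids.isdisjoint(model.background_ids)
            fitted = model.fit(seed=config.seed)
            log.append(f"enrichment cells: {len(fitted.results)} (B={config.B})")
            paths["enrichment"] = _write(
                "enrichment.tsv",
                lambda p: seio.write_enrichment_tsv(fitted.results, p, meta),
            )
            if config.write_null_dump:
                paths["null_dump"] = _write(
                    "null_medians.tsv",
                    lambda p: seio.write_null_dump_tsv(fitted.results, p, meta),
                )
        except PipelineError:
            raise
        except Exception as exc:
            raise _stage("enrichment")(exc) from exc

        paths["log"] = _write(
            "run_log.txt", lambda p: p.write_text("\n".join(log) + "\n")
        )
        return PipelineResult(
            de_table=de_table, enrichment=fitted, paths=paths, log_lines=log
        )
    except Exception:
        for p in written:
            try:
                p.unlink()
            except OSError:
                pass
        raise
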