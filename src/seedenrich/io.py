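"""File I/O: FASTA UTR pools, miRNA/expression TSVs, result tables, configs.

All TSVs are tab-separated with '.' decimals; result files start with '#'
comment lines recording the master seed and a hash of the configuration so
every output is auditable. FASTA parsing goes through Biopython.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml
from Bio import SeqIO

from .diffexp import ExpressionMatrix
from .enrichment import EnrichmentResult
from .records import MatureMiRNA, SiteMatch, UTRPool, UTRRecord

__all__ = [
    "read_utr_fasta",
    "write_utr_fasta",
    "read_mirna_tsv",
    "write_mirna_tsv",
    "read_expression_tsv",
    "write_expression_tsv",
    "write_groups_tsv",
    "read_gene_list",
    "write_de_table",
    "write_sites_tsv",
    "write_enrichment_tsv",
    "write_null_dump_tsv",
    "load_config",
    "config_hash",
]


def read_utr_fasta(path: str | Path) -> UTRPool:
    """Read a 3'UTR FASTA into a pool.

    The gene id is the first whitespace-delimited token of each header.
    Sequences are normalised (uppercase, U -> T). Duplicate ids and empty
    files are rejected.
    """
    pool = UTRPool()
    n = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        pool.add(UTRRecord(rec.id, str(rec.seq)))
        n += 1
    if n == 0:
        raise ValueError(f"no FASTA records found in {path}")
    return pool


def write_utr_fasta(pool: UTRPool, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in pool:
            fh.write(f">{rec.gene_id}\n")
            for i in range(0, rec.length, width):
                fh.write(rec.sequence[i:i + width] + "\n")


def read_mirna_tsv(path: str | Path) -> list[MatureMiRNA]:
    """Read a 2-column ``name<TAB>sequence`` TSV (header line required)."""
    mirnas: list[MatureMiRNA] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() and not ln.startswith("#")]
    if len(lines) < 2:
        raise ValueError(f"miRNA TSV {path} needs a header line and >= 1 entry")
    for ln in lines[1:]:
        parts = ln.split("\t")
        if len(parts) < 2:
            raise ValueError(f"malformed miRNA TSV line: {ln!r}")
        mirnas.append(MatureMiRNA(parts[0], parts[1]))
    names = [m.name for m in mirnas]
    if len(set(names)) != len(names):
        raise ValueError("duplicate miRNA names in panel")
    return mirnas


def write_mirna_tsv(mirnas: Iterable[MatureMiRNA], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("name\tsequence\n")
        for m in mirnas:
            fh.write(f"{m.name}\t{m.sequence}\n")


def read_expression_tsv(
    path: str | Path, groups_path: str | Path | None = None
) -> ExpressionMatrix:
    """Expression TSV (first column gene_id) plus optional group sidecar."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    groups = None
    if groups_path is not None:
        gdf = pd.read_csv(
            groups_path, sep="\t", header=None, names=["sample_id", "group"],
            comment="#",
        )
        groups = dict(zip(gdf["sample_id"], gdf["group"]))
    return ExpressionMatrix(df, groups=groups)


def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6f")


def write_groups_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    if matrix.groups is None:
        raise ValueError("expression matrix has no group labels")
    with open(path, "w") as fh:
        for s in matrix.data.columns:
            fh.write(f"{s}\t{matrix.groups[s]}\n")


def read_gene_list(path: str | Path) -> list[str]:
    """One gene id per line (first tab-delimited token); '#' comments skipped."""
    ids: list[str] = []
    with open(path) as fh:
        for ln in fh:
            ln = ln.strip()
            if not ln or ln.startswith("#"):
                continue
            ids.append(ln.split("\t")[0])
    if not ids:
        raise ValueError(f"no gene ids found in {path}")
    return ids


def _write_header(fh, meta: Mapping[str, object] | None) -> None:
    if meta:
        for k, v in meta.items():
            fh.write(f"# {k}: {v}\n")


def write_de_table(
    table: pd.DataFrame, path: str | Path, meta: Mapping[str, object] | None = None
) -> None:
    with open(path, "w") as fh:
        _write_header(fh, meta)
        table.to_csv(fh, sep="\t", index_label="gene_id", float_format="%.6g")


def write_sites_tsv(
    sites_with_density: Sequence[tuple[SiteMatch, float]],
    path: str | Path,
    meta: Mapping[str, object] | None = None,
) -> None:
    """BED-like 6-column site table (0-based, half-open coordinates)."""
    with open(path, "w") as fh:
        _write_header(fh, meta)
        fh.write("gene_id\tstart\tend\tmirna_name\tsite_type\tdensity_context\n")
        for site, dens in sites_with_density:
            fh.write(
                f"{site.gene_id}\t{site.start}\t{site.end}\t"
                f"{site.mirna_name}\t{site.site_type}\t{dens:.6g}\n"
            )


def write_enrichment_tsv(
    results: Sequence[EnrichmentResult],
    path: str | Path,
    meta: Mapping[str, object] | None = None,
) -> None:
    with open(path, "w") as fh:
        _write_header(fh, meta)
        fh.write("mirna\tset_label\tn\tM_obs\tp_left\tp_right\tB\tseed\n")
        for r in results:
            fh.write(
                f"{r.mirna_name}\t{r.set_label}\t{r.n}\t{r.m_obs:.6g}\t"
                f"{r.p_left:.6g}\t{r.p_right:.6g}\t{r.B}\t{r.rng_seed}\n"
            )


def write_null_dump_tsv(
    results: Sequence[EnrichmentResult],
    path: str | Path,
    meta: Mapping[str, object] | None = None,
) -> None:
    """Per-replicate null medians for audit, one row per (cell, replicate)."""
    with open(path, "w") as fh:
        _write_header(fh, meta)
        fh.write("mirna\tset_label\treplicate\tnull_median\n")
        for r in results:
            for b, v in enumerate(r.null_medians):
                fh.write(f"{r.mirna_name}\t{r.set_label}\t{b}\t{v:.6g}\n")


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON configuration mapping."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    return cfg


def config_hash(config: Mapping[str, object]) -> str:
    """Short stable hash of a configuration mapping, for output headers."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
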