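"""Length-matched resampling test for miRNA target enrichment in gene sets.

For a gene set (e.g. the genes upregulated in aged islets) and one miRNA,
the observed statistic ``M_obs`` is the median density (sites per kilobase)
of canonical recognition elements across the set's 3'UTRs. Its null
distribution is built by resampling: in each of ``B`` replicates, for every
observed UTR length ``L_i`` a contiguous region of exactly ``L_i`` nt is
drawn from a randomly chosen non-differentially-expressed background UTR of
length >= ``L_i`` (UTR uniform among those eligible, start uniform), its
site density computed, and the replicate's median over the ``n`` regions
recorded. One-sided empirical p-values are the proportions of null medians
strictly smaller (depletion side) and strictly larger (enrichment side) than
``M_obs``; ties count toward neither side and no pseudocount is added, so a
statistic beyond the whole null yields an exact p of 0.

The model interface follows the estimator/results convention:
:class:`TargetEnrichment` is built from the data and ``fit()`` returns a
:class:`TargetEnrichmentResults` carrying the per-(miRNA x set) table, the
null medians and a ``summary()``.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .records import MatureMiRNA, UTRPool
from .sites import SiteCandidateIndex, find_sites

__all__ = [
    "GeneSet",
    "NullSpec",
    "EnrichmentResult",
    "observed_median_density",
    "null_distribution",
    "empirical_p",
    "run_enrichment",
    "TargetEnrichment",
    "TargetEnrichmentResults",
]


@dataclass(frozen=True)
class GeneSet:
    """A labelled gene set resolvable against a UTR pool."""

    label: str
    gene_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.label:
            raise ValueError("gene set label must be non-empty")
        if len(self.gene_ids) == 0:
            raise ValueError(f"gene set {self.label!r} is empty")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError(f"gene set {self.label!r} contains duplicate ids")
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))

    @property
    def n(self) -> int:
        return len(self.gene_ids)


@dataclass(frozen=True)
class NullSpec:
    """Configuration of the resampling null.

    ``B`` replicates (default 1000); ``background_ids`` are the non-DE UTRs
    sampled from; ``mode`` is ``"windows"`` (contiguous regions of exactly
    the observed lengths — the default) or ``"whole-utr"`` (whole background
    UTRs nearest in length, density substituted); ``fallback`` controls what
    happens when no background UTR reaches an observed length (``"error"`` or
    ``"longest"``); ``tie_mode`` is ``"strict"`` (ties count toward neither
    side) or ``"mid"`` (half-weight to ties).
    """

    B: int = 1000
    background_ids: tuple[str, ...] = ()
    rng_seed: int = 0
    mode: str = "windows"
    fallback: str = "error"
    tie_mode: str = "strict"
    nearest_k: int = 25

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if len(self.background_ids) == 0:
            raise ValueError("background pool is empty")
        if self.mode not in ("windows", "whole-utr"):
            raise ValueError(f"unknown null mode {self.mode!r}")
        if self.fallback not in ("error", "longest"):
            raise ValueError(f"unknown fallback policy {self.fallback!r}")
        if self.tie_mode not in ("strict", "mid"):
            raise ValueError(f"unknown tie mode {self.tie_mode!r}")
        object.__setattr__(self, "background_ids", tuple(self.background_ids))


@dataclass(frozen=True)
class EnrichmentResult:
    """Observed statistic, null medians and both one-sided empirical p-values."""

    mirna_name: str
    set_label: str
    n: int
    m_obs: float
    null_medians: np.ndarray
    p_left: float
    p_right: float
    rng_seed: int

    @property
    def B(self) -> int:
        return len(self.null_medians)


def observed_median_density(
    gene_set: GeneSet, utr_pool: UTRPool, mirna: MatureMiRNA
) -> float:
    """Median canonical-site density (sites/kb) over the set's UTRs.

    The median of an even-length list is the mean of the two central values.
    """
    densities = []
    for gid in gene_set.gene_ids:
        if gid not in utr_pool:
            raise KeyError(f"gene_id {gid!r} from set {gene_set.label!r} "
                           "is not present in the UTR pool")
        utr = utr_pool[gid]
        densities.append(1000.0 * len(find_sites(utr, mirna)) / utr.length)
    return float(np.median(densities))


def _sorted_background(
    spec: NullSpec, index: SiteCandidateIndex
) -> tuple[list[str], np.ndarray]:
    for gid in spec.background_ids:
        if gid not in index:
            raise KeyError(f"background gene_id {gid!r} not present in the UTR pool")
    ids = sorted(spec.background_ids, key=lambda g: (index.length_of(g), g))
    lens = np.array([index.length_of(g) for g in ids], dtype=np.int64)
    return ids, lens


def null_distribution(
    gene_set_lengths: Sequence[int],
    spec: NullSpec,
    utr_pool: UTRPool,
    mirna: MatureMiRNA,
    index: SiteCandidateIndex | None = None,
) -> np.ndarray:
    """``B`` null medians of length-matched resampled site densities.

    RNG protocol (fixed so results are reproducible from ``spec.rng_seed``
    alone): a ``numpy.random.default_rng(spec.rng_seed)`` generator is
    consumed gene by gene, in the order of ``gene_set_lengths``; for gene
    ``i`` the ``B`` background UTRs are drawn first
    (``rng.integers(0, n_eligible, size=B)``, indexing the background sorted
    by (length, id)), then the ``B`` window starts
    (``rng.integers(0, length - L_i + 1)`` elementwise). In ``whole-utr``
    mode a single draw per gene per replicate selects among the ``nearest_k``
    background UTRs closest in length and the whole-UTR density is used.
    """
    lengths = [int(x) for x in gene_set_lengths]
    if len(lengths) == 0:
        raise ValueError("gene_set_lengths is empty")
    if index is None:
        index = SiteCandidateIndex(
            (utr_pool[g] for g in spec.background_ids), mirna
        )
    bg_ids, bg_lens = _sorted_background(spec, index)
    nbg = len(bg_ids)
    rng = np.random.default_rng(spec.rng_seed)
    B = spec.B
    densities = np.empty((len(lengths), B), dtype=float)

    if spec.mode == "whole-utr":
        full = np.array([index.full_density(g) for g in bg_ids])
        for i, L in enumerate(lengths):
            # nearest_k background UTRs by |length - L|
            order = np.argsort(np.abs(bg_lens - L), kind="mergesort")
            near = order[: min(spec.nearest_k, nbg)]
            picks = rng.integers(0, len(near), size=B)
            densities[i] = full[near[picks]]
        return np.median(densities, axis=0)

    for i, L in enumerate(lengths):
        lo = int(np.searchsorted(bg_lens, L, side="left"))
        if lo >= nbg:
            if spec.fallback == "longest":
                # substitute the longest background UTR's whole-UTR density;
                # no RNG draws, so other genes' streams stay aligned
                densities[i] = index.full_density(bg_ids[-1])
                continue
            raise ValueError(
                f"no background UTR of length >= {L} nt "
                f"(longest is {int(bg_lens[-1])} nt); "
                "enable the 'longest' fallback or extend the background"
            )
        picks = lo + rng.integers(0, nbg - lo, size=B)
        starts = rng.integers(0, bg_lens[picks] - L + 1)
        counts = np.empty(B, dtype=float)
        for b in range(B):
            gid = bg_ids[picks[b]]
            s = int(starts[b])
            counts[b] = index.count_in_window(gid, s, s + L)
        densities[i] = 1000.0 * counts / L
    return np.median(densities, axis=0)


def empirical_p(
    m_obs: float, null_medians: Sequence[float], tie_mode: str = "strict"
) -> tuple[float, float]:
    """One-sided empirical p-values ``(p_left, p_right)``.

    ``p_left`` is the proportion of null medians strictly smaller than
    ``m_obs`` (depletion side), ``p_right`` strictly larger (enrichment
    side). With ``tie_mode="mid"`` ties contribute half to each side.
    """
    null = np.asarray(null_medians, dtype=float)
    if null.size == 0:
        raise ValueError("null distribution is empty")
    B = null.size
    below = int(np.count_nonzero(null < m_obs))
    above = int(np.count_nonzero(null > m_obs))
    if tie_mode == "mid":
        ties = B - below - above
        return (below + 0.5 * ties) / B, (above + 0.5 * ties) / B
    return below / B, above / B


def derive_stream_seed(master_seed: int, mirna_name: str, set_label: str) -> int:
    """Deterministic per-(miRNA, set) seed from the master seed.

    Each cell of the results table gets its own stream, so adding a miRNA or
    a set never perturbs the others' null distributions.
    """
    ss = np.random.SeedSequence(
        [int(master_seed) & 0x7FFFFFFF,
         zlib.crc32(mirna_name.encode()),
         zlib.crc32(set_label.encode())]
    )
    return int(ss.generate_state(1)[0]) % (2 ** 31)


def run_enrichment(
    de_sets: Iterable[GeneSet],
    mirnas: Iterable[MatureMiRNA],
    utr_pool: UTRPool,
    spec: NullSpec,
) -> list[EnrichmentResult]:
    """One :class:`EnrichmentResult` per (miRNA x gene set)."""
    de_sets = list(de_sets)
    mirnas = list(mirnas)
    background = set(spec.background_ids)
    for gs in de_sets:
        overlap = background.intersection(gs.gene_ids)
        if overlap:
            raise ValueError(
                f"gene set {gs.label!r} overlaps the background pool "
                f"(e.g. {sorted(overlap)[0]!r}); the null must be drawn from "
                "non-differentially-expressed UTRs only"
            )
    results: list[EnrichmentResult] = []
    for mirna in mirnas:
        index = SiteCandidateIndex(
            (utr_pool[g] for g in spec.background_ids), mirna
        )
        for gs in de_sets:
            m_obs = observed_median_density(gs, utr_pool, mirna)
            lengths = [utr_pool[g].length for g in gs.gene_ids]
            seed = derive_stream_seed(spec.rng_seed, mirna.name, gs.label)
            cell_spec = replace(spec, rng_seed=seed)
            null = null_distribution(lengths, cell_spec, utr_pool, mirna, index=index)
            p_left, p_right = empirical_p(m_obs, null, spec.tie_mode)
            results.append(
                EnrichmentResult(
                    mirna_name=mirna.name,
                    set_label=gs.label,
                    n=gs.n,
                    m_obs=m_obs,
                    null_medians=null,
                    p_left=p_left,
                    p_right=p_right,
                    rng_seed=seed,
                )
            )
    return results


class TargetEnrichment:
    """Model: miRNA recognition-element enrichment in DE gene sets.

    Built from a UTR pool, a miRNA panel, the gene sets under test and the
    non-DE background; ``fit`` runs the resampling test for every
    (miRNA x set) cell.

    Parameters
    ----------
    utr_pool : UTRPool
        3'UTRs of all genes (tested sets and background).
    mirnas : sequence of MatureMiRNA
        The differentially expressed miRNAs whose targets are examined.
    gene_sets : sequence of GeneSet
        Typically the up- and downregulated gene sets.
    background_ids : sequence of str
        Genes not differentially expressed; the null resamples their UTRs.
    B : int
        Null replicates per cell (default 1000).
    """

    def __init__(
        self,
        utr_pool: UTRPool,
        mirnas: Sequence[MatureMiRNA],
        gene_sets: Sequence[GeneSet],
        background_ids: Sequence[str],
        B: int = 1000,
        mode: str = "windows",
        fallback: str = "error",
        tie_mode: str = "strict",
        nearest_k: int = 25,
    ) -> None:
        self.utr_pool = utr_pool
        self.mirnas = list(mirnas)
        self.gene_sets = list(gene_sets)
        self.background_ids = tuple(background_ids)
        self.B = int(B)
        self.mode = mode
        self.fallback = fallback
        self.tie_mode = tie_mode
        self.nearest_k = nearest_k
        if not self.mirnas:
            raise ValueError("need at least one miRNA")
        if not self.gene_sets:
            raise ValueError("need at least one gene set")

    @classmethod
    def from_diffexp(
        cls,
        de_table: pd.DataFrame,
        utr_pool: UTRPool,
        mirnas: Sequence[MatureMiRNA],
        **kwargs,
    ) -> "TargetEnrichment":
        """Build the model from a DE table (`select_de` output).

        Genes called ``up``/``down`` become the tested sets (labels
        ``upregulated``/``downregulated``), genes called ``non_de`` the
        background. Genes whose UTR is absent from the pool are dropped.
        """
        in_pool = de_table.index.map(lambda g: g in utr_pool)
        tbl = de_table[in_pool]
        sets = []
        for call, label in (("up", "upregulated"), ("down", "downregulated")):
            ids = tuple(tbl.index[tbl["call"] == call])
            if not ids:
                raise ValueError(
                    f"empty gene set: no genes called {call!r} in the DE table"
                )
            sets.append(GeneSet(label, ids))
        background = tuple(tbl.index[tbl["call"] == "non_de"])
        return cls(utr_pool, mirnas, sets, background, **kwargs)

    def _null_spec(self, seed: int) -> NullSpec:
        return NullSpec(
            B=self.B,
            background_ids=self.background_ids,
            rng_seed=int(seed),
            mode=self.mode,
            fallback=self.fallback,
            tie_mode=self.tie_mode,
            nearest_k=self.nearest_k,
        )

    def fit(self, seed: int = 0, B: int | None = None) -> "TargetEnrichmentResults":
        """Run the resampling test; ``seed`` is the master RNG seed."""
        if B is not None:
            self.B = int(B)
        spec = self._null_spec(seed)
        results = run_enrichment(self.gene_sets, self.mirnas, self.utr_pool, spec)
        return TargetEnrichmentResults(self, results, master_seed=int(seed))


class TargetEnrichmentResults:
    """Fitted results: per-cell M_obs, null medians and empirical p-values."""

    def __init__(
        self,
        model: TargetEnrichment,
        results: list[EnrichmentResult],
        master_seed: int,
    ) -> None:
        self.model = model
        self.results = results
        self.master_seed = master_seed

    @property
    def table(self) -> pd.DataFrame:
        rows = [
            {
                "mirna": r.mirna_name,
                "set_label": r.set_label,
                "n": r.n,
                "M_obs": r.m_obs,
                "p_left": r.p_left,
                "p_right": r.p_right,
                "B": r.B,
                "seed": r.rng_seed,
            }
            for r in self.results
        ]
        return pd.DataFrame(rows)

    def result_for(self, mirna_name: str, set_label: str) -> EnrichmentResult:
        for r in self.results:
            if r.mirna_name == mirna_name and r.set_label == set_label:
                return r
        raise KeyError(f"no result for ({mirna_name!r}, {set_label!r})")

    def summary(self) -> str:
        """Plain-text summary table of the fitted enrichment results."""
        tbl = self.table
        lines = [
            "miRNA target enrichment (length-matched resampling null)",
            f"cells: {len(tbl)}  B: {self.model.B}  mode: {self.model.mode}  "
            f"background n: {len(self.model.background_ids)}  "
            f"master seed: {self.master_seed}",
            "M_obs: median canonical-site density (sites/kb) of the set's 3'UTRs",
            "p_left / p_right: proportion of null medians strictly below / above M_obs",
            "-" * 78,
            tbl.to_string(
                index=False,
                float_format=lambda v: f"{v:.4g}",
            ),
        ]
        return "\n".join(lines)

    def plot_null(self, mirna_name: str, set_label: str, ax=None):
        """Histogram of the null medians with the observed statistic marked."""
        from .plotting import plot_null_distribution

        return plot_null_distribution(self.result_for(mirna_name, set_label), ax=ax)
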