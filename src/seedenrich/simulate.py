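"""Synthetic UTR pools, miRNA panels and expression matrices with ground truth.

The generator emulates the statistical structure the enrichment analysis
assumes: a pool of thousands of 3'UTRs with a log-normal length spread,
canonical seed sites planted at controlled per-group densities (enrichment
of one miRNA's sites in the upregulated set, depletion of another's — the
published qualitative pattern), and 3-vs-3 log2-scale expression with
planted fold changes and Gaussian noise.

Sequence background is i.i.d. at a configurable GC fraction, and any
spontaneous canonical match for a panel miRNA is scrubbed before planting,
so the emitted truth table is exactly reproducible by re-scanning the FASTA
with the site scanner — the generator's own acceptance test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .diffexp import ExpressionMatrix
from .records import MatureMiRNA, SiteMatch, UTRPool, UTRRecord
from .sites import seed_match_patterns

__all__ = [
    "SyntheticConfig",
    "TruthTable",
    "DEFAULT_PANEL",
    "generate_utr_pool",
    "generate_expression",
    "generate_two_mirna_scenario",
]

# Mature sequences of the two miRNAs whose targets the enrichment analysis
# examines (rat, miRBase): miR-34a-5p and miR-181a-5p.
DEFAULT_PANEL: tuple[tuple[str, str], ...] = (
    ("rno-miR-34a-5p", "UGGCAGUGUCUUAGCUGGUUGU"),
    ("rno-miR-181a-5p", "AACAUUCAACGCUGUCGGUGAGU"),
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic transcriptome.

    Lengths follow a log-normal law with the given median (nt) and log-space
    dispersion sigma (sigma = 0 gives constant lengths), truncated below at
    ``min_utr_length``. ``site_density_background`` is the expected planted
    canonical-site density (sites/kb) in non-DE UTRs; per-miRNA ratios scale
    it in true-up and true-down genes (1.0 = no effect). Expression is
    emulated at the study's design point: 3 replicates per group, planted
    |log2 fold change| of 2 on log2 intensities with Gaussian noise.
    """

    n_genes: int = 2000
    utr_length_median: float = 1000.0
    utr_length_sigma: float = 0.6
    min_utr_length: int = 50
    gc_fraction: float = 0.42
    mirna_panel: tuple[tuple[str, str], ...] = DEFAULT_PANEL
    de_fraction_up: float = 0.10
    de_fraction_down: float = 0.05
    planted_log2fc: float = 2.0
    noise_sd: float = 0.2
    site_density_background: float = 1.0
    site_density_ratio_up: Mapping[str, float] = field(default_factory=dict)
    site_density_ratio_down: Mapping[str, float] = field(default_factory=dict)
    replicates_per_group: int = 3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.min_utr_length < 50:
            raise ValueError("min_utr_length must be >= 50 nt")
        if not (0.0 <= self.gc_fraction <= 1.0):
            raise ValueError("gc_fraction must lie in [0, 1]")
        for name, frac in (("de_fraction_up", self.de_fraction_up),
                           ("de_fraction_down", self.de_fraction_down)):
            if not (0.0 <= frac <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.de_fraction_up + self.de_fraction_down > 1.0:
            raise ValueError("DE fractions sum to more than 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.site_density_background < 0:
            raise ValueError("site density must be >= 0")
        for ratios in (self.site_density_ratio_up, self.site_density_ratio_down):
            for name, r in ratios.items():
                if r <= 0:
                    raise ValueError(f"density ratio for {name!r} must be > 0")
        if self.replicates_per_group < 2:
            raise ValueError("replicates_per_group must be >= 2 for testing")
        if self.utr_length_sigma < 0:
            raise ValueError("utr_length_sigma must be >= 0")

    @property
    def mirnas(self) -> list[MatureMiRNA]:
        return [MatureMiRNA(n, s) for n, s in self.mirna_panel]

    def ratio(self, mirna_name: str, call: str) -> float:
        if call == "up":
            return float(self.site_density_ratio_up.get(mirna_name, 1.0))
        if call == "down":
            return float(self.site_density_ratio_down.get(mirna_name, 1.0))
        return 1.0


@dataclass
class TruthTable:
    """Ground truth emitted alongside the synthetic data.

    ``calls`` maps gene_id -> true call (up/down/non_de); ``sites`` lists
    every planted recognition element with its exact coordinates (all
    planted sites are 8mers).
    """

    calls: pd.Series
    sites: pd.DataFrame

    def sites_for(self, gene_id: str, mirna_name: str) -> pd.DataFrame:
        mask = (self.sites["gene_id"] == gene_id) & (
            self.sites["mirna_name"] == mirna_name
        )
        return self.sites[mask]


def _draw_calls(config: SyntheticConfig, rng: np.random.Generator) -> pd.Series:
    n = config.n_genes
    n_up = int(round(n * config.de_fraction_up))
    n_down = int(round(n * config.de_fraction_down))
    calls = np.array(["non_de"] * n, dtype=object)
    perm = rng.permutation(n)
    calls[perm[:n_up]] = "up"
    calls[perm[n_up:n_up + n_down]] = "down"
    gene_ids = [f"gene{idx:05d}" for idx in range(n)]
    return pd.Series(calls, index=pd.Index(gene_ids, name="gene_id"), name="call")


def _random_sequence(length: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=length, p=p)


def _panel_patterns(config: SyntheticConfig) -> dict[str, tuple[str, str, str]]:
    return {m.name: seed_match_patterns(m) for m in config.mirnas}


def _scrub(
    seq: np.ndarray,
    patterns: dict[str, tuple[str, str, str]],
    rng: np.random.Generator,
    max_rounds: int = 1000,
) -> np.ndarray:
    """Destroy every spontaneous canonical match for any panel miRNA.

    Any 7-nt pattern occurrence (the 8mer contains the 7mer-m8, so scanning
    the two 7-nt patterns suffices) is disrupted by redrawing one of its
    bases; repeated until the sequence is clean.
    """
    for _ in range(max_rounds):
        s = seq.tobytes().decode()
        hit = -1
        width = 7
        for pat8, pat7m8, pat7a1 in patterns.values():
            for pat in (pat7m8, pat7a1):
                j = s.find(pat)
                if j != -1 and (hit == -1 or j < hit):
                    hit = j
        if hit == -1:
            return seq
        pos = hit + int(rng.integers(0, width))
        old = seq[pos]
        choices = _BASES[_BASES != old]
        seq[pos] = rng.choice(choices)
    raise RuntimeError("failed to scrub spontaneous seed matches (pathological config)")


def _region_occurrences(
    s: str, lo: int, patterns: dict[str, tuple[str, str, str]]
) -> set[tuple[str, int, int]]:
    """(mirna, pattern_index, absolute_start) occurrences within s[lo:...]."""
    found: set[tuple[str, int, int]] = set()
    for name, pats in patterns.items():
        for k, pat in enumerate(pats):
            j = s.find(pat)
            while j != -1:
                found.add((name, k, lo + j))
                j = s.find(pat, j + 1)
    return found


def _plant_sites(
    seq: np.ndarray,
    gene_id: str,
    config: SyntheticConfig,
    call: str,
    patterns: dict[str, tuple[str, str, str]],
    rng: np.random.Generator,
    max_retries: int = 100,
) -> list[SiteMatch]:
    """Insert 8mer sites for each panel miRNA at its configured density.

    Planted counts are Poisson with mean density x (length - 7) / 1000 — a
    homogeneous rate over the valid start positions, so that a window cut
    from a longer UTR carries the same site law as a whole UTR of the same
    length. Counts are truncated to a packing capacity of length // 16 sites
    per miRNA. Each insertion is rejected (position redrawn, up to
    ``max_retries`` times) if it would overlap an existing planted site or
    create any unintended canonical match for any panel miRNA around the
    junctions; sites may otherwise sit adjacent, keeping the positional
    exclusion as small as the non-overlap constraint itself allows (a wider
    keep-out would make planted sites repel each other and measurably
    underdisperse the window counts the resampling null draws).
    """
    L = len(seq)
    planted: list[SiteMatch] = []
    occupied: list[tuple[int, int]] = []
    # implied pattern occurrences of every planted site, for junction checks
    implied: set[tuple[str, int, int]] = set()

    for mirna in config.mirnas:
        pat8 = patterns[mirna.name][0]
        expected = (
            config.site_density_background
            * config.ratio(mirna.name, call)
            * max(L - 7, 1) / 1000.0
        )
        k = int(rng.poisson(expected))
        k = min(k, L // 16)
        pat_arr = np.frombuffer(pat8.encode(), dtype=np.uint8)
        for _ in range(k):
            for _attempt in range(max_retries):
                p = int(rng.integers(0, L - 8 + 1))
                if any(p < e and q < p + 8 for q, e in occupied):
                    continue
                saved = seq[p:p + 8].copy()
                seq[p:p + 8] = pat_arr
                a = max(0, p - 14)
                b = min(L, p + 8 + 14)
                region = seq[a:b].tobytes().decode()
                occ = _region_occurrences(region, a, patterns)
                new_implied = {
                    (mirna.name, 0, p),      # 8mer pattern at p
                    (mirna.name, 1, p),      # 7mer-m8 prefix at p
                    (mirna.name, 2, p + 1),  # 7mer-A1 suffix at p+1
                }
                # hits from neighbouring planted sites whose patterns lie
                # fully inside the scanned region are expected, not spurious
                allowed = new_implied | {
                    (m, kind, pos) for (m, kind, pos) in implied
                    if pos >= a and pos + (8 if kind == 0 else 7) <= b
                }
                if occ == allowed:
                    planted.append(SiteMatch(gene_id, mirna.name, p, p + 8, "8mer"))
                    occupied.append((p, p + 8))
                    implied |= new_implied
                    break
                seq[p:p + 8] = saved
            else:
                raise RuntimeError(
                    f"could not place a site for {mirna.name} in {gene_id} "
                    f"after {max_retries} retries (density too high for "
                    f"length {L})"
                )
    planted.sort(key=lambda s: (s.mirna_name, s.start))
    return planted


def generate_utr_pool(
    config: SyntheticConfig,
    calls: pd.Series | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[UTRPool, TruthTable]:
    """Synthetic 3'UTR pool with planted canonical sites and full ground truth.

    If ``calls`` is given (e.g. shared with the expression generator) it
    fixes each gene's true DE status; otherwise calls are drawn from the
    configured fractions. Reproducible from ``config.rng_seed`` alone.
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    if calls is None:
        calls = _draw_calls(config, rng)
    patterns = _panel_patterns(config)

    n = len(calls)
    if config.utr_length_sigma == 0:
        lengths = np.full(n, int(round(config.utr_length_median)))
    else:
        lengths = np.round(
            rng.lognormal(np.log(config.utr_length_median), config.utr_length_sigma, n)
        ).astype(int)
    lengths = np.maximum(lengths, config.min_utr_length)

    records: list[UTRRecord] = []
    all_sites: list[SiteMatch] = []
    for gene_id, L in zip(calls.index, lengths):
        seq = _random_sequence(int(L), config.gc_fraction, rng)
        seq = _scrub(seq, patterns, rng)
        sites = _plant_sites(seq, gene_id, config, calls[gene_id], patterns, rng)
        all_sites.extend(sites)
        records.append(UTRRecord(gene_id, seq.tobytes().decode()))

    sites_df = pd.DataFrame(
        [
            {
                "gene_id": s.gene_id,
                "mirna_name": s.mirna_name,
                "start": s.start,
                "end": s.end,
                "site_type": s.site_type,
            }
            for s in all_sites
        ],
        columns=["gene_id", "mirna_name", "start", "end", "site_type"],
    )
    return UTRPool(records), TruthTable(calls=calls.copy(), sites=sites_df)


def generate_expression(
    config: SyntheticConfig,
    calls: pd.Series | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[ExpressionMatrix, TruthTable]:
    """3-vs-3 (by default) log2 expression with planted fold changes.

    Per-gene log2 baseline ~ Uniform(4, 12); true-up genes are offset by
    ``+planted_log2fc`` in group B, true-down genes by the negative; i.i.d.
    Gaussian noise of sd ``noise_sd`` is added per cell.
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    if calls is None:
        calls = _draw_calls(config, rng)
    n = len(calls)
    reps = config.replicates_per_group
    baseline = rng.uniform(4.0, 12.0, size=n)
    offset = np.zeros(n)
    offset[(calls == "up").to_numpy()] = config.planted_log2fc
    offset[(calls == "down").to_numpy()] = -config.planted_log2fc
    noise = rng.normal(0.0, config.noise_sd, size=(n, 2 * reps))
    values = np.empty((n, 2 * reps))
    values[:, :reps] = baseline[:, None] + noise[:, :reps]
    values[:, reps:] = (baseline + offset)[:, None] + noise[:, reps:]
    samples = [f"young_{i + 1}" for i in range(reps)] + [
        f"aged_{i + 1}" for i in range(reps)
    ]
    df = pd.DataFrame(values, index=calls.index.copy(), columns=samples)
    groups = {s: ("young" if s.startswith("young") else "aged") for s in samples}
    matrix = ExpressionMatrix(df, groups=groups, group_order=("young", "aged"))
    truth = TruthTable(
        calls=calls.copy(),
        sites=pd.DataFrame(
            columns=["gene_id", "mirna_name", "start", "end", "site_type"]
        ),
    )
    return matrix, truth


def generate_two_mirna_scenario(
    config: SyntheticConfig | None = None,
) -> tuple[UTRPool, list[MatureMiRNA], ExpressionMatrix, TruthTable]:
    """One coherent dataset reproducing the published qualitative pattern.

    With the default panel, miR-181a sites are enriched (ratio 3.0) in the
    true-up genes and depleted (0.2) in the true-down genes, while miR-34a
    sites are depleted (0.2) in the true-up genes and enriched (3.0) in the
    true-down genes. The expression layer shares the same true calls, so DE
    selection and enrichment are consistent by construction.
    """
    if config is None:
        config = SyntheticConfig()
    if len(config.mirna_panel) < 2:
        raise ValueError("the scenario needs a panel of >= 2 miRNAs")
    name_a, name_b = config.mirna_panel[0][0], config.mirna_panel[1][0]
    if not config.site_density_ratio_up:
        config.site_density_ratio_up = {name_b: 3.0, name_a: 0.2}
    if not config.site_density_ratio_down:
        config.site_density_ratio_down = {name_b: 0.2, name_a: 3.0}

    rng = np.random.default_rng(config.rng_seed)
    calls = _draw_calls(config, rng)
    pool, truth = generate_utr_pool(config, calls=calls, rng=rng)
    matrix, _ = generate_expression(config, calls=calls, rng=rng)
    return pool, config.mirnas, matrix, truth
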