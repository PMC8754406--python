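"""Synthetic ribosome-profiling datasets with planted pulldown enrichment.

The generator builds a toy yeast-like genome (genes laid out along
chromosomes with intergenic gaps, a small fraction carrying two CDS
segments, dubious and mitochondrial flags at realistic rates) and draws
matched input/pulldown footprint libraries per bait.  A chosen subset of
genes carries a planted log2 pulldown enrichment; every other gene has
effect 0.  Footprint 3'-end bookkeeping is exact: P-site assignment at the
configured offset always lands inside the source gene's CDS.

Both samples of a bait are padded with intergenic background footprints to
one common library size, so reads-per-million normalization cancels between
matched samples and the planted per-gene effect is recoverable as the log2
RPM ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..genes import FootprintTable, GeneModel

__all__ = ["RiboSimParams", "FootprintDataset", "generate_footprint_dataset"]

CHROM_NAMES = [f"chr{r}" for r in (
    "I II III IV V VI VII VIII IX X XI XII XIII XIV XV XVI".split())]
MITO_CHROM = "chrM"
LEADING_GAP_NT = 1000
INTERGENIC_GAP_NT = 400


@dataclass(frozen=True)
class RiboSimParams:
    n_genes: int = 4540
    n_enriched: int = 40
    true_log2_effect: float = 2.0
    mean_input_footprints: float = 1000.0
    gene_length_nt: int = 1000
    flag_fraction_dubious: float = 0.10
    flag_fraction_mito: float = 0.01
    n_baits: int = 2
    footprint_length_nt: int = 28
    psite_offset_nt: int = 15
    two_interval_fraction: float = 0.05
    library_padding_factor: float = 1.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_baits <= 0:
            raise ValueError("n_genes and n_baits must be positive")
        if not 0 <= self.n_enriched <= self.n_genes:
            raise ValueError("need 0 <= n_enriched <= n_genes")
        if self.mean_input_footprints <= 0 or self.gene_length_nt <= 0:
            raise ValueError("mean_input_footprints and gene_length_nt must be > 0")
        for f in (self.flag_fraction_dubious, self.flag_fraction_mito,
                  self.two_interval_fraction):
            if not 0 <= f <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        if self.gene_length_nt < self.psite_offset_nt + self.footprint_length_nt:
            raise ValueError(
                "gene_length_nt must be >= psite_offset_nt + footprint_length_nt")


@dataclass
class FootprintDataset:
    genes: list[GeneModel]
    samples: dict  # {bait_name: {"input": FootprintTable, "pulldown": FootprintTable}}
    truth: pd.DataFrame
    library_size: int
    meta: dict = field(default_factory=dict)


def generate_footprint_dataset(params: RiboSimParams) -> FootprintDataset:
    if params.n_genes == 0:
        return FootprintDataset([], {}, pd.DataFrame(), 0)
    rng = np.random.default_rng(params.seed)

    genes, gaps = _build_genome(params, rng)
    n = params.n_genes
    clean = np.array([not (g.dubious or g.mitochondrial) for g in genes])
    if clean.sum() < params.n_enriched:
        raise ValueError("not enough unflagged genes to plant enrichment in")
    enriched_idx = rng.choice(np.nonzero(clean)[0], size=params.n_enriched,
                              replace=False)
    effect = np.zeros(n)
    effect[enriched_idx] = params.true_log2_effect

    mu_in = np.full(n, params.mean_input_footprints)
    mu_pd = mu_in * 2.0 ** effect
    library_size = int(np.ceil(params.library_padding_factor
                               * max(mu_in.sum(), mu_pd.sum())))

    cds_concat, cds_offset, cds_len, gene_start_arr, strand_arr, chrom_arr = \
        _flatten_cds(genes)

    samples: dict[str, dict[str, FootprintTable]] = {}
    n_gene_footprints: dict[str, dict[str, int]] = {}
    for b in range(params.n_baits):
        bait = f"bait{b + 1}"
        samples[bait] = {}
        n_gene_footprints[bait] = {}
        for kind, mu in (("input", mu_in), ("pulldown", mu_pd)):
            counts = rng.poisson(mu)
            total = int(counts.sum())
            if total > library_size:
                raise RuntimeError(
                    "gene footprints exceeded the padded library size; "
                    "increase library_padding_factor")
            gene_idx = np.repeat(np.arange(n), counts)
            u = rng.integers(0, cds_len[gene_idx])
            psite = cds_concat[cds_offset[gene_idx] + u]
            strand = strand_arr[gene_idx]
            three_prime = np.where(strand == 1,
                                   psite + params.psite_offset_nt,
                                   psite - params.psite_offset_nt)
            chrom = chrom_arr[gene_idx]
            bg_chrom, bg_three_prime, bg_strand = _background_footprints(
                library_size - total, gaps, params, rng)
            samples[bait][kind] = FootprintTable.from_arrays(
                chrom=np.concatenate([chrom, bg_chrom]),
                strand=np.where(np.concatenate(
                    [strand, bg_strand]) == 1, "+", "-"),
                three_prime_pos=np.concatenate([three_prime, bg_three_prime]),
                length=np.full(library_size, params.footprint_length_nt,
                               dtype=np.int64),
            )
            # gene-derived rows come first; the rest is intergenic padding
            n_gene_footprints[bait][kind] = total
    del gene_start_arr

    truth = pd.DataFrame({
        "gene_id": [g.gene_id for g in genes],
        "enriched": np.isin(np.arange(n), enriched_idx),
        "true_log2_effect": effect,
        "dubious": [g.dubious for g in genes],
        "mitochondrial": [g.mitochondrial for g in genes],
    })
    return FootprintDataset(genes, samples, truth, library_size,
                            meta={"n_enriched": params.n_enriched,
                                  "true_log2_effect": params.true_log2_effect,
                                  "n_gene_footprints": n_gene_footprints})


def _build_genome(params: RiboSimParams, rng: np.random.Generator
                  ) -> tuple[list[GeneModel], dict[str, list[tuple[int, int]]]]:
    n = params.n_genes
    dubious = rng.random(n) < params.flag_fraction_dubious
    mito = rng.random(n) < params.flag_fraction_mito
    two_iv = rng.random(n) < params.two_interval_fraction
    strands = rng.choice(["+", "-"], size=n)

    cursor = {c: LEADING_GAP_NT for c in CHROM_NAMES + [MITO_CHROM]}
    gaps: dict[str, list[tuple[int, int]]] = {
        c: [(0, LEADING_GAP_NT)] for c in CHROM_NAMES + [MITO_CHROM]}
    genes: list[GeneModel] = []
    for i in range(n):
        chrom = MITO_CHROM if mito[i] else CHROM_NAMES[i % len(CHROM_NAMES)]
        start = cursor[chrom]
        L = params.gene_length_nt
        if two_iv[i]:
            # split the CDS in two around a 100-nt intron; total CDS length kept
            cut = L // 2
            intervals = [(start, start + cut), (start + cut + 100, start + L + 100)]
            end = start + L + 100
        else:
            intervals = [(start, start + L)]
            end = start + L
        genes.append(GeneModel(gene_id=f"G{i:05d}", chrom=chrom,
                               strand=str(strands[i]), cds_intervals=intervals,
                               dubious=bool(dubious[i]),
                               mitochondrial=bool(mito[i])))
        gaps[chrom].append((end, end + INTERGENIC_GAP_NT))
        cursor[chrom] = end + INTERGENIC_GAP_NT
    return genes, gaps


def _flatten_cds(genes: list[GeneModel]):
    cds_concat = np.concatenate([g.cds_positions() for g in genes])
    cds_len = np.array([g.cds_length for g in genes], dtype=np.int64)
    cds_offset = np.concatenate([[0], np.cumsum(cds_len)[:-1]])
    gene_start = np.array([g.span[0] for g in genes], dtype=np.int64)
    strand = np.array([1 if g.strand == "+" else -1 for g in genes], dtype=np.int8)
    chrom = np.array([g.chrom for g in genes], dtype=object)
    return cds_concat, cds_offset, cds_len, gene_start, strand, chrom


def _background_footprints(n_bg: int, gaps: dict[str, list[tuple[int, int]]],
                           params: RiboSimParams, rng: np.random.Generator):
    """Intergenic footprints padding the library to its fixed size.

    P-sites are drawn from gap interiors (a 50-nt margin keeps the whole
    footprint and its P-site clear of any CDS), so background reads count
    toward library size but never toward a gene.
    """
    if n_bg == 0:
        empty = np.empty(0, dtype=object)
        return empty, np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int8)
    margin = 50
    chroms, starts, ends = [], [], []
    for c, ivs in gaps.items():
        for s, e in ivs:
            if e - s > 2 * margin:
                chroms.append(c)
                starts.append(s + margin)
                ends.append(e - margin)
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    widths = ends - starts
    pick = rng.choice(len(starts), size=n_bg, p=widths / widths.sum())
    psite = starts[pick] + rng.integers(0, widths[pick])
    strand = rng.choice(np.array([1, -1], dtype=np.int8), size=n_bg)
    three_prime = np.where(strand == 1, psite + params.psite_offset_nt,
                           psite - params.psite_offset_nt)
    chrom = np.array(chroms, dtype=object)[pick]
    return chrom, three_prime, strand
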