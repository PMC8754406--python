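"""Gene-level translational enrichment from proximity-specific ribosome profiling.

The analysis compares streptavidin-pulldown footprint libraries against
matched input libraries.  Footprints are placed on the genome at their
P-site nucleotide (a fixed offset from the 3' end), counted within each
gene's countable CDS (regions overlapped by another same-strand CDS are
excluded), converted to reads-per-million densities, and summarized as

    log2 enrichment = log2(pulldown RPM density / input RPM density).

Genes are excluded when the input sample carries fewer than
``min_input_footprints`` CDS-mapping footprints, when annotated dubious,
or when mitochondrial.  Enrichments are additionally z-normalized (mean 0,
SD 1 over passing genes).  A gene is called enriched when its enrichment
exceeds the cutoff (default log2 = 0.5) — in every bait when the dual-bait
rule is active.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .genes import FootprintTable, GeneModel

__all__ = [
    "PsiteAssignment",
    "CountableMask",
    "assign_psites",
    "build_countable_mask",
    "count_and_density",
    "compute_enrichment",
    "call_enriched",
    "compare_localizations",
]


# ---------------------------------------------------------------------------
# P-site assignment
# ---------------------------------------------------------------------------

@dataclass
class PsiteAssignment:
    """P-site positions (one row per retained footprint) plus a drop report."""

    psites: pd.DataFrame  # columns chrom, strand, psite_pos
    n_dropped: int = 0


def assign_psites(footprints: FootprintTable, offset_nt: int = 15
                  ) -> PsiteAssignment:
    """Place each footprint at its P-site nucleotide.

    The offset is measured from the 3' end toward the read 5' direction in
    genome coordinates: ``psite = three_prime - offset`` on the plus
    strand, ``three_prime + offset`` on the minus strand.  Footprints whose
    P-site would fall below coordinate 0 are dropped and counted.
    """
    if offset_nt < 0:
        raise ValueError("offset_nt must be >= 0")
    df = footprints.df
    sign = np.where(df["strand"].to_numpy() == "+", -1, +1)
    psite = df["three_prime_pos"].to_numpy() + sign * offset_nt
    keep = psite >= 0
    out = pd.DataFrame({
        "chrom": df["chrom"].to_numpy()[keep],
        "strand": df["strand"].to_numpy()[keep],
        "psite_pos": psite[keep],
    })
    return PsiteAssignment(psites=out, n_dropped=int((~keep).sum()))


# ---------------------------------------------------------------------------
# countable CDS masks
# ---------------------------------------------------------------------------

@dataclass
class CountableMask:
    """Per-gene countable CDS intervals after same-strand overlap exclusion."""

    intervals: dict  # gene_id -> list[(start, end)]
    countable_length: dict  # gene_id -> int
    empty_genes: list = field(default_factory=list)  # fully excluded, flagged
    # flattened per-(chrom, strand) lookup arrays for fast counting
    _index: dict = field(default_factory=dict, repr=False)

    def lookup_arrays(self, chrom: str, strand: str):
        return self._index.get((chrom, strand))


def build_countable_mask(genes: list[GeneModel]) -> CountableMask:
    """Exclude CDS regions overlapped by another same-strand CDS.

    Opposite-strand overlap does not exclude.  A gene whose CDS is fully
    covered by others ends up with an empty mask and is flagged.
    """
    by_key: dict[tuple[str, str], list[tuple[int, int, str]]] = {}
    for g in genes:
        for (s, e) in g.cds_intervals:
            by_key.setdefault((g.chrom, g.strand), []).append((s, e, g.gene_id))

    intervals: dict[str, list[tuple[int, int]]] = {g.gene_id: [] for g in genes}
    index: dict[tuple[str, str], tuple] = {}
    for key, ivs in by_key.items():
        # sweep: coverage counts over all same-strand CDS intervals
        events = sorted(
            [(s, +1) for s, _, _ in ivs] + [(e, -1) for _, e, _ in ivs])
        excluded: list[tuple[int, int]] = []  # coverage >= 2
        cov = 0
        pos = None
        for p, delta in events:
            if cov >= 2 and pos is not None and p > pos:
                if excluded and excluded[-1][1] == pos:
                    excluded[-1] = (excluded[-1][0], p)
                else:
                    excluded.append((pos, p))
            cov += delta
            pos = p
        ex_starts = np.array([s for s, _ in excluded], dtype=np.int64)
        ex_ends = np.array([e for _, e in excluded], dtype=np.int64)

        flat_starts, flat_ends, flat_gene = [], [], []
        for s, e, gid in sorted(ivs):
            for cs, ce in _subtract(s, e, ex_starts, ex_ends):
                intervals[gid].append((cs, ce))
                flat_starts.append(cs)
                flat_ends.append(ce)
                flat_gene.append(gid)
        order = np.argsort(flat_starts, kind="stable")
        index[key] = (
            np.asarray(flat_starts, dtype=np.int64)[order],
            np.asarray(flat_ends, dtype=np.int64)[order],
            np.asarray(flat_gene, dtype=object)[order],
        )

    lengths = {gid: sum(e - s for s, e in ivs) for gid, ivs in intervals.items()}
    empty = [gid for gid, L in lengths.items() if L == 0]
    for gid in intervals:
        intervals[gid].sort()
    return CountableMask(intervals=intervals, countable_length=lengths,
                         empty_genes=empty, _index=index)


def _subtract(s: int, e: int, ex_starts: np.ndarray, ex_ends: np.ndarray):
    """Yield sub-intervals of [s, e) not covered by the excluded intervals."""
    if ex_starts.size == 0:
        yield (s, e)
        return
    cursor = s
    i = int(np.searchsorted(ex_ends, s, side="right"))
    while cursor < e and i < ex_starts.size and ex_starts[i] < e:
        if ex_starts[i] > cursor:
            yield (cursor, int(ex_starts[i]))
        cursor = max(cursor, int(ex_ends[i]))
        i += 1
    if cursor < e:
        yield (cursor, e)


# ---------------------------------------------------------------------------
# counting and densities
# ---------------------------------------------------------------------------

def count_and_density(psites: PsiteAssignment | pd.DataFrame,
                      genes: list[GeneModel], mask: CountableMask,
                      library_size: int) -> pd.DataFrame:
    """Per-gene P-site counts and reads-per-million densities.

    A P-site is counted for a gene when it falls in the gene's countable
    mask on the gene's strand.  ``density_rpm = count * 1e6 /
    library_size``; the per-countable-position density is reported
    alongside.  Genes with an empty countable mask carry NaN densities and
    ``countable_length`` 0.
    """
    if library_size <= 0:
        raise ValueError("library_size must be > 0")
    df = psites.psites if isinstance(psites, PsiteAssignment) else psites
    counts = {g.gene_id: 0 for g in genes}
    for (chrom, strand), sub in df.groupby(["chrom", "strand"], observed=True):
        arrays = mask.lookup_arrays(str(chrom), str(strand))
        if arrays is None:
            continue
        starts, ends, gene_ids = arrays
        pos = sub["psite_pos"].to_numpy(dtype=np.int64)
        slot = np.searchsorted(starts, pos, side="right") - 1
        ok = slot >= 0
        ok[ok] &= pos[ok] < ends[slot[ok]]
        hit_genes, hit_counts = np.unique(gene_ids[slot[ok]], return_counts=True)
        for gid, c in zip(hit_genes, hit_counts):
            counts[gid] += int(c)

    rows = []
    for g in genes:
        c = counts[g.gene_id]
        L = mask.countable_length[g.gene_id]
        rpm = c * 1e6 / library_size
        rows.append((g.gene_id, c, rpm if L > 0 else np.nan,
                     rpm / L if L > 0 else np.nan, L))
    return pd.DataFrame(rows, columns=[
        "gene_id", "count", "density_rpm", "density_rpm_per_position",
        "countable_length"]).set_index("gene_id")


# ---------------------------------------------------------------------------
# enrichment records
# ---------------------------------------------------------------------------

def compute_enrichment(input_cd: pd.DataFrame, pulldown_cd: pd.DataFrame,
                       genes: list[GeneModel],
                       config: PipelineConfig = PipelineConfig()) -> pd.DataFrame:
    """Per-gene enrichment records for one bait.

    Filters (gene excluded, ``passed_filters`` False, no enrichment value):
    fewer than ``config.min_input_footprints`` input CDS footprints;
    dubious annotation; mitochondrial gene; empty countable mask.  A
    passing gene with zero pulldown density receives a -inf sentinel and is
    excluded from the z-normalization.
    """
    gene_ids = [g.gene_id for g in genes]
    if sorted(input_cd.index) != sorted(gene_ids) or \
            sorted(pulldown_cd.index) != sorted(gene_ids):
        raise ValueError("count tables must cover exactly the provided genes")
    inp = input_cd.loc[gene_ids]
    pul = pulldown_cd.loc[gene_ids]

    flags = pd.DataFrame({
        "dubious": [g.dubious for g in genes],
        "mitochondrial": [g.mitochondrial for g in genes],
    }, index=gene_ids)
    passed = (
        (inp["count"].to_numpy() >= config.min_input_footprints)
        & ~flags["dubious"].to_numpy()
        & ~flags["mitochondrial"].to_numpy()
        & (inp["countable_length"].to_numpy() > 0)
    )

    log2_enr = np.full(len(gene_ids), np.nan)
    in_rpm = inp["density_rpm"].to_numpy()
    pd_rpm = pul["density_rpm"].to_numpy()
    with np.errstate(divide="ignore"):
        vals = np.log2(pd_rpm / in_rpm)  # input RPM > 0 wherever passed
    log2_enr[passed] = vals[passed]

    finite = passed & np.isfinite(log2_enr)
    if finite.sum() >= 2 and np.std(log2_enr[finite]) > 0:
        mu, sd = log2_enr[finite].mean(), log2_enr[finite].std(ddof=0)
        normalized = (log2_enr - mu) / sd
    else:
        normalized = np.full_like(log2_enr, np.nan)
    normalized[~finite] = np.nan

    min_counts = np.minimum(inp["count"].to_numpy(), pul["count"].to_numpy())
    count_bin = np.floor(np.log10(np.maximum(min_counts, 1))).astype(int)

    return pd.DataFrame({
        "gene_id": gene_ids,
        "input_count": inp["count"].to_numpy(),
        "pulldown_count": pul["count"].to_numpy(),
        "input_density_rpm": in_rpm,
        "pulldown_density_rpm": pd_rpm,
        "log2_enrichment": log2_enr,
        "normalized_enrichment": normalized,
        "count_bin": count_bin,
        "passed_filters": passed,
        "zero_pulldown": passed & np.isneginf(log2_enr),
        "dubious": flags["dubious"].to_numpy(),
        "mitochondrial": flags["mitochondrial"].to_numpy(),
    }).set_index("gene_id")


def _called_mask(records: pd.DataFrame, cutoff: float, mode: str) -> pd.Series:
    if mode not in {"raw", "normalized"}:
        raise ValueError("mode must be 'raw' or 'normalized'")
    col = "log2_enrichment" if mode == "raw" else "normalized_enrichment"
    vals = records[col]
    return records["passed_filters"] & (vals > cutoff) & np.isfinite(vals)


def call_enriched(records_per_bait, cutoff: float = 0.5, mode: str = "raw",
                  require_all_baits: bool = True) -> set[str]:
    """Final called gene set across baits.

    Per bait a gene is called when it passed the filters and its (raw or
    z-normalized) enrichment is strictly above ``cutoff``.  The final set
    is the intersection across baits when ``require_all_baits`` (the
    dual-bait rule), else the union.
    """
    if isinstance(records_per_bait, pd.DataFrame):
        records_per_bait = [records_per_bait]
    records_per_bait = list(records_per_bait)
    if not records_per_bait:
        raise ValueError("need at least one record table")
    per_bait = [set(r.index[_called_mask(r, cutoff, mode)])
                for r in records_per_bait]
    out = per_bait[0]
    for s in per_bait[1:]:
        out = (out & s) if require_all_baits else (out | s)
    return out


def compare_localizations(records_a: pd.DataFrame, records_b: pd.DataFrame,
                          cutoff: float = 0.5, mode: str = "raw"
                          ) -> pd.DataFrame:
    """Classify each shared gene by which organelle's pulldown calls it.

    Classes: ``A-only``, ``B-only``, ``both``, ``neither`` over the shared
    gene universe (error if the two universes are disjoint).
    """
    shared = records_a.index.intersection(records_b.index)
    if len(shared) == 0:
        raise ValueError("record tables share no genes")
    called_a = _called_mask(records_a.loc[shared], cutoff, mode)
    called_b = _called_mask(records_b.loc[shared], cutoff, mode)
    cls = np.select(
        [called_a & called_b, called_a & ~called_b, ~called_a & called_b],
        ["both", "A-only", "B-only"], default="neither")
    return pd.DataFrame({"class": cls}, index=shared)
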