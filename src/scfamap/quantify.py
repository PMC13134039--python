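"""Per-sample pathway abundance estimation (P_genomes).

The estimator converts per-gene mapped-read counts into the percentage of
genomes in a sample that encode each pathway::

    P_genomes = [ Σ_genes (h_gene / l_gene) / l_pathway ]
                ÷ [ Σ_rplB (h_housekeeping / l_housekeeping) ] × 100

Dividing each gene's hit count by its length removes the length bias of
read recruitment; dividing by the number of genes in the pathway
(l_pathway) bases the estimate on average per-gene evidence so pathways
with long rosters are not over-counted; dividing by the summed
length-normalized counts of the single-copy housekeeping gene rplB scales
everything to genome equivalents, cancelling sequencing depth. Under the
single-copy assumption the estimate is the fraction of genomes carrying
the pathway; genomes with duplicated genes can push it above 100%, which
is reported as-is.

Reads hitting a gene shared by several pathways are apportioned in
proportion to the evidence from single-pathway genes in the same sample::

    h_gene = h_o · (Σ h_s / Σ h_m)

with h_o the observed count of the shared gene, Σh_s the summed counts of
the target pathway's single-pathway genes and Σh_m the same sum over all
pathways containing the shared gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .catalog import CatalogEntry, HousekeepingEntry
from .schema import PathwayRegistry

__all__ = [
    "RplBDepthError",
    "SampleGeneCounts",
    "SampleAbundanceProfile",
    "count_primary_alignments",
    "read_counts_tsv",
    "apportion_multi_pathway",
    "apportion_sample",
    "pathway_abundance",
    "abundance_table",
]

logger = logging.getLogger(__name__)


class RplBDepthError(ValueError):
    """Zero rplB signal: pathway abundance is undefined, never reported as 0."""


@dataclass
class SampleGeneCounts:
    """Mapped-read counts for one sample: catalog-gene counts plus rplB counts."""

    sample_id: str
    gene_counts: dict[str, float] = field(default_factory=dict)
    rplb_counts: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, counts in (("gene", self.gene_counts), ("rplB", self.rplb_counts)):
            for entry, c in counts.items():
                if c < 0:
                    raise ValueError(
                        f"sample {self.sample_id}: negative {name} count for {entry}"
                    )


@dataclass(frozen=True)
class SampleAbundanceProfile:
    """P_genomes per pathway for one sample, with per-product totals (%)."""

    sample_id: str
    per_pathway: Mapping[str, float]
    butyrate: float
    propionate: float

    @property
    def combined(self) -> float:
        return self.butyrate + self.propionate


# ---------------------------------------------------------------------------
# count input

def count_primary_alignments(sam_path: str | Path) -> dict[str, int]:
    """Count mapped reads per reference in a SAM/BAM file.

    Only primary, mapped alignments are counted — secondary, supplementary
    and unmapped records are skipped so a read contributes at most once.
    """
    import pysam

    counts: dict[str, int] = {}
    save = pysam.set_verbosity(0)  # silence missing-index warning for SAM input
    try:
        with pysam.AlignmentFile(str(sam_path), check_sq=False) as fh:
            for aln in fh:
                if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                    continue
                counts[aln.reference_name] = counts.get(aln.reference_name, 0) + 1
    finally:
        pysam.set_verbosity(save)
    return counts


def read_counts_tsv(path: str | Path) -> dict[str, dict[str, float]]:
    """Read a long-format count table (sample, entry, count) into
    ``{sample: {entry: count}}``."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "entry": str})
    missing = {"sample", "entry", "count"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: count TSV missing column(s) {sorted(missing)}")
    out: dict[str, dict[str, float]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.sample, {})[row.entry] = float(row.count)
    return out


# ---------------------------------------------------------------------------
# apportionment

def apportion_multi_pathway(
    h_o: float,
    single_pathway_counts: Mapping[str, float],
    sample_id: str = "?",
    gene: str = "?",
) -> dict[str, float]:
    """Split the observed count of a shared gene between its pathways.

    ``single_pathway_counts`` maps each candidate pathway to Σh_s, the
    summed counts of that pathway's single-pathway genes in the same
    sample; Σh_m is their total. When Σh_m is zero the formula is
    undefined and the count is split equally (logged), which preserves
    count conservation.
    """
    if h_o < 0:
        raise ValueError("h_o must be ≥ 0")
    pathways = list(single_pathway_counts)
    if not pathways:
        raise ValueError("no candidate pathways for apportionment")
    sum_hm = float(sum(single_pathway_counts.values()))
    if sum_hm == 0.0:
        if h_o > 0:
            logger.warning(
                "sample %s gene %s: no single-pathway evidence (Σh_m=0); "
                "splitting %g reads equally among %s",
                sample_id, gene, h_o, pathways,
            )
        return {p: h_o / len(pathways) for p in pathways}
    return {p: h_o * (single_pathway_counts[p] / sum_hm) for p in pathways}


def _normalize_catalog(
    catalog: Sequence[CatalogEntry] | pd.DataFrame,
) -> list[tuple[str, str, tuple[str, ...], float]]:
    """-> list of (entry_id, gene, pathways, length)."""
    if isinstance(catalog, pd.DataFrame):
        return [
            (str(r.entry), str(r.gene), tuple(str(r.pathways).split(";")), float(r.length))
            for r in catalog.itertuples(index=False)
        ]
    return [(e.entry_id, e.gene, e.pathways, float(e.length)) for e in catalog]


def _normalize_rplb(
    rplb: Sequence[HousekeepingEntry] | pd.DataFrame,
) -> list[tuple[str, float]]:
    if isinstance(rplb, pd.DataFrame):
        return [(str(r.entry), float(r.length)) for r in rplb.itertuples(index=False)]
    return [(e.entry_id, float(e.length)) for e in rplb]


def apportion_sample(
    counts: SampleGeneCounts,
    catalog: Sequence[CatalogEntry] | pd.DataFrame,
    registry: PathwayRegistry,
) -> dict[tuple[str, str], float]:
    """Effective per-(entry, pathway) counts after shared-gene apportionment.

    Entries of single-pathway genes contribute their full count to their
    pathway; entries of shared genes are split by
    :func:`apportion_multi_pathway` using single-pathway gene evidence from
    the same sample.
    """
    entries = _normalize_catalog(catalog)
    # Σ counts of single-pathway genes per pathway, for this sample
    single_sums: dict[str, float] = {p: 0.0 for p in registry.pathway_ids}
    for entry_id, gene, pathways, _length in entries:
        if len(pathways) == 1:
            single_sums[pathways[0]] += counts.gene_counts.get(entry_id, 0.0)

    out: dict[tuple[str, str], float] = {}
    for entry_id, gene, pathways, _length in entries:
        h = counts.gene_counts.get(entry_id, 0.0)
        if len(pathways) == 1:
            out[(entry_id, pathways[0])] = h
        else:
            shares = apportion_multi_pathway(
                h,
                {p: single_sums[p] for p in pathways},
                sample_id=counts.sample_id,
                gene=gene,
            )
            for p, v in shares.items():
                out[(entry_id, p)] = v
    return out


# ---------------------------------------------------------------------------
# the estimator

def pathway_abundance(
    counts: SampleGeneCounts,
    catalog: Sequence[CatalogEntry] | pd.DataFrame,
    rplb_catalog: Sequence[HousekeepingEntry] | pd.DataFrame,
    registry: PathwayRegistry,
) -> SampleAbundanceProfile:
    """P_genomes per pathway for one sample (percent of genomes).

    Raises :class:`RplBDepthError` when the sample has no rplB signal —
    the estimate is undefined in that case and is never reported as zero.
    """
    rplb_entries = _normalize_rplb(rplb_catalog)
    if not rplb_entries:
        raise RplBDepthError(f"sample {counts.sample_id}: empty rplB catalog")
    rplb_depth = sum(
        counts.rplb_counts.get(entry_id, 0.0) / length
        for entry_id, length in rplb_entries
    )
    if rplb_depth <= 0.0:
        raise RplBDepthError(
            f"sample {counts.sample_id}: zero rplB signal; "
            "pathway abundance is undefined for this sample"
        )

    entries = _normalize_catalog(catalog)
    length_of = {entry_id: length for entry_id, _g, _p, length in entries}
    effective = apportion_sample(counts, catalog, registry)

    per_pathway: dict[str, float] = {}
    for pid in registry.pathway_ids:
        num = sum(
            h / length_of[entry_id]
            for (entry_id, p), h in effective.items()
            if p == pid
        )
        per_pathway[pid] = (num / registry[pid].l_pathway) / rplb_depth * 100.0

    butyrate = sum(
        per_pathway[p] for p in registry.pathways_of_product("butyrate")
    )
    propionate = sum(
        per_pathway[p] for p in registry.pathways_of_product("propionate")
    )
    return SampleAbundanceProfile(
        sample_id=counts.sample_id,
        per_pathway=per_pathway,
        butyrate=butyrate,
        propionate=propionate,
    )


def abundance_table(
    profiles: Iterable[SampleAbundanceProfile], registry: PathwayRegistry
) -> pd.DataFrame:
    """Wide per-sample table: one column per pathway plus product totals."""
    rows = []
    for p in profiles:
        row: dict[str, object] = {"sample": p.sample_id}
        row.update({pid: p.per_pathway.get(pid, 0.0) for pid in registry.pathway_ids})
        row["butyrate_total"] = p.butyrate
        row["propionate_total"] = p.propionate
        row["combined_total"] = p.combined
        rows.append(row)
    cols = ["sample", *registry.pathway_ids, "butyrate_total", "propionate_total", "combined_total"]
    return pd.DataFrame(rows, columns=cols)
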