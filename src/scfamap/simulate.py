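"""Synthetic gut-community fixtures with known pathway genotypes.

Everything the pipeline consumes can be generated here without any
database access: per-genome homology-hit tables (with scores anchored to
the registry's model-strain references), gene and rplB sequences, species
abundance tables with taxonomy, literature-style phenotype tables, and
per-sample read-count tables.

The count model is deliberately the one the estimator assumes: pathway
genes are single copy in carriers (configurable violation rate doubles
them), read counts per catalog entry are Poisson with mean proportional
to source-genome abundance × gene length × sequencing depth (longer genes
recruit more reads), and rplB is present once per genome. Species
abundances are long-tailed (lognormal weights), mirroring communities in
which a few species hold most of the biomass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .catalog import CatalogEntry, HousekeepingEntry, build_catalog, build_rplb_catalog
from .classify import GeneHit
from .quantify import SampleGeneCounts
from .schema import PathwayRegistry, PRODUCTS, load_registry

__all__ = [
    "SimulationConfig",
    "CommunityTruth",
    "simulate_community",
    "simulate_sample_counts",
    "simulate_phenotypes",
    "simulate_hits",
    "expected_pathway_abundance",
]

#: Default per-pathway carriage probabilities. Chosen so that ~20% of
#: genomes carry a butyrate pathway and ~17% a propionate pathway, with the
#: acetyl-CoA and sodium-pumping succinate routes dominating their products,
#: as observed in gut strain collections.
DEFAULT_CARRIAGE: dict[str, float] = {
    "Ace": 0.12,
    "Lys": 0.04,
    "Glu": 0.02,
    "4-Ami": 0.02,
    "SP": 0.11,
    "Pro": 0.04,
    "Acr": 0.01,
    "WWC": 0.01,
}

#: family -> phylum for the synthetic taxonomy
FAMILY_PHYLUM: dict[str, str] = {
    "Lachnospiraceae": "Bacillota",
    "Oscillospiraceae": "Bacillota",
    "Eubacteriaceae": "Bacillota",
    "Veillonellaceae": "Bacillota",
    "Lactobacillaceae": "Bacillota",
    "Bacteroidaceae": "Bacteroidota",
    "Prevotellaceae": "Bacteroidota",
    "Weeksellaceae": "Bacteroidota",
    "Bifidobacteriaceae": "Actinomycetota",
    "Propionibacteriaceae": "Actinomycetota",
    "Enterobacteriaceae": "Pseudomonadota",
    "Akkermansiaceae": "Verrucomicrobiota",
}

_BUTYRATE_FAMILIES = ("Lachnospiraceae", "Oscillospiraceae", "Eubacteriaceae", "Weeksellaceae")
_PROPIONATE_FAMILIES = ("Bacteroidaceae", "Prevotellaceae", "Veillonellaceae", "Propionibacteriaceae")
_OTHER_FAMILIES = ("Bifidobacteriaceae", "Enterobacteriaceae", "Lactobacillaceae", "Akkermansiaceae")

#: Annotation text per gene; curated genes get descriptions that satisfy
#: the default keyword rules.
_GENE_DESCRIPTIONS: dict[str, str] = {
    "bcd": "butyryl-CoA dehydrogenase (NAD+)",
    "but": "butyryl-CoA:acetate CoA-transferase",
    "hbd": "3-hydroxybutyryl-CoA dehydrogenase",
    "cro": "crotonase (3-hydroxybutyryl-CoA dehydratase)",
    "thl": "acetyl-CoA C-acetyltransferase (thiolase)",
}

#: Non-specific decoy descriptions that the keyword rules must reject.
_DECOY_DESCRIPTIONS: dict[str, str] = {
    "bcd": "acyl-CoA dehydrogenase, short-chain specific",
    "but": "4-hydroxybutyrate CoA-transferase",
    "hbd": "3-hydroxyacyl-CoA dehydrogenase, generic",
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic community.

    ``depth`` is mean sequencing depth in reads per bp of reference at
    abundance 1; per-entry count means are abundance × length × depth.
    ``multi_pathway_rate`` is the probability that a pathway carrier also
    carries a second pathway for the same product (the mechanism that
    produces genuine multi-pathway genomes and exercises shared-gene
    apportionment). ``copy_number_violation_rate`` doubles a carrier's
    pathway genes, the mechanism behind abundance estimates above 100%.
    """

    seed: int = 0
    n_genomes: int = 60
    n_samples: int = 8
    carriage: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_CARRIAGE))
    multi_pathway_rate: float = 0.02
    gene_length_range: tuple[int, int] = (600, 1800)
    rplb_length: int = 830
    depth: float = 0.5
    copy_number_violation_rate: float = 0.0
    sequence_reuse_rate: float = 0.25
    abundance_sigma: float = 1.5
    unassigned_fraction: float = 0.05

    def __post_init__(self) -> None:
        for name in ("multi_pathway_rate", "copy_number_violation_rate",
                     "sequence_reuse_rate", "unassigned_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if any(not 0.0 <= p <= 1.0 for p in self.carriage.values()):
            raise ValueError("carriage probabilities must be in [0, 1]")
        if self.depth < 0:
            raise ValueError("depth must be ≥ 0")
        if self.n_genomes < 1:
            raise ValueError("n_genomes must be ≥ 1")


@dataclass
class CommunityTruth:
    """A simulated community with its ground-truth genotypes.

    ``truth`` has one row per genome: species, family, phylum, abundance,
    carried pathways (';'-joined), gene copy number. ``catalog`` and
    ``rplb_catalog`` are the deduplicated mapping references;
    ``gene_sequences``/``rplb_records`` retain the per-genome sequences so
    the catalog build can be reproduced from flat files.
    """

    config: SimulationConfig
    registry: PathwayRegistry
    truth: pd.DataFrame
    catalog: list[CatalogEntry]
    rplb_catalog: list[HousekeepingEntry]
    gene_sequences: dict[tuple[str, str], str]
    rplb_records: list[tuple[str, str, float]]
    gene_lengths: dict[str, int]

    def carried(self, genome: str) -> tuple[str, ...]:
        row = self.truth.loc[self.truth["genome"] == genome].iloc[0]
        return tuple(p for p in str(row["pathways"]).split(";") if p)

    @property
    def abundance_table(self) -> pd.DataFrame:
        return self.truth[["species", "family", "phylum", "abundance"]].reset_index(drop=True)


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def _mutate(rng: np.random.Generator, seq: str, rate: float = 0.02) -> str:
    chars = list(seq)
    n = max(1, rng.binomial(len(chars), rate))
    positions = rng.choice(len(chars), size=n, replace=False)
    for pos in positions:
        alternatives = [b for b in "ACGT" if b != chars[pos]]
        chars[pos] = alternatives[rng.integers(0, 3)]
    return "".join(chars)


def simulate_community(
    config: SimulationConfig, registry: PathwayRegistry | None = None
) -> CommunityTruth:
    """Draw a community of genomes with known pathway carriage.

    Fully deterministic under ``config.seed``. Families are assigned so
    that butyrate carriers concentrate in Bacillota families and propionate
    carriers in Bacteroidota families, with deliberate exceptions, echoing
    the family-level structure of real gut communities.
    """
    registry = registry if registry is not None else load_registry()
    rng = np.random.default_rng(config.seed)

    # one canonical length and sequence per gene family
    lo, hi = config.gene_length_range
    gene_lengths = {
        g: int(rng.integers(lo, hi + 1)) for g in sorted(registry.all_genes)
    }
    canonical = {g: _random_dna(rng, gene_lengths[g]) for g in sorted(registry.all_genes)}
    rplb_canonical = _random_dna(rng, config.rplb_length)

    rows = []
    gene_sequences: dict[tuple[str, str], str] = {}
    rplb_records: list[tuple[str, str, float]] = []
    width = len(str(config.n_genomes))
    for i in range(config.n_genomes):
        genome = f"G{i + 1:0{width}d}"
        carried: list[str] = []
        for product in PRODUCTS:
            pids = [p for p in registry.pathways_of_product(product) if p in config.carriage]
            probs = np.array([config.carriage[p] for p in pids])
            total = probs.sum()
            r = rng.random()
            if total > 0 and r < total:
                idx = int(np.searchsorted(np.cumsum(probs), r, side="right"))
                chosen = pids[min(idx, len(pids) - 1)]
                carried.append(chosen)
                if len(pids) > 1 and rng.random() < config.multi_pathway_rate:
                    extras = [p for p in pids if p != chosen]
                    carried.append(extras[rng.integers(0, len(extras))])
        copies = 2 if (carried and rng.random() < config.copy_number_violation_rate) else 1

        products = {registry.product_of(p) for p in carried}
        if products == {"butyrate"}:
            family = _BUTYRATE_FAMILIES[
                int(rng.choice(len(_BUTYRATE_FAMILIES), p=[0.45, 0.3, 0.2, 0.05]))
            ]
        elif products == {"propionate"}:
            family = _PROPIONATE_FAMILIES[
                int(rng.choice(len(_PROPIONATE_FAMILIES), p=[0.5, 0.3, 0.1, 0.1]))
            ]
        elif products:  # dual producer
            family = ("Veillonellaceae", "Lachnospiraceae")[int(rng.integers(0, 2))]
        else:
            family = _OTHER_FAMILIES[int(rng.integers(0, len(_OTHER_FAMILIES)))]

        genes = sorted({g for p in carried for g in registry[p].required_genes})
        for g in genes:
            if rng.random() < config.sequence_reuse_rate:
                seq = canonical[g]
            else:
                seq = _mutate(rng, canonical[g])
            gene_sequences[(genome, g)] = seq
        rplb_seq = (
            rplb_canonical
            if rng.random() < config.sequence_reuse_rate
            else _mutate(rng, rplb_canonical)
        )
        rplb_records.append((genome, rplb_seq, float(rng.uniform(450.0, 800.0))))

        rows.append(
            {
                "genome": genome,
                "species": f"s__{genome}",
                "family": family,
                "phylum": FAMILY_PHYLUM[family],
                "pathways": ";".join(sorted(carried, key=registry.pathway_ids.index)),
                "copies": copies,
            }
        )

    weights = rng.lognormal(mean=0.0, sigma=config.abundance_sigma, size=config.n_genomes)
    abundances = weights / weights.sum() * (1.0 - config.unassigned_fraction)
    truth = pd.DataFrame(rows)
    truth["abundance"] = abundances

    # the truth table already restricts genes to carried pathways, so the
    # catalog is built directly from the sequences (no classification pass)
    entries = (
        build_catalog(
            ((g, gene, seq) for (g, gene), seq in sorted(gene_sequences.items())),
            registry,
        )
        if gene_sequences
        else []
    )
    rplb_entries = build_rplb_catalog(rplb_records)

    return CommunityTruth(
        config=config,
        registry=registry,
        truth=truth,
        catalog=entries,
        rplb_catalog=rplb_entries,
        gene_sequences=gene_sequences,
        rplb_records=rplb_records,
        gene_lengths=gene_lengths,
    )


def simulate_sample_counts(
    truth: CommunityTruth,
    sample_id: str,
    seed: int | np.random.Generator,
    depth: float | None = None,
) -> SampleGeneCounts:
    """Poisson read counts for one sample against the community's catalogs.

    Per catalog entry the mean is depth × length × Σ over source genomes of
    (abundance × copy number); rplB entries use copy number 1.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    depth = truth.config.depth if depth is None else depth
    abund = dict(zip(truth.truth["genome"], truth.truth["abundance"]))
    copies = dict(zip(truth.truth["genome"], truth.truth["copies"]))

    gene_counts: dict[str, float] = {}
    for e in truth.catalog:
        mean = depth * e.length * sum(abund[g] * copies[g] for g in e.sources)
        gene_counts[e.entry_id] = int(rng.poisson(mean))
    rplb_counts: dict[str, float] = {}
    for e in truth.rplb_catalog:
        mean = depth * e.length * sum(abund[g] for g in e.sources)
        rplb_counts[e.entry_id] = int(rng.poisson(mean))
    return SampleGeneCounts(
        sample_id=sample_id, gene_counts=gene_counts, rplb_counts=rplb_counts
    )


def expected_pathway_abundance(truth: CommunityTruth) -> dict[str, float]:
    """Closed-form expectation of P_genomes per pathway for this community.

    The denominator is the total abundance of genomes contributing rplB
    (every genome); the numerator for a pathway is the copy-weighted
    abundance of its carriers.
    """
    total = float(truth.truth["abundance"].sum())
    out: dict[str, float] = {}
    for pid in truth.registry.pathway_ids:
        mask = truth.truth["pathways"].str.split(";").apply(lambda ps: pid in ps)
        num = float((truth.truth["abundance"] * truth.truth["copies"])[mask].sum())
        out[pid] = 100.0 * num / total if total > 0 else math.nan
    return out


def simulate_phenotypes(
    truth: CommunityTruth,
    error_rate: float = 0.0,
    unknown_rate: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Literature-style phenotype table derived from the genotype truth.

    Per product the reported phenotype equals the genomic truth with
    probability 1−error_rate and is flipped otherwise; each field is then
    masked to unknown with ``unknown_rate``. Species with both fields
    unknown are dropped (they simply have no literature record).
    """
    if not 0.0 <= error_rate <= 1.0 or not 0.0 <= unknown_rate <= 1.0:
        raise ValueError("error_rate and unknown_rate must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    registry = truth.registry
    rows = []
    for r in truth.truth.itertuples(index=False):
        carried = [p for p in str(r.pathways).split(";") if p]
        rec = {"species": r.species, "citation": "synthetic-truth"}
        for product in PRODUCTS:
            actual = any(registry.product_of(p) == product for p in carried)
            reported = (not actual) if rng.random() < error_rate else actual
            if rng.random() < unknown_rate:
                rec[product] = "unknown"
            else:
                rec[product] = "yes" if reported else "no"
        if rec["butyrate"] == "unknown" and rec["propionate"] == "unknown":
            continue
        rows.append(rec)
    return pd.DataFrame(rows, columns=["species", "butyrate", "propionate", "citation"])


def simulate_hits(
    truth: CommunityTruth, seed: int | np.random.Generator = 0
) -> list[GeneHit]:
    """Homology-hit tables consistent with the genotype truth.

    Carried genes receive scores between 80% and 110% of the mean
    model-strain score (always above the 50%-of-minimum cutoff) and
    specific descriptions. Decoy hits — below-cutoff scores on random
    genes, and high-scoring hits with non-specific descriptions that the
    keyword rules must reject — are interleaved so that filtering is
    actually exercised; classification of these tables recovers the truth
    exactly.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    registry = truth.registry
    all_genes = sorted(registry.all_genes)
    hits: list[GeneHit] = []
    for r in truth.truth.itertuples(index=False):
        carried = [p for p in str(r.pathways).split(";") if p]
        genes = sorted({g for p in carried for g in registry[p].required_genes})
        for g in genes:
            score = registry.mean_model_score(g) * rng.uniform(0.8, 1.1)
            hits.append(
                GeneHit(
                    genome_id=r.genome,
                    gene=g,
                    subject_id=f"{r.genome}|{g}",
                    score=round(float(score), 1),
                    length=truth.gene_lengths[g],
                    description=_GENE_DESCRIPTIONS.get(g, f"{g} pathway gene"),
                )
            )
        # below-cutoff decoys on random genes
        for _ in range(2):
            g = all_genes[int(rng.integers(0, len(all_genes)))]
            score = registry.min_model_score(g) * rng.uniform(0.05, 0.45)
            hits.append(
                GeneHit(
                    genome_id=r.genome,
                    gene=g,
                    subject_id=f"{r.genome}|decoy_{g}",
                    score=round(float(score), 1),
                    length=truth.gene_lengths[g],
                    description=_GENE_DESCRIPTIONS.get(g, f"{g} pathway gene"),
                )
            )
        # high-scoring but non-specific annotation: curation must drop it
        if rng.random() < 0.15:
            g = ("bcd", "but", "hbd")[int(rng.integers(0, 3))]
            hits.append(
                GeneHit(
                    genome_id=r.genome,
                    gene=g,
                    subject_id=f"{r.genome}|nonspecific_{g}",
                    score=round(float(registry.mean_model_score(g) * 0.95), 1),
                    length=truth.gene_lengths[g],
                    description=_DECOY_DESCRIPTIONS[g],
                )
            )
    return hits
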