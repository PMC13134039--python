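"""Genotype classification: from homology hits to per-genome pathway calls.

Three steps, applied per genome:

1. keyword curation of hit descriptions, then a bit-score filter at a
   configurable fraction (default 50%) of the lowest-scoring model strain
   for the same gene;
2. complete-gene-set calling — a pathway is present only when *every*
   required gene has at least one surviving hit;
3. single-pathway resolution — a genome complete for several pathways of
   the same product is assigned the pathway whose hits score consistently
   higher relative to the model strains (mean per-gene score ratio), with
   a tie margin that deliberately lets genuine multi-pathway genomes keep
   more than one call.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .schema import ConfigError, PathwayRegistry, apply_curation

__all__ = [
    "GeneHit",
    "GenomePathwayProfile",
    "read_hits_tsv",
    "parse_hmmer_tblout",
    "curate_hits",
    "filter_hits",
    "call_complete_pathways",
    "pathway_score_ratios",
    "resolve_single_pathway",
    "classify_genome",
    "classify_genomes",
    "profiles_to_frame",
    "write_profiles_tsv",
    "read_profiles_tsv",
]


@dataclass(frozen=True)
class GeneHit:
    """One homology-search hit linking a genome's sequence to a pathway gene."""

    genome_id: str
    gene: str
    subject_id: str
    score: float
    length: int = 0
    description: str = ""

    def __post_init__(self) -> None:
        if not math.isfinite(self.score) or self.score < 0:
            raise ValueError(
                f"hit {self.genome_id}/{self.gene}: bit score must be finite and ≥0, "
                f"got {self.score}"
            )


@dataclass(frozen=True)
class GenomePathwayProfile:
    """Pathway calls for one genome, before and after resolution.

    ``complete_pathways`` holds every pathway whose full gene roster was hit;
    ``assigned_pathways`` the subset surviving single-pathway resolution
    (per product: a singleton, nothing, or several for genuine multi-pathway
    carriers). ``mean_score_ratios`` is the resolution statistic per
    complete pathway: the mean over required genes of (best genome hit
    score ÷ mean model-strain score).
    """

    genome_id: str
    complete_pathways: frozenset[str]
    assigned_pathways: frozenset[str]
    mean_score_ratios: Mapping[str, float]

    def __post_init__(self) -> None:
        if not self.assigned_pathways <= self.complete_pathways:
            raise ValueError(
                f"{self.genome_id}: assigned pathways not a subset of complete ones"
            )

    def products(self, registry: PathwayRegistry) -> frozenset[str]:
        return frozenset(registry.product_of(p) for p in self.assigned_pathways)


# ---------------------------------------------------------------------------
# input parsing

_HIT_COLUMNS = ("genome", "gene", "subject", "score", "length", "description")


def read_hits_tsv(path: str | Path) -> list[GeneHit]:
    """Read hits from a generic TSV with columns
    genome, gene, subject, score, length, description (header required;
    length and description optional)."""
    hits: list[GeneHit] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or "genome" not in reader.fieldnames:
            raise ValueError(f"{path}: expected a header with columns {_HIT_COLUMNS}")
        for i, row in enumerate(reader, start=2):
            try:
                hits.append(
                    GeneHit(
                        genome_id=row["genome"],
                        gene=row["gene"],
                        subject_id=row.get("subject", "") or "",
                        score=float(row["score"]),
                        length=int(row.get("length") or 0),
                        description=row.get("description", "") or "",
                    )
                )
            except (KeyError, ValueError) as exc:
                raise ValueError(f"{path}:{i}: malformed hit row ({exc})") from exc
    return hits


def parse_hmmer_tblout(path: str | Path, genome_id: str) -> list[GeneHit]:
    """Parse HMMER3 ``--tblout`` output for one genome.

    The query (profile) name is taken as the gene symbol, the target name as
    the subject sequence id, and the full-sequence bit score as the hit
    score. The free-text description (columns 19+) feeds keyword curation.
    """
    hits: list[GeneHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split(None, 18)
            if len(fields) < 18:
                raise ValueError(f"{path}:{lineno}: truncated tblout row")
            description = fields[18].strip() if len(fields) > 18 else ""
            hits.append(
                GeneHit(
                    genome_id=genome_id,
                    gene=fields[2],
                    subject_id=fields[0],
                    score=float(fields[5]),
                    description=description,
                )
            )
    return hits


# ---------------------------------------------------------------------------
# filtering

def curate_hits(hits: Iterable[GeneHit], registry: PathwayRegistry) -> list[GeneHit]:
    """Drop hits whose descriptions fail the registry's keyword rules."""
    return [
        h for h in hits if apply_curation(h.description, h.gene, registry.curation_rules)
    ]


def filter_hits(
    hits: Iterable[GeneHit],
    model_scores: PathwayRegistry | Mapping[str, Sequence[float]],
    score_frac: float = 0.5,
) -> list[GeneHit]:
    """Keep hits scoring at least ``score_frac`` × the lowest model-strain
    score for the same gene (boundary value retained).

    ``model_scores`` may be a registry or a plain ``gene -> scores`` mapping.
    A hit whose gene has no reference scores raises :class:`ConfigError`
    naming the gene.
    """

    def cutoff(gene: str) -> float:
        if isinstance(model_scores, PathwayRegistry):
            return score_frac * model_scores.min_model_score(gene)
        scores = model_scores.get(gene)
        if not scores:
            raise ConfigError(f"no model-strain scores for gene {gene!r}")
        return score_frac * min(scores)

    return [h for h in hits if h.score >= cutoff(h.gene)]


# ---------------------------------------------------------------------------
# pathway calling

def call_complete_pathways(
    hits: Iterable[GeneHit], registry: PathwayRegistry
) -> frozenset[str]:
    """Pathways for which every required gene has ≥1 (filtered) hit.

    All hits must belong to a single genome; mixing genomes is an error.
    """
    hits = list(hits)
    genomes = {h.genome_id for h in hits}
    if len(genomes) > 1:
        raise ValueError(f"hits span multiple genomes: {sorted(genomes)}")
    genes_hit = {h.gene for h in hits}
    return frozenset(
        pw.pathway_id
        for pw in registry.pathways
        if set(pw.required_genes) <= genes_hit
    )


def pathway_score_ratios(
    hits: Iterable[GeneHit],
    registry: PathwayRegistry,
    pathways: Iterable[str],
) -> dict[str, float]:
    """Mean per-gene score ratio for each candidate pathway.

    Per required gene the best (maximum) surviving hit score is divided by
    the mean model-strain score for that gene; the pathway statistic is the
    mean of these ratios over its roster.
    """
    best: dict[str, float] = {}
    for h in hits:
        if h.score > best.get(h.gene, -1.0):
            best[h.gene] = h.score
    ratios: dict[str, float] = {}
    for pid in pathways:
        pw = registry[pid]
        vals = [
            best[g] / registry.mean_model_score(g)
            for g in pw.required_genes
            if g in best
        ]
        if len(vals) != pw.l_pathway:
            missing = [g for g in pw.required_genes if g not in best]
            raise ValueError(
                f"cannot score incomplete pathway {pid!r}: no hit for {missing}"
            )
        ratios[pid] = sum(vals) / len(vals)
    return ratios


def resolve_single_pathway(
    profile: GenomePathwayProfile,
    registry: PathwayRegistry,
    tie_margin: float = 0.1,
) -> GenomePathwayProfile:
    """Resolve multi-pathway calls within each product independently.

    Among a product's complete pathways the one with the highest mean score
    ratio wins; any other pathway within ``tie_margin`` of the top ratio is
    retained as well (genuine multi-pathway carrier). With ``tie_margin=0``
    exactly one pathway per product survives, exact ties broken by registry
    order; with ``tie_margin=inf`` every complete pathway is kept. A genome
    may end up with one butyrate *and* one propionate pathway — products are
    never resolved against each other.
    """
    if tie_margin < 0:
        raise ValueError("tie_margin must be ≥ 0")
    assigned: set[str] = set()
    for product in ("butyrate", "propionate"):
        candidates = [
            p for p in registry.pathway_ids
            if p in profile.complete_pathways and registry.product_of(p) == product
        ]
        if len(candidates) <= 1:
            assigned.update(candidates)
            continue
        ratios = profile.mean_score_ratios
        top = max(ratios[p] for p in candidates)
        kept = [p for p in candidates if top - ratios[p] < tie_margin]
        if not kept:  # tie_margin == 0: keep the top pathway, registry order on ties
            kept = [p for p in candidates if ratios[p] == top][:1]
        assigned.update(kept)
    return replace(profile, assigned_pathways=frozenset(assigned))


def classify_genome(
    genome_id: str,
    hits: Iterable[GeneHit],
    registry: PathwayRegistry,
    score_frac: float = 0.5,
    tie_margin: float = 0.1,
    curate: bool = True,
) -> GenomePathwayProfile:
    """Full per-genome classification: curation → score filter → complete
    gene sets → single-pathway resolution."""
    own = [h for h in hits if h.genome_id == genome_id]
    if curate:
        own = curate_hits(own, registry)
    own = filter_hits(own, registry, score_frac=score_frac)
    complete = call_complete_pathways(own, registry)
    ratios = pathway_score_ratios(own, registry, complete)
    profile = GenomePathwayProfile(
        genome_id=genome_id,
        complete_pathways=complete,
        assigned_pathways=complete,
        mean_score_ratios=ratios,
    )
    return resolve_single_pathway(profile, registry, tie_margin=tie_margin)


def classify_genomes(
    hits: Iterable[GeneHit],
    registry: PathwayRegistry,
    score_frac: float = 0.5,
    tie_margin: float = 0.1,
    curate: bool = True,
) -> list[GenomePathwayProfile]:
    """Classify every genome appearing in ``hits``; genomes sorted by id."""
    registry.validate_model_scores()
    by_genome: dict[str, list[GeneHit]] = {}
    for h in hits:
        by_genome.setdefault(h.genome_id, []).append(h)
    return [
        classify_genome(g, by_genome[g], registry, score_frac, tie_margin, curate)
        for g in sorted(by_genome)
    ]


# ---------------------------------------------------------------------------
# tabular output

def profiles_to_frame(
    profiles: Iterable[GenomePathwayProfile], registry: PathwayRegistry
) -> pd.DataFrame:
    rows = []
    for p in profiles:
        rows.append(
            {
                "genome": p.genome_id,
                "complete_pathways": ";".join(
                    sorted(p.complete_pathways, key=registry.pathway_ids.index)
                ),
                "assigned_pathways": ";".join(
                    sorted(p.assigned_pathways, key=registry.pathway_ids.index)
                ),
                "butyrate": any(
                    registry.product_of(x) == "butyrate" for x in p.assigned_pathways
                ),
                "propionate": any(
                    registry.product_of(x) == "propionate" for x in p.assigned_pathways
                ),
                "mean_score_ratios": ";".join(
                    f"{pid}={p.mean_score_ratios[pid]:.6f}"
                    for pid in registry.pathway_ids
                    if pid in p.mean_score_ratios
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "genome",
            "complete_pathways",
            "assigned_pathways",
            "butyrate",
            "propionate",
            "mean_score_ratios",
        ],
    )


def write_profiles_tsv(
    profiles: Iterable[GenomePathwayProfile],
    registry: PathwayRegistry,
    path: str | Path,
) -> None:
    profiles_to_frame(profiles, registry).to_csv(path, sep="\t", index=False)


def read_profiles_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", dtype={"complete_pathways": str, "assigned_pathways": str}
    )
    for col in ("complete_pathways", "assigned_pathways"):
        df[col] = df[col].fillna("")
    return df
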