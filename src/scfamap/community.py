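"""Community-level analysis: phenotype validation and abundance weighting.

Genome-level pathway calls are lifted to the species level (a species is
a predicted producer of a product if any of its genomes carries an
assigned pathway for it), compared against literature-reported
fermentation phenotypes as a confusion matrix, and aggregated by family
or phylum with species relative abundances as weights — so dominant taxa
carry the weight they actually have in the community.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .classify import GenomePathwayProfile
from .schema import PathwayRegistry, PRODUCTS

__all__ = [
    "ProductValidation",
    "ValidationSummary",
    "species_predictions",
    "validate",
    "aggregate_by_taxon",
    "producer_abundance_share",
]

logger = logging.getLogger(__name__)

PHENOTYPE_VALUES = ("yes", "no", "unknown")


@dataclass(frozen=True)
class ProductValidation:
    """Confusion-matrix counts for one product, plus abundance weighting."""

    tp: int
    fp: int
    tn: int
    fn: int
    unknown: int
    #: % of evaluated (literature-characterized) abundance that is concordant
    weighted_concordant_pct: float | None = None
    weighted_discordant_pct: float | None = None

    @property
    def n_evaluated(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def tp_rate_among_predicted(self) -> float | None:
        """Fraction of predicted producers confirmed by the literature."""
        pred = self.tp + self.fp
        return self.tp / pred if pred else None

    @property
    def tn_rate_among_unpredicted(self) -> float | None:
        """Fraction of predicted non-producers confirmed by the literature."""
        unpred = self.tn + self.fn
        return self.tn / unpred if unpred else None

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "unknown": self.unknown,
            "tp_rate_among_predicted": self.tp_rate_among_predicted,
            "tn_rate_among_unpredicted": self.tn_rate_among_unpredicted,
            "weighted_concordant_pct": self.weighted_concordant_pct,
            "weighted_discordant_pct": self.weighted_discordant_pct,
        }


@dataclass(frozen=True)
class ValidationSummary:
    """Per-product validation plus an 'any producer' roll-up."""

    n_species: int
    n_excluded_multi_pathway: int
    per_product: Mapping[str, ProductValidation]

    def to_dict(self) -> dict:
        return {
            "n_species": self.n_species,
            "n_excluded_multi_pathway": self.n_excluded_multi_pathway,
            "per_product": {k: v.to_dict() for k, v in self.per_product.items()},
        }


def species_predictions(
    profiles: Iterable[GenomePathwayProfile] | pd.DataFrame,
    registry: PathwayRegistry,
    species_of: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Species-level producer predictions from genome profiles.

    Accepts profile objects or the profile TSV as a DataFrame. A species is
    predicted positive for a product if *any* of its genomes carries an
    assigned pathway of that product (disagreements between genomes of one
    species are logged). ``multi_pathway`` flags species where a genome
    kept ≥2 assigned pathways of the same product after resolution.
    """
    rows = []
    if isinstance(profiles, pd.DataFrame):
        for r in profiles.itertuples(index=False):
            assigned = [p for p in str(r.assigned_pathways).split(";") if p]
            rows.append((str(r.genome), assigned))
    else:
        for p in profiles:
            rows.append((p.genome_id, sorted(p.assigned_pathways)))

    recs: dict[str, dict] = {}
    per_genome: dict[str, list[dict]] = {}
    for genome, assigned in rows:
        species = species_of.get(genome, genome) if species_of else genome
        by_product = {
            prod: [a for a in assigned if registry.product_of(a) == prod]
            for prod in PRODUCTS
        }
        flags = {
            "butyrate": bool(by_product["butyrate"]),
            "propionate": bool(by_product["propionate"]),
            "multi_pathway": any(len(v) >= 2 for v in by_product.values()),
        }
        per_genome.setdefault(species, []).append(flags)
        rec = recs.setdefault(
            species,
            {"species": species, "butyrate": False, "propionate": False, "multi_pathway": False},
        )
        for k in ("butyrate", "propionate", "multi_pathway"):
            rec[k] = rec[k] or flags[k]

    for species, genome_flags in per_genome.items():
        for prod in PRODUCTS:
            vals = {f[prod] for f in genome_flags}
            if len(vals) > 1:
                logger.warning(
                    "species %s: genomes disagree on %s prediction; "
                    "species counted as predicted positive",
                    species, prod,
                )
    return pd.DataFrame(
        sorted(recs.values(), key=lambda r: r["species"]),
        columns=["species", "butyrate", "propionate", "multi_pathway"],
    )


def _phenotype_value(v: object) -> str:
    s = str(v).strip().lower()
    if s in ("yes", "true", "1"):
        return "yes"
    if s in ("no", "false", "0"):
        return "no"
    return "unknown"


def validate(
    predictions: pd.DataFrame,
    phenotypes: pd.DataFrame,
    abundances: pd.DataFrame | None = None,
    exclude_multi_pathway: bool = True,
) -> ValidationSummary:
    """Compare species-level predictions with reported phenotypes.

    ``predictions``: output of :func:`species_predictions`.
    ``phenotypes``: columns species, butyrate, propionate (yes/no/unknown).
    ``abundances``: optional columns species, abundance — when given, each
    category is also reported as the share of evaluated relative abundance.

    Unknown phenotypes never enter the rates. Species flagged
    ``multi_pathway`` (ambiguous after resolution) are excluded by default.
    Raises ``ValueError`` when no species is evaluable.
    """
    pred = predictions.copy()
    n_multi = int(pred["multi_pathway"].sum()) if "multi_pathway" in pred else 0
    if exclude_multi_pathway and "multi_pathway" in pred:
        pred = pred[~pred["multi_pathway"]]

    pheno = phenotypes.set_index("species")
    abund: Mapping[str, float] = {}
    if abundances is not None:
        abund = dict(zip(abundances["species"].astype(str), abundances["abundance"]))

    per_product: dict[str, ProductValidation] = {}
    any_counts = {"tp": 0, "fp": 0, "tn": 0, "fn": 0, "unknown": 0}
    any_w = {"conc": 0.0, "disc": 0.0}
    total_evaluable = 0

    merged = pred[pred["species"].isin(pheno.index)]
    for product in PRODUCTS:
        c = {"tp": 0, "fp": 0, "tn": 0, "fn": 0, "unknown": 0}
        w = {"conc": 0.0, "disc": 0.0}
        for r in merged.itertuples(index=False):
            reported = _phenotype_value(pheno.loc[r.species, product])
            predicted = bool(getattr(r, product))
            if reported == "unknown":
                c["unknown"] += 1
                continue
            a = float(abund.get(r.species, 0.0))
            is_producer = reported == "yes"
            if predicted and is_producer:
                c["tp"] += 1
                w["conc"] += a
            elif predicted and not is_producer:
                c["fp"] += 1
                w["disc"] += a
            elif not predicted and not is_producer:
                c["tn"] += 1
                w["conc"] += a
            else:
                c["fn"] += 1
                w["disc"] += a
        total_evaluable += c["tp"] + c["fp"] + c["tn"] + c["fn"]
        per_product[product] = _finish_product(c, w, abundances is not None)

    # 'any producer' roll-up: predicted/reported producer of either product;
    # unknown only when both phenotype fields are unknown
    c = {"tp": 0, "fp": 0, "tn": 0, "fn": 0, "unknown": 0}
    w = {"conc": 0.0, "disc": 0.0}
    for r in merged.itertuples(index=False):
        reported_vals = {
            _phenotype_value(pheno.loc[r.species, prod]) for prod in PRODUCTS
        }
        if reported_vals == {"unknown"}:
            c["unknown"] += 1
            continue
        is_producer = "yes" in reported_vals
        predicted = bool(r.butyrate or r.propionate)
        a = float(abund.get(r.species, 0.0))
        key = (
            "tp" if predicted and is_producer
            else "fp" if predicted
            else "fn" if is_producer
            else "tn"
        )
        c[key] += 1
        w["conc" if key in ("tp", "tn") else "disc"] += a
    total_evaluable += c["tp"] + c["fp"] + c["tn"] + c["fn"]
    per_product["any"] = _finish_product(c, w, abundances is not None)

    if total_evaluable == 0:
        raise ValueError(
            "no evaluable species: every phenotype is unknown or no species ids join"
        )
    return ValidationSummary(
        n_species=len(pred),
        n_excluded_multi_pathway=n_multi,
        per_product=per_product,
    )


def _finish_product(c: dict, w: dict, weighted: bool) -> ProductValidation:
    tot = w["conc"] + w["disc"]
    return ProductValidation(
        tp=c["tp"], fp=c["fp"], tn=c["tn"], fn=c["fn"], unknown=c["unknown"],
        weighted_concordant_pct=(100.0 * w["conc"] / tot if weighted and tot > 0 else None),
        weighted_discordant_pct=(100.0 * w["disc"] / tot if weighted and tot > 0 else None),
    )


def aggregate_by_taxon(
    predictions: pd.DataFrame,
    abundances: pd.DataFrame,
    rank: str = "family",
) -> pd.DataFrame:
    """Aggregate producer predictions by family or phylum.

    ``abundances`` needs columns species, family, phylum, abundance. Returns
    per taxon: n_species, fraction of species predicted to produce each
    product, summed relative abundance, and producer-weighted abundance
    (summed abundance of members with the relevant prediction). Species with
    missing taxonomy are dropped with a warning reporting how many.
    """
    if rank not in ("family", "phylum"):
        raise ValueError(f"rank must be 'family' or 'phylum', got {rank!r}")
    df = predictions.merge(abundances, on="species", how="inner")
    missing = df[rank].isna() | (df[rank].astype(str) == "")
    if missing.any():
        warnings.warn(f"{int(missing.sum())} species lack {rank} taxonomy; excluded")
        df = df[~missing]
    grouped = df.groupby(rank, sort=True)
    out = grouped.agg(
        n_species=("species", "size"),
        frac_butyrate=("butyrate", "mean"),
        frac_propionate=("propionate", "mean"),
        abundance=("abundance", "sum"),
    )
    out["butyrate_abundance"] = grouped.apply(
        lambda g: g.loc[g["butyrate"], "abundance"].sum(), include_groups=False
    )
    out["propionate_abundance"] = grouped.apply(
        lambda g: g.loc[g["propionate"], "abundance"].sum(), include_groups=False
    )
    return out.reset_index()


def producer_abundance_share(
    predictions: pd.DataFrame,
    abundances: pd.DataFrame,
) -> dict[str, float]:
    """Partition classified community abundance (%) by predicted producer type.

    Returns butyrate-only, propionate-only, both and neither shares, each as
    percent of total community abundance; the four values sum to the total
    classified abundance.
    """
    zero = {"butyrate_only": 0.0, "propionate_only": 0.0, "both": 0.0, "neither": 0.0}
    if predictions.empty or abundances.empty:
        warnings.warn("no species to partition; all shares are 0")
        return zero
    df = predictions.merge(abundances, on="species", how="inner")
    if df.empty:
        warnings.warn("no species to partition; all shares are 0")
        return zero
    b = df["butyrate"].astype(bool)
    p = df["propionate"].astype(bool)
    a = df["abundance"].astype(float)
    return {
        "butyrate_only": float(a[b & ~p].sum()) * 100.0,
        "propionate_only": float(a[~b & p].sum()) * 100.0,
        "both": float(a[b & p].sum()) * 100.0,
        "neither": float(a[~b & ~p].sum()) * 100.0,
    }
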