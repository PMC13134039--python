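"""Pathway registry: definitions, shared genes, curation rules, reference scores.

The registry is the single source of truth for what a pathway *is*: which
genes are required for a presence call, which genes are shared between
pathways (and therefore need read-count apportionment), which free-text
annotation keywords separate specific from non-specific homologs, and the
reference bit scores of experimentally characterized producer strains that
anchor the hit-score cutoff.

Eight routes are modelled, named by their primary entry metabolite:
butyrate via glutarate (Glu), acetyl-CoA (Ace), lysine (Lys) and
4-aminobutyrate/succinate (4-Ami); propionate via propanediol (Pro),
acrylate (Acr) and the two succinate routes, the Wood-Werkman cycle (WWC)
and the sodium-pumping pathway (SP).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

__all__ = [
    "ConfigError",
    "PathwayDefinition",
    "CurationRule",
    "PathwayRegistry",
    "load_registry",
    "default_registry_path",
    "apply_curation",
    "CANONICAL_PRODUCTS",
    "BUTYRATE_PATHWAYS",
    "PROPIONATE_PATHWAYS",
    "PRODUCTS",
]

#: Product of each canonical pathway id. A config that maps a canonical id to
#: the other product is rejected.
CANONICAL_PRODUCTS: dict[str, str] = {
    "Glu": "butyrate",
    "Ace": "butyrate",
    "Lys": "butyrate",
    "4-Ami": "butyrate",
    "Pro": "propionate",
    "Acr": "propionate",
    "WWC": "propionate",
    "SP": "propionate",
}

BUTYRATE_PATHWAYS = tuple(p for p, prod in CANONICAL_PRODUCTS.items() if prod == "butyrate")
PROPIONATE_PATHWAYS = tuple(p for p, prod in CANONICAL_PRODUCTS.items() if prod == "propionate")
PRODUCTS = ("butyrate", "propionate")


class ConfigError(ValueError):
    """Raised when a registry config is missing, contradictory or malformed."""


@dataclass(frozen=True)
class PathwayDefinition:
    """One biosynthesis route and the gene roster required to call it present."""

    pathway_id: str
    product: str
    required_genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.product not in PRODUCTS:
            raise ConfigError(
                f"pathway {self.pathway_id!r}: unknown product {self.product!r}"
            )
        if len(self.required_genes) < 1:
            raise ConfigError(f"pathway {self.pathway_id!r}: empty gene roster")
        if len(set(self.required_genes)) != len(self.required_genes):
            raise ConfigError(f"pathway {self.pathway_id!r}: duplicate gene in roster")

    @property
    def l_pathway(self) -> int:
        """Number of required genes; the pathway-length normalizer."""
        return len(self.required_genes)


@dataclass(frozen=True)
class CurationRule:
    """Keyword filter applied to free-text gene descriptions.

    A hit is kept iff its description matches at least one include keyword
    (when any are given) and no exclude keyword. Matching is case-insensitive
    substring matching.
    """

    gene: str
    include: tuple[str, ...] = ()
    exclude: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.include and not self.exclude:
            raise ConfigError(f"curation rule for {self.gene!r} has no keywords")

    def keep(self, description: str) -> bool:
        text = description.lower()
        if self.include and not any(k.lower() in text for k in self.include):
            return False
        return not any(k.lower() in text for k in self.exclude)


class PathwayRegistry:
    """Validated collection of pathway definitions and associated metadata.

    Parameters
    ----------
    pathways
        Pathway definitions in registry order. Order matters: deterministic
        tie-breaks during single-pathway resolution follow it.
    excluded_genes
        Genes banned from every roster (unreliable database annotations).
    curation_rules
        Keyword rules keyed implicitly by their gene.
    model_scores
        ``gene -> [(strain, bit score), ...]`` reference scores from
        characterized producer strains.
    shared_genes
        Optional explicit ``gene -> [pathway ids]`` map; validated against
        the map derived from the rosters.
    """

    def __init__(
        self,
        pathways: Sequence[PathwayDefinition],
        excluded_genes: Iterable[str] = (),
        curation_rules: Iterable[CurationRule] = (),
        model_scores: Mapping[str, Sequence[tuple[str, float]]] | None = None,
        shared_genes: Mapping[str, Iterable[str]] | None = None,
        require_all_pathways: bool = True,
    ) -> None:
        self._pathways: dict[str, PathwayDefinition] = {}
        for pw in pathways:
            if pw.pathway_id in self._pathways:
                raise ConfigError(f"duplicate pathway id {pw.pathway_id!r}")
            canonical = CANONICAL_PRODUCTS.get(pw.pathway_id)
            if canonical is not None and canonical != pw.product:
                raise ConfigError(
                    f"pathway {pw.pathway_id!r} declared as {pw.product!r}, "
                    f"expected {canonical!r}"
                )
            self._pathways[pw.pathway_id] = pw
        if require_all_pathways:
            missing = [p for p in CANONICAL_PRODUCTS if p not in self._pathways]
            if missing:
                raise ConfigError(f"missing pathway definition(s): {', '.join(missing)}")

        self.excluded_genes: tuple[str, ...] = tuple(excluded_genes)
        for pw in self._pathways.values():
            bad = set(pw.required_genes) & set(self.excluded_genes)
            if bad:
                raise ConfigError(
                    f"gene(s) {', '.join(sorted(bad))} listed as required for "
                    f"{pw.pathway_id!r} and also excluded"
                )

        self.curation_rules: dict[str, CurationRule] = {}
        for rule in curation_rules:
            if rule.gene in self.curation_rules:
                raise ConfigError(f"duplicate curation rule for {rule.gene!r}")
            self.curation_rules[rule.gene] = rule

        self.model_scores: dict[str, tuple[tuple[str, float], ...]] = {}
        for gene, entries in (model_scores or {}).items():
            scores = tuple((str(s), float(v)) for s, v in entries)
            if any(v < 0 for _, v in scores):
                raise ConfigError(f"negative model-strain score for gene {gene!r}")
            self.model_scores[gene] = scores

        if shared_genes is not None:
            derived = self.shared_gene_map
            declared = {g: frozenset(ps) for g, ps in shared_genes.items()}
            for gene, pids in declared.items():
                unknown = pids - set(self._pathways)
                if unknown:
                    raise ConfigError(
                        f"shared gene {gene!r} references unknown pathway(s) "
                        f"{', '.join(sorted(unknown))}"
                    )
                if gene not in derived:
                    raise ConfigError(
                        f"gene {gene!r} declared shared but occurs in at most one roster"
                    )
                if derived[gene] != pids:
                    raise ConfigError(
                        f"shared-gene map for {gene!r} disagrees with rosters: "
                        f"declared {sorted(pids)}, derived {sorted(derived[gene])}"
                    )
            if set(declared) != set(derived):
                missing = sorted(set(derived) - set(declared))
                raise ConfigError(
                    f"shared_genes map omits roster-shared gene(s): {', '.join(missing)}"
                )

    # -- lookups ---------------------------------------------------------

    @property
    def pathway_ids(self) -> tuple[str, ...]:
        return tuple(self._pathways)

    @property
    def pathways(self) -> tuple[PathwayDefinition, ...]:
        return tuple(self._pathways.values())

    def __getitem__(self, pathway_id: str) -> PathwayDefinition:
        return self._pathways[pathway_id]

    def __contains__(self, pathway_id: str) -> bool:
        return pathway_id in self._pathways

    def __len__(self) -> int:
        return len(self._pathways)

    def product_of(self, pathway_id: str) -> str:
        return self._pathways[pathway_id].product

    def pathways_of_product(self, product: str) -> tuple[str, ...]:
        return tuple(p for p in self._pathways if self._pathways[p].product == product)

    @property
    def all_genes(self) -> frozenset[str]:
        return frozenset(g for pw in self._pathways.values() for g in pw.required_genes)

    def pathways_for_gene(self, gene: str) -> frozenset[str]:
        return frozenset(
            p for p, pw in self._pathways.items() if gene in pw.required_genes
        )

    @property
    def shared_gene_map(self) -> dict[str, frozenset[str]]:
        """Genes in ≥2 rosters, mapped to the pathways containing them."""
        out: dict[str, frozenset[str]] = {}
        for gene in self.all_genes:
            pids = self.pathways_for_gene(gene)
            if len(pids) >= 2:
                out[gene] = pids
        return out

    @property
    def single_pathway_genes(self) -> frozenset[str]:
        return frozenset(g for g in self.all_genes if len(self.pathways_for_gene(g)) == 1)

    # -- model-strain scores --------------------------------------------

    def gene_model_scores(self, gene: str) -> tuple[float, ...]:
        entries = self.model_scores.get(gene, ())
        return tuple(v for _, v in entries)

    def min_model_score(self, gene: str) -> float:
        scores = self.gene_model_scores(gene)
        if not scores:
            raise ConfigError(f"no model-strain scores for gene {gene!r}")
        return min(scores)

    def mean_model_score(self, gene: str) -> float:
        scores = self.gene_model_scores(gene)
        if not scores:
            raise ConfigError(f"no model-strain scores for gene {gene!r}")
        return sum(scores) / len(scores)

    def validate_model_scores(self) -> None:
        """Ensure every required gene has ≥1 reference score (needed before
        any classification run)."""
        missing = sorted(g for g in self.all_genes if not self.model_scores.get(g))
        if missing:
            raise ConfigError(
                f"model-strain scores missing for gene(s): {', '.join(missing)}"
            )

    # -- (de)serialization ----------------------------------------------

    def to_dict(self) -> dict:
        return {
            "pathways": [
                {"id": pw.pathway_id, "product": pw.product, "genes": list(pw.required_genes)}
                for pw in self._pathways.values()
            ],
            "shared_genes": {g: sorted(ps) for g, ps in sorted(self.shared_gene_map.items())},
            "excluded_genes": list(self.excluded_genes),
            "curation_rules": [
                {"gene": r.gene, "include": list(r.include), "exclude": list(r.exclude)}
                for r in self.curation_rules.values()
            ],
            "model_strain_scores": {
                g: [{"strain": s, "score": v} for s, v in entries]
                for g, entries in self.model_scores.items()
            },
        }

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PathwayRegistry):
            return NotImplemented
        return self.to_dict() == other.to_dict()


def default_registry_path() -> Path:
    """Path of the registry config shipped with the package."""
    return Path(importlib.resources.files("scfamap").joinpath("data/pathways.yaml"))


def load_registry(
    config_path: str | Path | None = None, require_all_pathways: bool = True
) -> PathwayRegistry:
    """Load and validate a pathway registry from a YAML/JSON config file.

    With no argument, loads the config shipped with the package. Raises
    :class:`ConfigError` naming the offending entry on any inconsistency
    (missing pathway, duplicate id, gene both required and excluded,
    shared-gene map disagreeing with the rosters, ...).
    """
    path = Path(config_path) if config_path is not None else default_registry_path()
    if not path.exists():
        raise ConfigError(f"registry config not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:  # pragma: no cover - passthrough message
        raise ConfigError(f"cannot parse registry config {path}: {exc}") from exc
    if not isinstance(raw, dict) or "pathways" not in raw:
        raise ConfigError(f"registry config {path} lacks a 'pathways' section")

    pathways = [
        PathwayDefinition(
            pathway_id=str(p["id"]),
            product=str(p["product"]),
            required_genes=tuple(str(g) for g in p["genes"]),
        )
        for p in raw["pathways"]
    ]
    rules = [
        CurationRule(
            gene=str(r["gene"]),
            include=tuple(str(k) for k in r.get("include", ()) or ()),
            exclude=tuple(str(k) for k in r.get("exclude", ()) or ()),
        )
        for r in raw.get("curation_rules", ()) or ()
    ]
    model_scores = {
        str(gene): [(str(e["strain"]), float(e["score"])) for e in entries]
        for gene, entries in (raw.get("model_strain_scores") or {}).items()
    }
    return PathwayRegistry(
        pathways,
        excluded_genes=[str(g) for g in raw.get("excluded_genes", ()) or ()],
        curation_rules=rules,
        model_scores=model_scores,
        shared_genes=raw.get("shared_genes"),
        require_all_pathways=require_all_pathways,
    )


def apply_curation(
    annotation_text: str,
    gene: str,
    rules: Mapping[str, CurationRule] | Iterable[CurationRule],
) -> bool:
    """Keep/drop decision for one annotation description.

    Genes without a rule always pass; otherwise the rule's include/exclude
    keywords decide (case-insensitive substring matching).
    """
    if not isinstance(rules, Mapping):
        rules = {r.gene: r for r in rules}
    rule = rules.get(gene)
    if rule is None:
        return True
    return rule.keep(annotation_text)
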