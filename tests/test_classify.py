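"""Hit filtering, complete-gene-set calling and single-pathway resolution."""

import numpy as np
import pytest

from scfamap.classify import (
    GeneHit,
    GenomePathwayProfile,
    call_complete_pathways,
    classify_genomes,
    filter_hits,
    parse_hmmer_tblout,
    pathway_score_ratios,
    read_hits_tsv,
    resolve_single_pathway,
)
from scfamap.schema import ConfigError


def _hit(gene, score, genome="G1", **kw):
    return GeneHit(genome_id=genome, gene=gene, subject_id=f"{genome}|{gene}",
                   score=score, **kw)


class TestFilterHits:
    MODEL = {"but": [200.0, 150.0, 180.0]}

    def test_retained_at_half_of_lowest_model_score(self):
        # lowest model score 150 -> cutoff 75
        kept = filter_hits([_hit("but", 80.0)], self.MODEL)
        assert len(kept) == 1

    def test_boundary_score_exactly_at_cutoff_is_retained(self):
        assert len(filter_hits([_hit("but", 75.0)], self.MODEL)) == 1

    def test_below_cutoff_dropped(self):
        assert filter_hits([_hit("but", 74.9)], self.MODEL) == []

    def test_empty_input_is_identity(self):
        assert filter_hits([], self.MODEL) == []

    def test_gene_without_model_scores_raises_naming_gene(self):
        with pytest.raises(ConfigError, match="mysteryGene"):
            filter_hits([_hit("mysteryGene", 100.0)], self.MODEL)

    def test_matches_bruteforce_and_is_idempotent_order_independent(self, rng, registry):
        genes = sorted(registry.all_genes)
        hits = [
            _hit(genes[rng.integers(0, len(genes))],
                 float(rng.uniform(0, 900)), genome=f"G{rng.integers(1, 6)}")
            for _ in range(300)
        ]
        kept = filter_hits(hits, registry)
        # independent per-hit threshold check
        expected = [
            h for h in hits
            if h.score >= 0.5 * min(registry.gene_model_scores(h.gene))
        ]
        assert kept == expected
        assert filter_hits(kept, registry) == kept  # idempotent
        shuffled = list(hits)
        rng.shuffle(shuffled)
        assert sorted(filter_hits(shuffled, registry), key=lambda h: h.score) == sorted(
            kept, key=lambda h: h.score
        )

    def test_negative_or_nonfinite_scores_rejected_at_construction(self):
        with pytest.raises(ValueError):
            _hit("but", -1.0)
        with pytest.raises(ValueError):
            _hit("but", float("nan"))


class TestCompletePathways:
    def test_missing_one_gene_means_absent(self, registry):
        genes = registry["Ace"].required_genes[:-1]
        hits = [_hit(g, 500.0) for g in genes]
        assert "Ace" not in call_complete_pathways(hits, registry)

    def test_independent_calls_per_pathway(self, registry):
        genes = set(registry["SP"].required_genes) | set(registry["Ace"].required_genes)
        hits = [_hit(g, 500.0) for g in genes]
        assert call_complete_pathways(hits, registry) == {"SP", "Ace"}

    def test_matches_bruteforce_set_cover_on_random_genomes(self, rng, registry):
        genes = sorted(registry.all_genes)
        for _ in range(100):
            present = {g for g in genes if rng.random() < 0.35}
            hits = [_hit(g, 500.0) for g in present]
            called = call_complete_pathways(hits, registry)
            oracle = {
                pw.pathway_id
                for pw in registry.pathways
                if all(g in present for g in pw.required_genes)
            }
            assert called == oracle

    def test_monotone_adding_hits_never_removes_pathways(self, rng, registry):
        genes = sorted(registry.all_genes)
        present = [g for g in genes if rng.random() < 0.5]
        rng.shuffle(present)
        called_so_far = set()
        for i in range(len(present) + 1):
            hits = [_hit(g, 500.0) for g in present[:i]]
            called = call_complete_pathways(hits, registry)
            assert called >= called_so_far
            called_so_far = called

    def test_mixed_genomes_rejected(self, registry):
        hits = [_hit("thl", 500.0, genome="G1"), _hit("hbd", 500.0, genome="G2")]
        with pytest.raises(ValueError, match="multiple genomes"):
            call_complete_pathways(hits, registry)


def _profile(ratios, registry):
    return GenomePathwayProfile(
        genome_id="G1",
        complete_pathways=frozenset(ratios),
        assigned_pathways=frozenset(ratios),
        mean_score_ratios=dict(ratios),
    )


class TestResolution:
    def test_clear_winner_assigned(self, registry):
        p = resolve_single_pathway(
            _profile({"SP": 0.95, "Pro": 0.60}, registry), registry, tie_margin=0.1
        )
        assert p.assigned_pathways == {"SP"}

    def test_within_margin_retains_both(self, registry):
        p = resolve_single_pathway(
            _profile({"SP": 0.95, "Pro": 0.90}, registry), registry, tie_margin=0.1
        )
        assert p.assigned_pathways == {"SP", "Pro"}

    def test_single_complete_pathway_is_identity(self, registry):
        before = _profile({"Ace": 0.8}, registry)
        after = resolve_single_pathway(before, registry, tie_margin=0.0)
        assert after.assigned_pathways == before.complete_pathways

    def test_infinite_margin_returns_all_complete(self, registry):
        ratios = {"Glu": 0.5, "Ace": 0.9, "SP": 0.7, "WWC": 0.6}
        p = resolve_single_pathway(_profile(ratios, registry), registry,
                                   tie_margin=float("inf"))
        assert p.assigned_pathways == set(ratios)

    def test_zero_margin_returns_exactly_one_per_product(self, registry):
        ratios = {"Glu": 0.5, "Ace": 0.9, "Lys": 0.9, "SP": 0.7, "WWC": 0.7}
        p = resolve_single_pathway(_profile(ratios, registry), registry, tie_margin=0.0)
        butyrate = {x for x in p.assigned_pathways if registry.product_of(x) == "butyrate"}
        propionate = p.assigned_pathways - butyrate
        assert len(butyrate) == 1 and len(propionate) == 1
        # exact ties break by registry order: Ace before Lys, WWC before SP
        assert butyrate == {"Ace"} and propionate == {"WWC"}

    def test_products_resolved_independently(self, registry):
        p = resolve_single_pathway(
            _profile({"Ace": 0.9, "SP": 0.8}, registry), registry, tie_margin=0.0
        )
        assert p.assigned_pathways == {"Ace", "SP"}

    def test_assignment_stays_within_complete_pathways(self, rng, registry):
        pids = list(registry.pathway_ids)
        for _ in range(50):
            chosen = [p for p in pids if rng.random() < 0.5]
            if not chosen:
                continue
            ratios = {p: float(rng.uniform(0.3, 1.2)) for p in chosen}
            out = resolve_single_pathway(
                _profile(ratios, registry), registry, tie_margin=float(rng.uniform(0, 0.3))
            )
            assert out.assigned_pathways <= frozenset(chosen)
            for product in ("butyrate", "propionate"):
                had = [p for p in chosen if registry.product_of(p) == product]
                got = [p for p in out.assigned_pathways
                       if registry.product_of(p) == product]
                assert bool(had) == bool(got)


class TestScoreRatios:
    def test_mean_ratio_uses_best_hit_per_gene(self, registry):
        genes = registry["Acr"].required_genes
        hits = []
        for g in genes:
            hits.append(_hit(g, registry.mean_model_score(g) * 0.5))
            hits.append(_hit(g, registry.mean_model_score(g) * 0.9))  # best
        ratios = pathway_score_ratios(hits, registry, ["Acr"])
        assert ratios["Acr"] == pytest.approx(0.9)

    def test_incomplete_pathway_rejected(self, registry):
        hits = [_hit("pct", 500.0)]
        with pytest.raises(ValueError, match="lcd"):
            pathway_score_ratios(hits, registry, ["Acr"])


class TestEndToEndClassification:
    def test_curation_removes_nonspecific_high_scorers(self, registry):
        genes = registry["Ace"].required_genes
        hits = [
            GeneHit("G1", g, f"G1|{g}", registry.mean_model_score(g),
                    description="butyryl-CoA dehydrogenase" if g == "bcd"
                    else "3-hydroxybutyryl-CoA dehydrogenase" if g == "hbd"
                    else "butyryl-CoA:acetate CoA-transferase" if g == "but"
                    else f"{g} protein")
            for g in genes
        ]
        profiles = classify_genomes(hits, registry)
        assert profiles[0].assigned_pathways == {"Ace"}
        # same hits but bcd annotated as a non-specific dehydrogenase
        bad = [
            h if h.gene != "bcd" else GeneHit(
                "G1", "bcd", h.subject_id, h.score,
                description="acyl-CoA dehydrogenase, short-chain")
            for h in hits
        ]
        profiles = classify_genomes(bad, registry)
        assert profiles[0].assigned_pathways == frozenset()

    def test_recovers_simulated_truth(self, demo_truth, registry):
        from scfamap.simulate import simulate_hits

        hits = simulate_hits(demo_truth, seed=11)
        profiles = classify_genomes(hits, registry)
        carried = {
            g: frozenset(p for p in ps.split(";") if p)
            for g, ps in zip(demo_truth.truth["genome"], demo_truth.truth["pathways"])
        }
        assert len(profiles) == len(carried)
        for p in profiles:
            assert p.complete_pathways == carried[p.genome_id]
            assert p.assigned_pathways <= p.complete_pathways
            for product in ("butyrate", "propionate"):
                had = any(registry.product_of(x) == product for x in carried[p.genome_id])
                got = any(registry.product_of(x) == product for x in p.assigned_pathways)
                assert had == got


class TestInputFormats:
    def test_hits_tsv_roundtrip(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text(
            "genome\tgene\tsubject\tscore\tlength\tdescription\n"
            "G1\tbcd\tG1|bcd\t321.5\t1140\tbutyryl-CoA dehydrogenase\n"
            "G2\tmmdA\tG2|mmdA\t410.0\t980\t\n"
        )
        hits = read_hits_tsv(path)
        assert [h.genome_id for h in hits] == ["G1", "G2"]
        assert hits[0].score == 321.5 and hits[0].length == 1140
        assert hits[1].description == ""

    def test_hits_tsv_malformed_row_names_line(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text("genome\tgene\tsubject\tscore\nG1\tbcd\tx\tnot_a_number\n")
        with pytest.raises(ValueError, match="hits.tsv:2"):
            read_hits_tsv(path)

    def test_parse_hmmer_tblout(self, tmp_path):
        path = tmp_path / "g1.tbl"
        path.write_text(
            "#                                     --- full sequence ----\n"
            "# target name        accession  query name accession E-value score bias "
            "E1 s1 b1 exp reg clu ov env dom rep inc description of target\n"
            "G1_00042 - bcd - 1.2e-200 652.3 0.1 "
            "1.5e-200 651.9 0.1 1.0 1 0 0 1 1 1 1 butyryl-CoA dehydrogenase\n"
            "G1_00099 - thl - 3.3e-150 498.0 0.0 "
            "4.0e-150 497.5 0.0 1.0 1 0 0 1 1 1 1 thiolase\n"
        )
        hits = parse_hmmer_tblout(path, genome_id="G1")
        assert [(h.gene, h.subject_id) for h in hits] == [
            ("bcd", "G1_00042"), ("thl", "G1_00099")
        ]
        assert hits[0].score == 652.3
        assert hits[0].description == "butyryl-CoA dehydrogenase"
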