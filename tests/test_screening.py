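"""Filter cascade: genotype-configuration rule, novelty filter, cascade
composition and breed distribution."""

import numpy as np
import pytest

from lofscreen.io_formats import KnownSites
from lofscreen.screening import (
    BreedDistribution,
    ScreenResult,
    breed_distribution,
    exclude_known,
    genotype_config_filter,
    intersect_candidate_genes,
    screen,
)
from lofscreen.variants import (
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    GenotypeMatrix,
    VariantSite,
)


def panel_from_patterns(patterns, n_samples=11):
    """patterns: dict site pos -> list of genotype codes."""
    sites = [VariantSite("chr1", pos, "G", "A") for pos in sorted(patterns)]
    samples = [f"S{i}" for i in range(n_samples)]
    calls = np.stack([np.array(patterns[pos], dtype=np.int8) for pos in sorted(patterns)], axis=1)
    return GenotypeMatrix(sites, samples, calls)


class TestGenotypeConfigFilter:
    def test_het_only_pattern_retained(self):
        p = panel_from_patterns({100: [HET, HET] + [HOM_REF] * 9})
        assert 0 in genotype_config_filter(p)

    def test_hom_alt_present_dropped(self):
        p = panel_from_patterns({100: [HET, HOM_ALT] + [HOM_REF] * 9})
        assert genotype_config_filter(p) == {}

    def test_all_wild_type_dropped(self):
        p = panel_from_patterns({100: [HOM_REF] * 11})
        assert genotype_config_filter(p) == {}

    def test_all_het_still_retained(self):
        # the rule bars only the mutant homozygote, not the absence of hom_ref
        p = panel_from_patterns({100: [HET] * 11})
        assert 0 in genotype_config_filter(p)

    def test_missing_calls_carry_no_evidence(self):
        p = panel_from_patterns({100: [HET, MISSING, MISSING] + [HOM_REF] * 8})
        counts = genotype_config_filter(p)[0]
        assert counts == (8, 1, 0, 2)


def test_exclude_known_counting():
    sites = [VariantSite("chr1", p, "G", "A") for p in (1, 2, 3, 4, 5)]
    known = KnownSites({("chr1", 2, "G", "A"), ("chr1", 4, "G", "A")}, set())
    kept = exclude_known(sites, known)
    assert [s.pos for s in kept] == [1, 3, 5]
    assert exclude_known(sites, KnownSites()) == sites


def test_intersect_candidate_genes(toy_gene):
    import dataclasses

    other = dataclasses.replace(toy_gene, transcript_id="toy2", exons=[(30, 60)], cds_start=33, cds_end=50)
    p = panel_from_patterns({15: [HET] + [HOM_REF] * 10,  # toy_gene only
                            31: [HET] + [HOM_REF] * 10,  # overlap of both
                            500: [HET] + [HOM_REF] * 10})  # intergenic
    p = GenotypeMatrix([VariantSite("t", s.pos, s.ref, s.alt) for s in p.sites], p.samples, p.calls)
    hits = intersect_candidate_genes(p, [toy_gene, other])
    assert set(hits) == {0, 1}
    assert len(hits[1]) == 2  # overlapping genes: assigned to both


class TestScreenCascade:
    def test_planted_panel_walkthrough(self, sim_bundle):
        """Of the six planted variants exactly the two novel high-impact
        het-only ones survive, matching the manual case-by-case walk."""
        from lofscreen.io_formats import read_known_sites
        import lofscreen.synthetic_data as sd

        known_rows = sim_bundle.known_rows
        known = KnownSites(
            {(r["chrom"], r["pos"], r["ref"], r["alt"]) for r in known_rows}, set()
        )
        results = screen(sim_bundle.panel, sim_bundle.models, sim_bundle.genome, known)
        got = sorted(r.site.site_id for r in results)
        assert got == sorted(sim_bundle.truth["expected_retained"])
        for r in results:
            assert r.panel_counts[2] == 0 and r.panel_counts[1] >= 1
            assert r.passed_filters == ["candidate_gene", "novel", "genotype_config", "high_impact"]

    def test_empty_panel(self, sim_bundle):
        empty = GenotypeMatrix([], sim_bundle.panel.samples,
                               np.empty((11, 0), dtype=np.int8), sim_bundle.panel.breed_of)
        assert screen(empty, sim_bundle.models, sim_bundle.genome, KnownSites()) == []

    def test_zero_splice_window_drops_splice_variants(self, sim_bundle):
        known = KnownSites(
            {(r["chrom"], r["pos"], r["ref"], r["alt"]) for r in sim_bundle.known_rows}, set()
        )
        full = screen(sim_bundle.panel, sim_bundle.models, sim_bundle.genome, known)
        narrow = screen(sim_bundle.panel, sim_bundle.models, sim_bundle.genome, known,
                        splice_window=0)
        splice_ids = {r.site.site_id for r in full
                      if r.effect.category.startswith("splice")}
        assert splice_ids  # the default plant includes a splice survivor
        assert {r.site.site_id for r in narrow} == {r.site.site_id for r in full} - splice_ids

    def test_filter_order_soundness(self):
        """genotype-config filter before or after the novelty filter retains
        the same site set."""
        patterns = {
            100: [HET, HET] + [HOM_REF] * 9,
            200: [HET, HOM_ALT] + [HOM_REF] * 9,
            300: [HET] + [HOM_REF] * 10,
            400: [HOM_REF] * 11,
        }
        p = panel_from_patterns(patterns)
        known = KnownSites({("chr1", 300, "G", "A")}, set())
        # order A: novelty then genotype config
        novel_idx = [j for j, s in enumerate(p.sites) if not known.contains(s)]
        sub = p.subset_sites(novel_idx)
        a = {sub.sites[j].pos for j in genotype_config_filter(sub)}
        # order B: genotype config then novelty
        cfg = genotype_config_filter(p)
        b = {p.sites[j].pos for j in cfg if not known.contains(p.sites[j])}
        assert a == b == {100}

    def test_monotonicity_adding_hom_alt_removes_site(self):
        base = [HET, HET] + [HOM_REF] * 9
        p1 = panel_from_patterns({100: base})
        assert 0 in genotype_config_filter(p1)
        sites = p1.sites
        calls = np.concatenate([p1.calls, np.array([[HOM_ALT]], dtype=np.int8)])
        p2 = GenotypeMatrix(sites, p1.samples + ["extra"], calls)
        assert genotype_config_filter(p2) == {}


def test_screen_result_invariant_enforced(toy_gene):
    from lofscreen.effect_annotation import EffectCall

    e = EffectCall("g.29G>A", "TOY", "toy_tx", "splice_donor")
    with pytest.raises(ValueError, match="hom_alt"):
        ScreenResult(VariantSite("t", 29, "G", "A"), e, (8, 2, 1, 0))


class TestBreedDistribution:
    def make_cohort(self, breed_carriers):
        """breed_carriers: breed -> (n_carriers, n_total)."""
        samples, breeds, col = [], {}, []
        for breed, (k, n) in breed_carriers.items():
            for i in range(n):
                sid = f"{breed}{i}"
                samples.append(sid)
                breeds[sid] = breed
                col.append(HET if i < k else HOM_REF)
        sites = [VariantSite("chr1", 100, "G", "A", "g.100G>A")]
        return GenotypeMatrix(sites, samples, np.array(col, dtype=np.int8)[:, None], breeds)

    def test_shared_across_nine_breeds(self):
        cohort = self.make_cohort({f"B{i}": (1, 3) for i in range(9)})
        d = breed_distribution("g.100G>A", cohort)
        assert d.n_breeds_with_mutant == 9 and not d.private

    def test_private_single_breed(self):
        cohort = self.make_cohort({"Icelandic": (2, 5), "Hanoverian": (0, 5)})
        d = breed_distribution("g.100G>A", cohort)
        assert d.private and d.n_breeds_with_mutant == 1

    def test_no_carriers(self):
        cohort = self.make_cohort({"A": (0, 5), "B": (0, 5)})
        d = breed_distribution("g.100G>A", cohort)
        assert d.n_breeds_with_mutant == 0 and not d.private

    def test_invariant_enforced(self):
        with pytest.raises(ValueError):
            BreedDistribution("x", 2, True, {})
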