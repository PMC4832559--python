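"""Detection-panel filter cascade for candidate loss-of-function variants.

The screen keeps a variant when (1) it falls inside a candidate-gene
transcript span, (2) it is absent from the known-site databases, (3) its
panel genotypes show the mutant allele only in heterozygotes — the
homozygous mutant genotype is missing — and (4) its predicted consequence is
high impact. Missing genotype calls carry no evidence either way; a site
where every called sample is heterozygous is still retained, since the rule
bars only the mutant homozygote.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .effect_annotation import (
    DEFAULT_SPLICE_WINDOW,
    EffectCall,
    classify_snv,
    is_high_impact,
)
from .io_formats import KnownSites
from .variants import HET, HOM_ALT, GeneModel, GenotypeMatrix, VariantSite


@dataclass
class ScreenResult:
    site: VariantSite
    effect: EffectCall
    panel_counts: tuple[int, int, int, int]  # hom_ref, het, hom_alt, missing
    carriers_by_breed: dict[str, list[str]] = field(default_factory=dict)
    passed_filters: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        n_hom_ref, n_het, n_hom_alt, n_missing = self.panel_counts
        if n_hom_alt != 0:
            raise ValueError(f"retained variant {self.site.site_id} has hom_alt calls")
        if n_het < 1:
            raise ValueError(f"retained variant {self.site.site_id} has no carriers")


@dataclass
class BreedDistribution:
    site_id: str
    n_breeds_with_mutant: int
    private: bool
    carriers_per_breed: dict[str, int]

    def __post_init__(self) -> None:
        if self.private != (self.n_breeds_with_mutant == 1):
            raise ValueError("private flag inconsistent with breed count")


def intersect_candidate_genes(
    variants: GenotypeMatrix, models: list[GeneModel]
) -> dict[int, list[GeneModel]]:
    """Map site column index -> candidate transcripts whose span contains it.

    A site inside overlapping genes is assigned to each; sites outside every
    span are dropped.
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for m in models:
        by_chrom.setdefault(m.chrom, []).append(m)
    out: dict[int, list[GeneModel]] = {}
    for j, site in enumerate(variants.sites):
        hits = [m for m in by_chrom.get(site.chrom, ()) if m.contains(site.pos)]
        if hits:
            out[j] = hits
    return out


def exclude_known(
    sites: list[VariantSite], known: KnownSites, allele_aware: bool = True
) -> list[VariantSite]:
    """Novelty filter: drop sites with database hits."""
    return [s for s in sites if not known.contains(s, allele_aware=allele_aware)]


def genotype_config_filter(panel: GenotypeMatrix) -> dict[int, tuple[int, int, int, int]]:
    """Missing-homozygous-mutant filter.

    Retain site j iff no sample is hom_alt and at least one is het; returns
    retained column index -> panel genotype counts.
    """
    out = {}
    for j in range(panel.n_sites):
        counts = panel.genotype_counts(j)
        if counts[2] == 0 and counts[1] >= 1:
            out[j] = counts
    return out


def screen(
    panel: GenotypeMatrix,
    models: list[GeneModel],
    genome,
    known: KnownSites,
    splice_window: int = DEFAULT_SPLICE_WINDOW,
    allele_aware: bool = True,
    audit: dict | None = None,
) -> list[ScreenResult]:
    """Full filter cascade; returns one result per retained (site, gene) pair,
    sorted by chromosome and position.

    ``audit``, if supplied, is filled with per-stage counts.
    """
    gene_hits = intersect_candidate_genes(panel, models)
    novel = {
        j
        for j in gene_hits
        if not known.contains(panel.sites[j], allele_aware=allele_aware)
    }
    config = genotype_config_filter(panel)
    results: list[ScreenResult] = []
    n_high = 0
    for j in sorted(gene_hits):
        if j not in novel or j not in config:
            continue
        site = panel.sites[j]
        for model in gene_hits[j]:
            effect = classify_snv(site, model, genome, splice_window=splice_window)
            if not is_high_impact(effect):
                continue
            n_high += 1
            carriers: dict[str, list[str]] = {}
            for i, sample in enumerate(panel.samples):
                if panel.calls[i, j] in (HET, HOM_ALT):
                    carriers.setdefault(panel.breed_of[sample], []).append(sample)
            results.append(
                ScreenResult(
                    site=site,
                    effect=effect,
                    panel_counts=config[j],
                    carriers_by_breed=carriers,
                    passed_filters=[
                        "candidate_gene",
                        "novel",
                        "genotype_config",
                        "high_impact",
                    ],
                )
            )
    results.sort(key=lambda r: (r.site.chrom, r.site.pos))
    if audit is not None:
        audit.update(
            {
                "panel_sites": panel.n_sites,
                "in_candidate_genes": len(gene_hits),
                "novel": len(novel),
                "genotype_config_pass": len(set(gene_hits) & novel & set(config)),
                "high_impact": n_high,
                "retained": len(results),
            }
        )
    return results


def breed_distribution(site_id: str, cohort: GenotypeMatrix) -> BreedDistribution:
    """Count breeds carrying the mutant allele (het or hom) at one site."""
    j = cohort.site_index(site_id)
    per_breed: dict[str, int] = {}
    for i, sample in enumerate(cohort.samples):
        if cohort.calls[i, j] in (HET, HOM_ALT):
            breed = cohort.breed_of[sample]
            per_breed[breed] = per_breed.get(breed, 0) + 1
    n_breeds = len(per_breed)
    return BreedDistribution(
        site_id=site_id,
        n_breeds_with_mutant=n_breeds,
        private=n_breeds == 1,
        carriers_per_breed=per_breed,
    )


def write_screen_report(results: list[ScreenResult], path: str | Path) -> None:
    """TSV of retained variants with effect and panel genotype pattern."""
    lines = ["site_id\tchrom\tpos\tgene\tcategory\tprotein_change\tn_hom_ref\tn_het\tn_hom_alt\tn_missing"]
    seen = set()
    for r in results:
        key = (r.site.site_id, r.effect.gene_symbol)
        if key in seen:  # dedup at report time by (site, gene)
            continue
        seen.add(key)
        c = r.panel_counts
        lines.append(
            f"{r.site.site_id}\t{r.site.chrom}\t{r.site.pos}\t{r.effect.gene_symbol}"
            f"\t{r.effect.category}\t{r.effect.protein_change}\t{c[0]}\t{c[1]}\t{c[2]}\t{c[3]}"
        )
    Path(path).write_text("".join(line + "\n" for line in lines))


def write_audit_log(audit: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(audit, indent=2) + "\n")
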