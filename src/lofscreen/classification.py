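"""Three-class verdicts for validated high-impact variants.

Class I: significantly associated with the breeding-value phenotype after
Bonferroni correction — a confirmed fertility locus. Class II: the mutant
allele segregates in more than one breed but the mutant homozygote is never
observed — a candidate (in)fertility locus. Class III: everything else —
private variants and variants with all three genotypes but no significant
association.
"""

from __future__ import annotations

from dataclasses import dataclass

from .association import AssociationResult, bonferroni_adjust
from .popgen_stats import SiteStats
from .screening import BreedDistribution

ALPHA_EXPERIMENT_WIDE = 0.05


@dataclass
class VariantVerdict:
    site_id: str
    gene: str
    maf_group: str
    n_breeds: int
    private: bool
    missing_hom_mutant: bool
    assoc_significant: bool
    variant_class: str  # "I" | "II" | "III"

    def __post_init__(self) -> None:
        if self.variant_class not in {"I", "II", "III"}:
            raise ValueError(f"invalid class {self.variant_class!r}")
        if self.variant_class == "I" and not self.assoc_significant:
            raise ValueError("class I requires a significant association")


def classify_variant(
    stats: SiteStats,
    dist: BreedDistribution,
    assoc: AssociationResult | None = None,
    gene: str = "",
    m_tests: int | None = None,
    alpha: float = ALPHA_EXPERIMENT_WIDE,
) -> VariantVerdict:
    """Apply the class I/II/III rules to one validated variant.

    ``assoc`` may be absent (variant not tested for association); such a
    variant can still be class II or III, never class I. When ``m_tests`` is
    given and the association result lacks a corrected P, Bonferroni
    correction is applied here.
    """
    if stats.site_id and dist.site_id and stats.site_id != dist.site_id:
        raise ValueError(
            f"site mismatch: stats for {stats.site_id!r}, breed distribution for {dist.site_id!r}"
        )
    significant = False
    if assoc is not None and assoc.testable and assoc.p_nominal is not None:
        p_corr = assoc.p_bonferroni
        if p_corr is None:
            p_corr = (
                bonferroni_adjust(assoc.p_nominal, m_tests) if m_tests else assoc.p_nominal
            )
        significant = p_corr < alpha
    if significant:
        variant_class = "I"
    elif stats.missing_hom_mutant and stats.maf > 0 and not dist.private:
        variant_class = "II"
    else:
        variant_class = "III"
    return VariantVerdict(
        site_id=stats.site_id,
        gene=gene,
        maf_group=stats.maf_group or "I",
        n_breeds=dist.n_breeds_with_mutant,
        private=dist.private,
        missing_hom_mutant=stats.missing_hom_mutant,
        assoc_significant=significant,
        variant_class=variant_class,
    )


def partition_sizes(verdicts: list[VariantVerdict]) -> dict[str, int]:
    return {
        c: sum(1 for v in verdicts if v.variant_class == c) for c in ("I", "II", "III")
    }


def write_class_report(verdicts: list[VariantVerdict], path) -> None:
    from pathlib import Path

    lines = ["site_id\tgene\tclass\tmaf_group\tn_breeds\tprivate\tmissing_hom_mutant\tassoc_significant"]
    for v in sorted(verdicts, key=lambda v: (v.variant_class, v.site_id)):
        lines.append(
            f"{v.site_id}\t{v.gene}\t{v.variant_class}\t{v.maf_group}\t{v.n_breeds}"
            f"\t{int(v.private)}\t{int(v.missing_hom_mutant)}\t{int(v.assoc_significant)}"
        )
    Path(path).write_text("".join(line + "\n" for line in lines))
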