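"""Bundled reference table: the 17 validated high-impact SNPs.

The table holds the published validation-cohort genotype counts (337 fertile
stallions, 19 breeds) for the 17 polymorphic high-impact SNPs, together with
the number of breeds carrying each mutant allele, the private flags, and the
one nominally significant association (the NOTCH1 splice-donor variant,
P = 0.00003 over 15 tested SNPs). It drives the desk-scale reproduction of
the per-site statistics, cohort summaries and class partition.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .association import AssociationResult, bonferroni_adjust
from .classification import VariantVerdict, classify_variant
from .popgen_stats import PanelSummary, SiteStats, site_stats, summarize_panel
from .screening import BreedDistribution

#: full validation cohort size (fertile stallions across all 19 breeds)
VALIDATION_COHORT_N = 337


def load_validation_counts() -> pd.DataFrame:
    path = resources.files("lofscreen.data") / "stallion_validation_counts.tsv"
    with resources.as_file(path) as p:
        df = pd.read_csv(p, sep="\t")
    return df


def validation_site_stats(n_ref: int = VALIDATION_COHORT_N) -> list[SiteStats]:
    """Per-site statistics for the 17 validated SNPs, with e_hom at n_ref."""
    out = []
    for _, row in load_validation_counts().iterrows():
        s = site_stats(int(row.n_AA), int(row.n_AB), int(row.n_BB), site_id=row.site_id)
        s.e_hom = s.q * s.q * n_ref
        s.e_hom_n_ref = n_ref
        out.append(s)
    return out


def validation_verdicts(
    alpha: float = 0.05,
) -> tuple[list[SiteStats], list[VariantVerdict], PanelSummary]:
    """Apply the full per-site statistics and class rules to the 17 SNPs."""
    df = load_validation_counts()
    stats_list = validation_site_stats()
    verdicts = []
    for s, (_, row) in zip(stats_list, df.iterrows()):
        dist = BreedDistribution(
            site_id=row.site_id,
            n_breeds_with_mutant=int(row.n_breeds),
            private=bool(row.private),
            carriers_per_breed={},
        )
        assoc = None
        if pd.notna(row.assoc_p_nominal):
            p = float(row.assoc_p_nominal)
            m = int(row.assoc_m)
            assoc = AssociationResult(
                site_id=row.site_id,
                method="GLM",
                p_nominal=p,
                p_bonferroni=bonferroni_adjust(p, m),
            )
        verdicts.append(
            classify_variant(s, dist, assoc, gene=row.gene, alpha=alpha)
        )
    return stats_list, verdicts, summarize_panel(stats_list)
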