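"""Per-site validation statistics: allele frequencies, heterozygosity,
Hardy-Weinberg chi-square, expected mutant-homozygote counts and MAF groups.

The A allele is the wild type and B the mutant (alt) allele by construction
of the screen; the minor allele is whichever of the two is rarer. The HWE
test is the uncorrected 1-df chi-square on the three genotype classes with
expected counts from the observed allele frequencies — no continuity
correction and no exact test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass
class SiteStats:
    site_id: str
    n_AA: int
    n_AB: int
    n_BB: int
    n: int
    p: float
    q: float
    maf: float
    het_obs: float
    chi2: float | None = None
    df: int = 1
    p_hwe: float | None = None
    monomorphic: bool = False
    e_hom: float | None = None
    e_hom_n_ref: int | None = None
    maf_group: str | None = None

    @property
    def missing_hom_mutant(self) -> bool:
        """Mutant allele observed, but never as a homozygote."""
        return self.n_BB == 0 and self.n_AB >= 1

    @property
    def all_three_genotypes(self) -> bool:
        return self.n_AA > 0 and self.n_AB > 0 and self.n_BB > 0


def site_stats(n_AA: int, n_AB: int, n_BB: int, site_id: str = "") -> SiteStats:
    """Frequencies and observed heterozygosity from genotype counts.

    q is the mutant (B) allele frequency ``(2 n_BB + n_AB) / 2n``; maf is
    ``min(p, q)``; het_obs is ``n_AB / n``.
    """
    if min(n_AA, n_AB, n_BB) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_AB + n_BB
    if n == 0:
        raise ValueError("no genotyped samples (n == 0)")
    q = (2 * n_BB + n_AB) / (2 * n)
    p = 1.0 - q
    s = SiteStats(
        site_id=site_id,
        n_AA=n_AA,
        n_AB=n_AB,
        n_BB=n_BB,
        n=n,
        p=p,
        q=q,
        maf=min(p, q),
        het_obs=n_AB / n,
    )
    s.chi2, s.df, s.p_hwe, s.monomorphic = _hwe(n_AA, n_AB, n_BB, p, q, n)
    s.maf_group = maf_group(s.maf)
    return s


def _hwe(n_AA, n_AB, n_BB, p, q, n):
    if p == 0.0 or q == 0.0:
        # monomorphic: chi2 defined as 0, P undefined (reported as a dash)
        return 0.0, 1, None, True
    exp = np.array([p * p * n, 2 * p * q * n, q * q * n])
    obs = np.array([n_AA, n_AB, n_BB], dtype=float)
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    p_hwe = float(sps.chi2.sf(chi2, df=1))
    return chi2, 1, p_hwe, False


def hwe_test(n_AA: int, n_AB: int, n_BB: int) -> tuple[float, int, float | None]:
    """Uncorrected 1-df Hardy-Weinberg chi-square from genotype counts.

    Returns (chi2, df, p); p is None for monomorphic sites, where the test is
    undefined and chi2 is reported as 0.
    """
    n = n_AA + n_AB + n_BB
    if n < 1:
        raise ValueError("no genotyped samples")
    q = (2 * n_BB + n_AB) / (2 * n)
    chi2, df, p_hwe, _ = _hwe(n_AA, n_AB, n_BB, 1.0 - q, q, n)
    return chi2, df, p_hwe


def expected_hom_mutant(q: float, n_ref: int) -> float:
    """Expected count of mutant homozygotes, q^2 x n_ref.

    ``n_ref`` is a stated reference sample size: either the per-site
    genotyped n or the full cohort size, depending on the report.
    """
    if not (0.0 <= q <= 1.0):
        raise ValueError(f"q outside [0,1]: {q}")
    if n_ref < 0:
        raise ValueError("n_ref must be >= 0")
    return q * q * n_ref


def maf_group(maf: float) -> str:
    """MAF bins: I absent (0), II rare (<0.01), III low [0.01, 0.1], IV moderate (>0.1)."""
    if not (0.0 <= maf <= 0.5):
        raise ValueError(f"maf outside [0, 0.5]: {maf}")
    if maf == 0.0:
        return "I"
    if maf < 0.01:
        return "II"
    if maf <= 0.1:
        return "III"
    return "IV"


@dataclass
class PanelSummary:
    n_sites: int
    mean_maf: float
    maf_range: tuple[float, float]
    n_all_three_genotypes: int
    mean_hom_mutant_freq: float | None
    hom_mutant_freq_range: tuple[float, float] | None
    n_missing_hom_mutant: int
    n_hwe_deviating: int


def write_hwe_table(sites: list["SiteStats"], path, gene_of: dict[str, str] | None = None) -> None:
    """HWE-report TSV: HET, chi-square, df and P per site ('-' when undefined)."""
    from pathlib import Path

    gene_of = gene_of or {}
    lines = ["site_id\tgene\thet\tchi2\tdf\tp_hwe"]
    for s in sites:
        p_txt = "-" if s.p_hwe is None else f"{s.p_hwe:.4g}"
        lines.append(
            f"{s.site_id}\t{gene_of.get(s.site_id, '')}\t{s.het_obs:.3f}"
            f"\t{s.chi2:.3f}\t{s.df}\t{p_txt}"
        )
    Path(path).write_text("".join(line + "\n" for line in lines))


def write_frequency_table(sites: list["SiteStats"], path, gene_of: dict[str, str] | None = None) -> None:
    """Frequency-report TSV: MAF, genotype frequencies and 'x/n' counts."""
    from pathlib import Path

    gene_of = gene_of or {}
    lines = ["site_id\tgene\tmaf\tfreq_AA\tfreq_AB\tfreq_BB\tcounts_AA\tcounts_AB\tcounts_BB"]
    for s in sites:
        lines.append(
            f"{s.site_id}\t{gene_of.get(s.site_id, '')}\t{s.maf:.4f}"
            f"\t{s.n_AA / s.n:.3f}\t{s.n_AB / s.n:.3f}\t{s.n_BB / s.n:.3f}"
            f"\t{s.n_AA}/{s.n}\t{s.n_AB}/{s.n}\t{s.n_BB}/{s.n}"
        )
    Path(path).write_text("".join(line + "\n" for line in lines))


def write_evaluation_table(
    sites: list["SiteStats"],
    path,
    n_breeds_of: dict[str, int] | None = None,
    gene_of: dict[str, str] | None = None,
) -> None:
    """Evaluation TSV: missing-hom flag, het frequency, expected mutant
    homozygotes (labelled with the reference n used), breed count, MAF group."""
    from pathlib import Path

    gene_of = gene_of or {}
    n_breeds_of = n_breeds_of or {}
    lines = ["site_id\tgene\tgt_missing\thet_obs\te_hom\te_hom_n_ref\tn_breeds\tmaf_group"]
    for s in sites:
        e_hom = "" if s.e_hom is None else f"{s.e_hom:.2f}"
        n_ref = "" if s.e_hom_n_ref is None else str(s.e_hom_n_ref)
        nb = n_breeds_of.get(s.site_id, "")
        lines.append(
            f"{s.site_id}\t{gene_of.get(s.site_id, '')}\t{int(s.missing_hom_mutant)}"
            f"\t{s.het_obs:.3f}\t{e_hom}\t{n_ref}\t{nb}\t{s.maf_group}"
        )
    Path(path).write_text("".join(line + "\n" for line in lines))


def summarize_panel(sites: list[SiteStats], alpha: float = 0.05) -> PanelSummary:
    """Cohort-level summary across validated sites.

    Means are unweighted arithmetic means over sites (zero-MAF sites are
    included in the MAF mean); a site deviates from HWE when its defined HWE
    P-value is below ``alpha``.
    """
    if not sites:
        raise ValueError("need at least one site")
    mafs = np.array([s.maf for s in sites])
    three = [s for s in sites if s.all_three_genotypes]
    bb_freqs = np.array([s.n_BB / s.n for s in three]) if three else None
    return PanelSummary(
        n_sites=len(sites),
        mean_maf=float(mafs.mean()),
        maf_range=(float(mafs.min()), float(mafs.max())),
        n_all_three_genotypes=len(three),
        mean_hom_mutant_freq=float(bb_freqs.mean()) if bb_freqs is not None else None,
        hom_mutant_freq_range=(
            (float(bb_freqs.min()), float(bb_freqs.max())) if bb_freqs is not None else None
        ),
        n_missing_hom_mutant=sum(s.missing_hom_mutant for s in sites),
        n_hwe_deviating=sum(1 for s in sites if s.p_hwe is not None and s.p_hwe < alpha),
    )
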