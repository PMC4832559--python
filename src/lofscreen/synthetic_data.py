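"""Synthetic inputs with the statistical structure the pipeline assumes.

The generator emulates the study design end to end: a small detection panel
of sequenced horses carrying planted loss-of-function SNVs only as
heterozygotes, a multi-breed validation cohort genotyped at the retained
sites, a SNP chip inducing half-sib family structure for the kinship matrix,
and breeding-value phenotypes standardized to mean 100, SD 20 with optional
planted genotype effects and a polygenic component of heritability h2.

All randomness flows from a single seed; every stage derives its own
generator from (seed, stage index), so stages are reproducible in isolation
and the full bundle is byte-identical across runs with the same seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .association import ibs_kinship
from .effect_annotation import classify_snv
from .io_formats import DictGenome, write_genotype_table, write_vcf
from .variants import (
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    GeneModel,
    GenotypeMatrix,
    PhenotypeRecord,
    PhenotypeTable,
    VariantSite,
)

STOPS = ("TAA", "TAG", "TGA")
_CODONS = [
    a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT" if a + b + c not in STOPS
]

#: detection panel of the study: 11 sequenced horses (7 stallions, 4 mares)
PANEL_BREEDS = [
    ("Arabian_stallion", "Arabian"),
    ("Sorraia_stallion", "Sorraia"),
    ("Hanoverian_stallion_1", "Hanoverian"),
    ("Hanoverian_stallion_2", "Hanoverian"),
    ("Duelmen_mare", "Duelmen"),
    ("Icelandic_stallion", "Icelandic"),
    ("Przewalski_stallion", "Przewalski"),
    ("Standardbred_stallion", "Standardbred"),
    ("Norwegian_fjord_mare", "NorwegianFjord"),
    ("Arabian_mare", "Arabian"),
    ("Twilight_mare", "Thoroughbred"),
]


def default_breeds() -> dict[str, int]:
    """337 stallions over 19 breeds, Hanoverians dominating (AI sires)."""
    others = [
        "Oldenburg", "Holsteiner", "Trakehner", "Westphalian", "Icelandic",
        "Arabian", "Standardbred", "Thoroughbred", "Haflinger", "Friesian",
        "Shetland", "Welsh", "Fjord", "Knabstrupper", "Lipizzaner",
        "Morgan", "Quarter", "Tinker",
    ]
    sizes = [7, 7, 7] + [6] * 15  # 111 non-Hanoverians
    return {"Hanoverian": 226, **dict(zip(others, sizes))}


@dataclass(frozen=True)
class PlantSpec:
    """One variant to plant in the detection panel.

    ``n_het``/``n_hom_alt`` fix the panel genotype pattern (remaining samples
    are wild type); ``known`` adds the site to the emitted known-sites file so
    the novelty filter removes it; ``cohort_maf``/``inbreeding_f`` drive the
    validation-cohort genotype draw; ``beta`` is the additive phenotype effect
    per mutant allele before final standardization.
    """

    category: str
    n_het: int = 2
    n_hom_alt: int = 0
    known: bool = False
    cohort_maf: float = 0.05
    inbreeding_f: float = 0.0
    beta: float = 0.0

    @property
    def survives_screen(self) -> bool:
        from .effect_annotation import HIGH_IMPACT_CATEGORIES

        return (
            self.category in HIGH_IMPACT_CATEGORIES
            and not self.known
            and self.n_hom_alt == 0
            and self.n_het >= 1
        )


def default_planted() -> tuple[PlantSpec, ...]:
    """Six planted variants: two survivors and four negative controls."""
    return (
        PlantSpec("stop_gained", n_het=2, cohort_maf=0.13, beta=-8.0),
        PlantSpec("splice_donor", n_het=1, cohort_maf=0.05),
        PlantSpec("stop_gained", n_het=2, known=True),
        PlantSpec("splice_acceptor", n_het=1, known=True),
        PlantSpec("start_lost", n_het=2, n_hom_alt=1),
        PlantSpec("other", n_het=2),
    )


@dataclass
class SimConfig:
    seed: int = 1
    n_genes: int = 6
    exons_per_gene: tuple[int, int] = (2, 4)
    n_panel_samples: int = 11
    breeds: dict[str, int] = field(default_factory=default_breeds)
    planted: tuple[PlantSpec, ...] = field(default_factory=default_planted)
    chip_n_snps: int = 2000
    chip_maf_range: tuple[float, float] = (0.10, 0.50)
    family_size: int = 10
    phenotype_mean: float = 100.0
    phenotype_sd: float = 20.0
    h2: float = 0.3
    cohort_missing_rate: float = 0.0
    phenotyped_breed: str = "Hanoverian"
    n_phenotyped: int = 216
    splice_window: int = 2

    def __post_init__(self) -> None:
        if not (0.0 <= self.h2 <= 1.0):
            raise ValueError(f"h2 outside [0,1]: {self.h2}")
        for spec in self.planted:
            if not (0.0 <= spec.cohort_maf <= 0.5):
                raise ValueError(f"cohort MAF outside [0,0.5]: {spec.cohort_maf}")

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stage])


# ---------------------------------------------------------------------------
# genome and gene models


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    body = "".join(rng.choice(_CODONS) for _ in range(n_codons - 2))
    return "ATG" + body + str(rng.choice(STOPS))


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def simulate_genome_and_genes(cfg: SimConfig) -> tuple[list[GeneModel], DictGenome]:
    """Random contig with multi-exon genes on both strands.

    Every transcript has a valid ATG...stop CDS free of internal stops, short
    UTRs in the terminal exons, and canonical GT/AG intron boundaries (in
    transcript orientation).
    """
    rng = cfg.rng(0)
    chrom = "chr1"
    parts: list[str] = []
    models: list[GeneModel] = []
    cursor = 1  # next free genomic position
    for gi in range(cfg.n_genes):
        gap = int(rng.integers(200, 500))
        parts.append(_random_seq(rng, gap))
        cursor += gap
        n_exons = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
        n_codons = int(rng.integers(30, 80))
        cds = _random_cds(rng, n_codons)
        utr5 = _random_seq(rng, int(rng.integers(8, 25)))
        utr3 = _random_seq(rng, int(rng.integers(8, 25)))
        tx_exonic = utr5 + cds + utr3
        # split exonic sequence into n_exons chunks of >= 12 bases
        cuts = sorted(rng.choice(range(12, len(tx_exonic) - 12), size=n_exons - 1, replace=False)) if n_exons > 1 else []
        while len(cuts) > 1 and min(np.diff(cuts)) < 12:
            cuts = sorted(rng.choice(range(12, len(tx_exonic) - 12), size=n_exons - 1, replace=False))
        bounds = [0, *cuts, len(tx_exonic)]
        exon_seqs = [tx_exonic[a:b] for a, b in zip(bounds, bounds[1:])]
        introns = [
            "GT" + _random_seq(rng, int(rng.integers(40, 120))) + "AG"
            for _ in range(n_exons - 1)
        ]
        strand = "+" if rng.random() < 0.5 else "-"
        # transcript-orientation region sequence and local exon intervals
        region = []
        local_exons: list[tuple[int, int]] = []
        lpos = 1
        for k, es in enumerate(exon_seqs):
            region.append(es)
            local_exons.append((lpos, lpos + len(es) - 1))
            lpos += len(es)
            if k < len(introns):
                region.append(introns[k])
                lpos += len(introns[k])
        region_seq = "".join(region)
        length = len(region_seq)

        def exonic_to_region(offset: int) -> int:
            # map 1-based offset in the spliced exonic sequence to a 1-based
            # region coordinate (introns included)
            cum = 0
            for (ls, le), es in zip(local_exons, exon_seqs):
                if offset <= cum + len(es):
                    return ls + (offset - cum) - 1
                cum += len(es)
            raise AssertionError("offset beyond exonic sequence")

        cds_lo_local = exonic_to_region(len(utr5) + 1)
        cds_hi_local = exonic_to_region(len(utr5) + len(cds))
        if strand == "+":
            genomic_seq = region_seq
            exons = [(cursor + a - 1, cursor + b - 1) for a, b in local_exons]
            cds_start = cursor + cds_lo_local - 1
            cds_end = cursor + cds_hi_local - 1
        else:
            from .effect_annotation import reverse_complement

            genomic_seq = reverse_complement(region_seq)
            exons = [
                (cursor + length - b, cursor + length - a) for a, b in local_exons
            ]
            cds_start = cursor + length - cds_hi_local
            cds_end = cursor + length - cds_lo_local
        parts.append(genomic_seq)
        cursor += length
        models.append(
            GeneModel(
                gene_symbol=f"GENE{gi + 1}",
                transcript_id=f"tx{gi + 1}",
                chrom=chrom,
                strand=strand,
                exons=sorted(exons),
                cds_start=cds_start,
                cds_end=cds_end,
            )
        )
    parts.append(_random_seq(rng, int(rng.integers(200, 500))))
    genome = DictGenome({chrom: "".join(parts)})
    return models, genome


def write_fasta(genome: DictGenome, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom in genome.contigs():
            seq = genome.fetch(chrom, 1, len(genome._seqs[chrom]))
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gff3(models: list[GeneModel], path: str | Path) -> None:
    lines = ["##gff-version 3"]
    for m in models:
        lo, hi = m.span
        gid, tid = f"gene_{m.transcript_id}", m.transcript_id
        attr = f"gene={m.gene_symbol}"
        lines.append(f"{m.chrom}\tsim\tgene\t{lo}\t{hi}\t.\t{m.strand}\t.\tID={gid};{attr}")
        lines.append(
            f"{m.chrom}\tsim\tmRNA\t{lo}\t{hi}\t.\t{m.strand}\t.\tID={tid};Parent={gid};{attr}"
        )
        for a, b in m.exons:
            lines.append(f"{m.chrom}\tsim\texon\t{a}\t{b}\t.\t{m.strand}\t.\tParent={tid}")
        for a, b in m.exons:
            clo, chi = max(a, m.cds_start), min(b, m.cds_end)
            if clo <= chi:
                lines.append(
                    f"{m.chrom}\tsim\tCDS\t{clo}\t{chi}\t.\t{m.strand}\t0\tParent={tid}"
                )
    Path(path).write_text("".join(line + "\n" for line in lines))


# ---------------------------------------------------------------------------
# detection panel


def _find_snv(
    model: GeneModel,
    genome: DictGenome,
    category: str,
    rng: np.random.Generator,
    used: set[int],
    splice_window: int,
) -> VariantSite | None:
    lo, hi = model.span
    positions = np.arange(lo, hi + 1)
    rng.shuffle(positions)
    for pos in positions:
        pos = int(pos)
        if pos in used:
            continue
        ref = genome.base(model.chrom, pos)
        alts = [b for b in "ACGT" if b != ref]
        rng.shuffle(alts)
        for alt in alts:
            site = VariantSite(model.chrom, pos, ref, alt)
            effect = classify_snv(site, model, genome, splice_window=splice_window)
            if effect.category == category:
                return site
    return None


def simulate_detection_panel(
    cfg: SimConfig, models: list[GeneModel], genome: DictGenome
) -> tuple[GenotypeMatrix, list[dict], dict]:
    """Plant the configured variants into an 11-sample detection panel.

    Returns the panel genotype matrix, the known-sites rows to write, and a
    truth record mapping each planted site to its spec, host gene and
    expected screening outcome. Categories are verified by classification; if
    a category is unplantable in the chosen gene the next gene is tried and
    the substitution logged in the truth record.
    """
    rng = cfg.rng(1)
    samples = [s for s, _ in PANEL_BREEDS][: cfg.n_panel_samples]
    breed_of = dict(PANEL_BREEDS[: cfg.n_panel_samples])
    used: set[int] = set()
    sites: list[VariantSite] = []
    columns: list[np.ndarray] = []
    known_rows: list[dict] = []
    truth: dict = {"planted": [], "expected_retained": [], "expected_rejected": []}
    gene_cycle = list(range(len(models)))
    for k, spec in enumerate(cfg.planted):
        site = None
        host = None
        tried = []
        for gi in gene_cycle[k % len(models) :] + gene_cycle[: k % len(models)]:
            site = _find_snv(models[gi], genome, spec.category, rng, used, cfg.splice_window)
            if site is not None:
                host = models[gi]
                break
            tried.append(models[gi].gene_symbol)
        if site is None:
            raise RuntimeError(f"could not plant category {spec.category!r} in any gene")
        used.add(site.pos)
        col = np.full(len(samples), HOM_REF, dtype=np.int8)
        carriers = rng.choice(len(samples), size=spec.n_het + spec.n_hom_alt, replace=False)
        for i in carriers[: spec.n_het]:
            col[i] = HET
        for i in carriers[spec.n_het :]:
            col[i] = HOM_ALT
        sites.append(site)
        columns.append(col)
        if spec.known:
            known_rows.append(
                {"chrom": site.chrom, "pos": site.pos, "ref": site.ref, "alt": site.alt}
            )
        entry = {
            "site_id": site.site_id,
            "chrom": site.chrom,
            "pos": site.pos,
            "category": spec.category,
            "gene": host.gene_symbol,
            "known": spec.known,
            "n_het": spec.n_het,
            "n_hom_alt": spec.n_hom_alt,
            "cohort_maf": spec.cohort_maf,
            "inbreeding_f": spec.inbreeding_f,
            "beta": spec.beta,
            "substituted_from": tried,
        }
        truth["planted"].append(entry)
        (truth["expected_retained"] if spec.survives_screen else truth["expected_rejected"]).append(
            site.site_id
        )
    order = np.argsort([s.pos for s in sites])
    panel = GenotypeMatrix(
        [sites[i] for i in order],
        samples,
        np.stack([columns[i] for i in order], axis=1),
        breed_of,
    )
    return panel, known_rows, truth


def write_known_sites(rows: list[dict], path: str | Path) -> None:
    lines = ["chrom\tpos\tref\talt"]
    for r in rows:
        lines.append(f"{r['chrom']}\t{r['pos']}\t{r['ref']}\t{r['alt']}")
    Path(path).write_text("".join(line + "\n" for line in lines))


# ---------------------------------------------------------------------------
# validation cohort, chip and phenotypes


def genotype_probs(q: float, f: float) -> tuple[float, float, float]:
    """Genotype class probabilities under inbreeding coefficient F.

    (p^2 + Fpq, 2pq(1-F), q^2 + Fpq); F=0 recovers Hardy-Weinberg.
    """
    p = 1.0 - q
    probs = (p * p + f * p * q, 2 * p * q * (1 - f), q * q + f * p * q)
    if min(probs) < -1e-12:
        raise ValueError(f"inbreeding F={f} makes a genotype class negative at q={q}")
    return tuple(max(x, 0.0) for x in probs)


def simulate_cohort_genotypes(
    cfg: SimConfig, sites: list[VariantSite], site_params: dict[str, tuple[float, float]] | None = None
) -> GenotypeMatrix:
    """Multi-breed cohort genotypes at the validated sites.

    ``site_params`` maps site_id -> (maf, inbreeding F); defaults come from
    the planted specs. Genotypes are drawn independently per breed from the
    inbreeding-adjusted genotype frequencies; optional missingness is applied
    uniformly at ``cfg.cohort_missing_rate``.
    """
    rng = cfg.rng(2)
    if site_params is None:
        site_params = {}
    samples: list[str] = []
    breed_of: dict[str, str] = {}
    for breed, size in cfg.breeds.items():
        for i in range(size):
            sid = f"{breed}_{i + 1:03d}"
            samples.append(sid)
            breed_of[sid] = breed
    calls = np.empty((len(samples), len(sites)), dtype=np.int8)
    for j, site in enumerate(sites):
        q, f = site_params.get(site.site_id, (0.05, 0.0))
        probs = genotype_probs(q, f)
        calls[:, j] = rng.choice([HOM_REF, HET, HOM_ALT], size=len(samples), p=probs)
    if cfg.cohort_missing_rate > 0:
        mask = rng.random(calls.shape) < cfg.cohort_missing_rate
        calls[mask] = MISSING
    return GenotypeMatrix(sites, samples, calls, breed_of)


def simulate_chip_and_phenotypes(
    cfg: SimConfig, cohort: GenotypeMatrix
) -> tuple[GenotypeMatrix, PhenotypeTable, dict]:
    """Chip genotypes with half-sib family structure, plus phenotypes.

    Samples within each breed are grouped into paternal half-sib families of
    ``cfg.family_size``; each offspring inherits one allele from the family
    sire and one from the breed allele pool, which induces the block-wise
    elevated IBS the mixed model must absorb. Phenotypes for the phenotyped
    subset are y = mean + sum(beta * dosage) + u + e with cov(u) = h2 sigma^2
    K_true and var(e) = (1-h2) sigma^2, then standardized to mean 100 SD 20.

    Returns (chip, phenotypes, truth) where truth carries the true betas, h2
    and K_true (as nested lists) for recovery tests.
    """
    rng = cfg.rng(3)
    n_snps = cfg.chip_n_snps
    lo, hi = cfg.chip_maf_range
    freqs = rng.uniform(lo, hi, size=n_snps)
    samples = cohort.samples
    n = len(samples)
    calls = np.empty((n, n_snps), dtype=np.int8)
    sire_of: dict[str, int] = {}
    sire_counter = 0
    by_breed: dict[str, list[int]] = {}
    for i, s in enumerate(samples):
        by_breed.setdefault(cohort.breed_of[s], []).append(i)
    for breed, idx in by_breed.items():
        for fam_start in range(0, len(idx), cfg.family_size):
            fam = idx[fam_start : fam_start + cfg.family_size]
            sire = rng.binomial(2, freqs)  # sire dosage per SNP
            sire_counter += 1
            for i in fam:
                sire_of[samples[i]] = sire_counter
                transmitted = rng.binomial(1, sire / 2.0)
                dam_allele = rng.binomial(1, freqs)
                calls[i] = (transmitted + dam_allele).astype(np.int8)
    chip_sites = [
        VariantSite("chip", j + 1, "A", "C", f"snp{j + 1:05d}") for j in range(n_snps)
    ]
    chip = GenotypeMatrix(chip_sites, samples, calls, cohort.breed_of)

    phenotyped = [s for s in samples if cohort.breed_of[s] == cfg.phenotyped_breed][
        : cfg.n_phenotyped
    ]
    if len(phenotyped) < cfg.n_phenotyped:
        raise ValueError(
            f"breed {cfg.phenotyped_breed} has only {len(phenotyped)} samples, "
            f"need {cfg.n_phenotyped}"
        )
    k_true = ibs_kinship(chip.subset_samples(phenotyped)).values
    sd = cfg.phenotype_sd
    eigvals, u_mat = np.linalg.eigh(k_true)
    root = u_mat @ (np.sqrt(np.clip(eigvals, 0, None))[:, None] * u_mat.T)
    u = np.sqrt(cfg.h2) * sd * (root @ rng.standard_normal(len(phenotyped)))
    e = np.sqrt(1.0 - cfg.h2) * sd * rng.standard_normal(len(phenotyped))
    y = np.full(len(phenotyped), cfg.phenotype_mean) + u + e
    truth_betas = {}
    idx_of = {s: i for i, s in enumerate(samples)}
    ph_rows = [idx_of[s] for s in phenotyped]
    for j, site in enumerate(cohort.sites):
        beta = _beta_for_site(cfg, site.site_id)
        if beta:
            dose = cohort.calls[ph_rows, j].astype(float)
            dose[dose == MISSING] = 0.0
            y = y + beta * dose
            truth_betas[site.site_id] = beta
    y = cfg.phenotype_mean + sd * (y - y.mean()) / y.std(ddof=0)
    reliability = 0.7
    records = {}
    for s, val in zip(phenotyped, y):
        ebv = cfg.phenotype_mean + reliability * (val - cfg.phenotype_mean)
        records[s] = PhenotypeRecord(ebv=float(ebv), dereg_ebv=float(val), reliability=reliability)
    phenotypes = PhenotypeTable(records)
    truth = {
        "h2": cfg.h2,
        "betas": truth_betas,
        "phenotyped": phenotyped,
        "sire_of": sire_of,
        "k_true": k_true.tolist(),
    }
    return chip, phenotypes, truth


def _beta_for_site(cfg: SimConfig, site_id: str) -> float:
    # the truth record written by simulate_detection_panel links specs to
    # site_ids; here we match through the per-config registry set up below
    return getattr(cfg, "_beta_by_site", {}).get(site_id, 0.0)


# ---------------------------------------------------------------------------
# full bundle


@dataclass
class SimBundle:
    models: list[GeneModel]
    genome: DictGenome
    panel: GenotypeMatrix
    known_rows: list[dict]
    cohort: GenotypeMatrix
    chip: GenotypeMatrix
    phenotypes: PhenotypeTable
    truth: dict


def simulate_all(cfg: SimConfig, outdir: str | Path | None = None) -> SimBundle:
    """Run every generator stage and optionally write the file bundle."""
    models, genome = simulate_genome_and_genes(cfg)
    panel, known_rows, panel_truth = simulate_detection_panel(cfg, models, genome)
    site_params = {}
    beta_by_site = {}
    for entry in panel_truth["planted"]:
        site_params[entry["site_id"]] = (entry["cohort_maf"], entry["inbreeding_f"])
        if entry["beta"]:
            beta_by_site[entry["site_id"]] = entry["beta"]
    retained_ids = set(panel_truth["expected_retained"])
    cohort_sites = [s for s in panel.sites if s.site_id in retained_ids]
    cohort = simulate_cohort_genotypes(cfg, cohort_sites, site_params)
    cfg._beta_by_site = beta_by_site  # registry consumed by _beta_for_site
    chip, phenotypes, pheno_truth = simulate_chip_and_phenotypes(cfg, cohort)
    truth = {**panel_truth, **pheno_truth, "seed": cfg.seed}
    bundle = SimBundle(models, genome, panel, known_rows, cohort, chip, phenotypes, truth)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(genome, outdir / "genome.fa")
        write_gff3(models, outdir / "genes.gff3")
        contig_lengths = {c: len(genome._seqs[c]) for c in genome.contigs()}
        write_vcf(panel, outdir / "panel.vcf", contig_lengths)
        write_known_sites(known_rows, outdir / "known_sites.tsv")
        write_genotype_table(cohort, outdir / "cohort.tsv")
        write_genotype_table(chip, outdir / "chip.tsv")
        _write_phenotypes(phenotypes, outdir / "phenotypes.tsv")
        slim = {k: v for k, v in truth.items() if k != "k_true"}
        (outdir / "truth.json").write_text(json.dumps(slim, indent=2) + "\n")
    return bundle


def _write_phenotypes(table: PhenotypeTable, path: str | Path) -> None:
    lines = ["sample\tebv\tdereg_ebv\treliability"]
    for s, r in table.records.items():
        lines.append(f"{s}\t{r.ebv:.6f}\t{r.dereg_ebv:.6f}\t{r.reliability}")
    Path(path).write_text("".join(line + "\n" for line in lines))
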