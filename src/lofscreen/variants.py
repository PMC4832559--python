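"""Core domain containers shared across the pipeline.

Coordinates are 1-based and intervals closed throughout (VCF/GFF convention).
Genotypes are unphased categorical calls; phase information is normalized
away on input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

BASES = frozenset("ACGT")

# integer genotype codes used in GenotypeMatrix.calls
HOM_REF = 0
HET = 1
HOM_ALT = 2
MISSING = -1

GENOTYPE_NAMES = {HOM_REF: "hom_ref", HET: "het", HOM_ALT: "hom_alt", MISSING: "missing"}


@dataclass(frozen=True)
class VariantSite:
    """A biallelic SNV.

    The ``site_id`` follows the HGVS-like genomic label used in variant
    reports, e.g. ``g.37455302G>A``, unless the source VCF carries an ID.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    site_id: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref not in BASES or self.alt not in BASES:
            raise ValueError(f"ref/alt must be single bases in ACGT: {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt are identical at {self.chrom}:{self.pos}")
        if not self.site_id:
            object.__setattr__(self, "site_id", f"g.{self.pos}{self.ref}>{self.alt}")


class GenotypeMatrix:
    """Per-sample genotype calls at an ordered list of biallelic SNVs.

    ``calls`` is an int8 array of shape (n_samples, n_sites) holding the
    codes ``HOM_REF``/``HET``/``HOM_ALT``/``MISSING``. Every sample carries a
    breed label; a single default breed is allowed.
    """

    def __init__(
        self,
        sites: list[VariantSite],
        samples: list[str],
        calls: np.ndarray,
        breed_of: dict[str, str] | None = None,
    ) -> None:
        calls = np.asarray(calls, dtype=np.int8)
        if calls.shape != (len(samples), len(sites)):
            raise ValueError(
                f"calls shape {calls.shape} does not match "
                f"{len(samples)} samples x {len(sites)} sites"
            )
        if len(set(samples)) != len(samples):
            raise ValueError("duplicate sample IDs")
        bad = ~np.isin(calls, (HOM_REF, HET, HOM_ALT, MISSING))
        if bad.any():
            raise ValueError("invalid genotype codes in calls")
        self.sites = list(sites)
        self.samples = list(samples)
        self.calls = calls
        if breed_of is None:
            breed_of = {s: "default" for s in samples}
        missing_breed = set(samples) - set(breed_of)
        if missing_breed:
            raise ValueError(f"samples without breed label: {sorted(missing_breed)[:5]}")
        self.breed_of = {s: breed_of[s] for s in samples}

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def site_index(self, site_id: str) -> int:
        for i, s in enumerate(self.sites):
            if s.site_id == site_id:
                return i
        raise KeyError(site_id)

    def genotype_counts(self, j: int) -> tuple[int, int, int, int]:
        """(n_hom_ref, n_het, n_hom_alt, n_missing) at site column ``j``."""
        col = self.calls[:, j]
        return (
            int((col == HOM_REF).sum()),
            int((col == HET).sum()),
            int((col == HOM_ALT).sum()),
            int((col == MISSING).sum()),
        )

    def dosage(self, j: int) -> np.ndarray:
        """Alt-allele dosage at site ``j`` as float with NaN for missing."""
        col = self.calls[:, j].astype(float)
        col[self.calls[:, j] == MISSING] = np.nan
        return col

    def subset_sites(self, indices: list[int]) -> "GenotypeMatrix":
        return GenotypeMatrix(
            [self.sites[i] for i in indices],
            self.samples,
            self.calls[:, indices],
            self.breed_of,
        )

    def subset_samples(self, keep: list[str]) -> "GenotypeMatrix":
        idx = [self.samples.index(s) for s in keep]
        return GenotypeMatrix(self.sites, keep, self.calls[idx, :], self.breed_of)


@dataclass
class GeneModel:
    """A single transcript model in genomic coordinates.

    ``exons`` are 1-based closed intervals sorted by genomic position and
    non-overlapping. ``cds_start``/``cds_end`` are genomic positions with
    ``cds_start <= cds_end`` regardless of strand; on the minus strand the
    initiator codon begins at ``cds_end`` reading leftwards.
    """

    gene_symbol: str
    transcript_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise ValueError("at least one exon required")
        exons = sorted((int(a), int(b)) for a, b in self.exons)
        for (a, b) in exons:
            if a > b:
                raise ValueError(f"exon interval reversed: {(a, b)}")
        for (a1, b1), (a2, b2) in zip(exons, exons[1:]):
            if a2 <= b1:
                raise ValueError(f"exons overlap: {(a1, b1)} and {(a2, b2)}")
        self.exons = exons
        if not (self._in_exon(self.cds_start) and self._in_exon(self.cds_end)):
            raise ValueError("CDS bounds fall outside exons")
        if self.cds_start > self.cds_end:
            raise ValueError("cds_start must be <= cds_end (genomic order)")

    def _in_exon(self, pos: int) -> bool:
        return any(a <= pos <= b for a, b in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        """Transcript span: first exon start to last exon end (genomic)."""
        return self.exons[0][0], self.exons[-1][1]

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Genomic intron intervals between consecutive exons."""
        return [
            (b + 1, a2 - 1) for (_, b), (a2, _) in zip(self.exons, self.exons[1:])
        ]

    def contains(self, pos: int) -> bool:
        lo, hi = self.span
        return lo <= pos <= hi


@dataclass
class PhenotypeRecord:
    ebv: float
    dereg_ebv: float
    reliability: float | None = None

    def __post_init__(self) -> None:
        for v in (self.ebv, self.dereg_ebv):
            if not np.isfinite(v):
                raise ValueError("non-finite phenotype value")
        if self.reliability is not None and not (0.0 <= self.reliability <= 1.0):
            raise ValueError(f"reliability outside [0,1]: {self.reliability}")


@dataclass
class PhenotypeTable:
    """Breeding-value phenotypes on the standardized 100 +/- 20 scale."""

    records: dict[str, PhenotypeRecord] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def samples(self) -> list[str]:
        return list(self.records)

    def dereg_values(self, samples: list[str]) -> np.ndarray:
        return np.array([self.records[s].dereg_ebv for s in samples], dtype=float)

    def ebv_values(self, samples: list[str]) -> np.ndarray:
        return np.array([self.records[s].ebv for s in samples], dtype=float)
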