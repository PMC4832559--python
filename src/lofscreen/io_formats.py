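"""Readers and writers for the standard formats the pipeline touches.

All downstream modules consume only the in-memory domain types; nothing past
this module parses a file. VCF I/O goes through pysam, gene models through
gffutils, genome sequence through pyfaidx, and tabular inputs through pandas.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd
import pysam
from pyfaidx import Fasta

from .variants import (
    BASES,
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

log = logging.getLogger(__name__)


@dataclass
class SkipLog:
    """Plain-text QC log of records dropped on input."""

    skipped: list[str] = field(default_factory=list)

    def add(self, reason: str) -> None:
        self.skipped.append(reason)

    def write(self, path: str | Path) -> None:
        Path(path).write_text("".join(line + "\n" for line in self.skipped))

    def __len__(self) -> int:
        return len(self.skipped)


class VcfParseError(ValueError):
    pass


def read_vcf(path: str | Path, skip_log: SkipLog | None = None) -> GenotypeMatrix:
    """Read a multi-sample VCF into a :class:`GenotypeMatrix`.

    Only biallelic SNVs are retained; multi-allelic records, indels and
    symbolic alleles are dropped and counted in ``skip_log``. ``./.`` maps to
    missing; phased and unphased separators are both accepted and phase is
    discarded. Site order follows the file.
    """
    skip_log = skip_log if skip_log is not None else SkipLog()
    try:
        vcf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise VcfParseError(f"cannot parse VCF header of {path}: {exc}") from exc
    samples = list(vcf.header.samples)
    if not samples:
        raise VcfParseError(f"{path}: no sample columns")
    sites: list[VariantSite] = []
    columns: list[np.ndarray] = []
    for lineno, rec in enumerate(vcf, start=1):
        alts = rec.alts or ()
        if len(alts) != 1:
            skip_log.add(f"{rec.chrom}:{rec.pos} multi-allelic or missing ALT, dropped")
            continue
        ref, alt = rec.ref, alts[0]
        if len(ref) != 1 or len(alt) != 1 or ref not in BASES or alt not in BASES:
            skip_log.add(f"{rec.chrom}:{rec.pos} not a simple SNV ({ref}>{alt}), dropped")
            continue
        col = np.empty(len(samples), dtype=np.int8)
        for i, sample in enumerate(samples):
            try:
                gt = rec.samples[sample]["GT"]
            except KeyError as exc:
                raise VcfParseError(
                    f"{path} record {lineno} ({rec.chrom}:{rec.pos}): no GT subfield"
                ) from exc
            alleles = tuple(a for a in (gt or ()) if a is not None)
            if len(alleles) < 2:
                col[i] = MISSING
            else:
                code = alleles[0] + alleles[1]
                if not all(a in (0, 1) for a in alleles[:2]):
                    raise VcfParseError(
                        f"{path} record {lineno}: allele index out of range for "
                        f"biallelic site {rec.chrom}:{rec.pos}"
                    )
                col[i] = (HOM_REF, HET, HOM_ALT)[code]
        site_id = rec.id if rec.id not in (None, ".") else f"g.{rec.pos}{ref}>{alt}"
        sites.append(VariantSite(rec.chrom, rec.pos, ref, alt, site_id))
        columns.append(col)
    calls = (
        np.stack(columns, axis=1) if columns else np.empty((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(sites, samples, calls)


_GT_STRINGS = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}


def write_vcf(matrix: GenotypeMatrix, path: str | Path, contig_lengths: dict[str, int] | None = None) -> None:
    """Write a :class:`GenotypeMatrix` as an uncompressed VCF v4.2 file."""
    contigs = {s.chrom for s in matrix.sites}
    lines = ["##fileformat=VCFv4.2"]
    for c in sorted(contigs):
        if contig_lengths and c in contig_lengths:
            lines.append(f"##contig=<ID={c},length={contig_lengths[c]}>")
        else:
            lines.append(f"##contig=<ID={c}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(matrix.samples)
    )
    order = sorted(range(matrix.n_sites), key=lambda j: (matrix.sites[j].chrom, matrix.sites[j].pos))
    for j in order:
        s = matrix.sites[j]
        gts = "\t".join(_GT_STRINGS[int(g)] for g in matrix.calls[:, j])
        lines.append(f"{s.chrom}\t{s.pos}\t{s.site_id}\t{s.ref}\t{s.alt}\t.\tPASS\t.\tGT\t{gts}")
    Path(path).write_text("".join(line + "\n" for line in lines))


class GenomeSequence:
    """1-based closed-interval accessor over a FASTA file (pyfaidx-backed)."""

    def __init__(self, path: str | Path) -> None:
        self._fasta = Fasta(str(path), as_raw=True, sequence_always_upper=True)

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if chrom not in self._fasta:
            raise KeyError(f"contig {chrom!r} absent from FASTA")
        return str(self._fasta[chrom][start - 1 : end])

    def base(self, chrom: str, pos: int) -> str:
        return self.fetch(chrom, pos, pos)

    def contigs(self) -> list[str]:
        return list(self._fasta.keys())


class DictGenome:
    """In-memory genome accessor with the same interface as GenomeSequence."""

    def __init__(self, sequences: dict[str, str]) -> None:
        self._seqs = {c: s.upper() for c, s in sequences.items()}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if chrom not in self._seqs:
            raise KeyError(f"contig {chrom!r} absent")
        return self._seqs[chrom][start - 1 : end]

    def base(self, chrom: str, pos: int) -> str:
        return self.fetch(chrom, pos, pos)

    def contigs(self) -> list[str]:
        return list(self._seqs)


def read_gene_models(
    path_gff: str | Path, path_fasta: str | Path
) -> tuple[list[GeneModel], GenomeSequence]:
    """Load transcript models from GFF3/GTF and the genome from FASTA.

    One :class:`GeneModel` is produced per transcript with exon and CDS
    features. Transcripts without CDS, or whose CDS escapes the exon set, are
    rejected with a warning. Minus-strand models keep genomic coordinates
    plus the strand flag.
    """
    genome = GenomeSequence(path_fasta)
    db = gffutils.create_db(
        str(path_gff),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    models: list[GeneModel] = []
    for tx in db.features_of_type(("mRNA", "transcript")):
        exons = [(f.start, f.end) for f in db.children(tx, featuretype="exon")]
        cds = [(f.start, f.end) for f in db.children(tx, featuretype="CDS")]
        if not cds:
            log.warning("transcript %s has no CDS features; rejected", tx.id)
            continue
        gene_symbol = tx.attributes.get("gene", tx.attributes.get("gene_id", [tx.id]))[0]
        if tx.seqid not in genome.contigs():
            raise ValueError(f"contig {tx.seqid!r} of transcript {tx.id} missing from FASTA")
        cds_start = min(a for a, _ in cds)
        cds_end = max(b for _, b in cds)
        try:
            model = GeneModel(
                gene_symbol=gene_symbol,
                transcript_id=tx.id,
                chrom=tx.seqid,
                strand=tx.strand,
                exons=exons,
                cds_start=cds_start,
                cds_end=cds_end,
            )
        except ValueError as exc:
            log.warning("transcript %s rejected: %s", tx.id, exc)
            continue
        models.append(model)
    return models, genome


def read_known_sites(*paths: str | Path, skip_log: SkipLog | None = None) -> "KnownSites":
    """Union dbSNP-style tables of known sites over one or more files.

    Each file is TSV/CSV with at least ``chrom`` and ``pos`` columns;
    ``ref``/``alt`` columns are optional. Rows carrying alleles are keyed on
    (chrom, pos, ref, alt); rows without alleles match any allele at that
    position. Unparseable rows are skipped and counted.
    """
    skip_log = skip_log if skip_log is not None else SkipLog()
    allele_keys: set[tuple[str, int, str, str]] = set()
    pos_keys: set[tuple[str, int]] = set()
    for path in paths:
        df = pd.read_csv(path, sep=None, engine="python", dtype=str, comment="#")
        if df.empty:
            continue
        cols = {c.lower(): c for c in df.columns}
        if "chrom" not in cols or "pos" not in cols:
            raise ValueError(f"{path}: expected 'chrom' and 'pos' columns, got {list(df.columns)}")
        has_alleles = "ref" in cols and "alt" in cols
        for _, row in df.iterrows():
            try:
                chrom = str(row[cols["chrom"]])
                pos = int(row[cols["pos"]])
            except (TypeError, ValueError):
                skip_log.add(f"{path}: unparseable row {row.to_dict()}")
                continue
            ref = str(row[cols["ref"]]).upper() if has_alleles else ""
            alt = str(row[cols["alt"]]).upper() if has_alleles else ""
            if has_alleles and ref in BASES and alt in BASES:
                allele_keys.add((chrom, pos, ref, alt))
            else:
                pos_keys.add((chrom, pos))
    return KnownSites(allele_keys, pos_keys)


@dataclass(frozen=True)
class KnownSites:
    """Membership set for the novelty filter.

    ``allele_aware=True`` (the default downstream) requires matching alleles
    where the source file provided them; position-only rows always match any
    allele at their position.
    """

    allele_keys: frozenset = frozenset()
    pos_keys: frozenset = frozenset()

    def __init__(self, allele_keys=(), pos_keys=()):
        object.__setattr__(self, "allele_keys", frozenset(allele_keys))
        object.__setattr__(self, "pos_keys", frozenset(pos_keys))

    def __len__(self) -> int:
        return len(self.allele_keys) + len(self.pos_keys)

    def contains(self, site: VariantSite, allele_aware: bool = True) -> bool:
        if (site.chrom, site.pos) in self.pos_keys:
            return True
        if allele_aware:
            return (site.chrom, site.pos, site.ref, site.alt) in self.allele_keys
        return any(k[0] == site.chrom and k[1] == site.pos for k in self.allele_keys)


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    """Read a phenotype TSV with columns sample, ebv, dereg_ebv[, reliability]."""
    df = pd.read_csv(path, sep="\t")
    if df["sample"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample IDs")
    records = {}
    for _, row in df.iterrows():
        try:
            ebv = float(row["ebv"])
            dereg = float(row["dereg_ebv"])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: non-numeric EBV for sample {row['sample']}") from exc
        rel = float(row["reliability"]) if "reliability" in df.columns else None
        records[str(row["sample"])] = PhenotypeRecord(ebv, dereg, rel)
    return PhenotypeTable(records)


def read_genotype_table(path: str | Path) -> GenotypeMatrix:
    """Read a dosage-coded genotype table into a :class:`GenotypeMatrix`.

    Layout: one row per sample with a ``sample`` column, an optional ``breed``
    column, and one column per site whose header is the site ID. Cells are
    alt-allele dosage 0/1/2 or NA for a missing call.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample": str})
    if df["sample"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample IDs")
    samples = df["sample"].tolist()
    breed_of = (
        dict(zip(samples, df["breed"].astype(str))) if "breed" in df.columns else None
    )
    site_cols = [c for c in df.columns if c not in ("sample", "breed")]
    sites = [_site_from_label(c) for c in site_cols]
    calls = np.full((len(samples), len(site_cols)), MISSING, dtype=np.int8)
    for j, c in enumerate(site_cols):
        vals = pd.to_numeric(df[c], errors="coerce")
        ok = vals.notna()
        if not vals[ok].isin([0, 1, 2]).all():
            raise ValueError(f"{path}: column {c} has dosage outside 0/1/2")
        calls[ok.to_numpy(), j] = vals[ok].astype(np.int8)
    return GenotypeMatrix(sites, samples, calls, breed_of)


def write_genotype_table(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write a GenotypeMatrix as the dosage TSV read by read_genotype_table."""
    data: dict[str, object] = {"sample": matrix.samples, "breed": [matrix.breed_of[s] for s in matrix.samples]}
    for j, s in enumerate(matrix.sites):
        col = matrix.calls[:, j].astype(object)
        data[s.site_id] = ["NA" if v == MISSING else int(v) for v in col]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


_SITE_LABEL = re.compile(r"^(?:(?P<chrom>[^:]+):)?g\.(?P<pos>\d+)(?P<ref>[ACGT])>(?P<alt>[ACGT])$")


def _site_from_label(label: str) -> VariantSite:
    m = _SITE_LABEL.match(label)
    if m:
        return VariantSite(
            m.group("chrom") or "un", int(m.group("pos")), m.group("ref"), m.group("alt"), label
        )
    # opaque chip SNP name: synthesize a placeholder site
    return VariantSite("un", abs(hash(label)) % 10**8 + 1, "A", "C", label)
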