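"""Transcript-model SNV consequence classifier for loss-of-function screening.

Implements the minimal set of HIGH-impact consequence categories relevant to
single-nucleotide variants: stop gained, stop lost, start lost, and
donor/acceptor splice-site disruption. The splice window is the 2 intronic
bases flanking each exon (the canonical GT/AG footprint) and is configurable.
Only the annotated transcript is evaluated; there is no canonical-transcript
election. Frameshift and exon-loss categories apply to indels and are out of
scope: the screen is restricted to SNVs.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

from .variants import GeneModel, VariantSite

#: categories counted as high impact (loss-of-function class)
HIGH_IMPACT_CATEGORIES = frozenset(
    {"stop_gained", "stop_lost", "start_lost", "splice_donor", "splice_acceptor"}
)

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: default splice window: intronic bases within this distance of an exon
#: boundary are splice-site bases
DEFAULT_SPLICE_WINDOW = 2


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class EffectCall:
    site_id: str
    gene_symbol: str
    transcript_id: str
    category: str
    protein_change: str = ""
    feature_kind: str = ""  # "exon" | "intron" | "intergenic"
    feature_index: int = 0  # 1-based, transcript orientation

    def __post_init__(self) -> None:
        protein_categories = {"stop_gained", "stop_lost", "start_lost"}
        if (self.category in protein_categories) != bool(self.protein_change):
            raise ValueError(
                f"protein_change must be set exactly for protein-level categories; "
                f"got category={self.category!r} protein_change={self.protein_change!r}"
            )
        if self.category == "stop_gained" and not self.protein_change.endswith("*"):
            raise ValueError(f"stop notation must end with '*': {self.protein_change}")


@dataclass(frozen=True)
class TranscriptLocation:
    """Where a genomic position falls within one transcript.

    ``kind`` is exon/intron/intergenic; ``index`` is the 1-based exon or
    intron number in transcript orientation. ``cds_offset`` is the 1-based
    position within the spliced coding sequence (transcript orientation,
    minus-strand transcripts read right-to-left), or None outside the CDS.
    For intronic positions ``donor_offset``/``acceptor_offset`` give the
    1-based distance from the donor (5') and acceptor (3') end of the intron.
    """

    kind: str
    index: int = 0
    cds_offset: int | None = None
    donor_offset: int | None = None
    acceptor_offset: int | None = None


def _cds_pieces(model: GeneModel) -> list[tuple[int, int]]:
    """Genomic-order exon fragments inside the CDS bounds."""
    pieces = []
    for a, b in model.exons:
        lo, hi = max(a, model.cds_start), min(b, model.cds_end)
        if lo <= hi:
            pieces.append((lo, hi))
    return pieces


def spliced_cds(model: GeneModel, genome) -> str:
    """Spliced coding sequence in transcript orientation (starts with ATG for
    a well-formed model)."""
    seq = "".join(genome.fetch(model.chrom, a, b) for a, b in _cds_pieces(model))
    return reverse_complement(seq) if model.strand == "-" else seq


def cds_offset_of(model: GeneModel, pos: int) -> int | None:
    """1-based offset of genomic ``pos`` within the spliced CDS, or None."""
    pieces = _cds_pieces(model)
    if model.strand == "+":
        off = 0
        for a, b in pieces:
            if a <= pos <= b:
                return off + (pos - a) + 1
            off += b - a + 1
    else:
        off = 0
        for a, b in reversed(pieces):
            if a <= pos <= b:
                return off + (b - pos) + 1
            off += b - a + 1
    return None


def locate_in_transcript(site: VariantSite, model: GeneModel) -> TranscriptLocation:
    """Locate a site within a transcript; never raises for off-transcript sites."""
    if site.chrom != model.chrom:
        raise ValueError(
            f"site {site.site_id} on {site.chrom} does not match transcript "
            f"{model.transcript_id} on {model.chrom}"
        )
    pos = site.pos
    if not model.contains(pos):
        return TranscriptLocation(kind="intergenic")
    n_exons = len(model.exons)
    for k, (a, b) in enumerate(model.exons, start=1):
        if a <= pos <= b:
            index = k if model.strand == "+" else n_exons - k + 1
            return TranscriptLocation(
                kind="exon", index=index, cds_offset=cds_offset_of(model, pos)
            )
    for k, (a, b) in enumerate(model.introns, start=1):
        if a <= pos <= b:
            if model.strand == "+":
                index = k
                donor_off = pos - a + 1
                acceptor_off = b - pos + 1
            else:
                index = (n_exons - 1) - k + 1
                donor_off = b - pos + 1
                acceptor_off = pos - a + 1
            return TranscriptLocation(
                kind="intron", index=index, donor_offset=donor_off, acceptor_offset=acceptor_off
            )
    raise AssertionError("unreachable: position inside span but in no exon/intron")


def _aa(codon: str) -> str:
    return str(Seq(codon).translate())


def classify_snv(
    site: VariantSite,
    model: GeneModel,
    genome,
    splice_window: int = DEFAULT_SPLICE_WINDOW,
) -> EffectCall:
    """Assign a consequence category to one SNV on one transcript.

    Splice calls take the 2 bp (configurable) intronic window on each side of
    an exon, in transcript orientation: donor on the 3' side of the upstream
    exon, acceptor on the 5' side of the downstream exon. Coding calls
    mutate the affected codon of the spliced CDS and compare against the
    standard codon table. Everything else — UTR exon bases, deep intron,
    off-transcript — is ``other``.
    """
    ref_base = genome.base(site.chrom, site.pos)
    if ref_base != site.ref:
        raise ValueError(
            f"reference mismatch at {site.site_id}: VCF says {site.ref}, genome has {ref_base}"
        )
    loc = locate_in_transcript(site, model)

    def call(category: str, protein_change: str = "") -> EffectCall:
        return EffectCall(
            site_id=site.site_id,
            gene_symbol=model.gene_symbol,
            transcript_id=model.transcript_id,
            category=category,
            protein_change=protein_change,
            feature_kind=loc.kind,
            feature_index=loc.index,
        )

    if loc.kind == "intron":
        if loc.donor_offset is not None and loc.donor_offset <= splice_window:
            return call("splice_donor")
        if loc.acceptor_offset is not None and loc.acceptor_offset <= splice_window:
            return call("splice_acceptor")
        return call("other")
    if loc.kind != "exon" or loc.cds_offset is None:
        return call("other")

    cds = spliced_cds(model, genome)
    off0 = loc.cds_offset - 1
    codon_idx = off0 // 3
    within = off0 % 3
    start = codon_idx * 3
    ref_codon = cds[start : start + 3]
    if len(ref_codon) < 3:
        return call("other")
    alt_tx = site.alt if model.strand == "+" else site.alt.translate(_COMPLEMENT)
    mut_codon = ref_codon[:within] + alt_tx + ref_codon[within + 1 :]
    codon_number = codon_idx + 1

    if codon_number == 1 and mut_codon != "ATG":
        return call("start_lost", f"p.M1{_aa(mut_codon)}")
    ref_is_stop = ref_codon in STOP_CODONS
    mut_is_stop = mut_codon in STOP_CODONS
    if mut_is_stop and not ref_is_stop:
        return call("stop_gained", f"p.{_aa(ref_codon)}{codon_number}*")
    if ref_is_stop and not mut_is_stop:
        return call("stop_lost", f"p.*{codon_number}{_aa(mut_codon)}")
    return call("other")


def is_high_impact(effect: EffectCall) -> bool:
    """True iff the consequence belongs to the loss-of-function class."""
    return effect.category in HIGH_IMPACT_CATEGORIES
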