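import numpy as np
import pytest

from lofscreen.io_formats import DictGenome
from lofscreen.variants import GeneModel

# Hand-built two-exon plus-strand toy gene.
#
# genomic layout (1-based):
#   1-10    TTTTTTTTTT          upstream pad
#   11-18   GGATGAAA            exon 1 (UTR5 "GG" + CDS start)
#   19-26   GTAAATAG            intron 1 (GT...AG)
#   27-34   TGGTAACC            exon 2 (CDS end + UTR3 "CC")
#   35-44   TTTTTTTTTT          downstream pad
#
# spliced CDS = ATG AAA TGG TAA  ->  protein M K W *
TOY_SEQ = "TTTTTTTTTT" + "GGATGAAA" + "GTAAATAG" + "TGGTAACC" + "TTTTTTTTTT"


@pytest.fixture(scope="session")
def toy_genome():
    return DictGenome({"t": TOY_SEQ})


@pytest.fixture(scope="session")
def toy_gene():
    return GeneModel(
        gene_symbol="TOY",
        transcript_id="toy_tx",
        chrom="t",
        strand="+",
        exons=[(11, 18), (27, 34)],
        cds_start=13,
        cds_end=32,
    )


def random_gene(rng, chrom="r", n_exons=None, strand=None):
    """Random multi-exon mini-gene plus its genome, built independently of
    the generator module: exon/intron layout assembled by hand."""
    from lofscreen.effect_annotation import reverse_complement

    stops = ("TAA", "TAG", "TGA")
    codons = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT" if a + b + c not in stops]
    n_exons = n_exons or int(rng.integers(2, 5))
    strand = strand or ("+" if rng.random() < 0.5 else "-")
    n_codons = int(rng.integers(10, 30))
    cds = "ATG" + "".join(rng.choice(codons) for _ in range(n_codons - 2)) + str(rng.choice(stops))
    bases = list("ACGT")
    utr5 = "".join(rng.choice(bases, size=int(rng.integers(4, 12))))
    utr3 = "".join(rng.choice(bases, size=int(rng.integers(4, 12))))
    exonic = utr5 + cds + utr3
    cuts = sorted(rng.choice(range(4, len(exonic) - 4), size=n_exons - 1, replace=False))
    bounds = [0, *cuts, len(exonic)]
    exon_seqs = [exonic[a:b] for a, b in zip(bounds, bounds[1:])]
    region_parts, local_exons, lpos = [], [], 1
    for k, es in enumerate(exon_seqs):
        region_parts.append(es)
        local_exons.append((lpos, lpos + len(es) - 1))
        lpos += len(es)
        if k < n_exons - 1:
            intron = "GT" + "".join(rng.choice(bases, size=int(rng.integers(8, 30)))) + "AG"
            region_parts.append(intron)
            lpos += len(intron)
    region = "".join(region_parts)
    pad5 = "".join(rng.choice(bases, size=20))
    pad3 = "".join(rng.choice(bases, size=20))
    offset = len(pad5)  # genomic start of region is offset+1

    def exonic_to_region(o):
        cum = 0
        for (ls, _), es in zip(local_exons, exon_seqs):
            if o <= cum + len(es):
                return ls + (o - cum) - 1
            cum += len(es)
        raise AssertionError

    cds_lo = exonic_to_region(len(utr5) + 1)
    cds_hi = exonic_to_region(len(utr5) + len(cds))
    length = len(region)
    if strand == "+":
        genome_seq = pad5 + region + pad3
        exons = [(offset + a, offset + b) for a, b in local_exons]
        cds_start, cds_end = offset + cds_lo, offset + cds_hi
    else:
        genome_seq = pad5 + reverse_complement(region) + pad3
        exons = sorted((offset + length - b + 1, offset + length - a + 1) for a, b in local_exons)
        cds_start = offset + length - cds_hi + 1
        cds_end = offset + length - cds_lo + 1
    model = GeneModel(
        gene_symbol="RND",
        transcript_id="rnd_tx",
        chrom=chrom,
        strand=strand,
        exons=exons,
        cds_start=cds_start,
        cds_end=cds_end,
    )
    return model, DictGenome({chrom: genome_seq})


@pytest.fixture(scope="session")
def sim_bundle():
    """One shared synthetic bundle at a fixed seed."""
    from lofscreen.synthetic_data import SimConfig, simulate_all

    return simulate_all(SimConfig(seed=11))
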