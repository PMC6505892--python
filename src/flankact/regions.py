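"""Extraction of the three region sequences around a (gene, insertion) pair.

UPS1K    -- the 1 kb immediately upstream of the translation start site on
            the gene's coding strand (core promoter proxy); the TLS base
            itself is excluded.
DISTANCE -- the genomic sequence between the TLS and the insertion junction,
            endpoints included, reported 5'->3' on the coding strand; its
            length in bp (minus one) is the enhancer-to-gene distance x.
MIDDLE   -- the 301 bp window centred on the central nucleotide of DISTANCE
            (chromatin-looping proxy); shorter when DISTANCE is.

The insertion junction coordinate stands in for the position of the 35S
enhancer tetramer carried on the T-DNA; an optional fixed offset can shift
it when the enhancer's offset inside the construct is known.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

from .io import GenomeAssembly, GeneModel, InsertionEvent

logger = logging.getLogger("flankact")

UPS1K_LENGTH = 1000
MIDDLE_LENGTH = 301

REGIONS = ("UPS1K", "DISTANCE", "MIDDLE")


@dataclass(frozen=True)
class RegionSequences:
    gene_id: str
    line_id: str
    ups1k: str
    distance_seq: str
    middle: str
    distance_bp: int
    location_class: str  # US / DS / IG


def extract_ups1k(genome: GenomeAssembly, gene: GeneModel) -> str:
    """The ≤1000 bases immediately 5' of the TLS, coding strand 5'->3'."""
    chrom_len = genome.length(gene.chrom)
    if gene.strand == "+":
        start = max(1, gene.tls - UPS1K_LENGTH)
        end = gene.tls - 1
        if end < start:
            raise ValueError(
                f"gene {gene.gene_id}: TLS at chromosome edge, no upstream sequence"
            )
        seq = genome.fetch(gene.chrom, start, end, "+")
    else:
        start = gene.tls + 1
        end = min(chrom_len, gene.tls + UPS1K_LENGTH)
        if end < start:
            raise ValueError(
                f"gene {gene.gene_id}: TLS at chromosome edge, no upstream sequence"
            )
        seq = genome.fetch(gene.chrom, start, end, "-")
    if len(seq) < UPS1K_LENGTH:
        logger.warning(
            "gene %s: upstream window truncated to %d nt by chromosome end",
            gene.gene_id,
            len(seq),
        )
        warnings.warn(
            f"gene {gene.gene_id}: upstream window truncated to {len(seq)} nt"
        )
    return seq


def compute_distance(gene: GeneModel, ins: InsertionEvent) -> int:
    """Absolute bp distance between the insertion junction and the TLS."""
    if gene.chrom != ins.chrom:
        raise ValueError(
            f"gene {gene.gene_id} on {gene.chrom} but insertion "
            f"{ins.line_id} on {ins.chrom}"
        )
    return abs(ins.position - gene.tls)


def extract_distance_seq(
    genome: GenomeAssembly, gene: GeneModel, ins: InsertionEvent
) -> str:
    """Genomic sequence between TLS and junction, inclusive, coding strand."""
    d = compute_distance(gene, ins)
    if d == 0:
        raise ValueError(
            f"{gene.gene_id}/{ins.line_id}: insertion coincides with the TLS, "
            "DISTANCE region is empty"
        )
    lo = min(gene.tls, ins.position)
    hi = max(gene.tls, ins.position)
    return genome.fetch(gene.chrom, lo, hi, gene.strand)


def extract_middle(distance_seq: str) -> str:
    """Up to 301 bp centred on the central nucleotide of DISTANCE.

    The central nucleotide sits at 1-based index ceil(L/2); for even L this
    biases the centre at most one base leftward.
    """
    if not distance_seq:
        raise ValueError("DISTANCE sequence is empty")
    L = len(distance_seq)
    c = math.ceil(L / 2)
    half = (MIDDLE_LENGTH - 1) // 2
    start = max(1, c - half)
    end = min(L, c + half)
    return distance_seq[start - 1 : end]


def classify_location(gene: GeneModel, ins: InsertionEvent) -> str:
    """US / DS / IG relative to the gene on its coding strand."""
    if gene.chrom != ins.chrom:
        raise ValueError("gene and insertion on different chromosomes")
    if gene.span_start <= ins.position <= gene.span_end:
        return "IG"
    upstream_on_forward = ins.position < gene.span_start
    if gene.strand == "+":
        return "US" if upstream_on_forward else "DS"
    return "DS" if upstream_on_forward else "US"


def extract_regions(
    genome: GenomeAssembly, gene: GeneModel, ins: InsertionEvent
) -> RegionSequences:
    """Full region triple for one (gene, insertion) pair."""
    d = compute_distance(gene, ins)
    distance_seq = extract_distance_seq(genome, gene, ins) if d > 0 else ""
    middle = extract_middle(distance_seq) if distance_seq else ""
    return RegionSequences(
        gene_id=gene.gene_id,
        line_id=ins.line_id,
        ups1k=extract_ups1k(genome, gene),
        distance_seq=distance_seq,
        middle=middle,
        distance_bp=d,
        location_class=classify_location(gene, ins),
    )
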