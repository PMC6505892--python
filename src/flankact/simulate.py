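"""Fully synthetic activation-tagging studies for testing every stage.

A study is a random genome, non-overlapping genes, one insertion per gene
at a distance drawn from the configured range, and Ac/NAc labels drawn
from the distance logistic.  Class-dependent signal is then planted:
consensus motifs are written into the UPS1K and MIDDLE regions with
probability q_Ac for activated records and q_NAc otherwise, and a CpG-rich
block can be planted per class at a configured rate.  A manifest records
every planted position and the true activation probability per record, so
tests can verify the plants by direct string comparison.

Insertion distances are drawn log-uniformly over the distance range; with
the default logistic coefficients this yields roughly a 2:1 Ac:NAc balance,
mirroring the 190:90 composition of the motivating training data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .distance import DEFAULT_BETA0, DEFAULT_BETA1
from .io import (
    DINUCLEOTIDES,
    GeneModel,
    GenomeAssembly,
    InsertionEvent,
    Motif,
    MotifLibrary,
    PropertyTable,
)
from .regions import RegionSequences, extract_regions

PLANTED_CONSENSUS = ("TGACGTCATG", "GGCCAATCAG")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SyntheticSpec:
    n_chromosomes: int = 6
    chrom_length: int = 4_500_000
    gc_fraction: float = 0.45
    n_genes: int = 360
    distance_range: tuple[int, int] = (100, 30_000)
    beta0: float = DEFAULT_BETA0
    beta1: float = DEFAULT_BETA1
    planted_motifs: tuple[str, ...] = PLANTED_CONSENSUS
    q_ac: float = 0.8
    q_nac: float = 0.2
    cpg_island_rate: dict = field(default_factory=lambda: {"Ac": 0.15, "NAc": 0.15})
    seed: int = 7

    def __post_init__(self):
        if not 0 < self.gc_fraction < 1 and self.gc_fraction not in (0.0, 1.0):
            raise ValueError("gc_fraction must be in [0, 1]")
        if not (0 <= self.q_ac <= 1 and 0 <= self.q_nac <= 1):
            raise ValueError("plant probabilities must be in [0, 1]")
        if self.distance_range[1] >= self.chrom_length:
            raise ValueError("distance range exceeds chromosome length")


@dataclass
class SyntheticStudy:
    genome: GenomeAssembly
    genes: list[GeneModel]
    insertions: list[InsertionEvent]
    labels: pd.DataFrame  # line_id, gene_id, label
    manifest: dict
    spec: SyntheticSpec

    def region_sequences(self) -> dict[str, RegionSequences]:
        """RegionSequences per record id ('gene|line')."""
        import warnings

        gene_by_id = {g.gene_id: g for g in self.genes}
        ins_by_id = {i.line_id: i for i in self.insertions}
        out = {}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for row in self.labels.itertuples(index=False):
                rid = f"{row.gene_id}|{row.line_id}"
                out[rid] = extract_regions(
                    self.genome, gene_by_id[row.gene_id], ins_by_id[row.line_id]
                )
        return out

    def label_map(self) -> dict[str, str]:
        return {
            f"{row.gene_id}|{row.line_id}": row.label
            for row in self.labels.itertuples(index=False)
        }


# ---------------------------------------------------------------------------
# genome


def generate_genome(spec: SyntheticSpec) -> GenomeAssembly:
    """i.i.d. bases at the configured GC fraction, seeded."""
    rng = np.random.default_rng(spec.seed)
    chroms = {}
    p_gc = spec.gc_fraction / 2.0
    p_at = (1.0 - spec.gc_fraction) / 2.0
    probs = np.array([p_at, p_gc, p_gc, p_at])
    for c in range(spec.n_chromosomes):
        draw = rng.choice(4, size=spec.chrom_length, p=probs)
        chroms[f"chr{c + 1}"] = _BASES[draw].tobytes().decode("ascii")
    return GenomeAssembly(chroms)


# ---------------------------------------------------------------------------
# genes + insertions


def generate_genes_and_insertions(
    spec: SyntheticSpec, genome: GenomeAssembly
) -> tuple[list[GeneModel], list[InsertionEvent]]:
    """Place non-overlapping genes and one insertion per gene.

    Each gene occupies a slot wide enough for the upstream kilobase and the
    maximum insertion distance on either side; distances are log-uniform
    over the configured range, side (5'/3') a fair coin.
    """
    rng = np.random.default_rng(spec.seed + 1)
    d_lo, d_hi = spec.distance_range
    margin = d_hi + 2_000
    slot = 2 * margin + 4_000
    per_chrom = (spec.chrom_length - 2_000) // slot
    capacity = per_chrom * spec.n_chromosomes
    if capacity < spec.n_genes:
        raise ValueError(
            f"cannot place {spec.n_genes} genes without overlap; "
            f"capacity {capacity} -- use longer chromosomes"
        )
    genes: list[GeneModel] = []
    insertions: list[InsertionEvent] = []
    g = 0
    for c in range(spec.n_chromosomes):
        chrom = f"chr{c + 1}"
        for s in range(per_chrom):
            if g >= spec.n_genes:
                break
            centre = 1_000 + s * slot + margin + int(rng.integers(0, 2_000))
            length = int(rng.integers(1_000, 3_000))
            span_start = centre
            span_end = centre + length
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "+":
                tls = span_start + int(rng.integers(0, min(300, length)))
            else:
                tls = span_end - int(rng.integers(0, min(300, length)))
            gene = GeneModel(
                gene_id=f"G{g + 1:04d}",
                chrom=chrom,
                strand=strand,
                tls=tls,
                span_start=span_start,
                span_end=span_end,
            )
            genes.append(gene)
            d = int(round(math.exp(rng.uniform(math.log(d_lo), math.log(d_hi)))))
            d = min(max(d, d_lo), d_hi)
            side = 1 if rng.random() < 0.5 else -1
            pos = tls + side * d
            pos = min(max(pos, 1), genome.length(chrom))
            insertions.append(
                InsertionEvent(
                    line_id=f"L{g + 1:04d}",
                    chrom=chrom,
                    position=pos,
                    tdna_orientation="+" if rng.random() < 0.5 else "-",
                )
            )
            g += 1
    return genes, insertions


# ---------------------------------------------------------------------------
# labels + planted signal


def _region_to_genomic(
    window_lo: int, window_hi: int, strand: str, offset: int, width: int
) -> tuple[int, int]:
    """Genomic (start, end) of a width-``width`` plant at 1-based region
    ``offset`` within the window [window_lo, window_hi] read on ``strand``."""
    if strand == "+":
        start = window_lo + offset - 1
        return start, start + width - 1
    end = window_hi - offset + 1
    return end - width + 1, end


def _write_plant(
    chrom_arr: bytearray, start: int, end: int, strand: str, motif: str
) -> None:
    from .io import reverse_complement

    s = motif if strand == "+" else reverse_complement(motif)
    chrom_arr[start - 1 : end] = s.encode("ascii")


def assign_labels_and_plant_signal(
    spec: SyntheticSpec,
    genome: GenomeAssembly,
    genes: list[GeneModel],
    insertions: list[InsertionEvent],
) -> SyntheticStudy:
    """Draw Ac/NAc labels from the distance logistic and plant class signal."""
    rng = np.random.default_rng(spec.seed + 2)
    arrays = {c: bytearray(s, "ascii") for c, s in genome.chromosomes.items()}
    gene_by_id = {g.gene_id: g for g in genes}
    rows = []
    plants = []
    true_pi = {}
    max_w = max((len(m) for m in spec.planted_motifs), default=0)
    for gene, ins in zip(genes, insertions):
        d = abs(ins.position - gene.tls)
        eta = np.clip(spec.beta0 + spec.beta1 * d, -700, 700)
        pi = float(1.0 / (1.0 + np.exp(-eta)))
        label = "Ac" if rng.random() < pi else "NAc"
        rid = f"{gene.gene_id}|{ins.line_id}"
        true_pi[rid] = pi
        rows.append({"line_id": ins.line_id, "gene_id": gene.gene_id, "label": label})

        used: list[tuple[int, int]] = []  # genomic intervals already written

        def _place(window_lo, window_hi, win_len, width, strand):
            """Sample a non-overlapping region offset; None if congested."""
            for _ in range(60):
                off = int(rng.integers(1, win_len - width + 2))
                gs, ge = _region_to_genomic(window_lo, window_hi, strand, off, width)
                if all(ge < s or gs > e for s, e in used):
                    used.append((gs, ge))
                    return off, gs, ge
            return None

        q = spec.q_ac if label == "Ac" else spec.q_nac
        planted = rng.random() < q
        if planted and spec.planted_motifs:
            # UPS1K window on the coding strand
            if gene.strand == "+":
                u_lo, u_hi = max(1, gene.tls - 1000), gene.tls - 1
            else:
                u_lo, u_hi = gene.tls + 1, min(
                    genome.length(gene.chrom), gene.tls + 1000
                )
            u_len = u_hi - u_lo + 1
            # MIDDLE window inside DISTANCE
            lo, hi = min(gene.tls, ins.position), max(gene.tls, ins.position)
            L = hi - lo + 1
            c = math.ceil(L / 2)
            m_start = max(1, c - 150)
            m_end = min(L, c + 150)
            m_len = m_end - m_start + 1
            for motif in spec.planted_motifs:
                w = len(motif)
                if w > u_len or w > m_len:
                    raise ValueError(
                        f"planted motif ({w} nt) longer than target region"
                    )
                hit = _place(u_lo, u_hi, u_len, w, gene.strand)
                if hit is not None:
                    off_u, gs, ge = hit
                    _write_plant(arrays[gene.chrom], gs, ge, gene.strand, motif)
                    plants.append(
                        {"record": rid, "region": "UPS1K", "offset": off_u,
                         "motif": motif}
                    )
                # MIDDLE offsets are sampled within the 301-nt window but
                # written through DISTANCE coordinates
                for _ in range(60):
                    off_m = int(rng.integers(1, m_len - w + 2))
                    off_d = m_start + off_m - 1
                    gs, ge = _region_to_genomic(lo, hi, gene.strand, off_d, w)
                    if all(ge < s or gs > e for s, e in used):
                        used.append((gs, ge))
                        _write_plant(arrays[gene.chrom], gs, ge, gene.strand, motif)
                        plants.append(
                            {"record": rid, "region": "MIDDLE", "offset": off_m,
                             "motif": motif}
                        )
                        break
        rate = spec.cpg_island_rate.get(label, 0.0)
        if rng.random() < rate:
            # CpG-rich block in UPS1K: 250 nt of strongly CG-biased sequence
            block_len = 250
            if gene.strand == "+":
                u_lo, u_hi = max(1, gene.tls - 1000), gene.tls - 1
            else:
                u_lo, u_hi = gene.tls + 1, min(
                    genome.length(gene.chrom), gene.tls + 1000
                )
            u_len = u_hi - u_lo + 1
            if u_len > block_len:
                block = "".join(
                    rng.choice(["CG", "GC", "CC", "GG", "CA", "TG"], p=[0.45, 0.2, 0.1, 0.1, 0.075, 0.075])
                    for _ in range(block_len // 2)
                )
                hit = _place(u_lo, u_hi, u_len, block_len, gene.strand)
                if hit is not None:
                    off, gs, ge = hit
                    _write_plant(arrays[gene.chrom], gs, ge, gene.strand, block)
                    plants.append(
                        {"record": rid, "region": "UPS1K", "offset": off,
                         "motif": block}
                    )
    mutated = GenomeAssembly(
        {c: arr.decode("ascii") for c, arr in arrays.items()}
    )
    labels = pd.DataFrame(rows, columns=["line_id", "gene_id", "label"])
    manifest = {"plants": plants, "true_pi": true_pi}
    return SyntheticStudy(
        genome=mutated,
        genes=genes,
        insertions=insertions,
        labels=labels,
        manifest=manifest,
        spec=spec,
    )


def generate_study(spec: SyntheticSpec | None = None) -> SyntheticStudy:
    spec = spec or SyntheticSpec()
    genome = generate_genome(spec)
    genes, insertions = generate_genes_and_insertions(spec, genome)
    return assign_labels_and_plant_signal(spec, genome, genes, insertions)


# ---------------------------------------------------------------------------
# auxiliary synthetic inputs


def synthetic_motif_library(
    consensus: tuple[str, ...] = PLANTED_CONSENSUS,
    n_decoys: int = 8,
    strength: float = 0.91,
    seed: int = 11,
) -> MotifLibrary:
    """PWMs concentrated on the given consensus strings plus random decoys."""
    rng = np.random.default_rng(seed)
    motifs = []
    base_index = {b: i for i, b in enumerate("ACGT")}

    def pwm_from(seq: str) -> np.ndarray:
        w = len(seq)
        pwm = np.full((w, 4), (1.0 - strength) / 3.0)
        for j, b in enumerate(seq):
            pwm[j, base_index[b]] = strength
        return pwm

    for i, cons in enumerate(consensus):
        motifs.append(Motif(f"planted{i + 1}", pwm_from(cons), len(cons)))
    for i in range(n_decoys):
        w = int(rng.integers(6, 11))
        seq = "".join(rng.choice(list("ACGT")) for _ in range(w))
        motifs.append(Motif(f"decoy{i + 1:02d}", pwm_from(seq), w))
    return MotifLibrary(motifs=motifs)


def synthetic_property_table(n_properties: int = 125, seed: int = 13) -> PropertyTable:
    """Random dinucleotide property table standing in for a measured one.

    Synthetic: values are seeded Gaussians with per-property scale and
    offset, full rank with probability one -- structurally equivalent to a
    DiProDB-style table but with no physical meaning.
    """
    rng = np.random.default_rng(seed)
    scale = rng.uniform(0.5, 20.0, size=n_properties)
    offset = rng.uniform(-5.0, 5.0, size=n_properties)
    vals = rng.normal(size=(16, n_properties)) * scale + offset
    df = pd.DataFrame(
        vals,
        index=DINUCLEOTIDES,
        columns=[f"prop{j + 1:03d}" for j in range(n_properties)],
    )
    return PropertyTable(values=df)


def worked_fixture() -> SyntheticStudy:
    """Deterministic miniature study: 2 chromosomes, 6 genes, 8 insertions.

    Two genes carry two insertion lines each (the repeat-observation case);
    one insertion sits exactly 301 bp from its gene's TLS so MIDDLE equals
    the whole DISTANCE region.  Every derived value is frozen in the test
    suite.
    """
    rng = np.random.default_rng(424242)
    chroms = {
        "c1": _BASES[rng.integers(0, 4, size=9000)].tobytes().decode(),
        "c2": _BASES[rng.integers(0, 4, size=7000)].tobytes().decode(),
    }
    genome = GenomeAssembly(chroms)
    genes = [
        GeneModel("g1", "c1", "+", 3001, 3001, 4200),
        GeneModel("g2", "c1", "-", 6400, 5200, 6500),
        GeneModel("g3", "c1", "+", 8050, 8000, 8900),
        GeneModel("g4", "c2", "-", 2980, 2000, 3000),
        GeneModel("g5", "c2", "+", 4500, 4450, 5300),
        GeneModel("g6", "c2", "-", 6800, 6100, 6900),
    ]
    insertions = [
        InsertionEvent("t1", "c1", 2500, "+"),   # g1, US, d=501
        InsertionEvent("t2", "c1", 2701, "-"),   # g1, US, d=300 -> MIDDLE == DISTANCE
        InsertionEvent("t3", "c1", 7000, "+"),   # g2, US (- strand), d=600
        InsertionEvent("t4", "c1", 8500, "-"),   # g3, IG, d=450
        InsertionEvent("t5", "c2", 1200, "+"),   # g4, DS (- strand), d=1780
        InsertionEvent("t6", "c2", 5100, "-"),   # g5, IG, d=600
        InsertionEvent("t7", "c2", 6950, "+"),   # g6, US, d=150
        InsertionEvent("t8", "c2", 4100, "+"),   # g5, US, d=400 (second line on g5)
    ]
    labels = pd.DataFrame(
        [
            ("t1", "g1", "Ac"),
            ("t2", "g1", "Ac"),
            ("t3", "g2", "NAc"),
            ("t4", "g3", "Ac"),
            ("t5", "g4", "NAc"),
            ("t6", "g5", "Ac"),
            ("t7", "g6", "Ac"),
            ("t8", "g5", "NAc"),
        ],
        columns=["line_id", "gene_id", "label"],
    )
    spec = SyntheticSpec(
        n_chromosomes=2,
        chrom_length=9000,
        n_genes=6,
        distance_range=(100, 2000),
        seed=424242,
    )
    return SyntheticStudy(
        genome=genome,
        genes=genes,
        insertions=insertions,
        labels=labels,
        manifest={"plants": [], "true_pi": {}},
        spec=spec,
    )
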