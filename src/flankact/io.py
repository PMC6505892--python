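"""Readers and writers for the standard formats the pipeline touches.

Genomic coordinates are 1-based inclusive throughout (GFF3 convention).
The translation start site (TLS) of a gene is the single coordinate of the
first base of the start codon: the minimum CDS start on the plus strand,
the maximum CDS end on the minus strand.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs as bio_motifs

logger = logging.getLogger("flankact")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

PWM_PSEUDOCOUNT = 1e-4  # replaces exact zeros before renormalisation


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# genome


class GenomeAssembly:
    """Named chromosome sequences with strand-aware 1-based inclusive lookup."""

    def __init__(self, chromosomes: dict[str, str]):
        if not chromosomes:
            raise ValueError("assembly has no chromosomes")
        norm = {}
        for name, seq in chromosomes.items():
            if not seq:
                raise ValueError(f"chromosome {name!r} is empty")
            norm[name] = seq.upper()
        self._chroms = norm

    @property
    def chromosomes(self) -> dict[str, str]:
        return self._chroms

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._chroms

    def length(self, chrom: str) -> int:
        return len(self._chroms[chrom])

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        """Sequence of ``chrom`` between ``start`` and ``end`` inclusive.

        Minus-strand lookups return the reverse complement, so the result is
        always read 5'->3' on the requested strand.
        """
        if chrom not in self._chroms:
            raise KeyError(f"unknown chromosome {chrom!r}")
        seq = self._chroms[chrom]
        if start < 1 or end > len(seq) or start > end:
            raise ValueError(
                f"coordinates {start}-{end} out of bounds for {chrom} "
                f"(length {len(seq)})"
            )
        sub = seq[start - 1 : end]
        if strand == "-":
            return reverse_complement(sub)
        if strand != "+":
            raise ValueError(f"strand must be '+' or '-', got {strand!r}")
        return sub


def read_genome(path: str | Path) -> GenomeAssembly:
    """Load a FASTA file into a :class:`GenomeAssembly` (uppercased)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    chroms: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in chroms:
            raise ValueError(f"duplicate chromosome name {rec.id!r}")
        chroms[rec.id] = str(rec.seq).upper()
    return GenomeAssembly(chroms)


def write_genome(assembly: GenomeAssembly, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in assembly.chromosomes.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# gene models


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    tls: int
    span_start: int
    span_end: int

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (self.span_start <= self.tls <= self.span_end):
            raise ValueError(
                f"gene {self.gene_id}: TLS {self.tls} outside span "
                f"{self.span_start}-{self.span_end}"
            )


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Parse gene + CDS features from GFF3; TLS from the CDS extremity.

    Genes without any CDS are skipped with a warning.
    """
    import gffutils

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        cds = list(db.children(g, featuretype="CDS"))
        if not cds:
            logger.warning("gene %s has no CDS; skipped", g.id)
            warnings.warn(f"gene {g.id} has no CDS; skipped")
            continue
        if g.strand == "+":
            tls = min(c.start for c in cds)
        else:
            tls = max(c.end for c in cds)
        genes.append(
            GeneModel(
                gene_id=g.id,
                chrom=g.seqid,
                strand=g.strand,
                tls=tls,
                span_start=g.start,
                span_end=g.end,
            )
        )
    return genes


def write_gene_models(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write genes as minimal GFF3 (gene + single-CDS features)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id}"
            fh.write(
                f"{g.chrom}\tflankact\tgene\t{g.span_start}\t{g.span_end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )
            if g.strand == "+":
                c_start, c_end = g.tls, g.span_end
            else:
                c_start, c_end = g.span_start, g.tls
            fh.write(
                f"{g.chrom}\tflankact\tCDS\t{c_start}\t{c_end}\t.\t"
                f"{g.strand}\t0\tID=cds-{g.gene_id};Parent={g.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# insertions


@dataclass(frozen=True)
class InsertionEvent:
    line_id: str
    chrom: str
    position: int
    tdna_orientation: str = "unknown"  # '+', '-', or 'unknown'


def read_insertions(path: str | Path) -> list[InsertionEvent]:
    """TSV with header line_id, chrom, position[, orientation]."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"line_id", "chrom", "position"}
    if not required.issubset(df.columns):
        raise ValueError(f"insertion TSV must have columns {sorted(required)}")
    events = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            pos = int(row.position)
        except (TypeError, ValueError):
            raise ValueError(
                f"row {i}: position {row.position!r} is not an integer"
            ) from None
        ori = getattr(row, "orientation", None)
        if ori is None or pd.isna(ori) or ori not in ("+", "-"):
            ori = "unknown"
        events.append(InsertionEvent(row.line_id, row.chrom, pos, ori))
    return events


def write_insertions(events: Iterable[InsertionEvent], path: str | Path) -> None:
    rows = [
        (e.line_id, e.chrom, e.position, e.tdna_orientation) for e in events
    ]
    pd.DataFrame(
        rows, columns=["line_id", "chrom", "position", "orientation"]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# motif library


@dataclass(frozen=True)
class Motif:
    motif_id: str
    pwm: np.ndarray  # shape (width, 4), columns A,C,G,T; rows sum to 1
    width: int


@dataclass
class MotifLibrary:
    """Ordered PWM collection; order defines the motif index and is persisted."""

    motifs: list[Motif]
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )

    def __len__(self) -> int:
        return len(self.motifs)

    def checksum(self) -> str:
        h = hashlib.sha256()
        for m in self.motifs:
            h.update(m.motif_id.encode())
            h.update(np.ascontiguousarray(m.pwm, dtype=np.float64).tobytes())
        h.update(np.ascontiguousarray(self.background, dtype=np.float64).tobytes())
        return h.hexdigest()


def _normalise_pwm(mat: np.ndarray, motif_id: str) -> np.ndarray:
    sums = mat.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 0.01):
        raise ValueError(
            f"motif {motif_id}: PWM rows must sum to 1 (max deviation "
            f"{np.max(np.abs(sums - 1.0)):.3g})"
        )
    mat = mat / sums[:, None]
    mat = np.where(mat <= 0.0, PWM_PSEUDOCOUNT, mat)
    return mat / mat.sum(axis=1, keepdims=True)


def read_motif_library(path: str | Path) -> MotifLibrary:
    """Parse a MEME minimal-format motif file into a :class:`MotifLibrary`.

    Zero probabilities are replaced by a small pseudocount and each position
    renormalised, so log-odds scores stay finite.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if "MOTIF" not in path.read_text():
        raise ValueError("no motifs found")
    with open(path) as fh:
        try:
            parsed = bio_motifs.parse(fh, "minimal")
        except Exception as exc:  # malformed file
            raise ValueError(f"could not parse MEME file {path}: {exc}") from exc
    if not parsed:
        raise ValueError("no motifs found")
    out: list[Motif] = []
    background = np.full(4, 0.25)
    for m in parsed:
        if m.length == 0:
            raise ValueError(f"motif {m.name}: width 0")
        counts = np.array(
            [m.counts[b] for b in "ACGT"], dtype=float
        ).T  # (width, 4)
        totals = counts.sum(axis=1, keepdims=True)
        pwm = _normalise_pwm(counts / totals, m.name)
        out.append(Motif(motif_id=m.name, pwm=pwm, width=m.length))
        if m.background:
            background = np.array([m.background[b] for b in "ACGT"], dtype=float)
            background = background / background.sum()
    return MotifLibrary(motifs=out, background=background)


def write_motif_library(library: MotifLibrary, path: str | Path) -> None:
    bg = library.background
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(
            f"A {bg[0]:.5f} C {bg[1]:.5f} G {bg[2]:.5f} T {bg[3]:.5f}\n\n"
        )
        for m in library.motifs:
            fh.write(f"MOTIF {m.motif_id}\n")
            # large nsites keeps parser count-rounding loss negligible
            fh.write(
                f"letter-probability matrix: alength= 4 w= {m.width} "
                f"nsites= 1000000 E= 0\n"
            )
            for row in m.pwm:
                fh.write(" " + " ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# dinucleotide property table

DINUCLEOTIDES = [a + b for a in "ACGT" for b in "ACGT"]


@dataclass
class PropertyTable:
    """16 dinucleotides x P physicochemical property values."""

    values: pd.DataFrame  # index = dinucleotides, columns = property names

    def __post_init__(self):
        if list(self.values.index) != DINUCLEOTIDES:
            raise ValueError(
                "property table must have exactly the 16 dinucleotides "
                "AA..TT as rows, in lexicographic order"
            )

    @property
    def n_properties(self) -> int:
        return self.values.shape[1]


def read_property_table(path: str | Path) -> PropertyTable:
    """TSV: first column dinucleotide, remaining columns named properties."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    df = df.reindex(DINUCLEOTIDES)
    if df.isna().any().any():
        raise ValueError("property table missing dinucleotide rows or values")
    return PropertyTable(values=df.astype(float))


def write_property_table(table: PropertyTable, path: str | Path) -> None:
    table.values.to_csv(path, sep="\t", index_label="dinucleotide")


# ---------------------------------------------------------------------------
# labels


def read_labels(path: str | Path) -> pd.DataFrame:
    """TSV with columns line_id, gene_id, label (Ac / NAc)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"line_id", "gene_id", "label"}
    if not required.issubset(df.columns):
        raise ValueError(f"label TSV must have columns {sorted(required)}")
    bad = set(df["label"]) - {"Ac", "NAc"}
    if bad:
        raise ValueError(f"unknown labels {sorted(bad)}; expected Ac/NAc")
    return df[["line_id", "gene_id", "label"]]


def write_labels(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# model bundle

BUNDLE_FORMAT_VERSION = 1


def save_bundle(model, out_dir: str | Path) -> None:
    """Persist a trained TwoLayerModel as a directory.

    Layout: ``manifest.json`` (format version, motif checksum, masks,
    training metadata, seeds) + ``estimators.joblib`` holding the fitted
    scikit-learn objects.
    """
    import joblib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "format_version": BUNDLE_FORMAT_VERSION,
        "motif_checksum": model.motif_library.checksum(),
        "seed": model.seed,
        "combo": sorted(model.combo),
        "distance": {
            "beta0": model.distance_model.beta0,
            "beta1": model.distance_model.beta1,
        },
        "weighting": model.config.weighting,
        "pattern_masks": {
            key: {
                "mask": mask.mask.astype(int).tolist(),
                "p_values": mask.p_values.tolist(),
            }
            for key, mask in model.masks.items()
        },
        "layer_one_pairs": [list(p) for p in model.layer_one_order],
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    joblib.dump(model, out / "estimators.joblib")


def load_bundle(in_dir: str | Path):
    import joblib

    in_dir = Path(in_dir)
    with open(in_dir / "manifest.json") as fh:
        manifest = json.load(fh)
    if manifest["format_version"] != BUNDLE_FORMAT_VERSION:
        raise ValueError(
            f"unsupported bundle format version {manifest['format_version']}"
        )
    model = joblib.load(in_dir / "estimators.joblib")
    if model.motif_library.checksum() != manifest["motif_checksum"]:
        raise ValueError("motif library checksum mismatch in bundle")
    return model
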