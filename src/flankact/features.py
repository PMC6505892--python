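"""The four promoter feature encodings and the significant-pattern filter.

N-gram -- overlapping k-mer counts for k in 3..6, one column per k-mer,
          5440 columns in total (64+256+1024+4096).
Motif  -- per PWM in the library, six channels summarising its occurrences
          on the promoter: number, conservation (mean log-odds score),
          plus/minus strand fractions, density, and mean distance of the
          occurrences to the translation start site; 6*M columns.
NPC    -- dinucleotide counts weighted by PCA-reduced physicochemical
          property values, normalised by the number of dinucleotide
          windows; 16 x 15 = 240 columns.
CGI    -- five summary statistics of predicted CpG islands.

Motif occurrences come from a FIMO-style scan: log-odds against a 0-order
background, with per-position p-values computed from the exact score
distribution of the quantized PWM under that background (dynamic program
over score-discretized columns).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import DINUCLEOTIDES, Motif, MotifLibrary, PropertyTable

logger = logging.getLogger("flankact")

NGRAM_KS = (3, 4, 5, 6)
NGRAM_DIM = sum(4**k for k in NGRAM_KS)  # 5440
MOTIF_CHANNELS = ("number", "conserve", "pos_ori", "neg_ori", "density", "dis_tls")
NPC_COMPONENTS = 15
NPC_DIM = 16 * NPC_COMPONENTS
CGI_CHANNELS = ("number", "length_ratio", "dis", "cg_ratio", "oe")

FIMO_P_THRESHOLD = 1e-4  # FIMO's default per-occurrence p-value cutoff

_BASE_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i


def _encode_bases(seq: str) -> np.ndarray:
    """Map A,C,G,T -> 0..3 and anything else (N) -> -1."""
    return _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


# ---------------------------------------------------------------------------
# N-gram


def ngram_names() -> list[str]:
    names = []
    for k in NGRAM_KS:
        for kmer in itertools.product("ACGT", repeat=k):
            names.append(f"{k}mer:{''.join(kmer)}")
    return names


def count_ngrams(seq: str) -> np.ndarray:
    """Overlapping k-mer counts for k=3..6, concatenated (length 5440).

    Windows containing N are skipped; counts are raw occurrences, not
    length-normalised.
    """
    arr = _encode_bases(seq.upper())
    out = np.zeros(NGRAM_DIM, dtype=np.float64)
    offset = 0
    for k in NGRAM_KS:
        n_windows = len(arr) - k + 1
        if n_windows > 0:
            win = np.lib.stride_tricks.sliding_window_view(arr, k)
            valid = (win >= 0).all(axis=1)
            if valid.any():
                powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
                codes = (win[valid].astype(np.int64) * powers).sum(axis=1)
                out[offset : offset + 4**k] = np.bincount(
                    codes, minlength=4**k
                )
        offset += 4**k
    return out


# ---------------------------------------------------------------------------
# motif scanning


@dataclass(frozen=True)
class MotifOccurrence:
    motif_id: str
    start: int  # 1-based on the scanned sequence
    end: int
    strand: str
    score: float  # log2 odds vs background
    pvalue: float


@dataclass
class _ScanTables:
    int_scores_fwd: np.ndarray  # (width, 4) quantized log-odds
    int_scores_rev: np.ndarray
    survival: np.ndarray  # p-value for each achievable integer total
    eps: float


_SCAN_BINS = 1000  # quantization bins per PWM (FIMO uses a comparable grid)


def _prepare_scan(motif: Motif, background: np.ndarray) -> _ScanTables:
    lodds = np.log2(motif.pwm / background[None, :])  # (w, 4)
    lo = lodds.min(axis=1).sum()
    hi = lodds.max(axis=1).sum()
    eps = max((hi - lo) / _SCAN_BINS, 1e-12)
    int_fwd = np.rint((lodds - lodds.min(axis=1, keepdims=True)) / eps).astype(
        np.int64
    )
    # reverse-complement PWM: reverse positions, swap A<->T, C<->G
    int_rev = int_fwd[::-1, ::-1].copy()
    # exact distribution of the integer total under the background
    pmf = np.array([1.0])
    for j in range(motif.width):
        col = np.zeros(int_fwd[j].max() + 1)
        np.add.at(col, int_fwd[j], background)
        pmf = np.convolve(pmf, col)
    survival = np.cumsum(pmf[::-1])[::-1]
    survival = np.minimum(survival, 1.0)
    return _ScanTables(int_fwd, int_rev, survival, eps)


def _window_int_scores(arr: np.ndarray, table: np.ndarray) -> np.ndarray:
    """Quantized scores of every window; windows containing N get -1."""
    w = table.shape[0]
    if len(arr) < w:
        return np.empty(0, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(arr, w)
    valid = (win >= 0).all(axis=1)
    scores = np.full(win.shape[0], -1, dtype=np.int64)
    if valid.any():
        idx = np.clip(win[valid], 0, 3)
        scores[valid] = table[np.arange(w)[None, :], idx].sum(axis=1)
    return scores


class MotifScanner:
    """Both-strand PWM scanner with per-motif score tables cached once."""

    def __init__(self, library: MotifLibrary, p_threshold: float = FIMO_P_THRESHOLD):
        self.library = library
        self.p_threshold = p_threshold
        self._tables = [_prepare_scan(m, library.background) for m in library.motifs]
        self._lodds = [
            np.log2(m.pwm / library.background[None, :]) for m in library.motifs
        ]

    def scan(self, seq: str) -> list[MotifOccurrence]:
        arr = _encode_bases(seq.upper())
        hits: list[MotifOccurrence] = []
        for motif, tables, lodds in zip(
            self.library.motifs, self._tables, self._lodds
        ):
            for strand, int_table, real_table in (
                ("+", tables.int_scores_fwd, lodds),
                ("-", tables.int_scores_rev, lodds[::-1, ::-1]),
            ):
                ints = _window_int_scores(arr, int_table)
                if ints.size == 0:
                    continue
                ok = ints >= 0
                pvals = np.ones_like(ints, dtype=float)
                pvals[ok] = tables.survival[
                    np.minimum(ints[ok], len(tables.survival) - 1)
                ]
                keep = ok & (pvals <= self.p_threshold)
                for pos in np.nonzero(keep)[0]:
                    w = motif.width
                    real = real_table[
                        np.arange(w), np.clip(arr[pos : pos + w], 0, 3)
                    ].sum()
                    hits.append(
                        MotifOccurrence(
                            motif_id=motif.motif_id,
                            start=int(pos) + 1,
                            end=int(pos) + w,
                            strand=strand,
                            score=float(real),
                            pvalue=float(pvals[pos]),
                        )
                    )
        hits.sort(key=lambda h: (h.start, h.motif_id, h.strand))
        return hits


def scan_motifs(
    seq: str,
    library: MotifLibrary,
    p_threshold: float = FIMO_P_THRESHOLD,
) -> list[MotifOccurrence]:
    """Scan both strands of ``seq`` with every PWM in the library.

    Returns occurrences with p-value <= ``p_threshold`` sorted by start.
    Motifs wider than the sequence yield no occurrences.
    """
    return MotifScanner(library, p_threshold).scan(seq)


def motif_names(library: MotifLibrary) -> list[str]:
    return [
        f"motif{i:04d}:{ch}"
        for i in range(len(library))
        for ch in MOTIF_CHANNELS
    ]


def encode_motifs(
    occurrences: list[MotifOccurrence],
    library: MotifLibrary,
    seq_len: int,
    tls_offset: int,
) -> np.ndarray:
    """Six summary channels per library motif (vector length 6*M).

    ``tls_offset`` is the position of the TLS relative to the scanned
    sequence; for UPS1K it is seq_len + 1 (the TLS sits one base past the
    3' end).  Motifs with no occurrences contribute six zeros.
    """
    width_by_id = {m.motif_id: m.width for m in library.motifs}
    index_by_id = {m.motif_id: i for i, m in enumerate(library.motifs)}
    out = np.zeros(6 * len(library), dtype=np.float64)
    by_motif: dict[str, list[MotifOccurrence]] = {}
    for occ in occurrences:
        by_motif.setdefault(occ.motif_id, []).append(occ)
    for motif_id, occs in by_motif.items():
        if motif_id not in index_by_id:
            raise KeyError(f"occurrence for unknown motif {motif_id!r}")
        i = index_by_id[motif_id]
        n = len(occs)
        width = width_by_id[motif_id]
        starts = np.array(sorted(o.start for o in occs))
        ends = np.array([o.end for o in occs])
        span = int(ends.max() - starts.min() + 1)  # = width when n == 1
        base = 6 * i
        out[base + 0] = n
        out[base + 1] = float(np.mean([o.score for o in occs]))
        pos = sum(1 for o in occs if o.strand == "+")
        out[base + 2] = pos / n
        out[base + 3] = (n - pos) / n
        out[base + 4] = width * n / span
        out[base + 5] = float(np.mean([abs(tls_offset - o.start) for o in occs]))
    return out


# ---------------------------------------------------------------------------
# NPC


def reduce_property_table(table: PropertyTable, k: int = NPC_COMPONENTS) -> PropertyTable:
    """Project the property table onto its top-k principal components.

    Columns are centred and scaled to unit variance first.  The sign of each
    component is fixed so its largest-magnitude loading is positive, making
    the reduction deterministic.
    """
    from sklearn.decomposition import PCA

    X = table.values.to_numpy(dtype=float)
    if X.shape[1] < k:
        raise ValueError(
            f"need at least {k} properties, table has {X.shape[1]}"
        )
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("property table has constant columns; rank deficient")
    Z = (X - mu) / sd
    if np.linalg.matrix_rank(Z) < k:
        raise ValueError(
            f"centered/scaled property table has rank "
            f"{np.linalg.matrix_rank(Z)} < {k}"
        )
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(Z)
    for j in range(k):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, j] = -scores[:, j]
    df = pd.DataFrame(
        scores,
        index=DINUCLEOTIDES,
        columns=[f"pc{j + 1}" for j in range(k)],
    )
    return PropertyTable(values=df)


def npc_names(reduced: PropertyTable) -> list[str]:
    return [
        f"npc:{di}:{pc}" for di in DINUCLEOTIDES for pc in reduced.values.columns
    ]


def count_dinucleotides(seq: str) -> tuple[np.ndarray, int]:
    """16 dinucleotide counts and the number of valid (N-free) windows."""
    arr = _encode_bases(seq.upper())
    if len(arr) < 2:
        return np.zeros(16), 0
    a, b = arr[:-1], arr[1:]
    valid = (a >= 0) & (b >= 0)
    counts = np.bincount(a[valid] * 4 + b[valid], minlength=16).astype(float)
    return counts, int(valid.sum())


def encode_npc(seq: str, reduced: PropertyTable) -> np.ndarray:
    """count(di) * value(di, pc) / n_windows for each pair (length 240)."""
    if len(seq) < 2:
        raise ValueError("sequence shorter than 2 nt")
    counts, n_windows = count_dinucleotides(seq)
    F = reduced.values.to_numpy(dtype=float)  # (16, k)
    if n_windows == 0:
        return np.zeros(F.size)
    return (counts[:, None] * F / n_windows).ravel()


# ---------------------------------------------------------------------------
# CpG islands


@dataclass(frozen=True)
class CpGIsland:
    start: int  # 1-based inclusive on the scanned sequence
    end: int
    length: int
    gc_percent: float
    obs_exp: float  # standard length-corrected observed/expected CpG


def detect_cpg_islands(
    seq: str,
    min_len: int = 200,
    gc_min: float = 50.0,
    oe_min: float = 0.6,
    window: int = 100,
    shift: int = 1,
) -> list[CpGIsland]:
    """Windowed CpG-island prediction in the newcpgreport style.

    Windows of ``window`` nt (step ``shift``) passing GC% >= gc_min and
    observed/expected CpG >= oe_min are merged when overlapping or adjacent;
    merged segments shorter than ``min_len`` are discarded.
    """
    L = len(seq)
    if L < window:
        return []
    arr = _encode_bases(seq.upper())
    is_c = (arr == 1).astype(np.int64)
    is_g = (arr == 2).astype(np.int64)
    is_cg = ((arr[:-1] == 1) & (arr[1:] == 2)).astype(np.int64)
    cum_c = np.concatenate([[0], np.cumsum(is_c)])
    cum_g = np.concatenate([[0], np.cumsum(is_g)])
    cum_cg = np.concatenate([[0], np.cumsum(is_cg)])

    starts = np.arange(0, L - window + 1, shift)
    n_c = cum_c[starts + window] - cum_c[starts]
    n_g = cum_g[starts + window] - cum_g[starts]
    # CpG windows: dinucleotide starting inside [start, start+window-2]
    n_cg = cum_cg[np.minimum(starts + window - 1, L - 1)] - cum_cg[starts]
    gc = (n_c + n_g) * 100.0 / window
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.where(n_c * n_g > 0, n_cg * window / (n_c * n_g), 0.0)
    passing = (gc >= gc_min) & (oe >= oe_min)

    islands: list[CpGIsland] = []
    seg_start = None
    seg_end = None
    for s, ok in zip(starts, passing):
        if ok:
            if seg_start is None:
                seg_start, seg_end = s, s + window - 1
            elif s <= seg_end + 1:
                seg_end = s + window - 1
            else:
                islands.append(_finalise_island(seg_start, seg_end, cum_c, cum_g, cum_cg))
                seg_start, seg_end = s, s + window - 1
    if seg_start is not None:
        islands.append(_finalise_island(seg_start, seg_end, cum_c, cum_g, cum_cg))
    return [isl for isl in islands if isl.length >= min_len]


def _finalise_island(s0: int, e0: int, cum_c, cum_g, cum_cg) -> CpGIsland:
    length = e0 - s0 + 1
    n_c = int(cum_c[e0 + 1] - cum_c[s0])
    n_g = int(cum_g[e0 + 1] - cum_g[s0])
    n_cg = int(cum_cg[min(e0, len(cum_cg) - 1)] - cum_cg[s0])
    gc = (n_c + n_g) * 100.0 / length
    oe = n_cg * length / (n_c * n_g) if n_c * n_g > 0 else 0.0
    return CpGIsland(start=s0 + 1, end=e0 + 1, length=length, gc_percent=gc, obs_exp=oe)


def cgi_names() -> list[str]:
    return [f"cgi:{ch}" for ch in CGI_CHANNELS]


def encode_cgi(
    islands: list[CpGIsland], seq: str, promoter_len: int, tls_offset: int
) -> np.ndarray:
    """Five-channel CpG-island summary of a promoter.

    The encoded obs/expected channel is the raw count ratio
    #CpG / (#C * #G) pooled over islands, without the length factor of the
    detection-time formula (the two definitions are deliberately distinct;
    both are available, the detector reports the length-corrected one per
    island).
    """
    if not islands:
        return np.zeros(5)
    n = len(islands)
    total_len = sum(i.length for i in islands)
    dis = min(abs(tls_offset - i.start) for i in islands)
    cg_percents = []
    tot_cg = tot_c = tot_g = 0
    for isl in islands:
        sub = seq[isl.start - 1 : isl.end]
        n_cg = sum(
            1 for j in range(len(sub) - 1) if sub[j] == "C" and sub[j + 1] == "G"
        )
        n_c = sub.count("C")
        n_g = sub.count("G")
        tot_cg += n_cg
        tot_c += n_c
        tot_g += n_g
        cg_percents.append(100.0 * n_cg / (isl.length - 1) if isl.length > 1 else 0.0)
    cg_ratio = sum(cg_percents) / n
    oe = tot_cg / (tot_c * tot_g) if tot_c * tot_g > 0 else 0.0
    return np.array([n, total_len / promoter_len, dis, cg_ratio, oe], dtype=float)


# ---------------------------------------------------------------------------
# significant-pattern selection


@dataclass
class PatternMask:
    mask: np.ndarray  # boolean, one entry per pattern column
    p_values: np.ndarray

    def apply(self, X: np.ndarray) -> np.ndarray:
        return X[:, self.mask]


def select_patterns(
    count_matrix: np.ndarray, labels: np.ndarray, alpha: float = 0.05
) -> PatternMask:
    """Welch two-sample t-test per pattern column; keep p < alpha.

    ``labels`` is a boolean/0-1 array (True = Ac).  Columns with zero
    variance in both classes are excluded with p recorded as 1.
    """
    labels = np.asarray(labels).astype(bool)
    a = count_matrix[labels]
    b = count_matrix[~labels]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each class needs at least 2 records for the t-test")
    with np.errstate(divide="ignore", invalid="ignore"):
        _, p = stats.ttest_ind(a, b, axis=0, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)
    degenerate = (a.std(axis=0) == 0) & (b.std(axis=0) == 0)
    p = np.where(degenerate, 1.0, p)
    return PatternMask(mask=p < alpha, p_values=p)


def write_mask(mask: PatternMask, names: list[str], path) -> None:
    pd.DataFrame({"name": names, "p_value": mask.p_values}).to_csv(
        path, sep="\t", index=False
    )
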