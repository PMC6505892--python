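import itertools

import numpy as np
import pandas as pd
import pytest

import flankact as fa
from flankact import features as ff
from flankact.io import Motif, MotifLibrary, PropertyTable
from flankact.simulate import synthetic_property_table


def naive_kmer_counts(seq: str) -> np.ndarray:
    """Independent oracle: dictionary of literal substring counts."""
    out = np.zeros(ff.NGRAM_DIM)
    names = ff.ngram_names()
    index = {n.split(":")[1]: i for i, n in enumerate(names)}
    for k in (3, 4, 5, 6):
        for i in range(len(seq) - k + 1):
            sub = seq[i : i + k]
            if set(sub) <= set("ACGT"):
                out[index[sub]] += 1
    return out


def test_count_ngrams_hand_examples():
    v = fa.count_ngrams("ACGT")
    names = ff.ngram_names()
    d = dict(zip(names, v))
    assert d["3mer:ACG"] == 1 and d["3mer:CGT"] == 1
    assert d["4mer:ACGT"] == 1
    assert v.sum() == 3  # 2 three-mers + 1 four-mer

    v = fa.count_ngrams("AAAA")
    d = dict(zip(names, v))
    assert d["3mer:AAA"] == 2 and d["4mer:AAAA"] == 1
    assert v[:64].sum() == 2  # 4 - 3 + 1


def test_count_ngrams_skips_n_windows():
    v = fa.count_ngrams("ACGNACG")
    # only windows without N: ACG (x2)
    assert v.sum() == 2


def test_count_ngrams_total_mass_invariant(rng):
    for _ in range(10):
        L = int(rng.integers(10, 300))
        seq = "".join(rng.choice(list("ACGT"), size=L))
        v = fa.count_ngrams(seq)
        offset = 0
        for k in (3, 4, 5, 6):
            assert v[offset : offset + 4**k].sum() == max(0, L - k + 1)
            offset += 4**k


def test_count_ngrams_matches_naive_scan(rng):
    for _ in range(20):
        seq = "".join(rng.choice(list("ACGTN"), size=200, p=[0.24, 0.24, 0.24, 0.24, 0.04]))
        assert np.array_equal(fa.count_ngrams(seq), naive_kmer_counts(seq))


# ---------------------------------------------------------------------------
# motif scanning


def indicator_motif(consensus: str, name="ind") -> Motif:
    pwm = np.full((len(consensus), 4), 1e-9)
    for j, b in enumerate(consensus):
        pwm[j, "ACGT".index(b)] = 1.0
    pwm /= pwm.sum(axis=1, keepdims=True)
    return Motif(name, pwm, len(consensus))


def test_scan_consensus_indicator_hit():
    lib = MotifLibrary(motifs=[indicator_motif("TATAAT")])
    hits = fa.scan_motifs("GGTATAATGG", lib, p_threshold=1e-3)
    assert len(hits) == 1
    h = hits[0]
    assert (h.start, h.end, h.strand) == (3, 8, "+")

    rc = fa.reverse_complement("GGTATAATGG")
    (h2,) = fa.scan_motifs(rc, lib, p_threshold=1e-3)
    assert h2.strand == "-"
    assert h2.score == pytest.approx(h.score)


def test_scan_motif_wider_than_sequence():
    lib = MotifLibrary(motifs=[indicator_motif("TATAATTATAAT")])
    assert fa.scan_motifs("ACGT", lib) == []


def test_scan_pvalues_match_exhaustive_enumeration(rng):
    """Fraction of all 8-mers with p <= 0.05 is ~0.05 under uniform background."""
    pwm = rng.dirichlet(np.ones(4) * 2.0, size=8)
    lib = MotifLibrary(motifs=[Motif("m", pwm, 8)])
    scanner = ff.MotifScanner(lib, p_threshold=1.0)
    # all 65,536 8-mers once each, N-separated so windows do not interact
    total = 4**8
    kmers = [
        "".join("ACGT"[(code >> (2 * (7 - j))) & 3] for j in range(8))
        for code in range(total)
    ]
    seq = "N".join(kmers)
    hits = [h for h in scanner.scan(seq) if h.strand == "+"]
    assert len(hits) == total  # every 8-mer window scores exactly once
    count_le = sum(1 for h in hits if h.pvalue <= 0.05)
    assert abs(count_le / total - 0.05) <= 0.005


def test_encode_motifs_hand_example(small_library):
    lib = small_library
    occ = ff.MotifOccurrence(
        motif_id=lib.motifs[0].motif_id, start=101, end=100 + lib.motifs[0].width,
        strand="+", score=9.2, pvalue=1e-5,
    )
    v = fa.encode_motifs([occ], lib, seq_len=1000, tls_offset=1001)
    number, conserve, pos, neg, density, dis = v[:6]
    assert number == 1
    assert conserve == pytest.approx(9.2)
    assert (pos, neg) == (1.0, 0.0)
    assert density == pytest.approx(1.0)  # single hit: span = width
    assert dis == pytest.approx(900.0)
    # all other motifs contribute zeros
    assert np.all(v[6:] == 0)


def test_encode_motifs_means_and_zero_case(small_library):
    lib = small_library
    w = lib.motifs[0].width
    occs = [
        ff.MotifOccurrence(lib.motifs[0].motif_id, 10, 9 + w, "+", 4.0, 1e-5),
        ff.MotifOccurrence(lib.motifs[0].motif_id, 50, 49 + w, "-", 6.0, 1e-5),
    ]
    v = fa.encode_motifs(occs, lib, 1000, 1001)
    assert v[1] == pytest.approx(5.0)
    assert v[2] == pytest.approx(0.5)
    assert v[3] == pytest.approx(0.5)
    assert np.all(fa.encode_motifs([], lib, 1000, 1001) == 0)


def test_encode_motifs_order_invariance(small_library):
    lib = small_library
    w = lib.motifs[1].width
    occs = [
        ff.MotifOccurrence(lib.motifs[1].motif_id, s, s + w - 1, st, sc, 1e-5)
        for s, st, sc in [(5, "+", 1.0), (40, "-", 3.0), (90, "+", 2.0)]
    ]
    a = fa.encode_motifs(occs, lib, 500, 501)
    b = fa.encode_motifs(occs[::-1], lib, 500, 501)
    assert np.array_equal(a, b)


def test_motif_vector_dimension(small_library):
    assert len(fa.encode_motifs([], small_library, 100, 101)) == 6 * len(small_library)


# ---------------------------------------------------------------------------
# NPC


def test_reduce_property_table_shape(property_table, reduced_table):
    assert property_table.n_properties == 125
    assert reduced_table.values.shape == (16, 15)


def test_reduce_matches_eigendecomposition_oracle(property_table):
    """Explained variances agree with a direct eigendecomposition."""
    X = property_table.values.to_numpy()
    Z = (X - X.mean(0)) / X.std(0)
    evals = np.sort(np.linalg.eigvalsh(np.cov(Z, rowvar=False)))[::-1][:15]
    scores = fa.reduce_property_table(property_table).values.to_numpy()
    assert np.allclose(scores.var(axis=0, ddof=1), evals, rtol=1e-8)


def test_reduce_duplicate_column_keeps_projection_variance(property_table):
    df = property_table.values.copy()
    df["dup"] = df.iloc[:, 0]
    dup = fa.reduce_property_table(PropertyTable(values=df))
    base = fa.reduce_property_table(property_table)
    assert np.isclose(
        dup.values.to_numpy().var(axis=0, ddof=1).sum(),
        base.values.to_numpy().var(axis=0, ddof=1).sum(),
        rtol=0.05,
    )


def test_reduce_rejects_rank_deficiency():
    from flankact.io import DINUCLEOTIDES

    df = pd.DataFrame(
        np.ones((16, 20)), index=DINUCLEOTIDES, columns=[f"p{i}" for i in range(20)]
    )
    with pytest.raises(ValueError):
        fa.reduce_property_table(PropertyTable(values=df))
    small = PropertyTable(
        values=pd.DataFrame(
            np.random.default_rng(0).normal(size=(16, 10)),
            index=DINUCLEOTIDES, columns=[f"p{i}" for i in range(10)],
        )
    )
    with pytest.raises(ValueError, match="at least 15"):
        fa.reduce_property_table(small)


def test_encode_npc_homopolymer(reduced_table):
    v = fa.encode_npc("AAAA", reduced_table).reshape(16, 15)
    # S(AA)=3, windows=3 -> value = F(AA, j) exactly; all other rows zero
    assert np.allclose(v[0], reduced_table.values.loc["AA"].to_numpy())
    assert np.all(v[1:] == 0)


def test_encode_npc_linearity(reduced_table):
    seq = "ACGTACGGTT"
    base = fa.encode_npc(seq, reduced_table).reshape(16, 15)
    doubled = PropertyTable(values=reduced_table.values * 1.0)
    doubled.values.iloc[:, 3] *= 2
    v2 = fa.encode_npc(seq, doubled).reshape(16, 15)
    assert np.allclose(v2[:, 3], 2 * base[:, 3])
    other = [j for j in range(15) if j != 3]
    assert np.allclose(v2[:, other], base[:, other])


def test_encode_npc_short_sequence_errors(reduced_table):
    with pytest.raises(ValueError):
        fa.encode_npc("A", reduced_table)


def test_npc_dimension(reduced_table):
    assert len(fa.encode_npc("ACGTAC", reduced_table)) == 240


# ---------------------------------------------------------------------------
# CpG islands


def test_cpg_islands_absent_on_at_sequence():
    assert fa.detect_cpg_islands("A" * 1000) == []


def test_cpg_island_cg_repeat():
    seq = "CG" * 150  # 300 nt, GC 100%, window O/E = 2
    (isl,) = fa.detect_cpg_islands(seq)
    assert (isl.start, isl.end, isl.length) == (1, 300, 300)
    assert isl.gc_percent == pytest.approx(100.0)
    # whole-island O/E: 150 CpG * 300 / (150*150)
    assert isl.obs_exp == pytest.approx(2.0)


def test_cpg_island_embedded_boundaries():
    seq = "A" * 400 + "CG" * 150 + "A" * 300
    (isl,) = fa.detect_cpg_islands(seq)
    assert abs(isl.start - 401) <= 99  # within window-1 of the embed
    assert abs(isl.end - 700) <= 99


def test_encode_cgi_zero_and_bounds():
    assert np.all(fa.encode_cgi([], "", 1000, 1001) == 0)
    seq = "CG" * 500
    islands = fa.detect_cpg_islands(seq)
    v = fa.encode_cgi(islands, seq, 1000, 1001)
    assert v[1] == pytest.approx(1.0)  # island covers the whole promoter


def test_encode_cgi_literal_oe_arithmetic():
    # one island with #CpG=3, #C=3, #G=3 -> encoded oe = 3/9
    isl = ff.CpGIsland(start=1, end=6, length=6, gc_percent=100.0, obs_exp=2.0)
    v = fa.encode_cgi([isl], "CGCGCG", 1000, 1001)
    assert v[4] == pytest.approx(3 / 9)
    # CpG% = 100 * 3/(6-1) averaged over the single island
    assert v[3] == pytest.approx(100 * 3 / 5)
    assert v[0] == 1
    assert v[2] == 1000  # |1001 - 1|


# ---------------------------------------------------------------------------
# pattern selection


def test_select_patterns_degenerate_and_indicator(rng):
    n = 20
    labels = np.array([1] * n + [0] * n)
    X = np.zeros((2 * n, 3))
    X[:, 0] = 5.0  # constant everywhere
    X[:, 1] = labels + rng.normal(0, 0.01, size=2 * n)  # label indicator
    X[:, 2] = rng.normal(size=2 * n)  # noise
    mask = fa.select_patterns(X, labels)
    assert not mask.mask[0] and mask.p_values[0] == 1.0
    assert mask.mask[1] and mask.p_values[1] < 1e-6


def test_select_patterns_requires_two_per_class():
    with pytest.raises(ValueError):
        fa.select_patterns(np.ones((3, 2)), np.array([1, 0, 0]))


def test_select_patterns_null_calibration(rng):
    """On permuted labels the inclusion rate stays near alpha."""
    n, p = 40, 400
    X = rng.poisson(3.0, size=(n, p)).astype(float)
    labels = np.array([1] * (n // 2) + [0] * (n // 2))
    fracs = []
    for _ in range(200):
        perm = rng.permutation(labels)
        mask = fa.select_patterns(X, perm)
        fracs.append(mask.mask.mean())
    assert abs(np.mean(fracs) - 0.05) <= 0.02


def test_encoders_deterministic(small_library, reduced_table):
    seq = "ACGT" * 100
    assert np.array_equal(fa.count_ngrams(seq), fa.count_ngrams(seq))
    assert np.array_equal(
        fa.encode_npc(seq, reduced_table), fa.encode_npc(seq, reduced_table)
    )
    h1 = fa.scan_motifs(seq, small_library, 0.01)
    h2 = fa.scan_motifs(seq, small_library, 0.01)
    assert h1 == h2
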