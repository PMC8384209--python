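"""Built-in nucleotide aligner: affine-gap pairwise DP and a progressive
profile aligner for small homologous region groups.

The pairwise core is Gotoh's three-state dynamic programme (match /
gap-in-A / gap-in-B) with scores match=+1, mismatch=-1, gap open -4
(charged on the first gap base) and gap extend -1, and deterministic
tie-breaking (diagonal, then up, then left).  Group alignment builds a
UPGMA guide tree from shared 8-mer counts and merges profiles with the
same DP, with terminal gaps free, which is adequate for the highly
similar plastome regions this package compares.  Externally aligned
FASTA can always be passed through instead.
"""

from __future__ import annotations

import logging
from collections import Counter

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .io import AlignmentMatrix

log = logging.getLogger("plastovar")

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
NEG = -1e30


def _encode(seq: str) -> np.ndarray:
    return np.fromiter((_CODE.get(c, 4) for c in seq), dtype=np.int8,
                       count=len(seq))


def _profile(rows: list[str]) -> np.ndarray:
    """Per-column frequencies over A,C,G,T (ambiguity and gaps carry no
    score mass)."""
    arr = np.stack([_encode(r.replace("-", "N")) for r in rows])
    gap = np.stack([np.frombuffer(r.encode(), dtype=np.uint8) == ord("-")
                    for r in rows])
    prof = np.zeros((arr.shape[1], 4), dtype=np.float32)
    for b in range(4):
        prof[:, b] = ((arr == b) & ~gap).sum(axis=0)
    prof /= len(rows)
    return prof


def _score_grid(pa: np.ndarray, pb: np.ndarray,
                match: float, mismatch: float) -> np.ndarray:
    """Expected pair score for every column pair of two profiles."""
    ident = pa @ pb.T                                   # sum_a fa*fb (a==b)
    mass = pa.sum(axis=1)[:, None] * pb.sum(axis=1)[None, :]
    return (match - mismatch) * ident + mismatch * mass


def _gotoh(S: np.ndarray, gap_open: float, gap_extend: float,
           free_ends: bool) -> tuple[list[tuple[int, int]], float]:
    """Affine-gap DP over a precomputed column-pair score grid.

    Returns the aligned path as (i, j) pairs with -1 marking a gap, and
    the optimal score.  A gap run of length L costs open + (L-1)*extend.
    """
    n, m = S.shape
    Sf = S.astype(np.float32)
    M = np.full((n + 1, m + 1), NEG, dtype=np.float32)
    X = np.full((n + 1, m + 1), NEG, dtype=np.float32)  # gap in B (up)
    Y = np.full((n + 1, m + 1), NEG, dtype=np.float32)  # gap in A (left)
    ptrM = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptrX = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptrY = np.zeros((n + 1, m + 1), dtype=np.int8)

    # free_ends: terminal gaps cost extend-only (no opening charge), so
    # region-boundary slack is cheap but staircase shifts are not free
    M[0, 0] = 0.0
    js = np.arange(1, m + 1, dtype=np.float32)
    Y[0, 1:] = js * gap_extend if free_ends \
        else gap_open + (js - 1) * gap_extend
    is_ = np.arange(1, n + 1, dtype=np.float32)
    X[1:, 0] = is_ * gap_extend if free_ends \
        else gap_open + (is_ - 1) * gap_extend

    for i in range(1, n + 1):
        pM, pX, pY = M[i - 1], X[i - 1], Y[i - 1]
        # X: vertical gap, from any state above (tie pref: M > X > Y)
        candX = np.stack([pM + gap_open, pX + gap_extend, pY + gap_open])
        ptrX[i, 1:] = np.argmax(candX[::-1, 1:], axis=0)
        ptrX[i, 1:] = 2 - ptrX[i, 1:]          # prefer lower index on ties
        X[i, 1:] = candX[ptrX[i, 1:], np.arange(1, m + 1)]
        # M: diagonal, from any state at (i-1, j-1)
        diag = np.stack([pM[:-1], pX[:-1], pY[:-1]])
        ptrM[i, 1:] = np.argmax(diag[::-1], axis=0)
        ptrM[i, 1:] = 2 - ptrM[i, 1:]
        M[i, 1:] = Sf[i - 1] + diag[ptrM[i, 1:], np.arange(m)]
        # Y: horizontal gap within this row (running-max over gap starts)
        base = np.maximum(M[i], X[i])
        from_base = base[:-1] + gap_open
        t = from_base - np.arange(1, m + 1, dtype=np.float32) * gap_extend
        run = np.maximum.accumulate(t)
        Y[i, 1:] = run + np.arange(1, m + 1, dtype=np.float32) * gap_extend
        # pointer: 0 = opened here from base[j-1], 1 = extended Y[i,j-1]
        ptrY[i, 1:] = np.where(
            np.isclose(Y[i, 1:], from_base, atol=1e-4), 0, 1)

    # choose the end cell
    if free_ends:
        lastrow = np.maximum(np.maximum(M[n], X[n]), Y[n]) \
            + (m - np.arange(m + 1)) * gap_extend
        lastcol = np.maximum(np.maximum(M[:, m], X[:, m]), Y[:, m]) \
            + (n - np.arange(n + 1)) * gap_extend
        jbest = int(np.argmax(lastrow))
        ibest = int(np.argmax(lastcol))
        if lastrow[jbest] >= lastcol[ibest]:
            ei, ej = n, jbest
        else:
            ei, ej = ibest, m
        score = float(max(lastrow[jbest], lastcol[ibest]))
    else:
        ei, ej = n, m
        score = float(max(M[n, m], X[n, m], Y[n, m]))

    path: list[tuple[int, int]] = []
    # terminal gaps (free-end padding)
    for j in range(m - 1, ej - 1, -1):
        path.append((-1, j))
    for i in range(n - 1, ei - 1, -1):
        path.append((i, -1))

    i, j = ei, ej
    vals = (M[i, j], X[i, j], Y[i, j])
    state = 0  # tie preference at the end cell: M > X > Y
    for s in (0, 1, 2):
        if np.isclose(vals[s], max(vals), atol=1e-4):
            state = s
            break
    while i > 0 or j > 0:
        if free_ends and (i == 0 or j == 0):
            break
        if i == 0:
            state = 2  # only horizontal gaps remain
        elif j == 0:
            state = 1
        if state == 0:
            path.append((i - 1, j - 1))
            state = int(ptrM[i, j])
            i, j = i - 1, j - 1
        elif state == 1:
            path.append((i - 1, -1))
            state = int(ptrX[i, j])
            i -= 1
        else:
            if ptrY[i, j] == 0:
                bM, bX = M[i, j - 1], X[i, j - 1]
                state = 0 if bM >= bX else 1
            else:
                state = 2
            path.append((-1, j - 1))
            j -= 1
    while i > 0:
        path.append((i - 1, -1))
        i -= 1
    while j > 0:
        path.append((-1, j - 1))
        j -= 1
    path.reverse()
    return path, score


def _apply_path(rows_a: list[str], rows_b: list[str],
                path: list[tuple[int, int]]) -> list[str]:
    out_a = ["" for _ in rows_a]
    out_b = ["" for _ in rows_b]
    for i, j in path:
        for r, row in enumerate(rows_a):
            out_a[r] += row[i] if i >= 0 else "-"
        for r, row in enumerate(rows_b):
            out_b[r] += row[j] if j >= 0 else "-"
    return out_a + out_b


def align_pair(a: str, b: str, match: float = 1.0, mismatch: float = -1.0,
               gap_open: float = -4.0, gap_extend: float = -1.0,
               taxa: tuple[str, str] = ("a", "b"),
               region_name: str = "pair") -> AlignmentMatrix:
    """Optimal global alignment of two sequences under affine gap
    scoring, with deterministic tie-breaking."""
    if not a or not b:
        raise ValueError("align_pair needs non-empty sequences")
    a, b = a.upper(), b.upper()
    pa, pb = _profile([a]), _profile([b])
    S = _score_grid(pa, pb, match, mismatch)
    path, _ = _gotoh(S, gap_open, gap_extend, free_ends=False)
    rows = _apply_path([a], [b], path)
    return AlignmentMatrix(region_name, "other", list(taxa), rows)


def alignment_score(aln: AlignmentMatrix, match: float = 1.0,
                    mismatch: float = -1.0, gap_open: float = -4.0,
                    gap_extend: float = -1.0,
                    free_ends: bool = False) -> float:
    """Score a 2-row alignment under the affine model (for oracle checks)."""
    a, b = aln.rows
    score = 0.0
    in_gap = False
    ncol = len(a)
    first, last = 0, ncol
    if free_ends:
        both = [k for k in range(ncol) if a[k] != "-" and b[k] != "-"]
        if both:
            first, last = both[0], both[-1] + 1
    for k in range(first, last):
        x, y = a[k], b[k]
        if x == "-" or y == "-":
            score += gap_extend if in_gap else gap_open
            in_gap = True
        else:
            score += match if x == y else mismatch
            in_gap = False
    return score


def _kmer_distance(a: str, b: str, k: int = 8) -> float:
    ka, kb = (Counter(s[i:i + k] for i in range(len(s) - k + 1))
              for s in (a, b))
    if not ka or not kb:
        return 1.0
    shared = sum((ka & kb).values())
    return 1.0 - shared / min(sum(ka.values()), sum(kb.values()))


def align_group(seqs: dict[str, str], match: float = 1.0,
                mismatch: float = -1.0, gap_open: float = -4.0,
                gap_extend: float = -1.0, region_name: str = "group",
                region_class: str = "other") -> AlignmentMatrix:
    """Progressive multiple alignment of one homologous region group.

    8-mer distances -> UPGMA guide tree -> profile-profile merges with
    the pairwise scoring; terminal gaps are free during merges because
    region boundaries across taxa are inexact.
    """
    items = [(t, s.upper()) for t, s in seqs.items() if s]
    for t, s in seqs.items():
        if not s:
            log.warning("%s: empty sequence for %s dropped", region_name, t)
    if len(items) < 2:
        raise ValueError(f"{region_name}: need >= 2 non-empty sequences")
    taxa = [t for t, _ in items]
    seql = [s for _, s in items]

    if len(set(seql)) == 1:  # identical inputs: gapless by construction
        return AlignmentMatrix(region_name, region_class, taxa, list(seql))

    k = len(items)
    dm = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            dm[i, j] = dm[j, i] = _kmer_distance(seql[i], seql[j])
    Z = linkage(squareform(dm, checks=False), method="average")

    clusters: dict[int, tuple[list[int], list[str]]] = {
        i: ([i], [seql[i]]) for i in range(k)}
    nxt = k
    for za, zb, _, _ in Z:
        ia, ib = clusters.pop(int(za)), clusters.pop(int(zb))
        pa, pb = _profile(ia[1]), _profile(ib[1])
        S = _score_grid(pa, pb, match, mismatch)
        path, _ = _gotoh(S, gap_open, gap_extend, free_ends=True)
        merged_rows = _apply_path(ia[1], ib[1], path)
        clusters[nxt] = (ia[0] + ib[0], merged_rows)
        nxt += 1
    order, rows = clusters.popitem()[1]
    by_taxon = {taxa[t]: r for t, r in zip(order, rows)}
    aln = AlignmentMatrix(region_name, region_class, taxa,
                          [by_taxon[t] for t in taxa])
    return aln.drop_gap_only_columns()


def pairwise_identity(aln: AlignmentMatrix) -> float:
    """Mean pairwise percent identity over comparable (both non-gap)
    columns, one decimal."""
    if aln.n_rows < 2:
        raise ValueError("pairwise identity needs >= 2 rows")
    mat = np.stack([np.frombuffer(r.encode(), dtype=np.uint8)
                    for r in aln.rows])
    nongap = mat != ord("-")
    idents = []
    for i in range(aln.n_rows):
        for j in range(i + 1, aln.n_rows):
            both = nongap[i] & nongap[j]
            comp = int(both.sum())
            ident = int(((mat[i] == mat[j]) & both).sum())
            if comp == 0:
                log.warning("%s: no comparable columns between %s and %s",
                            aln.region_name, aln.taxa[i], aln.taxa[j])
                continue
            idents.append(100.0 * ident / comp)
    if not idents:
        raise ValueError("no comparable row pairs")
    return round(float(np.mean(idents)), 1)
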