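"""lncRNA target prediction: genomic proximity (cis) and RNA-RNA
hybridization free energy (trans).

Cis targets are protein-coding genes whose span lies within 100 kb of the
lncRNA span (closest-edge distance, boundary inclusive, either strand).

Trans targets use a hybridization model: one sequence is slid along the
reverse complement of the other; at every register the maximal contiguous
complementary runs (Watson-Crick plus G·U wobble) are scored as
``dG = duplex initiation + sum of nearest-neighbor stack energies`` from
the embedded Turner 2004 RNA/RNA parameter table, and the hit minimizing
the length-normalized energy ``ndG = dG / paired_length`` is reported.
Runs shorter than ``min_pair`` are ignored; a pair is called a target when
its best ndG falls at or below the (negative) threshold. Intramolecular
structure and accessibility are deliberately ignored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import TranscriptModel

__all__ = [
    "CisPair",
    "DuplexHit",
    "DUPLEX_INIT_KCAL",
    "stack_table",
    "cis_targets",
    "duplex_energy",
    "trans_targets",
    "merge_targets",
]

DUPLEX_INIT_KCAL = 4.10
DEFAULT_WINDOW_BP = 100_000
DEFAULT_NDG_THRESHOLD = -2.3
DEFAULT_MIN_PAIR = 4

_PAIR_ORDER = ("CG", "GC", "GU", "UG", "AU", "UA")
_PAIR_CODE = {p: i for i, p in enumerate(_PAIR_ORDER)}
# reading a pair from the opposite strand: (X,Y) -> (Y,X)
_FLIP = np.array([_PAIR_CODE[p[::-1]] for p in _PAIR_ORDER])


def stack_table(include_wobble: bool = True) -> np.ndarray:
    """6x6 stack free-energy matrix indexed by pair codes (kcal/mol).

    Entry [p1][p2] scores the stack 5'-X1 X2-3'/3'-Y1 Y2-5' with
    p1 = code(X1,Y1) and p2 = code(Y2,X2). With ``include_wobble=False``
    G·U rows/columns are disabled (+inf), restricting runs to Watson-Crick
    pairs.
    """
    return _stack_table_cached(include_wobble).copy()


from functools import lru_cache


@lru_cache(maxsize=2)
def _stack_table_cached(include_wobble: bool) -> np.ndarray:
    text = (
        resources.files("cerna_switch.data")
        .joinpath("rna_stack_turner2004.tsv")
        .read_text()
    )
    rows = [
        line.split("\t")
        for line in text.splitlines()
        if line and not line.startswith("#")
    ]
    header = rows[0][1:]
    assert tuple(header) == _PAIR_ORDER
    mat = np.array([[float(x) for x in r[1:]] for r in rows[1:]])
    if not include_wobble:
        for wob in ("GU", "UG"):
            mat[_PAIR_CODE[wob], :] = np.inf
            mat[:, _PAIR_CODE[wob]] = np.inf
    return mat


@dataclass(frozen=True)
class CisPair:
    lncRNA_id: str
    gene_id: str
    distance: int  # signed bp between closest span edges; 0 if overlapping
    side: str  # upstream | downstream | overlap


@dataclass(frozen=True)
class DuplexHit:
    lncRNA_id: str
    mRNA_id: str
    dG: float  # kcal/mol
    paired_length: int
    ndG: float  # dG / paired_length
    lnc_start: int  # 0-based inclusive positions on the lncRNA
    lnc_end: int
    m_start: int  # 0-based inclusive positions on the mRNA
    m_end: int


def cis_targets(
    lncRNAs: Sequence[TranscriptModel],
    coding_genes: Sequence[TranscriptModel],
    window_bp: int = DEFAULT_WINDOW_BP,
) -> list[CisPair]:
    """Protein-coding genes within ``window_bp`` of each lncRNA span.

    Inclusion is strand-agnostic and boundary inclusive (a closest-edge
    distance of exactly ``window_bp`` qualifies); the reported side is
    relative to the lncRNA's own strand. Chromosomes present in only one
    of the two sets are skipped with a warning.
    """
    lnc_chroms = {t.chromosome for t in lncRNAs}
    gene_chroms = {t.chromosome for t in coding_genes}
    lonely = lnc_chroms ^ gene_chroms
    if lonely:
        warnings.warn(
            f"chromosomes present in only one input, pairs skipped: {sorted(lonely)}"
        )
    genes_by_chrom: dict[str, list[TranscriptModel]] = {}
    for g in coding_genes:
        genes_by_chrom.setdefault(g.chromosome, []).append(g)
    out: list[CisPair] = []
    for lnc in lncRNAs:
        for g in genes_by_chrom.get(lnc.chromosome, []):
            if g.gene_id == lnc.gene_id:
                continue
            if g.start > lnc.end:
                gap = g.start - lnc.end
                left_of_lnc = False
            elif g.end < lnc.start:
                gap = lnc.start - g.end
                left_of_lnc = True
            else:
                gap = 0
                left_of_lnc = False
            if gap > window_bp:
                continue
            if gap == 0:
                side = "overlap"
                signed = 0
            else:
                # upstream/downstream in the lncRNA's transcription sense
                upstream = left_of_lnc if lnc.strand == "+" else not left_of_lnc
                side = "upstream" if upstream else "downstream"
                signed = -gap if upstream else gap
            out.append(CisPair(lnc.transcript_id, g.gene_id, signed, side))
    return out


_BASE_CODE = {"A": 0, "C": 1, "G": 2, "U": 3, "T": 3}
_BASE_LOOKUP = np.full(256, -1, dtype=np.int8)
for _b, _v in _BASE_CODE.items():
    _BASE_LOOKUP[ord(_b)] = _v
    _BASE_LOOKUP[ord(_b.lower())] = _v


def _encode(seq: str) -> np.ndarray:
    return _BASE_LOOKUP[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


# pair code lookup: 4x4 (top base, bottom base) -> pair code or -1
_PAIR_LOOKUP = -np.ones((5, 5), dtype=np.int8)
for _p, _c in _PAIR_CODE.items():
    _top = {"A": 0, "C": 1, "G": 2, "U": 3}[_p[0]]
    _bot = {"A": 0, "C": 1, "G": 2, "U": 3}[_p[1]]
    _PAIR_LOOKUP[_top, _bot] = _c


def duplex_energy(
    lnc_seq: str,
    m_seq: str,
    min_pair: int = DEFAULT_MIN_PAIR,
    include_wobble: bool = True,
    lncRNA_id: str = "lncRNA",
    mRNA_id: str = "mRNA",
) -> DuplexHit | None:
    """Best (minimum-ndG) antiparallel complementary run between two RNAs.

    Returns ``None`` when no maximal complementary run reaches ``min_pair``
    bases. Ties on ndG break toward more negative dG, then the earliest
    position, so the result is deterministic.
    """
    if not lnc_seq or not m_seq:
        raise ValueError("empty sequence")
    S = stack_table(include_wobble)
    # pre-fold the strand flip into the stack lookup: consecutive cells
    # along a scan diagonal carry pair codes q[k], q[k+1] (both as
    # (top, bottom)); their stack is S[q[k]][flip(q[k+1])].
    S2 = S[:, _FLIP]
    a = _encode(lnc_seq)
    b = _encode(m_seq)
    n1, n2 = len(a), len(b)
    a_ = np.where(a < 0, 4, a)
    b_ = np.where(b < 0, 4, b)
    # cell (i, k): a[i] paired with b[n2-1-k]  (antiparallel register)
    q = _PAIR_LOOKUP[a_[:, None], b_[::-1][None, :]]  # n1 x n2, -1 = no pair
    if include_wobble is False:
        q = np.where(np.isin(q, (_PAIR_CODE["GU"], _PAIR_CODE["UG"])), -1, q)

    # lay the diagonals out as columns of a padded array, then flatten
    # column-major with a sentinel row so runs never cross diagonals:
    # shifting row i right by (n1 - 1 - i) aligns constant (k - i) into
    # one column
    width = n1 + n2  # columns index diagonals d = k - i + (n1 - 1)
    pad = np.full((n1 + 1, width), -1, dtype=np.int8)
    for i in range(n1):
        off = n1 - 1 - i
        pad[i, off : off + n2] = q[i]
    flat = np.asfortranarray(pad).reshape(-1, order="F")

    comp = flat >= 0
    if not comp.any():
        return None
    prev = np.concatenate(([False], comp[:-1]))
    nxt = np.concatenate((comp[1:], [False]))
    starts = np.flatnonzero(comp & ~prev)
    ends = np.flatnonzero(comp & ~nxt)
    lengths = ends - starts + 1
    keep = lengths >= min_pair
    if not keep.any():
        return None
    starts, ends, lengths = starts[keep], ends[keep], lengths[keep]

    # adjacent-stack energies summed per run (adjacent cells are both
    # complementary everywhere inside a run)
    q1 = flat[:-1]
    q2 = flat[1:]
    both = (q1 >= 0) & (q2 >= 0)
    adj = np.zeros(flat.shape[0] - 1)
    adj[both] = S2[q1[both], q2[both]]
    segs = np.column_stack((starts, ends)).ravel()
    sums = np.add.reduceat(adj, segs)[::2]
    dg = DUPLEX_INIT_KCAL + sums
    ndg = dg / lengths

    order = np.lexsort((starts, dg, ndg))
    best = order[0]
    s, e, L = int(starts[best]), int(ends[best]), int(lengths[best])
    dG = float(dg[best])
    # map flat indices back to (i on lnc, position on m)
    d = s // (n1 + 1)  # diagonal column
    i0 = s % (n1 + 1)
    i1 = e % (n1 + 1)
    k0 = d - (n1 - 1) + i0
    k1 = d - (n1 - 1) + i1
    m0, m1 = n2 - 1 - k1, n2 - 1 - k0  # m positions, ascending
    return DuplexHit(
        lncRNA_id, mRNA_id, dG, L, float(dG / L), i0, i1, m0, m1
    )


def trans_targets(
    lnc_seqs: Mapping[str, str],
    m_seqs: Mapping[str, str],
    ndG_threshold: float = DEFAULT_NDG_THRESHOLD,
    min_pair: int = DEFAULT_MIN_PAIR,
    include_wobble: bool = True,
) -> list[DuplexHit]:
    """All lncRNA/mRNA pairs whose best ndG is at or below the threshold."""
    hits: list[DuplexHit] = []
    missing: list[str] = []
    for lid, lseq in lnc_seqs.items():
        for mid, mseq in m_seqs.items():
            if not lseq or not mseq:
                missing.append(f"{lid}/{mid}")
                continue
            hit = duplex_energy(
                lseq, mseq, min_pair, include_wobble, lncRNA_id=lid, mRNA_id=mid
            )
            if hit is not None and hit.ndG <= ndG_threshold:
                hits.append(hit)
    if missing:
        warnings.warn(f"pairs skipped for missing sequence: {missing[:10]}")
    return hits


def merge_targets(
    cis: Sequence[CisPair], trans: Sequence[DuplexHit]
) -> pd.DataFrame:
    """Union of cis and trans calls with per-pair evidence flags.

    Returns a DataFrame with columns ``lncRNA_id``, ``gene_id``,
    ``evidence`` (cis | trans | both), ``distance`` and ``ndG`` (NaN where
    the evidence channel is absent).
    """
    rows: dict[tuple[str, str], dict] = {}
    for p in cis:
        rows[(p.lncRNA_id, p.gene_id)] = {
            "lncRNA_id": p.lncRNA_id,
            "gene_id": p.gene_id,
            "evidence": "cis",
            "distance": p.distance,
            "ndG": np.nan,
        }
    for h in trans:
        key = (h.lncRNA_id, h.mRNA_id)
        if key in rows:
            rows[key]["evidence"] = "both"
            rows[key]["ndG"] = h.ndG
        else:
            rows[key] = {
                "lncRNA_id": h.lncRNA_id,
                "gene_id": h.mRNA_id,
                "evidence": "trans",
                "distance": np.nan,
                "ndG": h.ndG,
            }
    df = pd.DataFrame(
        list(rows.values()),
        columns=["lncRNA_id", "gene_id", "evidence", "distance", "ndG"],
    )
    return df.reset_index(drop=True)
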