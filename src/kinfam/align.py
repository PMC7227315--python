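"""Pairwise global alignment and center-star multiple alignment.

Pairwise alignment is global Needleman-Wunsch with affine gaps (BLOSUM62 by
default for protein, a simple match/mismatch scheme for nucleotide), via
Bio.Align.PairwiseAligner. Identity is matches over alignment columns with
terminal-gap columns excluded; coverage (used by the duplication screen) is
the aligned span on the longer sequence over that sequence's length.

The multiple aligner is center-star: the center is the input sequence with
the highest summed pairwise score against all others, and the remaining
sequences are merged against it under "once a gap, always a gap". This is a
deterministic substitute for progressive alignment, adequate for the
distance-based trees built downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices


@dataclass
class PairwiseResult:
    aligned_a: str
    aligned_b: str
    score: float
    identity: float
    coverage: float


@lru_cache(maxsize=8)
def _aligner(alphabet: str, gap_open: float, gap_extend: float,
             match: float, mismatch: float) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    if alphabet == "protein":
        al.substitution_matrix = substitution_matrices.load("BLOSUM62")
    else:
        al.match_score = match
        al.mismatch_score = mismatch
    # Biopython's open score applies to the first gap position; make a
    # k-gap cost open + (k-1)*extend like classic affine NW.
    al.open_gap_score = gap_open
    al.extend_gap_score = gap_extend
    return al


def _identity(a: str, b: str) -> float:
    """Matches / columns, excluding terminal-gap columns of either row."""
    start = 0
    while start < len(a) and (a[start] == "-" or b[start] == "-"):
        start += 1
    end = len(a)
    while end > start and (a[end - 1] == "-" or b[end - 1] == "-"):
        end -= 1
    cols = end - start
    if cols <= 0:
        return 0.0
    matches = sum(1 for i in range(start, end) if a[i] == b[i] and a[i] != "-")
    return matches / cols


def _coverage(a: str, b: str, len_a: int, len_b: int) -> float:
    """Aligned span on the longer sequence (terminal gaps excluded) / its length."""
    longer_row, longer_len = (a, len_a) if len_a >= len_b else (b, len_b)
    other_row = b if len_a >= len_b else a
    start = 0
    while start < len(a) and (a[start] == "-" or b[start] == "-"):
        start += 1
    end = len(a)
    while end > start and (a[end - 1] == "-" or b[end - 1] == "-"):
        end -= 1
    span = sum(1 for i in range(start, end) if longer_row[i] != "-")
    return span / longer_len if longer_len else 0.0


def global_align(a: str, b: str, *, alphabet: str = "protein",
                 gap_open: float = -10.0, gap_extend: float = -1.0,
                 match: float = 2.0, mismatch: float = -1.0) -> PairwiseResult:
    """Optimal global alignment of two sequences with identity and coverage."""
    if not a or not b:
        raise ValueError("global_align: empty sequence")
    al = _aligner(alphabet, gap_open, gap_extend, match, mismatch)
    aln = al.align(a, b)[0]
    ra, rb = str(aln[0]), str(aln[1])
    return PairwiseResult(
        aligned_a=ra,
        aligned_b=rb,
        score=float(aln.score),
        identity=_identity(ra, rb),
        coverage=_coverage(ra, rb, len(a), len(b)),
    )


@dataclass
class Msa:
    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("MSA rows must have equal length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def degapped(self, i: int) -> str:
        return self.rows[i].replace("-", "")


def _merge(center_aln: str, other_aln: str, msa_center: str, msa_rows: list[str]):
    """Merge a new pairwise alignment against the running center row.

    Gaps already in the MSA's center row and gaps newly introduced by the
    pairwise alignment are united; existing rows get gaps where the new
    alignment inserts, the new row gets gaps where the MSA already has them.
    """
    out_center: list[str] = []
    out_rows: list[list[str]] = [[] for _ in msa_rows]
    out_new: list[str] = []
    i = j = 0  # i over msa_center, j over center_aln
    n, m = len(msa_center), len(center_aln)
    while i < n or j < m:
        msa_gap = i < n and msa_center[i] == "-"
        pair_gap = j < m and center_aln[j] == "-"
        if msa_gap and not pair_gap:
            out_center.append("-")
            for k, row in enumerate(msa_rows):
                out_rows[k].append(row[i])
            out_new.append("-")
            i += 1
        elif pair_gap and not msa_gap:
            out_center.append("-")
            for k in range(len(msa_rows)):
                out_rows[k].append("-")
            out_new.append(other_aln[j])
            j += 1
        else:
            # both real residues (identical center residue) or both gaps
            out_center.append(msa_center[i] if i < n else "-")
            for k, row in enumerate(msa_rows):
                out_rows[k].append(row[i] if i < n else "-")
            out_new.append(other_aln[j] if j < m else "-")
            i += 1
            j += 1
    return "".join(out_center), ["".join(r) for r in out_rows], "".join(out_new)


def center_star_msa(ids: list[str], seqs: list[str], *, alphabet: str = "protein",
                    gap_open: float = -10.0, gap_extend: float = -1.0) -> Msa:
    """Center-star multiple alignment ("once a gap, always a gap")."""
    if len(ids) != len(seqs):
        raise ValueError("ids and seqs length mismatch")
    if not seqs:
        raise ValueError("no sequences")
    if len(seqs) == 1:
        return Msa(ids=list(ids), rows=list(seqs))
    n = len(seqs)
    pair: dict[tuple[int, int], PairwiseResult] = {}
    sums = [0.0] * n
    for i in range(n):
        for j in range(i + 1, n):
            res = global_align(seqs[i], seqs[j], alphabet=alphabet,
                               gap_open=gap_open, gap_extend=gap_extend)
            pair[(i, j)] = res
            sums[i] += res.score
            sums[j] += res.score
    center = max(range(n), key=lambda i: (sums[i], -i))
    msa_center = seqs[center]
    order = [i for i in range(n) if i != center]
    msa_rows: list[str] = []
    for idx in order:
        i, j = (center, idx) if center < idx else (idx, center)
        res = pair[(i, j)]
        c_aln, o_aln = (res.aligned_a, res.aligned_b) if i == center else (res.aligned_b, res.aligned_a)
        msa_center, msa_rows, new_row = _merge(c_aln, o_aln, msa_center, msa_rows)
        msa_rows.append(new_row)
    out_ids = [ids[center]] + [ids[i] for i in order]
    return Msa(ids=out_ids, rows=[msa_center] + msa_rows)
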