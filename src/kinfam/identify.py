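"""Kinase-domain family screening and basic protein properties.

Family membership is defined by at least one hit of a position-specific
scoring matrix (PSSM) built from trusted, pre-aligned kinase-domain cores
(the anchor sequences). The scan slides the profile over every window of
the protein and reports windows scoring above a threshold expressed as a
fraction of the consensus (maximum attainable) score.

Molecular weight uses average residue masses plus one water; the
isoelectric point solves net charge = 0 by bisection on the
Henderson-Hasselbalch charge function with the EMBOSS pKa set. ProtParam
(the tool usually cited for these properties) uses a slightly different
pKa table, so small numeric differences from its output are expected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

# Average residue masses (Da); peptide MW = sum + one water (18.0153).
RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.0153
_MEAN_RESIDUE_MASS = sum(RESIDUE_MASS.values()) / len(RESIDUE_MASS)

# EMBOSS pKa values.
PKA_NTERM = 8.6
PKA_CTERM = 3.6
PKA_POSITIVE = {"K": 10.8, "R": 12.5, "H": 6.5}
PKA_NEGATIVE = {"D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1}

# Uniform background; the profile screen only needs a null that the decoy
# model of the simulator matches.
UNIFORM_BG = {a: 1.0 / 20 for a in AMINO_ACIDS}


@dataclass
class DomainHit:
    start: int
    end: int  # 0-based half-open
    score: float


@dataclass
class ProteinRecord:
    id: str
    sequence: str
    domain_hits: list[DomainHit] = field(default_factory=list)
    aliases: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.id}: empty sequence")
        bad = set(self.sequence) - set(AMINO_ACIDS) - {"X"}
        if bad:
            raise ValueError(f"protein {self.id}: invalid residues {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def mw(self) -> float:
        return molecular_weight(self.sequence)

    @property
    def pi(self) -> float:
        return isoelectric_point(self.sequence)

    @property
    def is_member(self) -> bool:
        return len(self.domain_hits) > 0


@dataclass
class DomainProfile:
    """Log-odds PSSM over the 20-letter alphabet.

    ``pssm[c, r]`` is log2 of the pseudocount-smoothed column frequency of
    residue r over its background frequency. ``score_threshold`` is in bits.
    """

    pssm: np.ndarray  # (width, 20)
    background: dict[str, float]
    score_threshold: float

    @property
    def width(self) -> int:
        return int(self.pssm.shape[0])

    @property
    def consensus_score(self) -> float:
        return float(self.pssm.max(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join(AMINO_ACIDS[i] for i in self.pssm.argmax(axis=1))


def build_profile(aligned_domain_seqs: list[str], pseudocount: float = 1.0,
                  threshold_fraction: float = 0.6,
                  background: dict[str, float] | None = None) -> DomainProfile:
    """Build a PSSM from gap-free, equal-length anchor domain sequences.

    Column score for residue r: log2(((count_r + pseudocount*bg_r) / (n + pseudocount)) / bg_r).
    The default detection threshold is ``threshold_fraction`` of the
    consensus path score.
    """
    if not aligned_domain_seqs or len(aligned_domain_seqs) < 2:
        raise ValueError("build_profile: need at least 2 sequences")
    width = len(aligned_domain_seqs[0])
    if any(len(s) != width for s in aligned_domain_seqs):
        raise ValueError("build_profile: sequences must have equal length")
    if any("-" in s for s in aligned_domain_seqs):
        raise ValueError("build_profile: gaps not allowed")
    bg = background or UNIFORM_BG
    n = len(aligned_domain_seqs)
    pssm = np.empty((width, 20))
    for c in range(width):
        col = [s[c] for s in aligned_domain_seqs]
        for r, aa in enumerate(AMINO_ACIDS):
            count = col.count(aa)
            num = count + pseudocount * bg[aa]
            if num <= 0:
                raise ValueError(
                    "build_profile: zero probability cell; use pseudocount > 0"
                )
            pssm[c, r] = math.log2(num / (n + pseudocount) / bg[aa])
    profile = DomainProfile(pssm=pssm, background=dict(bg), score_threshold=0.0)
    profile.score_threshold = threshold_fraction * profile.consensus_score
    return profile


def _window_scores(sequence: str, profile: DomainProfile) -> np.ndarray:
    """Score of the profile at every window start; X scores 0 per column."""
    w = profile.width
    n = len(sequence)
    if n < w:
        return np.empty(0)
    # residue index per position, -1 for X
    idx = np.array([_AA_INDEX.get(ch, -1) for ch in sequence])
    scores = np.zeros(n - w + 1)
    for c in range(w):
        col_idx = idx[c:c + n - w + 1]
        col_scores = np.where(col_idx >= 0, profile.pssm[c][col_idx], 0.0)
        scores += col_scores
    return scores


def scan_kinase_domain(sequence: str, profile: DomainProfile) -> list[DomainHit]:
    """All above-threshold windows, greedily pruned to non-overlapping hits."""
    bad = set(sequence) - set(AMINO_ACIDS) - {"X"}
    if bad:
        raise ValueError(f"scan: invalid residues {sorted(bad)}")
    scores = _window_scores(sequence, profile)
    candidates = [
        (float(scores[i]), i) for i in range(len(scores))
        if scores[i] > profile.score_threshold
    ]
    candidates.sort(key=lambda t: (-t[0], t[1]))
    taken: list[DomainHit] = []
    w = profile.width
    for score, start in candidates:
        if all(start + w <= h.start or start >= h.end for h in taken):
            taken.append(DomainHit(start=start, end=start + w, score=score))
    taken.sort(key=lambda h: h.start)
    return taken


def identify_family(proteome: dict[str, str], profile: DomainProfile,
                    gene_models: list | None = None) -> list[ProteinRecord]:
    """Screen a proteome; return domain-containing members, nonredundant.

    Byte-identical sequences collapse to one record (first id kept, the
    rest recorded as aliases). With gene models supplied, members are
    sorted by genomic position (chromosome, then start); otherwise by id.
    """
    if not proteome:
        raise ValueError("identify_family: empty proteome")
    seen: dict[str, ProteinRecord] = {}
    members: list[ProteinRecord] = []
    for pid, seq in proteome.items():
        if seq in seen:
            seen[seq].aliases.append(pid)
            continue
        hits = scan_kinase_domain(seq, profile)
        if hits:
            rec = ProteinRecord(id=pid, sequence=seq, domain_hits=hits)
            seen[seq] = rec
            members.append(rec)
    if gene_models is not None:
        pos = {g.id: (g.chromosome, g.start) for g in gene_models}
        members.sort(key=lambda r: pos.get(r.id, ("~", 0)))
    else:
        members.sort(key=lambda r: r.id)
    return members


def molecular_weight(sequence: str) -> float:
    """Average-mass peptide MW in Daltons; X uses the mean residue mass."""
    if not sequence:
        raise ValueError("molecular_weight: empty sequence")
    total = WATER_MASS
    for ch in sequence:
        if ch == "X":
            total += _MEAN_RESIDUE_MASS
        elif ch in RESIDUE_MASS:
            total += RESIDUE_MASS[ch]
        else:
            raise ValueError(f"molecular_weight: invalid residue {ch!r}")
    return total


def net_charge(sequence: str, ph: float) -> float:
    """Henderson-Hasselbalch net charge at a given pH (EMBOSS pKa set)."""
    charge = 1.0 / (1.0 + 10 ** (ph - PKA_NTERM))
    charge -= 1.0 / (1.0 + 10 ** (PKA_CTERM - ph))
    for aa, pka in PKA_POSITIVE.items():
        n = sequence.count(aa)
        if n:
            charge += n / (1.0 + 10 ** (ph - pka))
    for aa, pka in PKA_NEGATIVE.items():
        n = sequence.count(aa)
        if n:
            charge -= n / (1.0 + 10 ** (pka - ph))
    return charge


def isoelectric_point(sequence: str, tol: float = 1e-6) -> float:
    """pH at which the peptide's net charge is zero, by bisection.

    Net charge is strictly decreasing in pH, so the root is unique.
    """
    if not sequence:
        raise ValueError("isoelectric_point: empty sequence")
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = (lo + hi) / 2
        if net_charge(sequence, mid) > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2
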