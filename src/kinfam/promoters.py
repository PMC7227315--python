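"""Promoter extraction and IUPAC cis-element scanning.

Promoters are the 2 kb immediately upstream of the transcription start
site, strand-aware: for minus-strand genes the window downstream of the
genomic gene end is taken and reverse-complemented, so the returned string
always reads 5'→3' toward the gene. Scanning matches a dictionary of IUPAC
degenerate patterns (defaults: ABRE core ACGTG, DRE/CRT core RCCGAC) at
every offset on both strands; overlapping matches are all reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .io import GeneModel, revcomp

logger = logging.getLogger(__name__)

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "K": "GT", "M": "AC", "S": "CG", "W": "AT",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

DEFAULT_ELEMENTS = {"ABRE": "ACGTG", "DRE": "RCCGAC"}


@dataclass
class CisElementHit:
    gene: str
    element: str
    position: int  # 0-based offset within the promoter
    strand: str
    matched: str


def validate_dictionary(elements: dict[str, str]) -> dict[str, str]:
    for name, pat in elements.items():
        bad = set(pat.upper()) - set(IUPAC)
        if bad:
            raise ValueError(f"element {name}: invalid IUPAC codes {sorted(bad)}")
    return {n: p.upper() for n, p in elements.items()}


def extract_promoter(genome: dict[str, str], gene: GeneModel,
                     length: int = 2000) -> str:
    """Upstream window of the TSS, oriented 5'→3' relative to the gene."""
    if gene.chromosome not in genome:
        raise ValueError(f"gene {gene.id}: chromosome {gene.chromosome!r} not in genome")
    chrom = genome[gene.chromosome]
    if gene.strand == "+":
        start = max(gene.start - length, 0)
        window = chrom[start:gene.start]
    else:
        end = min(gene.end + length, len(chrom))
        window = revcomp(chrom[gene.end:end])
    if len(window) < length:
        logger.warning("gene %s: promoter truncated to %d bp at contig boundary",
                       gene.id, len(window))
    return window


def _matches(base: str, code: str) -> bool:
    # N in the sequence matches only the N code
    if base == "N":
        return code == "N"
    return base in IUPAC[code]


def _match_at(seq: str, pos: int, pattern: str) -> bool:
    if pos + len(pattern) > len(seq):
        return False
    return all(_matches(seq[pos + k], pattern[k]) for k in range(len(pattern)))


def scan_cis_elements(promoter: str, elements: dict[str, str] | None = None,
                      both_strands: bool = True, gene: str = "") -> list[CisElementHit]:
    """All IUPAC matches, overlaps allowed, ordered by (position, strand, element).

    A minus-strand hit at position p means the reverse complement of the
    pattern matches the promoter at p; the reported matched sequence is the
    promoter substring as written.
    """
    elements = validate_dictionary(elements or DEFAULT_ELEMENTS)
    promoter = promoter.upper()
    bad = set(promoter) - set("ACGTN")
    if bad:
        raise ValueError(f"promoter: invalid bases {sorted(bad)}")
    hits = []
    for name, pattern in elements.items():
        w = len(pattern)
        rc_pattern = revcomp(pattern)
        for pos in range(len(promoter) - w + 1):
            if _match_at(promoter, pos, pattern):
                hits.append(CisElementHit(gene=gene, element=name, position=pos,
                                          strand="+", matched=promoter[pos:pos + w]))
            if both_strands and _match_at(promoter, pos, rc_pattern):
                hits.append(CisElementHit(gene=gene, element=name, position=pos,
                                          strand="-", matched=promoter[pos:pos + w]))
    hits.sort(key=lambda h: (h.position, h.strand, h.element))
    return hits


def family_cis_summary(hits_per_gene: dict[str, list[CisElementHit]]) -> dict:
    """Per element: genes with >=1 hit, mean hits per positive gene, per-gene counts."""
    elements = sorted({h.element for hits in hits_per_gene.values() for h in hits})
    out = {}
    for el in elements:
        counts = {g: sum(1 for h in hits if h.element == el)
                  for g, hits in hits_per_gene.items()}
        positive = {g: c for g, c in counts.items() if c > 0}
        mean = sum(positive.values()) / len(positive) if positive else None
        out[el] = {
            "n_positive_genes": len(positive),
            "mean_hits_per_positive_gene": mean,
            "per_gene_counts": counts,
        }
    return out
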