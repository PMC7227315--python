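"""Paralog-pair detection, tandem/segmental classification, orthologs.

A gene pair is a duplication pair when a global alignment of the two
proteins (i) covers more than 70% of the longer gene and (ii) shows more
than 70% identity over the aligned region — both strict inequalities.
Pairs on different chromosomes are segmental; same-chromosome pairs are
tandem when at most ``tandem_max_separation`` genes intervene, otherwise
segmental ("intra-chromosomal distal"). Orthologs across genomes are
reciprocal best hits by alignment score, with score ties dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .align import global_align
from .io import GeneModel, subgenome_of

logger = logging.getLogger(__name__)


@dataclass
class DuplicationPair:
    gene_a: str
    gene_b: str  # canonical: gene_a < gene_b
    coverage: float
    identity: float
    mode: str | None = None  # tandem | segmental | None (undetermined)
    distal: bool = False  # same chromosome but beyond the tandem window


@dataclass
class OrthologPair:
    gene_subgenome: str
    gene_ancestral: str
    score: float
    reciprocal: bool = True


def detect_duplication_pairs(members: dict[str, str],
                             coverage_threshold: float = 0.70,
                             identity_threshold: float = 0.70,
                             alphabet: str = "protein") -> list[DuplicationPair]:
    """All-vs-all screen for duplication pairs under the dual >70% rule."""
    for name, t in (("coverage", coverage_threshold), ("identity", identity_threshold)):
        if not 0 < t <= 1:
            raise ValueError(f"{name} threshold must be in (0, 1]")
    if len(members) < 2:
        raise ValueError("detect_duplication_pairs: need at least 2 members")
    ids = list(members)
    pairs = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            res = global_align(members[ids[i]], members[ids[j]], alphabet=alphabet)
            if res.coverage > coverage_threshold and res.identity > identity_threshold:
                a, b = sorted((ids[i], ids[j]))
                pairs.append(DuplicationPair(gene_a=a, gene_b=b,
                                             coverage=res.coverage,
                                             identity=res.identity))
    pairs.sort(key=lambda p: (p.gene_a, p.gene_b))
    return pairs


def classify_pair_mode(pair: DuplicationPair, gene_models: dict[str, GeneModel],
                       tandem_max_separation: int = 1) -> DuplicationPair:
    """Assign tandem/segmental mode in place (returns the pair).

    Unplaced genes leave the mode undetermined (logged, not an error).
    """
    ga = gene_models.get(pair.gene_a)
    gb = gene_models.get(pair.gene_b)
    if ga is None or gb is None:
        missing = pair.gene_a if ga is None else pair.gene_b
        logger.warning("pair (%s, %s): gene %s unplaced; mode undetermined",
                       pair.gene_a, pair.gene_b, missing)
        pair.mode = None
        return pair
    if ga.chromosome != gb.chromosome:
        pair.mode = "segmental"
        return pair
    # count genes strictly between the two on the same chromosome
    lo, hi = sorted([ga.start, gb.start])
    intervening = sum(
        1 for g in gene_models.values()
        if g.chromosome == ga.chromosome and lo < g.start < hi
        and g.id not in (pair.gene_a, pair.gene_b)
    )
    if intervening <= tandem_max_separation:
        pair.mode = "tandem"
    else:
        pair.mode = "segmental"
        pair.distal = True
        logger.info("pair (%s, %s): same chromosome, %d intervening genes; "
                    "classified intra-chromosomal distal segmental",
                    pair.gene_a, pair.gene_b, intervening)
    return pair


def classify_all(pairs: list[DuplicationPair], gene_models: dict[str, GeneModel],
                 tandem_max_separation: int = 1) -> list[DuplicationPair]:
    return [classify_pair_mode(p, gene_models, tandem_max_separation) for p in pairs]


def reciprocal_best_hit_orthologs(set_a: dict[str, str], set_b: dict[str, str],
                                  alphabet: str = "protein") -> list[OrthologPair]:
    """Reciprocal best hits by global alignment score; ties drop both genes."""
    if not set_a or not set_b:
        raise ValueError("reciprocal_best_hit_orthologs: empty input set")
    scores: dict[tuple[str, str], float] = {}
    for a, sa in set_a.items():
        for b, sb in set_b.items():
            scores[(a, b)] = global_align(sa, sb, alphabet=alphabet).score

    def best(partner_scores: list[tuple[str, float]]) -> str | None:
        partner_scores.sort(key=lambda t: (-t[1], t[0]))
        if len(partner_scores) > 1 and partner_scores[0][1] == partner_scores[1][1]:
            logger.warning("tied best scores (%s vs %s); candidates dropped",
                           partner_scores[0][0], partner_scores[1][0])
            return None
        return partner_scores[0][0]

    best_a = {a: best([(b, scores[(a, b)]) for b in set_b]) for a in set_a}
    best_b = {b: best([(a, scores[(a, b)]) for a in set_a]) for b in set_b}
    out = []
    for a, b in best_a.items():
        if b is not None and best_b.get(b) == a:
            out.append(OrthologPair(gene_subgenome=a, gene_ancestral=b,
                                    score=scores[(a, b)]))
    out.sort(key=lambda p: p.gene_subgenome)
    return out


def subgenome_census(member_ids: list[str], gene_models: dict[str, GeneModel],
                     on_unparseable: str = "unknown") -> dict:
    """Member counts per subgenome and per chromosome, plus unplaced list."""
    per_subgenome: dict[str, int] = {}
    per_chromosome: dict[str, int] = {}
    unplaced: list[str] = []
    for mid in member_ids:
        g = gene_models.get(mid)
        if g is None:
            unplaced.append(mid)
            continue
        sub = g.subgenome or subgenome_of(g.chromosome)
        if sub is None:
            if on_unparseable == "error":
                raise ValueError(f"gene {mid}: cannot parse subgenome from "
                                 f"chromosome {g.chromosome!r}")
            unplaced.append(mid)
            continue
        per_subgenome[sub] = per_subgenome.get(sub, 0) + 1
        per_chromosome[g.chromosome] = per_chromosome.get(g.chromosome, 0) + 1
    return {"per_subgenome": per_subgenome, "per_chromosome": per_chromosome,
            "unplaced": unplaced}
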