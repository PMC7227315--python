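"""Synthetic allotetraploid genome, family proteome, promoters, expression.

The generator emulates the statistical structure a kinase gene-family
survey assumes, with a machine-readable truth table for every planted
feature:

* an allotetraploid genome with A/D subgenome chromosome naming
  (A01..A0k, D01..D0k) and uniform-random intergenic background;
* a three-subfamily family (RAF-like, MEKK-like, ZIK-like). All family
  proteins share one conserved kinase-domain core (lightly mutated per
  member); each subfamily additionally has its own flanking template,
  mutated heavily enough per member that non-duplicate pairs stay well
  below the duplication screen's 70% identity rule;
* planted duplication pairs: the partner is a copy of the source protein
  with flank-only mutations (identity well above 70%). Segmental pairs are
  forced onto different chromosomes, tandem pairs are immediately adjacent
  on one chromosome;
* a planted intronless subset within the MEKK-like genes (single-exon
  models); all other genes get 2-5 exons;
* promoters with exact planted ABRE/DRE occurrence counts — background is
  resampled wherever an accidental dictionary match appears, so a scan of
  the emitted promoter returns exactly the planted hits;
* a drought time course (0, 2, 4, 6, 8 days, three replicates) with
  planted induced / repressed / continuously-induced / unchanged profiles,
  matching qPCR Ct tables (constant housekeeping reference), and a VIGS
  physiology table (three replicates per group x treatment).

One RNG stream per artifact class (proteins, genome placement, promoters,
expression, physiology), all derived from the master seed, so regenerating
one artifact never perturbs the others. Identical seeds give byte-identical
files.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .identify import AMINO_ACIDS
from .io import GeneModel, revcomp, write_fasta, write_gff3
from .promoters import DEFAULT_ELEMENTS, IUPAC, scan_cis_elements

DNA = "ACGT"
# fixed reverse-translation table (one codon per residue)
_CODON = {
    "A": "GCT", "R": "CGT", "N": "AAT", "D": "GAT", "C": "TGT", "E": "GAA",
    "Q": "CAA", "G": "GGT", "H": "CAT", "I": "ATT", "L": "CTT", "K": "AAA",
    "M": "ATG", "F": "TTT", "P": "CCT", "S": "TCT", "T": "ACT", "W": "TGG",
    "Y": "TAT", "V": "GTT",
}
_STOP = "TAA"

SUBFAMILIES = ("RAF", "MEKK", "ZIK")
PROFILES = ("induced", "repressed", "continuous", "unchanged")
TIMEPOINTS = (0, 2, 4, 6, 8)  # days of drought
N_REPLICATES = 3


@dataclass
class FamilySimConfig:
    n_raf: int = 20
    n_mekk: int = 12
    n_zik: int = 8
    n_chromosomes_per_subgenome: int = 5
    n_segmental_pairs: int = 10
    n_tandem_pairs: int = 3
    n_intronless: int = 5  # within the MEKK-like set
    promoter_len: int = 2000
    abre_counts: dict[str, int] | None = None  # gene name -> planted count
    dre_counts: dict[str, int] | None = None
    n_decoy_genes: int = 60
    expr_profiles: dict[str, str] | None = None  # gene name -> profile label
    expr_noise_sd: float = 0.1  # log2-scale replicate noise
    seed: int = 0
    # sequence model knobs: one family-wide template; subfamily templates
    # diverge from it (kinase-domain signature + flank drift); members
    # diverge from their subfamily template with a well-conserved core
    core_len: int = 60
    flank_n: int = 100
    flank_c: int = 140
    subfamily_core_divergence: float = 0.20  # subfamily signature inside the domain
    subfamily_flank_divergence: float = 0.25
    core_divergence: float = 0.05  # per member
    flank_divergence: float = 0.30  # per member
    pair_divergence: float = 0.05  # flank-only, applied to the copied partner
    n_anchors_per_subfamily: int = 2

    @property
    def family_size(self) -> int:
        return self.n_raf + self.n_mekk + self.n_zik

    def validate(self) -> None:
        counts = {
            "n_raf": self.n_raf, "n_mekk": self.n_mekk, "n_zik": self.n_zik,
            "n_chromosomes_per_subgenome": self.n_chromosomes_per_subgenome,
            "n_segmental_pairs": self.n_segmental_pairs,
            "n_tandem_pairs": self.n_tandem_pairs,
            "n_intronless": self.n_intronless,
            "n_decoy_genes": self.n_decoy_genes,
            "promoter_len": self.promoter_len,
        }
        for name, v in counts.items():
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if self.n_chromosomes_per_subgenome < 1:
            raise ValueError("need at least one chromosome per subgenome")
        if 2 * (self.n_segmental_pairs + self.n_tandem_pairs) > self.family_size:
            raise ValueError("planted pairs exceed half the family size")
        if self.n_intronless > self.n_mekk:
            raise ValueError("n_intronless cannot exceed n_mekk")
        max_w = max(len(p) for p in DEFAULT_ELEMENTS.values())
        if self.promoter_len < max_w:
            raise ValueError("promoter_len shorter than the longest planted element")
        if self.expr_profiles:
            bad = set(self.expr_profiles.values()) - set(PROFILES)
            if bad:
                raise ValueError(f"unknown expression profiles: {sorted(bad)}")


@dataclass
class TruthTable:
    """Ground truth for every planted feature, plus emitted file paths."""

    genes: dict[str, dict] = field(default_factory=dict)
    anchor_labels: dict[str, str] = field(default_factory=dict)
    subfamily_counts: dict[str, int] = field(default_factory=dict)
    pair_modes: dict[str, list[list[str]]] = field(default_factory=dict)
    files: dict[str, str] = field(default_factory=dict)
    config: dict = field(default_factory=dict)

    def to_json(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "TruthTable":
        with open(path) as fh:
            return cls(**json.load(fh))


def _mutate(rng: np.random.Generator, seq: str, rate: float,
            lo: int = 0, hi: int | None = None) -> str:
    """Substitute residues in [lo, hi) with a different residue at ``rate``."""
    hi = len(seq) if hi is None else hi
    out = list(seq)
    for i in range(lo, hi):
        if rng.random() < rate:
            choices = AMINO_ACIDS.replace(out[i], "")
            out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def _random_protein(rng: np.random.Generator, n: int) -> str:
    return "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=n))


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(DNA[i] for i in rng.integers(0, 4, size=n))


def generate_family_genome(config: FamilySimConfig, out_dir: str | os.PathLike):
    """Emit genome FASTA, gene models GFF3, proteome and anchors FASTA.

    Returns the TruthTable (also written to ``truth.json``); expression and
    physiology tables are produced by :func:`generate_expression_tables`.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng_prot = np.random.default_rng([config.seed % (2**31), 11])
    rng_place = np.random.default_rng([config.seed % (2**31), 13])
    rng_prom = np.random.default_rng([config.seed % (2**31), 17])

    truth = TruthTable(config=asdict(config))

    # --- protein sequences -------------------------------------------------
    core_lo = config.flank_n
    core_hi = config.flank_n + config.core_len
    family_template = (_random_protein(rng_prot, config.flank_n)
                       + _random_protein(rng_prot, config.core_len)
                       + _random_protein(rng_prot, config.flank_c))
    templates = {}
    for fam in SUBFAMILIES:
        t = _mutate(rng_prot, family_template, config.subfamily_flank_divergence,
                    0, core_lo)
        t = _mutate(rng_prot, t, config.subfamily_flank_divergence,
                    core_hi, len(t))
        templates[fam] = _mutate(rng_prot, t, config.subfamily_core_divergence,
                                 core_lo, core_hi)

    def make_member(fam: str) -> str:
        t = templates[fam]
        s = _mutate(rng_prot, t, config.flank_divergence, 0, core_lo)
        s = _mutate(rng_prot, s, config.flank_divergence, core_hi, len(t))
        return _mutate(rng_prot, s, config.core_divergence, core_lo, core_hi)

    fam_counts = {"RAF": config.n_raf, "MEKK": config.n_mekk, "ZIK": config.n_zik}
    # working ids; final names assigned after placement, in position order
    members: list[dict] = []
    for fam in SUBFAMILIES:
        for _ in range(fam_counts[fam]):
            members.append({"subfamily": fam, "seq": None, "partner": None,
                            "mode": None})

    # plant duplication pairs: partner is a flank-mutated copy of the source
    pair_slots = []
    by_fam: dict[str, list[int]] = {fam: [i for i, m in enumerate(members)
                                          if m["subfamily"] == fam]
                                    for fam in SUBFAMILIES}
    n_pairs = config.n_segmental_pairs + config.n_tandem_pairs
    fam_cycle = [fam for fam in SUBFAMILIES for _ in range(fam_counts[fam] // 2)]
    pi = 0
    for k in range(n_pairs):
        # draw both pair members from one subfamily, round-robin by capacity
        while True:
            fam = fam_cycle[pi % len(fam_cycle)]
            pi += 1
            free = [i for i in by_fam[fam] if members[i]["partner"] is None]
            if len(free) >= 2:
                break
        a, b = free[0], free[1]
        mode = "segmental" if k < config.n_segmental_pairs else "tandem"
        members[a]["partner"], members[a]["mode"] = b, mode
        members[b]["partner"], members[b]["mode"] = a, mode
        pair_slots.append((a, b, mode))

    for i, m in enumerate(members):
        if m["seq"] is None and (m["partner"] is None or m["partner"] > i):
            m["seq"] = make_member(m["subfamily"])
    for a, b, _ in pair_slots:
        src, dst = (a, b) if members[a]["seq"] is not None else (b, a)
        s = members[src]["seq"]
        s2 = _mutate(rng_prot, s, config.pair_divergence, 0, core_lo)
        s2 = _mutate(rng_prot, s2, config.pair_divergence, core_hi, len(s))
        members[dst]["seq"] = s2

    # intronless subset: first n_intronless MEKK-like genes
    mekk_idx = by_fam["MEKK"]
    intronless_set = set(mekk_idx[:config.n_intronless])

    # anchors: full-length labelled references plus their aligned domain cores
    anchors: dict[str, str] = {}
    anchor_domains: dict[str, str] = {}
    for fam in SUBFAMILIES:
        for k in range(config.n_anchors_per_subfamily):
            aid = f"ANC_{fam}{k + 1}"
            seq = make_member(fam)
            anchors[aid] = seq
            anchor_domains[aid] = seq[core_lo:core_hi]
            truth.anchor_labels[aid] = fam

    # decoys: random proteins without the domain core
    decoys = {f"DEC{k + 1:03d}": _random_protein(rng_prot, int(rng_prot.integers(250, 400)))
              for k in range(config.n_decoy_genes)}

    # --- chromosome placement ---------------------------------------------
    chroms = [f"{sub}{i + 1:02d}" for sub in "AD"
              for i in range(config.n_chromosomes_per_subgenome)]
    GAP, TANDEM_GAP = 5000, 2500
    cursor = {c: GAP for c in chroms}
    placements: list[dict] = []  # one entry per gene (members + decoys)

    def place(idx_key, seq_aa, chrom, strand, intronless, tandem_with=None):
        cds = "".join(_CODON[a] for a in seq_aa) + _STOP
        if intronless:
            exon_lens = [len(cds)]
        else:
            n_ex = int(rng_place.integers(2, 6))
            cuts = sorted(rng_place.choice(np.arange(1, len(cds) // 3), size=n_ex - 1,
                                           replace=False) * 3)
            bounds = [0] + [int(c) for c in cuts] + [len(cds)]
            exon_lens = [bounds[i + 1] - bounds[i] for i in range(n_ex)]
        intron_lens = [int(rng_place.integers(100, 301)) for _ in range(len(exon_lens) - 1)]
        start = cursor[chrom]
        exons, pos = [], start
        for i, el in enumerate(exon_lens):
            exons.append((pos, pos + el))
            pos += el
            if i < len(intron_lens):
                pos += intron_lens[i]
        end = pos
        cursor[chrom] = end + (TANDEM_GAP if tandem_with else GAP)
        placements.append({"key": idx_key, "chrom": chrom, "strand": strand,
                           "start": start, "end": end, "exons": exons,
                           "cds": cds, "seq": seq_aa})

    # choose chromosomes: tandem pairs adjacent on one chromosome; segmental
    # partners forced onto different chromosomes; everything else round-robin
    placed = set()
    order = list(range(len(members)))
    chrom_of: dict[int, str] = {}
    ci = 0
    for a, b, mode in pair_slots:
        if mode == "tandem":
            c = chroms[ci % len(chroms)]
            ci += 1
            chrom_of[a] = chrom_of[b] = c
        else:
            ca = chroms[ci % len(chroms)]
            cb = chroms[(ci + 1) % len(chroms)]
            ci += 2
            chrom_of[a], chrom_of[b] = ca, cb
    for i in order:
        if i not in chrom_of:
            chrom_of[i] = chroms[ci % len(chroms)]
            ci += 1

    # place tandem pairs back-to-back first, then the rest in index order
    for a, b, mode in pair_slots:
        if mode != "tandem":
            continue
        strand = "+" if rng_place.random() < 0.5 else "-"
        place(("M", a), members[a]["seq"], chrom_of[a], strand,
              a in intronless_set, tandem_with=b)
        place(("M", b), members[b]["seq"], chrom_of[b], strand,
              b in intronless_set, tandem_with=None)
        placed.update((a, b))
    for i in order:
        if i in placed:
            continue
        strand = "+" if rng_place.random() < 0.5 else "-"
        place(("M", i), members[i]["seq"], chrom_of[i], strand, i in intronless_set)
    for did, dseq in decoys.items():
        c = chroms[int(rng_place.integers(len(chroms)))]
        strand = "+" if rng_place.random() < 0.5 else "-"
        place(("D", did), dseq, c, strand, bool(rng_place.random() < 0.2))

    # --- final gene names, position-ordered within subfamily ----------------
    member_place = {p["key"][1]: p for p in placements if p["key"][0] == "M"}
    names: dict[int, str] = {}
    for fam in SUBFAMILIES:
        idxs = sorted(by_fam[fam],
                      key=lambda i: (member_place[i]["chrom"], member_place[i]["start"]))
        for rank, i in enumerate(idxs, 1):
            names[i] = f"{fam}{rank:02d}"

    # --- promoters with exact planted element counts ------------------------
    abre_counts, dre_counts = _default_element_counts(config, names, rng_prom)
    planted_elements: dict[str, list] = {}
    promoter_strings: dict[str, str] = {}
    for i in sorted(names):
        name = names[i]
        prom, planted = _build_promoter(
            rng_prom, config.promoter_len,
            {"ABRE": abre_counts.get(name, 0), "DRE": dre_counts.get(name, 0)},
        )
        promoter_strings[name] = prom
        planted_elements[name] = planted

    # --- assemble genome ----------------------------------------------------
    genome: dict[str, str] = {}
    chrom_len = {c: cursor[c] + GAP for c in chroms}
    arrays = {c: np.array(list(_random_dna(rng_place, chrom_len[c]))) for c in chroms}
    gene_models: list[GeneModel] = []
    proteome: dict[str, str] = {}
    for p in placements:
        kind, key = p["key"]
        name = names[key] if kind == "M" else key
        # write exonic CDS (strand-aware) into the chromosome
        # genomic exon concatenation equals the CDS (+) or its reverse
        # complement (-); either way it lays out left to right
        cds = p["cds"] if p["strand"] == "+" else revcomp(p["cds"])
        offset = 0
        for s, e in p["exons"]:
            arrays[p["chrom"]][s:e] = list(cds[offset:offset + (e - s)])
            offset += e - s
        gene_models.append(GeneModel(
            id=name, chromosome=p["chrom"], strand=p["strand"],
            start=p["start"], end=p["end"], exons=p["exons"],
            subgenome=p["chrom"][0],
        ))
        proteome[name] = p["seq"]
        if kind == "M":
            # plant the promoter upstream of the TSS, strand-aware
            prom = promoter_strings[name]
            if p["strand"] == "+":
                arrays[p["chrom"]][p["start"] - len(prom):p["start"]] = list(prom)
            else:
                arrays[p["chrom"]][p["end"]:p["end"] + len(prom)] = list(revcomp(prom))
    genome = {c: "".join(arrays[c]) for c in chroms}
    gene_models.sort(key=lambda g: (g.chromosome, g.start))

    # --- truth table --------------------------------------------------------
    for i, m in enumerate(members):
        name = names[i]
        p = member_place[i]
        truth.genes[name] = {
            "subfamily": m["subfamily"],
            "chromosome": p["chrom"],
            "subgenome": p["chrom"][0],
            "strand": p["strand"],
            "start": p["start"], "end": p["end"],
            "n_exons": len(p["exons"]),
            "intronless": len(p["exons"]) == 1,
            "partner": names[m["partner"]] if m["partner"] is not None else None,
            "mode": m["mode"],
            "abre_count": abre_counts.get(name, 0),
            "dre_count": dre_counts.get(name, 0),
            "planted_elements": planted_elements[name],
            "is_family": True,
        }
    for did in decoys:
        truth.genes[did] = {"subfamily": None, "is_family": False}
    truth.subfamily_counts = dict(fam_counts)
    truth.pair_modes = {
        "segmental": sorted(sorted([names[a], names[b]]) for a, b, md in pair_slots
                            if md == "segmental"),
        "tandem": sorted(sorted([names[a], names[b]]) for a, b, md in pair_slots
                         if md == "tandem"),
    }

    # --- write artifacts ----------------------------------------------------
    files = {
        "genome": str(out / "genome.fa"),
        "gff": str(out / "genes.gff3"),
        "proteome": str(out / "proteome.fa"),
        "anchors": str(out / "anchors.fa"),
        "anchor_domains": str(out / "anchor_domains.fa"),
        "truth": str(out / "truth.json"),
    }
    write_fasta(genome, files["genome"])
    write_gff3(gene_models, files["gff"])
    write_fasta(proteome, files["proteome"])
    write_fasta(anchors, files["anchors"])
    write_fasta(anchor_domains, files["anchor_domains"])
    truth.files.update(files)
    truth.to_json(files["truth"])
    return truth


def _default_element_counts(config, names, rng):
    """Planted ABRE/DRE counts per gene.

    Defaults mirror the survey's structure: roughly 60% of family genes
    carry ABREs (about 4 each) and roughly 15% carry a single DRE.
    """
    if config.abre_counts is not None and config.dre_counts is not None:
        return dict(config.abre_counts), dict(config.dre_counts)
    all_names = sorted(names.values())
    n = len(all_names)
    abre = dict(config.abre_counts or {})
    dre = dict(config.dre_counts or {})
    if config.abre_counts is None:
        n_pos = int(round(0.6 * n))
        pos = list(rng.choice(all_names, size=n_pos, replace=False))
        for g in pos:
            abre[g] = int(rng.integers(2, 7))  # mean about 4
    if config.dre_counts is None:
        n_pos = max(int(round(0.15 * n)), 1) if n else 0
        pos = list(rng.choice(all_names, size=n_pos, replace=False))
        for g in pos:
            dre[g] = 1
    return abre, dre


def _build_promoter(rng: np.random.Generator, length: int,
                    counts: dict[str, int]) -> tuple[str, list]:
    """Background promoter with exact planted element occurrence counts.

    Accidental matches of any dictionary element are removed by resampling
    their windows; planted windows are protected. Returns the promoter and
    the planted hits as [element, position, strand] triples.
    """
    elements = DEFAULT_ELEMENTS
    max_w = max(len(p) for p in elements.values())
    total = sum(counts.values())
    if total * (max_w + 6) > length:
        raise ValueError("planted elements do not fit in the promoter "
                         "without forced overlap")
    for _attempt in range(50):
        seq = list(_random_dna(rng, length))
        # choose well-separated positions
        positions = []
        tries = 0
        while len(positions) < total and tries < 1000:
            pos = int(rng.integers(0, length - max_w))
            if all(abs(pos - q) >= max_w + 6 for q in positions):
                positions.append(pos)
            tries += 1
        if len(positions) < total:
            continue
        planted = []
        protected = np.zeros(length, dtype=bool)
        k = 0
        for el, cnt in sorted(counts.items()):
            pattern = elements[el]
            for _ in range(cnt):
                pos = positions[k]
                k += 1
                concrete = "".join(IUPAC[c][rng.integers(len(IUPAC[c]))]
                                   for c in pattern)
                strand = "+" if rng.random() < 0.5 else "-"
                ins = concrete if strand == "+" else revcomp(concrete)
                seq[pos:pos + len(ins)] = list(ins)
                protected[pos:pos + len(ins)] = True
                planted.append([el, pos, strand])
        planted_keys = {(el, pos, st) for el, pos, st in planted}
        ok = False
        for _round in range(100):
            hits = scan_cis_elements("".join(seq), elements, both_strands=True)
            extra = [h for h in hits
                     if (h.element, h.position, h.strand) not in planted_keys]
            if not extra:
                ok = True
                break
            progress = False
            for h in extra:
                idxs = [i for i in range(h.position, h.position + len(h.matched))
                        if not protected[i]]
                for i in idxs:
                    seq[i] = DNA[rng.integers(4)]
                    progress = True
            if not progress:
                break  # accidental hit inside protected bases: replant
        if ok:
            return "".join(seq), planted
    raise RuntimeError("could not build a clean promoter (packing too tight)")


# ---------------------------------------------------------------------------
# expression, qPCR and physiology tables

_PROFILE_MULTIPLIERS = {
    # factors relative to day 0, for days 2, 4, 6, 8
    "continuous": (2.8, 4.0, 6.0, 9.0),
    "induced": (3.5, 4.5, 1.2, 1.0),
    "repressed": (0.35, 0.30, 0.40, 0.35),
    "unchanged": (1.0, 1.1, 0.9, 1.05),
}

PHYSIO_MEASURES = ("MDA", "proline", "SOD", "POD", "RWC_leaf", "RWC_soil",
                   "stomatal_ratio")
# group means under (control, drought); silenced genotypes shift under drought
_PHYSIO_BASE = {
    "MDA": (10.0, 18.0), "proline": (30.0, 80.0), "SOD": (200.0, 320.0),
    "POD": (150.0, 260.0), "RWC_leaf": (92.0, 75.0), "RWC_soil": (90.0, 40.0),
    "stomatal_ratio": (2.6, 1.4),
}
_PHYSIO_SILENCED_DROUGHT_FACTOR = {
    "MDA": 1.5, "proline": 0.55, "SOD": 0.65, "POD": 0.6,
    "RWC_leaf": 0.75, "RWC_soil": 0.7, "stomatal_ratio": 1.5,
}


def default_expression_profiles(truth: TruthTable,
                                rng: np.random.Generator) -> dict[str, str]:
    """Planted drought profiles: 3 continuous, 8 induced, 4 repressed, rest
    unchanged (scaled down when the family is smaller)."""
    genes = sorted(g for g, info in truth.genes.items() if info.get("is_family"))
    n = len(genes)
    n_cont, n_ind, n_rep = min(3, n), min(8, max(n - 3, 0)), min(4, max(n - 11, 0))
    shuffled = list(rng.permutation(genes))
    profiles = {}
    for g in shuffled[:n_cont]:
        profiles[g] = "continuous"
    for g in shuffled[n_cont:n_cont + n_ind]:
        profiles[g] = "induced"
    for g in shuffled[n_cont + n_ind:n_cont + n_ind + n_rep]:
        profiles[g] = "repressed"
    for g in shuffled[n_cont + n_ind + n_rep:]:
        profiles[g] = "unchanged"
    return profiles


def generate_expression_tables(config: FamilySimConfig, truth: TruthTable,
                               out_dir: str | os.PathLike,
                               library_size: int = 20_000_000):
    """Emit drought counts/FPKM, qPCR Ct, physiology and survival tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng([config.seed % (2**31), 19])
    rng_phys = np.random.default_rng([config.seed % (2**31), 23])

    family = sorted(g for g, info in truth.genes.items() if info.get("is_family"))
    profiles = dict(config.expr_profiles) if config.expr_profiles else \
        default_expression_profiles(truth, rng)
    missing = set(family) - set(profiles)
    if missing:
        raise ValueError(f"expression profiles missing for genes: {sorted(missing)}")

    gene_len = {g: int(rng.integers(800, 2200)) for g in family}
    baseline = {g: float(2 ** rng.normal(4.5, 1.0)) for g in family}  # FPKM scale

    samples = [f"d{t}_r{r + 1}" for t in TIMEPOINTS for r in range(N_REPLICATES)]
    counts = pd.DataFrame(0, index=family, columns=samples, dtype=int)
    for g in family:
        mult = (1.0,) + _PROFILE_MULTIPLIERS[profiles[g]]
        for ti, t in enumerate(TIMEPOINTS):
            for r in range(N_REPLICATES):
                noise = 2.0 ** rng.normal(0.0, config.expr_noise_sd)
                f = baseline[g] * mult[ti] * noise
                c = f * library_size * gene_len[g] / 1e9
                counts.loc[g, f"d{t}_r{r + 1}"] = int(round(c))
    lengths = pd.Series(gene_len, name="length")
    lib = pd.Series(library_size, index=samples, name="library_size")
    fpkm_df = 1e9 * counts.div(lib, axis=1).div(lengths, axis=0)

    # qPCR panel: genes with planted non-unchanged profiles plus a few others
    panel = [g for g in family if profiles[g] != "unchanged"][:11] or family[:3]
    ct_rows = []
    for g in panel:
        mult = (1.0,) + _PROFILE_MULTIPLIERS[profiles[g]]
        base_rel = float(2 ** rng.normal(-4.0, 0.5))  # relative to housekeeping
        for ti, t in enumerate(TIMEPOINTS):
            for r in range(N_REPLICATES):
                rel = base_rel * mult[ti] * 2.0 ** rng.normal(0.0, config.expr_noise_sd)
                ct_rows.append({"gene": g, "sample": f"d{t}_r{r + 1}",
                                "timepoint": t, "replicate": r + 1,
                                "ct_target": round(25.0 - np.log2(rel), 3),
                                "ct_reference": 25.0})
    ct_df = pd.DataFrame(ct_rows)

    # physiology: three genotypes x two treatments x three replicates
    groups = ("TRV2:00", "TRV2:geneA", "TRV2:geneB")
    phys_rows = []
    for measure in PHYSIO_MEASURES:
        ctrl_mean, drought_mean = _PHYSIO_BASE[measure]
        for group in groups:
            for treatment, mean in (("control", ctrl_mean), ("drought", drought_mean)):
                m = mean
                if treatment == "drought" and group != "TRV2:00":
                    m = mean * _PHYSIO_SILENCED_DROUGHT_FACTOR[measure]
                for rep in range(1, N_REPLICATES + 1):
                    val = m * (1.0 + rng_phys.normal(0.0, 0.04))
                    phys_rows.append({"measure": measure, "group": group,
                                      "treatment": treatment, "replicate": rep,
                                      "value": round(float(val), 4)})
    phys_df = pd.DataFrame(phys_rows)
    survival = pd.DataFrame([
        {"group": "TRV2:00", "n_survived": 12, "n_total": 12},
        {"group": "TRV2:geneA", "n_survived": 8, "n_total": 12},
        {"group": "TRV2:geneB", "n_survived": 6, "n_total": 12},
    ])

    files = {
        "counts": str(out / "drought_counts.tsv"),
        "fpkm": str(out / "drought_fpkm.tsv"),
        "gene_lengths": str(out / "gene_lengths.tsv"),
        "library_sizes": str(out / "library_sizes.tsv"),
        "ct": str(out / "qpcr_ct.tsv"),
        "physiology": str(out / "physiology.tsv"),
        "survival": str(out / "survival.tsv"),
    }
    counts.rename_axis("gene").to_csv(files["counts"], sep="\t")
    fpkm_df.rename_axis("gene").round(4).to_csv(files["fpkm"], sep="\t")
    lengths.rename_axis("gene").to_frame().to_csv(files["gene_lengths"], sep="\t")
    lib.rename_axis("sample").to_frame().to_csv(files["library_sizes"], sep="\t")
    ct_df.to_csv(files["ct"], sep="\t", index=False)
    phys_df.to_csv(files["physiology"], sep="\t", index=False)
    survival.to_csv(files["survival"], sep="\t", index=False)

    for g in family:
        truth.genes[g]["profile"] = profiles[g]
        truth.genes[g]["gene_length"] = gene_len[g]
    truth.files.update(files)
    if "truth" in truth.files:
        truth.to_json(truth.files["truth"])
    return truth


def simulate_all(config: FamilySimConfig, out_dir: str | os.PathLike) -> TruthTable:
    """Run the full generator (genome + expression artifacts)."""
    truth = generate_family_genome(config, out_dir)
    return generate_expression_tables(config, truth, out_dir)
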