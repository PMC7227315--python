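"""End-to-end survey: identify -> phylogeny -> duplication -> structure ->
promoters -> expression, with a machine-readable report.

The report carries only quantities re-derivable from stage outputs; a
validator compares a report against a simulation truth table field by
field and returns the list of mismatches (empty means perfect recovery).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .align import center_star_msa
from .duplication import classify_all, detect_duplication_pairs, subgenome_census
from .expression import classify_drought_response, fold_change, fpkm
from .identify import build_profile, identify_family
from .io import read_fasta, read_gff3
from .phylo import assign_subfamily, bootstrap_support, neighbor_joining, p_distance_matrix
from .promoters import extract_promoter, family_cis_summary, scan_cis_elements
from .simulate import FamilySimConfig, TruthTable, simulate_all
from .structure import exon_intron_stats

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1
PROFILE_TO_CLASS = {"continuous": "continuously_induced", "induced": "induced",
                    "repressed": "repressed", "unchanged": "unchanged"}


def run_survey(files: dict[str, str], *,
               promoter_len: int = 2000,
               coverage_threshold: float = 0.70,
               identity_threshold: float = 0.70,
               tandem_max_separation: int = 1,
               bootstrap_replicates: int = 1000,
               up_threshold: float = 2.0,
               down_threshold: float = 0.5,
               seed: int = 0) -> dict:
    """Run every survey stage over the input files and build the report.

    ``files`` must provide genome, gff, proteome, anchors, anchor_domains;
    the expression block (counts, gene_lengths, library_sizes) is optional
    and leaves the expression fields null when absent.
    """
    for key in ("genome", "gff", "proteome", "anchors", "anchor_domains"):
        if key not in files:
            raise ValueError(f"run_survey: missing input {key!r}")
        if not Path(files[key]).exists():
            raise FileNotFoundError(f"run_survey: input file missing: {files[key]}")

    stage = "identify"
    try:
        genome = read_fasta(files["genome"])
        gene_models = {g.id: g for g in read_gff3(files["gff"])}
        proteome = read_fasta(files["proteome"])
        anchor_domains = read_fasta(files["anchor_domains"])
        profile = build_profile(list(anchor_domains.values()))
        members = identify_family(proteome, profile, list(gene_models.values()))
        member_seqs = {m.id: m.sequence for m in members}

        stage = "phylogeny"
        anchors = read_fasta(files["anchors"])
        anchor_labels = _anchor_labels(anchors, files)
        ids = list(member_seqs) + list(anchors)
        seqs = list(member_seqs.values()) + list(anchors.values())
        msa = center_star_msa(ids, seqs)
        if bootstrap_replicates > 0:
            tree = bootstrap_support(msa, n_replicates=bootstrap_replicates, seed=seed)
        else:
            tree = neighbor_joining(*p_distance_matrix(msa))
        subfamilies = assign_subfamily(tree, anchor_labels)

        stage = "duplication"
        pairs = detect_duplication_pairs(member_seqs,
                                         coverage_threshold=coverage_threshold,
                                         identity_threshold=identity_threshold)
        pairs = classify_all(pairs, gene_models, tandem_max_separation)
        census = subgenome_census(list(member_seqs), gene_models)

        stage = "structure"
        member_models = [gene_models[m] for m in member_seqs if m in gene_models]
        structure = exon_intron_stats(member_models, subfamilies)

        stage = "promoters"
        hits_per_gene = {}
        for mid in member_seqs:
            g = gene_models.get(mid)
            if g is None:
                hits_per_gene[mid] = []
                continue
            prom = extract_promoter(genome, g, length=promoter_len)
            hits_per_gene[mid] = scan_cis_elements(prom, gene=mid)
        cis = family_cis_summary(hits_per_gene)

        stage = "expression"
        expression = None
        if files.get("counts"):
            counts = pd.read_csv(files["counts"], sep="\t", index_col=0)
            lengths = pd.read_csv(files["gene_lengths"], sep="\t", index_col=0)["length"]
            lib = None
            if files.get("library_sizes"):
                lib = pd.read_csv(files["library_sizes"], sep="\t", index_col=0)["library_size"]
            fpkm_df = fpkm(counts, lengths, lib)
            expression = _classify_expression(fpkm_df, up_threshold, down_threshold)
    except Exception as exc:
        raise RuntimeError(f"survey stage {stage!r} failed: {exc}") from exc

    mode_counts = {"segmental": 0, "tandem": 0, "undetermined": 0}
    for p in pairs:
        mode_counts[p.mode or "undetermined"] += 1

    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "n_members": len(members),
        "member_ids": sorted(member_seqs),
        "subfamily_assignments": {m: subfamilies.get(m, "unassigned")
                                  for m in member_seqs},
        "subfamily_counts": _count_values(
            {m: subfamilies.get(m, "unassigned") for m in member_seqs}),
        "subgenome_counts": census["per_subgenome"],
        "per_chromosome_counts": census["per_chromosome"],
        "n_unplaced": len(census["unplaced"]),
        "duplication": {
            "total": len(pairs),
            **mode_counts,
            "pairs": [{"gene_a": p.gene_a, "gene_b": p.gene_b, "mode": p.mode,
                       "coverage": round(p.coverage, 4),
                       "identity": round(p.identity, 4)} for p in pairs],
        },
        "ortholog_pairs": None,
        "intronless": {
            "total": structure["summary"]["total_intronless"],
            "per_subfamily": structure["summary"].get("intronless_per_subfamily", {}),
        },
        "cis_elements": {
            el: {"n_positive_genes": v["n_positive_genes"],
                 "mean_hits_per_positive_gene": v["mean_hits_per_positive_gene"],
                 "per_gene_counts": v["per_gene_counts"]}
            for el, v in cis.items()
        },
        "drought_response": expression,
        "bootstrap_supports": sorted(tree.supports.values(), reverse=True) or None,
        "provenance": {
            "seed": seed,
            "package_version": __version__,
            "inputs_sha256": {k: _sha256(v) for k, v in sorted(files.items())
                              if v and Path(v).exists()},
        },
    }
    return report


def _anchor_labels(anchors: dict[str, str], files: dict[str, str]) -> dict[str, str]:
    """Anchor subfamily labels from the truth table when present, else from
    the ``ANC_<LABEL><k>`` naming convention."""
    if files.get("truth"):
        truth = TruthTable.from_json(files["truth"])
        if truth.anchor_labels:
            return dict(truth.anchor_labels)
    labels = {}
    for aid in anchors:
        name = aid.removeprefix("ANC_")
        labels[aid] = name.rstrip("0123456789")
    return labels


def _classify_expression(fpkm_df: pd.DataFrame, up: float, down: float) -> dict:
    """Average replicates per timepoint, fold change vs the first timepoint,
    then classify each gene's drought response."""
    tps = sorted({c.split("_")[0] for c in fpkm_df.columns},
                 key=lambda s: int(s.lstrip("d")))
    means = pd.DataFrame({t: fpkm_df[[c for c in fpkm_df.columns
                                      if c.split("_")[0] == t]].mean(axis=1)
                          for t in tps})
    t0 = tps[0]
    classes = {}
    for gene in means.index:
        fc = [fold_change(means.loc[gene, t], means.loc[gene, t0], gene=gene)
              for t in tps[1:]]
        classes[gene] = classify_drought_response(fc, up, down)
    return {"classes": classes, "counts": _count_values(classes)}


def _count_values(mapping: dict[str, str]) -> dict[str, int]:
    out: dict[str, int] = {}
    for v in mapping.values():
        out[v] = out.get(v, 0) + 1
    return dict(sorted(out.items()))


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_simulated_survey(config: FamilySimConfig, out_dir, **kwargs):
    """Simulate a dataset and immediately survey it. Returns (report, truth)."""
    truth = simulate_all(config, out_dir)
    report = run_survey(truth.files, seed=config.seed,
                        promoter_len=config.promoter_len, **kwargs)
    return report, truth


def validate_report(report: dict, truth: TruthTable) -> list[str]:
    """Field-by-field comparison of a survey report against planted truth.

    Returns human-readable mismatch descriptions; an empty list means
    perfect recovery. A null expression block against planted profiles is
    reported as a skipped stage, not an error.
    """
    if "n_members" not in report or "subfamily_assignments" not in report:
        raise ValueError("validate_report: report does not match schema")
    mism: list[str] = []
    family = {g: info for g, info in truth.genes.items() if info.get("is_family")}

    if report["n_members"] != len(family):
        mism.append(f"n_members: report {report['n_members']} != truth {len(family)}")
    if set(report["member_ids"]) != set(family):
        extra = set(report["member_ids"]) - set(family)
        missing = set(family) - set(report["member_ids"])
        mism.append(f"member_ids: extra {sorted(extra)}, missing {sorted(missing)}")

    for g, info in family.items():
        got = report["subfamily_assignments"].get(g)
        if got != info["subfamily"]:
            mism.append(f"subfamily[{g}]: report {got} != truth {info['subfamily']}")

    truth_sub: dict[str, int] = {}
    for info in family.values():
        truth_sub[info["subgenome"]] = truth_sub.get(info["subgenome"], 0) + 1
    if report["subgenome_counts"] != truth_sub:
        mism.append(f"subgenome_counts: report {report['subgenome_counts']} "
                    f"!= truth {truth_sub}")

    got_pairs = {(p["gene_a"], p["gene_b"]): p["mode"]
                 for p in report["duplication"]["pairs"]}
    truth_pairs = {}
    for mode, pairs in truth.pair_modes.items():
        for a, b in pairs:
            truth_pairs[(a, b)] = mode
    if set(got_pairs) != set(truth_pairs):
        mism.append(f"duplication pairs: extra {sorted(set(got_pairs) - set(truth_pairs))}, "
                    f"missing {sorted(set(truth_pairs) - set(got_pairs))}")
    else:
        for key, mode in truth_pairs.items():
            if got_pairs[key] != mode:
                mism.append(f"duplication mode{key}: report {got_pairs[key]} != truth {mode}")

    truth_intronless = sum(1 for info in family.values() if info["intronless"])
    if report["intronless"]["total"] != truth_intronless:
        mism.append(f"intronless total: report {report['intronless']['total']} "
                    f"!= truth {truth_intronless}")

    for el, key in (("ABRE", "abre_count"), ("DRE", "dre_count")):
        truth_counts = {g: info.get(key, 0) for g, info in family.items()}
        positive = {g: c for g, c in truth_counts.items() if c > 0}
        mean = sum(positive.values()) / len(positive) if positive else None
        got = report["cis_elements"].get(el, {"n_positive_genes": 0,
                                              "mean_hits_per_positive_gene": None,
                                              "per_gene_counts": {}})
        if got["n_positive_genes"] != len(positive):
            mism.append(f"cis {el} positive genes: report {got['n_positive_genes']} "
                        f"!= truth {len(positive)}")
        got_mean = got["mean_hits_per_positive_gene"]
        if (got_mean is None) != (mean is None) or (
                mean is not None and abs(got_mean - mean) > 1e-9):
            mism.append(f"cis {el} mean hits: report {got_mean} != truth {mean}")
        got_counts = {g: got["per_gene_counts"].get(g, 0) for g in family}
        if got_counts != truth_counts:
            diff = {g: (got_counts[g], truth_counts[g]) for g in family
                    if got_counts[g] != truth_counts[g]}
            mism.append(f"cis {el} per-gene counts differ: {diff}")

    has_profiles = any("profile" in info for info in family.values())
    if report.get("drought_response") is None:
        if has_profiles:
            mism.append("drought_response: stage skipped (truth has profiles)")
    elif has_profiles:
        classes = report["drought_response"]["classes"]
        for g, info in family.items():
            want = PROFILE_TO_CLASS[info["profile"]]
            got = classes.get(g)
            if got != want:
                mism.append(f"drought_response[{g}]: report {got} != truth {want}")
    return mism
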