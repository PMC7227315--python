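"""Exon/intron statistics from gene models."""

from __future__ import annotations

from .io import GeneModel


def exon_intron_stats(gene_models: list[GeneModel],
                      subfamilies: dict[str, str] | None = None) -> dict:
    """Per-gene exon/intron counts and a per-subfamily intronless summary.

    Gene-model invariants (sorted, disjoint exons inside the gene span) are
    enforced by GeneModel itself; a model with no exon records is rejected
    here because its structure is unknown, not intronless.
    """
    per_gene = {}
    for g in gene_models:
        if g.n_exons == 0:
            raise ValueError(f"gene {g.id}: no exon records")
        per_gene[g.id] = {
            "n_exons": g.n_exons,
            "n_introns": g.n_introns,
            "intronless": g.intronless,
        }
    summary: dict[str, int] = {"total_intronless": sum(1 for v in per_gene.values() if v["intronless"])}
    if subfamilies:
        per_subfam: dict[str, int] = {}
        for gid, v in per_gene.items():
            if v["intronless"]:
                fam = subfamilies.get(gid, "unassigned")
                per_subfam[fam] = per_subfam.get(fam, 0) + 1
        summary["intronless_per_subfamily"] = per_subfam
    return {"per_gene": per_gene, "summary": summary}
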