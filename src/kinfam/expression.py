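"""Expression quantification and drought-physiology statistics.

FPKM follows the standard closed form 1e9 * c / (N * L) for c mapped
fragments on a gene of length L bp in a library of N mapped fragments.
qPCR relative expression is 2^-(Ct_target - Ct_reference) against a
housekeeping control; fold change between conditions is the plain ratio of
expression values. Concordance between qPCR and RNA-seq fold changes is
the sample Pearson correlation. Group comparisons use the equal-variance
two-sample Student's t (Welch optional), with the usual star notation
(* p<0.05, ** p<0.01).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def fpkm(counts: pd.DataFrame, gene_lengths: pd.Series,
         library_sizes: pd.Series | None = None) -> pd.DataFrame:
    """FPKM matrix from a genes x samples count matrix.

    ``gene_lengths`` in bp, indexed like the rows; ``library_sizes``
    defaults to per-sample column sums.
    """
    lengths = gene_lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = lengths[lengths.isna()].index.tolist()
        raise ValueError(f"fpkm: missing gene lengths for {missing}")
    if (lengths <= 0).any():
        raise ValueError("fpkm: gene lengths must be positive")
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    if (library_sizes <= 0).any():
        raise ValueError("fpkm: library sizes must be positive")
    return 1e9 * counts.div(library_sizes, axis=1).div(lengths, axis=0)


def heatmap_normalize(matrix: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """log2(x+1) then per-row z-score; constant rows map to zeros (flagged)."""
    if (matrix < 0).any().any():
        raise ValueError("heatmap_normalize: negative values")
    logm = np.log2(matrix + 1.0)
    mean = logm.mean(axis=1)
    sd = logm.std(axis=1, ddof=1)
    constant = sd[sd == 0].index.tolist()
    z = logm.sub(mean, axis=0).div(sd.replace(0.0, 1.0), axis=0)
    z.loc[constant] = 0.0
    return z, constant


@dataclass
class QpcrRecord:
    gene: str
    sample: str
    ct_target: float
    ct_reference: float

    def __post_init__(self) -> None:
        for name, ct in (("target", self.ct_target), ("reference", self.ct_reference)):
            if ct is None or math.isnan(ct):
                raise ValueError(f"{self.gene}/{self.sample}: missing {name} Ct")
            if not 0 < ct < 50:
                raise ValueError(f"{self.gene}/{self.sample}: {name} Ct {ct} out of range")


def relative_expression_dct(record: QpcrRecord) -> float:
    """2^-(Ct_target - Ct_reference)."""
    return 2.0 ** -(record.ct_target - record.ct_reference)


def fold_change(treated: float, control: float, pseudocount: float = 0.0,
                gene: str = "") -> float:
    """(treated + pseudocount) / (control + pseudocount)."""
    if treated < 0 or control < 0:
        raise ValueError(f"fold_change{' for ' + gene if gene else ''}: negative expression")
    denom = control + pseudocount
    if denom == 0:
        raise ValueError(
            f"fold_change: zero control expression{' for gene ' + gene if gene else ''}"
            " (set a pseudocount to proceed)"
        )
    return (treated + pseudocount) / denom


def concordance_r(fc_qpcr, fc_rnaseq) -> float:
    """Sample Pearson correlation between paired fold-change vectors."""
    x = np.asarray(fc_qpcr, dtype=float)
    y = np.asarray(fc_rnaseq, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("concordance_r: vectors must be paired 1-D")
    if len(x) < 3:
        raise ValueError("concordance_r: need at least 3 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("concordance_r: zero variance")
    return float(stats.pearsonr(x, y).statistic)


def classify_drought_response(fc_series, up_threshold: float = 2.0,
                              down_threshold: float = 0.5) -> str:
    """Classify a fold-change series over post-treatment timepoints.

    continuously_induced: FC above the up threshold at every timepoint;
    induced: at >=1 timepoint; repressed: below the down threshold at >=1
    timepoint and never above the up threshold; otherwise unchanged.
    A series both above and below resolves to induced (precedence).
    """
    fc = list(fc_series)
    if len(fc) < 2:
        raise ValueError("classify_drought_response: need >=2 post-treatment timepoints")
    up = [f > up_threshold for f in fc]
    down = [f < down_threshold for f in fc]
    if all(up):
        return "continuously_induced"
    if any(up):
        return "induced"
    if any(down):
        return "repressed"
    return "unchanged"


def student_t_test(group_a, group_b, welch: bool = False) -> dict:
    """Two-sample t-test (pooled variance by default) with star notation."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("student_t_test: need >=2 values per group")
    if np.std(a) == 0 and np.std(b) == 0 and a.mean() == b.mean():
        return {"t": 0.0, "df": len(a) + len(b) - 2, "p": 1.0, "stars": ""}
    res = stats.ttest_ind(a, b, equal_var=not welch)
    p = float(res.pvalue)
    stars = "**" if p < 0.01 else ("*" if p < 0.05 else "")
    return {"t": float(res.statistic), "df": float(res.df), "p": p, "stars": stars}


def survival_rate(n_survived: int, n_total: int) -> float:
    """Percentage of plants surviving re-watering."""
    if n_total <= 0:
        raise ValueError("survival_rate: n_total must be positive")
    if not 0 <= n_survived <= n_total:
        raise ValueError("survival_rate: n_survived outside [0, n_total]")
    return 100.0 * n_survived / n_total


def relative_water_content(fresh: float, turgid: float, dry: float) -> float:
    """RWC = 100 * (fresh - dry) / (turgid - dry)."""
    if turgid == dry:
        raise ValueError("relative_water_content: turgid weight equals dry weight")
    if turgid < dry:
        raise ValueError("relative_water_content: turgid weight below dry weight")
    rwc = 100.0 * (fresh - dry) / (turgid - dry)
    if not 0 <= rwc <= 100:
        import logging
        logging.getLogger(__name__).warning(
            "RWC %.1f%% outside [0, 100]: fresh weight outside dry..turgid range", rwc
        )
    return rwc


def stomatal_ratio_summary(lengths, widths) -> dict:
    """Per-stoma length/width ratios with group mean/sd and an n>50 check."""
    lengths = np.asarray(lengths, dtype=float)
    widths = np.asarray(widths, dtype=float)
    if lengths.shape != widths.shape:
        raise ValueError("stomatal_ratio_summary: unpaired values")
    if (widths <= 0).any() or (lengths <= 0).any():
        raise ValueError("stomatal_ratio_summary: non-positive measurement")
    ratios = lengths / widths
    n = len(ratios)
    warning = None
    if n <= 50:
        warning = f"n={n} stomata measured; more than 50 per sample expected"
        import logging
        logging.getLogger(__name__).warning(warning)
    return {
        "ratios": ratios.tolist(),
        "mean": float(ratios.mean()),
        "sd": float(ratios.std(ddof=1)) if n > 1 else 0.0,
        "n": n,
        "warning": warning,
    }
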