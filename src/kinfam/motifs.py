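"""De novo conserved-motif discovery by ZOOPS expectation-maximization.

The ZOOPS model (zero or one occurrence per sequence, MEME's default)
treats each sequence as containing one motif occurrence with probability
lambda, at a uniformly chosen position, against an i.i.d. background. EM
alternates a posterior over site positions/absence (E) with PWM and lambda
re-estimation (M) until the log-likelihood gain falls below tolerance.
Several seeded restarts are run and the best kept; motifs are discovered
sequentially, erasing each motif's committed sites before the next search,
which keeps site sets pairwise disjoint. Motif order is discovery order,
not necessarily the order an external tool would report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .identify import AMINO_ACIDS

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


@dataclass
class MotifModel:
    width: int
    pwm: np.ndarray  # (width, 20), columns sum to 1
    lam: float  # ZOOPS prior of occurrence
    background: np.ndarray  # (20,)
    log_likelihood: float
    sites: dict[str, tuple[int, float]] = field(default_factory=dict)  # id -> (pos, posterior)

    @property
    def consensus(self) -> str:
        return "".join(AMINO_ACIDS[i] for i in self.pwm.argmax(axis=1))

    @property
    def information_content(self) -> float:
        ratio = self.pwm / self.background[None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(self.pwm > 0, self.pwm * np.log2(ratio), 0.0)
        return float(terms.sum())


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_AA_INDEX[c] for c in seq], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"invalid residue {exc.args[0]!r}") from None


def _window_ratios(enc: np.ndarray, mask: np.ndarray, log_odds: np.ndarray) -> np.ndarray:
    """Likelihood ratio motif/background for every window; masked windows -> 0."""
    w = log_odds.shape[0]
    n = len(enc)
    if n < w:
        return np.empty(0)
    m = n - w + 1
    scores = np.zeros(m)
    for c in range(w):
        scores += log_odds[c][enc[c:c + m]]
    ratios = np.exp(scores)
    # windows overlapping an erased position are disallowed
    if mask.any():
        bad = np.convolve(mask.astype(int), np.ones(w, dtype=int), mode="valid") > 0
        ratios[bad] = 0.0
    return ratios


def _em_once(encs, masks, background, width, init_pwm, pseudocount_weight,
             max_iter, tol):
    """One EM run. The monotone objective is the log-joint (data
    log-likelihood plus the Dirichlet smoothing term the M-step maximizes);
    it is asserted non-decreasing every iteration."""
    pwm = init_pwm.copy()
    lam = 0.5
    pc = pseudocount_weight * background
    prev_obj = -np.inf
    obj_trace: list[float] = []
    for _ in range(max_iter):
        with np.errstate(divide="ignore"):
            log_odds = np.log(pwm) - np.log(background)[None, :]
        z_list = []
        ll = 0.0
        for enc, mask in zip(encs, masks):
            ratios = _window_ratios(enc, mask, log_odds)
            m = len(ratios)
            if m == 0:
                z_list.append(np.empty(0))
                continue
            total = (lam / m) * ratios.sum()
            denom = (1.0 - lam) + total
            z = (lam / m) * ratios / denom
            z_list.append(z)
            ll += np.log(denom)
        obj = ll + float((pc[None, :] * np.log(pwm)).sum())
        obj_trace.append(obj)
        assert obj >= prev_obj - 1e-9, "EM objective decreased"
        if obj - prev_obj < tol:
            prev_obj = obj
            break
        prev_obj = obj
        # M-step
        counts = np.tile(pc, (width, 1))
        occ = 0.0
        n_seq = 0
        for enc, z in zip(encs, z_list):
            if len(z) == 0:
                continue
            n_seq += 1
            occ += z.sum()
            nz = np.nonzero(z > 1e-12)[0]
            for j in nz:
                counts[np.arange(width), enc[j:j + width]] += z[j]
        pwm = counts / counts.sum(axis=1, keepdims=True)
        lam = min(max(occ / max(n_seq, 1), 1e-6), 1.0 - 1e-6)
    return pwm, lam, prev_obj, z_list, obj_trace


def _refine_shifts(result, encs, masks, background, width,
                   pseudocount_weight, max_iter, tol, max_rounds: int = 4):
    """Try moving all sites one column left/right and re-running EM.

    EM alone is prone to phase-shifted local optima (all sites off by one);
    a coordinated shift move escapes them when it raises the objective.
    """
    for _ in range(max_rounds):
        improved = False
        for shift in (-1, 1):
            z_list = result[3]
            counts = np.tile(pseudocount_weight * background, (width, 1))
            n_used = 0
            for enc, z in zip(encs, z_list):
                if len(z) == 0 or z.sum() < 0.5:
                    continue
                pos = int(z.argmax()) + shift
                if pos < 0 or pos + width > len(enc):
                    continue
                counts[np.arange(width), enc[pos:pos + width]] += 1.0
                n_used += 1
            if n_used == 0:
                continue
            init = counts / counts.sum(axis=1, keepdims=True)
            cand = _em_once(encs, masks, background, width, init,
                            pseudocount_weight, max_iter, tol)
            if cand[2] > result[2] + 1e-9:
                result = cand
                improved = True
        if not improved:
            break
    return result


def discover_motifs_zoops(seqs: dict[str, str], n_motifs: int = 10, width: int = 15,
                          n_starts: int = 10, seed: int = 0, max_iter: int = 200,
                          tol: float = 1e-6, pseudocount_weight: float = 0.01,
                          site_threshold: float = 0.5) -> list[MotifModel]:
    """Discover up to ``n_motifs`` motifs of fixed ``width`` by ZOOPS-EM."""
    if len(seqs) < 5:
        raise ValueError("discover_motifs_zoops: need at least 5 sequences")
    min_len = min(len(s) for s in seqs.values())
    if width > min_len:
        raise ValueError(f"discover_motifs_zoops: width {width} exceeds shortest "
                         f"sequence ({min_len})")
    ids = list(seqs)
    encs = [_encode(seqs[i]) for i in ids]
    masks = [np.zeros(len(e), dtype=bool) for e in encs]
    # background from overall residue frequencies, smoothed
    all_counts = np.bincount(np.concatenate(encs), minlength=20).astype(float) + 1.0
    background = all_counts / all_counts.sum()
    rng = np.random.default_rng(seed)
    motifs: list[MotifModel] = []
    for _ in range(n_motifs):
        best = None
        for _start in range(n_starts):
            # seed PWM from a random unmasked window of the data
            for _try in range(50):
                si = rng.integers(len(encs))
                if len(encs[si]) < width:
                    continue
                pos = rng.integers(len(encs[si]) - width + 1)
                if not masks[si][pos:pos + width].any():
                    break
            else:
                break
            seed_window = encs[si][pos:pos + width]
            init = np.tile(background, (width, 1)) * 0.5
            init[np.arange(width), seed_window] += 0.5
            init /= init.sum(axis=1, keepdims=True)
            result = _em_once(encs, masks, background, width, init,
                              pseudocount_weight, max_iter, tol)
            if best is None or result[2] > best[2]:
                best = result
        if best is None:
            break
        best = _refine_shifts(best, encs, masks, background, width,
                              pseudocount_weight, max_iter, tol)
        pwm, lam, ll, z_list, _trace = best
        sites: dict[str, tuple[int, float]] = {}
        for sid, z in zip(ids, z_list):
            if len(z) == 0:
                continue
            posterior_occ = float(z.sum())
            if posterior_occ > site_threshold:
                sites[sid] = (int(z.argmax()), posterior_occ)
        motif = MotifModel(width=width, pwm=pwm, lam=lam, background=background,
                           log_likelihood=float(ll), sites=sites)
        motifs.append(motif)
        # sequential erasure of committed sites
        for si, sid in enumerate(ids):
            if sid in sites:
                pos = sites[sid][0]
                masks[si][pos:pos + width] = True
    return motifs


def motif_presence_matrix(motifs: list[MotifModel], seqs: dict[str, str],
                          posterior_threshold: float = 0.5) -> dict[str, dict[int, bool]]:
    """Gene x motif presence: ZOOPS posterior of occurrence above threshold."""
    out: dict[str, dict[int, bool]] = {}
    for sid, seq in seqs.items():
        enc = _encode(seq)
        row = {}
        for k, motif in enumerate(motifs):
            with np.errstate(divide="ignore"):
                log_odds = np.log(motif.pwm) - np.log(motif.background)[None, :]
            ratios = _window_ratios(enc, np.zeros(len(enc), dtype=bool), log_odds)
            if len(ratios) == 0:
                row[k] = False
                continue
            m = len(ratios)
            total = (motif.lam / m) * ratios.sum()
            posterior = total / ((1.0 - motif.lam) + total)
            row[k] = bool(posterior > posterior_threshold)
        out[sid] = row
    return out
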