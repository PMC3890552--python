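"""Fixed-width motif discovery by ZOOPS EM with positional constraints.

Promoter elements are searched in the 60 bases upstream of each TSS: the
-10 hexamer must end 3-11 nt before the +1 base, and the -35 hexamer must
sit 16-19 nt upstream of the -10.  Shine-Dalgarno (RBS) motifs are searched
in trimmed 5'-UTR windows.  The motif model is a position weight matrix
learned by expectation-maximization under a zero-or-one-occurrence-per-
sequence (ZOOPS) model with a 0-order background estimated from the input
windows; the likelihood is non-decreasing across iterations and the best of
several seeded restarts is returned.

Consensus strings are case-coded by column conservation: upper case at
>= 80% frequency, lower case above 40%, and 'n' at or below 40%.  The
per-column information content is 2 + sum_b p_b log2 p_b bits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core_io import GenomeSequence

_BASE_INDEX = {c: i for i, c in enumerate("ACGT")}


class EMError(ValueError):
    pass


@dataclass(frozen=True)
class MotifModel:
    width: int
    pwm: np.ndarray                 # width x 4, rows sum to 1
    background: np.ndarray          # 4-vector
    consensus: str
    ic: np.ndarray                  # per-column bits
    log_likelihood: float
    n_iterations: int


@dataclass(frozen=True)
class MotifHit:
    seq_index: int
    offset: int                     # within the searched window
    score: float                    # log2 odds vs background
    spacer: int | None = None       # nt strictly between motif 3' end and anchor


def consensus_and_information(pwm: np.ndarray) -> tuple[str, np.ndarray]:
    """Case-coded consensus and information content of a PWM.

    Per column the most frequent base is upper case at frequency >= 0.8,
    lower case strictly between 0.4 and 0.8, and 'n' at <= 0.4.
    """
    pwm = np.asarray(pwm, dtype=float)
    if pwm.ndim != 2 or pwm.shape[1] != 4:
        raise ValueError("pwm must be width x 4")
    if not np.allclose(pwm.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("pwm rows must sum to 1")
    letters = []
    for row in pwm:
        b = int(row.argmax())
        f = row[b]
        base = "ACGT"[b]
        if f >= 0.8:
            letters.append(base)
        elif f > 0.4:
            letters.append(base.lower())
        else:
            letters.append("n")
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(pwm > 0, pwm * np.log2(pwm), 0.0)
    ic = 2.0 + plogp.sum(axis=1)
    return "".join(letters), ic


def consensus_distance(learned: str, planted: str) -> int:
    """Mismatches between consensus strings at the planted motif's defined
    positions (case-insensitive; 'n'/'N' in the planted string is a
    wildcard)."""
    if len(learned) != len(planted):
        raise ValueError("consensus lengths differ")
    return sum(1 for a, b in zip(learned.upper(), planted.upper())
               if b != "N" and a != b)


def _encode(seq: str) -> np.ndarray:
    try:
        return np.fromiter((_BASE_INDEX[c] for c in seq.upper()), dtype=np.int64,
                           count=len(seq))
    except KeyError as exc:
        raise EMError(f"non-ACGT base {exc} in motif search window") from exc


def em_motif_find(seqs: Sequence[str], width: int, seed: int = 0,
                  n_restarts: int = 10, pseudocount: float = 0.25,
                  tol: float = 1e-6, max_iter: int = 200,
                  min_occupancy: float = 0.5,
                  ) -> tuple[MotifModel, list[MotifHit | None]]:
    """ZOOPS EM over equal-role windows; deterministic given the seed.

    Returns the model from the restart with the highest log-likelihood and
    the best site per sequence (``None`` where the posterior probability of
    the sequence containing a site falls below ``min_occupancy``).
    """
    if len(seqs) < 2:
        raise EMError("need at least 2 sequences")
    for s in seqs:
        if len(s) < width:
            raise EMError("sequence shorter than motif width")

    enc = [_encode(s) for s in seqs]
    # all windows stacked; seg boundaries delimit each sequence's windows
    windows = []
    seg_sizes = []
    for e in enc:
        m = len(e) - width + 1
        idx = np.arange(m)[:, None] + np.arange(width)[None, :]
        windows.append(e[idx])
        seg_sizes.append(m)
    X = np.concatenate(windows, axis=0)            # (n_windows, width)
    seg_sizes = np.array(seg_sizes)
    seg_starts = np.concatenate(([0], np.cumsum(seg_sizes)[:-1]))
    seg_ids = np.repeat(np.arange(len(seqs)), seg_sizes)
    n_seq = len(seqs)

    flat = np.concatenate(enc)
    background = (np.bincount(flat, minlength=4) + 1.0)
    background = background / background.sum()
    log_bg = np.log(background)

    def e_step(pwm: np.ndarray, gamma: float):
        log_pwm = np.log(pwm)
        # per-window log likelihood ratio motif/background
        lr = (log_pwm[np.arange(width)[None, :], X] - log_bg[X]).sum(axis=1)
        log_site = lr + np.log(gamma) - np.log(seg_sizes)[seg_ids]
        # segment-wise logsumexp against the no-site alternative
        seg_max = np.maximum.reduceat(log_site, seg_starts)
        seg_max = np.maximum(seg_max, np.log1p(-gamma))
        sums = np.add.reduceat(np.exp(log_site - seg_max[seg_ids]), seg_starts)
        z = sums + np.exp(np.log1p(-gamma) - seg_max)
        log_z = np.log(z) + seg_max
        ll = float(log_z.sum())
        # pseudocounts act as a Dirichlet prior; MAP-EM guarantees
        # monotonicity of ll + log prior, not of ll alone
        obj = ll + pseudocount * float(log_pwm.sum())
        post = np.exp(log_site - log_z[seg_ids])
        return ll, obj, post, lr

    def run_em(pwm: np.ndarray, gamma: float):
        prev_obj = prev_ll = -np.inf
        n_it = 0
        for n_it in range(1, max_iter + 1):
            ll, obj, post, _ = e_step(pwm, gamma)
            occupancy = np.add.reduceat(post, seg_starts)
            counts = np.full((width, 4), pseudocount)
            for w in range(width):
                counts[w] += np.bincount(X[:, w], weights=post, minlength=4)
            pwm = counts / counts.sum(axis=1, keepdims=True)
            gamma = float(np.clip(occupancy.mean(), 1e-4, 1 - 1e-4))
            if obj < prev_obj - 1e-8:
                raise AssertionError("EM objective decreased")
            converged = obj - prev_obj < tol
            prev_obj, prev_ll = obj, ll
            if converged:
                break
        return prev_ll, prev_obj, pwm, gamma, n_it

    rng = np.random.default_rng(seed)
    best: tuple | None = None
    for _ in range(n_restarts):
        # seed the PWM from a random window
        row = X[rng.integers(len(X))]
        pwm0 = np.full((width, 4), 0.15)
        pwm0[np.arange(width), row] = 0.55
        res = run_em(pwm0, 0.5)
        if best is None or res[1] > best[1]:
            best = res

    # phase-shift move: a converged motif is often the planted one shifted
    # by a column; accept a +/-1 shift whenever it improves the objective
    for _ in range(3):
        improved = False
        for shift in (-1, 1):
            pwm_s = np.full((width, 4), background)
            if shift == 1:
                pwm_s[:-1] = best[2][1:]
            else:
                pwm_s[1:] = best[2][:-1]
            res = run_em(pwm_s, best[3])
            if res[1] > best[1] + 1e-9:
                best = res
                improved = True
        if not improved:
            break

    ll_best, _, pwm, gamma, n_it = best
    # final E-step for hit extraction
    log_pwm = np.log(pwm)
    lr = (log_pwm[np.arange(width)[None, :], X] - log_bg[X]).sum(axis=1)
    log_site = lr + np.log(gamma) - np.log(seg_sizes)[seg_ids]
    seg_max = np.maximum.reduceat(log_site, seg_starts)
    seg_max = np.maximum(seg_max, np.log1p(-gamma))
    sums = np.add.reduceat(np.exp(log_site - seg_max[seg_ids]), seg_starts)
    z = sums + np.exp(np.log1p(-gamma) - seg_max)
    log_z = np.log(z) + seg_max
    post = np.exp(log_site - log_z[seg_ids])
    occupancy = np.add.reduceat(post, seg_starts)

    consensus, ic = consensus_and_information(pwm)
    model = MotifModel(width=width, pwm=pwm, background=background,
                       consensus=consensus, ic=ic,
                       log_likelihood=ll_best, n_iterations=n_it)
    hits: list[MotifHit | None] = []
    for i in range(n_seq):
        if occupancy[i] < min_occupancy:
            hits.append(None)
            continue
        sl = slice(seg_starts[i], seg_starts[i] + seg_sizes[i])
        j = int(np.argmax(post[sl]))
        hits.append(MotifHit(seq_index=i, offset=j,
                             score=float(lr[seg_starts[i] + j] / np.log(2))))
    return model, hits


# ---------------------------------------------------------------------------
# Anchored searches
# ---------------------------------------------------------------------------

@dataclass
class PromoterSearch:
    """EM result over anchored windows, with per-input indices preserved."""

    model: MotifModel
    hits: dict[int, MotifHit]        # input index -> retained hit
    windows: dict[int, str]          # input index -> searched window


def upstream_window(genome: GenomeSequence, position: int, strand: str,
                    size: int) -> str:
    """The ``size`` bases immediately 5' of ``position``, 5'->3' on the
    given strand, truncated at the contig edge."""
    if strand == "+":
        return genome.seq[max(position - size, 0):position]
    return genome.subseq(position + 1, position + 1 + size, "-")


def find_minus10(tss_records: Sequence, genome: GenomeSequence,
                 window: int = 60, spacer_range: tuple[int, int] = (3, 11),
                 width: int = 6, seed: int = 0, **em_kwargs) -> PromoterSearch:
    """-10 search in the upstream windows of the given TSSs.

    The EM is run on the spacer-admissible tail of each window (motif 3'
    end 3-11 nt before the +1 base); without this positional constraint the
    search drifts to whichever upstream element is most informative (often
    the -35).  Hit offsets refer to the full upstream window, and a per-TSS
    hit is retained only when its spacer falls in ``spacer_range``.
    """
    if len(tss_records) == 0:
        raise ValueError("no TSS records")
    lo, hi = spacer_range
    windows: dict[int, str] = {}
    sub_start: dict[int, int] = {}
    for i, r in enumerate(tss_records):
        w = upstream_window(genome, r.position, r.strand, window)
        a = max(len(w) - (hi + width), 0)
        b = len(w) - lo
        if b - a >= width:
            windows[i] = w
            sub_start[i] = a
    order = sorted(windows)
    model, raw_hits = em_motif_find(
        [windows[i][sub_start[i]:len(windows[i]) - lo] for i in order],
        width, seed=seed, **em_kwargs)
    hits: dict[int, MotifHit] = {}
    for i, h in zip(order, raw_hits):
        if h is None:
            continue
        offset = sub_start[i] + h.offset
        spacer = len(windows[i]) - (offset + width)
        if lo <= spacer <= hi:
            hits[i] = MotifHit(seq_index=i, offset=offset, score=h.score,
                               spacer=spacer)
    return PromoterSearch(model=model, hits=hits, windows=windows)


def find_minus35(minus10: PromoterSearch, spacer_range: tuple[int, int] = (16, 19),
                 width: int = 6, seed: int = 0, **em_kwargs) -> PromoterSearch:
    """-35 search immediately 5' of each retained -10 hit.

    The searched sub-window covers exactly the offsets compatible with a
    -10/-35 gap in ``spacer_range``; reported spacers are that gap.
    """
    lo_gap, hi_gap = spacer_range
    sub: dict[int, str] = {}
    sub_start: dict[int, int] = {}
    for i, h in minus10.hits.items():
        win = minus10.windows[i]
        a = h.offset - hi_gap - width
        b = h.offset - lo_gap
        a_clip = max(a, 0)
        if b - a_clip >= width:
            sub[i] = win[a_clip:b]
            sub_start[i] = a_clip
    if len(sub) < 2:
        return PromoterSearch(model=None, hits={}, windows=sub)  # type: ignore
    order = sorted(sub)
    model, raw_hits = em_motif_find([sub[i] for i in order], width,
                                    seed=seed, **em_kwargs)
    hits: dict[int, MotifHit] = {}
    for i, h in zip(order, raw_hits):
        if h is None:
            continue
        j35 = sub_start[i] + h.offset
        gap = minus10.hits[i].offset - (j35 + width)
        if lo_gap <= gap <= hi_gap:
            hits[i] = MotifHit(seq_index=i, offset=j35, score=h.score,
                               spacer=gap)
    return PromoterSearch(model=model, hits=hits, windows=sub)


def find_rbs_sites(unique_utrs: Sequence, width: int = 5,
                   min_len: int = 14, max_len: int = 20, seed: int = 0,
                   **em_kwargs) -> PromoterSearch:
    """RBS search in unique 5'-UTRs trimmed to their final ``max_len`` nt.

    UTRs shorter than ``min_len`` are excluded.  The spacer of each hit is
    the nt count strictly between the motif 3' end and the start codon, fed
    to the spacing statistics.
    """
    windows: dict[int, str] = {}
    for i, u in enumerate(unique_utrs):
        if u.utr_length >= min_len:
            windows[i] = u.utr_seq[-max_len:]
    if len(windows) < 2:
        raise ValueError("not enough qualifying UTRs for an RBS search")
    order = sorted(windows)
    model, raw_hits = em_motif_find([windows[i] for i in order], width,
                                    seed=seed, **em_kwargs)
    hits: dict[int, MotifHit] = {}
    for i, h in zip(order, raw_hits):
        if h is None:
            continue
        spacer = len(windows[i]) - (h.offset + width)
        hits[i] = MotifHit(seq_index=i, offset=h.offset, score=h.score,
                           spacer=spacer)
    return PromoterSearch(model=model, hits=hits, windows=windows)
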