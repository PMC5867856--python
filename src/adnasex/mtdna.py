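"""Mitochondrial pileup, consensus calling, coverage and contamination.

The mitochondrial reference is circular: fragments may span the origin, and
every aligned base is assigned to one position modulo the reference length.
Consensus follows a depth/frequency rule (default: at least 5 reads and a
majority-base frequency of at least 80%, boundary inclusive); positions
failing it are reported as N with the reason.

Modern contamination is estimated with a two-component likelihood mixture:
each read is explained either by the endogenous consensus (with a
damage-aware terminal mismatch model) or by its best-matching sequence from
a panel of candidate modern contaminant haplotypes (background mismatch rate
only — modern molecules carry no post-mortem damage).  The mixture weight is
maximised by EM and its 95% CI obtained by non-parametric bootstrap over
reads.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Iterable, Sequence

import numpy as np

from .damage import DamageParams
from .reads import AlignedRead

log = logging.getLogger(__name__)

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}

CALLED = "called"
LOW_DEPTH = "low_depth"
LOW_FREQUENCY = "low_frequency"


@dataclasses.dataclass
class Pileup:
    """Per-position base counts over a circular reference.

    ``counts`` has shape (5, ref_length): rows A, C, G, T, other.
    """

    ref_length: int
    counts: np.ndarray

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def total_bases(self) -> int:
        return int(self.counts.sum())


def build_pileup(
    reads: Iterable[AlignedRead],
    ref_length: int,
    circular: bool = True,
) -> Pileup:
    """Accumulate base counts; reads may wrap the origin when circular.

    A read extending beyond the reference on a non-circular reference is an
    error.  Bases are taken in alignment (reference-forward) orientation.
    """
    counts = np.zeros((5, ref_length), dtype=np.int64)
    for r in reads:
        if r.end > ref_length and not circular:
            raise ValueError(
                f"read {r.read_id} spans [{r.start}, {r.end}) beyond reference "
                f"length {ref_length} on a non-circular reference"
            )
        pos = (r.start + np.arange(r.length)) % ref_length
        rows = np.fromiter((_BASE_INDEX.get(b, 4) for b in r.seq),
                           dtype=np.int64, count=r.length)
        np.add.at(counts, (rows, pos), 1)
    return Pileup(ref_length=ref_length, counts=counts)


@dataclasses.dataclass
class ConsensusCall:
    """Consensus sequence with per-position status.

    ``sequence`` uses A/C/G/T for called positions and N otherwise;
    ``status`` holds 'called', 'low_depth' or 'low_frequency' per position.
    """

    sequence: str
    status: list[str]
    min_depth: int
    min_freq: float

    @property
    def n_uncalled(self) -> int:
        return sum(s != CALLED for s in self.status)


def call_consensus(pileup: Pileup, min_depth: int = 5,
                   min_freq: float = 0.80) -> ConsensusCall:
    """Majority-base consensus under the depth/frequency rule.

    A position is called to its majority base iff depth >= min_depth and the
    majority base's share of the depth is >= min_freq (boundary inclusive).
    A tie between two top bases is never called.  Non-ACGT bases count
    toward depth but are never the call.
    """
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    if not (0.5 < min_freq <= 1.0):
        raise ValueError("min_freq must be in (0.5, 1]")
    depth = pileup.depth
    acgt = pileup.counts[:4]
    top = acgt.argmax(axis=0)
    top_count = acgt.max(axis=0)
    # a tie exists when a second base matches the top count
    tie = (acgt == top_count[None, :]).sum(axis=0) > 1
    seq = []
    status = []
    for p in range(pileup.ref_length):
        if depth[p] < min_depth:
            seq.append("N")
            status.append(LOW_DEPTH)
        elif tie[p] or top_count[p] < min_freq * depth[p]:
            seq.append("N")
            status.append(LOW_FREQUENCY)
        else:
            seq.append(_BASES[top[p]])
            status.append(CALLED)
    return ConsensusCall("".join(seq), status, min_depth, min_freq)


@dataclasses.dataclass
class CoverageStats:
    min_depth: int
    max_depth: int
    mean_depth: float

    def rounded(self) -> tuple[int, int, float]:
        return (self.min_depth, self.max_depth, round(self.mean_depth, 1))


def coverage_stats(pileup: Pileup) -> CoverageStats:
    """Minimum, maximum and mean per-position depth (mean = total aligned
    bases / reference length)."""
    depth = pileup.depth
    return CoverageStats(
        min_depth=int(depth.min()),
        max_depth=int(depth.max()),
        mean_depth=float(pileup.total_bases / pileup.ref_length),
    )


@dataclasses.dataclass
class ContamEstimate:
    proportion: float
    ci_low: float
    ci_high: float
    panel_size: int
    n_informative: int
    n_bootstrap: int
    log_likelihood: float


def _column_logliks(obs: str, ref: str, strand: str,
                    params: DamageParams, damage_aware: bool) -> float:
    """Read log-likelihood against one reference haplotype slice.

    ``obs`` and ``ref`` are in alignment orientation; damage offsets are
    taken in molecule orientation (reversed for minus-strand reads).
    """
    L = len(obs)
    e = params.epsilon
    log_match_null = math.log1p(-e)
    log_mis_null = math.log(e / 3.0)
    total = 0.0
    for i in range(L):
        r = ref[i]
        o = obs[i]
        if r == "N" or o == "N":
            continue
        if damage_aware:
            # molecule orientation: minus-strand 5' end is the alignment's right
            if strand == "+":
                z5, z3 = i, L - 1 - i
            else:
                z5, z3 = L - 1 - i, i
            if strand == "+" and r == "C":
                D = params.rate(z5)
                total += math.log(D) if o == "T" else (
                    math.log1p(-D) if o == "C" else log_mis_null)
                continue
            if strand == "+" and r == "G":
                D = params.rate(z3)
                total += math.log(D) if o == "A" else (
                    math.log1p(-D) if o == "G" else log_mis_null)
                continue
            if strand == "-" and r == "G":
                # molecule-strand C at molecule-5' offset z5; C→T appears as G→A here
                D = params.rate(z5)
                total += math.log(D) if o == "A" else (
                    math.log1p(-D) if o == "G" else log_mis_null)
                continue
            if strand == "-" and r == "C":
                # molecule-strand G at molecule-3' offset z3; G→A appears as C→T here
                D = params.rate(z3)
                total += math.log(D) if o == "T" else (
                    math.log1p(-D) if o == "C" else log_mis_null)
                continue
        total += log_match_null if o == r else log_mis_null
    return total


def _circular_slice(seq: str, start: int, length: int) -> str:
    L = len(seq)
    start %= L
    if start + length <= L:
        return seq[start:start + length]
    return seq[start:] + seq[:(start + length) % L]


def _em_mixture(logliks: np.ndarray, counts: np.ndarray | None = None,
                tol: float = 1e-8, max_iter: int = 5000,
                w0: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Maximise the weights of a fixed-component mixture by EM.

    ``logliks`` has shape (n_components, n_reads): per-read log-likelihood
    under each component (row 0 = endogenous, rows 1.. = one per panel
    haplotype).  ``counts`` has shape (n_batches, n_reads) and gives each
    read's multiplicity per batch — a row of ones is the plain estimate and
    a multinomial draw is one bootstrap replicate; all batches run in
    parallel.  Returns (weights (n_batches, n_components), loglik
    (n_batches,)).  The log-likelihood is asserted non-decreasing every
    iteration (EM guarantee; a violation indicates a numerical defect).
    """
    k, n = logliks.shape
    if counts is None:
        counts = np.ones((1, n))
    counts = np.asarray(counts, dtype=float)
    b = counts.shape[0]
    n_eff = counts.sum(axis=1)
    # normalise per read so component likelihood ratios survive exp()
    mx = logliks.max(axis=0)
    lt = np.exp(logliks - mx[None, :])  # (k, n), entries in (0, 1]
    if w0 is None:
        w = np.full((b, k), 1.0 / k)
    else:
        w = np.broadcast_to(np.asarray(w0, dtype=float), (b, k)).copy()
    prev_ll = np.full(b, -np.inf)
    for _ in range(max_iter):
        den = w @ lt  # (b, n)
        den = np.maximum(den, 1e-300)
        ll = (counts * (np.log(den) + mx[None, :])).sum(axis=1)
        assert (ll >= prev_ll - 1e-6 * np.maximum(np.abs(prev_ll), 1.0)).all(), \
            "EM log-likelihood decreased"
        q = counts / den  # (b, n)
        w_new = w * (q @ lt.T) / n_eff[:, None]
        w_new /= w_new.sum(axis=1, keepdims=True)
        delta = np.abs(w_new - w).max()
        w = w_new
        prev_ll = ll
        if delta < max(1e-12, tol * max(float(w[:, 1:].sum(axis=1).max()), 1e-12)):
            break
    return w, prev_ll


def estimate_contamination(
    reads: Sequence[AlignedRead],
    consensus: str,
    panel: Sequence[str],
    damage_params: DamageParams,
    n_bootstrap: int = 200,
    seed: int = 0,
    tol: float = 1e-8,
) -> ContamEstimate:
    """ML mixture estimate of the modern-contaminant read fraction.

    The mixture has one endogenous component (the called consensus, scored
    with the damage-aware terminal mismatch model) plus one component per
    panel haplotype (scored at the background rate only — modern molecules
    carry no post-mortem damage).  EM maximises all component weights and
    the contamination proportion is one minus the endogenous weight; this
    keeps an endogenous read that mismatches the true contaminant haplotype
    as evidence *against* contamination even when another panel haplotype
    matches it locally.  Only reads overlapping at least one diagnostic
    site (a position where some panel haplotype differs from the called
    consensus) enter the likelihood; reads elsewhere carry no divergence
    signal.
    """
    if not panel:
        raise ValueError("contaminant panel is empty")
    L = len(consensus)
    for i, hap in enumerate(panel):
        if len(hap) != L:
            raise ValueError(f"panel sequence {i} length {len(hap)} != consensus {L}")
    diagnostic = np.zeros(L, dtype=bool)
    cons = np.frombuffer(consensus.encode(), dtype=np.uint8)
    for hap in panel:
        h = np.frombuffer(hap.encode(), dtype=np.uint8)
        diagnostic |= (h != cons) & (cons != ord("N")) & (h != ord("N"))
    if not diagnostic.any():
        raise ValueError("contamination unidentifiable: panel identical to consensus")

    cols: list[list[float]] = []
    for r in reads:
        pos = (r.start + np.arange(r.length)) % L
        if not diagnostic[pos].any():
            continue
        cons_slice = _circular_slice(consensus, r.start, r.length)
        col = [_column_logliks(r.seq, cons_slice, r.strand,
                               damage_params, damage_aware=True)]
        col += [_column_logliks(r.seq, _circular_slice(hap, r.start, r.length),
                                r.strand, damage_params, damage_aware=False)
                for hap in panel]
        cols.append(col)
    if not cols:
        raise ValueError("contamination unidentifiable: no read overlaps a "
                         "diagnostic site")
    logliks = np.asarray(cols).T  # (1 + panel_size, n_reads)
    n = logliks.shape[1]
    w_full, ll = _em_mixture(logliks, tol=tol)
    w_hat = float(1.0 - w_full[0, 0])

    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        w0 = np.clip(w_full[0], 1e-6, None)
        w0 /= w0.sum()
        counts = rng.multinomial(n, np.full(n, 1.0 / n), size=n_bootstrap)
        wb, _ = _em_mixture(logliks, counts=counts, tol=tol, w0=w0)
        boots = 1.0 - wb[:, 0]
        lo, hi = np.percentile(boots, [2.5, 97.5])
    else:
        lo = hi = w_hat
    return ContamEstimate(
        proportion=w_hat,
        ci_low=float(min(lo, w_hat)),
        ci_high=float(max(hi, w_hat)),
        panel_size=len(panel),
        n_informative=n,
        n_bootstrap=n_bootstrap,
        log_likelihood=float(ll[0]),
    )
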