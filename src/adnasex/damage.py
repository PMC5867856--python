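"""Post-mortem deamination profiling and damage-based read selection.

Ancient DNA carries cytosine deamination concentrated at fragment ends,
observed as C→T substitutions near the molecule's 5' end and (for
double-stranded libraries) G→A near the 3' end.  This module quantifies
those terminal substitution frequencies, fits the standard geometric decay
model

    D(z) = delta * phi**z + epsilon

(z = distance from the relevant end, delta the terminal amplitude, phi the
per-position decay, epsilon the background mismatch rate), and scores each
read with a log-likelihood ratio of damage model vs. null — reads scoring
above a threshold (default 3 nats) are unlikely to be modern contaminants.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .reads import AlignedRead

log = logging.getLogger(__name__)


@dataclasses.dataclass
class DamageParams:
    """Geometric terminal-deamination model D(z) = delta*phi^z + epsilon."""

    delta: float
    phi: float = 0.5
    epsilon: float = 0.01
    residual: float | None = None  # norm from fit_damage_params, if fitted

    def __post_init__(self) -> None:
        if not (0.0 <= self.delta <= 1.0):
            raise ValueError("delta must be in [0, 1]")
        if not (0.0 <= self.phi < 1.0):
            raise ValueError("phi must be in [0, 1)")
        if self.epsilon < 0 or self.delta + self.epsilon > 1.0:
            raise ValueError("need 0 <= epsilon and delta + epsilon <= 1")

    def rate(self, z) -> float | np.ndarray:
        """Substitution probability at distance z from the fragment end."""
        return self.delta * self.phi**z + self.epsilon


#: Amplitude measured for an untreated (no effective UDG) library.
NO_UDG = DamageParams(delta=0.27)
#: Amplitude typical after partial UDG treatment (about three-fold lower).
PARTIAL_UDG = DamageParams(delta=0.084)


@dataclasses.dataclass
class EndProfile:
    """Per-offset substitution counts from one fragment end."""

    opportunities: np.ndarray  # reference C (5') or G (3') count at offset z
    events: np.ndarray         # observed C→T (5') or G→A (3') count

    @property
    def frequency(self) -> np.ndarray:
        """events/opportunities; NaN where there were no opportunities."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.opportunities > 0,
                            self.events / np.maximum(self.opportunities, 1), np.nan)


@dataclasses.dataclass
class DamageProfile:
    """Terminal substitution frequencies: 5' C→T and 3' G→A by offset."""

    max_offset: int
    five_prime: EndProfile
    three_prime: EndProfile
    n_reads: int = 0
    n_skipped: int = 0


def terminal_substitution_profile(
    reads: Iterable[AlignedRead], max_offset: int = 25
) -> DamageProfile:
    """Count C→T (from the 5' end) and G→A (from the 3' end) substitution
    opportunities and events at offsets 0..max_offset-1.

    Reads are oriented to their original molecule before counting, so offset
    0 is each fragment's own terminal base.  Reads flagged as containing
    indels are skipped (their offsets are unreliable) and counted.
    """
    opp5 = np.zeros(max_offset, dtype=np.int64)
    ev5 = np.zeros(max_offset, dtype=np.int64)
    opp3 = np.zeros(max_offset, dtype=np.int64)
    ev3 = np.zeros(max_offset, dtype=np.int64)
    n_reads = 0
    n_skipped = 0
    for r in reads:
        if r.has_indels:
            n_skipped += 1
            continue
        n_reads += 1
        ref = r.molecule_ref
        obs = r.molecule_seq
        L = r.length
        k = min(max_offset, L)
        for z in range(k):
            if ref[z] == "C":
                opp5[z] += 1
                if obs[z] == "T":
                    ev5[z] += 1
            if ref[L - 1 - z] == "G":
                opp3[z] += 1
                if obs[L - 1 - z] == "A":
                    ev3[z] += 1
    if n_skipped:
        log.warning("terminal_substitution_profile: skipped %d read(s) with indels",
                    n_skipped)
    return DamageProfile(
        max_offset=max_offset,
        five_prime=EndProfile(opp5, ev5),
        three_prime=EndProfile(opp3, ev3),
        n_reads=n_reads,
        n_skipped=n_skipped,
    )


def fit_damage_params(profile: DamageProfile) -> DamageParams:
    """Least-squares fit of D(z) = delta*phi^z + epsilon to the 5' profile.

    Requires at least 3 offsets with defined frequencies.  Parameters are
    clipped to their valid ranges; the residual norm is stored on the result.
    """
    freq = profile.five_prime.frequency
    z = np.arange(profile.max_offset, dtype=float)
    mask = ~np.isnan(freq)
    if mask.sum() < 3:
        raise ValueError("need at least 3 defined 5' offsets to fit damage parameters")
    z, f = z[mask], freq[mask]

    def model(zz, delta, phi, eps):
        return delta * phi**zz + eps

    f_inf = float(np.median(f[len(f) // 2:]))
    p0 = (max(float(f[0]) - f_inf, 1e-3), 0.5, max(f_inf, 1e-6))
    popt, _ = curve_fit(model, z, f, p0=p0,
                        bounds=([0.0, 0.0, 0.0], [1.0, 0.999, 1.0]),
                        maxfev=20000)
    delta, phi, eps = (float(v) for v in popt)
    resid = float(np.linalg.norm(model(z, *popt) - f))
    delta = min(max(delta, 0.0), 1.0)
    eps = min(max(eps, 0.0), 1.0 - delta)
    return DamageParams(delta=delta, phi=min(max(phi, 0.0), 0.999),
                        epsilon=eps, residual=resid)


def pmd_score(read: AlignedRead, params: DamageParams) -> float:
    """Log-likelihood ratio (nats) of the damage model over the null.

    Summed over matched columns in molecule orientation: at a reference C at
    5' offset z the damage model gives C→T probability D(z) and the null
    epsilon; symmetrically G→A from the 3' end.  Columns whose reference
    base is neither C nor G — and observed bases explained equally by both
    models — contribute 0.  A read with no C/G opportunities scores 0.
    """
    ref = read.molecule_ref
    obs = read.molecule_seq
    L = read.length
    d, p, e = params.delta, params.phi, params.epsilon
    score = 0.0
    for i in range(L):
        r = ref[i]
        if r == "C":
            z = i
            product = "T"
        elif r == "G":
            z = L - 1 - i
            product = "A"
        else:
            continue
        D = d * p**z + e
        o = obs[i]
        if o == product:
            score += math.log(D / e) if e > 0 else math.inf
        elif o == r:
            score += math.log((1.0 - D) / (1.0 - e))
        # other observed bases: same probability under both models
    return score


def pmd_scores(reads: Sequence[AlignedRead], params: DamageParams) -> np.ndarray:
    return np.array([pmd_score(r, params) for r in reads], dtype=float)


def filter_damaged(
    reads: Sequence[AlignedRead],
    params: DamageParams,
    threshold: float = 3.0,
    return_scores: bool = False,
):
    """Retain reads whose damage score is >= threshold (default 3 nats).

    With ``return_scores=True`` also returns the per-read score array for
    the *input* reads, in input order.
    """
    scores = pmd_scores(reads, params)
    kept = [r for r, s in zip(reads, scores) if s >= threshold]
    if return_scores:
        return kept, scores
    return kept
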