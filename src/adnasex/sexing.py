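"""Biological sexing from shotgun read counts: the R_Y and R_X statistics.

R_Y = nY / (nX + nY), the fraction of sex-chromosome reads mapping to Y,
with a Wald 95% CI (estimate ± 1.96·SE, SE = sqrt(R_Y(1−R_Y)/(nX+nY))).
The call is female when the CI's upper bound is below 0.016 and male when
its lower bound exceeds 0.075; anything else is indeterminate.

R_X compares X-chromosome read density to each of the 22 autosomes:
r_i = (nX/L_X)/(n_i/L_i), R_X = mean(r_i), CI = R_X ± 1.96·SD(r_i)/√22.
Male when the CI's upper bound is below 0.60, female when its lower bound
exceeds 0.80.  (The CI form is a reconstruction of the method's published
normal-approximation interval; see docs/methods.md.)

Both statistics can be recomputed on the damage-filtered read subset so a
sex call can be made from molecules unlikely to be modern contaminants.
"""

from __future__ import annotations

import dataclasses
import decimal
import logging
import math
from typing import Iterable, Mapping, Sequence

import numpy as np

from .damage import DamageParams, filter_damaged
from .genome import AUTOSOME_KEYS
from .read_processing import ChromCountTable, count_by_chromosome
from .reads import AlignedRead

log = logging.getLogger(__name__)

Z95 = 1.96


@dataclasses.dataclass(frozen=True)
class SexThresholds:
    """CI-bound decision thresholds for the two statistics."""

    ry_female_max: float = 0.016
    ry_male_min: float = 0.075
    rx_male_max: float = 0.60
    rx_female_min: float = 0.80

    def __post_init__(self) -> None:
        if not (self.ry_female_max < self.ry_male_min):
            raise ValueError("ry_female_max must be < ry_male_min")
        if not (self.rx_male_max < self.rx_female_min):
            raise ValueError("rx_male_max must be < rx_female_min")


DEFAULT_THRESHOLDS = SexThresholds()


@dataclasses.dataclass
class SexEstimate:
    method: str            # "RY" or "RX"
    estimate: float
    ci_low: float
    ci_high: float
    n_used: int            # reads contributing to the statistic
    call: str = "indeterminate"

    def rounded(self, ndigits: int = 4) -> tuple[float, float, float]:
        """(estimate, ci_low, ci_high) rounded half-up, for report display."""
        return (round_half_up(self.estimate, ndigits),
                round_half_up(self.ci_low, ndigits),
                round_half_up(self.ci_high, ndigits))


def round_half_up(x: float, ndigits: int) -> float:
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP))


def assign_sex(estimate: SexEstimate,
               thresholds: SexThresholds = DEFAULT_THRESHOLDS) -> str:
    """Categorical call from a CI: decided only when the whole interval is
    beyond the relevant threshold, else indeterminate."""
    if not (math.isfinite(estimate.ci_low) and math.isfinite(estimate.ci_high)):
        raise ValueError("CI bounds must be finite")
    if estimate.method == "RY":
        if estimate.ci_high < thresholds.ry_female_max:
            return "female"
        if estimate.ci_low > thresholds.ry_male_min:
            return "male"
        return "indeterminate"
    if estimate.method == "RX":
        if estimate.ci_high < thresholds.rx_male_max:
            return "male"
        if estimate.ci_low > thresholds.rx_female_min:
            return "female"
        return "indeterminate"
    raise ValueError(f"unknown method {estimate.method!r}")


def compute_ry(nX: int, nY: int,
               thresholds: SexThresholds = DEFAULT_THRESHOLDS) -> SexEstimate:
    """R_Y = nY/(nX+nY) with Wald 95% CI clipped to [0, 1]."""
    n = nX + nY
    if n <= 0:
        raise ValueError("no sex-chromosome reads (nX + nY == 0)")
    p = nY / n
    se = math.sqrt(p * (1.0 - p) / n)
    lo = max(0.0, p - Z95 * se)
    hi = min(1.0, p + Z95 * se)
    est = SexEstimate(method="RY", estimate=p, ci_low=lo, ci_high=hi, n_used=n)
    est.call = assign_sex(est, thresholds)
    return est


def compute_rx(table: ChromCountTable,
               thresholds: SexThresholds = DEFAULT_THRESHOLDS) -> SexEstimate:
    """R_X from per-autosome length-normalised density ratios.

    Autosomes with zero reads are excluded with a warning; fewer than two
    usable autosomes is an error.  The CI lower bound is clipped at 0.
    """
    if "X" not in table.counts or "X" not in table.lengths:
        raise ValueError("count table lacks chromosome X (count or length)")
    nX = table.counts["X"]
    LX = table.lengths["X"]
    ratios = []
    n_used = nX
    for a in AUTOSOME_KEYS:
        if a not in table.counts or a not in table.lengths:
            raise ValueError(f"count table lacks autosome {a}")
        n_i = table.counts[a]
        if n_i == 0:
            log.warning("compute_rx: autosome %s has zero reads; excluded", a)
            continue
        ratios.append((nX / LX) / (n_i / table.lengths[a]))
        n_used += n_i
    if len(ratios) < 2:
        raise ValueError("fewer than 2 autosomes with reads; R_X undefined")
    r = np.asarray(ratios, dtype=float)
    mean = float(r.mean())
    sd = float(r.std(ddof=1))
    half = Z95 * sd / math.sqrt(len(r))
    est = SexEstimate(method="RX", estimate=mean,
                      ci_low=max(0.0, mean - half), ci_high=mean + half,
                      n_used=n_used)
    est.call = assign_sex(est, thresholds)
    return est


@dataclasses.dataclass
class SexReport:
    """R_Y and R_X on all reads and on the damage-filtered subset."""

    all_ry: SexEstimate
    all_rx: SexEstimate
    damaged_ry: SexEstimate | None
    damaged_rx: SexEstimate | None
    n_reads: int
    n_damaged: int
    table_all: ChromCountTable
    table_damaged: ChromCountTable


def sex_report(
    reads: Sequence[AlignedRead],
    lengths: Mapping[str, int],
    damage_params: DamageParams,
    thresholds: SexThresholds = DEFAULT_THRESHOLDS,
    pmd_threshold: float = 3.0,
) -> SexReport:
    """Compute all four sex estimates (R_Y/R_X × all/damage-filtered).

    ``reads`` should already be quality-filtered and deduplicated.  The
    damage-filtered estimates are None when the filtered subset has no
    sex-chromosome reads (R_Y) or too few covered autosomes (R_X).
    """
    table_all = count_by_chromosome(reads, lengths)
    damaged = filter_damaged(reads, damage_params, threshold=pmd_threshold)
    table_dam = count_by_chromosome(damaged, lengths)

    all_ry = compute_ry(table_all.counts.get("X", 0), table_all.counts.get("Y", 0),
                        thresholds)
    all_rx = compute_rx(table_all, thresholds)
    try:
        dam_ry = compute_ry(table_dam.counts.get("X", 0),
                            table_dam.counts.get("Y", 0), thresholds)
    except ValueError:
        dam_ry = None
    try:
        dam_rx = compute_rx(table_dam, thresholds)
    except ValueError:
        dam_rx = None
    return SexReport(all_ry=all_ry, all_rx=all_rx,
                     damaged_ry=dam_ry, damaged_rx=dam_rx,
                     n_reads=len(reads), n_damaged=len(damaged),
                     table_all=table_all, table_damaged=table_dam)


def combined_verdict(ry: SexEstimate, rx: SexEstimate) -> str:
    """A single verdict only when both methods agree; else indeterminate."""
    if ry.call == rx.call and ry.call != "indeterminate":
        return ry.call
    return "indeterminate"


def format_sex_table(report: SexReport) -> str:
    """Human-readable table of the four estimates (rows mirror the usual
    published layout: mapped reads, X/Y counts, each statistic with CI)."""

    def col(est_ry, est_rx, table, n):
        nX = table.counts.get("X", 0)
        nY = table.counts.get("Y", 0)
        rows = [f"{n:,}", f"{nX:,}", f"{nY:,}"]
        for est in (est_ry, est_rx):
            if est is None:
                rows += ["NA", "NA"]
            else:
                e, lo, hi = est.rounded(4)
                rows += [f"{e:.4f}", f"{lo:.4f}-{hi:.4f} ({est.call})"]
        return rows

    left = ["Mapped reads", "Mapped to X", "Mapped to Y",
            "R_Y", "  95% CI", "R_X", "  95% CI"]
    c1 = col(report.all_ry, report.all_rx, report.table_all, report.n_reads)
    c2 = col(report.damaged_ry, report.damaged_rx, report.table_damaged,
             report.n_damaged)
    width = max(len(s) for s in left) + 2
    w1 = max(len(s) for s in c1 + ["All reads"]) + 2
    lines = [f"{'':<{width}}{'All reads':<{w1}}Damaged reads"]
    for name, a, b in zip(left, c1, c2):
        lines.append(f"{name:<{width}}{a:<{w1}}{b}")
    return "\n".join(lines)
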