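"""Shared fixtures: hand-built reads and session-scoped simulated datasets.

The simulations are the study conditions the package targets: 50,000-read
nuclear shotgun libraries (XX and XY, untreated and partial-UDG damage) and
mito-capture style datasets at ~108x coverage, with and without a 10%
modern contaminant admixture.
"""

from __future__ import annotations

import dataclasses

import pytest

import adnasex as ax
from adnasex.read_processing import remove_duplicates
from adnasex.simulate import MT_NAME


def make_read(read_id="r1", chrom="chr1", start=0, strand="+", mapq=60,
              seq="ACGT", ref=None):
    """An AlignedRead with defaults convenient for hand-built fixtures."""
    ref = seq if ref is None else ref
    return ax.AlignedRead(read_id, chrom, start, len(seq), strand, mapq, seq, ref)


@dataclasses.dataclass
class SimData:
    cfg: ax.SimConfig
    ref: object
    reads: list
    truth: object
    filtered: list  # quality/length-filtered and deduplicated


def _simulate(cfg: ax.SimConfig) -> SimData:
    ref = ax.simulate_reference(cfg)
    reads, truth = ax.simulate_reads(cfg, ref)
    kept, _ = ax.filter_reads(reads)
    kept = remove_duplicates(kept)
    return SimData(cfg=cfg, ref=ref, reads=reads, truth=truth, filtered=kept)


@pytest.fixture(scope="session")
def xy_sim() -> SimData:
    """50k-read XY shotgun library, untreated damage, no contamination."""
    return _simulate(ax.SimConfig(seed=1, karyotype="XY", n_reads=50_000))


@pytest.fixture(scope="session")
def xx_sim() -> SimData:
    """50k-read XX shotgun library, untreated damage, no contamination."""
    return _simulate(ax.SimConfig(seed=2, karyotype="XX", n_reads=50_000))


@pytest.fixture(scope="session")
def partial_udg_sim() -> SimData:
    """50k-read XY library with partial-UDG damage (amplitude 0.084)."""
    return _simulate(ax.SimConfig(seed=5, karyotype="XY", n_reads=50_000,
                                  udg_mode="partial"))


@pytest.fixture(scope="session")
def mito_sim() -> SimData:
    """Contamination-free mito capture at the study's scale (~108x)."""
    return _simulate(ax.mito_capture_config(seed=3))


@pytest.fixture(scope="session")
def contam_sim() -> SimData:
    """Mito capture with a 10% modern contaminant admixture."""
    return _simulate(ax.mito_capture_config(seed=4, n_reads=75_000,
                                            contam_fraction=0.10))


@pytest.fixture(scope="session")
def mito_reads(mito_sim) -> list:
    return [r for r in mito_sim.reads if r.chrom == MT_NAME]


@pytest.fixture(scope="session")
def contam_mito_reads(contam_sim) -> list:
    return [r for r in contam_sim.reads if r.chrom == MT_NAME]
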