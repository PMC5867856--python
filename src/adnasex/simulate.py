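"""Truth-tagged ancient-read simulator.

Generates a miniature diploid human-like genome — 22 autosomes plus X and Y
at roughly 1/1000 of the hg19 chromosome proportions, and a full-length
16,569 bp circular mitochondrial genome — then draws degraded fragments
from it with:

* a truncated log-normal fragment-length distribution parameterised by its
  mode (ancient shotgun libraries typically peak near 38 or 47 bp),
* terminal cytosine deamination following D(z) = delta*phi^z + epsilon with
  C→T from each fragment's 5' end and G→A from its 3' end, the amplitude
  set by the UDG treatment mode (none 0.27, partial 0.084, full 0.01),
* optional modern contamination: undamaged reads drawn from a divergent
  mitochondrial haplotype and/or from a second nuclear genome of
  configurable karyotype.

Reads are emitted pre-aligned at their true coordinates (no mapping step),
together with a per-read truth table, so every downstream stage can be
verified against ground truth.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome import HG19_LENGTHS
from .reads import AlignedRead, revcomp, write_sam, write_tsv

MT_NAME = "chrMT"
MT_LENGTH = 16569  # rCRS length; not scaled down with the nuclear genome

#: Nuclear chromosomes at ~1/1000 hg19 proportions, mito at full length.
SIM_CHROM_LENGTHS: dict[str, int] = {
    name: (MT_LENGTH if name == "chrMT" else round(length / 1000))
    for name, length in HG19_LENGTHS.items()
}

NUCLEAR_NAMES = tuple(n for n in SIM_CHROM_LENGTHS if n != MT_NAME)

_UDG_DELTA = {"none": 0.27, "partial": 0.084, "full": 0.01}


@dataclasses.dataclass
class SimConfig:
    """All knobs of one simulated dataset; identical configs (including the
    seed) produce byte-identical outputs."""

    seed: int = 0
    karyotype: str = "XY"
    chrom_lengths: dict[str, int] = dataclasses.field(
        default_factory=lambda: dict(SIM_CHROM_LENGTHS))
    n_reads: int = 50_000
    length_mode: float = 38.0       # modal fragment length, bp
    length_sigma: float = 0.35      # log-normal shape
    length_min: int = 20
    length_max: int = 120
    udg_mode: str = "none"          # none | partial | full
    phi: float = 0.5
    epsilon: float = 0.001
    contam_fraction: float = 0.0
    contam_karyotype: str = "XY"
    contam_haplotype_divergence: int = 25   # mito sites
    n_contam_haplotypes: int = 3
    mt_copy_number: float = 2.0
    duplicate_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.karyotype not in ("XX", "XY"):
            raise ValueError("karyotype must be 'XX' or 'XY'")
        if self.contam_karyotype not in ("XX", "XY"):
            raise ValueError("contam_karyotype must be 'XX' or 'XY'")
        if self.udg_mode not in _UDG_DELTA:
            raise ValueError(f"udg_mode must be one of {sorted(_UDG_DELTA)}")
        if not (0.0 <= self.contam_fraction <= 1.0):
            raise ValueError("contam_fraction must be in [0, 1]")
        if self.length_min > self.length_max:
            raise ValueError("length_min must be <= length_max")
        if self.contam_haplotype_divergence > self.chrom_lengths.get(MT_NAME, MT_LENGTH):
            raise ValueError("divergence sites exceed the mito reference length")

    @property
    def delta(self) -> float:
        return _UDG_DELTA[self.udg_mode]

    def copy_numbers(self, karyotype: str | None = None) -> dict[str, float]:
        """Per-chromosome copy number for the sampling weights."""
        kt = karyotype or self.karyotype
        copies: dict[str, float] = {}
        for name in self.chrom_lengths:
            if name == "chrX":
                copies[name] = 2.0 if kt == "XX" else 1.0
            elif name == "chrY":
                copies[name] = 0.0 if kt == "XX" else 1.0
            elif name == MT_NAME:
                copies[name] = float(self.mt_copy_number)
            else:
                copies[name] = 2.0
        return copies


@dataclasses.dataclass
class ReferenceSet:
    """Simulated reference: 25 chromosomes (incl. circular chrMT) plus the
    divergent modern mitochondrial haplotypes used as contaminant panel."""

    chromosomes: dict[str, str]
    contaminant_mt: list[str]

    @property
    def lengths(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.chromosomes.items()}


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def simulate_reference(cfg: SimConfig) -> ReferenceSet:
    """Draw i.i.d. uniform A/C/G/T chromosomes and contaminant haplotypes.

    Each contaminant haplotype differs from the endogenous mitochondrial
    sequence at exactly ``contam_haplotype_divergence`` sites.
    """
    rng = np.random.default_rng([cfg.seed, 0])
    chromosomes = {name: _random_sequence(rng, cfg.chrom_lengths[name])
                   for name in sorted(cfg.chrom_lengths)}
    mt = chromosomes[MT_NAME]
    haplotypes = []
    for _ in range(cfg.n_contam_haplotypes):
        sites = rng.choice(len(mt), size=cfg.contam_haplotype_divergence,
                           replace=False)
        hap = list(mt)
        for s in sites:
            alternatives = [b for b in "ACGT" if b != mt[s]]
            hap[s] = alternatives[rng.integers(0, 3)]
        haplotypes.append("".join(hap))
    return ReferenceSet(chromosomes=chromosomes, contaminant_mt=haplotypes)


def _sample_lengths(rng: np.random.Generator, cfg: SimConfig, n: int) -> np.ndarray:
    """Truncated log-normal fragment lengths, rounded to integer bp.

    The log-normal is parameterised so its continuous mode equals
    ``length_mode``: mu = ln(mode) + sigma^2.
    """
    mu = math.log(cfg.length_mode) + cfg.length_sigma**2
    out = np.empty(n, dtype=np.int64)
    filled = 0
    while filled < n:
        draw = rng.lognormal(mu, cfg.length_sigma, size=2 * (n - filled))
        draw = np.rint(draw).astype(np.int64)
        ok = draw[(draw >= cfg.length_min) & (draw <= cfg.length_max)]
        take = min(len(ok), n - filled)
        out[filled:filled + take] = ok[:take]
        filled += take
    return out


def simulate_reads(
    cfg: SimConfig, reference: ReferenceSet
) -> tuple[list[AlignedRead], pd.DataFrame]:
    """Draw truth-tagged reads from the simulated genome.

    Fragment origins are uniform over chromosome copies weighted by
    copy number × length; deamination is applied to endogenous reads only.
    Contaminant mitochondrial reads come from the first panel haplotype and
    nuclear contaminant reads from an undamaged genome of
    ``contam_karyotype``; both are recorded against the endogenous
    reference (so divergent sites appear as mismatches).  Distinct reads
    are guaranteed distinct duplicate keys; ``duplicate_fraction`` then
    re-emits that share of reads as exact clones with fresh ids.

    Returns the reads and a truth table with one row per read
    (read_id, chrom, contaminant, damaged_offsets, original_seq).
    """
    rng = np.random.default_rng([cfg.seed, 1])
    names = sorted(cfg.chrom_lengths)
    lengths = np.array([cfg.chrom_lengths[n] for n in names], dtype=float)

    def probs(karyotype: str) -> np.ndarray:
        copies = cfg.copy_numbers(karyotype)
        w = np.array([copies[n] for n in names]) * lengths
        if w.sum() <= 0:
            raise ValueError("all sampling weights are zero")
        return w / w.sum()

    p_endo = probs(cfg.karyotype)
    p_cont = probs(cfg.contam_karyotype)

    n = cfg.n_reads
    contam = rng.random(n) < cfg.contam_fraction
    chrom_idx = np.where(
        contam,
        rng.choice(len(names), size=n, p=p_cont),
        rng.choice(len(names), size=n, p=p_endo),
    )
    frag_lengths = _sample_lengths(rng, cfg, n)
    strands = np.where(rng.random(n) < 0.5, "+", "-")

    reads: list[AlignedRead] = []
    truth_rows: list[tuple] = []
    used_keys: set[tuple] = set()
    d, phi, eps = cfg.delta, cfg.phi, cfg.epsilon

    for i in range(n):
        chrom = names[chrom_idx[i]]
        L = int(cfg.chrom_lengths[chrom])
        ln = int(frag_lengths[i])
        circular = chrom == MT_NAME
        strand = str(strands[i])
        is_cont = bool(contam[i])
        # source sequence: contaminant mito reads come from the divergent
        # haplotype; everything else from the endogenous chromosomes
        if is_cont and chrom == MT_NAME:
            source = reference.contaminant_mt[0]
        else:
            source = reference.chromosomes[chrom]
        if not circular and ln > L:
            ln = L
        for _attempt in range(100):
            if circular:
                start = int(rng.integers(0, L))
            else:
                start = int(rng.integers(0, L - ln + 1))
            five_prime = start if strand == "+" else start + ln
            key = (chrom, strand, five_prime, ln)
            if key not in used_keys:
                break
        used_keys.add(key)

        if circular and start + ln > L:
            frag = source[start:] + source[:(start + ln) % L]
            ref_frag = reference.chromosomes[chrom][start:] + \
                reference.chromosomes[chrom][:(start + ln) % L]
        else:
            frag = source[start:start + ln]
            ref_frag = reference.chromosomes[chrom][start:start + ln]

        mol = frag if strand == "+" else revcomp(frag)
        original = mol
        damaged_offsets: list[int] = []
        if not is_cont:
            mol_list = list(mol)
            u = rng.random(ln)
            for z in range(ln):
                b = mol_list[z]
                if b == "C":
                    if u[z] < d * phi**z + eps:
                        mol_list[z] = "T"
                        damaged_offsets.append(z)
                elif b == "G":
                    z3 = ln - 1 - z
                    if u[z] < d * phi**z3 + eps:
                        mol_list[z] = "A"
                        damaged_offsets.append(z)
            mol = "".join(mol_list)
        seq = mol if strand == "+" else revcomp(mol)

        read_id = f"sim{i:07d}"
        reads.append(AlignedRead(read_id, chrom, start, ln, strand, 60,
                                 seq, ref_frag))
        truth_rows.append((read_id, chrom, is_cont,
                           ",".join(map(str, damaged_offsets)), original))

    if cfg.duplicate_fraction > 0 and reads:
        n_dup = int(round(cfg.duplicate_fraction * len(reads)))
        dup_idx = rng.choice(len(reads), size=n_dup, replace=True)
        for j, src in enumerate(dup_idx):
            r = reads[src]
            dup_id = f"{r.read_id}_dup{j}"
            reads.append(dataclasses.replace(r, read_id=dup_id))
            t = truth_rows[src]
            truth_rows.append((dup_id, *t[1:]))

    truth = pd.DataFrame(truth_rows, columns=["read_id", "chrom", "contaminant",
                                              "damaged_offsets", "original_seq"])
    return reads, truth


def mito_capture_config(**overrides) -> SimConfig:
    """A configuration emulating mitochondrial hybridization capture: the
    mito copy number is set so high that essentially every read is
    mitochondrial.  Defaults to 40,910 reads (~108x mean coverage)."""
    defaults = dict(n_reads=40_910, mt_copy_number=1e9)
    defaults.update(overrides)
    return SimConfig(**defaults)


def write_fixtures(
    reads: list[AlignedRead],
    truth: pd.DataFrame,
    outdir: str | Path,
    reference: ReferenceSet,
) -> dict[str, Path]:
    """Write a simulated dataset as plain-text files.

    Emits reference and contaminant-panel FASTA, reads as SAM (origin-
    wrapping mito fragments are skipped there; the TSV is lossless) and
    FASTQ (molecule orientation, constant quality), the alignment TSV, the
    truth TSV, and a chromosome-length TSV.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "reference": outdir / "reference.fasta",
        "panel": outdir / "panel.fasta",
        "sam": outdir / "reads.sam",
        "tsv": outdir / "reads.tsv",
        "fastq": outdir / "reads.fastq",
        "truth": outdir / "truth.tsv",
        "lengths": outdir / "lengths.tsv",
    }
    SeqIO.write(
        (SeqRecord(Seq(s), id=name, description="")
         for name, s in reference.chromosomes.items()),
        paths["reference"], "fasta")
    SeqIO.write(
        (SeqRecord(Seq(s), id=f"contaminant_{i}", description="synthetic modern haplotype")
         for i, s in enumerate(reference.contaminant_mt)),
        paths["panel"], "fasta")
    write_sam(reads, paths["sam"], reference.lengths)
    write_tsv(reads, paths["tsv"])
    SeqIO.write(
        (SeqRecord(Seq(r.molecule_seq), id=r.read_id, description="",
                   letter_annotations={"phred_quality": [40] * r.length})
         for r in reads),
        paths["fastq"], "fastq")
    truth.to_csv(paths["truth"], sep="\t", index=False)
    pd.DataFrame({"chrom": list(reference.lengths),
                  "length": list(reference.lengths.values())}
                 ).to_csv(paths["lengths"], sep="\t", index=False)
    return paths
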