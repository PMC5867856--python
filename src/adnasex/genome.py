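"""Chromosome naming helpers and bundled hg19 chromosome lengths.

The sexing statistics need per-chromosome lengths; for real data mapped to
hg19 the bundled table below is the default, and for simulated miniature
genomes the simulator's own length map overrides it.
"""

from __future__ import annotations

from typing import Mapping

#: hg19 (GRCh37) chromosome lengths in bp.
HG19_LENGTHS: dict[str, int] = {
    "chr1": 249250621, "chr2": 243199373, "chr3": 198022430, "chr4": 191154276,
    "chr5": 180915260, "chr6": 171115067, "chr7": 159138663, "chr8": 146364022,
    "chr9": 141213431, "chr10": 135534747, "chr11": 135006516, "chr12": 133851895,
    "chr13": 115169878, "chr14": 107349540, "chr15": 102531392, "chr16": 90354753,
    "chr17": 81195210, "chr18": 78077248, "chr19": 59128983, "chr20": 63025520,
    "chr21": 48129895, "chr22": 51304566, "chrX": 155270560, "chrY": 59373566,
    "chrMT": 16571,
}

AUTOSOME_KEYS = tuple(str(i) for i in range(1, 23))


def normalize_chrom(name: str) -> str:
    """Map a chromosome name to a canonical key: '1'..'22', 'X', 'Y', 'MT'.

    Accepts 'chr'-prefixed and bare names; 'M', 'chrM' and 'chrMT' all map
    to 'MT'.  Unrecognised names are returned stripped of any 'chr' prefix.
    """
    key = name[3:] if name.lower().startswith("chr") else name
    key = key.upper()
    if key == "M":
        key = "MT"
    return key


def is_autosome(name: str) -> bool:
    return normalize_chrom(name) in AUTOSOME_KEYS


def normalized_lengths(lengths: Mapping[str, int]) -> dict[str, int]:
    """Re-key a length map by canonical chromosome key."""
    return {normalize_chrom(k): int(v) for k, v in lengths.items()}
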