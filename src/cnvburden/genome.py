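"""Canonical hg19 chromosome names and lengths.

Lengths are compiled in so that simulation and validation never require a
genome download; only the 24 canonical human chromosomes are recognized.
"""

from __future__ import annotations

HG19_LENGTHS: dict[str, int] = {
    "chr1": 249250621,
    "chr2": 243199373,
    "chr3": 198022430,
    "chr4": 191154276,
    "chr5": 180915260,
    "chr6": 171115067,
    "chr7": 159138663,
    "chr8": 146364022,
    "chr9": 141213431,
    "chr10": 135534747,
    "chr11": 135006516,
    "chr12": 133851895,
    "chr13": 115169878,
    "chr14": 107349540,
    "chr15": 102531392,
    "chr16": 90354753,
    "chr17": 81195210,
    "chr18": 78077248,
    "chr19": 59128983,
    "chr20": 63025520,
    "chr21": 48129895,
    "chr22": 51304566,
    "chrX": 155270560,
    "chrY": 59373566,
}

CHROMOSOMES: tuple[str, ...] = tuple(HG19_LENGTHS)
AUTOSOMES: tuple[str, ...] = tuple(f"chr{i}" for i in range(1, 23))

_AUTOSOME_SET = frozenset(AUTOSOMES)
_CHROM_SET = frozenset(CHROMOSOMES)


def normalize_chrom(name: str) -> str:
    """Normalize a chromosome token to canonical ``chrN`` form.

    Accepts ``"8"`` or ``"chr8"`` (and ``X``/``Y``, case-insensitive for the
    ``chr`` prefix); anything outside the 24 canonical chromosomes raises
    ``ValueError``.
    """
    token = name.strip()
    if token.lower().startswith("chr"):
        token = token[3:]
    if token.lower() in ("x", "y"):
        token = token.upper()
    token = "chr" + token
    if token not in _CHROM_SET:
        raise ValueError(f"unknown chromosome: {name!r}")
    return token


def is_autosome(chrom: str) -> bool:
    return chrom in _AUTOSOME_SET
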