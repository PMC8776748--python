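"""Small DNA helpers shared across the package.

Sequences are plain ``str`` over {A,C,G,T} at the API surface and
``numpy.uint8`` codes (A=0, C=1, G=2, T=3) internally.
"""

from __future__ import annotations

import numpy as np

ALPHABET = "ACGT"

_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(ALPHABET):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_DECODE = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

# standard genetic code (table 1)
_BASES = "TCAG"
_AMINO = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)
CODON_TABLE = {
    a + b + c: _AMINO[i * 16 + j * 4 + k]
    for i, a in enumerate(_BASES)
    for j, b in enumerate(_BASES)
    for k, c in enumerate(_BASES)
}


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as uint8 codes; non-ACGT become 255."""
    return _ENCODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode()


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return (3 - codes)[::-1]


def random_seq(rng: np.random.Generator, length: int) -> str:
    return decode(rng.integers(0, 4, size=length).astype(np.uint8))


def translate_codon(codon: str) -> str:
    return CODON_TABLE[codon.upper()]


def is_synonymous(codon_ref: str, codon_alt: str) -> bool:
    return translate_codon(codon_ref) == translate_codon(codon_alt)


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming requires equal lengths")
    return int(np.count_nonzero(encode(a) != encode(b)))


def kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Packed integer k-mers (base-4) for every offset of an encoded sequence."""
    if len(codes) < k:
        return np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(codes, k).astype(np.int64)
    weights = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    return windows @ weights
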