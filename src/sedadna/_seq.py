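"""Low-level nucleotide sequence helpers shared across the package.

Sequences are plain uppercase ``str`` over the alphabet ACGTN.  For the
inner alignment loops sequences are encoded into small ``numpy`` integer
arrays; the encoding deliberately maps read-side N and reference-side N to
*different* codes so that an ambiguous base never counts as a match on
either side.
"""

from __future__ import annotations

import numpy as np

ALPHABET = "ACGTN"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# Read-side and reference-side encodings differ at N so N==N is a mismatch.
_READ_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_REF_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 5}

_READ_LUT = np.full(128, 4, dtype=np.uint8)
_REF_LUT = np.full(128, 5, dtype=np.uint8)
for _b, _c in _READ_CODE.items():
    _READ_LUT[ord(_b)] = _c
for _b, _c in _REF_CODE.items():
    _REF_LUT[ord(_b)] = _c


class SequenceAlphabetError(ValueError):
    """A sequence contains symbols outside ACGTN."""


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGTN string."""
    return seq.translate(_COMPLEMENT)[::-1]


def validate_sequence(seq: str, *, what: str = "sequence") -> str:
    s = seq.upper()
    if not s:
        raise SequenceAlphabetError(f"{what} is empty")
    if any(ch not in ALPHABET for ch in set(s)):
        bad = sorted(set(s) - set(ALPHABET))
        raise SequenceAlphabetError(f"{what} contains non-ACGTN symbols: {bad}")
    return s


def encode_read(seq: str) -> np.ndarray:
    return _READ_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def encode_ref(seq: str) -> np.ndarray:
    return _REF_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def random_sequence(length: int, rng: np.random.Generator) -> str:
    """Uniform random ACGT sequence (no N)."""
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def is_transversion(a: str, b: str) -> bool:
    """True if a<->b is a purine/pyrimidine change (damage-safe marker class)."""
    purines = {"A", "G"}
    return (a in purines) != (b in purines)
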