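"""RNA alphabet helpers shared across modules.

Internal alphabet is strictly {A, C, G, U}; DNA input (T) is transcribed to
U on ingest and lower case is folded to upper. All 6mer "words" are handled
5'->3'.
"""

from __future__ import annotations

import itertools

import numpy as np

RNA_ALPHABET = "ACGU"
_COMPLEMENT = str.maketrans("ACGU", "UGCA")
# base -> integer code used for vectorised k-mer counting
_CODE = {b: i for i, b in enumerate(RNA_ALPHABET)}


def normalize_rna(seq: str) -> str:
    """Uppercase and transcribe (T -> U). Does not validate."""
    return seq.upper().replace("T", "U")


def validate_word(word: str, length: int | None = None, *, name: str | None = None) -> str:
    """Normalize ``word`` and check alphabet (and optionally length).

    Raises ValueError naming the offending word (or ``name`` if given).
    """
    w = normalize_rna(word)
    label = name if name is not None else w
    if length is not None and len(w) != length:
        raise ValueError(f"word {label!r} has length {len(w)}, expected {length}")
    bad = set(w) - set(RNA_ALPHABET)
    if bad:
        raise ValueError(f"word {label!r} contains invalid letters {sorted(bad)}")
    return w


def reverse_complement(seq: str) -> str:
    """Reverse complement in the RNA alphabet, returned 5'->3'."""
    return seq.translate(_COMPLEMENT)[::-1]


def all_kmers(k: int = 6) -> list[str]:
    """All 4^k RNA words of length k in lexicographic (ACGU) order."""
    return ["".join(p) for p in itertools.product(RNA_ALPHABET, repeat=k)]


def encode(seq: str) -> np.ndarray:
    """Integer-encode a normalized RNA string (A=0, C=1, G=2, U=3)."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int64)
    for base, code in _CODE.items():
        out[arr == ord(base)] = code
    if (out < 0).any():
        i = int(np.argmax(out < 0))
        raise ValueError(f"invalid letter {seq[i]!r} at position {i}")
    return out


def word_id(word: str, k: int | None = None) -> int:
    """Lexicographic index of a k-mer (base-4 over ACGU)."""
    codes = encode(word)
    if k is not None and len(codes) != k:
        raise ValueError(f"word {word!r} is not a {k}-mer")
    out = 0
    for c in codes:
        out = out * 4 + int(c)
    return out


def kmer_window_ids(seq_codes: np.ndarray, k: int) -> np.ndarray:
    """Base-4 ids of all overlapping k-windows of an encoded sequence."""
    n = seq_codes.size
    if n < k:
        return np.empty(0, dtype=np.int64)
    ids = np.zeros(n - k + 1, dtype=np.int64)
    for j in range(k):
        ids = ids * 4 + seq_codes[j : n - k + 1 + j]
    return ids
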