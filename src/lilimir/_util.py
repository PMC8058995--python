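"""Small shared helpers: alphabets, reverse complement, seeded RNG derivation."""

from __future__ import annotations

import numpy as np

DNA = "ACGT"

_COMP = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")


def revcomp(seq: str) -> str:
    """Reverse complement (DNA alphabet; U treated as T)."""
    return seq.translate(_COMP)[::-1]


def rng_for(seed: int, *labels) -> np.random.Generator:
    """Derive an independent generator from a base seed and string/int labels.

    Uses SeedSequence spawn keys built by hashing the labels, so every
    (seed, label...) combination gets a reproducible, decorrelated stream.
    """
    entropy = [int(seed)]
    for lab in labels:
        if isinstance(lab, int):
            entropy.append(lab & 0x7FFFFFFF)
        else:
            entropy.append(abs(hash_str(str(lab))) & 0x7FFFFFFF)
    return np.random.default_rng(np.random.SeedSequence(entropy))


def hash_str(s: str) -> int:
    # deterministic across processes (builtin hash is salted)
    h = 2166136261
    for ch in s.encode():
        h = ((h ^ ch) * 16777619) & 0xFFFFFFFF
    return h


def random_seq(rng: np.random.Generator, length: int, alphabet: str = DNA) -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=length))


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)
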