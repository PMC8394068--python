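"""Internal nucleotide encoding shared by the scanner and the null model.

Bases are coded as uint8 in the order T, C, G, A (the order base
frequencies are reported in throughout the package). Any character
outside {A, C, G, T} (case-insensitive) maps to the sentinel
:data:`AMBIG`, which never matches anything during scanning.
"""

from __future__ import annotations

import numpy as np

BASE_ORDER = "TCGA"
AMBIG = np.uint8(255)

_LUT = np.full(256, AMBIG, dtype=np.uint8)
for _i, _b in enumerate(BASE_ORDER):
    _LUT[ord(_b)] = _i
    _LUT[ord(_b.lower())] = _i

# complement in code space: T<->A (0<->3), C<->G (1<->2); AMBIG stays AMBIG
_COMP = np.full(256, AMBIG, dtype=np.uint8)
_COMP[[0, 1, 2, 3]] = [3, 2, 1, 0]


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string into uint8 codes (ambiguous -> 255)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _LUT[raw]


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode`; ambiguous codes render as ``N``."""
    lut = np.frombuffer(b"TCGA", dtype=np.uint8)
    out = np.full(codes.shape, ord("N"), dtype=np.uint8)
    ok = codes < 4
    out[ok] = lut[codes[ok]]
    return out.tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    """Reverse complement in code space."""
    return _COMP[codes][::-1]


def window_identities(target_codes: np.ndarray, motif_codes: np.ndarray) -> np.ndarray:
    """Identity count of every length-W window of ``target_codes`` vs the motif.

    Returns an int array of length ``len(target) - W + 1`` (empty when the
    target is shorter than the motif). Ambiguous bases never match.
    """
    w = motif_codes.size
    if target_codes.size < w:
        return np.zeros(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(target_codes, w)
    # AMBIG in the target cannot equal a motif code (motif is unambiguous)
    return (windows == motif_codes).sum(axis=1)
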