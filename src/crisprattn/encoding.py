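"""Tokenisation of sgRNA and aligned sgRNA–DNA sequences.

Two vocabularies, both of size 16, feed the models:

* **base-pair tokens** — for the off-target task each aligned position
  contributes one token encoding the ordered (sgRNA base, DNA base)
  combination; 4 x 4 = 16 types. A length-L aligned pair yields L tokens
  (20 for Cas9 spacers, 27 for Cas12a including its 5' PAM window).
* **dimer tokens** — for the on-target task a sliding window of length 2
  walks the guide 5'->3'; the k-th token encodes the bases at positions
  k and k+1. A length-L sequence yields L-1 tokens (19 for 20-base Cas9
  guides, 33 for 34-base Cas12a guides). E.g. AUGCU -> AU, UG, GC, CU.

Token ids are the lexicographic rank of the ordered pair over (A, C, G, T):
(A,A)=0, (A,C)=1, ... (T,T)=15. Positions are 0-based, oriented 5'->3' of
the sgRNA. Internally sequences are stored in the DNA alphabet (U -> T on
ingest); use ``rna=True`` on the decoders to render uracils back.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np

from .errors import AlignmentError, ValidationError

__all__ = [
    "CasSystem",
    "AlignedPair",
    "GuideRecord",
    "TokenSequence",
    "canonicalize",
    "encode_base_pairs",
    "encode_dimers",
    "decode_base_pairs",
    "decode_dimers",
    "PAIR_TO_TOKEN",
    "TOKEN_TO_PAIR",
    "MATCH_TOKENS",
]

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}

#: Ordered (first base, second base) -> token id, lexicographic over ACGT.
PAIR_TO_TOKEN: dict[tuple[str, str], int] = {
    (a, b): 4 * _BASE_INDEX[a] + _BASE_INDEX[b] for a in _BASES for b in _BASES
}
TOKEN_TO_PAIR: dict[int, tuple[str, str]] = {v: k for k, v in PAIR_TO_TOKEN.items()}
#: Token ids of the four perfect-match base pairs (AA, CC, GG, TT).
MATCH_TOKENS = frozenset(PAIR_TO_TOKEN[(b, b)] for b in _BASES)


class CasSystem(str, Enum):
    """Nuclease system; fixes the expected input lengths.

    Cas9: 20-base spacer (3' PAM, not part of the window) for both tasks.
    Cas12a: 27-base aligned window (off-target) and 34-base guide window
    (on-target), each including the 4-base 5' PAM context.
    """

    CAS9 = "cas9"
    CAS12A = "cas12a"

    @property
    def pair_length(self) -> int:
        return 20 if self is CasSystem.CAS9 else 27

    @property
    def guide_length(self) -> int:
        return 20 if self is CasSystem.CAS9 else 34


def canonicalize(seq: str) -> str:
    """Uppercase and map U->T; reject anything outside the unambiguous alphabet."""
    out = seq.upper().replace("U", "T")
    bad = set(out) - set(_BASES)
    if bad:
        raise ValidationError(
            f"sequence contains non-ACGTU characters: {sorted(bad)} in {seq!r}"
        )
    return out


@dataclass
class AlignedPair:
    """An sgRNA aligned to an equal-length genomic site — the off-target unit."""

    sgrna_seq: str
    dna_seq: str
    score: Optional[float] = None  # indel frequency, percent
    label: Optional[int] = None  # 1 = active (high indel frequency)
    system: CasSystem = CasSystem.CAS9

    def __post_init__(self):
        self.sgrna_seq = canonicalize(self.sgrna_seq)
        self.dna_seq = canonicalize(self.dna_seq)
        if len(self.sgrna_seq) != len(self.dna_seq):
            raise AlignmentError(
                f"aligned pair length mismatch: sgRNA {len(self.sgrna_seq)} vs "
                f"DNA {len(self.dna_seq)}"
            )

    @property
    def n_mismatches(self) -> int:
        return sum(a != b for a, b in zip(self.sgrna_seq, self.dna_seq))


@dataclass
class GuideRecord:
    """A guide(+context) sequence with its efficiency — the on-target unit."""

    seq: str
    efficiency: float
    gene_id: Optional[str] = None
    cell_line: Optional[str] = None
    copy_number: Optional[float] = None
    netexpress: Optional[float] = None

    def __post_init__(self):
        self.seq = canonicalize(self.seq)
        if not np.isfinite(self.efficiency):
            raise ValidationError(f"non-finite efficiency for guide {self.seq}")


@dataclass
class TokenSequence:
    """Integer tokens in [0, 16) with 0-based positions, 5'->3' of the sgRNA."""

    tokens: np.ndarray
    positions: np.ndarray = field(default=None)  # type: ignore[assignment]
    vocab: str = "base_pair"  # or "dimer"

    def __post_init__(self):
        self.tokens = np.asarray(self.tokens, dtype=np.int64)
        if self.positions is None:
            self.positions = np.arange(len(self.tokens))
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.tokens.size and (self.tokens.min() < 0 or self.tokens.max() > 15):
            raise ValidationError("token ids must lie in [0, 15]")
        if len(self.tokens) != len(self.positions):
            raise ValidationError("tokens and positions must have equal length")

    def __len__(self) -> int:
        return len(self.tokens)


def encode_base_pairs(pair: AlignedPair) -> TokenSequence:
    """One token per aligned position: the ordered (sgRNA base, DNA base) id.

    A perfect match yields only the four match-type tokens (AA, CC, GG, TT).
    """
    s = np.frombuffer(pair.sgrna_seq.encode(), dtype=np.uint8)
    d = np.frombuffer(pair.dna_seq.encode(), dtype=np.uint8)
    lut = np.zeros(256, dtype=np.int64)
    for b, i in _BASE_INDEX.items():
        lut[ord(b)] = i
    tokens = 4 * lut[s] + lut[d]
    return TokenSequence(tokens=tokens, vocab="base_pair")


def encode_dimers(seq: str) -> TokenSequence:
    """L-1 overlapping dimer tokens from a length-L sequence (5'->3')."""
    seq = canonicalize(seq)
    if len(seq) < 2:
        raise ValidationError("dimer encoding needs a sequence of length >= 2")
    idx = np.array([_BASE_INDEX[b] for b in seq], dtype=np.int64)
    tokens = 4 * idx[:-1] + idx[1:]
    return TokenSequence(tokens=tokens, vocab="dimer")


def decode_base_pairs(ts: TokenSequence, rna: bool = False) -> tuple[str, str]:
    """Invert :func:`encode_base_pairs`; returns (sgRNA, DNA) strings."""
    if ts.vocab != "base_pair":
        raise ValidationError(f"expected base_pair tokens, got {ts.vocab}")
    sg = "".join(TOKEN_TO_PAIR[t][0] for t in ts.tokens.tolist())
    dna = "".join(TOKEN_TO_PAIR[t][1] for t in ts.tokens.tolist())
    if rna:
        sg = sg.replace("T", "U")
    return sg, dna


def decode_dimers(ts: TokenSequence, rna: bool = False) -> str:
    """Invert :func:`encode_dimers` back to the full sequence."""
    if ts.vocab != "dimer":
        raise ValidationError(f"expected dimer tokens, got {ts.vocab}")
    if len(ts) == 0:
        raise ValidationError("cannot decode an empty dimer sequence")
    toks = ts.tokens.tolist()
    seq = TOKEN_TO_PAIR[toks[0]][0] + "".join(TOKEN_TO_PAIR[t][1] for t in toks)
    return seq.replace("T", "U") if rna else seq


def dimer_name(token: int, rna: bool = False) -> str:
    """Human-readable dimer label for a token id, e.g. 3 -> 'AT' (or 'AU')."""
    a, b = TOKEN_TO_PAIR[token]
    s = a + b
    return s.replace("T", "U") if rna else s
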