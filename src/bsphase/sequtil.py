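"""Nucleotide alphabet algebra for bisulfite work.

IUPAC ambiguity codes, complementation and cytosine context classification
(CG / CHG / CHH, the three plant methylation contexts). All coordinates in
this package are 0-based, half-open; "sense" always means the orientation of
the stored reference string.
"""

from __future__ import annotations

from Bio.Data import IUPACData

__all__ = [
    "BASES",
    "IUPAC_CODES",
    "merge_bases",
    "expand_code",
    "complement",
    "reverse_complement",
    "classify_context",
    "CytosineContext",
    "InvalidAlphabetError",
]


class InvalidAlphabetError(ValueError):
    """A symbol outside the IUPAC DNA alphabet (or U) was supplied."""


BASES = frozenset("ACGT")

# symbol -> base set, from Biopython's IUPAC table (DNA, no gap symbol).
_EXPAND: dict[str, frozenset[str]] = {
    sym: frozenset(bases)
    for sym, bases in IUPACData.ambiguous_dna_values.items()
    if sym != "X"
}
_MERGE: dict[frozenset[str], str] = {bs: sym for sym, bs in _EXPAND.items()}
_COMPLEMENT: dict[str, str] = dict(IUPACData.ambiguous_dna_complement)

IUPAC_CODES = frozenset(_EXPAND)


def merge_bases(bases) -> str:
    """Return the unique IUPAC symbol whose base set equals ``bases``.

    >>> merge_bases({"C", "T"})
    'Y'
    """
    bs = frozenset(str(b).upper() for b in bases)
    if not bs or not bs <= BASES:
        raise InvalidAlphabetError(f"not a nonempty subset of ACGT: {set(bases)!r}")
    return _MERGE[bs]


def expand_code(code: str) -> frozenset[str]:
    """Return the base set of an IUPAC symbol (inverse of :func:`merge_bases`)."""
    sym = str(code).upper()
    if sym not in _EXPAND:
        raise InvalidAlphabetError(f"unknown IUPAC symbol: {code!r}")
    return _EXPAND[sym]


def complement(symbol: str) -> str:
    sym = str(symbol).upper()
    if sym not in _EXPAND:
        raise InvalidAlphabetError(f"unknown IUPAC symbol: {symbol!r}")
    return _COMPLEMENT[sym]


def clean_seq(seq: str) -> str:
    """Upper-case and validate a sequence of IUPAC DNA symbols (U rejected)."""
    s = str(seq).upper()
    bad = set(s) - IUPAC_CODES
    if bad:
        raise InvalidAlphabetError(f"invalid symbols in sequence: {sorted(bad)}")
    return s


def reverse_complement(seq: str) -> str:
    """Reverse complement over the full IUPAC alphabet (Y <-> R etc.)."""
    s = clean_seq(seq)
    return "".join(_COMPLEMENT[c] for c in reversed(s))


class CytosineContext:
    """Labels for the sequence context of a cytosine on its own strand."""

    CG = "CG"
    CHG = "CHG"
    CHH = "CHH"
    EDGE = "EDGE"


_H = frozenset("ACT")


def classify_context(seq: str, pos: int, strand: str = "sense") -> str:
    """Classify the methylation context of the cytosine at ``pos``.

    ``strand="antisense"`` classifies the complementary strand's cytosine:
    the call runs on the reverse complement with the mapped coordinate
    (``len(seq) - 1 - pos``). The base at the requested position, on the
    requested strand, must be C.

    Context is read 3' of the cytosine on its strand: CG if the next base is
    G; CHG if (H, G) follows; CHH if (H, H) follows; EDGE when the strand
    ends before the context can be resolved (H = A, C or T).
    """
    s = clean_seq(seq)
    if strand == "antisense":
        return classify_context(reverse_complement(s), len(s) - 1 - pos, "sense")
    if strand != "sense":
        raise ValueError(f"strand must be 'sense' or 'antisense', got {strand!r}")
    if not 0 <= pos < len(s):
        raise IndexError(f"position {pos} outside sequence of length {len(s)}")
    if s[pos] != "C":
        raise ValueError(f"base at position {pos} is {s[pos]!r}, not C")
    if pos + 1 >= len(s):
        return CytosineContext.EDGE
    if s[pos + 1] == "G":
        return CytosineContext.CG
    if pos + 2 >= len(s):
        return CytosineContext.EDGE
    if s[pos + 1] in _H and s[pos + 2] == "G":
        return CytosineContext.CHG
    if s[pos + 1] in _H and s[pos + 2] in _H:
        return CytosineContext.CHH
    # next base in H, the one after ambiguous only if non-ACGT slipped in;
    # clean_seq guarantees ACGT/ambiguity codes but contexts are defined on
    # plain bases — treat any ambiguity downstream as unresolvable.
    return CytosineContext.EDGE


def context_map(seq: str) -> list[str | None]:
    """Context label for every cytosine of a plain base string, else None.

    Single linear pass; equivalent to calling :func:`classify_context` at
    every C (used on hot paths where per-call validation would dominate).
    """
    s = clean_seq(seq)
    n = len(s)
    out: list[str | None] = [None] * n
    for i, b in enumerate(s):
        if b != "C":
            continue
        if i + 1 >= n:
            out[i] = CytosineContext.EDGE
        elif s[i + 1] == "G":
            out[i] = CytosineContext.CG
        elif i + 2 >= n or s[i + 1] not in _H:
            out[i] = CytosineContext.EDGE
        elif s[i + 2] == "G":
            out[i] = CytosineContext.CHG
        elif s[i + 2] in _H:
            out[i] = CytosineContext.CHH
        else:
            out[i] = CytosineContext.EDGE
    return out
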