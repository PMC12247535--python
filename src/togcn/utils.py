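"""Small shared helpers: natural sorting, rounding, IUPAC handling."""

from __future__ import annotations

import re

from .exceptions import FormatError

#: IUPAC nucleotide codes -> set of concrete bases.
IUPAC_CODES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def natural_key(name: str) -> tuple:
    """Sort key treating digit runs numerically, so chr09 < chr10 < chr11."""
    parts = re.split(r"(\d+)", name)
    return tuple(int(p) if p.isdigit() else p for p in parts)


def percent_share(count: float, total: float, ndigits: int = 0) -> float:
    """Percentage share ``100 * count / total`` rounded to ``ndigits``.

    ``ndigits=0`` returns a nearest-integer float (half away from zero, the
    convention of printed percentage tables), ``ndigits=1`` a 1-decimal share.
    """
    if total <= 0:
        raise ValueError("total must be positive")
    pct = 100.0 * count / total
    # round half away from zero; Python's round() is banker's rounding
    factor = 10 ** ndigits
    shifted = pct * factor
    rounded = int(shifted + 0.5) if shifted >= 0 else -int(-shifted + 0.5)
    return rounded / factor if ndigits else float(rounded)


def validate_iupac(pattern: str) -> str:
    """Upper-case and validate an IUPAC nucleotide pattern."""
    up = pattern.upper()
    for i, ch in enumerate(up):
        if ch not in IUPAC_CODES:
            raise FormatError(f"invalid IUPAC symbol {ch!r} at position {i} in {pattern!r}")
    return up


def iupac_to_regex(pattern: str) -> str:
    """Translate an IUPAC pattern to a plain character-class regex."""
    up = validate_iupac(pattern)
    out = []
    for ch in up:
        bases = IUPAC_CODES[ch]
        out.append(bases if len(bases) == 1 else f"[{bases}]")
    return "".join(out)


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (IUPAC-aware)."""
    return seq.upper().translate(_COMPLEMENT)[::-1]


def iupac_matches(pattern: str, window: str) -> bool:
    """True if ``window`` (concrete bases) matches ``pattern`` positionally."""
    if len(pattern) != len(window):
        return False
    return all(b in IUPAC_CODES.get(p, "") for p, b in zip(pattern, window.upper()))
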