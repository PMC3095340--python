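"""Small shared sequence helpers."""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: Tag geometry: SuperSAGE tags are 26 nt anchored at the NlaIII site CATG.
TAG_LENGTH = 26
ANCHOR = "CATG"
DITAG_LENGTH = 2 * TAG_LENGTH


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def percentage(part: float, whole: float, decimals: int = 1) -> float:
    """Percentage of ``part`` in ``whole`` rounded to ``decimals`` places."""
    if whole == 0:
        raise ValueError("percentage of an empty total is undefined")
    return round(100.0 * part / whole, decimals)
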