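"""Small shared helpers."""

from __future__ import annotations


def percent(numerator: float, denominator: float, decimals: int = 2) -> float:
    """``numerator / denominator`` expressed as a percentage, rounded.

    Used for headline report figures (marker homozygosity, conserved-base
    fractions, assigned-genome coverage).
    """
    if denominator == 0:
        raise ZeroDivisionError("percent of an empty denominator")
    return round(100.0 * numerator / denominator, decimals)
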