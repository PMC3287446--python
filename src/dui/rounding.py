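"""Half-up decimal rounding for display values.

Python's built-in round() uses banker's rounding on binary floats, which
disagrees with the half-up convention of printed indicator tables exactly at
the ties that matter (e.g. 8.65625 -> 8.66). All display rounding in this
package goes through round_half_up.
"""

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round x half-up to ndigits decimal places.

    Uses repr(x) so the decimal value rounded is the shortest decimal
    representation of the float, not its full binary expansion.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
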