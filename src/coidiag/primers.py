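"""Bundled primer set for partial COI amplification from cixiid planthoppers.

Two universal pairs (Ron/Calvin and UEA3/UEA8, both ~1000 bp products on
COI) and the Pentastiridius leporinus-specific pair fw1/rv1 (341 bp
product).  fw1/rv1 were designed against the P. leporinus COI gene to match
it perfectly while mismatching the COI of the look-alike cixiids
(Reptalus, Hyalesthes), with the discriminating mismatches at the primer
3' ends.
"""

from __future__ import annotations

from .seq_core import Primer, PrimerRole

__all__ = [
    "FW1",
    "RV1",
    "RON",
    "CALVIN",
    "UEA3",
    "UEA8",
    "SPECIFIC_PAIR",
    "UNIVERSAL_PAIRS",
    "ALL_PRIMERS",
    "primer_by_name",
]

FW1 = Primer("fw1", "TTATTGCAGTACCAACAGGT", PrimerRole.FORWARD, "rv1")
RV1 = Primer(
    "rv1", "TGTGAAATTTACTCCTGTAAATATAGTAAAG", PrimerRole.REVERSE, "fw1"
)
RON = Primer("Ron", "GGATCACCTGATATAGCATTCCC", PrimerRole.FORWARD, "Calvin")
CALVIN = Primer("Calvin", "GGRAARAAWGTTAARTTWACTCC", PrimerRole.REVERSE, "Ron")
UEA3 = Primer("UEA3", "TATAGCATTCCCACGAATAAATAA", PrimerRole.FORWARD, "UEA8")
UEA8 = Primer("UEA8", "AAAAATGTTGAGGGAAAAATGTTA", PrimerRole.REVERSE, "UEA3")

SPECIFIC_PAIR: tuple[Primer, Primer] = (FW1, RV1)
UNIVERSAL_PAIRS: dict[str, tuple[Primer, Primer]] = {
    "Ron/Calvin": (RON, CALVIN),
    "UEA3/UEA8": (UEA3, UEA8),
}
ALL_PRIMERS: dict[str, Primer] = {
    p.name: p for p in (FW1, RV1, RON, CALVIN, UEA3, UEA8)
}

#: Expected product sizes (bp) for the bundled pairs.
PRODUCT_SIZES: dict[str, int | str] = {
    "fw1/rv1": 341,
    "Ron/Calvin": "~1000",
    "UEA3/UEA8": "~1000",
}


def primer_by_name(name: str) -> Primer:
    try:
        return ALL_PRIMERS[name]
    except KeyError:
        raise KeyError(
            f"unknown primer {name!r}; bundled primers: {sorted(ALL_PRIMERS)}"
        ) from None
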