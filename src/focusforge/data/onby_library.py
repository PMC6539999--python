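"""Reference focused library for the ONBY-specific *Mj*TyrRS redesign.

The published curated library diversifies 17 first- and second-shell positions
of *Methanocaldococcus jannaschii* tyrosyl-tRNA synthetase for the photocaged
substrate ortho-nitrobenzyl tyrosine (ONBY).  Each row is
(position, wild-type identity, allowed identity set, selected-variant
identity), the selected variant being the high-activity synthetase isolated
from this library (here called ONBYRS-1).  All library members additionally
carry a fixed D286R background mutation improving suppressor-tRNA recognition;
it is metadata, never counted toward library diversity.
"""

LIBRARY_TABLE = [
    (32, "Y", ("A", "S"), "A"),
    (65, "L", ("A", "I", "L", "F", "S"), "A"),
    (67, "A", ("A", "Q"), "A"),
    (69, "L", ("L", "K", "G", "W"), "L"),
    (70, "H", ("A", "N", "S"), "N"),
    (105, "G", ("G", "A", "Q"), "Q"),
    (108, "F", ("F", "L"), "F"),
    (109, "Q", ("A", "Q", "Y"), "A"),
    (154, "M", ("E", "M", "T", "G"), "M"),
    (158, "D", ("A", "G", "S"), "S"),
    (159, "I", ("A", "G", "S", "I"), "A"),
    (162, "L", ("A", "M"), "A"),
    (164, "V", ("A", "T", "V"), "V"),
    (167, "A", ("N", "Q", "G", "S"), "S"),
    (177, "H", ("A", "H", "Q", "Y"), "H"),
    (180, "A", ("A", "Q"), "Q"),
    (188, "V", ("N", "Q", "T", "V"), "V"),
]

#: fixed background mutation present in every library member
FIXED_BACKGROUND = {286: "R"}

#: positions designable during the design stage (the library table retains the
#: 17 of these that stayed diversified after curation)
N_DESIGNABLE_POSITIONS = 26


def wild_type() -> dict[int, str]:
    return {pos: wt for pos, wt, _, _ in LIBRARY_TABLE}


def allowed_sets() -> dict[int, tuple[str, ...]]:
    return {pos: allowed for pos, _, allowed, _ in LIBRARY_TABLE}


def selected_variant() -> dict[int, str]:
    """The experimentally selected ONBYRS-1 sequence over the library positions."""
    return {pos: sel for pos, _, _, sel in LIBRARY_TABLE}
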