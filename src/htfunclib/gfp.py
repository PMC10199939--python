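"""GFP chromophore-pocket position sets used by the published library designs.

Positions are author numbering on the eGFP crystal structure (PDB 2WUR).
Two designed libraries targeted the pocket: one including positions that
hydrogen-bond to the chromophore (24 positions) and one excluding them
(27 positions).  The union list covers the 38 chromophore-pocket positions
used when filtering external mutational datasets down to pocket-only
variants.
"""

from __future__ import annotations

#: 27 designed positions (library excluding chromophore H-bonding positions)
POCKET_POSITIONS_27_RAW = (
    "14, 16, 18, 42, 44, 46, 61, 64, 66, 68, 69, 72, 108, 110, 112, 119, "
    "123, 145, 150, 163, 165, 167, 181, 185, 201, 220, 224"
)

#: 24 designed positions (library including chromophore H-bonding positions)
POCKET_POSITIONS_24_RAW = (
    "42, 44, 61, 62, 69, 92, 94, 96, 112, 121, 145, 148, 150, 163, 165, "
    "167, 181, 183, 185, 203, 205, 220, 222, 224"
)

#: all 38 chromophore-pocket positions (union list used for pocket-only filtering)
CHROMOPHORE_POCKET_RAW = (
    "14, 16, 18, 42, 44, 46, 61, 62, 63, 64, 66, 68, 69, 72, 92, 94, 96, "
    "108, 110, 112, 119, 121, 123, 145, 148, 150, 163, 165, 167, 181, 183, "
    "185, 201, 203, 205, 220, 222, 224"
)


def parse_position_list(raw: str) -> list[int]:
    """Parse a comma-separated residue-number list into sorted unique ints."""
    positions = [int(tok) for tok in raw.replace(",", " ").split()]
    if len(set(positions)) != len(positions):
        raise ValueError("duplicate positions in list")
    return sorted(positions)


POCKET_POSITIONS_27 = parse_position_list(POCKET_POSITIONS_27_RAW)
POCKET_POSITIONS_24 = parse_position_list(POCKET_POSITIONS_24_RAW)
CHROMOPHORE_POCKET_POSITIONS = parse_position_list(CHROMOPHORE_POCKET_RAW)
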