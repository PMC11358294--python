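from __future__ import annotations

import pytest

from mpolytop import canonical_graph


def make_molblock(atoms: list[str], bonds: list[tuple[int, int]], title: str = "mol") -> str:
    """Assemble a minimal MDL MOL V2000 block (1-based bond indices)."""
    lines = [title, "  synthetic", ""]
    lines.append(f"{len(atoms):3d}{len(bonds):3d}  0  0  0  0  0  0  0  0999 V2000")
    for sym in atoms:
        lines.append(f"    0.0000    0.0000    0.0000 {sym:<3s} 0  0  0  0  0  0  0  0  0  0  0  0")
    for i, j in bonds:
        lines.append(f"{i:3d}{j:3d}  1  0")
    lines.append("M  END")
    return "\n".join(lines) + "\n"


@pytest.fixture
def water_molblock() -> str:
    return make_molblock(["O", "H", "H"], [(1, 2), (1, 3)], "water")


@pytest.fixture
def ethane_molblock() -> str:
    bonds = [(1, 2), (1, 3), (1, 4), (1, 5), (2, 6), (2, 7), (2, 8)]
    return make_molblock(["C", "C"] + ["H"] * 6, bonds, "ethane")


@pytest.fixture
def triangle():
    return canonical_graph("cycle_3")


@pytest.fixture
def star4():
    return canonical_graph("star_4")
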