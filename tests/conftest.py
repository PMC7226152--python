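"""Shared fixtures: random topology generation and the atom-graph oracle glue."""

from __future__ import annotations

import numpy as np
import pytest

from glycoseek.fragments import FragmentIon
from glycoseek.topology import GlycanNode, GlycanTopology, Linkage

from atomgraph import AtomGraph

_PARENT_CLASSES = ("Hex", "HexNAc", "Fuc")


def random_topology(rng: np.random.Generator, max_residues: int = 6,
                    aglycone: str | None = None) -> GlycanTopology:
    """A random valid rooted glycan tree of <= max_residues residues.

    Sialic acid is only ever attached as a terminal residue (as in mucin-type
    O-glycans); any free hydroxyl position of Hex/HexNAc/Fuc can take a child.
    """
    n = int(rng.integers(1, max_residues + 1))
    if aglycone is None:
        aglycone = ("benzyl", "free_reducing")[int(rng.integers(2))]
    from glycoseek.residues import DEFAULT_RESIDUES as table

    root = {"name": _PARENT_CLASSES[int(rng.integers(2))], "children": []}
    slots = [(root, p) for p in table[root["name"]].hydroxyl_positions]
    for _ in range(n - 1):
        if not slots:
            break
        k = int(rng.integers(len(slots)))
        parent, pos = slots.pop(k)
        if rng.random() < 0.25:
            name = "NeuAc"
        else:
            name = _PARENT_CLASSES[int(rng.integers(3))]
        child = {"name": name, "children": []}
        anomer = "a" if name in ("NeuAc", "Fuc") else "b"
        child_pos = table[name].anomeric_position
        parent["children"].append((Linkage(anomer, child_pos, pos), child))
        if name != "NeuAc":
            slots += [(child, p) for p in table[name].hydroxyl_positions]

    def freeze(d) -> GlycanNode:
        return GlycanNode(d["name"], tuple((lk, freeze(c)) for lk, c in d["children"]))

    return GlycanTopology(freeze(root), aglycone)


def oracle_mz(graph: AtomGraph, fragment: FragmentIon) -> float:
    """Recompute one package fragment with the atom-graph oracle, using only
    the fragment's structural coordinates (parsed from its site string)."""
    site = fragment.site
    benzyl_loss = site.endswith(";-BnOH")
    if benzyl_loss:
        site = site[: -len(";-BnOH")]
    child_idx = None
    ring = None
    glyco_kind = None
    ring_kind = None
    for part in site.split(";"):
        if part[0] in "BCYZ" and part[1] == "@":
            glyco_kind = part[0]
            child_idx = int(part.rsplit("#", 1)[1])
        elif part[0] in "AX":
            ring_kind = part[0]
            spec, _ = part[1:].split("@", 1)
            ring = (int(part.rsplit("#", 1)[1]),
                    tuple(int(x) for x in spec.split(",")))
        else:  # pragma: no cover - defensive
            raise ValueError(f"unparseable site {fragment.site!r}")
    if ring is not None and glyco_kind is not None:
        kind = {"X": {"Y": "YX", "Z": "ZX"}, "A": {"Y": "AY", "Z": "AZ"}}[ring_kind][glyco_kind]
    elif ring is not None:
        kind = ring_kind
    else:
        kind = glyco_kind
    return graph.fragment_mz(kind, child_idx, ring, benzyl_loss)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240861)
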