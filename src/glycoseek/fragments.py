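"""Domon-Costello fragment enumeration for (derivatized) glycan topologies.

Glycosidic cleavages give B/C (non-reducing side) and Y/Z (reducing side)
ions; cross-ring cleavages give A (non-reducing) and X (reducing) ions
labelled with the pair of ring bonds broken (bond 0 = O5-C1, 1 = C1-C2, ...,
5 = C5-O5 around the pyranose ring).  Fragment masses are computed from the
fragment's explicit residue/ring-atom content; methyl "scars" are bookkept
automatically because a glycosidic position is never methylated in the intact
permethylated molecule, so a severed position re-appears as a free hydroxyl.

Identities used throughout (single charge, proton adduct):

* mz(B) + mz(Y) = mz([M+H]+) + 1.007276 for the B/Y pair of any edge
* C = B + H2O, Y = Z + H2O, and the same identities for A/X pairs.

Cross-ring support covers the six-membered rings of Hex, HexNAc and Fuc for
the bond pairs 0,2 / 0,3 / 1,3 / 2,4 / 3,5 / 2,5 — the set needed to discern
type-1 (sialyl-Lewis A) from type-2 (sialyl-Lewis X) chains.  Sialic acid
cross-ring ions are not enumerated.
"""

from __future__ import annotations

from dataclasses import dataclass

from .mass import DerivatizationScheme, PROTONATED, mz as _mz
from .residues import ATOMIC_MASS, BENZYL_INCREMENT, CH2, PROTON, WATER
from .topology import GlycanNode, GlycanTopology, count_methylation_sites

__all__ = ["FragmentIon", "enumerate_fragments", "RING_BOND_PAIRS", "ION_TYPES"]

ION_TYPES = frozenset("BCYZAX")

# Ring-bond pairs -> carbons on the arc *not* containing C1 (the arc lost by
# an X ion and kept by the matching A ion).  "O5" marks the ring oxygen; C6
# travels with C5.
RING_BOND_PAIRS: dict[tuple[int, int], tuple[str, ...]] = {
    (0, 2): ("C3", "C4", "C5", "O5"),
    (0, 3): ("C4", "C5", "O5"),
    (1, 3): ("C2", "C3"),
    (2, 4): ("C3", "C4"),
    (3, 5): ("C4", "C5"),
    (2, 5): ("C3", "C4", "C5"),
}

_O = ATOMIC_MASS["O"]
_H = ATOMIC_MASS["H"]
_CH = ATOMIC_MASS["C"] + ATOMIC_MASS["H"]
_CH3 = ATOMIC_MASS["C"] + 3 * ATOMIC_MASS["H"]
_OH = _O + ATOMIC_MASS["H"]
_OME = _O + _CH3
_NHAC = ATOMIC_MASS["N"] + 4 * ATOMIC_MASS["H"] + 2 * ATOMIC_MASS["C"] + _O
_NMEAC = _NHAC + CH2
BENZYL_ALCOHOL = WATER + BENZYL_INCREMENT  # C7H8O, the benzyl-tag neutral loss

_RING_CLASSES = {"Hex", "HexNAc", "Fuc"}


@dataclass(frozen=True)
class FragmentIon:
    """One theoretical fragment at charge 1 (proton adduct)."""

    dc_label: str  # e.g. "B2", "Y1", "3,5X1", "Z1/3,5X1", suffix "-Bn"
    site: str  # structural coordinate: cleaved edge(s)/residue, unique
    ion_kind: str  # B, C, Y, Z, A or X (the cross-ring / terminal type)
    neutral_mass: float
    mz: float
    retains_aglycone: bool
    cleavage_count: int
    benzyl_loss: bool = False


class _Indexer:
    """Per-node bookkeeping: residues, methyl counts, subtree masses."""

    def __init__(self, topo: GlycanTopology, scheme: DerivatizationScheme):
        self.topo = topo
        self.perm = scheme.kind == "permethylated"
        self.table = topo.table
        self.nodes: list[GlycanNode] = topo.nodes()
        self.index = {id(n): i for i, n in enumerate(self.nodes)}
        self.parent: dict[int, GlycanNode | None] = {id(topo.root): None}
        self.depth: dict[int, int] = {id(topo.root): 0}
        for node in self.nodes:
            for _, child in node.children:
                self.parent[id(child)] = node
                self.depth[id(child)] = self.depth[id(node)] + 1
        self._methyls: dict[int, int] = {}
        if self.perm:
            for node in self.nodes:
                res = self.table[node.name]
                occupied = {lk.parent_pos for lk, _ in node.children}
                if None in occupied:
                    raise ValueError(
                        "fragment enumeration needs fully specified linkage "
                        f"positions; {node.name} has an unknown linkage"
                    )
                free_oh = len(set(res.hydroxyl_positions) - occupied)
                n = free_oh + res.amide_nh_count + res.carboxyl_count
                if node is topo.root and topo.root_aglycone == "free_reducing":
                    n += 1
                self._methyls[id(node)] = n
            assert sum(self._methyls.values()) == count_methylation_sites(topo)
        self._subtree: dict[int, float] = {}
        self._fill_subtree(topo.root)
        agl = {"free_reducing": WATER, "benzyl": WATER + BENZYL_INCREMENT,
               "serine_threonine": 0.0}[topo.root_aglycone]
        self.total_neutral = self._subtree[id(topo.root)] + agl

    def _fill_subtree(self, node: GlycanNode) -> float:
        m = self.table[node.name].monoisotopic_mass
        m += self._methyls.get(id(node), 0) * CH2
        for _, child in node.children:
            m += self._fill_subtree(child)
        self._subtree[id(node)] = m
        return m

    def subtree_mass(self, node: GlycanNode) -> float:
        return self._subtree[id(node)]

    def height(self, node: GlycanNode) -> int:
        if not node.children:
            return 1
        return 1 + max(self.height(c) for _, c in node.children)

    def position_sub_mass(self, node: GlycanNode, pos: int) -> tuple[float, GlycanNode | None]:
        """Mass of the exocyclic substituent at ring position ``pos``.

        A child subtree contributes the glycosidic oxygen plus its atoms —
        the net-of-water residue sum plus the one hydrogen its anomeric
        carbon keeps when the subtree is severed from the ring.
        """
        for link, child in node.children:
            if link.parent_pos == pos:
                return _O + self.subtree_mass(child) + _H, child
        res = self.table[node.name]
        if pos in res.hydroxyl_positions:
            return (_OME if self.perm else _OH), None
        raise ValueError(f"no substituent defined at position {pos} of {node.name}")

    def arc(self, node: GlycanNode, pair: tuple[int, int]) -> tuple[float, list[GlycanNode]]:
        """Mass of the ring arc lost by an i,jX ion, plus detached subtrees."""
        cls = self.table.canonical(node.name)
        if cls not in _RING_CLASSES:
            raise ValueError(f"cross-ring cleavage unsupported for {cls}")
        removed = RING_BOND_PAIRS[pair]
        mass = 0.0
        detached: list[GlycanNode] = []
        for atom in removed:
            if atom == "O5":
                mass += _O
                continue
            pos = int(atom[1])
            if pos == 2 and cls == "HexNAc":
                mass += _CH + (_NMEAC if self.perm else _NHAC)
            elif pos == 5:
                mass += _CH
                if cls == "Fuc":
                    mass += _CH3  # 6-deoxy: C6 is a methyl group
                else:
                    sub, child = self.position_sub_mass(node, 6)
                    mass += CH2 + sub  # C6H2 plus its oxygen substituent
                    if child is not None:
                        detached.append(child)
            else:
                sub, child = self.position_sub_mass(node, pos)
                mass += _CH + sub
                if child is not None:
                    detached.append(child)
        return mass, detached


def _edge_sites(ix: _Indexer):
    """All glycosidic edges: (parent or None for the aglycone bond, child)."""
    edges = []
    if ix.topo.root_aglycone in ("benzyl", "serine_threonine"):
        edges.append((None, ix.topo.root))
    for node in ix.nodes:
        for link, child in node.children:
            edges.append((node, child))
    return edges


def _descendants(node: GlycanNode) -> set[int]:
    return {id(n) for n in node.walk()}


def enumerate_fragments(
    topo: GlycanTopology,
    scheme: DerivatizationScheme,
    ion_types: frozenset | set | str = ION_TYPES,
    max_cleavages: int = 1,
    include_benzyl_loss: bool = True,
) -> list[FragmentIon]:
    """Enumerate theoretical singly-protonated fragments of a topology.

    ``max_cleavages`` 1 gives all single glycosidic (B/C/Y/Z) and cross-ring
    (A/X) ions; 2 additionally combines one cross-ring event with one
    glycosidic Y- or Z-type subtree loss (e.g. the Z/3,5X ions that discern
    sialyl-Lewis isomers).  For benzyl glycosides, fragments retaining the
    aglycone are also emitted with the benzyl tag lost as benzyl alcohol
    when ``include_benzyl_loss`` is set.
    """
    ion_types = frozenset(ion_types)
    unknown = ion_types - ION_TYPES
    if unknown:
        raise ValueError(f"unsupported ion types: {sorted(unknown)}")
    if max_cleavages not in (1, 2):
        raise ValueError("max_cleavages must be 1 or 2")

    ix = _Indexer(topo, scheme)
    M = ix.total_neutral
    frags: list[FragmentIon] = []

    def emit(label, site, kind, neutral, retains_agl, n_cleav, bn_loss=False):
        frags.append(
            FragmentIon(label, site, kind, neutral, neutral + PROTON,
                        retains_agl, n_cleav, bn_loss)
        )
        if (
            include_benzyl_loss
            and retains_agl
            and topo.root_aglycone == "benzyl"
            and not bn_loss
            and neutral - BENZYL_ALCOHOL > 1.0
        ):
            frags.append(
                FragmentIon(f"{label}-Bn", f"{site};-BnOH", kind,
                            neutral - BENZYL_ALCOHOL,
                            neutral - BENZYL_ALCOHOL + PROTON,
                            False, n_cleav, True)
            )

    # --- single glycosidic cleavages -------------------------------------
    for parent, child in _edge_sites(ix):
        sub = ix.subtree_mass(child)
        edge = (
            f"{(parent.name if parent else topo.root_aglycone)}"
            f"<-{child.name}#{ix.index[id(child)]}"
        )
        j = ix.depth[id(child)]  # glycosidic bonds from the reducing end
        i = ix.height(child)  # chain length of the detached subtree
        if "B" in ion_types:
            emit(f"B{i}", f"B@{edge}", "B", sub, False, 1)
        if "C" in ion_types:
            emit(f"C{i}", f"C@{edge}", "C", sub + WATER, False, 1)
        if "Y" in ion_types:
            emit(f"Y{j}", f"Y@{edge}", "Y", M - sub, True, 1)
        if "Z" in ion_types:
            emit(f"Z{j}", f"Z@{edge}", "Z", M - sub - WATER, True, 1)

    # --- cross-ring cleavages (and glycosidic combinations) --------------
    if not (ion_types & {"A", "X"}):
        return frags
    for node in ix.nodes:
        if ix.table.canonical(node.name) not in _RING_CLASSES:
            continue
        n_red = ix.depth[id(node)]  # X subscript: position from reducing end
        n_nonred = ix.height(node)  # A subscript: position from non-reducing end
        for pair, _ in RING_BOND_PAIRS.items():
            arc_mass, detached = ix.arc(node, pair)
            tag = f"{pair[0]},{pair[1]}"
            ring_site = f"{tag}@{node.name}#{ix.index[id(node)]}"
            removed_ids = set()
            for d in detached:
                removed_ids |= _descendants(d)
            if "X" in ion_types:
                x_neutral = M - arc_mass
                emit(f"{tag}X{n_red}", f"X{ring_site}", "X", x_neutral, True, 1)
                if max_cleavages == 2:
                    blocked = removed_ids | {id(node)}
                    for parent, child in _edge_sites(ix):
                        if parent is None:
                            continue
                        csub = _descendants(child)
                        if csub & blocked or id(node) in csub:
                            continue
                        sub = ix.subtree_mass(child)
                        j = ix.depth[id(child)]
                        edge = f"{parent.name}<-{child.name}#{ix.index[id(child)]}"
                        if "Y" in ion_types:
                            emit(f"Y{j}/{tag}X{n_red}", f"Y@{edge};X{ring_site}",
                                 "X", x_neutral - sub, True, 2)
                        if "Z" in ion_types:
                            emit(f"Z{j}/{tag}X{n_red}", f"Z@{edge};X{ring_site}",
                                 "X", x_neutral - sub - WATER, True, 2)
            if "A" in ion_types:
                emit(f"{tag}A{n_nonred}", f"A{ring_site}", "A", arc_mass, False, 1)
                if max_cleavages == 2:
                    for parent, child in _edge_sites(ix):
                        if parent is None or id(parent) not in removed_ids:
                            continue
                        sub = ix.subtree_mass(child)
                        j = ix.height(child)
                        edge = f"{parent.name}<-{child.name}#{ix.index[id(child)]}"
                        if "Y" in ion_types:
                            emit(f"{tag}A{n_nonred}/Y{j}", f"A{ring_site};Y@{edge}",
                                 "A", arc_mass - sub, False, 2)
                        if "Z" in ion_types:
                            emit(f"{tag}A{n_nonred}/Z{j}", f"A{ring_site};Z@{edge}",
                                 "A", arc_mass - sub - WATER, False, 2)
    return frags


def precursor_mz(topo: GlycanTopology, scheme: DerivatizationScheme) -> float:
    """Convenience: [M+H]+ of the intact derivatized glycan."""
    from .mass import neutral_mass

    return _mz(neutral_mass(topo, scheme), PROTONATED)
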