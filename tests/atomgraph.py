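"""Independent brute-force oracle for fragment masses.

Builds an explicit molecular graph — one vertex per ring atom (with its
exocyclic substituents folded into the vertex formula), one vertex per
glycosidic oxygen, sialic acids as single linked-formula vertices — then
computes fragment masses by deleting the cleaved bonds and summing the atoms
of the connected component, applying the standard hydrogen-transfer
conventions (Y gains the hydroxyl H; Z = Y - H2O; C = B + H2O; cross-ring
cleavages transfer nothing).  Shares no mass-arithmetic code with the
package: masses come from its own atomic-mass table and explicit formulas.
"""

from __future__ import annotations

from collections import Counter

# independent atomic masses (NIST values, not imported from the package)
AM = {"C": 12.0, "H": 1.0078250319, "N": 14.0030740052, "O": 15.9949146221}
H2O = 2 * AM["H"] + AM["O"]
PROTON_ = 1.007276466


def fmass(counter: Counter) -> float:
    return sum(AM[e] * n for e, n in counter.items())


def _c(**kw) -> Counter:
    return Counter({k: v for k, v in kw.items() if v})


class AtomGraph:
    """Explicit atom-group graph of one (optionally permethylated) glycan."""

    def __init__(self, topo, permethylated: bool):
        self.topo = topo
        self.perm = permethylated
        self.vertices: dict[str, Counter] = {}
        self.edges: set[frozenset] = set()
        self.ring_bond: dict[tuple[int, int], frozenset] = {}  # (node_idx, bond) -> edge
        self.glyco_bond: dict[int, frozenset] = {}  # child node_idx -> O-C1(child) edge
        self.anchor: dict[int, str] = {}  # node_idx -> anomeric vertex id
        nodes = topo.nodes()
        self.index = {id(n): i for i, n in enumerate(nodes)}
        self._build(topo.root, parent_vertex=None)
        if topo.root_aglycone == "benzyl":
            self.vertices[self.anchor[0]] += _c(O=1, C=7, H=7)  # O-CH2-C6H5
        elif topo.root_aglycone == "free_reducing":
            self.vertices[self.anchor[0]] += self._oxy()

    def _oxy(self) -> Counter:
        return _c(O=1, C=1, H=3) if self.perm else _c(O=1, H=1)

    def _add_edge(self, a: str, b: str) -> frozenset:
        e = frozenset((a, b))
        self.edges.add(e)
        return e

    def _build(self, node, parent_vertex):
        idx = self.index[id(node)]
        cls = self.topo.table.canonical(node.name)
        children = {lk.parent_pos: child for lk, child in node.children}
        if cls == "NeuAc":
            vid = f"{idx}:blob"
            atoms = _c(C=11, H=18, N=1, O=8)  # linked Neu5Ac
            if self.perm:
                atoms += Counter({"C": 6, "H": 12})  # 4 OMe + N-Me + COOMe
            self.vertices[vid] = atoms
            self.anchor[idx] = vid
            if parent_vertex is not None:
                self._link_to_parent(idx, parent_vertex, vid)
            if children:
                raise ValueError("oracle models sialic acid as a terminal residue")
            return
        ids = {a: f"{idx}:{a}" for a in ("O5", "C1", "C2", "C3", "C4", "C5")}
        self.vertices[ids["O5"]] = _c(O=1)
        self.vertices[ids["C1"]] = _c(C=1, H=1)
        self.anchor[idx] = ids["C1"]
        for pos in (2, 3, 4):
            v = _c(C=1, H=1)
            if pos == 2 and cls == "HexNAc":
                # N-acetyl: NH-C(=O)-CH3, N-methylated under permethylation
                v += _c(N=1, C=3, H=6, O=1) if self.perm else _c(N=1, C=2, H=4, O=1)
            elif pos in children:
                pass  # glycosidic O becomes its own vertex below
            elif pos in self.topo.table[node.name].hydroxyl_positions:
                v += self._oxy()
            self.vertices[ids[f"C{pos}"]] = v
        c5 = _c(C=1, H=1)
        if cls == "Fuc":
            c5 += _c(C=1, H=3)  # 6-deoxy methyl
        else:
            c5 += _c(C=1, H=2)  # C6H2
            if 6 in children:
                pass
            else:
                c5 += self._oxy()
        self.vertices[ids["C5"]] = c5
        ring = ["O5", "C1", "C2", "C3", "C4", "C5"]
        for bond in range(6):
            a, b = ring[bond], ring[(bond + 1) % 6]
            self.ring_bond[(idx, bond)] = self._add_edge(ids[a], ids[b])
        if parent_vertex is not None:
            self._link_to_parent(idx, parent_vertex, ids["C1"])
        for pos, child in children.items():
            carbon = ids["C5"] if pos == 6 else ids[f"C{pos}"]
            self._build(child, carbon)

    def _link_to_parent(self, child_idx: int, parent_vertex: str, child_anchor: str):
        ovid = f"glyco:{child_idx}"
        self.vertices[ovid] = _c(O=1)
        self._add_edge(parent_vertex, ovid)
        self.glyco_bond[child_idx] = self._add_edge(ovid, child_anchor)

    # -- fragment mass computation ---------------------------------------

    def total_mass(self) -> float:
        return sum(fmass(v) for v in self.vertices.values())

    def _component(self, start: str, removed: set[frozenset]) -> float:
        seen, stack = {start}, [start]
        while stack:
            u = stack.pop()
            for e in self.edges:
                if e in removed or u not in e:
                    continue
                (v,) = e - {u}
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        return sum(fmass(self.vertices[v]) for v in seen)

    def fragment_mz(self, kind: str, child_idx: int | None = None,
                    ring: tuple[int, tuple[int, int]] | None = None,
                    benzyl_loss: bool = False) -> float:
        """m/z (charge 1) of one fragment described structurally.

        kind: B/C/Y/Z need ``child_idx`` (the subtree detached at its
        glycosidic bond); X/A need ``ring`` = (node_idx, (i, j)); the
        combined reducing ions Y+X / Z+X and the non-reducing A-Y / A-Z need
        both.
        """
        if child_idx == 0 and ring is None:
            # aglycone bond of the root: the aglycone atoms are folded into
            # the root C1 vertex, so compute algebraically
            agl = {"benzyl": _c(O=1, C=7, H=7),
                   "free_reducing": self._oxy(),
                   "serine_threonine": _c()}[self.topo.root_aglycone]
            sugar = self.total_mass() - fmass(agl)
            mz = {"B": sugar, "C": sugar + H2O,
                  "Y": fmass(agl) + AM["H"] + PROTON_,
                  "Z": fmass(agl) + AM["H"] + PROTON_ - H2O}[kind]
            if benzyl_loss:
                mz -= H2O + 7 * AM["C"] + 6 * AM["H"]
            return mz
        removed: set[frozenset] = set()
        if child_idx is not None:
            removed.add(self.glyco_bond[child_idx])
        if ring is not None:
            node_idx, (i, j) = ring
            removed.add(self.ring_bond[(node_idx, i)])
            removed.add(self.ring_bond[(node_idx, j)])
        root_side = self._component(self.anchor[0], removed)
        if kind == "B":
            mz = self._component(self.anchor[child_idx], removed)  # oxocarbenium
        elif kind == "C":
            mz = self._component(self.anchor[child_idx], removed) + H2O
        elif kind == "X":
            mz = root_side + PROTON_  # ring cleavage transfers no hydrogen
        elif kind in ("Y", "YX"):
            mz = root_side + AM["H"] + PROTON_  # severed glycosidic O gains H
        elif kind in ("Z", "ZX"):
            mz = root_side + AM["H"] + PROTON_ - H2O
        elif kind == "A":
            mz = self.total_mass() - root_side + PROTON_
        elif kind in ("AY", "AZ"):
            piece = (self.total_mass() - root_side
                     - self._component(self.anchor[child_idx], removed))
            mz = piece + AM["H"] + PROTON_  # Y-type loss inside the A piece
            if kind == "AZ":
                mz -= H2O
        else:
            raise ValueError(f"unknown kind {kind!r}")
        if benzyl_loss:
            mz -= H2O + 7 * AM["C"] + 6 * AM["H"]  # benzyl alcohol C7H8O
        return mz
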