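"""Molecular graphs parsed from MDL molfiles (V2000 connection tables).

A compound is represented as a heavy-atom graph: atoms carry their element
symbol, a chirality (stereo parity) code, and flags for the two kinds of
structural ambiguity found in KEGG-style molfiles — R-group placeholder
atoms (``R``, ``R#``, ``R1`` ...) standing for an unspecified substituent,
and repeat-unit markers (``*``) standing for a repeated subunit whose
structure is not spelled out.  Explicit hydrogens present in the molfile are
kept; implicit hydrogens are never synthesized, so parsing is deterministic
and molfile-faithful.  Charge/isotope property lines are read and ignored.

V3000 files, SMILES and 3-D geometry are out of scope.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from pathlib import Path
__all__ = [
    "Atom",
    "Bond",
    "MolecularGraph",
    "MolfileParseError",
    "parse_molfile",
    "write_molfile",
    "read_molfile_dir",
    "count_non_hydrogen_atoms",
    "detect_ambiguity",
    "substitute_ambiguous",
]

_R_GROUP_RE = re.compile(r"^R(#|\d*)$")

#: bond order codes accepted from the bond block (1,2,3 plus 4 = aromatic/other)
VALID_BOND_ORDERS = (1, 2, 3, 4)


class MolfileParseError(ValueError):
    """Raised when a molfile cannot be interpreted; names the offending line."""


@dataclass(frozen=True)
class Atom:
    index: int
    element: str
    chirality: int = 0
    is_r_group: bool = False
    is_repeat_marker: bool = False

    def __post_init__(self) -> None:
        if not self.element:
            raise ValueError(f"atom {self.index}: element symbol is empty")
        if self.index < 0:
            raise ValueError("atom index must be >= 0")
        if self.chirality < 0:
            raise ValueError(f"atom {self.index}: chirality must be >= 0")
        if self.is_r_group and self.is_repeat_marker:
            raise ValueError(
                f"atom {self.index}: R-group and repeat-marker flags are mutually exclusive"
            )


@dataclass(frozen=True)
class Bond:
    """Undirected bond; endpoints are stored sorted."""

    a: int
    b: int
    order: int = 1
    stereo: int = 0

    def __post_init__(self) -> None:
        if self.a == self.b:
            raise ValueError(f"bond endpoints must be distinct, got ({self.a}, {self.b})")
        if self.a > self.b:
            lo, hi = self.b, self.a
            object.__setattr__(self, "a", lo)
            object.__setattr__(self, "b", hi)

    @property
    def endpoints(self) -> tuple[int, int]:
        return (self.a, self.b) if self.a < self.b else (self.b, self.a)


@dataclass
class MolecularGraph:
    """Heavy-atom molecular graph (may be disconnected, e.g. salts)."""

    atoms: list[Atom]
    bonds: list[Bond]
    source_id: str = ""

    def __post_init__(self) -> None:
        n = len(self.atoms)
        seen: set[tuple[int, int]] = set()
        for b in self.bonds:
            lo, hi = b.endpoints
            if not (0 <= lo < n and 0 <= hi < n):
                raise ValueError(
                    f"{self.source_id or 'graph'}: bond ({lo}, {hi}) references a "
                    f"missing atom (atom count {n})"
                )
            if (lo, hi) in seen:
                raise ValueError(
                    f"{self.source_id or 'graph'}: duplicate bond between atoms {lo} and {hi}"
                )
            seen.add((lo, hi))

    def adjacency(self) -> list[list[tuple[int, Bond]]]:
        """Per-atom list of (neighbor index, bond)."""
        adj: list[list[tuple[int, Bond]]] = [[] for _ in self.atoms]
        for b in self.bonds:
            lo, hi = b.endpoints
            adj[lo].append((hi, b))
            adj[hi].append((lo, b))
        return adj

    def __len__(self) -> int:
        return len(self.atoms)


def _classify_symbol(symbol: str) -> tuple[bool, bool]:
    """(is_r_group, is_repeat_marker) for a molfile atom symbol."""
    if symbol == "*":
        return False, True
    if _R_GROUP_RE.match(symbol):
        return True, False
    return False, False


def parse_molfile(text: str, source_id: str = "") -> MolecularGraph:
    """Parse a V2000 molfile string into a :class:`MolecularGraph`.

    The three header lines are skipped; the counts line, atom block and bond
    block are read by their fixed V2000 columns (with a whitespace-split
    fallback for loosely formatted files).  Element symbols are preserved
    verbatim apart from surrounding whitespace.
    """
    lines = text.splitlines()
    if len(lines) < 4:
        raise MolfileParseError(
            f"{source_id or 'molfile'}: truncated file, no counts line (line 4)"
        )
    counts = lines[3]
    try:
        n_atoms = int(counts[0:3])
        n_bonds = int(counts[3:6])
    except (ValueError, IndexError) as exc:
        raise MolfileParseError(
            f"{source_id or 'molfile'}: malformed counts line (line 4): {counts!r}"
        ) from exc
    if n_atoms < 0 or n_bonds < 0:
        raise MolfileParseError(
            f"{source_id or 'molfile'}: negative counts on line 4: {counts!r}"
        )
    if len(lines) < 4 + n_atoms + n_bonds:
        raise MolfileParseError(
            f"{source_id or 'molfile'}: truncated blocks; counts line promises "
            f"{n_atoms} atoms and {n_bonds} bonds but only "
            f"{len(lines) - 4} lines follow line 4"
        )

    atoms: list[Atom] = []
    for i in range(n_atoms):
        ln = lines[4 + i]
        symbol = ln[31:34].strip() if len(ln) > 31 else ""
        parity = 0
        if symbol:
            if len(ln) >= 42:
                parity_txt = ln[39:42].strip()
                parity = int(parity_txt) if parity_txt else 0
        else:
            parts = ln.split()
            if len(parts) < 4:
                raise MolfileParseError(
                    f"{source_id or 'molfile'}: malformed atom line {5 + i}: {ln!r}"
                )
            symbol = parts[3]
            if len(parts) >= 7:
                try:
                    parity = int(parts[6])
                except ValueError:
                    parity = 0
        is_r, is_rep = _classify_symbol(symbol)
        atoms.append(
            Atom(
                index=i,
                element=symbol,
                chirality=max(parity, 0),
                is_r_group=is_r,
                is_repeat_marker=is_rep,
            )
        )

    bonds: list[Bond] = []
    for i in range(n_bonds):
        ln = lines[4 + n_atoms + i]
        try:
            if len(ln) >= 9:
                a = int(ln[0:3])
                b = int(ln[3:6])
                order = int(ln[6:9])
                stereo_txt = ln[9:12].strip() if len(ln) >= 10 else ""
                stereo = int(stereo_txt) if stereo_txt else 0
            else:
                parts = ln.split()
                a, b, order = int(parts[0]), int(parts[1]), int(parts[2])
                stereo = int(parts[3]) if len(parts) > 3 else 0
        except (ValueError, IndexError) as exc:
            raise MolfileParseError(
                f"{source_id or 'molfile'}: malformed bond line {5 + n_atoms + i}: {ln!r}"
            ) from exc
        if order not in VALID_BOND_ORDERS:
            raise MolfileParseError(
                f"{source_id or 'molfile'}: unknown bond order code {order} on "
                f"line {5 + n_atoms + i} (accepted: {VALID_BOND_ORDERS})"
            )
        if not (1 <= a <= n_atoms and 1 <= b <= n_atoms):
            raise MolfileParseError(
                f"{source_id or 'molfile'}: bond line {5 + n_atoms + i} references "
                f"atom index outside 1..{n_atoms}: ({a}, {b})"
            )
        bonds.append(Bond(a=min(a, b) - 1, b=max(a, b) - 1, order=order, stereo=stereo))

    return MolecularGraph(atoms=atoms, bonds=bonds, source_id=source_id)


def write_molfile(g: MolecularGraph, name: str | None = None) -> str:
    """Serialize a graph to a V2000 molfile string (planar zero coordinates).

    ``parse_molfile(write_molfile(g))`` round-trips atom count, bond count,
    element symbols, chirality codes, marker flags, bond orders and stereo.
    """
    out: list[str] = [name if name is not None else g.source_id, "  metpath", ""]
    out.append(f"{len(g.atoms):3d}{len(g.bonds):3d}  0  0  0  0  0  0  0  0999 V2000")
    for a in g.atoms:
        out.append(
            f"{0.0:10.4f}{0.0:10.4f}{0.0:10.4f} {a.element:<3} 0  0"
            f"{a.chirality:3d}  0  0  0  0  0  0  0  0  0"
        )
    for b in g.bonds:
        lo, hi = b.endpoints
        out.append(f"{lo + 1:3d}{hi + 1:3d}{b.order:3d}{b.stereo:3d}")
    out.append("M  END")
    return "\n".join(out) + "\n"


def read_molfile_dir(path: str | Path, pattern: str = "*.mol") -> dict[str, MolecularGraph]:
    """Read a directory of molfiles keyed by filename stem (= compound ID)."""
    path = Path(path)
    graphs: dict[str, MolecularGraph] = {}
    for f in sorted(path.glob(pattern)):
        graphs[f.stem] = parse_molfile(f.read_text(), source_id=f.stem)
    return graphs


def count_non_hydrogen_atoms(g: MolecularGraph) -> int:
    """Number of atoms whose element is not hydrogen.

    R-group and repeat-marker atoms count as non-hydrogen: they stand for
    real (if unspecified) heavy structure.
    """
    return sum(1 for a in g.atoms if a.element != "H")


def detect_ambiguity(g: MolecularGraph) -> tuple[bool, bool]:
    """(has_r_group, has_repeat_marker) over all atoms of the graph."""
    has_r = any(a.is_r_group for a in g.atoms)
    has_rep = any(a.is_repeat_marker for a in g.atoms)
    return has_r, has_rep


def substitute_ambiguous(g: MolecularGraph) -> MolecularGraph:
    """Replace every R-group and repeat-marker atom's element with carbon.

    The placeholder stands for obfuscated structure that is most often
    attached through carbon, so substituting C keeps the known chemistry in
    the features rather than exposing models to a bogus "element".  The
    ambiguity flags are retained (they drive the ambiguous/non-ambiguous
    subset assignment later); all other fields are unchanged.  Idempotent.
    """
    atoms = [
        replace(a, element="C") if (a.is_r_group or a.is_repeat_marker) else a
        for a in g.atoms
    ]
    return MolecularGraph(atoms=atoms, bonds=list(g.bonds), source_id=g.source_id)
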