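"""Readers and writers for the external formats the pipeline touches.

Formats: FASTA multiple alignments, PHYLIP-style square similarity matrices,
PDB coordinate files (single chain), Newick trees with reliability labels,
and YAML family configurations.

Conventions fixed here:

* alignment rows are uppercased; ``.`` gaps are normalized to ``-``; ``X``
  is kept but treated as missing by downstream frequency counting;
* PDB residues are keyed by *author* numbering plus insertion code — the
  catalytic-residue labels used throughout (Glu67, Ser120, ...) are author
  numbers, never serial renumbering;
* the matrix dialect is PHYLIP square with the full matrix (no
  lower-triangle variant).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import dendropy
import numpy as np
import yaml
from Bio import SeqIO
from Bio.PDB import PDBParser

from .errors import (
    AlignmentFormatError,
    ChainNotFoundError,
    ConfigError,
    EmptyInputError,
    MatrixFormatError,
    StructureFormatError,
)

logger = logging.getLogger(__name__)

#: one-letter amino-acid alphabet used for all frequency vectors
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(ALPHABET)}

GAP = "-"
MISSING = "X"

#: residue-name constraints for the four catalytic roles:
#: A = general-acid Glu, B = general-base Glu/Asp, C = water-positioning
#: Ser/Thr, D = accessory Gln of the hairpin motif.
ROLE_RESIDUES = {
    "A": {"GLU"},
    "B": {"GLU", "ASP"},
    "C": {"SER", "THR"},
    "D": {"GLN"},
}


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------

@dataclass
class AlignedFamily:
    """A gapped multiple alignment for one GH family."""

    family_id: str
    sequence_ids: list[str]
    rows: list[str]
    representative_id: str

    def __post_init__(self) -> None:
        if not self.rows:
            raise EmptyInputError(f"alignment {self.family_id!r} has no rows")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise AlignmentFormatError(
                f"alignment {self.family_id!r} is ragged: row lengths {sorted(lengths)}"
            )
        if len(self.sequence_ids) != len(self.rows):
            raise AlignmentFormatError("sequence_ids and rows differ in count")
        if len(set(self.sequence_ids)) != len(self.sequence_ids):
            raise AlignmentFormatError("duplicate sequence identifiers")
        if self.representative_id not in self.sequence_ids:
            raise AlignmentFormatError(
                f"representative {self.representative_id!r} not among sequences"
            )

    @property
    def n_sequences(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    def row(self, sequence_id: str) -> str:
        return self.rows[self.sequence_ids.index(sequence_id)]

    def slice_columns(self, start: int, stop: int) -> "AlignedFamily":
        """Column block [start, stop) as a new alignment (0-based, half-open)."""
        return AlignedFamily(
            family_id=self.family_id,
            sequence_ids=list(self.sequence_ids),
            rows=[r[start:stop] for r in self.rows],
            representative_id=self.representative_id,
        )


def _normalize_row(seq: str) -> str:
    return seq.upper().replace(".", GAP)


def read_fasta_alignment(
    path: str | Path,
    family_id: str | None = None,
    representative_id: str | None = None,
) -> AlignedFamily:
    """Read an aligned FASTA file into an :class:`AlignedFamily`.

    Record order is preserved; the representative defaults to the first
    record. Lowercase residues are uppercased and ``.`` gaps become ``-``.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise EmptyInputError(f"no FASTA records in {path}")
    ids = [r.id for r in records]
    rows = [_normalize_row(str(r.seq)) for r in records]
    fam = family_id if family_id is not None else path.stem
    rep = representative_id if representative_id is not None else ids[0]
    return AlignedFamily(family_id=fam, sequence_ids=ids, rows=rows,
                         representative_id=rep)


def write_fasta_alignment(family: AlignedFamily, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, row in zip(family.sequence_ids, family.rows):
            fh.write(f">{sid}\n{row}\n")


# ---------------------------------------------------------------------------
# square matrices
# ---------------------------------------------------------------------------

def read_square_matrix(path: str | Path, symmetry_warn: float = 0.5):
    """Read a PHYLIP square matrix into a :class:`~ghmotif.cluster.SimilarityMatrix`.

    Format: first line the taxon count ``n``; then ``n`` lines of
    ``label v1 ... vn``. The matrix is symmetrized by averaging
    ``(Sij + Sji) / 2``; asymmetries beyond ``symmetry_warn`` are logged.
    """
    from .cluster import SimilarityMatrix

    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not lines:
        raise EmptyInputError(f"empty matrix file {path}")
    try:
        n = int(lines[0].split()[0])
    except ValueError as exc:
        raise MatrixFormatError(f"first line of {path} must be the taxon count") from exc
    if len(lines) != n + 1:
        raise MatrixFormatError(
            f"{path}: expected {n} matrix rows, found {len(lines) - 1}"
        )
    labels: list[str] = []
    values = np.empty((n, n), dtype=float)
    for i, line in enumerate(lines[1:]):
        parts = line.split()
        if len(parts) != n + 1:
            raise MatrixFormatError(
                f"{path}: row {i + 1} has {len(parts) - 1} values, expected {n}"
            )
        labels.append(parts[0])
        values[i] = [float(v) for v in parts[1:]]
    if len(set(labels)) != n:
        raise MatrixFormatError(f"{path}: duplicate labels")
    asym = float(np.max(np.abs(values - values.T))) if n else 0.0
    if asym > symmetry_warn:
        logger.warning("matrix %s asymmetric by up to %.3f; averaging", path, asym)
    values = (values + values.T) / 2.0
    return SimilarityMatrix(labels=labels, values=values)


def write_square_matrix(matrix, path: str | Path, fmt: str = "%.10g") -> None:
    """Write a labelled square matrix in the PHYLIP square dialect."""
    with open(path, "w") as fh:
        fh.write(f"{len(matrix.labels)}\n")
        for label, row in zip(matrix.labels, matrix.values):
            fh.write(label + " " + " ".join(fmt % v for v in row) + "\n")


# ---------------------------------------------------------------------------
# structures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ResidueRecord:
    """One residue of a single-chain structure, author numbering."""

    number: int
    icode: str
    name: str
    atoms: Mapping[str, np.ndarray]

    @property
    def key(self) -> tuple[int, str]:
        return (self.number, self.icode)


@dataclass
class StructureModel:
    """Atomic coordinates of one chain, in file order."""

    structure_id: str
    chain_id: str
    residues: list[ResidueRecord]

    def __post_init__(self) -> None:
        keys = [r.key for r in self.residues]
        if len(set(keys)) != len(keys):
            raise StructureFormatError(
                f"{self.structure_id}: duplicate residue keys in chain {self.chain_id}"
            )
        for r in self.residues:
            for name, xyz in r.atoms.items():
                if not np.all(np.isfinite(xyz)):
                    raise StructureFormatError(
                        f"{self.structure_id}: non-finite coordinates at "
                        f"residue {r.number}{r.icode.strip()} atom {name}"
                    )

    def residue(self, number: int, icode: str = " ") -> ResidueRecord:
        for r in self.residues:
            if r.number == number and r.icode == icode:
                return r
        raise KeyError(f"residue {number}{icode.strip()} not in chain {self.chain_id}")

    def coord(self, number: int, atom: str, icode: str = " ") -> np.ndarray:
        res = self.residue(number, icode)
        try:
            return res.atoms[atom]
        except KeyError as exc:
            raise KeyError(
                f"atom {atom} absent from residue {res.name}{number}"
            ) from exc


def read_pdb_subset(path: str | Path, chain: str | None = None) -> StructureModel:
    """Parse ATOM records of one chain from a PDB file.

    When ``chain`` is None the first chain encountered is used (crystal
    structures of this superfamily conventionally put the biological chain
    first, usually named A). Alternate locations are resolved by keeping the
    blank or 'A' conformer; HETATM records are ignored.
    """
    path = Path(path)
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(path.stem, str(path))
    try:
        model = next(structure.get_models())
    except StopIteration:
        raise EmptyInputError(f"no coordinates in {path}")
    chains = [c.id for c in model]
    if not chains:
        raise EmptyInputError(f"no chains in {path}")
    if chain is None:
        chain = chains[0]
    if chain not in chains:
        raise ChainNotFoundError(
            f"chain {chain!r} not in {path.name}; available: {', '.join(chains)}"
        )
    residues: list[ResidueRecord] = []
    for res in model[chain]:
        hetfield, resseq, icode = res.id
        if hetfield != " ":
            continue  # HETATM / water
        atoms: dict[str, np.ndarray] = {}
        for atom in res:
            if atom.is_disordered():
                alts = atom.disordered_get_id_list()
                pick = "A" if "A" in alts else alts[0]
                if pick not in (" ", "A"):
                    logger.warning(
                        "%s %s%d %s: no blank/'A' altloc, keeping %r",
                        path.stem, res.resname, resseq, atom.get_id(), pick,
                    )
                chosen = atom.disordered_get(pick)
            else:
                chosen = atom
            atoms[atom.get_id()] = np.asarray(chosen.coord, dtype=float)
        residues.append(
            ResidueRecord(number=resseq, icode=icode, name=res.resname, atoms=atoms)
        )
    return StructureModel(structure_id=path.stem, chain_id=chain, residues=residues)


# ---------------------------------------------------------------------------
# Newick trees
# ---------------------------------------------------------------------------

def _newick_node(node, parent_height: float | None) -> str:
    from .cluster import ClusterNode  # noqa: F401  (type reference only)

    if node.is_leaf:
        body = node.label
    else:
        body = "(" + ",".join(
            _newick_node(c, node.height) for c in node.children
        ) + ")"
        if node.reliability is not None:
            body += "100" if node.reliability else "0"
    if parent_height is not None:
        length = parent_height - node.height
        body += ":%.10g" % length
    return body


def write_newick(tree, path: str | Path) -> None:
    """Serialize a ClusterTree; reliability flags become internal node labels.

    Branch lengths are height differences, so leaf-to-root path lengths equal
    the root height (the tree is ultrametric). Reliable internal nodes are
    labelled ``100``, unreliable ones ``0``; unassessed nodes carry no label.
    """
    if tree is None or getattr(tree, "root", None) is None:
        raise EmptyInputError("cannot write an empty tree")
    with open(path, "w") as fh:
        fh.write(_newick_node(tree.root, None) + ";\n")


def read_newick(path: str | Path):
    """Parse a Newick file written by :func:`write_newick` back to a ClusterTree."""
    from .cluster import ClusterNode, ClusterTree

    dtree = dendropy.Tree.get(path=str(path), schema="newick",
                              preserve_underscores=True)

    def depth_of(node) -> float:
        d = 0.0
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        return d

    max_depth = max(depth_of(leaf) for leaf in dtree.leaf_node_iter())

    def convert(dnode) -> "ClusterNode":
        height = max_depth - depth_of(dnode)
        if dnode.is_leaf():
            label = dnode.taxon.label if dnode.taxon else dnode.label
            return ClusterNode(height=0.0, children=(), label=label,
                               clade=frozenset([label]))
        children = tuple(convert(c) for c in dnode.child_nodes())
        clade = frozenset().union(*(c.clade for c in children))
        rel = None
        if dnode.label is not None:
            rel = dnode.label.strip() == "100"
        return ClusterNode(height=height, children=children, label=None,
                           clade=clade, reliability=rel)

    root = convert(dtree.seed_node)
    return ClusterTree(root=root)


# ---------------------------------------------------------------------------
# family configuration
# ---------------------------------------------------------------------------

@dataclass
class FamilyConfig:
    """Per-family analysis configuration.

    ``roles`` maps the catalytic roles A–D to (author residue number,
    three-letter residue name); absent roles are simply omitted, matching
    the "/" convention of the active-site tables. ``representative_start``
    anchors alignment columns onto author numbering of the representative
    structure. Residue ranges are inclusive author-number pairs.
    """

    family_id: str
    representative: str
    chain: str | None = None
    representative_start: int = 1
    motif_range: tuple[int, int] | None = None
    hairpin_range: tuple[int, int] | None = None
    strand_ranges: tuple[tuple[int, int], tuple[int, int]] | None = None
    roles: dict[str, tuple[int, str]] = field(default_factory=dict)
    scoring_matrix: str | None = None  # accepted for provenance, unused by entropy

    def __post_init__(self) -> None:
        for role, (num, name) in self.roles.items():
            if role not in ROLE_RESIDUES:
                raise ConfigError(f"unknown role {role!r} (expected A-D)")
            if name.upper() not in ROLE_RESIDUES[role]:
                raise ConfigError(
                    f"role {role} must be one of {sorted(ROLE_RESIDUES[role])}, "
                    f"got {name!r}"
                )
            self.roles[role] = (int(num), name.upper())
        for rng in (self.motif_range, self.hairpin_range):
            if rng is not None and rng[0] > rng[1]:
                raise ConfigError(f"invalid range {rng}: start > end")


def read_family_config(path: str | Path) -> FamilyConfig:
    """Load a :class:`FamilyConfig` from YAML (or JSON, a YAML subset)."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: expected a mapping")
    roles = {
        role: (entry[0], entry[1])
        for role, entry in (raw.get("roles") or {}).items()
    }
    def _pair(key):
        v = raw.get(key)
        return None if v is None else (int(v[0]), int(v[1]))
    strands = raw.get("strand_ranges")
    if strands is not None:
        strands = tuple((int(a), int(b)) for a, b in strands)
    return FamilyConfig(
        family_id=raw["family_id"],
        representative=raw["representative"],
        chain=raw.get("chain"),
        representative_start=int(raw.get("representative_start", 1)),
        motif_range=_pair("motif_range"),
        hairpin_range=_pair("hairpin_range"),
        strand_ranges=strands,
        roles=roles,
        scoring_matrix=raw.get("scoring_matrix"),
    )
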