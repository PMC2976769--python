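"""Synthetic inputs with the statistical/geometric structure the analysis assumes.

Four generators, each a pure function of its spec plus seed:

* clustered similarity matrices — families of structures with high
  within-family and low between-family similarity plus Gaussian noise,
  emulating a Dali-style Z-score matrix (real Z-scores in this
  superfamily span roughly 1–47);
* family alignments with a planted conserved motif block on a variable
  background, emulating hand-curated family alignments;
* peptide backbones built from prescribed (φ, ψ, ω) internal coordinates
  with standard peptide geometry (NeRF construction), including strand,
  type-I-turn and β-hairpin presets, plus explicitly placed side-chain
  pseudo-atoms for active-site tests;
* labelled sequence databases (planted motif instances in random flanks
  vs pure background) for profile-search benchmarking.

Every generator returns the ground truth needed to score downstream
stages, so no stage ever re-derives its own truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .cluster import SimilarityMatrix
from .errors import GHMotifError
from .io import ALPHABET, AlignedFamily, ResidueRecord, StructureModel

# ---------------------------------------------------------------------------
# similarity matrices
# ---------------------------------------------------------------------------


@dataclass
class ClusterSpec:
    """Planted-partition similarity matrix.

    Defaults emulate the observed regime: within-family Z-scores well above
    between-family ones, self-scores highest of all.
    """

    family_sizes: tuple[int, ...] = (4, 4, 4)
    within_mean: float = 35.0
    within_sd: float = 2.0
    between_mean: float = 5.0
    between_sd: float = 2.0
    self_mean: float = 45.0
    self_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.within_mean <= self.between_mean:
            raise GHMotifError("within-family mean must exceed between-family mean")


def generate_similarity_matrix(
    spec: ClusterSpec,
) -> tuple[SimilarityMatrix, dict[str, str]]:
    """Symmetric planted-cluster similarity matrix plus the truth partition."""
    rng = np.random.default_rng(spec.seed)
    labels: list[str] = []
    family_of: dict[str, str] = {}
    for f, size in enumerate(spec.family_sizes):
        fam = f"F{f + 1}"
        for k in range(size):
            label = f"{fam}_{k + 1}"
            labels.append(label)
            family_of[label] = fam
    n = len(labels)
    S = np.zeros((n, n))
    for i in range(n):
        S[i, i] = max(rng.normal(spec.self_mean, spec.self_sd), 0.0)
    for i in range(n):
        for j in range(i + 1, n):
            same = family_of[labels[i]] == family_of[labels[j]]
            mu, sd = (
                (spec.within_mean, spec.within_sd)
                if same
                else (spec.between_mean, spec.between_sd)
            )
            v = max(rng.normal(mu, sd), 0.0)
            v = min(v, S[i, i], S[j, j])  # keep self-scores maximal
            S[i, j] = S[j, i] = v
    return SimilarityMatrix(labels=labels, values=S), family_of


def generate_ultrametric_matrix(
    n: int, seed: int = 0, height_range: tuple[float, float] = (1.0, 50.0)
):
    """Random ultrametric distance matrix with its generating tree heights.

    Built by recursively splitting the taxon set with strictly decreasing
    merge heights, so average-linkage clustering must reproduce the
    cophenetic matrix exactly. Returns a
    :class:`~ghmotif.cluster.DistanceMatrix`.
    """
    from .cluster import DistanceMatrix

    rng = np.random.default_rng(seed)
    labels = [f"T{i:02d}" for i in range(n)]
    D = np.zeros((n, n))

    def split(indices: list[int], top: float) -> None:
        if len(indices) < 2:
            return
        # merge height strictly below the parent's: heights shrink down the tree
        height = top * rng.uniform(0.4, 0.95)
        k = int(rng.integers(1, len(indices)))
        left, right = indices[:k], indices[k:]
        for a in left:
            for b in right:
                D[a, b] = D[b, a] = 2.0 * height
        split(left, height)
        split(right, height)

    order = list(rng.permutation(n))
    split(order, height_range[1])
    return DistanceMatrix(labels=labels, values=D)


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------


@dataclass
class MsaSpec:
    """Alignment with a planted high-conservation block.

    Defaults emulate a mid-sized family: 40 sequences, 120 columns,
    a 13-column motif (columns 40–52 inclusive) emitting its consensus with
    probability 0.95 per sequence, uniform background (5% column identity)
    and sparse gaps outside the motif.
    """

    n_sequences: int = 40
    length: int = 120
    motif_start: int = 40           # 0-based, inclusive
    motif_end: int = 52             # inclusive
    p_conserved: float = 0.95
    gap_probability: float = 0.02
    background: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_conserved <= 1.0):
            raise GHMotifError("p_conserved must be in [0, 1]")
        if not (0 <= self.motif_start <= self.motif_end < self.length):
            raise GHMotifError("motif range outside alignment")


@dataclass
class MsaTruth:
    motif_start: int
    motif_end: int
    consensus: str


def generate_msa(spec: MsaSpec) -> tuple[AlignedFamily, MsaTruth]:
    """Planted-motif alignment plus its truth record."""
    rng = np.random.default_rng(spec.seed)
    bg = (
        np.asarray(spec.background, dtype=float)
        if spec.background is not None
        else np.full(len(ALPHABET), 1.0 / len(ALPHABET))
    )
    bg = bg / bg.sum()
    letters = np.array(list(ALPHABET))
    consensus = "".join(
        rng.choice(letters, size=spec.motif_end - spec.motif_start + 1, p=bg)
    )
    rows = []
    in_motif = lambda c: spec.motif_start <= c <= spec.motif_end
    for _ in range(spec.n_sequences):
        chars = []
        for c in range(spec.length):
            if in_motif(c):
                if rng.random() < spec.p_conserved:
                    chars.append(consensus[c - spec.motif_start])
                else:
                    chars.append(str(rng.choice(letters, p=bg)))
            elif rng.random() < spec.gap_probability:
                chars.append("-")
            else:
                chars.append(str(rng.choice(letters, p=bg)))
        rows.append("".join(chars))
    ids = [f"seq{k + 1:03d}" for k in range(spec.n_sequences)]
    family = AlignedFamily(
        family_id="synthetic",
        sequence_ids=ids,
        rows=rows,
        representative_id=ids[0],
    )
    return family, MsaTruth(spec.motif_start, spec.motif_end, consensus)


# ---------------------------------------------------------------------------
# peptide geometry
# ---------------------------------------------------------------------------

# standard peptide internal coordinates (Å, degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8

#: ideal antiparallel β-strand backbone
STRAND_PHI_PSI = (-120.0, 130.0)

#: canonical central dihedrals of a type I β-turn (residues i+1, i+2)
TYPE_I_CENTRAL = ((-60.0, -30.0), (-90.0, 0.0))


@dataclass
class GeometrySpec:
    """Backbone build recipe: one (φ, ψ, ω) triple per residue.

    φ of the first residue and ψ/ω of the last are not used by the
    construction but are kept so torsion round trips are exact where
    defined. ``extra_atoms`` places side-chain pseudo-atoms by explicit
    coordinates, keyed by residue number then atom name.
    """

    torsions: list[tuple[float, float, float]]
    residue_names: list[str] | None = None
    start_number: int = 1
    extra_atoms: dict[int, dict[str, tuple[float, float, float]]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        if len(self.torsions) < 2:
            raise GHMotifError("a peptide needs at least 2 residues")
        if self.residue_names is not None and len(self.residue_names) != len(
            self.torsions
        ):
            raise GHMotifError("one residue name per torsion triple required")


def place_atom(
    a: np.ndarray, b: np.ndarray, c: np.ndarray,
    bond: float, angle: float, torsion: float,
) -> np.ndarray:
    """Natural-extension (NeRF) placement of atom d from frame a-b-c.

    Returns d with |c-d| = bond, angle(b, c, d) = ``angle`` and
    dihedral(a, b, c, d) = ``torsion`` (degrees).
    """
    ang = math.radians(angle)
    tor = -math.radians(torsion)  # sign chosen so dihedral(a, b, c, d) == +torsion
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * math.cos(ang),
            bond * math.cos(tor) * math.sin(ang),
            bond * math.sin(tor) * math.sin(ang),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def generate_peptide(spec: GeometrySpec) -> StructureModel:
    """Build backbone coordinates (N, CA, C, O) from internal coordinates."""
    n_res = len(spec.torsions)
    names = spec.residue_names or ["ALA"] * n_res
    N = [None] * n_res
    CA = [None] * n_res
    C = [None] * n_res
    O = [None] * n_res

    N[0] = np.zeros(3)
    CA[0] = np.array([BOND_N_CA, 0.0, 0.0])
    # virtual previous atom fixes the first N-CA-C plane
    virtual = np.array([0.0, -1.0, 0.0])
    C[0] = place_atom(virtual, N[0], CA[0], BOND_CA_C, ANGLE_N_CA_C, 0.0)

    for i in range(n_res - 1):
        _, psi_i, _ = spec.torsions[i]
        _, _, omega_next = spec.torsions[i + 1]
        phi_next = spec.torsions[i + 1][0]
        N[i + 1] = place_atom(N[i], CA[i], C[i], BOND_C_N, ANGLE_CA_C_N, psi_i)
        CA[i + 1] = place_atom(CA[i], C[i], N[i + 1], BOND_N_CA, ANGLE_C_N_CA,
                               omega_next)
        C[i + 1] = place_atom(C[i], N[i + 1], CA[i + 1], BOND_CA_C, ANGLE_N_CA_C,
                              phi_next)
    for i in range(n_res):
        psi_i = spec.torsions[i][1]
        O[i] = place_atom(N[i], CA[i], C[i], BOND_C_O, ANGLE_CA_C_O,
                          psi_i + 180.0)

    residues = []
    for i in range(n_res):
        number = spec.start_number + i
        atoms = {"N": N[i], "CA": CA[i], "C": C[i], "O": O[i]}
        for name, xyz in spec.extra_atoms.get(number, {}).items():
            atoms[name] = np.asarray(xyz, dtype=float)
        residues.append(
            ResidueRecord(number=number, icode=" ", name=names[i], atoms=atoms)
        )
    return StructureModel(structure_id="synthetic", chain_id="A", residues=residues)


def strand_spec(n_residues: int, start_number: int = 1) -> GeometrySpec:
    """Ideal extended β-strand of ``n_residues``."""
    phi, psi = STRAND_PHI_PSI
    return GeometrySpec(
        torsions=[(phi, psi, 180.0)] * n_residues, start_number=start_number
    )


def type1_turn_spec(start_number: int = 1) -> GeometrySpec:
    """Six residues: extended flanks around a canonical type I β-turn.

    The turn window is residues 2..5 of the built peptide (0-based indices
    1..4 into the residue list): the two central residues carry the
    canonical type I dihedrals.
    """
    phi_e, psi_e = STRAND_PHI_PSI
    (p1, s1), (p2, s2) = TYPE_I_CENTRAL
    torsions = [
        (phi_e, psi_e, 180.0),
        (phi_e, psi_e, 180.0),
        (p1, s1, 180.0),
        (p2, s2, 180.0),
        (phi_e, psi_e, 180.0),
        (phi_e, psi_e, 180.0),
    ]
    return GeometrySpec(torsions=torsions, start_number=start_number)


#: loop dihedrals of the hairpin presets, found once by constrained
#: optimisation of the built geometry (loop closure + antiparallel
#: cross-strand Cα pairing) with the canonical type I turn fixed at the
#: loop's two central residues; see docs/methods.md.
HAIRPIN_LOOP_4 = [
    (-172.4, -91.9, 180.0),
    (-60.0, -30.0, 180.0),
    (-90.0, 0.0, 180.0),
    (77.9, -63.6, 180.0),
]

HAIRPIN_LOOP_2 = [
    (72.7, 74.8, 180.0),
    (66.2, 30.1, 180.0),
]


def hairpin_spec(
    strand_length: int = 4, loop_length: int = 4, start_number: int = 1
) -> GeometrySpec:
    """β-hairpin preset: strand, loop, antiparallel strand.

    ``loop_length`` 4 gives the canonical 4:4 hairpin with a type I β-turn
    in the loop; 2 gives a tight 2:2 hairpin. The strand dihedrals are
    slightly relaxed from ideal so the two strands pair within 5.5 Å.
    """
    if loop_length == 4:
        loop = list(HAIRPIN_LOOP_4)
    elif loop_length == 2:
        loop = list(HAIRPIN_LOOP_2)
    else:
        raise GHMotifError("hairpin preset supports loop lengths 2 and 4")
    strand = [(-120.0, 125.0, 180.0)] * strand_length
    torsions = strand + loop + strand
    return GeometrySpec(torsions=torsions, start_number=start_number)


# ---------------------------------------------------------------------------
# sequence databases
# ---------------------------------------------------------------------------


@dataclass
class SequenceDbTruth:
    labels: dict[str, bool]
    motif_start: dict[str, int]     # planted 0-based start, positives only


def generate_sequence_db(
    consensus: str,
    n_positives: int = 50,
    n_negatives: int = 500,
    divergence: float = 0.1,
    flank_range: tuple[int, int] = (10, 40),
    background: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[dict[str, str], SequenceDbTruth]:
    """Labelled benchmark database for profile search.

    Positives embed the motif consensus, mutated per position with
    probability ``divergence``, inside random background flanks; negatives
    are pure background of comparable length.
    """
    if not (0.0 <= divergence <= 1.0):
        raise GHMotifError("divergence must be in [0, 1]")
    rng = np.random.default_rng(seed)
    bg = (
        np.asarray(background, dtype=float)
        if background is not None
        else np.full(len(ALPHABET), 1.0 / len(ALPHABET))
    )
    bg = bg / bg.sum()
    letters = np.array(list(ALPHABET))

    def background_run(k: int) -> str:
        return "".join(rng.choice(letters, size=k, p=bg))

    sequences: dict[str, str] = {}
    labels: dict[str, bool] = {}
    starts: dict[str, int] = {}
    for k in range(n_positives):
        sid = f"pos{k + 1:04d}"
        motif = []
        for a in consensus:
            if rng.random() < divergence:
                others = [b for b in ALPHABET if b != a]
                motif.append(str(rng.choice(others)))
            else:
                motif.append(a)
        left = int(rng.integers(flank_range[0], flank_range[1] + 1))
        right = int(rng.integers(flank_range[0], flank_range[1] + 1))
        sequences[sid] = background_run(left) + "".join(motif) + background_run(right)
        labels[sid] = True
        starts[sid] = left
    typical = len(consensus) + flank_range[0] + flank_range[1]
    for k in range(n_negatives):
        sid = f"neg{k + 1:04d}"
        sequences[sid] = background_run(typical)
        labels[sid] = False
    return sequences, SequenceDbTruth(labels=labels, motif_start=starts)
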