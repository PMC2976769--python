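"""Backbone geometry and active-site characterization.

Covers the structural side of the signature-motif analysis: backbone φ/ψ/ω
torsions (IUPAC sign convention, undefined across chain breaks), a coarse
partition of the Ramachandran plane into handed helical/extended classes,
β-turn typing against canonical central dihedrals, antiparallel hairpin
classing, and the catalytic-role distance matrix.

Role atom rule (matching the active-site table convention of the field):
distances between catalytic residues use side-chain oxygens for Asp
(OD1/OD2), Glu (OE1/OE2), Ser (OG) and Thr (OG1); for Gln only Cβ is used.
The reported pair distance is the minimum over the two atom sets.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import GHMotifError, StructureFormatError
from .io import FamilyConfig, ResidueRecord, StructureModel

logger = logging.getLogger(__name__)

#: maximum peptide-bond C–N distance; beyond this the chain is broken
CHAIN_BREAK = 2.5

#: side-chain atoms considered per residue type under the distance rule
ROLE_ATOMS = {
    "GLU": ("OE1", "OE2"),
    "ASP": ("OD1", "OD2"),
    "SER": ("OG",),
    "THR": ("OG1",),
    "GLN": ("CB",),
}

ROLE_PAIRS = [("A", "B"), ("A", "C"), ("B", "C"), ("A", "D"), ("B", "D")]


# ---------------------------------------------------------------------------
# torsions
# ---------------------------------------------------------------------------

def dihedral(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray, p4: np.ndarray) -> float:
    """Signed dihedral angle p1-p2-p3-p4 in degrees, in (-180, 180]."""
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    x = float(np.dot(n1, n2))
    y = float(np.dot(m, n2))
    ang = math.degrees(math.atan2(y, x))
    return 180.0 if ang == -180.0 else ang


def backbone_torsions(structure: StructureModel) -> pd.DataFrame:
    """φ/ψ/ω per residue (degrees); NaN at termini, breaks and missing atoms.

    φ(i) = C(i-1)-N(i)-CA(i)-C(i); ψ(i) = N(i)-CA(i)-C(i)-N(i+1);
    ω(i) = CA(i-1)-C(i-1)-N(i)-CA(i). Torsions spanning a peptide bond with
    C–N distance > 2.5 Å (a crystallographic gap) are left undefined.
    """
    res = structure.residues
    n = len(res)
    phi = np.full(n, np.nan)
    psi = np.full(n, np.nan)
    omega = np.full(n, np.nan)

    def atom(i: int, name: str) -> np.ndarray | None:
        return res[i].atoms.get(name)

    def bonded(i: int) -> bool:
        """Peptide bond between residue i and i+1 intact."""
        c, nn = atom(i, "C"), atom(i + 1, "N")
        if c is None or nn is None:
            return False
        return float(np.linalg.norm(nn - c)) <= CHAIN_BREAK

    for i in range(n):
        N, CA, C = atom(i, "N"), atom(i, "CA"), atom(i, "C")
        if N is None or CA is None or C is None:
            logger.warning(
                "%s: residue %s%d missing backbone atoms; torsions undefined",
                structure.structure_id, res[i].name, res[i].number,
            )
            continue
        if i > 0 and bonded(i - 1):
            Cprev = atom(i - 1, "C")
            phi[i] = dihedral(Cprev, N, CA, C)
            CAprev = atom(i - 1, "CA")
            if CAprev is not None:
                omega[i] = dihedral(CAprev, Cprev, N, CA)
        if i < n - 1 and bonded(i):
            phi_ok = atom(i + 1, "N") is not None
            if phi_ok:
                psi[i] = dihedral(N, CA, C, atom(i + 1, "N"))
    return pd.DataFrame(
        {
            "residue": [r.number for r in res],
            "icode": [r.icode for r in res],
            "name": [r.name for r in res],
            "phi": phi,
            "psi": psi,
            "omega": omega,
        }
    )


# ---------------------------------------------------------------------------
# conformation classes
# ---------------------------------------------------------------------------

LEFT_HANDED_HELICAL = "left-handed helical"
LEFT_HANDED_EXTENDED = "left-handed extended"
RIGHT_HANDED_HELICAL = "right-handed helical"
RIGHT_HANDED_EXTENDED = "right-handed extended"
UNCLASSIFIED = "unclassified"


def classify_conformation(phi: float, psi: float) -> str:
    """Coarse handed helical/extended class of a (φ, ψ) pair.

    Left-handed requires φ > 20°: helical for ψ ∈ [-45°, 90°), extended for
    ψ (mod 360°) ∈ [90°, 240°). Right-handed classes are the mirror images
    (φ < -20°). Everything else — including undefined angles — is
    unclassified. The boxes partition each half-plane; the exact bounds are
    a documented convention of this package.
    """
    if phi is None or psi is None or math.isnan(phi) or math.isnan(psi):
        return UNCLASSIFIED
    if phi > 20.0:
        cls = _left_handed_box(phi, psi)
        return cls if cls else UNCLASSIFIED
    if phi < -20.0:
        cls = _left_handed_box(-phi, -psi)
        if cls == LEFT_HANDED_HELICAL:
            return RIGHT_HANDED_HELICAL
        if cls == LEFT_HANDED_EXTENDED:
            return RIGHT_HANDED_EXTENDED
    return UNCLASSIFIED


def _left_handed_box(phi: float, psi: float) -> str | None:
    if phi <= 125.0 and -45.0 <= psi < 90.0:
        return LEFT_HANDED_HELICAL
    if 90.0 <= (psi % 360.0) < 240.0:
        return LEFT_HANDED_EXTENDED
    return None


# ---------------------------------------------------------------------------
# beta turns
# ---------------------------------------------------------------------------

#: canonical (φ_{i+1}, ψ_{i+1}, φ_{i+2}, ψ_{i+2}) of the named turn types
TURN_TYPES = {
    "I": (-60.0, -30.0, -90.0, 0.0),
    "I'": (60.0, 30.0, 90.0, 0.0),
    "II": (-60.0, 120.0, 80.0, 0.0),
    "II'": (60.0, -120.0, -80.0, 0.0),
}

TURN_CA_CUTOFF = 7.0


@dataclass
class TurnAssignment:
    start_index: int            # index into structure.residues of residue i
    start_residue: int          # author number of residue i
    turn_type: str              # I, I', II, II', IV
    ca_distance: float


def _angle_diff(a: float, b: float) -> float:
    d = (a - b) % 360.0
    return min(d, 360.0 - d)


def _matches_type(angles: Sequence[float], canon: Sequence[float],
                  tol: float = 30.0, tol_one: float = 45.0) -> bool:
    diffs = [_angle_diff(a, c) for a, c in zip(angles, canon)]
    if max(diffs) <= tol:
        return True
    over = [d for d in diffs if d > tol]
    return len(over) == 1 and over[0] <= tol_one


def _helix_run_mask(classes: Sequence[str], min_run: int = 4) -> np.ndarray:
    """Residues inside a continuous α-helix (≥ min_run helical in a row)."""
    mask = np.zeros(len(classes), dtype=bool)
    run_start = None
    for k, c in enumerate(list(classes) + [None]):
        if c == RIGHT_HANDED_HELICAL:
            if run_start is None:
                run_start = k
        else:
            if run_start is not None and k - run_start >= min_run:
                mask[run_start:k] = True
            run_start = None
    return mask


def assign_beta_turns(
    structure: StructureModel, torsions: pd.DataFrame | None = None
) -> list[TurnAssignment]:
    """Four-residue β-turns typed by central (φ, ψ) against canonical values.

    A window i..i+3 qualifies when Cα(i)–Cα(i+3) < 7 Å and its central
    residues are not interior to a continuous α-helix (a run of ≥ 4
    right-handed-helical residues). The central dihedrals are compared to the
    canonical type I/I'/II/II' values within ±30° (one angle may deviate up
    to ±45°); windows passing the distance gate but no named type are
    type IV.
    """
    if torsions is None:
        torsions = backbone_torsions(structure)
    res = structure.residues
    out: list[TurnAssignment] = []
    phi = torsions["phi"].to_numpy()
    psi = torsions["psi"].to_numpy()
    classes = [classify_conformation(p, s) for p, s in zip(phi, psi)]
    in_helix = _helix_run_mask(classes)
    for i in range(len(res) - 3):
        ca_i = res[i].atoms.get("CA")
        ca_l = res[i + 3].atoms.get("CA")
        if ca_i is None or ca_l is None:
            continue
        dist = float(np.linalg.norm(ca_l - ca_i))
        if dist >= TURN_CA_CUTOFF:
            continue
        angles = (phi[i + 1], psi[i + 1], phi[i + 2], psi[i + 2])
        if any(math.isnan(a) for a in angles):
            continue
        if in_helix[i + 1] and in_helix[i + 2]:
            continue  # interior of an alpha-helix, not a turn
        turn_type = "IV"
        for name, canon in TURN_TYPES.items():
            if _matches_type(angles, canon):
                turn_type = name
                break
        out.append(
            TurnAssignment(
                start_index=i,
                start_residue=res[i].number,
                turn_type=turn_type,
                ca_distance=dist,
            )
        )
    return out


# ---------------------------------------------------------------------------
# hairpins
# ---------------------------------------------------------------------------

PAIRING_CUTOFF = 5.5


@dataclass
class HairpinClass:
    """X:Y loop-length class of an antiparallel β-hairpin."""

    x: int          # loop residues between the innermost Cα-paired bracket
    y: int          # loop residues between the supplied strand ranges
    pairs: list[tuple[int, int]]    # cross-strand Cα pairs (residue indices)

    @property
    def label(self) -> str:
        return f"{self.x}:{self.y}"


def detect_hairpin(
    structure: StructureModel,
    strand_ranges: tuple[tuple[int, int], tuple[int, int]],
) -> HairpinClass:
    """Class an antiparallel hairpin formed by two strand residue ranges.

    ``strand_ranges`` are inclusive author-number ranges of the two
    strands, first strand N-terminal to the second. The strands are paired
    Cα-to-Cα by the best rigid register (antiparallel register n1 + n2 =
    const); if a parallel register (n2 − n1 = const) fits the geometry
    better, the strands are not antiparallel and an error is raised. X
    counts the loop residues between the innermost paired residues (pairs
    within 5.5 Å), Y the residues strictly between the two supplied
    ranges; the canonical conserved hairpin of this superfamily is 4:4.
    """
    (s1a, s1b), (s2a, s2b) = strand_ranges
    if s1a > s1b or s2a > s2b or s1b >= s2a:
        raise GHMotifError("strand ranges must be ordered, non-overlapping")
    index_of = {r.number: k for k, r in enumerate(structure.residues)}

    def ca(num: int) -> np.ndarray:
        return structure.coord(num, "CA")

    strand1 = [n for n in range(s1a, s1b + 1) if n in index_of]
    strand2 = [n for n in range(s2a, s2b + 1) if n in index_of]
    if len(strand1) < 2 or len(strand2) < 2:
        raise GHMotifError("strands need at least 2 resolvable residues each")

    def best_register(antiparallel: bool):
        offsets = (
            {n1 + n2 for n1 in strand1 for n2 in strand2}
            if antiparallel
            else {n2 - n1 for n1 in strand1 for n2 in strand2}
        )
        best_key, best_pairs = (0, math.inf), []
        for c in offsets:
            reg = []
            for n1 in strand1:
                n2 = (c - n1) if antiparallel else (n1 + c)
                if n2 in index_of and s2a <= n2 <= s2b:
                    reg.append((n1, n2, float(np.linalg.norm(ca(n1) - ca(n2)))))
            close = [d for _, _, d in reg if d < PAIRING_CUTOFF]
            if len(close) < 2:
                continue
            # most residues in register, then tightest pairing
            key = (-len(close), float(np.mean(close)))
            if key < best_key:
                best_key, best_pairs = key, reg
        return best_key, best_pairs

    anti_key, anti_pairs = best_register(antiparallel=True)
    para_key, _ = best_register(antiparallel=False)
    if para_key < anti_key:
        raise GHMotifError("strand pairing order not reversed: strands not antiparallel")
    pairs = [(n1, n2) for n1, n2, d in anti_pairs if d < PAIRING_CUTOFF]
    if len(pairs) < 2:
        raise GHMotifError("no antiparallel cross-strand pairing within 5.5 A")

    last_paired_1 = max(p[0] for p in pairs)
    first_paired_2 = min(p[1] for p in pairs)
    x = sum(
        1 for r in structure.residues if last_paired_1 < r.number < first_paired_2
    )
    y = sum(1 for r in structure.residues if s1b < r.number < s2a)
    return HairpinClass(x=x, y=y, pairs=pairs)


# ---------------------------------------------------------------------------
# active-site geometry
# ---------------------------------------------------------------------------

def _role_atoms(structure: StructureModel, number: int, expected_name: str
                ) -> list[np.ndarray] | None:
    try:
        res = structure.residue(number)
    except KeyError:
        logger.warning("%s: role residue %d absent", structure.structure_id, number)
        return None
    if res.name != expected_name:
        logger.warning(
            "%s: residue %d is %s, expected %s; role skipped",
            structure.structure_id, number, res.name, expected_name,
        )
        return None
    names = ROLE_ATOMS.get(expected_name)
    coords = [res.atoms[a] for a in names if a in res.atoms]
    if not coords:
        logger.warning(
            "%s: no role atoms (%s) on residue %s%d",
            structure.structure_id, "/".join(names), expected_name, number,
        )
        return None
    return coords


def active_site_distances(
    structure: StructureModel, config: FamilyConfig
) -> pd.DataFrame:
    """Minimum role-pair distances (Å) for one structure.

    One row per role pair in A–B, A–C, B–C, A–D, B–D order; missing roles
    (or role residues absent/mutated in this structure) yield NaN, rendered
    as "/" in formatted tables.
    """
    atoms: dict[str, list[np.ndarray] | None] = {}
    for role, (number, name) in config.roles.items():
        atoms[role] = _role_atoms(structure, number, name)
    rows = []
    for r1, r2 in ROLE_PAIRS:
        a1, a2 = atoms.get(r1), atoms.get(r2)
        if a1 is None or a2 is None:
            d = math.nan
        else:
            d = min(
                float(np.linalg.norm(x - y)) for x in a1 for y in a2
            )
            d = round(d, 2)
        rows.append({"pair": f"{r1}-{r2}", "distance": d})
    return pd.DataFrame(rows)


def family_distance_summary(
    structures: Sequence[StructureModel],
    configs: Sequence[FamilyConfig],
) -> pd.DataFrame:
    """Mean (population SD) of role-pair distances over a family's structures.

    Structures lacking a role are skipped for that pair. Pairs observed in
    a single structure report SD NaN (rendered "–"); pairs observed nowhere
    report mean NaN (rendered "/").
    """
    if len(structures) != len(configs):
        raise GHMotifError("one config per structure required")
    per_pair: dict[str, list[float]] = {f"{a}-{b}": [] for a, b in ROLE_PAIRS}
    for structure, config in zip(structures, configs):
        table = active_site_distances(structure, config)
        for _, row in table.iterrows():
            if not math.isnan(row["distance"]):
                per_pair[row["pair"]].append(row["distance"])
    rows = []
    for pair, vals in per_pair.items():
        if not vals:
            mean = sd = math.nan
        else:
            mean = float(np.mean(vals))
            sd = float(np.std(vals)) if len(vals) > 1 else math.nan
        rows.append({"pair": pair, "n": len(vals), "mean": mean, "sd": sd})
    return pd.DataFrame(rows)


def format_distance_table(summary: pd.DataFrame) -> pd.DataFrame:
    """Render a family summary with the "/" and "–" table conventions."""
    def fmt(row):
        if math.isnan(row["mean"]):
            return "/"
        sd = "–" if math.isnan(row["sd"]) else f"{row['sd']:.2f}"
        return f"{row['mean']:.2f}({sd})"

    out = summary.copy()
    out["formatted"] = out.apply(fmt, axis=1)
    return out[["pair", "formatted"]]
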