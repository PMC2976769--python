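"""Per-column conservation profiling of family alignments.

The profile follows the AL2CO entropy recipe: sequences are weighted
(position-based Henikoff weights, which down-weight near-duplicates),
weighted residue frequencies are computed per column, the raw conservation
index is the negative Shannon entropy in nats

    C = sum_a f_a ln f_a        (0 for an invariant column, -ln 20 minimum),

the raw index is smoothed by a centred moving average (default window 3,
shrinking at the edges), and finally z-normalized over the unflagged
columns (mean 0, population SD 1). Columns whose gap fraction exceeds a
threshold are flagged and excluded from smoothing and normalization
statistics.

The normalized profile is mapped onto the author numbering of the family's
representative structure, and the family signature motif is the contiguous
window of bounded length that contains the structurally conserved
β-hairpin and maximizes mean normalized conservation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import GHMotifError
from .io import AA_INDEX, ALPHABET, GAP, MISSING, AlignedFamily

logger = logging.getLogger(__name__)


def sequence_weights(msa: AlignedFamily) -> np.ndarray:
    """Position-based (Henikoff & Henikoff) sequence weights, scaled to sum n.

    At each column a sequence holding residue *a* receives 1/(r·s_a), where
    r is the number of distinct residue types in the column and s_a the
    number of sequences sharing residue *a*; gaps and 'X' contribute
    nothing. Per-sequence sums are averaged over contributing columns and
    rescaled so the weights sum to the number of sequences. Exact
    duplicates therefore share weight; with no duplication all weights are
    equal (to 1).
    """
    n = msa.n_sequences
    raw = np.zeros(n)
    contributing = 0
    for col in range(msa.n_columns):
        residues = [row[col] for row in msa.rows]
        counts: dict[str, int] = {}
        for a in residues:
            if a in (GAP, MISSING):
                continue
            counts[a] = counts.get(a, 0) + 1
        if not counts:
            continue
        contributing += 1
        r = len(counts)
        for s, a in enumerate(residues):
            if a in counts:
                raw[s] += 1.0 / (r * counts[a])
    if contributing == 0 or raw.sum() == 0:
        return np.ones(n)
    weights = raw / raw.sum() * n
    return weights


def column_frequencies(
    msa: AlignedFamily, weights: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted residue frequencies and gap fraction per column.

    Returns ``(freqs, gap_fraction)`` with ``freqs`` of shape
    (n_columns, 20) normalized over non-gap, non-'X' symbols (all-zero rows
    for columns with no residue). 'X' counts toward neither frequencies nor
    the gap fraction denominator — it is missing data.
    """
    if weights is None:
        weights = sequence_weights(msa)
    n_cols = msa.n_columns
    freqs = np.zeros((n_cols, len(ALPHABET)))
    gap_fraction = np.zeros(n_cols)
    for col in range(n_cols):
        total = 0.0
        gap_w = 0.0
        for row, w in zip(msa.rows, weights):
            a = row[col]
            if a == MISSING:
                continue
            if a == GAP:
                gap_w += w
                total += w
                continue
            idx = AA_INDEX.get(a)
            if idx is None:
                logger.warning("unknown symbol %r treated as missing", a)
                continue
            freqs[col, idx] += w
            total += w
        if total > 0:
            gap_fraction[col] = gap_w / total
        s = freqs[col].sum()
        if s > 0:
            freqs[col] /= s
    return freqs, gap_fraction


def entropy_conservation(frequencies: np.ndarray) -> float:
    """Raw conservation index of one column: C = Σ f ln f (nats, ≤ 0)."""
    f = np.asarray(frequencies, dtype=float)
    s = f.sum()
    if s <= 0:
        raise GHMotifError("zero-coverage column has no conservation index")
    if not math.isclose(s, 1.0, rel_tol=0, abs_tol=1e-8):
        raise GHMotifError(f"frequencies sum to {s:.6g}, expected 1")
    nz = f[f > 0]
    return float(np.sum(nz * np.log(nz)))


def smooth_profile(
    raw: np.ndarray, flagged: np.ndarray | None = None, window: int = 3
) -> np.ndarray:
    """Centred moving average; the window shrinks at edges and over flags.

    Flagged columns stay NaN in the output and are excluded from their
    neighbours' averages.
    """
    if window % 2 != 1:
        raise GHMotifError("smoothing window must be odd")
    raw = np.asarray(raw, dtype=float)
    n = len(raw)
    if flagged is None:
        flagged = np.zeros(n, dtype=bool)
    half = window // 2
    out = np.full(n, np.nan)
    for i in range(n):
        if flagged[i]:
            continue
        lo, hi = max(0, i - half), min(n, i + half + 1)
        vals = [raw[j] for j in range(lo, hi) if not flagged[j]]
        out[i] = float(np.mean(vals))
    return out


def normalize_profile(smoothed: np.ndarray, flagged: np.ndarray | None = None) -> np.ndarray:
    """Z-scores over unflagged columns (population SD); flags stay NaN."""
    smoothed = np.asarray(smoothed, dtype=float)
    if flagged is None:
        flagged = np.isnan(smoothed)
    else:
        flagged = flagged | np.isnan(smoothed)
    vals = smoothed[~flagged]
    if len(vals) < 2:
        raise GHMotifError("need at least 2 unflagged columns to normalize")
    mean = float(np.mean(vals))
    sd = float(np.std(vals))  # population SD
    out = np.full(len(smoothed), np.nan)
    if sd == 0:
        logger.warning("zero-variance profile; normalized indices set to 0")
        out[~flagged] = 0.0
        return out
    out[~flagged] = (smoothed[~flagged] - mean) / sd
    return out


@dataclass
class ConservationProfile:
    """Column-wise conservation indices for one family alignment."""

    family_id: str
    frequencies: np.ndarray          # (n_columns, 20)
    gap_fraction: np.ndarray
    flagged: np.ndarray              # excluded columns (gappy / zero coverage)
    raw: np.ndarray                  # Σ f ln f, NaN where flagged
    smoothed: np.ndarray
    normalized: np.ndarray
    column_to_residue: dict[int, int] = field(default_factory=dict)

    @property
    def n_columns(self) -> int:
        return len(self.raw)

    def residue_of(self, column: int) -> int | None:
        return self.column_to_residue.get(column)

    def column_of(self, residue: int) -> int:
        for col, num in self.column_to_residue.items():
            if num == residue:
                return col
        raise KeyError(f"residue {residue} not mapped")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "column": np.arange(self.n_columns),
                "residue": [self.column_to_residue.get(c) for c in range(self.n_columns)],
                "raw": self.raw,
                "smoothed": self.smoothed,
                "normalized": self.normalized,
                "gap_fraction": self.gap_fraction,
                "flagged": self.flagged.astype(int),
            }
        )


def compute_profile(
    msa: AlignedFamily,
    weights: np.ndarray | None = None,
    window: int = 3,
    gap_threshold: float = 0.5,
) -> ConservationProfile:
    """Full conservation pipeline: weights → frequencies → C → smooth → z."""
    if weights is None:
        weights = sequence_weights(msa)
    freqs, gap_fraction = column_frequencies(msa, weights)
    coverage = freqs.sum(axis=1)
    flagged = (gap_fraction > gap_threshold) | (coverage == 0)
    raw = np.full(msa.n_columns, np.nan)
    for col in range(msa.n_columns):
        if not flagged[col]:
            raw[col] = entropy_conservation(freqs[col])
    smoothed = smooth_profile(raw, flagged, window=window)
    normalized = normalize_profile(smoothed, flagged)
    return ConservationProfile(
        family_id=msa.family_id,
        frequencies=freqs,
        gap_fraction=gap_fraction,
        flagged=flagged,
        raw=raw,
        smoothed=smoothed,
        normalized=normalized,
    )


def map_to_representative(
    profile: ConservationProfile,
    msa: AlignedFamily,
    representative_id: str | None = None,
    start_number: int = 1,
) -> ConservationProfile:
    """Attach a column → representative-residue-number mapping to the profile.

    Columns where the representative row carries a gap are unmapped; mapped
    residue numbers increase monotonically from ``start_number`` (the author
    number of the representative's first aligned residue).
    """
    rep = representative_id or msa.representative_id
    row = msa.row(rep)
    mapping: dict[int, int] = {}
    num = start_number
    for col, symbol in enumerate(row):
        if symbol != GAP:
            mapping[col] = num
            num += 1
    if not mapping:
        raise GHMotifError(f"representative row {rep!r} is all gaps")
    profile.column_to_residue = mapping
    return profile


@dataclass
class MotifRegion:
    """The family signature region: most conserved window containing the hairpin."""

    family_id: str
    column_start: int               # inclusive, 0-based alignment columns
    column_end: int                 # inclusive
    residue_start: int | None       # representative author numbering
    residue_end: int | None
    mean_conservation: float

    @property
    def length(self) -> int:
        return self.column_end - self.column_start + 1


def extract_motif(
    profile: ConservationProfile,
    hairpin_columns: tuple[int, int],
    min_length: int = 8,
    max_length: int = 18,
) -> MotifRegion:
    """Best conserved window of bounded length containing the β-hairpin.

    Scans every contiguous column window with length in
    [``min_length``, ``max_length``] that fully contains
    ``hairpin_columns`` (inclusive 0-based pair) and returns the window
    maximizing the summed z-score of the *raw* (unsmoothed) conservation
    index. Summing z-scores gives the window a natural boundary — columns
    above average conservation extend it, below-average columns stop it —
    so a conserved block is recovered at its true edges; a windowed *mean*
    would instead collapse onto the shortest admissible sub-window.
    Flagged columns count as strongly negative, discouraging gappy
    extensions. Ties prefer the shorter, then the leftmost window. A
    hairpin longer than ``max_length`` is returned as-is with a warning.
    """
    h_start, h_end = hairpin_columns
    n = profile.n_columns
    if not (0 <= h_start <= h_end < n):
        raise GHMotifError(f"hairpin columns {hairpin_columns} outside profile")
    finite = ~(profile.flagged | np.isnan(profile.raw))
    vals = profile.raw[finite]
    if len(vals) < 2:
        raise GHMotifError("too few scored columns to extract a motif")
    sd = float(np.std(vals))
    z = np.where(
        finite,
        (profile.raw - float(np.mean(vals))) / (sd if sd > 0 else 1.0),
        -(3.0 + max_length),  # flagged: worse than any plausible column
    )

    hairpin_len = h_end - h_start + 1
    if hairpin_len > max_length:
        logger.warning(
            "hairpin span %d exceeds max motif length %d; returning hairpin range",
            hairpin_len, max_length,
        )
        return _region(profile, h_start, h_end)

    best: tuple[float, int, int] | None = None  # (-sum, length, start)
    lo_len = max(min_length, hairpin_len)
    for length in range(lo_len, max_length + 1):
        for start in range(max(0, h_end - length + 1), min(h_start, n - length) + 1):
            end = start + length - 1
            total = float(np.sum(z[start:end + 1]))
            key = (-total, length, start)
            if best is None or key < best:
                best = key
    if best is None:
        raise GHMotifError("no admissible motif window (length bounds too tight)")
    _, length, start = best
    return _region(profile, start, start + length - 1)


def _region(profile, start, end) -> MotifRegion:
    mapped = [profile.column_to_residue[c]
              for c in range(start, end + 1) if c in profile.column_to_residue]
    window = profile.normalized[start:end + 1]
    return MotifRegion(
        family_id=profile.family_id,
        column_start=start,
        column_end=end,
        residue_start=mapped[0] if mapped else None,
        residue_end=mapped[-1] if mapped else None,
        mean_conservation=float(np.nanmean(window)),
    )
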