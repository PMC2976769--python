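"""Position-specific signature models and profile search.

A signature motif alignment is turned into a position-specific log-odds
profile (weighted counts with background pseudocounts), searched against
sequences with a *glocal* affine-gap dynamic program — the motif must be
aligned end to end (matches or deletions), while the sequence contributes
a free local window — and the hit lists are summarized as true/false
positive rates against membership labels.

This is a deliberately transparent stand-in for a full plan-7 profile HMM:
the scientific question it answers is whether a family signature is
discriminative, and every score it produces can be checked against
exhaustive alignment enumeration.

Alignment grammar (shared by the DP and the brute-force oracle in the test
suite): an alignment is an optional leading deletion run, then columns of
matches, insertion runs and deletion runs where every gap run is bracketed
by matches or the alignment ends, insertions never touch deletions, and at
least one profile position is matched. Gap runs cost
``open + (k-1)·extend`` nats for k columns.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import GHMotifError
from .io import AA_INDEX, ALPHABET, GAP, MISSING, AlignedFamily

logger = logging.getLogger(__name__)

NEG_INF = float("-inf")

#: uniform amino-acid background
UNIFORM_BACKGROUND = np.full(len(ALPHABET), 1.0 / len(ALPHABET))


# ---------------------------------------------------------------------------
# logos
# ---------------------------------------------------------------------------

@dataclass
class LogoMatrix:
    """Per-position residue frequencies and information content (bits)."""

    frequencies: np.ndarray     # (m, 20)
    information: np.ndarray     # bits, in [0, log2 20]
    consensus: str
    flagged: np.ndarray         # all-gap positions (IC forced to 0)

    @property
    def length(self) -> int:
        return len(self.information)

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.frequencies, columns=list(ALPHABET))
        df.insert(0, "position", np.arange(1, self.length + 1))
        df["information_bits"] = self.information
        df["consensus"] = list(self.consensus)
        return df


def build_logo(motif_msa: AlignedFamily, weights: np.ndarray | None = None) -> LogoMatrix:
    """Sequence-logo content: relative frequencies and per-position IC.

    IC(p) = log2(20) − H2(f_p) with H2 the Shannon entropy in bits; no
    small-sample correction is applied. All-gap positions get IC = 0 and
    are flagged.
    """
    from .conservation import column_frequencies, sequence_weights

    if weights is None:
        weights = sequence_weights(motif_msa)
    freqs, _ = column_frequencies(motif_msa, weights)
    m = motif_msa.n_columns
    info = np.zeros(m)
    flagged = np.zeros(m, dtype=bool)
    consensus = []
    max_bits = math.log2(len(ALPHABET))
    for p in range(m):
        f = freqs[p]
        if f.sum() == 0:
            flagged[p] = True
            consensus.append("-")
            continue
        nz = f[f > 0]
        h2 = float(-np.sum(nz * np.log2(nz)))
        info[p] = max_bits - h2
        consensus.append(ALPHABET[int(np.argmax(f))])
    return LogoMatrix(frequencies=freqs, information=info,
                      consensus="".join(consensus), flagged=flagged)


# ---------------------------------------------------------------------------
# profile model
# ---------------------------------------------------------------------------

@dataclass
class ProfileModel:
    """Position-specific log-odds emission model with affine gap penalties."""

    family_id: str
    log_odds: np.ndarray            # (m, 20), nats
    background: np.ndarray
    gap_open: float = 4.0
    gap_extend: float = 0.5
    threshold: float | None = None
    consensus: str = ""

    @property
    def length(self) -> int:
        return self.log_odds.shape[0]

    def consensus_score(self) -> float:
        """Score of the per-position best residue (upper bound for matches)."""
        return float(np.sum(np.max(self.log_odds, axis=1)))


def build_profile(
    motif_msa: AlignedFamily,
    weights: np.ndarray | None = None,
    pseudocount: float = 1.0,
    background: np.ndarray | None = None,
    gap_open: float = 4.0,
    gap_extend: float = 0.5,
) -> ProfileModel:
    """Estimate per-position emissions with background pseudocounts.

    emission(p, a) = (wcount(p, a) + α·bg(a)) / (Σw_p + α), log-odds
    ln(emission/bg). With α = 0 unseen residues get −inf log-odds (allowed,
    the DP treats them as forbidden matches); as α → ∞ log-odds → 0.
    """
    from .conservation import sequence_weights

    if background is None:
        background = UNIFORM_BACKGROUND
    background = np.asarray(background, dtype=float)
    if not math.isclose(background.sum(), 1.0, abs_tol=1e-8):
        raise GHMotifError("background frequencies must sum to 1")
    if pseudocount < 0:
        raise GHMotifError("pseudocount strength must be >= 0")
    if weights is None:
        weights = sequence_weights(motif_msa)
    m = motif_msa.n_columns
    log_odds = np.empty((m, len(ALPHABET)))
    consensus = []
    for p in range(m):
        counts = np.zeros(len(ALPHABET))
        for row, w in zip(motif_msa.rows, weights):
            a = row[p]
            if a in (GAP, MISSING):
                continue
            idx = AA_INDEX.get(a)
            if idx is not None:
                counts[idx] += w
        total = counts.sum()
        emission = (counts + pseudocount * background) / (total + pseudocount) \
            if (total + pseudocount) > 0 else background.copy()
        with np.errstate(divide="ignore"):
            log_odds[p] = np.where(
                emission > 0, np.log(emission / background), NEG_INF
            )
        consensus.append(ALPHABET[int(np.argmax(emission))])
    return ProfileModel(
        family_id=motif_msa.family_id,
        log_odds=log_odds,
        background=background,
        gap_open=gap_open,
        gap_extend=gap_extend,
        consensus="".join(consensus),
    )


# ---------------------------------------------------------------------------
# glocal scoring
# ---------------------------------------------------------------------------

def score_sequence(profile: ProfileModel, sequence: str) -> tuple[float, int | None]:
    """Best glocal alignment score of the motif anywhere in ``sequence``.

    Returns ``(score, start)`` where ``start`` is the 0-based sequence
    index of the first matched residue of the best alignment. An empty (or
    unscorable) sequence returns ``(-inf, None)``.
    """
    m = profile.length
    L = profile.log_odds
    go, ge = profile.gap_open, profile.gap_extend
    seq = sequence.upper()
    n = len(seq)
    if n == 0 or m == 0:
        return NEG_INF, None

    aa = [AA_INDEX.get(c, -1) for c in seq]

    # leading deletion run: profile positions 1..i deleted before any match
    dlead = [NEG_INF] * (m + 1)
    for i in range(1, m + 1):
        dlead[i] = -(go + (i - 1) * ge)

    # M[i][j]: profile pos i matched to seq pos j (1-based); I: insertion
    # after pos i; D: pos i deleted after >=1 match. Start positions ride
    # along with the scores.
    M = np.full((m + 1, n + 1), NEG_INF)
    I = np.full((m + 1, n + 1), NEG_INF)
    D = np.full((m + 1, n + 1), NEG_INF)
    Ms = np.full((m + 1, n + 1), -1, dtype=int)
    Is = np.full((m + 1, n + 1), -1, dtype=int)
    Ds = np.full((m + 1, n + 1), -1, dtype=int)

    for j in range(1, n + 1):
        c = aa[j - 1]
        for i in range(1, m + 1):
            emit = L[i - 1, c] if c >= 0 else NEG_INF
            if emit > NEG_INF:
                # fresh start (i==1) or start after a leading deletion run
                best, bstart = (0.0, j - 1) if i == 1 else (dlead[i - 1], j - 1) \
                    if dlead[i - 1] > NEG_INF else (NEG_INF, -1)
                if i > 1:
                    if M[i - 1][j - 1] > best:
                        best, bstart = M[i - 1][j - 1], Ms[i - 1][j - 1]
                    if I[i - 1][j - 1] > best:
                        best, bstart = I[i - 1][j - 1], Is[i - 1][j - 1]
                    if D[i - 1][j - 1] > best:
                        best, bstart = D[i - 1][j - 1], Ds[i - 1][j - 1]
                if best > NEG_INF:
                    M[i][j] = best + emit
                    Ms[i][j] = bstart
            # insertions sit strictly between matches of pos i and i+1
            if i < m:
                cand_open = M[i][j - 1] - go
                cand_ext = I[i][j - 1] - ge
                if cand_open >= cand_ext:
                    I[i][j], Is[i][j] = cand_open, Ms[i][j - 1]
                else:
                    I[i][j], Is[i][j] = cand_ext, Is[i][j - 1]
            # deletion after at least one match
            cand_open = M[i - 1][j] - go
            cand_ext = D[i - 1][j] - ge
            if cand_open >= cand_ext:
                D[i][j], Ds[i][j] = cand_open, Ms[i - 1][j]
            else:
                D[i][j], Ds[i][j] = cand_ext, Ds[i - 1][j]

    best, bstart = NEG_INF, None
    for j in range(1, n + 1):
        if M[m][j] > best:
            best, bstart = float(M[m][j]), int(Ms[m][j])
        if D[m][j] > best:
            best, bstart = float(D[m][j]), int(Ds[m][j])
    return best, bstart


def calibrate_threshold(
    profile: ProfileModel,
    fpr_target: float = 0.01,
    n_null: int = 500,
    null_length: int = 60,
    seed: int = 0,
) -> float:
    """Score threshold at a target false-positive rate on a background null.

    Simulates ``n_null`` sequences from the profile background and returns
    the empirical (1 − fpr_target) quantile of their best scores.
    """
    rng = np.random.default_rng(seed)
    letters = np.array(list(ALPHABET))
    scores = np.empty(n_null)
    for k in range(n_null):
        seq = "".join(rng.choice(letters, size=null_length, p=profile.background))
        scores[k], _ = score_sequence(profile, seq)
    return float(np.quantile(scores, 1.0 - fpr_target))


# ---------------------------------------------------------------------------
# search evaluation
# ---------------------------------------------------------------------------

@dataclass
class SearchEvaluation:
    """TPR/FPR of a threshold search over labelled sequences."""

    tpr: float | None
    fpr: float | None
    threshold: float
    hits: list[tuple[str, float, int | None]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "tpr": self.tpr,
            "fpr": self.fpr,
            "threshold": self.threshold,
            "n_hits": len(self.hits),
        }


def evaluate_search(
    profile: ProfileModel,
    sequences: dict[str, str],
    labels: dict[str, bool],
    threshold: float,
    exclude: set[str] | None = None,
) -> SearchEvaluation:
    """Search all sequences and summarize as TPR/FPR.

    ``labels`` marks members (True) vs non-members; identifiers in
    ``exclude`` are dropped from the false-positive denominator before
    rates are computed (the arithmetic of a curated-database correction:
    apparent false hits known to belong to the family are removed). With
    no members or no non-members the corresponding rate is None.
    """
    exclude = exclude or set()
    hits: list[tuple[str, float, int | None]] = []
    tp = fp = n_pos = n_neg = 0
    for sid, seq in sequences.items():
        if sid not in labels:
            raise GHMotifError(f"sequence {sid!r} has no membership label")
        score, start = score_sequence(profile, seq)
        is_hit = score >= threshold
        if is_hit:
            hits.append((sid, score, start))
        if labels[sid]:
            n_pos += 1
            tp += is_hit
        elif sid not in exclude:
            n_neg += 1
            fp += is_hit
    hits.sort(key=lambda h: -h[1])
    tpr = tp / n_pos if n_pos else None
    fpr = fp / n_neg if n_neg else None
    return SearchEvaluation(tpr=tpr, fpr=fpr, threshold=threshold, hits=hits)
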