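import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from ghmotif.cluster import DistanceMatrix, SimilarityMatrix
from ghmotif.io import AlignedFamily


@pytest.fixture
def toy_alignment() -> AlignedFamily:
    """Four sequences, eight columns, conserved block in columns 2-5."""
    return AlignedFamily(
        family_id="toy",
        sequence_ids=["s1", "s2", "s3", "s4"],
        rows=[
            "AKWCDEYG",
            "GKWCDEYA",
            "PKWCDEYT",
            "LKWCDEYS",
        ],
        representative_id="s1",
    )


@pytest.fixture
def three_taxon_distance() -> DistanceMatrix:
    return DistanceMatrix(
        labels=["A", "B", "C"],
        values=np.array([[0.0, 2.0, 8.0], [2.0, 0.0, 8.0], [8.0, 8.0, 0.0]]),
    )


@pytest.fixture
def two_cluster_similarity() -> SimilarityMatrix:
    """Noise-free two-cluster matrix: within 40, between 5, self 45 (n=6)."""
    labels = ["A1", "A2", "A3", "B1", "B2", "B3"]
    n = len(labels)
    S = np.full((n, n), 5.0)
    for i in range(n):
        for j in range(n):
            if labels[i][0] == labels[j][0]:
                S[i, j] = 40.0
        S[i, i] = 45.0
    return SimilarityMatrix(labels=labels, values=S)


@pytest.fixture
def ambiguous_taxon_similarity() -> SimilarityMatrix:
    """Two clean clusters plus taxon X whose placement flips when A1 is removed.

    X is similar to A1 (d=3 scale) but dissimilar to A2/A3 (d=7), and
    uniformly intermediate to the B cluster (d=6): with A1 present, X joins
    the A cluster (mean 5.67 < 6); without A1 it joins B (7 > 6), so the
    clade {A*,X} must be flagged unreliable while {A1,A2}, {B...} stay
    reliable.
    """
    labels = ["A1", "A2", "A3", "B1", "B2", "B3", "X0"]
    pair_dist = {}
    for a in labels:
        for b in labels:
            if a == b:
                continue
            ga, gb = a[0], b[0]
            if ga == gb:
                d = 2.0
            elif {ga, gb} == {"A", "B"}:
                d = 10.0
            elif "X" in (ga, gb):
                other = a if ga != "X" else b
                if other == "A1":
                    d = 3.0
                elif other.startswith("A"):
                    d = 7.0
                else:
                    d = 6.0
            pair_dist[(a, b)] = d
    # embed distances into a similarity matrix under the default transform:
    # D = 100 * (1 - 2 S / (Sii + Sjj)) with self-scores 50 -> S = 50 - D/2
    n = len(labels)
    S = np.zeros((n, n))
    for i, a in enumerate(labels):
        S[i, i] = 50.0
        for j, b in enumerate(labels):
            if i != j:
                S[i, j] = 50.0 - pair_dist[(a, b)] / 2.0
    return SimilarityMatrix(labels=labels, values=S)
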