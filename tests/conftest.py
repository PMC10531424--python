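"""Shared fixtures: matrices, toy alphabets and synthetic libraries."""

import numpy as np
import pytest

from dastm import (GeneratorParams, HydrophobicityScale, build_pair_matrix,
                   default_matrix, synth_library)

#: Toy 3-letter alphabet spanning the hydrophobicity range
#: (L hydrophobic, A intermediate, S hydrophilic).
TOY_LETTERS = "ALS"


@pytest.fixture(scope="session")
def matrix():
    return default_matrix()


@pytest.fixture(scope="session")
def toy_matrix():
    scale = HydrophobicityScale(
        "toy", {"L": 3.8, "A": 1.8, "S": -0.8})
    background = {"L": 1 / 3, "A": 1 / 3, "S": 1 / 3}
    return build_pair_matrix(scale, background)


@pytest.fixture(scope="session")
def small_library():
    """8-member synthetic reference library, fixed seed."""
    return synth_library(GeneratorParams(seed=42), 8)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)


# ---------------------------------------------------------------------------
# Independent brute-force oracles (plain-Python restatements of the scoring
# definitions; deliberately loop-based and unvectorized).
# ---------------------------------------------------------------------------

def brute_surface(query: str, reference: str, matrix, window: int):
    """Triple-loop windowed pair-score surface."""
    w = (window - 1) // 2
    lq, lr = len(query), len(reference)
    surface = [[0.0] * lr for _ in range(lq)]
    for i in range(lq):
        for j in range(lr):
            total, count = 0.0, 0
            for k in range(-w, w + 1):
                if 0 <= i + k < lq and 0 <= j + k < lr:
                    total += matrix.score(query[i + k], reference[j + k])
                    count += 1
            surface[i][j] = total / count
    return surface


def brute_cross_weighted(surface):
    """Weighted column mean with weights = column means."""
    lq, lr = len(surface), len(surface[0])
    col_means = [sum(surface[i][j] for i in range(lq)) / lq for j in range(lr)]
    denom = sum(col_means)
    if denom == 0.0:
        return [0.0] * lq
    return [sum(surface[i][j] * col_means[j] for j in range(lr)) / denom
            for i in range(lq)]


def brute_das_profile(query_id: str, query: str, members, matrix, window: int):
    """Average of brute cross-weighted profiles, excluding id-equal members."""
    kept = [m for m in members if m.id != query_id]
    profiles = [brute_cross_weighted(brute_surface(query, m.residues,
                                                   matrix, window))
                for m in kept]
    return [sum(p[i] for p in profiles) / len(profiles)
            for i in range(len(query))]
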