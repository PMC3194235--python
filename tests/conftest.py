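"""Shared fixtures and independent oracles.

The oracles here are deliberately naive re-implementations (quadratic DP
with explicit 2-D tables, linear scans over all candidate thresholds) kept
separate from the package's optimised code paths so they can serve as
ground truth.
"""

from __future__ import annotations

import pytest

from markerphyler import default_params, simulate_marker_db, train_all


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def sw_oracle(query: str, subject: str, matrix, gap_open: int, gap_extend: int) -> int:
    """Textbook affine-gap local alignment DP (full 2-D tables)."""
    n, m = len(query), len(subject)
    NEG = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] + gap_open + gap_extend, E[i][j - 1] + gap_extend)
            F[i][j] = max(H[i - 1][j] + gap_open + gap_extend, F[i - 1][j] + gap_extend)
            H[i][j] = max(
                0.0,
                H[i - 1][j - 1] + matrix[(query[i - 1], subject[j - 1])],
                E[i][j],
                F[i][j],
            )
            if H[i][j] > best:
                best = H[i][j]
    return int(best)


def cutoff_oracle(b_level, b_else) -> tuple[float, int]:
    """Linear scan of the misclassification count over all candidates.

    Returns (largest minimising threshold, minimal error count).
    """
    candidates = sorted(set(b_level) | set(b_else))
    candidates.append(candidates[-1] + 1.0)
    best_b, best_err = None, None
    for b in candidates:
        err = sum(1 for s in b_level if s < b) + sum(1 for s in b_else if s >= b)
        if best_err is None or err < best_err or (err == best_err and b > best_b):
            best_b, best_err = b, err
    return best_b, best_err


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def params():
    return default_params()


@pytest.fixture(scope="session")
def tiny_db():
    """16 genes, 8 genera, 2 marker families, 80 aa."""
    return simulate_marker_db(
        (2, 1, 2, 1, 2), n_families=2, root_length_aa=80, seed=3
    )


@pytest.fixture(scope="session")
def species_db():
    """Six-level taxonomy (2 species per genus) for genus-rank training."""
    return simulate_marker_db(
        (1, 1, 1, 2, 2, 2), n_families=2, root_length_aa=80, seed=5
    )


@pytest.fixture(scope="session")
def tiny_classifiers(tiny_db):
    return train_all(tiny_db, seed=3)


@pytest.fixture(scope="session")
def species_classifiers(species_db):
    return train_all(species_db, seed=5)
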