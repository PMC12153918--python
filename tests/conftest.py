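import numpy as np
import pandas as pd
import pytest

import milkfa
from milkfa.reference import FA_TRAITS


@pytest.fixture(scope="session")
def state_models():
    return milkfa.default_state_models()


@pytest.fixture(scope="session")
def small_population(state_models):
    """A 30-herd, 4-month synthetic population with truth labels."""
    cfg = milkfa.SimConfig(n_herds=30, horizon_days=120, seed=11)
    return milkfa.simulate_population(state_models, cfg)


@pytest.fixture(scope="session")
def fat_basis_population(small_population):
    """Cleaned, fat-basis records aligned with their truth labels."""
    records, truth = small_population
    kept, log = milkfa.clean_records(records)
    assert log.empty  # no artifacts injected
    fat_basis = milkfa.convert_to_fat_basis(kept)
    return fat_basis, truth


def ward_oracle(points: np.ndarray) -> np.ndarray:
    """Exhaustive Ward linkage: recompute all inter-cluster merge costs
    from scratch at every step.

    Uses the centroid closed form of the Ward cost,
    d^2(A, B) = 2|A||B|/(|A|+|B|) * ||c_A - c_B||^2, with heights reported
    on the distance scale.  Ties merge the lexicographically smallest pair
    of active cluster ids.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    clusters = {i: [i] for i in range(n)}
    merges = []
    next_id = n
    for _ in range(n - 1):
        best = None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if b <= a:
                    continue
                ca = points[clusters[a]].mean(axis=0)
                cb = points[clusters[b]].mean(axis=0)
                na, nb = len(clusters[a]), len(clusters[b])
                d2 = 2.0 * na * nb / (na + nb) * float(((ca - cb) ** 2).sum())
                if best is None or d2 < best[0] - 1e-12:
                    best = (d2, a, b)
        d2, a, b = best
        merged = clusters.pop(a) + clusters.pop(b)
        merges.append([a, b, np.sqrt(d2), len(merged)])
        clusters[next_id] = merged
        next_id += 1
    return np.asarray(merges)
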