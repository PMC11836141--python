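import numpy as np
import pytest

from srmpt import expected_frequencies, storage_retrieval_model

# Aggregated Session-1 parameter estimates used as refit fixtures, together
# with the per-condition sample sizes (participants x 20 items per tree).
AGGREGATED_ESTIMATES = {
    "exp1_waking_rest": ({"s": 0.91, "r1": 0.98, "g": 0.46, "r2": 0.73}, 1020),
    "exp1_social_media": ({"s": 0.92, "r1": 0.98, "g": 0.38, "r2": 0.73}, 1000),
    "exp1_vocabulary": ({"s": 0.87, "r1": 0.96, "g": 0.27, "r2": 0.68}, 1060),
    "exp2_vocabulary": ({"s": 0.89, "r1": 0.99, "g": 0.27, "r2": 0.63}, 1040),
}


@pytest.fixture(scope="session")
def spec():
    return storage_retrieval_model()


@pytest.fixture(scope="session")
def waking_rest_params():
    return dict(AGGREGATED_ESTIMATES["exp1_waking_rest"][0])


@pytest.fixture(scope="session")
def waking_rest_counts(spec, waking_rest_params):
    return expected_frequencies(
        spec, waking_rest_params, {"target": 1020, "distractor": 1020}
    )


def random_interior_counts(spec, rng, n_per_tree=1000, low=0.2, high=0.8):
    """Multinomial counts at a random interior parameter vector (kept interior)."""
    from srmpt import category_probabilities

    while True:
        params = {
            "s": rng.uniform(low, high),
            "r1": rng.uniform(0.5, high + 0.15),
            "g": rng.uniform(low, high),
            "r2": rng.uniform(low, high),
        }
        probs = category_probabilities(spec, params)
        vec = []
        for tree in spec.trees:
            p = np.array([probs[tree.name][c] for c in tree.categories])
            vec.extend(rng.multinomial(n_per_tree, p))
        vec = np.asarray(vec, dtype=float)
        if np.all(vec > 0):
            from srmpt import CategoryCounts

            counts = CategoryCounts.from_vector(spec, vec)
            from srmpt import invert_saturated
            from srmpt.errors import InversionError

            try:
                est = invert_saturated(counts)
            except InversionError:
                continue
            if all(0.001 < v < 0.999 for v in est.values()):
                return counts, params
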