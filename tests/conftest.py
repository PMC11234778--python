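import numpy as np
import pytest

from consensv.merge import MergeParams
from consensv.model import SV_CLASSES, GenomeInfo, SVCall


@pytest.fixture
def small_genome() -> GenomeInfo:
    return GenomeInfo((("chr1", 10_000),))


def random_merge_instance(rng: np.random.Generator, max_genome: int = 3000):
    """One randomized differential-testing instance: a small genome, up
    to 6 callers with up to 20 calls each across all four classes, and
    random merge parameters (occasionally with a weighted caller)."""
    length = int(rng.integers(500, max_genome + 1))
    genome = GenomeInfo((("c1", length),))
    n_callers = int(rng.integers(1, 7))
    callers = [f"caller{i}" for i in range(n_callers)]
    calls: list[SVCall] = []
    for caller in callers:
        n_calls = int(rng.integers(0, 21))
        for _ in range(n_calls):
            sv_class = SV_CLASSES[int(rng.integers(0, 4))]
            if sv_class == "INS":
                start = int(rng.integers(0, length - 1))
                calls.append(SVCall(caller, "c1", "INS", start, start + 1))
            else:
                start = int(rng.integers(0, length - 10))
                end = int(rng.integers(start + 1, min(start + 400, length) + 1))
                calls.append(SVCall(caller, "c1", sv_class, start, end))
    weights: dict = {}
    if rng.random() < 0.5 and callers:
        lucky = callers[int(rng.integers(0, len(callers)))]
        if rng.random() < 0.5:
            weights[lucky] = 2
        else:
            weights[lucky] = {"INS": 2}
    params = MergeParams(
        min_callers_cnv=int(rng.integers(1, 4)),
        min_callers_inv=int(rng.integers(1, 4)),
        min_callers_ins=int(rng.integers(1, 4)),
        max_gap=int(rng.choice([0, 1, 5, 25, 100])),
        weights=weights,
    )
    return calls, genome, params
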