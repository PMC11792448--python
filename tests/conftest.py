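import numpy as np
import pytest

from mockdebias import GeneratorConfig, PipelineConfig, generate_experiment, generate_morphology, generate_references


@pytest.fixture(scope="session")
def config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def gen_config():
    # small but complete study: 8 protocols, 3 dilutions, all artifact types
    return GeneratorConfig(
        seed=42,
        dilutions=(1e4, 1e6, 1e8),
        mock_types=("even",),
        include_spike_in=True,
        n_skin_samples=2,
        depth=20_000,
    )


@pytest.fixture(scope="session")
def refs(gen_config):
    return generate_references(gen_config)


@pytest.fixture(scope="session")
def morph(gen_config):
    return generate_morphology(gen_config)


@pytest.fixture(scope="session")
def experiment(gen_config):
    return generate_experiment(gen_config)


def recursive_levenshtein(a: str, b: str) -> int:
    """Naive recursive edit distance with memoization (test oracle)."""
    memo: dict[tuple[int, int], int] = {}

    def rec(i: int, j: int) -> int:
        if i == len(a):
            return len(b) - j
        if j == len(b):
            return len(a) - i
        key = (i, j)
        if key not in memo:
            sub = rec(i + 1, j + 1) + (a[i] != b[j])
            ins = rec(i, j + 1) + 1
            dele = rec(i + 1, j) + 1
            memo[key] = min(sub, ins, dele)
        return memo[key]

    return rec(0, 0)
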