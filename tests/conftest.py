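import numpy as np
import pytest

from tubnum import fixtures


@pytest.fixture(scope="session")
def alpha_profile():
    return fixtures.consensus_profile("alpha")


@pytest.fixture(scope="session")
def all_profiles():
    return {f: fixtures.consensus_profile(f) for f in ("alpha", "beta", "gamma")}


@pytest.fixture(scope="session")
def standins():
    return fixtures.standin_sequences()


@pytest.fixture()
def rng():
    return np.random.default_rng(20231208)


def random_family_spec(rng, max_rate=0.1, n_range=(4, 9), len_range=(80, 161)):
    """A random but valid synthetic-family spec (shared by several tests)."""
    from tubnum.synth import IndelEvent, SyntheticFamilySpec

    n = int(rng.integers(*n_range))
    L = int(rng.integers(*len_range))
    rate = float(rng.uniform(0, max_rate))
    rows = rng.choice(n, size=min(3, n), replace=False)
    events = []
    for k in range(int(rng.integers(0, 4))):
        kind = "insertion" if rng.random() < 0.5 else "deletion"
        length = int(rng.integers(1, 4))
        pos = (
            int(rng.integers(0, L + 1))
            if kind == "insertion"
            else int(rng.integers(1, L - length))
        )
        events.append(IndelEvent(int(rows[k]), pos, length, kind))
    try:
        return SyntheticFamilySpec(
            n, L, rate, tuple(events), seed=int(rng.integers(0, 2**31))
        )
    except ValueError:  # rare: randomly drawn events overlap
        return SyntheticFamilySpec(n, L, rate, (), seed=int(rng.integers(0, 2**31)))
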