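import numpy as np
import pytest

import censherit as ch


@pytest.fixture(scope="session")
def small_population() -> ch.SimulatedPopulation:
    """A modest nested-design population shared by read-only tests."""
    design = ch.SimulationDesign(
        n_sires=20,
        n_dams=30,
        offspring_per_family_sa=6,
        offspring_per_family_sw=8,
        seed=20210505,
    )
    return ch.simulate_population(design)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(987654321)


@pytest.fixture()
def fullsib_trio() -> ch.Pedigree:
    """Two unrelated founders with two fullsib offspring."""
    return ch.sort_pedigree(
        ch.Pedigree(
            animal=["s", "d", "x", "y"],
            sire=["", "", "s", "s"],
            dam=["", "", "d", "d"],
        )
    )


def kinship_oracle(ped: ch.Pedigree) -> np.ndarray:
    """Brute-force additive relationships by recursive expectation over
    transmitted gametes, memoized top-down (independent of the tabular
    builder, which works bottom-up over matrix rows)."""
    si, di = ped.parent_indices()
    memo: dict[tuple[int, int], float] = {}

    def a(i: int, j: int) -> float:
        if i < j:
            i, j = j, i
        key = (i, j)
        if key in memo:
            return memo[key]
        s, d = si[i], di[i]
        if i == j:
            val = 1.0 + (0.5 * a(s, d) if (s >= 0 and d >= 0) else 0.0)
        else:
            val = 0.5 * ((a(s, j) if s >= 0 else 0.0) + (a(d, j) if d >= 0 else 0.0))
        memo[key] = val
        return val

    n = len(ped)
    return np.array([[a(i, j) for j in range(n)] for i in range(n)])


def random_pedigree(rng: np.random.Generator, n_founders: int, n_offspring: int) -> ch.Pedigree:
    """Random multi-generation pedigree; parents always precede offspring."""
    animal = [f"P{i}" for i in range(n_founders)]
    sire = [""] * n_founders
    dam = [""] * n_founders
    for k in range(n_offspring):
        i = len(animal)
        p1, p2 = rng.integers(0, i, size=2)
        if p1 == p2:
            p2 = (p2 + 1) % i
        animal.append(f"P{i}")
        sire.append(f"P{min(p1, p2)}")
        dam.append(f"P{max(p1, p2)}")
    return ch.Pedigree(animal, sire, dam, is_sorted=True)
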