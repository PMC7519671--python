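import numpy as np
import pytest

from trpml.gsm import Reaction, StoichiometricModel
from trpml.library import default_catalog


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture
def toy_chain():
    """uptake ≤ 10 → A → B → {growth, trp}: carbon conservation forces the split."""
    return StoichiometricModel(
        metabolites=["A", "B"],
        reactions=[
            Reaction("uptake", {"A": 1}, 0, 10, ("gU",), "transport"),
            Reaction("conv", {"A": -1, "B": 1}, 0, 1000, ("gC",), "glycolysis"),
            Reaction("growth", {"B": -1}, 0, 1000, (), None),
            Reaction("trp", {"B": -1}, 0, 1000, ("gT",), "shikimate"),
        ],
        objective="growth",
        target="trp",
    )


def random_feasible_model(rng: np.random.Generator, n_extra: int = 8) -> StoichiometricModel:
    """Linear backbone plus random forward shortcut reactions (always feasible)."""
    k = 6
    mets = [f"M{i}" for i in range(k + 1)]
    rxns = [Reaction("uptake", {"M0": 1}, 0, float(rng.uniform(5, 15)), ("g_up",), "transport")]
    for i in range(k):
        rxns.append(
            Reaction(
                f"chain{i}",
                {mets[i]: -1, mets[i + 1]: 1},
                -1000 if rng.random() < 0.3 else 0,
                1000,
                (f"g{i}",),
                "glycolysis" if i < 3 else "ppp",
            )
        )
    for e in range(n_extra):
        i, j = sorted(rng.choice(k + 1, size=2, replace=False))
        rxns.append(
            Reaction(
                f"extra{e}",
                {mets[i]: -1, mets[j]: 1},
                0,
                float(rng.uniform(0.5, 5)),
                (f"ge{e}",),
                "ppp",
            )
        )
    rxns.append(Reaction("growth", {mets[k]: -1}, 0, 1000, (), None))
    j = int(rng.integers(2, k + 1))
    rxns.append(Reaction("trp", {mets[j]: -1}, 0, 1000, ("g_trp",), "shikimate"))
    return StoichiometricModel(metabolites=mets, reactions=rxns, objective="growth", target="trp")


@pytest.fixture
def model_factory():
    return random_feasible_model
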