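import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from promcat import BankSpec, Item, ItemBank, ThetaGrid, generate_bank


@pytest.fixture(scope="session")
def grid() -> ThetaGrid:
    return ThetaGrid.standard_normal()


@pytest.fixture
def dichotomous_item() -> Item:
    return Item("dich", "yes or no?", ("no", "yes"), 1.0, (0.0,))


@pytest.fixture
def polytomous_item() -> Item:
    return Item(
        "poly",
        "how often?",
        ("rarely", "sometimes", "often", "always"),
        1.5,
        (-1.0, 0.0, 1.0),
    )


@pytest.fixture
def small_bank(dichotomous_item, polytomous_item) -> ItemBank:
    extra = Item("third", "a third item", ("0", "1", "2"), 2.0, (-0.5, 0.8))
    return ItemBank((dichotomous_item, polytomous_item, extra), name="small")


@pytest.fixture(scope="session")
def synthetic_bank_20() -> ItemBank:
    """20-item, 4-category bank in the style of a short depression scale."""
    return generate_bank(BankSpec(n_items=20, n_categories=4, seed=7))


@pytest.fixture(scope="session")
def default_bank() -> ItemBank:
    """The default 100-item synthetic bank used by the validation experiments."""
    return generate_bank(BankSpec(seed=42))


def random_item(rng: np.random.Generator, item_id: str = "r") -> Item:
    """A random valid GRM item: 2-5 categories, lognormal a, sorted distinct b."""
    k = int(rng.integers(2, 6))
    a = float(np.exp(rng.normal(np.log(1.5), 0.4)))
    b = np.sort(rng.normal(0.0, 1.5, size=k - 1))
    b += np.arange(k - 1) * 0.05  # enforce strict separation
    return Item(item_id, "random", tuple(str(c) for c in range(k)), a, tuple(b))
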