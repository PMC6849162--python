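import random

import pytest

from farmatch.phonetics import PhoneticEncoder

# Misspelt variants of "fluoxetina" with their known edit distances, as
# printed in the source variant table (duplicates in the original kept).
FLUOXETINA_VARIANTS = [
    ("dfluoxetina", 1), ("flluoxetina", 1), ("floxetina", 1),
    ("fluoexetina", 1), ("fluoixetina", 1), ("fluopxetina", 1),
    ("fluoxertina", 1), ("fluoxetiina", 1), ("fluoxetijna", 1),
    ("fluoxetin", 1), ("fluoxetinas", 1), ("fluoxetna", 1),
    ("fluoxetona", 1), ("fluoxettina", 1), ("fluoxetuina", 1),
    ("fluoxewtina", 1), ("fluoxtina", 1), ("fluozxetina", 1),
    ("fluuoxetina", 1), ("fluuoxetina", 1), ("fluxetina", 1),
    ("fluyoxetina", 1), ("flhuoxetin", 2), ("flluoxetin", 2),
    ("flouxetina", 2), ("fluoxeitna", 2), ("fluoxetian", 2),
    ("fluxoetina", 2), ("fluxotina", 2), ("fluloextina", 3),
    ("fluoxetinaate", 3), ("fluoxetinapor", 3), ("flxtina", 3),
    ("fluoxetinapara", 4), ("infloexetina", 4),
]

# Syllables rich in homophone-substitution contexts, used to generate word
# lists for the phonetic-invariance properties.
_SYLLABLES = [
    "ca", "ço", "ça", "ssa", "sso", "sse", "ce", "ci", "za", "zo", "ze",
    "sa", "se", "si", "cha", "che", "xi", "xa", "que", "qui", "ke", "ki",
    "ha", "ho", "la", "lo", "ma", "me", "na", "no", "pa", "po", "ra", "re",
    "ta", "to", "va", "vi", "ba", "bo", "da", "do", "fa", "fo", "ga", "go",
]


def make_word_list(n: int, seed: int, min_syllables: int = 2, max_syllables: int = 5):
    """Seeded pseudo-Portuguese words built from context-rich syllables."""
    rng = random.Random(seed)
    words = set()
    while len(words) < n:
        k = rng.randint(min_syllables, max_syllables)
        words.add("".join(rng.choice(_SYLLABLES) for _ in range(k)))
    return sorted(words)


@pytest.fixture(scope="session")
def encoder():
    return PhoneticEncoder()


def brute_force_edit_distance(a: str, b: str) -> int:
    """Independent recursive Levenshtein oracle (memoized, tiny inputs only)."""
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def go(i: int, j: int) -> int:
        if i == 0:
            return j
        if j == 0:
            return i
        return min(
            go(i - 1, j) + 1,
            go(i, j - 1) + 1,
            go(i - 1, j - 1) + (a[i - 1] != b[j - 1]),
        )

    return go(len(a), len(b))
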