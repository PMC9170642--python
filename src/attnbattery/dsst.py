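"""Digit Symbol Substitution Test: form generation, scoring, and a
parametric simulated responder.

A form is a 93-box sequence of prompt digits (1-9, no two consecutive
prompts equal) plus a digit-to-symbol key.  Symbols are abstract integer
ids, not glyphs — scoring is glyph-independent.  The score is the number of
correctly substituted symbols produced within the time budget.
"""

from __future__ import annotations

from dataclasses import dataclass

from attnbattery.seeding import rng_from_seed

__all__ = [
    "FORM_LENGTH",
    "SymbolKey",
    "DSSTForm",
    "DSSTResponse",
    "DSSTScore",
    "generate_form",
    "score_dsst",
    "simulate_responder",
]

FORM_LENGTH = 93
N_DIGITS = 9


@dataclass(frozen=True)
class SymbolKey:
    """Bijective mapping of digits 1..9 to 9 distinct abstract symbol ids."""

    mapping: tuple[int, ...]  # mapping[d-1] is the symbol for digit d

    def __post_init__(self) -> None:
        if len(self.mapping) != N_DIGITS or len(set(self.mapping)) != N_DIGITS:
            raise ValueError("key must map 9 digits to 9 distinct symbols")

    def symbol_for(self, digit: int) -> int:
        if not 1 <= digit <= N_DIGITS:
            raise ValueError(f"digit must be in 1..{N_DIGITS}, got {digit}")
        return self.mapping[digit - 1]


@dataclass(frozen=True)
class DSSTForm:
    prompts: tuple[int, ...]
    key: SymbolKey


@dataclass(frozen=True)
class DSSTResponse:
    entries: tuple[int, ...]


@dataclass(frozen=True)
class DSSTScore:
    n_attempted: int
    n_correct: int


def generate_form(seed: int, length: int = FORM_LENGTH) -> DSSTForm:
    """Generate a form: ``length`` prompt digits uniform on 1..9 with no two
    consecutive prompts equal, and a fresh random symbol key."""
    rng = rng_from_seed(seed)
    key = SymbolKey(tuple(int(s) for s in rng.permutation(N_DIGITS) + 1))
    prompts: list[int] = []
    for _ in range(length):
        while True:
            d = int(rng.integers(1, N_DIGITS + 1))
            if not prompts or d != prompts[-1]:
                break
        prompts.append(d)
    return DSSTForm(prompts=tuple(prompts), key=key)


def score_dsst(form: DSSTForm, response: DSSTResponse) -> DSSTScore:
    """Count positions where the response symbol matches the keyed symbol."""
    if len(response.entries) > len(form.prompts):
        raise ValueError("response is longer than the form")
    n_correct = sum(
        1
        for prompt, entry in zip(form.prompts, response.entries)
        if entry == form.key.symbol_for(prompt)
    )
    return DSSTScore(n_attempted=len(response.entries), n_correct=n_correct)


def simulate_responder(
    form: DSSTForm,
    rate: float,
    error_prob: float,
    duration: float,
    seed: int,
) -> DSSTResponse:
    """Synthetic participant filling boxes left to right.

    Attempts ``floor(rate * duration)`` entries, capped at the form length;
    each entry is the correct symbol with probability ``1 - error_prob``,
    otherwise a uniformly chosen wrong symbol.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    if not 0.0 <= error_prob <= 1.0:
        raise ValueError("error_prob must be in [0, 1]")
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = rng_from_seed(seed)
    n_attempted = min(int(rate * duration), len(form.prompts))
    symbols = form.key.mapping
    entries: list[int] = []
    for i in range(n_attempted):
        correct = form.key.symbol_for(form.prompts[i])
        if error_prob > 0.0 and rng.random() < error_prob:
            wrong = [s for s in symbols if s != correct]
            entries.append(wrong[int(rng.integers(0, len(wrong)))])
        else:
            entries.append(correct)
    return DSSTResponse(entries=tuple(entries))
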