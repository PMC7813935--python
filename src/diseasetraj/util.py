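"""Shared conventions: age groups, half-year intervals, seed derivation."""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

#: 5-year age groups as recorded on claims rows ("0-4" ... "90-94", "95+").
AGE_GROUPS: tuple[str, ...] = tuple(
    f"{5 * i}-{5 * i + 4}" for i in range(19)
) + ("95+",)

_AGE_INDEX = {g: i for i, g in enumerate(AGE_GROUPS)}

#: Half-years per 5-year age group under the package's aging convention.
PERIODS_PER_AGE_GROUP = 10


def age_group_index(group: str) -> int:
    try:
        return _AGE_INDEX[group]
    except KeyError:
        raise ValueError(f"unknown age group {group!r}") from None


def age_group_midpoint_years(index: int) -> float:
    """Midpoint in years of an age group (97.5 for the open-ended 95+)."""
    return 5.0 * index + 2.5


@dataclass(frozen=True)
class HalfYearInterval:
    """Half-open interval [start, stop) of integer half-year indices."""

    start: int
    stop: int

    def __post_init__(self) -> None:
        if self.stop < self.start:
            raise ValueError(f"empty-ordered interval {self.start}-{self.stop}")

    def __contains__(self, t: int) -> bool:
        return self.start <= t < self.stop

    def __len__(self) -> int:
        return self.stop - self.start

    @classmethod
    def parse(cls, text: str) -> "HalfYearInterval":
        """Parse 'START-STOP' (half-open), e.g. '12-36'."""
        try:
            a, b = text.split("-")
            return cls(int(a), int(b))
        except (ValueError, AttributeError):
            raise ValueError(f"cannot parse half-year interval {text!r}") from None


def stratum_rng(seed: int, key: str) -> np.random.Generator:
    """Generator whose stream depends only on (seed, key).

    Used so that per-stratum randomness (e.g. matching draws) is unaffected by
    the presence or absence of other strata.
    """
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(key.encode("utf-8"))])
    )


def derived_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage child seed in [0, 2**31)."""
    ss = np.random.SeedSequence([int(seed), zlib.crc32(stage.encode("utf-8"))])
    return int(ss.generate_state(1, np.uint64)[0] % (2**31))
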