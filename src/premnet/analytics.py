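"""Closed-form expectations under random treatment-class assignment.

When every individual is independently labelled A or B, dyads and triads drawn
uniformly at random from the group are *less* likely to be single-class than a
naive ``p**2``-style argument suggests, because sampling is without
replacement from finite class tallies.  These expectations serve as analytic
null oracles for the simulator and the permutation engine: they assume uniform
sampling of dyads/triads and ignore heterogeneity in visitation rates.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb


@dataclass(frozen=True)
class ClassTally:
    """Sizes of the two treatment classes."""

    n_a: int
    n_b: int

    def __post_init__(self) -> None:
        if self.n_a < 0 or self.n_b < 0:
            raise ValueError("class sizes must be non-negative")

    @property
    def total(self) -> int:
        return self.n_a + self.n_b


def expected_same_class_fraction(tally: ClassTally) -> float:
    """Probability that a uniformly random dyad is same-class.

    ``[C(n_A, 2) + C(n_B, 2)] / C(n_A + n_B, 2)``.  For balanced classes of
    size n this is ``(n - 1) / (2 n - 1) < 1/2``: same-class dyads are rarer
    than different-class dyads purely by chance.
    """
    if tally.total < 2:
        raise ValueError("need at least two individuals to form a dyad")
    return (comb(tally.n_a, 2) + comb(tally.n_b, 2)) / comb(tally.total, 2)


def expected_uniform_triad_fraction(tally: ClassTally) -> float:
    """Probability that a uniformly random triad is single-class.

    ``[C(n_A, 3) + C(n_B, 3)] / C(n_A + n_B, 3)``.  For balanced classes the
    value lies below 1/4 and approaches 1/4 from below as the group grows,
    which is why single-class triads are expected to be under-represented
    relative to mixed triads under random mixing.
    """
    if tally.total < 3:
        raise ValueError("need at least three individuals to form a triad")
    return (comb(tally.n_a, 3) + comb(tally.n_b, 3)) / comb(tally.total, 3)
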