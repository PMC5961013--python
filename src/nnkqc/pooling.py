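"""Mixing proportions for a mixed adjusted-complexity library pool.

When libraries of different insert lengths are pooled, a short library's
diversity saturates (20^6 distinct 6-mers is far below a typical
transformant count) while a long library's does not.  Equalising phage
counts would then give each unique short peptide many more copies than each
unique long one.  The adjusted mix instead equalises copies per unique
clone: member i receives N_i phages with N_i / U_i constant, where U_i is
the member's effective unique-clone count.

U_i is the coupon-collector expectation of distinct clones among the
member's transformants, capped by the transformant count:
``U = C(1 - (1 - 1/C)^n)`` for n draws from C equiprobable types.  This is
an interpretation of "same number of copies per unique peptide" — a plain
mode using U_i = transformant_count_i directly is also available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import LibraryDesign, theoretical_complexity


def expected_unique(n_draws: int, complexity: int) -> float:
    """Expected number of distinct types after n uniform draws from C types.

    Computed as ``-C * expm1(n * log1p(-1/C))``, numerically stable for the
    astronomically large C of long NNK designs where (1 - 1/C)^n underflows
    naive evaluation.
    """
    if n_draws < 0:
        raise ValueError("n_draws must be >= 0")
    if complexity < 1:
        raise ValueError("complexity must be >= 1")
    if n_draws == 0:
        return 0.0
    if complexity == 1:
        return 1.0
    c = float(complexity)
    return float(-c * np.expm1(n_draws * np.log1p(-1.0 / c)))


@dataclass(frozen=True)
class PoolMember:
    design: LibraryDesign
    titer: float  # phage per unit volume
    transformant_count: int

    def __post_init__(self) -> None:
        if self.titer <= 0:
            raise ValueError("titer must be > 0")
        if self.transformant_count < 1:
            raise ValueError("transformant_count must be >= 1")


@dataclass(frozen=True)
class PoolSpec:
    members: tuple[PoolMember, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("pool needs at least one member")


def effective_unique(member: PoolMember, mode: str = "expected") -> float:
    """Effective unique-clone count U for one member.

    ``expected``: coupon-collector expectation at amino-acid complexity,
    capped by the transformant count.  ``plain``: the transformant count.
    """
    if mode == "plain":
        return float(member.transformant_count)
    if mode != "expected":
        raise ValueError(f"unknown mode {mode!r}")
    u = expected_unique(
        member.transformant_count, theoretical_complexity(member.design)
    )
    return min(u, float(member.transformant_count))


def adjusted_mix(
    spec: PoolSpec, target: float, mode: str = "expected"
) -> pd.DataFrame:
    """Per-member phage counts and volumes equalising copies per unique clone.

    Solves N_i = target * U_i / sum(U) so that N_i / U_i is constant and
    sum(N_i) = target; volumes are N_i / titer_i.
    """
    if target <= 0:
        raise ValueError("target must be > 0")
    u = np.array([effective_unique(m, mode) for m in spec.members])
    n = target * u / u.sum()
    return pd.DataFrame(
        {
            "library": [m.design.name for m in spec.members],
            "effective_unique": u,
            "phage_count": n,
            "copies_per_unique": n / u,
            "volume": n / np.array([m.titer for m in spec.members]),
        }
    )
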