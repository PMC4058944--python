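"""Enumeration of phased fetal inheritance patterns.

A phased inheritance pattern (PP) is the multiset of parental haplotypes
(labels drawn from ``{M_A, M_B, P_A, P_B}``) carried by the fetus at a locus.
Normal inheritance carries one maternal and one paternal haplotype; a de novo
duplication adds a third haplotype from one parent; a de novo deletion drops
one parent's contribution entirely.  The full enumeration has 20 members:
4 normal, 6 maternal duplications, 6 paternal duplications, 2 maternal
deletions and 2 paternal deletions.  ``|PP|`` (the multiset size) is the
fetal copy count at the locus: 1, 2 or 3.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from enum import Enum
from functools import lru_cache
from typing import Tuple


class IpClass(str, Enum):
    """The five inheritance-pattern classes."""

    NORMAL = "normal"
    MATERNAL_DUP = "maternal_dup"
    PATERNAL_DUP = "paternal_dup"
    MATERNAL_DEL = "maternal_del"
    PATERNAL_DEL = "paternal_del"

    @property
    def is_cnv(self) -> bool:
        return self is not IpClass.NORMAL


CNV_CLASSES = (
    IpClass.MATERNAL_DUP,
    IpClass.PATERNAL_DUP,
    IpClass.MATERNAL_DEL,
    IpClass.PATERNAL_DEL,
)

MATERNAL_LABELS = ("M_A", "M_B")
PATERNAL_LABELS = ("P_A", "P_B")

_SHORT = {"M_A": "MA", "M_B": "MB", "P_A": "PA", "P_B": "PB"}
_CLASS_TAG = {
    IpClass.NORMAL: "NORM",
    IpClass.MATERNAL_DUP: "MDUP",
    IpClass.PATERNAL_DUP: "PDUP",
    IpClass.MATERNAL_DEL: "MDEL",
    IpClass.PATERNAL_DEL: "PDEL",
}


@dataclass(frozen=True)
class PhasedPattern:
    """One fetal haplotype configuration.

    Parameters
    ----------
    fetal_haplotypes
        Ordered multiset (tuple, maternal labels first) of the parental
        haplotype labels the fetus carries.
    ip_class
        The inheritance-pattern class this configuration belongs to.
    """

    fetal_haplotypes: Tuple[str, ...]
    ip_class: IpClass

    @property
    def copy_count(self) -> int:
        """Fetal copy count |PP| at the locus (1, 2 or 3)."""
        return len(self.fetal_haplotypes)

    @property
    def maternal_labels(self) -> Tuple[str, ...]:
        return tuple(h for h in self.fetal_haplotypes if h in MATERNAL_LABELS)

    @property
    def paternal_labels(self) -> Tuple[str, ...]:
        return tuple(h for h in self.fetal_haplotypes if h in PATERNAL_LABELS)

    @property
    def name(self) -> str:
        """Serialized state name, e.g. ``"MDUP:MA+MB|PA"``."""
        mat = "+".join(_SHORT[h] for h in self.maternal_labels)
        pat = "+".join(_SHORT[h] for h in self.paternal_labels)
        return f"{_CLASS_TAG[self.ip_class]}:{mat or '-'}|{pat or '-'}"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


@lru_cache(maxsize=1)
def enumerate_patterns() -> Tuple[PhasedPattern, ...]:
    """Enumerate the 20 phased inheritance patterns in canonical order.

    The order is fixed and stable: the 4 normal states first, then the 6
    maternal duplications, 6 paternal duplications, 2 maternal deletions and
    2 paternal deletions.  All downstream transition/emission matrices index
    states in this order.
    """
    normal = [
        PhasedPattern((m, p), IpClass.NORMAL)
        for m in MATERNAL_LABELS
        for p in PATERNAL_LABELS
    ]
    # duplications: any multiset of two haplotypes from the duplicated parent
    # (combinations_with_replacement gives MA+MA, MA+MB, MB+MB) times either
    # haplotype of the other parent.
    mdup = [
        PhasedPattern((m1, m2, p), IpClass.MATERNAL_DUP)
        for p in PATERNAL_LABELS
        for m1, m2 in itertools.combinations_with_replacement(MATERNAL_LABELS, 2)
    ]
    pdup = [
        PhasedPattern((m, p1, p2), IpClass.PATERNAL_DUP)
        for m in MATERNAL_LABELS
        for p1, p2 in itertools.combinations_with_replacement(PATERNAL_LABELS, 2)
    ]
    mdel = [PhasedPattern((p,), IpClass.MATERNAL_DEL) for p in PATERNAL_LABELS]
    pdel = [PhasedPattern((m,), IpClass.PATERNAL_DEL) for m in MATERNAL_LABELS]
    return tuple(normal + mdup + pdup + mdel + pdel)


N_STATES = 20

# state index ranges per class in canonical order
CLASS_SLICES = {
    IpClass.NORMAL: slice(0, 4),
    IpClass.MATERNAL_DUP: slice(4, 10),
    IpClass.PATERNAL_DUP: slice(10, 16),
    IpClass.MATERNAL_DEL: slice(16, 18),
    IpClass.PATERNAL_DEL: slice(18, 20),
}


def state_classes() -> Tuple[IpClass, ...]:
    """ip_class of each of the 20 canonical states."""
    return tuple(p.ip_class for p in enumerate_patterns())


def state_copy_counts() -> Tuple[int, ...]:
    """|PP| of each of the 20 canonical states."""
    return tuple(p.copy_count for p in enumerate_patterns())
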