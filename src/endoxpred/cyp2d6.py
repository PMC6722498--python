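"""CYP2D6 star-allele activity classes, diplotype groups, and impaired status.

Each star allele carries one activity class (PM nonfunctional, IM reduced,
NM fully functional, UM increased). A diplotype (unordered pair of alleles)
is grouped by the order-normalised pair of classes; the seven groups seen in
the study cohort are NM/UM, NM/NM, NM/IM, NM/PM, IM/IM, IM/PM, PM/PM. For
modeling, carriers of at least one IM or PM allele are "impaired
metabolizers"; NM/NM and NM/UM are "normal metabolizers".
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import yaml


class ActivityClass(str, enum.Enum):
    PM = "PM"
    IM = "IM"
    NM = "NM"
    UM = "UM"


#: Display order used to normalise diplotype group labels (higher-activity
#: class printed first: NM/PM rather than PM/NM, but PM/PM stays PM/PM).
_CLASS_ORDER = {ActivityClass.UM: 0, ActivityClass.NM: 1, ActivityClass.IM: 2, ActivityClass.PM: 3}

#: The seven functional groups observed when the default allele table is
#: paired without UM x (IM|PM) combinations.
SEVEN_GROUPS = ("NM/UM", "NM/NM", "NM/IM", "NM/PM", "IM/IM", "IM/PM", "PM/PM")
IMPAIRED_GROUPS = ("NM/IM", "NM/PM", "IM/IM", "IM/PM", "PM/PM")
NORMAL_GROUPS = ("NM/UM", "NM/NM")


class UnknownAlleleError(KeyError):
    """Star allele absent from the configured activity table."""


def load_allele_table(path=None) -> dict[str, ActivityClass]:
    """Load a star-allele -> activity-class table from YAML.

    The YAML maps each class name (PM/IM/NM/UM) to a list of star-allele
    labels. Without ``path`` the packaged default table is used.
    """
    if path is None:
        text = resources.files("endoxpred.data").joinpath("cyp2d6_alleles.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    table: dict[str, ActivityClass] = {}
    for class_name, alleles in raw.items():
        cls = ActivityClass(class_name)
        for allele in alleles:
            if allele in table:
                raise ValueError(f"allele {allele!r} assigned to more than one activity class")
            table[str(allele)] = cls
    return table


_DEFAULT_TABLE: dict[str, ActivityClass] | None = None


def _default_table() -> dict[str, ActivityClass]:
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = load_allele_table()
    return _DEFAULT_TABLE


def classify_allele(star: str, table: Mapping[str, ActivityClass] | None = None) -> ActivityClass:
    """Activity class of one star allele; unknown alleles raise, never default."""
    table = table if table is not None else _default_table()
    try:
        return table[star]
    except KeyError:
        raise UnknownAlleleError(f"unrecognised CYP2D6 star allele {star!r}") from None


@dataclass(frozen=True)
class Diplotype:
    """A pair of star alleles with its functional group and impaired status.

    ``extrapolated`` flags UM-carrying combinations with an IM or PM allele
    (UM/IM, UM/PM) and UM/UM, which do not occur among the seven in-cohort
    groups; they are classified by the at-least-one-IM-or-PM rule.
    """

    allele1: str
    allele2: str
    class1: ActivityClass
    class2: ActivityClass
    group: str
    impaired: bool
    extrapolated: bool = False


def classify_diplotype(
    allele1: str, allele2: str, table: Mapping[str, ActivityClass] | None = None
) -> Diplotype:
    """Group a star-allele pair and derive the binary impaired status.

    Symmetric in its two allele arguments. Impaired iff at least one allele
    is IM or PM; NM/NM and NM/UM (and, by extrapolation, UM/UM) are normal.
    """
    c1 = classify_allele(allele1, table)
    c2 = classify_allele(allele2, table)
    first, second = sorted((c1, c2), key=_CLASS_ORDER.__getitem__)
    group = f"{first.value}/{second.value}" if first != ActivityClass.UM else f"{second.value}/{first.value}"
    impaired = ActivityClass.IM in (c1, c2) or ActivityClass.PM in (c1, c2)
    extrapolated = group not in SEVEN_GROUPS
    return Diplotype(allele1, allele2, c1, c2, group, impaired, extrapolated)


def group_impaired(group: str) -> bool:
    """Impaired status of a functional-group label (for pre-grouped data)."""
    if group in IMPAIRED_GROUPS:
        return True
    if group in NORMAL_GROUPS:
        return False
    raise ValueError(f"unrecognised CYP2D6 functional group {group!r}")
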