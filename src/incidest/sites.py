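"""ICD-10 cancer site groups used for national incidence estimation.

Sites are grouped into the standard GLOBOCAN-style rubric groups (head and
neck through leukaemia, plus an "Other and unspecified" catch-all). The
grouping partitions all malignant neoplasm rubrics C00-C97, excluding
non-melanoma skin (C44) which is conventionally dropped from registry
comparisons. Unspecified uterus (C55) is kept as a distinct staging group
until it is reallocated to cervix/corpus (see
:func:`incidest.tables.reallocate_unspecified_uterus`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

MALE = "male"
FEMALE = "female"
SEXES = (MALE, FEMALE)

#: Number of 5-year age bands: 0-4, 5-9, ..., 80-84, 85+.
N_AGE_GROUPS = 18
AGE_LABELS = tuple(f"{5 * i}-{5 * i + 4}" for i in range(17)) + ("85+",)
#: Midpoint (years) of each age band; 87.5 is used for the open-ended 85+ band.
AGE_MIDPOINTS = tuple(5.0 * i + 2.5 for i in range(17)) + (87.5,)

OTHER_SITE = "Other and unspecified"
UTERUS_UNSPECIFIED = "Uterus unspecified"
NON_MELANOMA_SKIN_CODE = "C44"


@dataclass(frozen=True)
class SiteGroup:
    """A named group of ICD-10 rubrics, possibly restricted to one sex."""

    name: str
    icd10_codes: tuple[str, ...]
    sexes: frozenset[str] = field(default_factory=lambda: frozenset(SEXES))

    def valid_for(self, sex: str) -> bool:
        return sex in self.sexes


def _codes(*specs: str) -> tuple[str, ...]:
    """Expand specs like "C18-C21" or "C15" into rubric tuples."""
    out: list[str] = []
    for spec in specs:
        if "-" in spec:
            lo, hi = spec.split("-")
            for n in range(int(lo[1:]), int(hi[1:]) + 1):
                out.append(f"C{n:02d}")
        else:
            out.append(spec)
    return tuple(out)


_F = frozenset({FEMALE})
_M = frozenset({MALE})

#: The site groups of the standard male/female comparison tables (21 male,
#: 23 female including the catch-all), in canonical display order.
SITE_GROUPS: tuple[SiteGroup, ...] = (
    SiteGroup("Head and neck", _codes("C00-C14")),
    SiteGroup("Oesophagus", _codes("C15")),
    SiteGroup("Stomach", _codes("C16")),
    SiteGroup("Colon-rectum", _codes("C18-C21")),
    SiteGroup("Liver", _codes("C22")),
    SiteGroup("Gallbladder", _codes("C23-C24")),
    SiteGroup("Pancreas", _codes("C25")),
    SiteGroup("Larynx", _codes("C32")),
    SiteGroup("Lung", _codes("C33-C34")),
    SiteGroup("Melanoma of skin", _codes("C43")),
    SiteGroup("Breast", _codes("C50"), _F),
    SiteGroup("Cervix uteri", _codes("C53"), _F),
    SiteGroup("Corpus uteri", _codes("C54"), _F),
    SiteGroup("Ovary", _codes("C56"), _F),
    SiteGroup("Prostate", _codes("C61"), _M),
    SiteGroup("Testis", _codes("C62"), _M),
    SiteGroup("Kidney", _codes("C64-C66"), frozenset(SEXES)),
    SiteGroup("Bladder", _codes("C67")),
    SiteGroup("Brain and CNS", _codes("C70-C72")),
    SiteGroup("Thyroid", _codes("C73")),
    SiteGroup("Hodgkin lymphoma", _codes("C81")),
    SiteGroup("Non-Hodgkin lymphoma", _codes("C82-C85", "C96")),
    SiteGroup("Multiple myeloma", _codes("C88", "C90")),
    SiteGroup("Leukaemia", _codes("C91-C95")),
)

#: Staging group for unspecified uterine cancers, used only upstream of
#: the C55 reallocation step.
UTERUS_UNSPECIFIED_GROUP = SiteGroup(UTERUS_UNSPECIFIED, _codes("C55"), _F)

_EXPLICIT: dict[str, SiteGroup] = {}
for _g in SITE_GROUPS + (UTERUS_UNSPECIFIED_GROUP,):
    for _c in _g.icd10_codes:
        if _c in _EXPLICIT:  # pragma: no cover - construction-time guard
            raise ValueError(f"ICD-10 rubric {_c} assigned to two groups")
    for _c in _g.icd10_codes:
        _EXPLICIT[_c] = _g

OTHER_GROUP = SiteGroup(
    OTHER_SITE,
    tuple(
        f"C{n:02d}"
        for n in range(98)
        if f"C{n:02d}" not in _EXPLICIT and f"C{n:02d}" != NON_MELANOMA_SKIN_CODE
    ),
)

CODE_TO_GROUP: dict[str, SiteGroup] = dict(_EXPLICIT)
for _c in OTHER_GROUP.icd10_codes:
    CODE_TO_GROUP[_c] = OTHER_GROUP

GROUPS_BY_NAME: dict[str, SiteGroup] = {
    g.name: g for g in SITE_GROUPS + (UTERUS_UNSPECIFIED_GROUP, OTHER_GROUP)
}


def site_names(sex: str | None = None, include_other: bool = True) -> list[str]:
    """Canonical ordered site-group names, optionally restricted to one sex."""
    names = [g.name for g in SITE_GROUPS if sex is None or g.valid_for(sex)]
    if include_other:
        names.append(OTHER_SITE)
    return names


def group_for(site_or_code: str) -> SiteGroup:
    """Resolve a group name or raw ICD-10 rubric to its :class:`SiteGroup`.

    Raises ``KeyError`` for non-melanoma skin (C44, excluded by convention)
    and for labels that are neither a known group nor a C rubric.
    """
    token = site_or_code.strip()
    if token in GROUPS_BY_NAME:
        return GROUPS_BY_NAME[token]
    code = token.upper().split(".")[0]  # accept 4-character rubrics like C18.2
    if code in CODE_TO_GROUP:
        return CODE_TO_GROUP[code]
    raise KeyError(site_or_code)


#: Pseudo-site for all cancers combined (used by frequency partitioning).
ALL_SITES = "all"


def valid_sex_site(sex: str, site: str) -> bool:
    """True when ``site`` (group name or code) may occur for ``sex``."""
    if site == ALL_SITES:
        return sex in SEXES
    try:
        return group_for(site).valid_for(sex)
    except KeyError:
        return False
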