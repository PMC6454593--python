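"""The virtual gender model.

Gender requirements of a clinical trial are expressed over two axes:
the *transgender* axis (participants whose gender identity differs from
their sex assigned at birth) and the *biological* axis (everyone else).
Evidence found in text is represented as :class:`CompositeGender` values
(six labels, the ``*_ALL`` ones splittable), atomic evidence as the four
:class:`MetaGender` values, and the final per-trial requirement as a
:class:`GenderType` — one of 13 renderable labels: the 3x4 product of a
transgender component {Male, Female, All} with a biological component
{none, Male, Female, All}, plus the single collapsed ``Biological`` type
for trials with no transgender requirement at all.

The judgement functions (:func:`split_judgement`, :func:`sub_judgement`,
...) and transformation functions (:func:`split`, :func:`merge`,
:func:`trans_constrain`) encode the relations between these labels and
are the primitives the summarizer reasons with.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass


class MetaGender(enum.Enum):
    """The four atomic evidence categories composite labels split into."""

    TRANSGENDER_MALE = "Transgender Male"
    TRANSGENDER_FEMALE = "Transgender Female"
    BIOLOGICAL_MALE = "Biological Male"
    BIOLOGICAL_FEMALE = "Biological Female"

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"MetaGender.{self.name}"


#: Fixed order used for deterministic ranking tie-breaks.
META_ORDER = (
    MetaGender.TRANSGENDER_MALE,
    MetaGender.TRANSGENDER_FEMALE,
    MetaGender.BIOLOGICAL_MALE,
    MetaGender.BIOLOGICAL_FEMALE,
)


class Axis(enum.Enum):
    TRANSGENDER = "Transgender"
    BIOLOGICAL = "Biological"


class Sex(enum.Enum):
    MALE = "Male"
    FEMALE = "Female"
    ALL = "All"


class CompositeLabel(enum.Enum):
    """The six composite evidence labels (meta labels plus the two ``*_ALL``)."""

    TRANSGENDER_MALE = ("Transgender", "Male")
    TRANSGENDER_FEMALE = ("Transgender", "Female")
    TRANSGENDER_ALL = ("Transgender", "All")
    BIOLOGICAL_MALE = ("Biological", "Male")
    BIOLOGICAL_FEMALE = ("Biological", "Female")
    BIOLOGICAL_ALL = ("Biological", "All")

    @property
    def axis(self) -> Axis:
        return Axis(self.value[0])

    @property
    def sex(self) -> Sex:
        return Sex(self.value[1])

    def render(self) -> str:
        return f"{self.value[0]} {self.value[1]}"

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"CompositeLabel.{self.name}"


@dataclass(frozen=True)
class CompositeGender:
    """A composite evidence label plus its negation flag."""

    label: CompositeLabel
    negated: bool = False


def _as_label(g: CompositeGender | CompositeLabel) -> CompositeLabel:
    return g.label if isinstance(g, CompositeGender) else g


def split_judgement(g: CompositeGender | CompositeLabel) -> bool:
    """True iff ``g`` is an ``*_ALL`` label and can therefore be split."""
    return _as_label(g).sex is Sex.ALL


def sub_judgement(
    g1: CompositeGender | CompositeLabel, g2: CompositeGender | CompositeLabel
) -> bool:
    """True iff ``g1`` is a subordinate gender of ``g2``.

    Holds exactly when both labels lie on the same axis, ``g2`` is the
    ``*_ALL`` of that axis and ``g1`` is one of its sexed members.
    """
    l1, l2 = _as_label(g1), _as_label(g2)
    return l1.axis is l2.axis and l2.sex is Sex.ALL and l1.sex is not Sex.ALL


def super_judgement(
    g1: CompositeGender | CompositeLabel, g2: CompositeGender | CompositeLabel
) -> bool:
    """True iff ``g1`` is a superior gender of ``g2`` (converse of sub)."""
    return sub_judgement(g2, g1)


def reverse_judgement(
    g1: CompositeGender | CompositeLabel, g2: CompositeGender | CompositeLabel
) -> bool:
    """True iff the two labels differ."""
    return _as_label(g1) is not _as_label(g2)


def similar_judgement(
    g1: CompositeGender | CompositeLabel, g2: CompositeGender | CompositeLabel
) -> bool:
    """True iff both labels lie on the same category axis."""
    return _as_label(g1).axis is _as_label(g2).axis


class GenderModelError(ValueError):
    """A transformation was applied outside its parameter restrictions."""


def split(g: CompositeGender | CompositeLabel) -> tuple[CompositeGender, CompositeGender]:
    """Split an ``*_ALL`` label into its MALE and FEMALE members, in that order.

    The negation flag (when the input carries one) propagates to both halves.
    """
    if not split_judgement(g):
        raise GenderModelError(f"{_as_label(g).render()!r} is not splittable")
    negated = g.negated if isinstance(g, CompositeGender) else False
    axis = _as_label(g).axis
    male = CompositeLabel((axis.value, "Male"))
    female = CompositeLabel((axis.value, "Female"))
    return CompositeGender(male, negated), CompositeGender(female, negated)


def merge(
    g1: CompositeGender | CompositeLabel, g2: CompositeGender | CompositeLabel
) -> CompositeGender:
    """Merge two distinct sexed labels of one axis into that axis's ``*_ALL``."""
    if split_judgement(g1) or split_judgement(g2):
        raise GenderModelError("merge arguments must not be splittable")
    if not similar_judgement(g1, g2):
        raise GenderModelError("merge arguments must lie on the same axis")
    if not reverse_judgement(g1, g2):
        raise GenderModelError("merge arguments must be distinct labels")
    negated = (
        g1.negated and g2.negated
        if isinstance(g1, CompositeGender) and isinstance(g2, CompositeGender)
        else False
    )
    return CompositeGender(CompositeLabel((_as_label(g1).axis.value, "All")), negated)


_TRANS_CONSTRAIN = {
    CompositeLabel.BIOLOGICAL_MALE: CompositeLabel.TRANSGENDER_FEMALE,
    CompositeLabel.BIOLOGICAL_FEMALE: CompositeLabel.TRANSGENDER_MALE,
    CompositeLabel.BIOLOGICAL_ALL: CompositeLabel.TRANSGENDER_ALL,
}


def trans_constrain(g: CompositeGender | CompositeLabel) -> CompositeGender:
    """Transform a biological label into the transgender type it implies.

    The assigned sex flips to the identified gender: a person assigned
    male at birth who is in a transgender context identifies as female.
    """
    label = _as_label(g)
    if label.axis is not Axis.BIOLOGICAL:
        raise GenderModelError("trans_constrain requires a biological-axis label")
    negated = g.negated if isinstance(g, CompositeGender) else False
    return CompositeGender(_TRANS_CONSTRAIN[label], negated)


class Component(enum.Enum):
    """One axis component of a final :class:`GenderType`."""

    NONE = "None"
    MALE = "Male"
    FEMALE = "Female"
    ALL = "All"


class Conventional(enum.Enum):
    """The registry-style structured sex options."""

    MALE = "Male"
    FEMALE = "Female"
    ALL = "All"


@dataclass(frozen=True)
class GenderType:
    """A final 13-type label: a transgender and a biological component.

    Any value with ``transgender_component == NONE`` renders as the single
    collapsed ``'Biological'`` label; the biological component is still
    retained as the underlying sex evidence for the conventional mapping.
    """

    transgender_component: Component
    biological_component: Component

    def __post_init__(self) -> None:
        if (
            self.transgender_component is Component.NONE
            and self.biological_component is Component.NONE
        ):
            raise GenderModelError("GenderType components cannot both be NONE")

    @property
    def label(self) -> str:
        if self.transgender_component is Component.NONE:
            return "Biological"
        parts = [f"Transgender {self.transgender_component.value}"]
        if self.biological_component is not Component.NONE:
            parts.append(f"Biological {self.biological_component.value}")
        return ", ".join(parts)

    def __str__(self) -> str:
        return self.label


#: Renderable label strings of the 13-type model.
ALL_LABELS: tuple[str, ...] = tuple(
    dict.fromkeys(
        GenderType(tg, bio).label
        for tg in Component
        for bio in Component
        if not (tg is Component.NONE and bio is Component.NONE)
    )
)


def _component_of(members: set[Sex]) -> Component:
    if not members:
        return Component.NONE
    if members == {Sex.MALE}:
        return Component.MALE
    if members == {Sex.FEMALE}:
        return Component.FEMALE
    return Component.ALL


def compose_label(kept: set[MetaGender] | frozenset[MetaGender]) -> GenderType:
    """Compose the kept meta genders into one of the 13 final labels.

    Two sexed members of one axis merge (via :func:`merge`) to that axis's
    ALL component; a set with no transgender member collapses to the
    'Biological' type while retaining the sex evidence.
    """
    if not kept:
        raise GenderModelError("cannot compose a label from no evidence")
    axes: dict[Axis, set[Sex]] = {Axis.TRANSGENDER: set(), Axis.BIOLOGICAL: set()}
    for mg in kept:
        label = CompositeLabel[mg.name]
        axes[label.axis].add(label.sex)
    # pairwise merge of both sexed members is exactly the ALL component
    for axis, sexes in axes.items():
        if sexes == {Sex.MALE, Sex.FEMALE}:
            merged = merge(
                CompositeLabel((axis.value, "Male")), CompositeLabel((axis.value, "Female"))
            )
            axes[axis] = {merged.label.sex}
    return GenderType(
        _component_of(axes[Axis.TRANSGENDER]), _component_of(axes[Axis.BIOLOGICAL])
    )


_IDENTITY_SEXES = {
    Component.NONE: set(),
    Component.MALE: {Sex.MALE},
    Component.FEMALE: {Sex.FEMALE},
    Component.ALL: {Sex.MALE, Sex.FEMALE},
}

_ASSIGNED_SEXES = {
    Component.NONE: set(),
    Component.MALE: {Sex.FEMALE},
    Component.FEMALE: {Sex.MALE},
    Component.ALL: {Sex.MALE, Sex.FEMALE},
}


def to_conventional(g: GenderType, by_identity: bool = True) -> Conventional:
    """Map a 13-type label to the registry's Male/Female/All options.

    Transgender components map by gender identity by default (a trial for
    transgender women registers as Female); set ``by_identity=False`` to
    map by sex assigned at birth instead.
    """
    tg_map = _IDENTITY_SEXES if by_identity else _ASSIGNED_SEXES
    sexes = set(tg_map[g.transgender_component])
    sexes |= _IDENTITY_SEXES[g.biological_component]
    if sexes == {Sex.MALE}:
        return Conventional.MALE
    if sexes == {Sex.FEMALE}:
        return Conventional.FEMALE
    return Conventional.ALL
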