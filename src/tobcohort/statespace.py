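"""Tobacco-use state machine: use categories, duration memory and allowed edges.

A cohort member occupies exactly one *expanded state* per 5-year step: a use
category (never user, current smoker, current moist-smokeless-tobacco (MST)
user, dual user, or one of the former-use categories) together with a
duration profile counting, in 5-year bins, years smoked (YSM), years since
quitting smoking (YQSM), years of MST use, and years since quitting MST.
Duration memory is what lets the mortality component assign pathway-specific
risk: a smoker who switched to MST carries both a smoking history and an
ongoing MST exposure.

The set of permitted category-to-category moves is an :class:`EdgeCatalogue`.
Staying put is never an explicit edge; it is the residual probability after
all outgoing flows. Two *diversion* edges — the "would-be smoker"
(never-user initiates MST instead of cigarettes) and "would-be quitter"
(smoker switches to MST instead of quitting) — share endpoints with the
ordinary initiation/switching edges but are catalogued separately because
scenario derivation reroutes flow through them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, NamedTuple

import pandas as pd

__all__ = [
    "UseCategory",
    "DurationProfile",
    "ExpandedState",
    "Edge",
    "EdgeCatalogue",
    "build_default_catalogue",
    "step_state",
    "SMOKING_CATEGORIES",
    "MST_CATEGORIES",
]


class UseCategory(str, Enum):
    """Tobacco-use category of a cohort member."""

    NEVER = "NEVER"
    CUR_CIG = "CUR_CIG"
    CUR_MST = "CUR_MST"
    DUAL = "DUAL"
    FORMER_CIG = "FORMER_CIG"
    FORMER_MST = "FORMER_MST"
    FORMER_DUAL = "FORMER_DUAL"
    FORMER_ALL = "FORMER_ALL"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: categories in which cigarettes are actively smoked (accumulate YSM)
SMOKING_CATEGORIES = frozenset({UseCategory.CUR_CIG, UseCategory.DUAL})
#: categories in which MST is actively used (accumulate MST duration)
MST_CATEGORIES = frozenset({UseCategory.CUR_MST, UseCategory.DUAL})


class DurationProfile(NamedTuple):
    """Duration memory in 5-year bins.

    ``ysm_bins``   — bins spent smoking cigarettes (YSM / 5).
    ``yqsm_bins``  — bins elapsed since last smoking (YQSM / 5).
    ``mst_bins``   — bins spent using MST.
    ``yq_mst_bins``— bins elapsed since last MST use.
    """

    ysm_bins: int = 0
    yqsm_bins: int = 0
    mst_bins: int = 0
    yq_mst_bins: int = 0

    def validate(self) -> None:
        if any(b < 0 for b in self):
            raise ValueError(f"duration bins must be non-negative, got {self}")
        if self.yqsm_bins > 0 and self.ysm_bins == 0:
            raise ValueError("yqsm_bins > 0 requires ysm_bins > 0")
        if self.yq_mst_bins > 0 and self.mst_bins == 0:
            raise ValueError("yq_mst_bins > 0 requires mst_bins > 0")


class ExpandedState(NamedTuple):
    """A use category together with its duration memory."""

    category: UseCategory
    durations: DurationProfile = DurationProfile()

    @property
    def ysm_years(self) -> float:
        return 5.0 * self.durations.ysm_bins

    @property
    def yqsm_years(self) -> float:
        return 5.0 * self.durations.yqsm_bins

    @property
    def mst_years(self) -> float:
        return 5.0 * self.durations.mst_bins

    @property
    def yq_mst_years(self) -> float:
        return 5.0 * self.durations.yq_mst_bins


class Edge(NamedTuple):
    """A permitted category-to-category transition."""

    source: UseCategory
    target: UseCategory
    label: str = ""

    @property
    def pair(self) -> tuple[UseCategory, UseCategory]:
        return (self.source, self.target)


@dataclass
class EdgeCatalogue:
    """The set of permitted transitions between use categories.

    No self-loop is listed explicitly: remaining in a category is the
    residual probability after all outgoing flows at that age.
    """

    edges: list[Edge] = field(default_factory=list)

    def __post_init__(self) -> None:
        for e in self.edges:
            if e.source == e.target:
                raise ValueError(f"self-loop {e.source}->{e.target} not permitted")

    @property
    def categories(self) -> set[UseCategory]:
        cats = {UseCategory.NEVER, UseCategory.CUR_CIG}
        for e in self.edges:
            cats.add(e.source)
            cats.add(e.target)
        return cats

    @property
    def pairs(self) -> set[tuple[UseCategory, UseCategory]]:
        return {e.pair for e in self.edges}

    def contains(self, source: UseCategory, target: UseCategory) -> bool:
        return (source, target) in self.pairs

    def outgoing(self, source: UseCategory) -> list[Edge]:
        return [e for e in self.edges if e.source == source]

    def by_label(self, label: str) -> Edge:
        for e in self.edges:
            if e.label == label:
                return e
        raise KeyError(f"no edge labelled {label!r}")

    # -- serialization -----------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.source.value, e.target.value, e.label) for e in self.edges],
            columns=["from_category", "to_category", "label"],
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "EdgeCatalogue":
        edges = [
            Edge(UseCategory(r.from_category), UseCategory(r.to_category), str(r.label))
            for r in frame.itertuples()
        ]
        return cls(edges)

    @classmethod
    def from_csv(cls, path) -> "EdgeCatalogue":
        return cls.from_frame(pd.read_csv(path, keep_default_na=False))


def build_default_catalogue(*, include_relapse: bool = True) -> EdgeCatalogue:
    """Default transition-edge enumeration for a cigarettes-plus-MST market.

    Covers initiation to either product, switching, dual-use uptake and
    resolution, cessation from every current-use category, relapse from the
    former categories (rates default to zero in bundled tables), and the two
    scenario diversion edges. With 5-year duration bins over a 13→103
    horizon this category set expands to the finite state space the cohort
    engine propagates.
    """
    C = UseCategory
    edges = [
        Edge(C.NEVER, C.CUR_CIG, "cig_initiation"),
        Edge(C.NEVER, C.CUR_MST, "mst_initiation"),
        Edge(C.CUR_CIG, C.CUR_MST, "switching"),
        Edge(C.CUR_CIG, C.DUAL, "dual_uptake"),
        Edge(C.CUR_MST, C.DUAL, "dual_uptake_from_mst"),
        Edge(C.DUAL, C.CUR_MST, "dual_to_mst"),
        Edge(C.DUAL, C.CUR_CIG, "dual_to_cig"),
        Edge(C.CUR_CIG, C.FORMER_CIG, "cig_cessation"),
        Edge(C.CUR_MST, C.FORMER_MST, "mst_cessation"),
        Edge(C.DUAL, C.FORMER_DUAL, "dual_cessation"),
        # diversion edges: same endpoints as mst_initiation / switching but
        # catalogued separately so scenario derivation can reroute flow
        Edge(C.NEVER, C.CUR_MST, "would_be_smoker"),
        Edge(C.CUR_CIG, C.CUR_MST, "would_be_quitter"),
    ]
    if include_relapse:
        edges += [
            Edge(C.FORMER_CIG, C.CUR_CIG, "cig_relapse"),
            Edge(C.FORMER_MST, C.CUR_MST, "mst_relapse"),
            Edge(C.FORMER_DUAL, C.DUAL, "dual_relapse"),
        ]
    return EdgeCatalogue(edges)


def _advance_durations(d: DurationProfile, source: UseCategory) -> DurationProfile:
    """Advance duration bins for one 5-year interval spent in ``source``."""
    ysm, yqsm, mst, yqm = d
    if source in SMOKING_CATEGORIES:
        ysm += 1
    elif ysm > 0:
        yqsm += 1
    if source in MST_CATEGORIES:
        mst += 1
    elif mst > 0:
        yqm += 1
    return DurationProfile(ysm, yqsm, mst, yqm)


def step_state(
    state: ExpandedState,
    edge: Edge | tuple[UseCategory, UseCategory] | None = None,
    catalogue: EdgeCatalogue | None = None,
) -> ExpandedState:
    """Advance an expanded state by one 5-year step.

    Duration bins advance according to the *source* category occupied during
    the interval (smoking categories accrue YSM, MST categories accrue MST
    time, abstinent spells accrue the corresponding since-quit clocks), and
    the category then becomes the edge target; ``edge=None`` means staying.

    Raises ``ValueError`` for an edge whose source does not match ``state``
    or, when a catalogue is given, an edge not in it.
    """
    if edge is None:
        target = state.category
    else:
        source, target = (edge.source, edge.target) if isinstance(edge, Edge) else edge
        if source != state.category:
            raise ValueError(
                f"edge ({source}->{target}) does not start at occupied category "
                f"{state.category}"
            )
        if catalogue is not None and (source, target) not in catalogue.pairs:
            raise ValueError(f"illegal transition ({source}->{target}): not in catalogue")
    return ExpandedState(target, _advance_durations(state.durations, state.category))


def reachable_states(
    catalogue: EdgeCatalogue, n_steps: int, start: ExpandedState | None = None
) -> set[ExpandedState]:
    """Enumerate every expanded state reachable within ``n_steps`` steps."""
    if start is None:
        start = ExpandedState(UseCategory.NEVER)
    frontier = {start}
    seen = {start}
    for _ in range(n_steps):
        nxt: set[ExpandedState] = set()
        for s in frontier:
            nxt.add(step_state(s))
            for e in catalogue.outgoing(s.category):
                nxt.add(step_state(s, e))
        frontier = nxt - seen
        seen |= nxt
    return seen
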