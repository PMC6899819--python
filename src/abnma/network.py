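"""Arm-level network meta-analysis data structures and readers.

A network meta-analysis (NMA) dataset is a collection of randomized studies,
each contributing two or more *arms* (treatment groups).  For a binary
outcome, arm ``k`` of study ``i`` contributes the number of events ``y_ik``
out of ``n_ik`` participants.  The set of treatments compared in a study is
its *design*.  Everything downstream (model fitting, estimands) consumes the
:class:`Network` container defined here.

The inhaled-corticosteroids network (18 two-arm trials of seven inhaled
corticosteroids versus placebo, outcome = elimination of oral corticosteroid
use) ships as a packaged fixture; see :func:`load_corticosteroids`.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "ArmRecord",
    "Network",
    "DesignSummary",
    "NetworkValidationError",
    "read_network",
    "write_network",
    "read_wide_two_arm",
    "network_from_frame",
    "load_corticosteroids",
    "summarize_designs",
    "is_star",
    "count_zero_event_arms",
    "labbe_points",
]

#: Treatment coding of the packaged corticosteroids network.
CORTICOSTEROID_TREATMENTS = {
    1: "placebo",
    2: "beclomethasone",
    3: "budesonide",
    4: "ciclesonide",
    5: "flunisolide",
    6: "fluticasone",
    7: "mometasone",
    8: "triamcinolone",
}


class NetworkValidationError(ValueError):
    """Raised when arm-level data violate the Network invariants."""


@dataclass(frozen=True)
class ArmRecord:
    """One treatment arm of one study: ``events`` successes out of ``size``."""

    study_id: object
    treatment_id: int
    events: int
    size: int

    def __post_init__(self) -> None:
        if self.size < 1:
            raise NetworkValidationError(
                f"arm (study={self.study_id}, treatment={self.treatment_id}): "
                f"size must be >= 1, got {self.size}"
            )
        if self.events < 0 or self.events > self.size:
            raise NetworkValidationError(
                f"arm (study={self.study_id}, treatment={self.treatment_id}): "
                f"events={self.events} outside [0, size={self.size}]"
            )


@dataclass(frozen=True)
class DesignSummary:
    """A unique study design (treatment set) and how many studies use it."""

    design: tuple[int, ...]
    count: int


@dataclass
class Network:
    """A validated arm-level NMA dataset.

    Treatment ids are dense integers ``1..K``; if the input labels are not
    already of that form they are relabeled (preserving sort order) and the
    map is kept in :attr:`treatment_labels` (new id -> original label).
    """

    arms: tuple[ArmRecord, ...]
    reference_treatment: int = 1
    treatment_labels: dict[int, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.arms:
            raise NetworkValidationError("network has no arms")
        seen: set[tuple[object, int]] = set()
        for arm in self.arms:
            key = (arm.study_id, arm.treatment_id)
            if key in seen:
                raise NetworkValidationError(
                    f"duplicate arm for study {arm.study_id}, "
                    f"treatment {arm.treatment_id}"
                )
            seen.add(key)
        treatments = sorted({a.treatment_id for a in self.arms})
        if treatments != list(range(1, len(treatments) + 1)):
            raise NetworkValidationError(
                f"treatment ids must be dense 1..K, got {treatments}; "
                "use network_from_frame to relabel"
            )
        for sid in self.study_ids:
            if len(self.design_of(sid)) < 2:
                raise NetworkValidationError(
                    f"study {sid} has fewer than two distinct treatments"
                )

    # -- basic accessors ---------------------------------------------------

    @property
    def study_ids(self) -> tuple[object, ...]:
        out, seen = [], set()
        for arm in self.arms:
            if arm.study_id not in seen:
                seen.add(arm.study_id)
                out.append(arm.study_id)
        return tuple(out)

    @property
    def n_studies(self) -> int:
        return len(self.study_ids)

    @property
    def n_treatments(self) -> int:
        return max(a.treatment_id for a in self.arms)

    @property
    def n_arms(self) -> int:
        return len(self.arms)

    def design_of(self, study_id: object) -> tuple[int, ...]:
        """The design R_i of a study, as a sorted treatment tuple."""
        return tuple(
            sorted(a.treatment_id for a in self.arms if a.study_id == study_id)
        )

    @property
    def designs(self) -> dict[object, tuple[int, ...]]:
        return {sid: self.design_of(sid) for sid in self.study_ids}

    def study_arms(self, study_id: object) -> tuple[ArmRecord, ...]:
        return tuple(a for a in self.arms if a.study_id == study_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "study": [a.study_id for a in self.arms],
                "treatment": [a.treatment_id for a in self.arms],
                "events": [a.events for a in self.arms],
                "size": [a.size for a in self.arms],
            }
        )


# -- construction ----------------------------------------------------------


def network_from_frame(
    frame: pd.DataFrame, reference_treatment: object = 1
) -> Network:
    """Build a :class:`Network` from a long table.

    Requires columns ``study``, ``treatment``, ``events``, ``size`` (one row
    per arm).  Treatment labels are mapped to dense integers ``1..K``: labels
    already equal to ``1..K`` are kept as-is (preserving an existing
    published coding), otherwise
    labels are sorted, with the requested reference treatment first.
    """
    required = {"study", "treatment", "events", "size"}
    missing = required - set(frame.columns)
    if missing:
        raise NetworkValidationError(f"missing columns: {sorted(missing)}")
    if len(frame) == 0:
        raise NetworkValidationError("empty table")

    labels = sorted(frame["treatment"].unique(), key=lambda x: (str(type(x)), x))
    if set(labels) == set(range(1, len(labels) + 1)):
        if reference_treatment not in range(1, len(labels) + 1):
            raise NetworkValidationError(
                f"reference treatment {reference_treatment!r} not in network"
            )
        mapping = {t: t for t in labels}
        ref = int(reference_treatment)
    else:
        if reference_treatment not in labels:
            raise NetworkValidationError(
                f"reference treatment {reference_treatment!r} not in network"
            )
        ordered = [reference_treatment] + [
            t for t in labels if t != reference_treatment
        ]
        mapping = {label: i + 1 for i, label in enumerate(ordered)}
        ref = 1

    arms = []
    for row in frame.itertuples(index=False):
        try:
            arms.append(
                ArmRecord(
                    study_id=row.study,
                    treatment_id=int(mapping[row.treatment]),
                    events=int(row.events),
                    size=int(row.size),
                )
            )
        except NetworkValidationError as err:
            raise NetworkValidationError(
                f"row (study={row.study}, treatment={row.treatment}, "
                f"events={row.events}, size={row.size}): {err}"
            ) from None
    inverse = {v: k for k, v in mapping.items()}
    return Network(
        arms=tuple(arms), reference_treatment=ref, treatment_labels=inverse
    )


def read_network(path, reference_treatment: object = 1) -> Network:
    """Read a headered arm-level CSV (columns study,treatment,events,size)."""
    frame = pd.read_csv(path)
    return network_from_frame(frame, reference_treatment=reference_treatment)


def write_network(net: Network, path) -> None:
    """Write the arm-level CSV; read_network(write_network(x)) round-trips."""
    net.to_frame().to_csv(path, index=False)


def read_wide_two_arm(path) -> Network:
    """Read a wide two-arm table, one study per row.

    Columns: ``study, treatment1, events1, size1, treatment2, events2, size2``
    (mirroring a printed active-arm/control-arm layout).
    """
    wide = pd.read_csv(path)
    rows = []
    for row in wide.itertuples(index=False):
        rows.append((row.study, row.treatment1, row.events1, row.size1))
        rows.append((row.study, row.treatment2, row.events2, row.size2))
    frame = pd.DataFrame(rows, columns=["study", "treatment", "events", "size"])
    return network_from_frame(frame)


def load_corticosteroids() -> Network:
    """The packaged inhaled-corticosteroids network (18 trials, 8 treatments).

    Treatment coding: 1 placebo, 2 beclomethasone, 3 budesonide,
    4 ciclesonide, 5 flunisolide, 6 fluticasone, 7 mometasone,
    8 triamcinolone.  Four placebo arms have zero events; the exact binomial
    likelihood used by the models handles them without continuity correction.
    """
    ref = importlib.resources.files("abnma") / "datasets" / "corticosteroids.csv"
    with importlib.resources.as_file(ref) as path:
        net = read_network(path)
    net.treatment_labels = dict(CORTICOSTEROID_TREATMENTS)
    return net


# -- summaries -------------------------------------------------------------


def summarize_designs(net: Network) -> list[DesignSummary]:
    """Unique designs with study counts, in lexicographic design order."""
    counts: dict[tuple[int, ...], int] = {}
    for sid in net.study_ids:
        d = net.design_of(sid)
        counts[d] = counts.get(d, 0) + 1
    return [DesignSummary(design=d, count=counts[d]) for d in sorted(counts)]


def is_star(net: Network) -> bool:
    """True iff every design contains the reference treatment."""
    ref = net.reference_treatment
    return all(ref in d for d in net.designs.values())


def count_zero_event_arms(net: Network, treatment: int) -> int:
    """Number of arms of ``treatment`` with zero events."""
    if treatment not in range(1, net.n_treatments + 1):
        raise ValueError(f"unknown treatment {treatment}")
    return sum(
        1 for a in net.arms if a.treatment_id == treatment and a.events == 0
    )


def labbe_points(net: Network) -> list[tuple[object, float, float]]:
    """Per-study (reference-arm fraction, other-arm fraction) pairs.

    The coordinates of a L'Abbe plot: observed event fraction on the
    reference arm against the fraction on the comparator arm.  Requires
    every study to be two-arm and to contain the reference treatment.
    """
    out = []
    for sid in net.study_ids:
        arms = net.study_arms(sid)
        if len(arms) != 2:
            raise ValueError(f"study {sid} is not two-arm")
        ref = [a for a in arms if a.treatment_id == net.reference_treatment]
        if not ref:
            raise ValueError(f"study {sid} has no reference arm")
        other = [a for a in arms if a.treatment_id != net.reference_treatment][0]
        out.append(
            (sid, ref[0].events / ref[0].size, other.events / other.size)
        )
    return out
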