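"""Carcinogenic-potency label engineering.

Long-term bioassays summarize carcinogenic potency as TD50 — the dose-rate
(mg/kg body weight/day) estimated to halve the probability of remaining
tumor-free, computed as log(2)/beta-hat under a proportional-hazards dose
model lambda(t, d) = (1 + beta*d) * lambda0(t).  A molecule usually has
several experiments; we aggregate their TD50s with a harmonic mean (which
biases toward the low, i.e. potent, observations: a single positive
experiment is evidence the compound can be carcinogenic under some
conditions) and train on the log-reciprocal scale, where larger values mean
more potent.  Molecules whose experiments all showed no dose-tumor
relationship (beta = 0, no finite TD50) receive a configurable sentinel
target, -1.62 log units by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

#: Default log-potency value assigned to molecules with no carcinogenic
#: experiment (no finite TD50 exists for them).
SENTINEL_LOG_POTENCY = -1.62


class NoFiniteTD50Error(ValueError):
    """beta <= 0: no relationship between dose and tumor growth."""


@dataclass(frozen=True)
class PotencyRecord:
    """One experiment's TD50 observation (or a non-carcinogenic outcome)."""

    molecule_id: str
    experiment_id: str
    td50: float | None  # mg/kg/day, > 0; None <=> non-carcinogenic outcome

    def __post_init__(self):
        if self.td50 is not None and not self.td50 > 0:
            raise ValueError(f"td50 must be positive, got {self.td50}")

    @property
    def non_carcinogenic(self) -> bool:
        return self.td50 is None


@dataclass(frozen=True)
class PotencyLabel:
    """Aggregated continuous training target for one molecule."""

    molecule_id: str
    y: float  # log-reciprocal aggregated TD50, dimensionless log units
    is_sentinel: bool


def td50_from_beta(beta: float) -> float:
    """TD50 = log(2) / beta-hat (beta in 1/(mg/kg/day) units).

    Raises :class:`NoFiniteTD50Error` if ``beta <= 0``: a zero coefficient
    means no dose-tumor relationship, hence no finite TD50.
    """
    if beta <= 0:
        raise NoFiniteTD50Error(f"beta = {beta}: no finite TD50")
    return math.log(2) / beta


def aggregate_td50(records: list[PotencyRecord]) -> float | None:
    """Harmonic mean of the finite TD50s; ``None`` if none exist.

    Non-carcinogenic experiments are excluded from both the sum and the
    count, so the aggregate is pulled toward the experiments that did
    demonstrate carcinogenicity.
    """
    if not records:
        raise ValueError("no potency records to aggregate")
    finite = [r.td50 for r in records if r.td50 is not None]
    if not finite:
        return None
    return len(finite) / sum(1.0 / t for t in finite)


def to_log_potency(
    td50_agg: float | None,
    molecule_id: str = "",
    sentinel: float = SENTINEL_LOG_POTENCY,
    log_base: float = 10.0,
) -> PotencyLabel:
    """Continuous target y = log10(1 / TD50); sentinel for non-carcinogens.

    Strictly decreasing in TD50: a lower halving dose (more potent
    carcinogen) maps to a higher y.
    """
    if td50_agg is None:
        return PotencyLabel(molecule_id=molecule_id, y=sentinel, is_sentinel=True)
    if not td50_agg > 0:
        raise ValueError(f"aggregated TD50 must be positive, got {td50_agg}")
    y = -math.log(td50_agg) / math.log(log_base)
    return PotencyLabel(molecule_id=molecule_id, y=y, is_sentinel=False)


def labels_from_records(
    records: list[PotencyRecord], sentinel: float = SENTINEL_LOG_POTENCY
) -> list[PotencyLabel]:
    """Group records by molecule and run the aggregate -> log pipeline."""
    by_mol: dict[str, list[PotencyRecord]] = {}
    for r in records:
        by_mol.setdefault(r.molecule_id, []).append(r)
    return [
        to_log_potency(aggregate_td50(rs), molecule_id=mid, sentinel=sentinel)
        for mid, rs in by_mol.items()
    ]


def binarize_labels(labels: list[PotencyLabel]) -> list[int]:
    """1 iff the molecule showed carcinogenicity in at least one experiment."""
    return [0 if lab.is_sentinel else 1 for lab in labels]


def read_potency_csv(path) -> list[PotencyRecord]:
    """Read (molecule_id, experiment_id, td50) rows; empty td50 = negative."""
    df = pd.read_csv(path, dtype={"molecule_id": str, "experiment_id": str})
    out = []
    for row in df.itertuples(index=False):
        td50 = None if pd.isna(row.td50) else float(row.td50)
        out.append(
            PotencyRecord(
                molecule_id=row.molecule_id,
                experiment_id=str(row.experiment_id),
                td50=td50,
            )
        )
    return out


def write_labels_csv(labels: list[PotencyLabel], path) -> None:
    pd.DataFrame(
        {
            "molecule_id": [l.molecule_id for l in labels],
            "y": [l.y for l in labels],
            "is_sentinel": [int(l.is_sentinel) for l in labels],
        }
    ).to_csv(path, index=False)
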