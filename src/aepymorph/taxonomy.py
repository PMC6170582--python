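"""Nomenclatural resolution of morphometric clusters.

A cluster inherits the senior available species name among the type
specimens confidently assigned to it: the earliest publication year wins,
with ties broken by publication month (an unknown month is treated as
December, i.e. it cannot beat any known month in the same year).  Clusters
containing no well-predicted type specimen remain "unnamed".

Also provides assignment of literature specimens - known only from a
published measurement value or range - to clusters via discrete
(non-overlapping) diagnostic measurement intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .datamodel import SpecimenRecord
from .gmm import Assignment

UNNAMED = "unnamed"
UNASSIGNED = "unassigned"
AMBIGUOUS = "ambiguous"

_UNKNOWN_MONTH = 12


@dataclass(frozen=True)
class TypeEvidence:
    specimen_id: str
    taxon_name: str
    pub_year: int
    pub_month: int | None
    role: str
    uncertainty: float
    well_predicted: bool

    @property
    def seniority_key(self) -> tuple[int, int, str]:
        month = self.pub_month if self.pub_month is not None else _UNKNOWN_MONTH
        return (self.pub_year, month, self.taxon_name)


@dataclass
class TaxonResolution:
    """Cluster -> senior available species name with its evidence chain."""

    senior_names: dict[object, str] = field(default_factory=dict)
    evidence: dict[object, list[TypeEvidence]] = field(default_factory=dict)

    def name_of(self, cluster) -> str:
        return self.senior_names.get(cluster, UNNAMED)


def resolve_taxa(
    assignment: Assignment,
    records: list[SpecimenRecord],
    uncertainty_threshold: float = 0.05,
) -> TaxonResolution:
    """Attach the senior available species name to each cluster.

    Only type specimens classified with uncertainty strictly below the
    threshold count toward seniority; poorly predicted types are kept in
    the evidence chain, flagged, but never lend their name.  The outcome is
    a pure function of the (name, year, month) tuples and the memberships -
    permutation-invariant and deterministic.
    """
    by_id = {r.specimen_id: r for r in records}
    resolution = TaxonResolution()
    for cluster in sorted(assignment.labels.unique(), key=str):
        members = assignment.labels.index[assignment.labels == cluster]
        chain: list[TypeEvidence] = []
        for sid in members:
            rec = by_id.get(sid)
            if rec is None or rec.type_status is None:
                continue
            ts = rec.type_status
            unc = float(assignment.uncertainty.loc[sid])
            chain.append(
                TypeEvidence(
                    specimen_id=sid,
                    taxon_name=ts.taxon_name,
                    pub_year=ts.pub_year,
                    pub_month=ts.pub_month,
                    role=ts.role,
                    uncertainty=unc,
                    well_predicted=unc < uncertainty_threshold,
                )
            )
        chain.sort(key=lambda e: (e.seniority_key, e.specimen_id))
        resolution.evidence[cluster] = chain
        usable = [e for e in chain if e.well_predicted]
        resolution.senior_names[cluster] = (
            min(usable, key=lambda e: e.seniority_key).taxon_name if usable else UNNAMED
        )
    return resolution


@dataclass(frozen=True)
class DiagnosticInterval:
    """Per-cluster closed measurement intervals [min, max] in mm."""

    code: str
    intervals: dict[str, tuple[float, float]]

    @property
    def discrete(self) -> bool:
        """True when the cluster intervals are pairwise non-overlapping."""
        spans = sorted(self.intervals.values())
        return all(a[1] < b[0] for a, b in zip(spans, spans[1:]))

    def overlapping(self, lo: float, hi: float) -> list[str]:
        return [
            c for c, (a, b) in sorted(self.intervals.items())
            if not (hi < a or lo > b)
        ]


def intervals_from_members(
    code: str, labels: pd.Series, values: pd.Series
) -> DiagnosticInterval:
    """Build per-cluster intervals from observed member values."""
    iv = {}
    for cluster in sorted(labels.dropna().unique(), key=str):
        members = labels.index[labels == cluster]
        vals = values.loc[values.index.intersection(members)].dropna()
        if len(vals):
            iv[str(cluster)] = (float(vals.min()), float(vals.max()))
    return DiagnosticInterval(code=code, intervals=iv)


def interval_assign(
    value_mm: float | tuple[float, float],
    intervals: DiagnosticInterval,
    strict: bool = False,
) -> str:
    """Place a published value (or min-max range) into a cluster.

    The query maps to a cluster when it intersects exactly one cluster
    interval; a query falling in a gap is ``unassigned`` and one touching
    several intervals is ``ambiguous``.  With ``strict=True`` assignment is
    refused outright unless the interval set is globally discrete (some
    published sets are discrete only across the relevant pairs).
    """
    if strict and not intervals.discrete:
        raise ValueError(
            f"intervals for {intervals.code} are not pairwise non-overlapping; "
            "interval assignment refused"
        )
    if isinstance(value_mm, (tuple, list)):
        lo, hi = float(value_mm[0]), float(value_mm[1])
        if lo > hi:
            raise ValueError(f"inverted query range {value_mm!r}")
    else:
        lo = hi = float(value_mm)
    if lo <= 0:
        raise ValueError("measurement values must be positive")
    hits = intervals.overlapping(lo, hi)
    if not hits:
        return UNASSIGNED
    if len(hits) > 1:
        return AMBIGUOUS
    return hits[0]
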