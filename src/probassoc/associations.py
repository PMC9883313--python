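"""Daily dyadic associations and half-weight index matrices.

Associations are scored once per sampling period (calendar day) under one of
three criteria:

``probabilistic``
    the dyad shares a collection event with two identifications at most the
    association threshold apart (lag <= threshold, inclusive);
``same_frame``
    the dyad shares an identical (event, ordinal) pair — photographed in the
    very same frame;
``encounter``
    the dyad shares any collection event that day.

The criteria nest: same-frame associations are probabilistic associations,
which are encounter associations, so half-weight indices are ordered
elementwise HWI_same_frame <= HWI_probabilistic <= HWI_encounter.

Per-day indicators collapse to the half-weight index

    HWI = x / (x + yAB + (yA + yB) / 2)

where, over sampling days, x = days both individuals were identified and
associated, yAB = days both identified but not associated, yA / yB = days
only one of them was identified.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .records import records_to_frame

__all__ = [
    "CRITERIA",
    "AssociationData",
    "HWIMatrix",
    "restrict_individuals",
    "daily_associations",
    "hwi_matrix",
]

CRITERIA = ("probabilistic", "same_frame", "encounter")


@dataclass
class AssociationData:
    """Per-day identification sets and associated dyads.

    ``seen[day]`` is the set of individuals identified that day;
    ``associated[day]`` the set of unordered dyads (2-tuples, sorted) deemed
    associated that day.  Every member of an associated dyad is in the day's
    seen set; dyads are irreflexive.
    """

    days: list
    seen: Mapping[object, set]
    associated: Mapping[object, set]
    criterion: str
    threshold: int | None = None

    def __post_init__(self) -> None:
        for day in self.days:
            for a, b in self.associated[day]:
                if a == b:
                    raise ValueError(f"self-association {a!r} on {day!r}")
                if a not in self.seen[day] or b not in self.seen[day]:
                    raise ValueError(
                        f"associated dyad ({a!r},{b!r}) not seen on {day!r}")

    @property
    def individuals(self) -> list:
        out = set()
        for day in self.days:
            out |= self.seen[day]
        return sorted(out)


def restrict_individuals(records, min_days: int = 5,
                         require_periods: Sequence[int] | None = None
                         ) -> set[str]:
    """Individuals seen on >= ``min_days`` distinct dates and in every
    required calendar year.

    Filters out infrequently sighted individuals and those absent from the
    boundary years of a study (animals that died during it or were born into
    it). Returns the retained ID set; empty results warn rather than raise.
    """
    df = records_to_frame(records)
    dates = pd.to_datetime(df["date"])
    tall = pd.DataFrame({"individual": df["individual"],
                         "date": dates.dt.date, "year": dates.dt.year})
    day_counts = tall.groupby("individual")["date"].nunique()
    keep = set(day_counts[day_counts >= min_days].index)
    if require_periods:
        for year in require_periods:
            seen_that_year = set(tall.loc[tall["year"] == int(year),
                                          "individual"])
            keep &= seen_that_year
    if not keep:
        import warnings
        warnings.warn("individual restriction removed every individual")
    return keep


def _dyads(ids: Iterable[str]) -> set[tuple[str, str]]:
    return {tuple(sorted(p)) for p in combinations(set(ids), 2)}


def daily_associations(records, criterion: str,
                       threshold: int | None = None,
                       ids: Iterable[str] | None = None) -> AssociationData:
    """Score dyadic associations once per sampling day.

    ``threshold`` (in ordinal units, inclusive comparison) is required for
    the probabilistic criterion and ignored otherwise.  ``ids`` optionally
    restricts the analysis to a subset of individuals (records of others are
    dropped entirely, including from the seen sets).
    """
    if criterion not in CRITERIA:
        raise ValueError(f"unknown criterion {criterion!r}; expected one of {CRITERIA}")
    if criterion == "probabilistic":
        if threshold is None or threshold < 1:
            raise ValueError("probabilistic criterion requires an integer "
                             "threshold >= 1")
    df = records_to_frame(records).copy()
    if ids is not None:
        ids = set(ids)
        df = df[df["individual"].isin(ids)]
        if df.empty:
            raise ValueError("no records left after restricting individuals")
    df["date"] = pd.to_datetime(df["date"]).dt.date

    days, seen, associated = [], {}, {}
    for day, day_df in df.groupby("date", sort=True):
        days.append(day)
        seen[day] = set(day_df["individual"])
        pairs: set[tuple[str, str]] = set()
        for _, ev in day_df.groupby("event", sort=False):
            if criterion == "encounter":
                pairs |= _dyads(ev["individual"])
                continue
            if criterion == "same_frame":
                for _, frame in ev.groupby("ordinal", sort=False):
                    pairs |= _dyads(frame["individual"])
                continue
            # probabilistic: any two identifications <= threshold apart
            ords = ev["ordinal"].to_numpy(dtype=float)
            inds = ev["individual"].to_numpy()
            k = len(ords)
            if k < 2:
                continue
            iu, ju = np.triu_indices(k, k=1)
            close = np.abs(ords[iu] - ords[ju]) <= threshold
            diff = inds[iu] != inds[ju]
            for i, j in zip(iu[close & diff], ju[close & diff]):
                pairs.add(tuple(sorted((inds[i], inds[j]))))
        associated[day] = pairs
    return AssociationData(days=days, seen=seen, associated=associated,
                           criterion=criterion,
                           threshold=threshold if criterion == "probabilistic"
                           else None)


@dataclass
class HWIMatrix:
    """Half-weight association indices with their per-dyad tallies.

    ``values`` is symmetric with zero diagonal; entry (i, j) equals
    x / (x + yAB + (yA + yB)/2) from ``counts`` (a dict mapping sorted dyads
    to (x, yAB, yA, yB)).  Dyads never jointly sampled (zero denominator) are
    structural zeros, listed in ``undetermined``.
    """

    individuals: list
    values: np.ndarray
    counts: Mapping[tuple[str, str], tuple[int, int, int, int]]
    undetermined: set = field(default_factory=set)
    criterion: str | None = None
    threshold: int | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.individuals),) * 2:
            raise ValueError("matrix shape does not match individual list")
        if not np.allclose(v, v.T):
            raise ValueError("HWI matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("HWI diagonal must be zero")
        if np.any((v < 0) | (v > 1)):
            raise ValueError("HWI values must lie in [0, 1]")
        self.values = v

    def offdiag(self, nonzero_only: bool = False,
                exclude_undetermined: bool = False) -> np.ndarray:
        """Upper off-diagonal values as a flat vector."""
        iu, ju = np.triu_indices(len(self.individuals), k=1)
        vals = self.values[iu, ju]
        if exclude_undetermined and self.undetermined:
            idx = {ind: k for k, ind in enumerate(self.individuals)}
            und = np.zeros_like(vals, dtype=bool)
            flat = {(idx[a], idx[b]) for a, b in self.undetermined}
            for k, (i, j) in enumerate(zip(iu, ju)):
                if (min(i, j), max(i, j)) in flat:
                    und[k] = True
            vals = vals[~und]
        if nonzero_only:
            vals = vals[vals > 0]
        return vals

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.individuals,
                            columns=self.individuals)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    def edge_list(self) -> pd.DataFrame:
        rows = []
        for (a, b), (x, yab, ya, yb) in sorted(self.counts.items()):
            i, j = self.individuals.index(a), self.individuals.index(b)
            rows.append({"id1": a, "id2": b, "hwi": self.values[i, j],
                         "x": x, "yab": yab, "ya": ya, "yb": yb})
        return pd.DataFrame(rows)

    def to_graph(self):
        """Weighted networkx graph (zero-weight edges omitted)."""
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.individuals)
        n = len(self.individuals)
        for i in range(n):
            for j in range(i + 1, n):
                w = self.values[i, j]
                if w > 0:
                    g.add_edge(self.individuals[i], self.individuals[j],
                               weight=float(w))
        return g

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "HWIMatrix":
        """Build from a square labelled matrix (counts unavailable)."""
        ids = list(frame.index)
        return cls(individuals=ids, values=frame.to_numpy(dtype=float),
                   counts={})


def hwi_matrix(assoc: AssociationData,
               ids: Iterable[str] | None = None) -> HWIMatrix:
    """Collapse per-day associations into a half-weight index matrix."""
    individuals = sorted(set(ids)) if ids is not None else assoc.individuals
    idx = {ind: k for k, ind in enumerate(individuals)}
    n = len(individuals)
    x = np.zeros((n, n)); yab = np.zeros((n, n))
    seen_days = np.zeros(n)

    for day in assoc.days:
        seen = [i for i in assoc.seen[day] if i in idx]
        codes = [idx[i] for i in seen]
        for k in codes:
            seen_days[k] += 1
        both = np.zeros((n, n), dtype=bool)
        arr = np.array(codes)
        if len(arr) >= 2:
            both[np.ix_(arr, arr)] = True
        day_assoc = np.zeros((n, n), dtype=bool)
        for a, b in assoc.associated[day]:
            if a in idx and b in idx:
                i, j = idx[a], idx[b]
                day_assoc[i, j] = day_assoc[j, i] = True
        x += both & day_assoc
        yab += both & ~day_assoc

    np.fill_diagonal(x, 0); np.fill_diagonal(yab, 0)
    # only-A days: A seen while B not, regardless of anything else
    ya = seen_days[:, None] - x - yab   # days A seen with B also seen -> subtract
    yb = seen_days[None, :] - x - yab
    denom = x + yab + 0.5 * (ya + yb)
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(denom > 0, x / denom, 0.0)
    np.fill_diagonal(values, 0.0)

    counts, undetermined = {}, set()
    for i in range(n):
        for j in range(i + 1, n):
            dyad = (individuals[i], individuals[j])
            counts[dyad] = (int(x[i, j]), int(yab[i, j]),
                            int(ya[i, j]), int(yb[i, j]))
            if denom[i, j] == 0:
                undetermined.add(dyad)
    return HWIMatrix(individuals=individuals, values=values, counts=counts,
                     undetermined=undetermined, criterion=assoc.criterion,
                     threshold=assoc.threshold)
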