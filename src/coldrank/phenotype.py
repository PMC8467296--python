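"""Body-temperature-maintenance phenotype and extreme-group selection.

The phenotype is the area under an animal's in-ear temperature curve (AUC,
in °C·hours) over the coldest stretch of the recording period: an animal that
keeps its body temperature up through a cold spell accumulates a larger AUC
than one whose ear temperature sags. The coldest stretch is found from the
ambient series; the two contrast groups are the highest-AUC ("tolerant") and
lowest-AUC ("sensitive") animals, balanced for breed representation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import BalanceError, InsufficientDataError

SENSITIVE = "sensitive"
TOLERANT = "tolerant"


@dataclass
class TemperatureSeries:
    """A sensor time series: strictly increasing timestamps, finite °C values."""

    subject_id: str
    timestamps: np.ndarray  # datetime64
    values: np.ndarray  # °C

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype="datetime64[ns]")
        self.values = np.asarray(self.values, dtype=float)
        if len(self.timestamps) != len(self.values):
            raise ValueError("timestamps and values differ in length")
        if len(self.values) < 2:
            raise InsufficientDataError(
                f"series {self.subject_id!r} has fewer than 2 points"
            )
        if not np.all(np.diff(self.timestamps.astype("int64")) > 0):
            raise ValueError(f"series {self.subject_id!r} timestamps not increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"series {self.subject_id!r} has non-finite values")


@dataclass
class PhenotypeRecord:
    animal_id: str
    auc: float  # °C·hours over the selected interval
    breed: str


@dataclass
class GroupSpec:
    """Mapping of sample ids to contrast group and breed."""

    group_of: dict[str, str]
    breed_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = set(self.group_of.values())
        if labels and len(labels) != 2:
            raise ValueError(f"expected exactly two group labels, got {sorted(labels)}")

    @property
    def labels(self) -> tuple[str, str]:
        labels = sorted(set(self.group_of.values()))
        # keep the conventional (sensitive, tolerant) order when applicable
        if set(labels) == {SENSITIVE, TOLERANT}:
            return (SENSITIVE, TOLERANT)
        return tuple(labels)  # type: ignore[return-value]

    def samples(self, label: str) -> list[str]:
        return [s for s, g in self.group_of.items() if g == label]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": list(self.group_of),
                "group": [self.group_of[s] for s in self.group_of],
                "breed": [self.breed_of.get(s, "") for s in self.group_of],
            }
        )


def select_coldest_interval(
    ambient: TemperatureSeries, k_days: int = 5
) -> tuple[pd.Timestamp, pd.Timestamp]:
    """Find the contiguous ``k_days``-day window with the lowest mean ambient.

    Candidate windows start at the midnight of each observed calendar day and
    span ``k_days`` days; ties go to the earliest start. Returns the
    ``(start, end)`` timestamps of the window (``end = start + k_days``).
    """
    ts = pd.DatetimeIndex(ambient.timestamps)
    days = ts.normalize()
    first_day, last_day = days[0], days[-1]
    n_days = (last_day - first_day).days + 1
    if n_days < k_days:
        raise InsufficientDataError(
            f"ambient series spans {n_days} days; need at least {k_days}"
        )
    values = np.asarray(ambient.values, dtype=float)
    best_start, best_mean = None, np.inf
    for offset in range(n_days - k_days + 1):
        start = first_day + pd.Timedelta(days=offset)
        end = start + pd.Timedelta(days=k_days)
        inside = (ts >= start) & (ts < end)
        if not inside.any():
            continue
        mean = values[inside].mean()
        if mean < best_mean - 1e-12:
            best_start, best_mean = start, mean
    if best_start is None:
        raise InsufficientDataError("no ambient samples fall in any candidate window")
    return best_start, best_start + pd.Timedelta(days=k_days)


def compute_auc(
    series: TemperatureSeries, interval: tuple[pd.Timestamp, pd.Timestamp]
) -> float:
    """Trapezoidal AUC (°C·hours) of the series restricted to the interval.

    When samples straddle an interval boundary the piecewise-linear
    interpolant is evaluated at the boundary, so the integral covers exactly
    the overlap of the interval with the sampled range.
    """
    t0, t1 = (pd.Timestamp(b) for b in interval)
    if t1 <= t0:
        raise ValueError("interval end must be after its start")
    hours = (
        pd.DatetimeIndex(series.timestamps) - t0
    ).to_numpy() / np.timedelta64(1, "h")
    span_h = (t1 - t0) / pd.Timedelta(hours=1)
    vals = np.asarray(series.values, dtype=float)

    inside = (hours >= 0.0) & (hours <= span_h)
    if inside.sum() < 2:
        raise InsufficientDataError(
            f"series {series.subject_id!r} has fewer than 2 samples in the interval"
        )
    t_in = hours[inside]
    v_in = vals[inside]
    # interpolated boundary points, when the series extends past the boundary
    if hours[0] < 0.0 and t_in[0] > 0.0:
        t_in = np.concatenate([[0.0], t_in])
        v_in = np.concatenate([[np.interp(0.0, hours, vals)], v_in])
    if hours[-1] > span_h and t_in[-1] < span_h:
        t_in = np.concatenate([t_in, [span_h]])
        v_in = np.concatenate([v_in, [np.interp(span_h, hours, vals)]])
    return float(np.trapezoid(v_in, t_in))


def compute_phenotypes(
    series: dict[str, TemperatureSeries],
    interval: tuple[pd.Timestamp, pd.Timestamp],
    breed_of: dict[str, str],
) -> list[PhenotypeRecord]:
    """AUC phenotype for every animal series over the given interval."""
    return [
        PhenotypeRecord(animal_id=aid, auc=compute_auc(s, interval),
                        breed=breed_of.get(aid, ""))
        for aid, s in sorted(series.items())
    ]


def _breed_imbalance(tol: list[PhenotypeRecord], sen: list[PhenotypeRecord]) -> int:
    breeds = {p.breed for p in tol} | {p.breed for p in sen}
    count = lambda grp, b: sum(p.breed == b for p in grp)  # noqa: E731
    return sum(
        max(0, abs(count(tol, b) - count(sen, b)) - 1) for b in breeds
    )


def _separation(tol, sen) -> float:
    return float(np.mean([p.auc for p in tol]) - np.mean([p.auc for p in sen]))


def select_extreme_groups(
    phenotypes: list[PhenotypeRecord], per_group: int = 6
) -> GroupSpec:
    """Pick breed-balanced extreme AUC groups.

    Starts from the naive top/bottom ``per_group`` split by AUC (ties broken
    by animal id) and, while any breed's count differs by more than one
    between the groups, applies the single swap — replacing a group member
    with an unselected animal, or exchanging members between the groups —
    that reduces the imbalance while sacrificing the least AUC separation.
    Deterministic for a given input set.
    """
    if len(phenotypes) < 2 * per_group:
        raise InsufficientDataError(
            f"need at least {2 * per_group} phenotyped animals, have {len(phenotypes)}"
        )
    order = sorted(phenotypes, key=lambda p: (-p.auc, p.animal_id))
    tol = order[:per_group]
    sen = order[-per_group:]
    pool = order[per_group:-per_group] if len(order) > 2 * per_group else []

    while _breed_imbalance(tol, sen) > 0:
        current = _breed_imbalance(tol, sen)
        candidates = []  # (-(separation), new_imbalance, key, tol', sen', pool')
        for grp_name, grp in (("tol", tol), ("sen", sen)):
            other = sen if grp_name == "tol" else tol
            for i, member in enumerate(grp):
                for j, sub in enumerate(pool):
                    if sub.breed == member.breed:
                        continue
                    new_grp = grp[:i] + grp[i + 1 :] + [sub]
                    new_pool = pool[:j] + pool[j + 1 :] + [member]
                    new_tol = new_grp if grp_name == "tol" else other
                    new_sen = new_grp if grp_name == "sen" else other
                    imb = _breed_imbalance(new_tol, new_sen)
                    if imb < current:
                        candidates.append(
                            (-_separation(new_tol, new_sen), imb,
                             (grp_name, member.animal_id, sub.animal_id),
                             new_tol, new_sen, new_pool)
                        )
        for i, a in enumerate(tol):
            for j, b in enumerate(sen):
                if a.breed == b.breed:
                    continue
                new_tol = tol[:i] + tol[i + 1 :] + [b]
                new_sen = sen[:j] + sen[j + 1 :] + [a]
                imb = _breed_imbalance(new_tol, new_sen)
                if imb < current:
                    candidates.append(
                        (-_separation(new_tol, new_sen), imb,
                         ("xch", a.animal_id, b.animal_id),
                         new_tol, new_sen, pool)
                    )
        if not candidates:
            raise BalanceError(
                "no single swap reduces breed imbalance; balance unachievable"
            )
        candidates.sort(key=lambda c: (c[0], c[1], c[2]))
        _, _, _, tol, sen, pool = candidates[0]

    group_of = {p.animal_id: TOLERANT for p in tol}
    group_of.update({p.animal_id: SENSITIVE for p in sen})
    breed_of = {p.animal_id: p.breed for p in tol + sen}
    return GroupSpec(group_of=group_of, breed_of=breed_of)


def brute_force_extreme_groups(
    phenotypes: list[PhenotypeRecord], per_group: int = 6
) -> tuple[set[str], set[str]]:
    """Exhaustive balanced-split search (test oracle; feasible for n ≲ 14).

    Returns the (tolerant ids, sensitive ids) pair maximizing the difference
    in mean AUC subject to every breed's count differing by ≤ 1 between
    groups.
    """
    n = len(phenotypes)
    best = None
    for tol_idx in itertools.combinations(range(n), per_group):
        rest = [i for i in range(n) if i not in tol_idx]
        for sen_idx in itertools.combinations(rest, per_group):
            tol = [phenotypes[i] for i in tol_idx]
            sen = [phenotypes[i] for i in sen_idx]
            if _breed_imbalance(tol, sen) > 0:
                continue
            sep = _separation(tol, sen)
            if best is None or sep > best[0] + 1e-12:
                best = (sep, {p.animal_id for p in tol}, {p.animal_id for p in sen})
    if best is None:
        raise BalanceError("no balanced split exists")
    return best[1], best[2]
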