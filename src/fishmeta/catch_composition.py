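"""Catch-composition analysis: dominant species, sample allocation,
Shannon index and mean trophic level.

The dominant-species set is the minimal prefix of the catch table (ordered
by descending tonnage) whose cumulative share of the *total* catch reaches
a threshold (0.65 by default; river sport fisheries with unreliable catch
surveys may require >0.9).  Sequencing effort is then apportioned over the
dominant set proportionally to catch weight by the largest-remainder
(Hamilton) method.  The Shannon index is computed on the realized sample
composition — the per-species sequence counts — with the natural logarithm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .io_formats import CatchRecord, TrophicRecord, normalize_species

__all__ = [
    "DominantSet",
    "SampleAllocation",
    "ShannonResult",
    "TrophicSummary",
    "select_dominant_species",
    "allocate_samples",
    "shannon_index",
    "mean_trophic_level",
]


@dataclass(frozen=True)
class DominantSet:
    """Top-catch species reaching the cumulative threshold.

    ``fractions`` are shares of the *total* catch (an aggregate
    "Others" tonnage, if supplied, stays in the denominator).
    """

    species: tuple[str, ...]
    tonnages: tuple[float, ...]
    fractions: tuple[float, ...]
    cumulative_percent: float
    threshold: float

    def as_catch_records(self) -> list[CatchRecord]:
        return [CatchRecord(s, t) for s, t in zip(self.species, self.tonnages)]


@dataclass(frozen=True)
class SampleAllocation:
    counts: dict[str, int]
    n: int

    def __post_init__(self) -> None:
        assert sum(self.counts.values()) == self.n


@dataclass(frozen=True)
class ShannonResult:
    H: float
    proportions: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class TrophicSummary:
    mean: float
    variance: float


def select_dominant_species(
    catch: Sequence[CatchRecord],
    threshold: float = 0.65,
    total: Optional[float] = None,
) -> DominantSet:
    """Minimal top-tonnage prefix covering ``threshold`` of the total catch.

    Parameters
    ----------
    catch
        Catch records for individual species.  Ties in tonnage keep input
        order (stable sort).
    threshold
        Cumulative catch fraction to reach, in (0, 1].
    total
        Total catch tonnage used as the denominator.  Defaults to the sum
        of ``catch``; pass it explicitly when an aggregate remainder
        ("Others") is not listed as a row but belongs in the total.
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    if not catch:
        raise ValueError("empty catch table")
    table_sum = sum(r.tonnage for r in catch)
    denom = table_sum if total is None else float(total)
    if denom <= 0:
        raise ValueError("all-zero catch: no positive tonnage to rank")
    if total is not None and table_sum - denom > 1e-9 * max(denom, 1.0):
        raise ValueError("explicit total is smaller than the listed tonnages")

    ranked = sorted(catch, key=lambda r: -r.tonnage)
    chosen: list[CatchRecord] = []
    cum = 0.0
    for rec in ranked:
        chosen.append(rec)
        cum += rec.tonnage / denom
        if cum >= threshold - 1e-12:  # tolerate summation round-off at 1.0
            break
    else:
        if cum < threshold - 1e-12:
            raise ValueError(
                f"listed species cover only {100 * cum:.2f}% of the total; "
                f"threshold {100 * threshold:.0f}% unreachable"
            )
    return DominantSet(
        species=tuple(r.species for r in chosen),
        tonnages=tuple(r.tonnage for r in chosen),
        fractions=tuple(r.tonnage / denom for r in chosen),
        cumulative_percent=100.0 * cum,
        threshold=threshold,
    )


def allocate_samples(dominant: DominantSet, n: int) -> SampleAllocation:
    """Largest-remainder apportionment of ``n`` samples over the dominant set.

    Fractions are renormalized within the dominant set.  Remainder ties go
    to the larger fraction, then input order.  Every dominant species gets
    at least one sample; any deficit is taken from the largest count.
    """
    s = len(dominant.species)
    if n < s:
        raise ValueError(f"cannot allocate n={n} samples over {s} species (need n >= {s})")
    fracs = np.asarray(dominant.fractions, dtype=float)
    fracs = fracs / fracs.sum()
    quotas = n * fracs
    counts = np.floor(quotas).astype(int)
    remainders = quotas - counts
    short = n - int(counts.sum())
    # ties: larger remainder, then larger fraction, then input order
    order = sorted(range(s), key=lambda i: (-remainders[i], -fracs[i], i))
    for i in order[:short]:
        counts[i] += 1
    while (counts == 0).any():
        zero = int(np.argmax(counts == 0))
        counts[zero] += 1
        counts[int(np.argmax(counts))] -= 1
    return SampleAllocation(dict(zip(dominant.species, (int(c) for c in counts))), n)


def shannon_index(counts: Mapping[str, float] | Sequence[float]) -> ShannonResult:
    """Shannon diversity H = −Σ p_i ln p_i (natural log) of a composition.

    ``counts`` are per-species sample counts (or positive weights); zeros
    are dropped.
    """
    if isinstance(counts, Mapping):
        labels = list(counts.keys())
        values = np.asarray(list(counts.values()), dtype=float)
    else:
        values = np.asarray(list(counts), dtype=float)
        labels = [str(i) for i in range(len(values))]
    if (values < 0).any():
        raise ValueError("negative counts")
    total = values.sum()
    if total <= 0:
        raise ValueError("all-zero counts: Shannon index undefined")
    p = values / total
    nz = p > 0
    h = float(-(p[nz] * np.log(p[nz])).sum())
    return ShannonResult(H=h, proportions={l: float(x) for l, x in zip(labels, p)})


def mean_trophic_level(
    species: Sequence[str],
    trophic: Sequence[TrophicRecord] | Mapping[str, float],
    weights: Optional[Mapping[str, float]] = None,
) -> TrophicSummary:
    """Mean trophic level of a species set, with its sample variance.

    Unweighted across species by default (n−1 variance; 0 for a single
    species).  Passing catch ``weights`` switches to a catch-weighted mean
    with the matching weighted variance.
    """
    if isinstance(trophic, Mapping):
        table = {normalize_species(k): float(v) for k, v in trophic.items()}
    else:
        table = {normalize_species(r.species): r.trophic_level for r in trophic}
    levels = []
    for sp in species:
        key = normalize_species(sp)
        if key not in table:
            raise KeyError(f"species {sp!r} missing from trophic table")
        levels.append(table[key])
    x = np.asarray(levels, dtype=float)
    if weights is None:
        mean = float(x.mean())
        var = float(x.var(ddof=1)) if len(x) > 1 else 0.0
    else:
        w = np.asarray([weights[sp] for sp in species], dtype=float)
        if w.sum() <= 0:
            raise ValueError("non-positive total weight")
        w = w / w.sum()
        mean = float((w * x).sum())
        var = float((w * (x - mean) ** 2).sum())
    if var < 0:  # numerical guard
        var = 0.0
    assert math.isfinite(mean)
    return TrophicSummary(mean=mean, variance=var)
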