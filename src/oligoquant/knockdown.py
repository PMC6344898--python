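"""Single-cell knockdown quantification.

Microinjected cells are identified by the nuclear mean intensity of a
co-injected fluorescent tracer exceeding a threshold (chosen from the
tracer/target scatter plot; an automatic two-class Otsu suggestion is
available).  Target knockdown is the ratio of the injected group's mean
target intensity to the non-injected group's, with SEMs per group; a
relative level below 0.5 corresponds to >50% knockdown.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .segmentation import CellRecord


@dataclass
class KnockdownResult:
    """Group summary of target intensity for injected vs non-injected cells."""

    group_means: dict[str, float]  # % of max
    group_sems: dict[str, float]
    relative_level: float  # injected / non-injected
    n_per_group: dict[str, int]
    tracer_threshold: float  # % of max


def _tracer_values(records: Sequence[CellRecord], channel: str) -> np.ndarray:
    try:
        return np.asarray([r.mean_intensity[channel] for r in records])
    except KeyError as err:
        raise InvalidParameterError(
            f"record missing channel {err.args[0]!r}") from err


def suggest_tracer_threshold(records: Sequence[CellRecord],
                             tracer_channel: str) -> float:
    """Two-class Otsu on the tracer means — a suggestion only; the threshold
    remains an explicit analysis input.

    The between-class variance is maximized over every cut of the sorted
    sample values and the threshold is placed mid-gap between the two
    classes, so it stays clear of both clusters even when the criterion is
    flat across the separating region.
    """
    vals = np.sort(_tracer_values(records, tracer_channel).astype(float))
    n = vals.size
    if np.unique(vals).size < 2:
        raise InvalidParameterError(
            "tracer intensities are constant; no threshold suggestion")
    csum = np.cumsum(vals)
    total = csum[-1]
    k = np.arange(1, n)  # cut after index k-1
    mu0 = csum[:-1] / k
    mu1 = (total - csum[:-1]) / (n - k)
    sigma_b = k * (n - k) * (mu0 - mu1) ** 2
    valid = vals[1:] > vals[:-1]  # cuts inside a tie are meaningless
    sigma_b[~valid] = -np.inf
    best = int(np.argmax(sigma_b))
    return float(0.5 * (vals[best] + vals[best + 1]))


def classify_injected(records: Sequence[CellRecord], tracer_channel: str,
                      threshold: float) -> tuple[list[CellRecord], dict[str, int]]:
    """Flag records with tracer mean intensity > threshold as injected.

    Returns new records (input untouched) plus class counts.
    """
    vals = _tracer_values(records, tracer_channel)
    out = [replace(r, injected=bool(v > threshold))
           for r, v in zip(records, vals)]
    counts = {"injected": int(sum(r.injected for r in out)),
              "non_injected": int(sum(not r.injected for r in out))}
    return out, counts


def quantify_knockdown(records: Sequence[CellRecord], target_channel: str,
                       tracer_threshold: float = float("nan")) -> KnockdownResult:
    """Per-group mean +/- SEM of target intensity and the injected/non-injected
    ratio.  Both classes must be non-empty and every record classified."""
    if any(r.injected is None for r in records):
        raise InvalidParameterError("records must be classified first")
    groups = {"injected": [], "non_injected": []}
    for r in records:
        key = "injected" if r.injected else "non_injected"
        try:
            groups[key].append(r.mean_intensity[target_channel])
        except KeyError as err:
            raise InvalidParameterError(
                f"record missing channel {err.args[0]!r}") from err
    for name, vals in groups.items():
        if not vals:
            raise InvalidParameterError(f"empty class: {name}")
    means, sems, ns = {}, {}, {}
    for name, vals in groups.items():
        v = np.asarray(vals, dtype=float)
        means[name] = float(v.mean())
        sems[name] = float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else 0.0
        ns[name] = int(v.size)
    if means["non_injected"] == 0:
        raise InvalidParameterError("non-injected mean is zero; ratio undefined")
    return KnockdownResult(group_means=means, group_sems=sems,
                           relative_level=means["injected"] / means["non_injected"],
                           n_per_group=ns, tracer_threshold=float(tracer_threshold))


def dose_series(results: Mapping[float, KnockdownResult]
                | Iterable[tuple[float, KnockdownResult]]) -> pd.DataFrame:
    """Order knockdown results by injected copy number.

    Returns a DataFrame (copies, relative_level, n_injected, n_non_injected)
    sorted by dose, with a ``monotone`` attribute flag set when the relative
    level is non-increasing with dose.  Duplicated dose keys resolve
    last-writer-wins with a warning.
    """
    if isinstance(results, Mapping):
        items = list(results.items())
    else:
        items = list(results)
        seen: dict[float, KnockdownResult] = {}
        for dose, res in items:
            if dose in seen:
                warnings.warn(f"duplicate dose {dose!r}: keeping the last entry",
                              stacklevel=2)
            seen[dose] = res
        items = list(seen.items())
    if len(items) < 2:
        raise InvalidParameterError("need >= 2 dose levels")
    items.sort(key=lambda kv: kv[0])
    df = pd.DataFrame({
        "copies": [d for d, _ in items],
        "relative_level": [r.relative_level for _, r in items],
        "n_injected": [r.n_per_group["injected"] for _, r in items],
        "n_non_injected": [r.n_per_group["non_injected"] for _, r in items],
    })
    df.attrs["monotone"] = bool(np.all(np.diff(df["relative_level"]) <= 0))
    return df
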