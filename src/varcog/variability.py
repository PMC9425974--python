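"""Clade-normalized relative variability of protein families.

A family's mean column homogeneity ``h_C`` is placed on a clade-relative
scale through

    v_C = (1 - h_C) * h_T / ((1 - h_T) * h_C)

where ``h_T`` is the clade-wide mean homogeneity.  A family exactly as
homogeneous as the clade average has ``v_C = 1``; ``v_C < 0.5`` is classified
as conserved and ``v_C > 2`` as variable.  The same transform applies to
individual alignment columns, yielding position-level variability classes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

from .scoring import HomogeneityProfile

__all__ = [
    "CladeContext",
    "VariabilityRecord",
    "FeatureBins",
    "clade_mean_homogeneity",
    "relative_variability",
    "classify_variability",
    "position_variability_profile",
    "position_class_fractions",
    "family_variability",
    "bin_features",
    "VARIABILITY_SENTINEL",
]

VarClass = Literal["conserved", "intermediate", "variable"]

#: Reported variability for columns with h = 0 ("arbitrarily high").
VARIABILITY_SENTINEL = 1e6

#: Class thresholds: v below the first is conserved, above the second variable.
CONSERVED_MAX = 0.5
VARIABLE_MIN = 2.0


@dataclass(frozen=True)
class CladeContext:
    """Clade-wide homogeneity baseline ``h_T`` with pooling bookkeeping."""

    clade_id: str
    h_T: float
    n_families: int
    n_columns_total: int

    def __post_init__(self) -> None:
        if not (0.0 < self.h_T < 1.0):
            raise ValueError(
                f"clade mean homogeneity must lie strictly in (0, 1); got {self.h_T}"
            )


@dataclass(frozen=True)
class VariabilityRecord:
    family_id: str
    h_C: float
    v_C: float
    var_class: VarClass
    position_fractions: tuple[float, float, float]  # (conserved, intermediate, variable)


@dataclass(frozen=True)
class FeatureBins:
    paralogy_bin: Literal["low", "medium", "high"]
    gain_rate_bin: Literal["low", "medium", "high"]
    ancestral: bool
    membrane: bool
    secreted: bool


def clade_mean_homogeneity(
    profiles: Iterable[HomogeneityProfile],
    clade_id: str = "clade",
    mode: Literal["pooled", "mean_of_means"] = "pooled",
) -> CladeContext:
    """Clade-wide mean homogeneity ``h_T`` over a set of family profiles.

    ``mode="pooled"`` (default) averages over all scored columns pooled across
    families, so families contribute in proportion to their alignment length
    and position-level variability uses the same baseline.
    ``mode="mean_of_means"`` averages the per-family means instead.
    """
    profiles = list(profiles)
    means, counts = [], []
    for p in profiles:
        vals = p.scored
        if vals.size:
            means.append(float(vals.mean()))
            counts.append(vals.size)
    if not means:
        raise ValueError("no scored columns in any profile")
    counts_arr = np.asarray(counts)
    if mode == "pooled":
        h_T = float(np.average(means, weights=counts_arr))
    elif mode == "mean_of_means":
        h_T = float(np.mean(means))
    else:
        raise ValueError(f"unknown pooling mode {mode!r}")
    return CladeContext(
        clade_id=clade_id,
        h_T=h_T,
        n_families=len(profiles),
        n_columns_total=int(counts_arr.sum()),
    )


def relative_variability(h_C: float, h_T: float) -> float:
    """``v = (1 - h_C) h_T / ((1 - h_T) h_C)``.

    ``h_C = 0`` yields the sentinel value (arbitrarily high variability);
    ``h_C = 1`` yields exactly 0.
    """
    if not (0.0 < h_T < 1.0):
        raise ValueError(f"h_T must lie strictly in (0, 1); got {h_T}")
    if h_C < 0.0 or h_C > 1.0:
        raise ValueError(f"h_C must lie in [0, 1]; got {h_C}")
    if h_C == 0.0:
        return VARIABILITY_SENTINEL
    return (1.0 - h_C) * h_T / ((1.0 - h_T) * h_C)


def classify_variability(v: float) -> VarClass:
    """Classify: ``v < 0.5`` conserved, ``v > 2`` variable, else intermediate.

    The boundary values 0.5 and 2.0 fall in the intermediate class.
    """
    if v < 0.0:
        raise ValueError(f"variability must be non-negative; got {v}")
    if v < CONSERVED_MAX:
        return "conserved"
    if v > VARIABLE_MIN:
        return "variable"
    return "intermediate"


def position_variability_profile(
    profile: HomogeneityProfile,
    ctx: CladeContext,
    sentinel: float = VARIABILITY_SENTINEL,
) -> list[dict]:
    """Per-column variability from raw (unsmoothed) homogeneity.

    Returns one record per scored column with keys ``column``, ``h``, ``v``,
    ``var_class`` and ``sentinel`` (True where h = 0 and the configurable cap
    was reported instead of an infinite value).
    """
    out = []
    for j, h in zip(profile.scored_indices, profile.scored):
        is_sentinel = h == 0.0
        v = sentinel if is_sentinel else relative_variability(float(h), ctx.h_T)
        out.append(
            {
                "column": int(j),
                "h": float(h),
                "v": float(v),
                "var_class": classify_variability(v),
                "sentinel": bool(is_sentinel),
            }
        )
    return out


def position_class_fractions(
    classes: Sequence[str],
) -> tuple[float, float, float]:
    """Fractions of (conserved, intermediate, variable) positions."""
    n = len(classes)
    if n == 0:
        raise ValueError("no scored positions")
    f_c = sum(c == "conserved" for c in classes) / n
    f_i = sum(c == "intermediate" for c in classes) / n
    f_v = sum(c == "variable" for c in classes) / n
    return (f_c, f_i, f_v)


def family_variability(
    profile: HomogeneityProfile, ctx: CladeContext
) -> VariabilityRecord:
    """Family-level record: ``h_C``, ``v_C``, class, and position-class mix."""
    h_C = profile.mean_h
    v_C = relative_variability(h_C, ctx.h_T)
    positions = position_variability_profile(profile, ctx)
    fractions = position_class_fractions([p["var_class"] for p in positions])
    return VariabilityRecord(
        family_id=profile.family_id,
        h_C=h_C,
        v_C=v_C,
        var_class=classify_variability(v_C),
        position_fractions=fractions,
    )


def _bin3(x: float, low_edge: float, high_edge: float) -> str:
    # Half-open bins [lo, mid) / [mid, hi) / [hi, inf)
    if x < low_edge:
        return "low"
    if x < high_edge:
        return "medium"
    return "high"


def bin_features(
    paralogy: float,
    gain_rate: float,
    root_ancestral: bool,
    frac_tm: float,
    frac_signal: float,
) -> FeatureBins:
    """Discretize family features into the standard reporting bins.

    Paralogy (proteins per covered genome): 1-1.25 low, 1.25-3 medium, >=3
    high.  Gain rate (summed gains): 0-0.5 low, 0.5-2 medium, >=2 high.  Bins
    are half-open on the right.  Membrane/secreted flags are set when the
    respective protein fraction reaches 1/3.
    """
    if paralogy < 1.0:
        raise ValueError(
            f"paralogy ratio cannot be below 1 (got {paralogy}): a family has "
            "at least one protein per covered genome"
        )
    if gain_rate < 0 or frac_tm < 0 or frac_signal < 0:
        raise ValueError("features must be non-negative")
    return FeatureBins(
        paralogy_bin=_bin3(paralogy, 1.25, 3.0),
        gain_rate_bin=_bin3(gain_rate, 0.5, 2.0),
        ancestral=bool(root_ancestral),
        membrane=frac_tm >= 1.0 / 3.0,
        secreted=frac_signal >= 1.0 / 3.0,
    )
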