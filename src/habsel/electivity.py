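"""Manly's alpha and Chesson's electivity index.

Selection is quantified by comparing the habitat composition *used* by an
analysis unit (a square, an individual bird/covey, or a territory) with the
composition *available* to it:

    alpha_i = (r_i / n_i) / sum_j (r_j / n_j)

where r_i is the used proportion of habitat i, n_i its available proportion
and j runs over the m habitat types with nonzero availability.  Chesson's
electivity rescales alpha to [-1, 1] so that values are comparable across
units facing different numbers of available types:

    epsilon_i = (m * alpha_i - 1) / ((m - 2) * alpha_i + 1)

epsilon = 0 means use proportional to availability, +1 exclusive preference
and -1 complete avoidance; for m = 2 the formula reduces to 2*alpha - 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .landscape import (
    CircularPlot,
    CompositionProfile,
    Observation,
    PatchMap,
    plot_composition,
)

__all__ = [
    "AvailabilityFrame",
    "ElectivityRecord",
    "manly_alpha",
    "chesson_epsilon",
    "alpha_from_epsilon",
    "unit_electivity",
    "electivity_table",
]


class UnsupportedUseError(ValueError):
    """Positive use of a habitat type with zero availability.

    This signals an availability-frame mismatch rather than genuine
    selection, so it is an error, never silently dropped.
    """


@dataclass(frozen=True)
class AvailabilityFrame:
    """The availability proportions n_i a unit's use is compared against.

    ``mode`` records whether the frame was averaged over all survey squares
    (one common frame, as used at the rough scale) or built per square (as
    used at the fine scale, where averaging would credit units with habitat
    types absent from their own square).
    """

    proportions: Mapping[str, float]
    mode: str = "averaged_over_squares"  # or "per_square"
    source: str = ""

    def __post_init__(self) -> None:
        if self.mode not in ("averaged_over_squares", "per_square"):
            raise ValueError(f"unknown availability mode {self.mode!r}")
        vals = np.array(list(self.proportions.values()), dtype=float)
        if (vals < 0).any():
            raise ValueError("availability proportions must be >= 0")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise ValueError("availability proportions must sum to 1")
        if int((vals > 0).sum()) < 2:
            raise ValueError("need at least 2 available habitat types")

    @property
    def m(self) -> int:
        """Number of habitat types with nonzero availability."""
        return int(sum(1 for v in self.proportions.values() if v > 0))


@dataclass(frozen=True)
class ElectivityRecord:
    """Per-habitat selection result at one analysis level."""

    habitat: str
    level: str  # "square" | "individual" | "territory"
    alpha: float
    epsilon: float
    n_units: int
    ci_low: float | None = None
    ci_high: float | None = None
    significance: str = "not_tested"

    def __post_init__(self) -> None:
        if not (-1 - 1e-9 <= self.epsilon <= 1 + 1e-9):
            raise ValueError("epsilon must lie in [-1, 1]")


def _align(use: Mapping[str, float], avail: Mapping[str, float]):
    """Align use and availability over the union vocabulary, dropping types
    with zero availability AND zero use; returns (codes, r, n)."""
    codes = sorted(set(use) | set(avail))
    r = np.array([use.get(c, 0.0) for c in codes], dtype=float)
    n = np.array([avail.get(c, 0.0) for c in codes], dtype=float)
    keep = (r > 0) | (n > 0)
    codes = [c for c, k in zip(codes, keep) if k]
    return codes, r[keep], n[keep]


def manly_alpha(
    use: CompositionProfile | Mapping[str, float],
    avail: AvailabilityFrame | Mapping[str, float],
) -> pd.Series:
    """Manly's selection index alpha_i for one unit.

    Parameters
    ----------
    use
        Used proportions r_i (a plot composition or mean of several).
    avail
        Available proportions n_i.

    Returns
    -------
    pandas.Series
        alpha indexed by habitat code over the m types with n_i > 0;
        sums to 1.  alpha_i = 0 iff r_i = 0.
    """
    r_map = use.proportions if isinstance(use, CompositionProfile) else use
    n_map = avail.proportions if isinstance(avail, AvailabilityFrame) else avail
    codes, r, n = _align(r_map, n_map)
    bad = [c for c, ri, ni in zip(codes, r, n) if ri > 0 and ni == 0]
    if bad:
        raise UnsupportedUseError(
            f"positive use of habitat type(s) {bad} with zero availability")
    if not (r > 0).any():
        raise ValueError("all-zero use profile")
    if len(codes) < 2:
        raise ValueError("need at least 2 available habitat types (m >= 2)")
    ratio = np.where(n > 0, r / np.where(n > 0, n, 1.0), 0.0)
    alpha = ratio / ratio.sum()
    return pd.Series(alpha, index=pd.Index(codes, name="habitat"), name="alpha")


def chesson_epsilon(alpha, m: int | None = None):
    """Chesson's electivity epsilon_i = (m*alpha_i - 1)/((m-2)*alpha_i + 1).

    ``alpha`` may be a Series (m defaults to its length), array or scalar
    (then m is required).  Values lie in [-1, 1], increase strictly with
    alpha, and are 0 at alpha = 1/m; for m = 2 the expression reduces to
    2*alpha - 1.
    """
    if m is None:
        if not hasattr(alpha, "__len__"):
            raise ValueError("m is required for scalar alpha")
        m = len(alpha)
    if m < 2:
        raise ValueError("m must be >= 2")
    a = np.asarray(alpha, dtype=float)
    if ((a < -1e-12) | (a > 1 + 1e-12)).any():
        raise ValueError("alpha must lie in [0, 1]")
    eps = (m * a - 1.0) / ((m - 2) * a + 1.0)
    if isinstance(alpha, pd.Series):
        return pd.Series(eps, index=alpha.index, name="epsilon")
    if np.isscalar(alpha):
        return float(eps)
    return eps


def alpha_from_epsilon(epsilon, m: int | None = None):
    """Inverse of :func:`chesson_epsilon`: alpha = (1+eps)/(m - (m-2)*eps).

    Provided for verification; not an alternative selection index.
    """
    if m is None:
        if not hasattr(epsilon, "__len__"):
            raise ValueError("m is required for scalar epsilon")
        m = len(epsilon)
    if m < 2:
        raise ValueError("m must be >= 2")
    e = np.asarray(epsilon, dtype=float)
    alpha = (1.0 + e) / (m - (m - 2) * e)
    if isinstance(epsilon, pd.Series):
        return pd.Series(alpha, index=epsilon.index, name="alpha")
    if np.isscalar(epsilon):
        return float(alpha)
    return alpha


def unit_electivity(
    observations: Sequence[Observation],
    maps: Mapping[str, PatchMap],
    avail: AvailabilityFrame,
    radius: float = 100.0,
) -> tuple[pd.Series, pd.Series, int]:
    """alpha and epsilon for one analysis unit.

    The unit's use profile is the unweighted mean of the circular-plot
    compositions around its locations (plots share the same area, so equal
    weights).  Habitat types with zero availability and zero use are dropped
    before m is counted, so m may differ between units under a per-square
    availability frame.

    Returns (alpha, epsilon, m).
    """
    if not observations:
        raise ValueError("unit has no locations")
    profiles = []
    for obs in observations:
        pmap = maps[obs.square_id]
        plot = CircularPlot(center=obs.location, radius=radius, kind="use",
                            source=obs.obs_id)
        profiles.append(plot_composition(pmap, plot).as_dict())
    codes = sorted(set().union(*profiles))
    r = {c: float(np.mean([p.get(c, 0.0) for p in profiles])) for c in codes}
    alpha = manly_alpha(r, avail)
    eps = chesson_epsilon(alpha, m=len(alpha))
    return alpha, eps, len(alpha)


def _unit_groups(observations: Sequence[Observation], level: str):
    """Group observations into analysis units for the requested level."""
    if level == "square":
        keys: dict[str, list[Observation]] = {}
        for obs in observations:
            keys.setdefault(obs.square_id, []).append(obs)
        return keys
    if level == "individual":
        keys = {}
        for obs in observations:
            keys.setdefault(obs.unit_id, []).append(obs)
        return keys
    if level == "territory":
        # one spring unit (calling male or pair) per territory
        keys = {}
        for obs in observations:
            if obs.season == "spring":
                keys.setdefault(obs.unit_id, []).append(obs)
        return keys
    raise ValueError(f"unknown analysis level {level!r}")


def electivity_table(
    observations: Sequence[Observation],
    maps: Mapping[str, PatchMap],
    avail: AvailabilityFrame | Mapping[str, AvailabilityFrame],
    level: str = "square",
    radius: float = 100.0,
) -> pd.DataFrame:
    """Tidy long table of per-unit electivities, ready for resampling.

    Parameters
    ----------
    avail
        A single :class:`AvailabilityFrame` (averaged mode) or a mapping
        square_id -> frame (per-square mode).
    level
        "square" pools all locations within a square into one unit;
        "individual" treats each observation as a unit; "territory" keeps
        spring records only.

    Returns
    -------
    pandas.DataFrame
        Columns level, unit_id, habitat, alpha, epsilon, m — one row per
        unit x habitat type available to that unit.
    """
    groups = _unit_groups(list(observations), level)
    if not groups:
        raise ValueError(f"no analysis units at level {level!r}")
    rows = []
    for unit_id, obs_list in sorted(groups.items()):
        if isinstance(avail, AvailabilityFrame):
            frame = avail
        else:
            frame = avail[obs_list[0].square_id]
        alpha, eps, m = unit_electivity(obs_list, maps, frame, radius=radius)
        for habitat in alpha.index:
            rows.append({
                "level": level, "unit_id": unit_id, "habitat": habitat,
                "alpha": float(alpha[habitat]),
                "epsilon": float(eps[habitat]), "m": m,
            })
    return pd.DataFrame(rows)


def habitat_unit_counts(long_table: pd.DataFrame) -> pd.Series:
    """Number of analysis units contributing an epsilon to each habitat."""
    return long_table.groupby("habitat")["unit_id"].nunique()
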