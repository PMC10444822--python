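"""Inhibitory-cascade (IC) morphospace analysis of tooth-area triplets.

The inhibitory cascade model of sequential tooth patterning predicts that,
along a tooth row patterned by a single activation/inhibition cascade, the
relative areas of three successive teeth fall on the line

    T(n+2) / T(n) = 2 * T(n+1) / T(n) - 1

where ``T(n)`` is the area of the n-th tooth to develop.  In the ratio plane
``x = T(n+1)/T(n)``, ``y = T(n+2)/T(n)`` the model-permitted region is the
pair of wedges in which the middle tooth is intermediate in size (the row is
monotone): for a cascade that conforms, either all three teeth shrink along
the row or all three grow.  The fraction of species whose triplet falls in
that region ("morphospace occupancy") measures how well a tooth class follows
a single cascade.

Three triplets are analysed for post-canine dentitions:

* ``premolar``: P2-P3-P4, cascade running back-to-front (P4 develops first,
  then P3's deciduous precursor, then P2 -- areas are ordered along the
  cascade, i.e. a1 = P4, a2 = P3, a3 = P2);
* ``molar``: M1-M2-M3, front-to-back;
* ``mixed``: P4-M1-M2, spanning the two classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidMeasurementError, SchemaError

#: Tooth loci of each triplet, ordered along the cascade direction
#: (first element develops first, so it is the ratio denominator T(n)).
TRIPLETS: dict[str, tuple[str, str, str]] = {
    "premolar": ("P4", "P3", "P2"),
    "molar": ("M1", "M2", "M3"),
    "mixed": ("P4", "M1", "M2"),
}

#: Ratio-axis conventions: "first" plots (a2/a1, a3/a1); "adjacent"
#: plots (a2/a1, a3/a2).
CONVENTIONS = ("first", "adjacent")


def tooth_area(length: float, width: float) -> float:
    """Crown area (mm^2) as crown length times crown width.

    Parameters
    ----------
    length, width : float
        Crown dimensions in mm; both must be strictly positive.
    """
    if not np.all(np.asarray(length) > 0):
        raise InvalidMeasurementError(f"length must be > 0, got {length!r}")
    if not np.all(np.asarray(width) > 0):
        raise InvalidMeasurementError(f"width must be > 0, got {width!r}")
    return length * width


def ic_predicted_third(x):
    """IC-predicted third ratio ``T(n+2)/T(n) = 2*x - 1`` for ``x = T(n+1)/T(n)``.

    A non-positive return value (x <= 0.5) is interpreted by callers as
    "third tooth absent": the cascade's inhibition leaves no room for it.
    Accepts scalars or arrays.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(x > 0):
        raise InvalidMeasurementError(f"ratio x must be > 0, got {x!r}")
    out = 2.0 * x - 1.0
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class TripletRatios:
    """Ordered areas of a three-tooth triplet and the derived ratio coordinates.

    ``x`` and ``y`` are always recomputed from the areas under the stored
    convention, so they can never drift out of sync with ``a1..a3``.
    """

    triplet_label: str
    a1: float
    a2: float
    a3: float
    convention: str = "first"

    def __post_init__(self):
        if self.triplet_label not in TRIPLETS:
            raise ValueError(f"unknown triplet label {self.triplet_label!r}")
        if self.convention not in CONVENTIONS:
            raise ValueError(f"unknown convention {self.convention!r}")
        for name in ("a1", "a2", "a3"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise InvalidMeasurementError(f"area {name} must be > 0, got {v!r}")

    @property
    def x(self) -> float:
        return self.a2 / self.a1

    @property
    def y(self) -> float:
        if self.convention == "first":
            return self.a3 / self.a1
        return self.a3 / self.a2

    @property
    def in_ic(self) -> bool:
        return in_ic_morphospace(self)


def triplet_ratios(a1: float, a2: float, a3: float, label: str,
                   convention: str = "first") -> TripletRatios:
    """Build a :class:`TripletRatios` from three areas ordered along the cascade."""
    return TripletRatios(triplet_label=label, a1=float(a1), a2=float(a2),
                         a3=float(a3), convention=convention)


def _inside_halfplanes(x: float, y: float,
                       halfplanes: Sequence[tuple[float, float, float]],
                       eps: float) -> bool:
    # each constraint (alpha, beta, gamma) means alpha*x + beta*y <= gamma
    return all(a * x + b * y <= g + eps for a, b, g in halfplanes)


def in_ic_morphospace(t: TripletRatios, eps: float = 0.0,
                      region: Sequence[Sequence[tuple[float, float, float]]] | None = None,
                      ) -> bool:
    """Whether a triplet lies in the IC-permitted region of the ratio plane.

    Default region (closed; boundary points are inside): the middle tooth is
    size-intermediate, i.e. the triplet is monotone along the cascade.  Under
    the "first" convention that is ``(x <= 1 and y <= x) or (x >= 1 and
    y >= x)``; under "adjacent" it is ``(x <= 1 and y <= 1) or (x >= 1 and
    y >= 1)``.  ``eps`` widens every boundary by a tolerance band.

    A custom region may be supplied as a list of convex pieces, each piece a
    list of half-plane constraints ``(alpha, beta, gamma)`` meaning
    ``alpha*x + beta*y <= gamma``; the region is their union.  This lets
    alternative published morphospace polygons be swapped in.
    """
    x, y = t.x, t.y
    if region is not None:
        return any(_inside_halfplanes(x, y, piece, eps) for piece in region)
    if t.convention == "first":
        decreasing = x <= 1.0 + eps and y <= x + eps
        increasing = x >= 1.0 - eps and y >= x - eps
    else:
        decreasing = x <= 1.0 + eps and y <= 1.0 + eps
        increasing = x >= 1.0 - eps and y >= 1.0 - eps
    return bool(decreasing or increasing)


@dataclass(frozen=True)
class OccupancyResult:
    """Dataset-level IC morphospace occupancy for one triplet."""

    triplet_label: str
    n_species: int
    n_inside: int
    n_excluded: int
    convention: str
    eps: float = 0.0

    def __post_init__(self):
        if not (0 <= self.n_inside <= self.n_species):
            raise ValueError("n_inside must lie in [0, n_species]")

    @property
    def percent_inside(self) -> float:
        return 100.0 * self.n_inside / self.n_species

    def to_dict(self) -> dict:
        return {
            "triplet_label": self.triplet_label,
            "n_species": self.n_species,
            "n_inside": self.n_inside,
            "n_excluded": self.n_excluded,
            "percent_inside": self.percent_inside,
            "convention": self.convention,
            "eps": self.eps,
        }


def _species_mean_areas(table: pd.DataFrame, loci: Iterable[str],
                        aggregate: str) -> pd.DataFrame:
    """Per-species mean area at each locus (individuals and sides averaged)."""
    required = {"species_id", "tooth", "length_mm", "width_mm"}
    missing = required - set(table.columns)
    if missing:
        raise SchemaError(f"measurement table missing columns {sorted(missing)}")
    sub = table[table["tooth"].isin(list(loci))].copy()
    sub["area_mm2"] = sub["length_mm"].to_numpy() * sub["width_mm"].to_numpy()
    if np.any(sub["area_mm2"].to_numpy() <= 0) or sub["area_mm2"].isna().any():
        bad = sub.index[(sub["area_mm2"] <= 0) | sub["area_mm2"].isna()][0]
        raise InvalidMeasurementError(
            f"non-positive tooth area at table row {bad} "
            f"(species {sub.loc[bad, 'species_id']!r}, tooth {sub.loc[bad, 'tooth']!r})"
        )
    if aggregate not in ("mean_area", "mean_ratio"):
        raise ValueError(f"unknown aggregation {aggregate!r}")
    wide = sub.groupby(["species_id", "tooth"])["area_mm2"].mean().unstack("tooth")
    return wide


def ic_species_table(table: pd.DataFrame, triplet_label: str,
                     convention: str = "first", eps: float = 0.0,
                     aggregate: str = "mean_area",
                     region=None) -> pd.DataFrame:
    """Per-species triplet areas, ratio coordinates and IC membership.

    ``table`` is a long-format measurement table (one row per measured crown,
    replicates/sides/individuals allowed); individuals of the same species are
    aggregated by mean area per locus before ratios are formed.  Species
    missing any tooth of the triplet are excluded (their count is available
    from :func:`ic_occupancy`).

    Returns a frame indexed by ``species_id`` with columns
    ``a1, a2, a3, x, y, in_ic``.
    """
    loci = TRIPLETS[triplet_label]
    wide = _species_mean_areas(table, loci, aggregate)
    for locus in loci:
        if locus not in wide.columns:
            wide[locus] = np.nan
    wide = wide[list(loci)]
    complete = wide.dropna()
    rows = []
    for species_id, (a1, a2, a3) in complete.iterrows():
        t = triplet_ratios(a1, a2, a3, triplet_label, convention)
        rows.append((species_id, t.a1, t.a2, t.a3, t.x, t.y,
                     in_ic_morphospace(t, eps=eps, region=region)))
    out = pd.DataFrame(rows, columns=["species_id", "a1", "a2", "a3", "x", "y", "in_ic"])
    out = out.set_index("species_id")
    out.attrs["n_excluded"] = int(len(wide) - len(complete))
    out.attrs["convention"] = convention
    return out


def ic_occupancy(table: pd.DataFrame, triplet_label: str,
                 convention: str = "first", eps: float = 0.0,
                 aggregate: str = "mean_area", region=None) -> OccupancyResult:
    """Fraction of species whose triplet falls inside the IC morphospace.

    Raises
    ------
    SchemaError
        If, after excluding species with missing teeth, no species remain.
    """
    per_species = ic_species_table(table, triplet_label, convention=convention,
                                   eps=eps, aggregate=aggregate, region=region)
    if len(per_species) == 0:
        raise SchemaError(
            f"no species with a complete {triplet_label} triplet "
            f"({per_species.attrs['n_excluded']} excluded)"
        )
    return OccupancyResult(
        triplet_label=triplet_label,
        n_species=int(len(per_species)),
        n_inside=int(per_species["in_ic"].sum()),
        n_excluded=int(per_species.attrs["n_excluded"]),
        convention=convention,
        eps=eps,
    )
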