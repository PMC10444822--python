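"""Species-level dental morphometrics and embryonic growth profiles.

Covers four ingredients of the comparative analysis:

* body-mass normalization of jaw length (isometric cube-root scaling by
  default, so the result is dimensionless up to unit choice);
* classification of species into morphogroups combining premolar/molar
  counts (per side of the lower jaw) with a short/regular/long jaw-length
  class: 3P3MR (regular), 3P3ML (long), 2P3MR (intermediate), 2P3MS and
  2P2MS (short), 3P2M (marginal), plus "excluded" for vampire-like
  dentitions with at most one molar;
* per-locus coefficients of variation of species-mean tooth areas within
  morphogroups (which loci are evolutionarily labile);
* growth-rate profiles of the canine-to-P4 jaw segment across Carnegie
  stages, from embryonic length-vs-stage series.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InvalidMeasurementError, SchemaError

MORPHOGROUPS = ("3P3MR", "3P3ML", "2P3MR", "2P3MS", "2P2MS", "3P2M", "excluded")

#: Morphogroups flagged as marginal (kept for modeling, dropped from the
#: comparative analyses).
MARGINAL_MORPHOGROUPS = ("3P2M",)


def relative_jaw_length(jaw_length_mm: float, body_mass_g: float,
                        exponent: float = 1.0 / 3.0) -> float:
    """Jaw length normalized by body mass, ``jaw / mass**exponent``.

    The default exponent 1/3 makes the ratio dimensionless under isometry
    (mass scales as length cubed).
    """
    jaw = np.asarray(jaw_length_mm, dtype=float)
    mass = np.asarray(body_mass_g, dtype=float)
    if not np.all(jaw > 0):
        raise InvalidMeasurementError(f"jaw_length_mm must be > 0, got {jaw_length_mm!r}")
    if not np.all(mass > 0):
        raise InvalidMeasurementError(f"body_mass_g must be > 0, got {body_mass_g!r}")
    out = jaw / mass ** exponent
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class JawLengthThresholds:
    """Cut-points on relative jaw length separating short | regular | long."""

    short: float
    long: float

    def __post_init__(self):
        if not self.short <= self.long:
            raise ValueError("short cut-point must not exceed long cut-point")


def fit_jaw_length_thresholds(values: Sequence[float]) -> JawLengthThresholds:
    """Dataset tertiles of relative jaw length as default class cut-points."""
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("need at least 3 values to fit tertile thresholds")
    lo, hi = np.quantile(v, [1.0 / 3.0, 2.0 / 3.0])
    return JawLengthThresholds(short=float(lo), long=float(hi))


def classify_morphogroup(premolar_count: int, molar_count: int,
                         relative_jaw_length: float,
                         thresholds: JawLengthThresholds) -> str:
    """Morphogroup label from tooth counts and the jaw-length class.

    Counts are per side of the lower jaw.  (3,3) splits into long (3P3ML)
    vs regular (3P3MR) at ``thresholds.long``; (2,3) splits into short
    (2P3MS) vs intermediate (2P3MR) at ``thresholds.short``; (2,2) is always
    short (2P2MS); (3,2) is the marginal 3P2M; at most one molar (vampire-like
    reduced dentitions) is excluded from the comparative analysis.
    """
    p, m = int(premolar_count), int(molar_count)
    if not (0 <= p <= 3 and 0 <= m <= 3):
        raise ValueError(f"tooth counts must be in 0..3, got ({p}, {m})")
    if m <= 1:
        return "excluded"
    if (p, m) == (3, 3):
        return "3P3ML" if relative_jaw_length > thresholds.long else "3P3MR"
    if (p, m) == (2, 3):
        return "2P3MS" if relative_jaw_length < thresholds.short else "2P3MR"
    if (p, m) == (2, 2):
        return "2P2MS"
    if (p, m) == (3, 2):
        return "3P2M"
    return "excluded"


def classify_table(metadata: pd.DataFrame,
                   thresholds: JawLengthThresholds | None = None,
                   exponent: float = 1.0 / 3.0) -> pd.DataFrame:
    """Annotate a species-metadata table with relative jaw length and morphogroup.

    ``metadata`` needs columns ``species_id, jaw_length_mm, body_mass_g,
    premolar_count, molar_count``.  When ``thresholds`` is None the tertiles
    of the dataset's relative jaw lengths are used; either way the cut-points
    applied are echoed in ``result.attrs["thresholds"]`` for reproducibility.
    """
    required = {"species_id", "jaw_length_mm", "body_mass_g",
                "premolar_count", "molar_count"}
    missing = required - set(metadata.columns)
    if missing:
        raise SchemaError(f"species metadata missing columns {sorted(missing)}")
    out = metadata.copy()
    out["relative_jaw_length"] = relative_jaw_length(
        out["jaw_length_mm"].to_numpy(), out["body_mass_g"].to_numpy(), exponent)
    if thresholds is None:
        thresholds = fit_jaw_length_thresholds(out["relative_jaw_length"].to_numpy())
    out["morphogroup"] = [
        classify_morphogroup(p, m, r, thresholds)
        for p, m, r in zip(out["premolar_count"], out["molar_count"],
                           out["relative_jaw_length"])
    ]
    out["marginal"] = out["morphogroup"].isin(MARGINAL_MORPHOGROUPS)
    out.attrs["thresholds"] = {"short": thresholds.short, "long": thresholds.long}
    return out


def locus_size_variability(measurements: pd.DataFrame,
                           groups: pd.DataFrame) -> pd.DataFrame:
    """Coefficient of variation of species-mean tooth areas, per locus per morphogroup.

    ``measurements`` is the long-format crown table; ``groups`` maps
    ``species_id`` to ``morphogroup`` (e.g. the output of
    :func:`classify_table`).  The CV is sample sd / mean over the species
    means within a group; loci with fewer than two measured species in a
    group are reported as NaN with ``n_species`` giving the support.  Absent
    teeth simply contribute no rows (absence is visible through n_species).

    Returns a tidy frame with columns
    ``morphogroup, tooth, n_species, mean_area_mm2, cv``.
    """
    t = measurements.copy()
    t["area_mm2"] = t["length_mm"].to_numpy() * t["width_mm"].to_numpy()
    species_means = (t.groupby(["species_id", "tooth"])["area_mm2"]
                      .mean().reset_index())
    merged = species_means.merge(
        groups[["species_id", "morphogroup"]], on="species_id", how="inner")
    rows = []
    for (grp, tooth), sub in merged.groupby(["morphogroup", "tooth"]):
        areas = sub["area_mm2"].to_numpy()
        n = len(areas)
        mean = float(np.mean(areas))
        cv = float(np.std(areas, ddof=1) / mean) if n >= 2 else np.nan
        rows.append((grp, tooth, n, mean, cv))
    return pd.DataFrame(rows, columns=["morphogroup", "tooth", "n_species",
                                       "mean_area_mm2", "cv"])


_STAGE_RE = re.compile(r"^CS(\d+)$", re.IGNORECASE)


def _stage_value(stage) -> float:
    """Numeric value of a stage label: 'CS20' -> 20.0, numerics pass through."""
    if isinstance(stage, str):
        m = _STAGE_RE.match(stage.strip())
        if not m:
            raise SchemaError(f"unrecognized stage label {stage!r} (expected 'CSnn')")
        return float(m.group(1))
    return float(stage)


@dataclass(frozen=True)
class GrowthProfile:
    """First-difference growth rates of a jaw segment across ordered stages.

    ``rate[i] = (segment_length[i+1] - segment_length[i]) / (stage[i+1] - stage[i])``
    so the rate array has one fewer entry than the length array.  Carnegie
    stages are treated as equally spaced ordinal units unless their numeric
    spacing differs.
    """

    stages: tuple
    stage_values: tuple
    segment_length_um: tuple
    rate: tuple

    @property
    def peak_rate(self) -> float:
        """Largest interval rate; NaN for an all-flat profile is never produced
        (a flat profile peaks at 0)."""
        return float(np.max(self.rate))

    @property
    def peak_interval(self) -> tuple:
        """(stage_from, stage_to) of the fastest-growing interval."""
        i = int(np.argmax(self.rate))
        return (self.stages[i], self.stages[i + 1])

    @property
    def has_peak(self) -> bool:
        """True if some interval grows strictly faster than the profile's floor."""
        r = np.asarray(self.rate)
        return bool(r.max() > r.min())


def growth_rate_profile(stages: Sequence, segment_length_um: Sequence[float]
                        ) -> GrowthProfile:
    """Growth-rate profile from an embryonic (stage, segment length) series.

    Stages must be strictly increasing (duplicates or inversions raise).
    """
    if len(stages) != len(segment_length_um):
        raise SchemaError("stages and segment lengths must have equal length")
    if len(stages) < 2:
        raise SchemaError("need at least 2 stages to compute growth rates")
    sv = np.array([_stage_value(s) for s in stages], dtype=float)
    if not np.all(np.diff(sv) > 0):
        raise SchemaError(f"stages must be strictly increasing, got {list(stages)!r}")
    lengths = np.asarray(segment_length_um, dtype=float)
    rates = np.diff(lengths) / np.diff(sv)
    return GrowthProfile(
        stages=tuple(stages),
        stage_values=tuple(sv.tolist()),
        segment_length_um=tuple(lengths.tolist()),
        rate=tuple(rates.tolist()),
    )


def peak_rate_ratio(profile_a: GrowthProfile, profile_b: GrowthProfile) -> float:
    """Ratio of peak growth rates between two profiles (a / b)."""
    return profile_a.peak_rate / profile_b.peak_rate
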