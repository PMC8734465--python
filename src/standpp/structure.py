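"""Stand-level composition and structure summaries.

Density (individuals, with multi-stemmed plants collapsed), basal area,
allometric aboveground biomass, and diameter distributions, per species
and plot-wide.  Density counts individuals; basal area and biomass sum
over every qualifying stem, the standard convention for multi-stemmed
plants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .census import Census
from .errors import AllometryLookupError, DomainError, SchemaError, StandppError

__all__ = [
    "AllometryTable",
    "stem_basal_area",
    "stem_biomass",
    "species_summary",
    "diameter_distribution",
    "classify_size_distribution",
    "default_bin_edges",
]

FALLBACK_CODE = "*"  # wildcard allometry entry applied to unlisted species


@dataclass
class AllometryTable:
    """Species -> biomass-equation coefficients.

    Two interchangeable parameterisations of the same power law are
    accepted: ``power_law`` gives biomass ``a * dbh**b`` (kg, dbh in cm);
    ``log_linear`` gives ``exp(a + b*ln(dbh))``.  A wildcard row with
    species code ``*`` acts as the fallback for unlisted species.
    """

    entries: pd.DataFrame  # columns: species_code, form, a, b

    def __post_init__(self):
        need = {"species_code", "form", "a", "b"}
        missing = need - set(self.entries.columns)
        if missing:
            raise SchemaError(f"allometry table missing columns: {sorted(missing)}")
        bad = ~self.entries["form"].isin(["power_law", "log_linear"])
        if bad.any():
            raise StandppError(
                f"unknown allometry form(s): {self.entries.loc[bad, 'form'].unique()}")
        pl = self.entries["form"] == "power_law"
        if (self.entries.loc[pl, "a"] <= 0).any():
            raise StandppError("power_law coefficient a must be positive")
        self.entries = self.entries.set_index(
            self.entries["species_code"].astype(str))

    @classmethod
    def from_csv(cls, path) -> "AllometryTable":
        return cls(pd.read_csv(path))

    @classmethod
    def generic(cls, a: float = 0.12, b: float = 2.4) -> "AllometryTable":
        """Single wildcard power-law entry, a user-editable placeholder."""
        return cls(pd.DataFrame(
            {"species_code": [FALLBACK_CODE], "form": ["power_law"], "a": [a], "b": [b]}))

    def lookup(self, species_code: str) -> pd.Series:
        if species_code in self.entries.index:
            return self.entries.loc[species_code]
        if FALLBACK_CODE in self.entries.index:
            return self.entries.loc[FALLBACK_CODE]
        raise AllometryLookupError(
            f"no allometry entry or fallback for species {species_code!r}")

    def to_csv(self, path) -> None:
        self.entries.reset_index(drop=True).to_csv(path, index=False)


def stem_basal_area(dbh) -> np.ndarray | float:
    """Basal area (m^2) of a stem of diameter ``dbh`` cm: pi*(dbh/200)^2."""
    arr = np.asarray(dbh, dtype=float)
    if np.any(arr <= 0):
        raise DomainError("dbh must be positive")
    out = math.pi * (arr / 200.0) ** 2
    return float(out) if np.isscalar(dbh) else out


def stem_biomass(dbh, entry) -> np.ndarray | float:
    """Aboveground biomass (kg) of a stem from its allometry ``entry``.

    ``entry`` is a row with fields form, a, b (see :class:`AllometryTable`);
    the two forms evaluate identically when ``a_log = ln(a_power)``.
    """
    arr = np.asarray(dbh, dtype=float)
    if np.any(arr <= 0):
        raise DomainError("dbh must be positive")
    a, b = float(entry["a"]), float(entry["b"])
    if entry["form"] == "power_law":
        out = a * arr ** b
    elif entry["form"] == "log_linear":
        out = np.exp(a + b * np.log(arr))
    else:  # pragma: no cover - table constructor rejects this
        raise StandppError(f"unknown allometry form {entry['form']!r}")
    return float(out) if np.isscalar(dbh) else out


def species_summary(census: Census, allometry: AllometryTable,
                    status: str = "live") -> pd.DataFrame:
    """Per-species density, basal area (m^2) and biomass (Mg) summaries.

    Density counts distinct individuals (multi-stemmed plants collapse to
    one); basal area and biomass sum over all qualifying stems.  Per-ha
    columns divide by the window area.  A ``TOTAL`` row closes the table.
    """
    t = census.subset(status=status).table
    area_ha = census.window.area_ha
    rows = []
    for code, grp in t.groupby("species_code", sort=True):
        dbh = grp["dbh"].to_numpy(float)
        ba = float(np.sum(stem_basal_area(dbh)))
        bm = float(np.sum(stem_biomass(dbh, allometry.lookup(code)))) / 1000.0  # kg->Mg
        rows.append({
            "species_code": code,
            "n_individuals": int(grp["individual_id"].nunique()),
            "n_stems": len(grp),
            "basal_area_total_m2": ba,
            "biomass_total_Mg": bm,
        })
    out = pd.DataFrame(rows, columns=[
        "species_code", "n_individuals", "n_stems",
        "basal_area_total_m2", "biomass_total_Mg"])
    if len(out):
        total = {
            "species_code": "TOTAL",
            "n_individuals": int(out["n_individuals"].sum()),
            "n_stems": int(out["n_stems"].sum()),
            "basal_area_total_m2": float(out["basal_area_total_m2"].sum()),
            "biomass_total_Mg": float(out["biomass_total_Mg"].sum()),
        }
        out = pd.concat([out, pd.DataFrame([total])], ignore_index=True)
    out["density_per_ha"] = out["n_individuals"] / area_ha
    out["basal_area_per_ha_m2"] = out["basal_area_total_m2"] / area_ha
    out["biomass_per_ha_Mg"] = out["biomass_total_Mg"] / area_ha
    return out


def default_bin_edges(max_dbh: float) -> np.ndarray:
    """5-cm diameter classes starting at the 1-cm census threshold."""
    top = 5.0 * math.ceil(max(max_dbh, 1.0) / 5.0) + 1.0
    return np.concatenate([[1.0], np.arange(6.0, top + 1e-9, 5.0)])


def diameter_distribution(census: Census, species: str | Sequence[str] | None = None,
                          bin_edges=None, status: str = "live") -> pd.DataFrame:
    """Histogram of stem counts over diameter classes.

    Bins are left-closed, right-open; the last bin is closed so the counts
    partition the qualifying stems.  An absent species yields an all-zero
    histogram.
    """
    t = census.subset(species=species, status=status).table
    dbh = t["dbh"].to_numpy(float)
    if bin_edges is None:
        bin_edges = default_bin_edges(dbh.max() if len(dbh) else 10.0)
    edges = np.asarray(bin_edges, dtype=float)
    if len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise DomainError("bin edges must be strictly increasing")
    counts, _ = np.histogram(dbh, bins=edges)  # numpy closes the last bin
    return pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:],
                         "count": counts.astype(int)})


def classify_size_distribution(histogram) -> str:
    """Label a diameter histogram ``reverse_J``, ``unimodal`` or ``other``.

    ``reverse_J``: counts non-increasing across all bins (the declining
    size-class curve of continuously regenerating populations).
    ``unimodal``: counts rise to a single interior mode then fall.
    Anything else is ``other``.  Requires at least 3 bins.
    """
    if isinstance(histogram, pd.DataFrame):
        counts = histogram["count"].to_numpy()
    else:
        counts = np.asarray(histogram)
    if counts.size < 3:
        raise DomainError("size-distribution classification needs >= 3 bins")
    diffs = np.diff(counts.astype(float))
    if np.all(diffs <= 0):
        return "reverse_J"
    mode = int(np.argmax(counts))
    if 0 < mode < counts.size - 1 \
            and np.all(diffs[:mode] >= 0) and np.all(diffs[mode:] <= 0):
        return "unimodal"
    return "other"
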