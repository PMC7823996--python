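"""Lipid shorthand parsing and class/saturation analytics.

Lipid species are named in shorthand (``PC 34:1`` at sum-composition level,
``PC 16:0_20:4`` at single-fatty-acid resolution from negative-mode formate
adducts). This module parses those names, aggregates class totals over the
time course, profiles phosphatidylcholine double-bond saturation, and filters
species by a constituent fatty acid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chem import FORMATE_ADDUCT_DELTA
from .containers import FeatureTable

__all__ = [
    "LipidParseError",
    "LipidSpecies",
    "KNOWN_CLASSES",
    "SATURATION_BINS",
    "parse_lipid_name",
    "format_lipid_name",
    "formate_adduct_mz",
    "sum_by_class",
    "pc_saturation_profile",
    "filter_by_fatty_acid",
]

#: Lipid classes the analytics recognize (others parse as "other").
KNOWN_CLASSES = ("LPC", "LPE", "PC", "PE", "SM", "TAG", "HexCer")

#: Double-bond bins partitioning the PC saturation profile.
SATURATION_BINS = ("0", "1-2", "3", ">=4")


class LipidParseError(ValueError):
    """Malformed lipid shorthand; carries the offending position."""

    def __init__(self, name: str, position: int, message: str):
        self.position = position
        super().__init__(f"cannot parse lipid name {name!r} at position {position}: {message}")


@dataclass(frozen=True)
class LipidSpecies:
    """A parsed lipid: class, total carbons/double bonds, optional acyl chains.

    If ``acyl_chains`` is present, their carbon and double-bond sums equal the
    totals (enforced). ``class_label`` keeps the original class token so
    formatting round-trips even for unrecognized classes.
    """

    lipid_class: str
    total_carbons: int
    total_double_bonds: int
    acyl_chains: tuple[tuple[int, int], ...] | None = None
    class_label: str = ""

    def __post_init__(self) -> None:
        if self.total_carbons < 0 or self.total_double_bonds < 0:
            raise ValueError("carbon and double-bond counts must be >= 0")
        if self.acyl_chains is not None:
            cs = sum(c for c, _ in self.acyl_chains)
            ds = sum(d for _, d in self.acyl_chains)
            if cs != self.total_carbons or ds != self.total_double_bonds:
                raise ValueError(
                    f"acyl chain sums ({cs}:{ds}) do not match totals "
                    f"({self.total_carbons}:{self.total_double_bonds})"
                )
        if not self.class_label:
            object.__setattr__(self, "class_label", self.lipid_class)

    @property
    def db_bin(self) -> str:
        """Saturation bin of the total double-bond count."""
        d = self.total_double_bonds
        if d == 0:
            return "0"
        if d <= 2:
            return "1-2"
        if d == 3:
            return "3"
        return ">=4"

    def contains_fatty_acid(self, fa: tuple[int, int]) -> bool:
        return self.acyl_chains is not None and tuple(fa) in self.acyl_chains


def parse_lipid_name(name: str) -> LipidSpecies:
    """Parse shorthand ``CLASS C:D`` or ``CLASS C1:D1_C2:D2[_C3:D3]``.

    Unknown class tokens parse with ``lipid_class="other"`` and a warning;
    malformed strings raise :class:`LipidParseError` naming the position of
    the first offending character.
    """
    i = 0
    n = len(name)
    while i < n and (name[i].isalnum()):
        i += 1
    cls = name[:i]
    if not cls or not cls[0].isalpha():
        raise LipidParseError(name, 0, "expected a class token starting with a letter")
    if i >= n or name[i] != " ":
        raise LipidParseError(name, i, "expected a single space after the class token")
    i += 1

    def read_int(i: int) -> tuple[int, int]:
        j = i
        while j < n and name[j].isdigit():
            j += 1
        if j == i:
            raise LipidParseError(name, i, "expected a number")
        return int(name[i:j]), j

    chains: list[tuple[int, int]] = []
    while True:
        c, i = read_int(i)
        if i >= n or name[i] != ":":
            raise LipidParseError(name, i, "expected ':' between carbons and double bonds")
        d, i = read_int(i + 1)
        chains.append((c, d))
        if i == n:
            break
        if name[i] != "_":
            raise LipidParseError(name, i, "expected '_' between acyl chains or end of name")
        i += 1
        if len(chains) >= 3:
            raise LipidParseError(name, i, "at most 3 acyl chains supported")

    lipid_class = cls if cls in KNOWN_CLASSES else "other"
    if lipid_class == "other":
        warnings.warn(f"unknown lipid class {cls!r} in {name!r}; treating as 'other'")
    if len(chains) == 1:
        return LipidSpecies(lipid_class, chains[0][0], chains[0][1], None, cls)
    return LipidSpecies(
        lipid_class,
        sum(c for c, _ in chains),
        sum(d for _, d in chains),
        tuple(chains),
        cls,
    )


def format_lipid_name(species: LipidSpecies) -> str:
    """Canonical shorthand of a species; inverse of :func:`parse_lipid_name`."""
    if species.acyl_chains:
        chains = "_".join(f"{c}:{d}" for c, d in species.acyl_chains)
        return f"{species.class_label} {chains}"
    return f"{species.class_label} {species.total_carbons}:{species.total_double_bonds}"


def formate_adduct_mz(neutral_mass: float) -> float:
    """m/z of the [M+HCOO]- formate adduct observed in negative mode."""
    return neutral_mass + FORMATE_ADDUCT_DELTA


def _parse_annotations(annotations: pd.DataFrame) -> dict[str, LipidSpecies]:
    """feature_id -> parsed species, from a (feature_id, lipid_name) table."""
    if "lipid_name" not in annotations.columns:
        raise ValueError("annotations must have a 'lipid_name' column")
    return {str(fid): parse_lipid_name(str(nm))
            for fid, nm in annotations["lipid_name"].items()}


def _time_profile(table: FeatureTable, rows: pd.DataFrame) -> pd.Series:
    """Mean over replicates, per time point, of the per-sample sums in rows."""
    cells = table.cell_ids
    sums = rows[cells].sum(axis=0)
    times = table.sample_meta.loc[cells, "time_h"]
    return sums.groupby(times).mean()


def sum_by_class(table: FeatureTable, annotations: pd.DataFrame) -> pd.DataFrame:
    """Class x time-point profile of summed raw intensities.

    For each lipid class: the per-sample sum of member-species intensities,
    averaged over replicates at each time point. Intended for RAW (not
    quantile-normalized) intensities — class totals track cell growth, which
    is part of the signal here. Classes without any annotated species are
    simply absent from the result.
    """
    species = _parse_annotations(annotations)
    classes = sorted({sp.lipid_class for sp in species.values()})
    profiles = {}
    for cls in classes:
        fids = [fid for fid, sp in species.items() if sp.lipid_class == cls]
        fids = [f for f in fids if f in table.values.index]
        if not fids:
            warnings.warn(f"lipid class {cls} has no features in the table; omitted")
            continue
        profiles[cls] = _time_profile(table, table.values.loc[fids])
    return pd.DataFrame(profiles).T.rename_axis("lipid_class")


def pc_saturation_profile(
    table: FeatureTable, annotations: pd.DataFrame, weight: str = "intensity"
) -> pd.DataFrame:
    """Fraction of total PC intensity per double-bond bin, over time.

    Bins {0, 1-2, 3, >=4} partition the phosphatidylcholine species by total
    double-bond count; per sample, each bin's share of the summed PC
    intensity is computed and then averaged over replicates at each time
    point, so fractions sum to 1 at every time point. Use on
    quantile-normalized intensities (fractions are scale-free).
    ``weight="count"`` weights species equally instead of by intensity.
    """
    if weight not in ("intensity", "count"):
        raise ValueError("weight must be 'intensity' or 'count'")
    species = _parse_annotations(annotations)
    pc_ids = [fid for fid, sp in species.items()
              if sp.lipid_class == "PC" and fid in table.values.index]
    if not pc_ids:
        raise ValueError("no PC-annotated features in the table")
    cells = table.cell_ids
    vals = table.values.loc[pc_ids, cells]
    if weight == "count":
        vals = vals.where(vals <= 0, 1.0)
    bins = pd.Series({fid: species[fid].db_bin for fid in pc_ids})
    bin_sums = vals.groupby(bins).sum()  # bin x sample
    frac = bin_sums / bin_sums.sum(axis=0)
    times = table.sample_meta.loc[cells, "time_h"]
    out = frac.T.groupby(times).mean().T  # bin x time
    out = out.reindex(SATURATION_BINS).fillna(0.0)
    return out.rename_axis("db_bin")


def filter_by_fatty_acid(
    table: FeatureTable, annotations: pd.DataFrame, fa: tuple[int, int]
) -> pd.DataFrame:
    """Per-species time profiles of species containing a given fatty acid.

    ``fa`` is (carbons, double_bonds), e.g. ``(20, 4)`` for arachidonic acid.
    Requires chain-resolved annotations (single-fatty-acid names such as
    ``PC 16:0_20:4``, typically from negative-mode formate adducts of PCs).
    Returns a species x time DataFrame of replicate-mean intensities; empty
    if no species matches.
    """
    species = _parse_annotations(annotations)
    resolved = {fid: sp for fid, sp in species.items() if sp.acyl_chains is not None}
    if not resolved:
        raise ValueError(
            "no chain-resolved annotations: fatty-acid filtering needs names "
            "like 'PC 16:0_20:4' (e.g. from negative-mode formate adducts)"
        )
    hits = [fid for fid, sp in resolved.items()
            if sp.contains_fatty_acid(fa) and fid in table.values.index]
    cells = table.cell_ids
    times = table.sample_meta.loc[cells, "time_h"]
    rows = {}
    for fid in hits:
        rows[format_lipid_name(species[fid])] = (
            table.values.loc[fid, cells].groupby(times).mean()
        )
    out = pd.DataFrame(rows).T.rename_axis("species")
    return out
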