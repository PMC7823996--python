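"""Readers and writers for the pipeline's on-disk formats.

Feature tables travel as CSV (first columns: feature id, m/z, optional RT)
with a sample-metadata sidecar CSV (sample id, time_h, replicate, is_blank) —
the sidecar is the single source of truth for time/replicate/blank labels.
Spectra are read from mzML (centroid) via pyteomics or a 3-column TSV dialect
(sample_id, mz, intensity). Pathways come as GMT text or JSON; compound
databases as TSV. Deterministic outputs carry the run seed and config hash in
a comment header.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import FeatureTable, Spectrum
from .enrichment import PathwayDefinition
from .synthetic import CompoundRecord

__all__ = [
    "RunConfig",
    "write_feature_table",
    "read_feature_table",
    "write_spectra_tsv",
    "read_spectra_tsv",
    "read_mzml",
    "read_reference_masses",
    "write_compound_db",
    "read_compound_db",
    "write_pathways_gmt",
    "read_pathways_gmt",
    "write_pathways_json",
    "read_pathways_json",
    "write_annotations",
]

_META_COLS = ["mz", "rt"]


@dataclass
class RunConfig:
    """Per-run parameters; serializable to YAML and hashable for provenance."""

    seed: int = 0
    polarity: str = "-"
    method: str = "FIA"  # FIA | HILIC | polarRP | Lipids
    top_n: int = 1000
    tol_ppm: float = 5.0
    match_tol: float = 0.01
    delta_tol: float = 0.005
    annotation_tol_mDa: float = 3.0
    alpha: float = 0.05
    spline_df: int = 5
    n_components: int = 2
    n_perm: int = 1000
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("tol_ppm", "match_tol", "delta_tol", "annotation_tol_mDa"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.method not in ("FIA", "HILIC", "polarRP", "Lipids"):
            raise ValueError(f"unknown method label {self.method!r}")

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "extra"}
        d.update(self.extra)
        return d

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def header(self) -> str:
        return f"# metabodyn config_hash={self.config_hash} seed={self.seed}\n"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {k: data.pop(k) for k in list(data) if k in cls.__dataclass_fields__}
        return cls(**known, extra=data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _write_with_header(df: pd.DataFrame, path, config: RunConfig | None,
                       index: bool = True, sep: str = ",") -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if config is not None:
            fh.write(config.header())
        df.to_csv(fh, index=index, sep=sep)


def write_feature_table(table: FeatureTable, path, sidecar_path=None,
                        config: RunConfig | None = None) -> None:
    """Write a feature table CSV (+ sample-metadata sidecar CSV).

    The sidecar defaults to ``<path stem>.samples.csv``.
    """
    meta_cols = [c for c in _META_COLS if c in table.feature_meta.columns]
    out = pd.concat([table.feature_meta[meta_cols], table.values], axis=1)
    _write_with_header(out, path, config)
    if sidecar_path is None:
        p = Path(path)
        sidecar_path = p.with_suffix(".samples.csv")
    _write_with_header(table.sample_meta, sidecar_path, config)


def read_feature_table(path, sidecar_path=None) -> FeatureTable:
    """Read a feature table CSV and its sample-metadata sidecar."""
    if sidecar_path is None:
        sidecar_path = Path(path).with_suffix(".samples.csv")
    df = pd.read_csv(path, comment="#", index_col=0)
    meta_cols = [c for c in _META_COLS if c in df.columns]
    feature_meta = df[meta_cols].copy()
    values = df.drop(columns=meta_cols)
    sample_meta = pd.read_csv(sidecar_path, comment="#", index_col=0)
    sample_meta["is_blank"] = sample_meta["is_blank"].astype(bool)
    return FeatureTable(values, feature_meta, sample_meta)


def write_spectra_tsv(spectra: list[Spectrum], path,
                      config: RunConfig | None = None) -> None:
    """Write centroided spectra in the 3-column TSV dialect."""
    frames = [
        pd.DataFrame({"sample_id": sp.sample_id, "mz": sp.mz, "intensity": sp.intensity})
        for sp in spectra
    ]
    _write_with_header(pd.concat(frames, ignore_index=True), path, config,
                       index=False, sep="\t")


def read_spectra_tsv(path, polarity: str = "-") -> list[Spectrum]:
    """Read spectra from the 3-column TSV dialect (sample_id, mz, intensity)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"sample_id", "mz", "intensity"}
    if not required.issubset(df.columns):
        raise ValueError(f"spectra TSV needs columns {sorted(required)}")
    out = []
    for sid, grp in df.groupby("sample_id", sort=True):
        out.append(Spectrum(str(sid), grp["mz"].to_numpy(), grp["intensity"].to_numpy(),
                            polarity))
    return out


def read_mzml(path, polarity: str = "-") -> list[Spectrum]:
    """Read centroided MS1 spectra from an mzML file (one Spectrum per scan)."""
    from pyteomics import mzml as _mzml

    out = []
    with _mzml.MzML(str(path)) as reader:
        for i, scan in enumerate(reader):
            if scan.get("ms level", 1) != 1:
                continue
            sid = scan.get("id", f"scan{i}")
            out.append(Spectrum(str(sid), np.asarray(scan["m/z array"]),
                                np.asarray(scan["intensity array"]), polarity))
    return out


def read_reference_masses(path) -> list[float]:
    """Read a one-column text file of reference masses (Da); '#' comments."""
    masses = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                masses.append(float(line))
    return masses


def write_compound_db(db: list[CompoundRecord], path) -> None:
    pd.DataFrame(
        [(c.compound_id, c.name, c.formula, c.monoisotopic_mass) for c in db],
        columns=["compound_id", "name", "formula", "monoisotopic_mass"],
    ).to_csv(path, sep="\t", index=False)


def read_compound_db(path) -> list[CompoundRecord]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        CompoundRecord(str(r.compound_id), str(r.name), str(r.formula),
                       float(r.monoisotopic_mass))
        for r in df.itertuples(index=False)
    ]


def write_pathways_gmt(pathways: list[PathwayDefinition], path) -> None:
    """GMT format: pathway_id <tab> description <tab> member1 <tab> member2 ..."""
    with open(path, "w") as fh:
        for pw in pathways:
            fh.write("\t".join([pw.pathway_id, pw.name, *pw.members]) + "\n")


def read_pathways_gmt(path) -> list[PathwayDefinition]:
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: GMT line needs id, description, members")
            out.append(PathwayDefinition(parts[0], parts[1], tuple(parts[2:])))
    return out


def write_pathways_json(pathways: list[PathwayDefinition], path) -> None:
    data = {pw.pathway_id: {"name": pw.name, "members": list(pw.members)}
            for pw in pathways}
    with open(path, "w") as fh:
        json.dump(data, fh, indent=1)


def read_pathways_json(path) -> list[PathwayDefinition]:
    with open(path) as fh:
        data = json.load(fh)
    return [PathwayDefinition(pid, d.get("name", pid), tuple(d["members"]))
            for pid, d in data.items()]


def write_annotations(annotations, path, config: RunConfig | None = None) -> None:
    """Annotations TSV: feature_id, compound, adduct, mass_error_mDa."""
    rows = [
        (a.feature_id, cid, adduct, err)
        for a in annotations
        for cid, adduct, err in a.candidates
    ]
    df = pd.DataFrame(rows, columns=["feature_id", "compound", "adduct",
                                     "mass_error_mDa"])
    _write_with_header(df, path, config, index=False, sep="\t")
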