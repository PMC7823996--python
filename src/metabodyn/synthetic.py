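"""Synthetic study generator with embedded ground truth.

Emulates a 9-time-point (0-96 h, every 12 h) T cell activation time course
measured by flow-injection high-resolution MS: three biological replicates per
time point, a sterile-well blank, a tune-mix reference-mass series, planted
monotone and transient intensity trends, 13C isotopologue chains spaced
1.00335 Da, a quadratic drift of the mass axis, and multiplicative log-normal
intensity noise. Every generator records what it planted in a
:class:`SyntheticTruth` so downstream stages can be scored against known truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chem import (
    C13_DELTA,
    PROTON_MASS,
    TUNE_MIX_NEGATIVE,
    adduct_mz,
    isotopologue_ratio,
    monoisotopic_mass,
)
from .containers import FeatureTable, Spectrum

__all__ = [
    "StudyDesign",
    "PlantedFeature",
    "SyntheticTruth",
    "CompoundRecord",
    "trend_multiplier",
    "generate_feature_table",
    "generate_fia_spectra",
    "generate_compound_db",
    "generate_pathways",
    "generate_lipid_table",
]

DEFAULT_TIME_POINTS = (0.0, 12.0, 24.0, 36.0, 48.0, 60.0, 72.0, 84.0, 96.0)

#: m/z scan range of the emulated QTOF acquisition, in Da.
SCAN_RANGE = (20.0, 1050.0)

#: Blank background level for cell-derived features, as a fraction of
#: base_intensity: clearly separable from cells but nonzero, so the
#: above-blank t-test filter is exercised nontrivially.
BLANK_BACKGROUND_FRACTION = 0.05

#: Isotopologues with expected I(M+k)/I(M) below this are not planted.
ISOTOPE_MIN_RATIO = 0.02

#: Default quadratic mass drift (a, b, c): observed = true + a + b*m + c*m^2.
DEFAULT_DRIFT = (1e-3, 2e-6, 5e-10)

TREND_CLASSES = ("flat", "monotone_up", "monotone_down", "transient")


@dataclass(frozen=True)
class StudyDesign:
    """Sampling layout of the time-course experiment.

    time_points are hours post activation (default 0-96 h every 12 h);
    n_replicates biological replicates per time point; blank_replicates
    sterile-well blank samples (default 3 so the two-sample blank t-test has
    at least two observations per group).
    """

    time_points: tuple[float, ...] = DEFAULT_TIME_POINTS
    n_replicates: int = 3
    blank_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        tp = tuple(float(t) for t in self.time_points)
        if len(tp) < 2 or any(b <= a for a, b in zip(tp, tp[1:])):
            raise ValueError("time_points must be strictly increasing")
        if self.n_replicates < 1 or self.blank_replicates < 1:
            raise ValueError("replicate counts must be >= 1")
        object.__setattr__(self, "time_points", tp)

    @property
    def cell_sample_ids(self) -> list[str]:
        return [
            f"T{int(t):03d}_R{r + 1}"
            for t in self.time_points
            for r in range(self.n_replicates)
        ]

    @property
    def blank_sample_ids(self) -> list[str]:
        return [f"BLANK_B{r + 1}" for r in range(self.blank_replicates)]

    def sample_meta(self) -> pd.DataFrame:
        """Sample metadata sidecar: time_h (NaN for blanks), replicate, is_blank."""
        rows = []
        for t in self.time_points:
            for r in range(self.n_replicates):
                rows.append((f"T{int(t):03d}_R{r + 1}", float(t), r + 1, False))
        for r in range(self.blank_replicates):
            rows.append((f"BLANK_B{r + 1}", np.nan, r + 1, True))
        meta = pd.DataFrame(rows, columns=["sample_id", "time_h", "replicate", "is_blank"])
        return meta.set_index("sample_id")


@dataclass
class PlantedFeature:
    """One planted m/z feature and its intended time behaviour."""

    feature_id: str
    true_mz: float
    n_carbons: int
    trend_class: str
    trend_params: dict
    base_intensity: float
    above_blank: bool
    compound_id: str | None = None

    def __post_init__(self) -> None:
        if not (SCAN_RANGE[0] <= self.true_mz <= SCAN_RANGE[1]):
            raise ValueError(f"true_mz {self.true_mz} outside scan range {SCAN_RANGE}")
        if self.base_intensity <= 0:
            raise ValueError("base_intensity must be positive")
        if self.trend_class not in TREND_CLASSES:
            raise ValueError(f"unknown trend_class {self.trend_class!r}")


@dataclass
class SyntheticTruth:
    """Ground truth of a generated study: planted features, mass drift,
    isotope chain memberships and (once pathways are generated) the single
    planted-enriched pathway id."""

    features: list[PlantedFeature]
    drift: tuple[float, float, float]
    isotope_chains: dict[str, list[int]] = field(default_factory=dict)
    planted_pathway_id: str | None = None

    def trend_classes(self) -> pd.Series:
        return pd.Series(
            {f.feature_id: f.trend_class for f in self.features}, name="trend_class"
        )

    @property
    def trended_feature_ids(self) -> list[str]:
        return [f.feature_id for f in self.features if f.trend_class != "flat"]


@dataclass(frozen=True)
class CompoundRecord:
    """Annotation-database entry: a named compound with an elemental formula
    and its monoisotopic mass."""

    compound_id: str
    name: str
    formula: str
    monoisotopic_mass: float


def trend_multiplier(trend_class: str, trend_params: dict, t: np.ndarray) -> np.ndarray:
    """Deterministic fold-change multiplier of a trend at time(s) t (hours).

    Monotone trends are logistic in time (levels plateau, as polyamines do
    after activation); transient trends are a Gaussian bump centered at a
    sampled time point (as methyl-thioadenosine does). Flat is identically 1.
    """
    t = np.asarray(t, dtype=float)
    if trend_class == "flat":
        return np.ones_like(t)
    a = float(trend_params["amplitude"])
    t0 = float(trend_params["t0"])
    w = float(trend_params["width"])
    if trend_class == "monotone_up":
        return 1.0 + a / (1.0 + np.exp(-(t - t0) / w))
    if trend_class == "monotone_down":
        return 1.0 + a - a / (1.0 + np.exp(-(t - t0) / w))
    if trend_class == "transient":
        return 1.0 + a * np.exp(-0.5 * ((t - t0) / w) ** 2)
    raise ValueError(f"unknown trend_class {trend_class!r}")


def _draw_trend_params(rng: np.random.Generator, trend_class: str,
                       amplitude_range: tuple[float, float]) -> dict:
    a = rng.uniform(*amplitude_range)
    if trend_class == "transient":
        return {"amplitude": a, "t0": rng.uniform(24.0, 60.0), "width": rng.uniform(8.0, 14.0)}
    return {"amplitude": a, "t0": rng.uniform(12.0, 48.0), "width": rng.uniform(6.0, 10.0)}


def generate_feature_table(
    design: StudyDesign,
    n_features: int = 500,
    frac_trend: float = 0.5,
    noise_cv: float = 0.1,
    seed: int = 0,
    *,
    frac_above_blank: float = 0.8,
    amplitude_range: tuple[float, float] = (1.0, 3.0),
    drift: tuple[float, float, float] = DEFAULT_DRIFT,
    compound_db: list[CompoundRecord] | None = None,
    polarity: str = "-",
) -> tuple[FeatureTable, SyntheticTruth]:
    """Generate a feature × sample intensity table with planted time trends.

    Exactly ``round(frac_trend * n_features)`` features receive a non-flat
    trend (split between monotone up, monotone down and transient); the rest
    are flat. Observed intensity of feature f in a cell sample at time t is
    ``base_intensity * trend(t) * exp(eps)`` with ``eps ~ N(0, log(1+noise_cv))``.
    Blank columns of cell-derived (above_blank) features draw from a low
    background at 5% of base_intensity; medium-derived features show the same
    level in blanks as in cells.

    When ``compound_db`` is given, planted m/z values are the [M-H]- / [M+H]+
    adduct masses of randomly chosen database compounds (carbon counts taken
    from the formula), so that exact-mass annotation links features back to
    compounds; otherwise m/z are uniform over the scan range.
    """
    if n_features < 1:
        raise ValueError("n_features must be >= 1")
    if not (0.0 <= frac_trend <= 1.0):
        raise ValueError("frac_trend must be in [0, 1]")
    if not (0.0 <= frac_above_blank <= 1.0):
        raise ValueError("frac_above_blank must be in [0, 1]")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")

    rng = np.random.default_rng(seed)

    if compound_db is not None:
        if n_features > len(compound_db):
            raise ValueError("n_features exceeds the size of compound_db")
        picks = rng.choice(len(compound_db), size=n_features, replace=False)
        chosen = [compound_db[i] for i in picks]
        mzs = np.array([adduct_mz(c.monoisotopic_mass, polarity) for c in chosen])
        carbons = np.array([_count_carbons(c.formula) for c in chosen])
        compound_ids: list[str | None] = [c.compound_id for c in chosen]
        # keep only in-scan-range compounds
        ok = (mzs >= SCAN_RANGE[0]) & (mzs <= SCAN_RANGE[1])
        if not ok.all():
            raise ValueError("compound_db contains adduct masses outside the scan range")
    else:
        mzs = rng.uniform(60.0, 1040.0, size=n_features)
        # metabolite-like carbon counts: about one carbon per 19 Da, jittered
        carbons = np.clip(
            np.round(mzs / 19.0 + rng.normal(0, 2, size=n_features)), 2, 60
        ).astype(int)
        compound_ids = [None] * n_features

    order = np.argsort(mzs, kind="stable")
    mzs = mzs[order]
    carbons = np.asarray(carbons)[order]
    compound_ids = [compound_ids[i] for i in order]

    n_trend = int(round(frac_trend * n_features))
    trend_classes = np.array(["flat"] * n_features, dtype=object)
    trended_idx = rng.choice(n_features, size=n_trend, replace=False)
    kinds = ("monotone_up", "monotone_down", "transient")
    for j, idx in enumerate(trended_idx):
        trend_classes[idx] = kinds[j % len(kinds)]

    above = rng.random(n_features) < frac_above_blank
    above[trended_idx] = True  # a cell-intrinsic trend implies a cell-derived feature

    base = 10 ** rng.uniform(4.7, 7.7, size=n_features)
    sigma = math.log1p(noise_cv)
    times = np.array(design.time_points)

    features: list[PlantedFeature] = []
    chains: dict[str, list[int]] = {}
    for i in range(n_features):
        fid = f"F{i + 1:05d}"
        params = (
            _draw_trend_params(rng, trend_classes[i], amplitude_range)
            if trend_classes[i] != "flat"
            else {}
        )
        pf = PlantedFeature(
            feature_id=fid,
            true_mz=float(mzs[i]),
            n_carbons=int(carbons[i]),
            trend_class=str(trend_classes[i]),
            trend_params=params,
            base_intensity=float(base[i]),
            above_blank=bool(above[i]),
            compound_id=compound_ids[i],
        )
        features.append(pf)
        ks = []
        for k in (1, 2, 3):
            if (
                isotopologue_ratio(pf.n_carbons, k) >= ISOTOPE_MIN_RATIO
                and pf.true_mz + k * C13_DELTA <= SCAN_RANGE[1]
            ):
                ks.append(k)
            else:
                break
        if ks:
            chains[fid] = ks

    cell_ids = design.cell_sample_ids
    blank_ids = design.blank_sample_ids
    mat = np.empty((n_features, len(cell_ids) + len(blank_ids)))
    for i, pf in enumerate(features):
        mult = trend_multiplier(pf.trend_class, pf.trend_params, times)
        expected = pf.base_intensity * np.repeat(mult, design.n_replicates)
        eps = rng.normal(0.0, sigma, size=expected.size) if sigma > 0 else 0.0
        mat[i, : len(cell_ids)] = expected * np.exp(eps)
        blank_level = (
            pf.base_intensity * BLANK_BACKGROUND_FRACTION
            if pf.above_blank
            else pf.base_intensity
        )
        beps = rng.normal(0.0, sigma, size=len(blank_ids)) if sigma > 0 else 0.0
        mat[i, len(cell_ids):] = blank_level * np.exp(beps)

    index = pd.Index([f.feature_id for f in features], name="feature_id")
    values = pd.DataFrame(mat, index=index, columns=cell_ids + blank_ids)
    feature_meta = pd.DataFrame(
        {"mz": [f.true_mz for f in features],
         "n_carbons": [f.n_carbons for f in features]},
        index=index,
    )
    table = FeatureTable(values, feature_meta, design.sample_meta())
    truth = SyntheticTruth(features=features, drift=tuple(drift), isotope_chains=chains)
    return table, truth


def _count_carbons(formula: str) -> int:
    import re

    m = re.search(r"C(\d*)(?![a-z])", formula)
    if not m:
        return 0
    return int(m.group(1)) if m.group(1) else 1


def generate_fia_spectra(
    truth: SyntheticTruth,
    design: StudyDesign,
    tune_mix: tuple[float, ...] = TUNE_MIX_NEGATIVE,
    seed: int = 0,
    *,
    noise_cv: float = 0.1,
    min_peaks: int = 1200,
    polarity: str = "-",
) -> list[Spectrum]:
    """Generate one centroided FIA spectrum per sample (cells and blanks).

    Each spectrum contains the tune-mix reference peaks, every planted
    monoisotopic peak, 13C isotopologue peaks at +k*1.00335 Da whose intensity
    ratios follow the binomial model for the feature's carbon count, and
    uniform low-intensity noise peaks padding the list to ``min_peaks``. All
    observed m/z are shifted by the truth's quadratic drift
    a + b*m + c*m^2; all intensities are scaled by a per-sample injection
    efficiency so reference-based intensity normalization is exercised.
    """
    if len(tune_mix) < 3:
        raise ValueError("need at least 3 tune-mix reference masses for a quadratic fit")
    a, b, c = truth.drift
    if not all(math.isfinite(x) for x in (a, b, c)):
        raise ValueError("drift coefficients must be finite")

    rng = np.random.default_rng(seed)
    sigma = math.log1p(noise_cv)
    times = np.array(design.time_points)
    tune_mix = np.asarray(tune_mix, dtype=float)
    # fixed relative pattern of the tune-mix components
    tune_base = 5e6 * (1.0 + 0.25 * np.arange(len(tune_mix)))

    samples: list[tuple[str, float | None]] = [
        (sid, t)
        for t in times
        for sid in [f"T{int(t):03d}_R{r + 1}" for r in range(design.n_replicates)]
    ]
    samples += [(sid, None) for sid in design.blank_sample_ids]

    def drifted(m: np.ndarray) -> np.ndarray:
        return m + a + b * m + c * m**2

    spectra = []
    for sid, t in samples:
        gain = float(np.exp(rng.normal(0.0, 0.2)))  # injection efficiency
        mz_list = [tune_mix]
        int_list = [tune_base * gain]
        for pf in truth.features:
            if t is None:
                level = (
                    pf.base_intensity * BLANK_BACKGROUND_FRACTION
                    if pf.above_blank
                    else pf.base_intensity
                )
            else:
                level = pf.base_intensity * float(
                    trend_multiplier(pf.trend_class, pf.trend_params, np.array([t]))[0]
                )
            if sigma > 0:
                level *= float(np.exp(rng.normal(0.0, sigma)))
            level *= gain
            ks = truth.isotope_chains.get(pf.feature_id, [])
            mzs = [pf.true_mz] + [pf.true_mz + k * C13_DELTA for k in ks]
            ints = [level] + [level * isotopologue_ratio(pf.n_carbons, k) for k in ks]
            mz_list.append(np.array(mzs))
            int_list.append(np.array(ints))
        mz = np.concatenate(mz_list)
        inten = np.concatenate(int_list)
        n_noise = max(0, min_peaks - mz.size)
        if n_noise:
            nm = rng.uniform(SCAN_RANGE[0], SCAN_RANGE[1], size=n_noise)
            ni = np.exp(rng.uniform(np.log(5e2), np.log(2e4), size=n_noise)) * gain
            mz = np.concatenate([mz, nm])
            inten = np.concatenate([inten, ni])
        spectra.append(Spectrum(sid, drifted(mz), inten, polarity))
    return spectra


# -- compound database and pathways -------------------------------------------

_FORMULA_TEMPLATES = [
    # (C range, H per C range, N range, O range, P range, S range)
    ((3, 12), (1.2, 2.2), (0, 2), (1, 6), (0, 1), (0, 1)),   # small polar
    ((6, 20), (1.2, 2.0), (0, 4), (2, 8), (0, 2), (0, 0)),   # nucleotide-like
    ((10, 30), (1.5, 2.1), (0, 1), (2, 6), (0, 0), (0, 0)),  # acyl-like
]


def generate_compound_db(n: int = 300, seed: int = 0) -> list[CompoundRecord]:
    """Generate a synthetic annotation database of ``n`` compounds.

    Formulas are drawn from metabolite-like CHNOPS templates; monoisotopic
    masses are computed from the elemental formulas. Formulas are de-duplicated
    so no two records share a formula, but near-isobaric pairs (distinct
    formulas within a few mDa) arise naturally, exercising multi-annotation.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    seen: set[str] = set()
    records: list[CompoundRecord] = []
    i = 0
    while len(records) < n:
        i += 1
        tmpl = _FORMULA_TEMPLATES[rng.integers(len(_FORMULA_TEMPLATES))]
        c = int(rng.integers(tmpl[0][0], tmpl[0][1] + 1))
        h = max(2, int(round(c * rng.uniform(*tmpl[1]))))
        nn = int(rng.integers(tmpl[2][0], tmpl[2][1] + 1))
        o = int(rng.integers(tmpl[3][0], tmpl[3][1] + 1))
        p = int(rng.integers(tmpl[4][0], tmpl[4][1] + 1))
        s = int(rng.integers(tmpl[5][0], tmpl[5][1] + 1))
        formula = f"C{c}H{h}"
        if nn:
            formula += f"N{nn}"
        if o:
            formula += f"O{o}"
        if p:
            formula += f"P{p}"
        if s:
            formula += f"S{s}"
        if formula in seen:
            continue
        seen.add(formula)
        mass = monoisotopic_mass(formula)
        if not (SCAN_RANGE[0] + PROTON_MASS < mass < SCAN_RANGE[1] - PROTON_MASS):
            continue
        cid = f"C{len(records) + 1:05d}"
        records.append(CompoundRecord(cid, f"compound_{cid}", formula, mass))
    return records


def planted_pathway_members(
    truth: SyntheticTruth, design: StudyDesign, n: int = 15
) -> list[str]:
    """Compound ids of the ``n`` strongest trenders — the natural membership
    of a planted-enriched pathway.

    A coherently regulated pathway shows up in enrichment because its members
    all change strongly with time (as polyamine biosynthesis does during T
    cell activation). Features are scored by the standard deviation of their
    log trend multiplier over the design's time points — the planted total
    time variation, evaluated from the truth alone, before any analysis runs.
    Requires a compound-linked truth (table generated with a compound_db).
    """
    times = np.array(design.time_points)
    scored = []
    for f in truth.features:
        if f.trend_class == "flat" or not f.compound_id:
            continue
        m = np.log(trend_multiplier(f.trend_class, f.trend_params, times))
        scored.append((float(np.std(m)), f.compound_id))
    if len(scored) < n:
        raise ValueError(
            f"truth has only {len(scored)} compound-linked trenders; need {n}"
        )
    scored.sort(reverse=True)
    return [c for _, c in scored[:n]]


def generate_pathways(
    db: list[CompoundRecord],
    n_sets: int = 10,
    set_size: int = 15,
    planted_members: list[str] | None = None,
    seed: int = 0,
    truth: SyntheticTruth | None = None,
):
    """Generate pathway definitions; exactly one pathway is the planted set.

    ``planted_members`` (compound ids, must exist in ``db``) become the single
    planted-enriched pathway with id ``"PW_PLANTED"``; the remaining
    ``n_sets - 1`` pathways are random draws of ``set_size`` compounds. If a
    ``truth`` is passed, its ``planted_pathway_id`` is recorded.
    """
    from .enrichment import PathwayDefinition

    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    db_ids = {c.compound_id for c in db}
    planted_members = list(planted_members or [])
    missing = [m for m in planted_members if m not in db_ids]
    if missing:
        raise ValueError(f"planted members not in compound db: {missing[:5]}")
    rng = np.random.default_rng(seed)
    pathways = []
    if planted_members:
        pathways.append(
            PathwayDefinition("PW_PLANTED", "planted pathway", tuple(planted_members))
        )
    all_ids = sorted(db_ids)
    while len(pathways) < n_sets:
        members = rng.choice(all_ids, size=min(set_size, len(all_ids)), replace=False)
        pid = f"PW{len(pathways):03d}"
        pathways.append(PathwayDefinition(pid, f"random pathway {pid}", tuple(sorted(members))))
    if truth is not None and planted_members:
        truth.planted_pathway_id = "PW_PLANTED"
    return pathways


# -- lipidomics table ----------------------------------------------------------

_LIPID_SPECIES = {
    # class -> (species names, class time profile kind)
    "PC": (
        [
            "PC 32:0", "PC 34:0",                      # 0 double bonds
            "PC 32:1", "PC 34:1", "PC 34:2", "PC 36:2",  # 1-2
            "PC 36:3", "PC 34:3",                      # 3
            "PC 36:4", "PC 38:4", "PC 38:6", "PC 40:6",  # >= 4
        ],
        "up",
    ),
    "TAG": (["TAG 50:1", "TAG 52:2", "TAG 54:3"], "up"),
    "HexCer": (["HexCer 34:1", "HexCer 42:2"], "up"),
    "PE": (["PE 34:1", "PE 36:2", "PE 38:4"], "transient"),
    "LPC": (["LPC 16:0", "LPC 18:1"], "transient"),
    "LPE": (["LPE 16:0", "LPE 18:1"], "transient"),
    "SM": (["SM 34:1", "SM 42:2"], "down"),
}

#: Chain-resolved identities for a subset of PC species (negative-mode formate
#: adducts resolve single fatty acids).
_CHAIN_RESOLVED = {
    "PC 36:4": "PC 16:0_20:4",
    "PC 38:4": "PC 18:0_20:4",
    "PC 38:6": "PC 16:0_22:6",
    "PC 34:1": "PC 16:0_18:1",
    "PC 34:2": "PC 16:0_18:2",
    "PC 32:0": "PC 16:0_16:0",
}


def _db_bin(name: str) -> str:
    db = int(name.split(":")[-1])
    if db == 0:
        return "0"
    if db <= 2:
        return "1-2"
    if db == 3:
        return "3"
    return ">=4"


def generate_lipid_table(
    design: StudyDesign,
    seed: int = 0,
    *,
    noise_cv: float = 0.05,
    poly_start: float = 0.6,
    poly_end: float = 0.25,
    shift_end_h: float = 48.0,
    chain_resolved: bool = True,
) -> tuple[FeatureTable, pd.DataFrame, dict]:
    """Generate a lipidomics feature table with a planted PC saturation shift.

    The fraction of total phosphatidylcholine intensity carried by
    polyunsaturated species (>= 4 double bonds) declines from ``poly_start``
    to ``poly_end`` over the first ``shift_end_h`` hours and plateaus after,
    emulating the acyl-chain remodeling of activating T cells; the displaced
    intensity moves into the 1-2 double-bond bin. Class totals follow
    class-specific profiles (PC/TAG/HexCer rising, PE/LPC/LPE transient, SM
    declining). Returns ``(table, annotations, truth)`` where ``annotations``
    maps feature_id -> lipid shorthand name (chain-resolved where available)
    and ``truth`` records the planted bin fractions per time point.
    """
    rng = np.random.default_rng(seed)
    times = np.array(design.time_points)
    sigma = math.log1p(noise_cv)

    def class_profile(kind: str) -> np.ndarray:
        if kind == "up":
            return 1.0 + 2.0 / (1.0 + np.exp(-(times - 36.0) / 10.0))
        if kind == "down":
            return 1.0 + 0.6 - 0.6 / (1.0 + np.exp(-(times - 36.0) / 10.0))
        return 1.0 + 1.5 * np.exp(-0.5 * ((times - 48.0) / 16.0) ** 2)

    # planted polyunsaturated fraction per time point (monotone decline,
    # plateau after shift_end_h)
    prog = np.clip(times / shift_end_h, 0.0, 1.0)
    poly_frac = poly_start + (poly_end - poly_start) * prog
    other_bins = {"0": 0.08, "1-2": 0.0, "3": 0.10}  # "1-2" absorbs the rest

    rows = []
    names = []
    fids = []
    bin_members = {
        b: [s for s in _LIPID_SPECIES["PC"][0] if _db_bin(s) == b]
        for b in ("0", "1-2", "3", ">=4")
    }
    cell_n = len(design.cell_sample_ids)
    blank_n = len(design.blank_sample_ids)
    i = 0
    for cls, (species, kind) in _LIPID_SPECIES.items():
        prof = class_profile(kind)
        class_total = {"PC": 4e7, "TAG": 2e7, "HexCer": 5e6, "PE": 8e6,
                       "LPC": 3e6, "LPE": 2e6, "SM": 6e6}[cls]
        for sp in species:
            i += 1
            fid = f"L{i:04d}"
            if cls == "PC":
                b = _db_bin(sp)
                if b == ">=4":
                    frac_t = poly_frac
                elif b == "1-2":
                    frac_t = 1.0 - poly_frac - other_bins["0"] - other_bins["3"]
                else:
                    frac_t = np.full_like(times, other_bins[b])
                expected = class_total * prof * frac_t / len(bin_members[b])
            else:
                expected = class_total * prof / len(species)
            per_sample = np.repeat(expected, design.n_replicates)
            eps = rng.normal(0.0, sigma, size=cell_n) if sigma > 0 else 0.0
            cells = per_sample * np.exp(eps)
            blanks = (
                0.02
                * float(np.mean(expected))
                * np.exp(rng.normal(0.0, sigma, size=blank_n) if sigma > 0 else 0.0)
            )
            rows.append(np.concatenate([cells, np.atleast_1d(blanks) * np.ones(blank_n)]))
            name = _CHAIN_RESOLVED.get(sp, sp) if chain_resolved else sp
            names.append(name)
            fids.append(fid)

    index = pd.Index(fids, name="feature_id")
    values = pd.DataFrame(
        np.vstack(rows), index=index,
        columns=design.cell_sample_ids + design.blank_sample_ids,
    )
    # nominal m/z: PC-like masses are not used by the lipid analytics, but the
    # container requires an mz column
    feature_meta = pd.DataFrame({"mz": 600.0 + 2.0 * np.arange(len(fids))}, index=index)
    table = FeatureTable(values, feature_meta, design.sample_meta())
    annotations = pd.DataFrame({"feature_id": fids, "lipid_name": names}).set_index(
        "feature_id"
    )
    truth = {
        "poly_fraction_by_time": dict(zip(map(float, times), map(float, poly_frac))),
        "poly_start": poly_start,
        "poly_end": poly_end,
        "shift_end_h": shift_end_h,
    }
    return table, annotations, truth
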