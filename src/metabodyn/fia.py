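"""Flow-injection MS1 feature extraction.

Mirrors the in-house processing chain for direct-infusion QTOF data: the
tune-mix reference ions drive a quadratic recalibration of the mass axis and
an intensity normalization; the 1000 most intense peaks per sample are
detected and combined into a consensus feature list across samples; gaps are
filled from the raw data at the consensus m/z; consecutive isotopologue
chains (+1.00335 Da with carbon-plausible intensity ratios) are collapsed
onto the monoisotopic feature; and features are annotated by exact mass
against a compound database assuming [M+H]+ / [M-H]- ions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chem import C13_DELTA, C13_ABUNDANCE, PROTON_MASS
from .containers import FeatureTable, Spectrum
from .synthetic import CompoundRecord  # annotation database records

logger = logging.getLogger(__name__)

__all__ = [
    "CalibrationError",
    "NormalizationError",
    "CalibrationModel",
    "ConsensusFeature",
    "Annotation",
    "fit_mass_recalibration",
    "apply_recalibration",
    "normalize_by_reference",
    "detect_top_peaks",
    "build_consensus_features",
    "fill_gaps",
    "collapse_isotopes",
    "default_max_isotope_ratio",
    "annotate_features",
    "process_fia_batch",
]


class CalibrationError(ValueError):
    """Raised when too few reference masses can be matched for recalibration."""


class NormalizationError(ValueError):
    """Raised when no reference peak is available for intensity normalization."""


@dataclass
class CalibrationModel:
    """Quadratic mass-axis correction.

    ``coefficients`` = (c0, c1, c2) of the drift polynomial
    d(m) = c0 + c1*m + c2*m^2 expressed in the *true* m/z; an observed peak at
    x satisfies x = m + d(m). ``residuals`` are the fit residuals at the
    matched reference masses (Da). The identity model is (0, 0, 0).
    """

    coefficients: tuple[float, float, float]
    residuals: np.ndarray = field(default_factory=lambda: np.zeros(0))
    reference_masses: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def drift(self, m: np.ndarray) -> np.ndarray:
        c0, c1, c2 = self.coefficients
        m = np.asarray(m, dtype=float)
        return c0 + c1 * m + c2 * m**2

    def correct(self, observed_mz: np.ndarray, n_iter: int = 3) -> np.ndarray:
        """Corrected (true) m/z for observed peaks.

        Solves m + d(m) = x by fixed-point iteration m <- x - d(m), starting
        from m = x; the drift is a few mDa so this converges to well below
        1e-9 Da in two or three steps.
        """
        x = np.asarray(observed_mz, dtype=float)
        m = x - self.drift(x)
        for _ in range(n_iter - 1):
            m = x - self.drift(m)
        return m


def _match_references(
    spectrum: Spectrum, reference_masses, match_tol: float
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """Indices of the most intense spectrum peak within match_tol of each
    reference mass; returns (matched ref masses, matched peak indices,
    unmatched refs)."""
    refs = np.asarray(reference_masses, dtype=float)
    matched_refs, matched_idx, unmatched = [], [], []
    for r in refs:
        lo = np.searchsorted(spectrum.mz, r - match_tol, side="left")
        hi = np.searchsorted(spectrum.mz, r + match_tol, side="right")
        if hi > lo:
            j = lo + int(np.argmax(spectrum.intensity[lo:hi]))
            matched_refs.append(r)
            matched_idx.append(j)
        else:
            unmatched.append(float(r))
    return np.asarray(matched_refs), np.asarray(matched_idx, dtype=int), unmatched


def fit_mass_recalibration(
    spectrum: Spectrum, reference_masses, match_tol: float = 0.01
) -> CalibrationModel:
    """Fit a quadratic mass-axis recalibration from tune-mix reference ions.

    Each reference mass is matched to the most intense peak within
    ``match_tol`` Da; the drift (observed - reference) is fit by least squares
    as a quadratic polynomial in the reference mass. At least 3 references
    must match (a quadratic needs 3 points).

    Raises
    ------
    CalibrationError
        If fewer than 3 references match; the message names the unmatched
        reference masses.
    """
    refs, idx, unmatched = _match_references(spectrum, reference_masses, match_tol)
    if len(refs) < 3:
        raise CalibrationError(
            f"only {len(refs)} reference masses matched within {match_tol} Da; "
            f"need >= 3. Unmatched references: {unmatched}"
        )
    observed = spectrum.mz[idx]
    drift = observed - refs
    # Vandermonde in the reference (true) mass: exact coefficient recovery on
    # noise-free drift that is polynomial in the true m/z.
    coeffs = np.polynomial.polynomial.polyfit(refs, drift, 2)
    model = CalibrationModel(tuple(float(c) for c in coeffs))
    model.residuals = drift - model.drift(refs)
    model.reference_masses = refs
    return model


def apply_recalibration(spectrum: Spectrum, model: CalibrationModel) -> Spectrum:
    """Return the spectrum with the mass axis corrected by the model."""
    return spectrum.with_peaks(model.correct(spectrum.mz), spectrum.intensity.copy())


def normalize_by_reference(
    spectrum: Spectrum, reference_masses, match_tol: float = 0.01
) -> Spectrum:
    """Divide all intensities by the summed intensity of matched tune-mix peaks.

    Raises
    ------
    NormalizationError
        If no reference mass matches any peak.
    """
    refs, idx, _ = _match_references(spectrum, reference_masses, match_tol)
    if len(refs) == 0:
        raise NormalizationError(
            f"no reference mass matched within {match_tol} Da in sample "
            f"{spectrum.sample_id}"
        )
    total = float(spectrum.intensity[idx].sum())
    return spectrum.with_peaks(spectrum.mz.copy(), spectrum.intensity / total)


def detect_top_peaks(spectrum: Spectrum, n: int = 1000) -> Spectrum:
    """The ``n`` most intense peaks, returned m/z-sorted.

    Ties at rank ``n`` are broken toward the lower m/z (deterministic). If the
    spectrum has fewer than ``n`` peaks, all are returned.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if len(spectrum) <= n:
        return spectrum.with_peaks(spectrum.mz.copy(), spectrum.intensity.copy())
    order = np.lexsort((spectrum.mz, -spectrum.intensity))[:n]
    keep = np.sort(order)
    return spectrum.with_peaks(spectrum.mz[keep], spectrum.intensity[keep])


@dataclass
class ConsensusFeature:
    """A cross-sample consensus feature from single-linkage m/z clustering."""

    feature_id: str
    representative_mz: float  # intensity-weighted mean of member peaks
    members: dict[str, tuple[float, float]]  # sample_id -> (mz, intensity)
    isotope_role: str = "singleton"  # monoisotopic | isotope(k) | singleton


def build_consensus_features(
    peaklists: list[Spectrum], tol_ppm: float = 5.0
) -> list[ConsensusFeature]:
    """Combine per-sample peak lists into a consensus feature list.

    Peaks from all samples are pooled, sorted by m/z, and clustered by single
    linkage: consecutive peaks closer than ``tol_ppm`` belong to one cluster.
    Each sample contributes at most one peak per cluster (the most intense);
    the representative m/z is the intensity-weighted mean over the retained
    member peaks. Clustering is independent of sample order.
    """
    if not peaklists:
        raise ValueError("need at least one sample peak list")
    mzs, ints, sids = [], [], []
    for sp in peaklists:
        mzs.append(sp.mz)
        ints.append(sp.intensity)
        sids.extend([sp.sample_id] * len(sp))
    mz = np.concatenate(mzs) if mzs else np.zeros(0)
    inten = np.concatenate(ints) if ints else np.zeros(0)
    sids = np.asarray(sids, dtype=object)
    order = np.lexsort((sids, mz))  # secondary key makes ordering total
    mz, inten, sids = mz[order], inten[order], sids[order]

    features: list[ConsensusFeature] = []
    if mz.size == 0:
        return features
    gaps = np.diff(mz) > tol_ppm * 1e-6 * mz[:-1]
    cluster_starts = np.concatenate([[0], np.flatnonzero(gaps) + 1, [mz.size]])
    for ci in range(len(cluster_starts) - 1):
        lo, hi = cluster_starts[ci], cluster_starts[ci + 1]
        members: dict[str, tuple[float, float]] = {}
        for j in range(lo, hi):
            s = sids[j]
            if s not in members or inten[j] > members[s][1]:
                members[s] = (float(mz[j]), float(inten[j]))
        w = np.array([v[1] for v in members.values()])
        m = np.array([v[0] for v in members.values()])
        rep = float((m * w).sum() / w.sum()) if w.sum() > 0 else float(m.mean())
        features.append(ConsensusFeature(f"FIA{ci + 1:05d}", rep, members))
    features.sort(key=lambda f: f.representative_mz)
    for i, f in enumerate(features):
        f.feature_id = f"FIA{i + 1:05d}"
    return features


def fill_gaps(
    spectra: list[Spectrum],
    consensus_features: list[ConsensusFeature],
    tol_ppm: float = 5.0,
    sample_meta: pd.DataFrame | None = None,
) -> FeatureTable:
    """Build the complete feature × sample table, filling missing entries.

    For every (feature, sample) pair without a detected member peak the
    intensity is recovered by summing raw-spectrum peaks within ``tol_ppm``
    of the representative m/z; truly absent signals become 0. The result has
    no missing entries.
    """
    if not consensus_features:
        raise ValueError("consensus feature list is empty")
    sample_ids = [sp.sample_id for sp in spectra]
    by_id = {sp.sample_id: sp for sp in spectra}
    mat = np.zeros((len(consensus_features), len(sample_ids)))
    reps = np.array([f.representative_mz for f in consensus_features])
    col_of = {sid: j for j, sid in enumerate(sample_ids)}
    detected = np.zeros_like(mat, dtype=bool)
    for i, f in enumerate(consensus_features):
        for sid, (_, inten) in f.members.items():
            j = col_of[sid]
            mat[i, j] = inten
            detected[i, j] = True
    tol = tol_ppm * 1e-6 * reps
    for j, sid in enumerate(sample_ids):
        sp = by_id[sid]
        lo = np.searchsorted(sp.mz, reps - tol, side="left")
        hi = np.searchsorted(sp.mz, reps + tol, side="right")
        cum = np.concatenate([[0.0], np.cumsum(sp.intensity)])
        filled = cum[hi] - cum[lo]
        mat[:, j] = np.where(detected[:, j], mat[:, j], filled)
    index = pd.Index([f.feature_id for f in consensus_features], name="feature_id")
    values = pd.DataFrame(mat, index=index, columns=sample_ids)
    feature_meta = pd.DataFrame({"mz": reps}, index=index)
    if sample_meta is None:
        sample_meta = pd.DataFrame(
            {"time_h": np.nan, "replicate": 1, "is_blank": False},
            index=pd.Index(sample_ids, name="sample_id"),
        )
    else:
        sample_meta = sample_meta.loc[sample_ids]
    return FeatureTable(values, feature_meta, sample_meta)


def default_max_isotope_ratio(mz: float) -> float:
    """Upper bound for a plausible I(M+1)/I(M) isotopologue ratio at m/z.

    An all-carbon molecule of mass m has at most m/12 carbons, giving a 13C
    M+1 ratio of (m/12) * 0.0107; a 1.5x safety factor keeps genuine
    isotopologues while rejecting coincidental neighbors.
    """
    return 1.5 * C13_ABUNDANCE * (mz / 12.0)


def collapse_isotopes(
    table: FeatureTable,
    delta: float = C13_DELTA,
    delta_tol: float = 0.005,
    max_ratio_fn=default_max_isotope_ratio,
    keep: str = "sum",
) -> FeatureTable:
    """Collapse +1.00335 Da isotopologue chains onto the monoisotopic feature.

    Chains are built greedily from the lowest m/z: feature B extends the chain
    ending at A if |mz_B - mz_A - delta| <= delta_tol and the median over
    samples of I_B/I_A lies in (0, max_ratio_fn(mz_A)]. Each chain is replaced
    by a single feature at the monoisotopic m/z whose per-sample intensity is
    the sum over chain members (``keep="sum"``, conserving total signal) or
    the monoisotopic member alone (``keep="mono"``). The number of collapsed
    members is recorded in the feature metadata.
    """
    if keep not in ("sum", "mono"):
        raise ValueError("keep must be 'sum' or 'mono'")
    mz = table.feature_meta["mz"].to_numpy(dtype=float)
    if np.any(np.diff(mz) < 0):
        raise ValueError("feature table must be m/z-sorted before isotope collapsing")
    vals = table.values.to_numpy(dtype=float)
    n = len(mz)
    chain_of = np.full(n, -1, dtype=int)  # index of chain head per feature

    def _plausible(t: int, i: int) -> bool:
        denom = vals[t]
        if not np.any(denom > 0):
            return False
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(denom > 0, vals[i] / denom, np.nan)
        med = float(np.nanmedian(ratio))
        return np.isfinite(med) and 0.0 < med <= max_ratio_fn(float(mz[t]))

    active: list[int] = []  # heads of chains that can still be extended
    tails: dict[int, int] = {}  # head -> current tail index
    for i in range(n):
        active = [h for h in active if mz[i] - mz[tails[h]] <= delta + delta_tol]
        best_head, best_err = -1, None
        for h in active:
            t = tails[h]
            err = abs(mz[i] - mz[t] - delta)
            if err <= delta_tol and _plausible(t, i):
                if best_err is None or err < best_err:
                    best_head, best_err = h, err
        if best_head >= 0:
            chain_of[i] = best_head
            tails[best_head] = i
        else:
            chain_of[i] = i
            tails[i] = i
            active.append(i)

    new_rows, new_mz, n_collapsed, kept_ids, member_ids = [], [], [], [], []
    for h in sorted(set(chain_of)):
        members = np.flatnonzero(chain_of == h)
        if keep == "sum":
            new_rows.append(vals[members].sum(axis=0))
        else:
            new_rows.append(vals[h])
        new_mz.append(mz[h])
        n_collapsed.append(len(members) - 1)
        kept_ids.append(table.values.index[h])
        member_ids.append(";".join(str(table.values.index[m]) for m in members))
    index = pd.Index(kept_ids, name="feature_id")
    values = pd.DataFrame(np.vstack(new_rows), index=index, columns=table.values.columns)
    feature_meta = table.feature_meta.loc[index].copy()
    feature_meta["mz"] = new_mz
    feature_meta["n_collapsed"] = n_collapsed
    feature_meta["member_ids"] = member_ids
    logger.info(
        "isotope collapsing: %d features -> %d (removed %d isotopologues)",
        n, len(index), n - len(index),
    )
    return FeatureTable(values, feature_meta, table.sample_meta.copy())


@dataclass
class Annotation:
    """Exact-mass annotation candidates for one feature."""

    feature_id: str
    candidates: list[tuple[str, str, float]]  # (compound_id, adduct, mass_error_mDa)


def annotate_features(
    table: FeatureTable,
    compound_db: list[CompoundRecord],
    polarity: str = "-",
    tol_mDa: float = 3.0,
    rt_tol: float | None = None,
    compound_rt: dict[str, float] | None = None,
) -> list[Annotation]:
    """Annotate features by exact mass against a compound database.

    Positive-mode features are matched as [M+H]+ ions, negative-mode as
    [M-H]- (proton mass 1.007276 Da); every compound within ``tol_mDa`` of a
    feature becomes a candidate, so features may carry zero, one or several
    annotations. When both the table and ``compound_rt`` provide retention
    times and ``rt_tol`` is set, candidates are additionally required to match
    in RT.
    """
    if not compound_db:
        raise ValueError("compound database is empty")
    adduct = "[M+H]+" if polarity == "+" else "[M-H]-"
    sign = 1.0 if polarity == "+" else -1.0
    cmass = np.array([c.monoisotopic_mass + sign * PROTON_MASS for c in compound_db])
    order = np.argsort(cmass)
    cmass = cmass[order]
    cids = [compound_db[i].compound_id for i in order]
    tol = tol_mDa / 1000.0
    has_rt = rt_tol is not None and compound_rt is not None and "rt" in table.feature_meta
    out = []
    for fid, fmz in table.feature_meta["mz"].items():
        lo = np.searchsorted(cmass, fmz - tol, side="left")
        hi = np.searchsorted(cmass, fmz + tol, side="right")
        cands = []
        for j in range(lo, hi):
            if has_rt:
                crt = compound_rt.get(cids[j])
                frt = table.feature_meta.loc[fid, "rt"]
                if crt is not None and np.isfinite(frt) and abs(frt - crt) > rt_tol:
                    continue
            cands.append((cids[j], adduct, float((fmz - cmass[j]) * 1000.0)))
        out.append(Annotation(str(fid), cands))
    return out


def process_fia_batch(
    spectra: list[Spectrum],
    reference_masses,
    *,
    top_n: int = 1000,
    tol_ppm: float = 5.0,
    match_tol: float = 0.01,
    delta_tol: float = 0.005,
    collapse: bool = True,
    sample_meta: pd.DataFrame | None = None,
) -> FeatureTable:
    """Run the full FIA chain on a batch of spectra.

    recalibrate -> normalize by tune mix -> top-N detection -> consensus list
    -> gap filling -> (optional) isotope collapsing. Returns the final
    feature table; per-stage counts are logged.
    """
    corrected = []
    for sp in spectra:
        model = fit_mass_recalibration(sp, reference_masses, match_tol)
        sp2 = apply_recalibration(sp, model)
        sp2 = normalize_by_reference(sp2, reference_masses, match_tol)
        corrected.append(sp2)
    peaklists = [detect_top_peaks(sp, top_n) for sp in corrected]
    consensus = build_consensus_features(peaklists, tol_ppm)
    logger.info("consensus features: %d", len(consensus))
    table = fill_gaps(corrected, consensus, tol_ppm, sample_meta)
    if collapse:
        table = collapse_isotopes(table, delta_tol=delta_tol)
    return table
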